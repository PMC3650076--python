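# Methods

## Problem and data model

The package benchmarks a safety-duplication collection (the Svalbard Global
Seed Vault) against global *ex-situ* crop holdings as described by three
kinds of registry data: genebank-level holdings summaries (WIEWS-like:
institution × genus counts), accession-level passport records (GENESYS-like:
MCPD descriptors INSTCODE/ACCENUMB/GENUS/SPECIES/ORIGCTY), and deposit logs
(depositor × genus sample counts). An institution registry ties the three
together: each institute has a country, a type (`national`, `subnational`,
`regional`, `international_IARC`, `other`) and flags for an ITPGRFA
Article 15 agreement, a signed Standard Deposit Agreement and depositor
status.

Country codes are ISO 3166-1 alpha-3 internally; alpha-2 input is translated
through a shipped table and anything unmappable becomes the `UNKNOWN`
sentinel with a logged warning. `UNKNOWN` is deliberately never equated with
the host country: the distinct-accession rule hinges on that distinction. A
blank `n_indigenous` cell in a holdings summary is preserved as *absent*,
not zero, because "no origin information" and "no indigenous material" lead
to different estimates. Delimiters are explicit (no sniffing) so a run is
fully determined by its configuration.

## Study-genus selection

The cascade has a fixed stage order — name cleanup/synonym merge, non-PGRFA
exclusion, accession threshold, vault-presence filter — and an audit that
records each removal with its stage, so the narrowing is fully
reconstructable from the output. Choices worth noting:

* The threshold is strictly greater than `min_accessions` (default 1000);
  a genus with exactly 1000 accessions is excluded. The boundary is tested.
* The vault-presence filter is a flag (`require_sgsv_presence`), not a
  biological rule: it is a proxy that treats the current vault contents as
  representative of what is commonly seed-banked, and an analysis may
  legitimately switch it off.
* Genus normalization is trim + title-case + synonym map, idempotent, and
  never consults an external taxonomic backbone (out of scope). The shipped
  synonym map only merges the triticale spellings; *Lycopersicon* is kept
  distinct from *Solanum* because the benchmark tables list both.
* Seed-storage behavior is classified per genus as the majority class over a
  species-level evidence table, with ties broken pessimistically
  (recalcitrant > intermediate > orthodox) so a genus is only treated as
  seed-bankable on positive evidence; no evidence yields `unknown`.

## Distinct-accession estimation

The FAO counting rule estimates distinct accessions of a genus as
(a) accessions at non-IARC institutes whose recorded origin equals the
institute's country, plus (b) all accessions at IARC institutes. Per
institute the accession-level path is preferred; the summary path
(`n_indigenous`, or `n_total` for IARCs) is used only where no passport
records exist, and a disagreement between the two is logged with the
accession path winning. Records with `UNKNOWN` origin never count as
indigenous under the default policy; `unknown_origin_policy` also offers
`indigenous` (upper-bound sensitivity) and `drop` (remove such records
before counting). "Regional" institutes count as national-style component
(a) holders: only IARCs hold in-trust collections in component (b).

The rule's bias structure is explicit: within-country duplicates and
IARC copies of nationally held material are overcounted, missing origin
data undercount, and cross-country duplicates are correctly skipped. The
synthetic-world generator (below) reproduces all four mechanisms.

## ITPGRFA coverage

Coverage of the Treaty's Multilateral System is the sum of two disjoint
components: Annex 1 matches at institutes in Contracting-Party countries
(excluding Article 15 institutes), and all holdings of Article 15
institutes. The per-institute attribution is returned with the counts so
the no-double-counting property is directly assertable.

Annex 1 matching is rule-based: a (genus, species) pair matches if some rule
lists the genus, the epithet passes an optional inclusion list (single-species
crops like cassava) and is not on the exclusion list (wild relatives like
*Zea perennis*). An empty epithet matches only unrestricted rules and is
never blocked by an exclusion (an exclusion names a specific taxon; an
unidentified record cannot be shown to be it). The shipped rule file is a
curated genus-level approximation: the authoritative species-level list used
in published analyses is not public, so the default set is chosen to
reproduce the benchmark table's "not in Annex 1" footnotes exactly (a test
enforces this) and carries the best-known species exceptions; it is plain
YAML and meant to be replaced by users with better lists. Because the
species exceptions need epithets, Treaty counts are computed from
accession-level records only; institutes known only through summaries
contribute nothing to Treaty coverage.

## Reporting conventions

Backup shares are integer percentages, rounded half away from zero — the
convention that reproduces the published percentage cells — and a zero
denominator renders as `na` rather than 0 or 100. Shares above 100% are
reported as-is (a depositor can have more samples in the vault than an
accession-level database records for it). Profile averages round to one
decimal. Top-N rankings sort by descending holdings with ties broken by
institute code; N defaults to 10. A nonzero deposit implies "under deposit
agreement" even without a registry flag (depositing requires a signed
agreement); the converse is not assumed. Group aggregation is exact column
summation with a grand-total row appended; note that group rows computed
from the packaged 40 printed genus rows match the published group totals
only for Cereals and Food Legumes, because the published totals for the
other groups include genera whose individual rows were never printed.

## Synthetic collection worlds

`generate_world` builds a registry of `n_countries` countries ×
`institutes_per_country` national genebanks plus `n_iarcs` IARCs, then, per
genus, creates `n_founders` founder accessions. Each founder gets an origin
country and a home institute there; four Bernoulli knobs then act per
founder: a cross-country duplicate (`p_cross_country_dup`), an IARC copy
(`p_iarc_dup`), a domestic duplicate (`p_within_country_dup`) and loss of
the recorded origin (`p_missing_origin`). Duplicates inherit the founder's
*recorded* origin. Holdings summaries are tallied from the generated
records, so the summary and accession paths are consistent by construction;
deposits are `round(f × holdings)` with a per-institute fraction `f` drawn
once from `backup_fraction_range` and stored in the ground truth.

Defaults (0.20 / 0.15 / 0.10 / 0.05, contracting-party probability 0.70,
backup fractions 0–0.8, 320 founders over four genera) describe a moderately
duplicated system in which every bias mechanism is visible against the
founder signal. They are milder than the real global system — there, only
roughly a quarter to a third of all records are thought to be distinct,
which would require multiple copies per founder rather than the single
Bernoulli duplicate per mechanism modelled here — and the generator makes no
attempt to mimic real genus abundance distributions beyond its configurable
catalog. Passing tests on these worlds therefore demonstrates that the
estimators implement their counting rules exactly and that the bias
directions are as argued, not that the magnitude of bias in real data is
known.

Sampling is structured for exact coupling: every founder consumes a
fixed-size block of draws regardless of outcomes, so two configurations
differing only in a probability knob share their underlying uniforms under
the same seed. `bias_experiment` exploits this by reusing the same replicate
seeds at every grid point, which makes the mean-bias curves exactly monotone
in the duplication knobs (increasing) and in the missing-origin knob
(decreasing), as the tests assert over 20 replicates. All sampling is
integer/uniform draws from numpy's seeded generator; no platform-dependent
float ordering enters record generation, so equal (config, seed) yields
byte-identical tables.

## Fixture reconstruction choices

The packaged fixtures store every printed cell of the two benchmark tables
with three documented judgment calls: the garbled sweet-potato vault cell is
stored as 1,936 (the only value consistent with its printed group total);
the recalcitrant/intermediate exclusion list is stored as the 24 printed
names although the accompanying text says 23; and the full 156-genus
retained list, published only as supplementary spreadsheet material, is
reconstructed with 46 attested genera plus 110 plausible crop genera marked
`attested = 0` — a synthetic stand-in that preserves the printed list sizes
(206 = 156 + 26 + 24), which is the quantity the selection cascade is
benchmarked on. The top-ten-holder world reproduces the printed bracket
percentages exactly (holdings are multiples of 100, so integer brackets are
exact); where a printed backed-up count exceeds the row's nonzero brackets,
the gap is seated as single-sample deposits that round to a 0% bracket, and
signed-agreement flags are added to zero-deposit holders up to the printed
under-agreement count. Rows where brackets alone reproduce the printed count
carry `consistent = True`; the acceptance checks use those rows (barley,
wheat, rice).

## Problem sizes and limitations

The test and acceptance workloads are desk-scale by design: random-world
property suites use ≤ 320 records per world (100 worlds), bias sweeps use
20 replicates of 320 founders, and the published-table checks are pure
arithmetic on the fixtures. The global headline figures that require the
actual multi-million-record database downloads (7.2 M holdings, 2.19 M
distinct, 774,601 vault samples) are inputs recorded in the fixtures, not
quantities this package can recompute. Other known limitations: no
passport-similarity deduplication (the distinct rule is a counting
convention, not record linkage); no live connectors to the registry
databases; no authoritative taxonomic name resolution.
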