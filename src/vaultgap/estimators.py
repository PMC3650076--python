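"""Distinct-accession estimation and ITPGRFA coverage counting.

Two counting rules sit at the core of the gap analysis:

**Distinct accessions** (FAO State-of-the-World method). Most genebank
records worldwide are duplicates of material held elsewhere, so raw accession
totals wildly overstate conserved diversity. The FAO counting rule estimates
the distinct fraction as the sum of

(a) accessions in national (and other non-IARC) collections whose recorded
    country of origin equals the country of the holding genebank — the
    *indigenous* holdings, which are taken to be original material; and
(b) all accessions of the international in-trust collections held by the
    International Agricultural Research Centers (IARCs), regardless of
    origin.

The rule overcounts when material is duplicated within a country or between a
national bank and an IARC, and undercounts when origin data are missing —
:mod:`vaultgap.synthetic` quantifies both directions.

**ITPGRFA coverage**. The International Treaty's Multilateral System covers
(1) accessions of Annex 1 crops (with its species-level inclusion/exclusion
exceptions) held by institutions in Contracting-Party countries, plus
(2) everything in the IARC collections placed under the Treaty by Article 15
agreements. Article 15 institutes are excluded from component (1) so that no
accession is counted twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .model import UNKNOWN, WorldCollections

logger = logging.getLogger(__name__)

UNKNOWN_ORIGIN_POLICIES = ("non_indigenous", "indigenous", "drop")


@dataclass(frozen=True)
class Annex1Rule:
    """One Annex 1 crop entry: covered genera with optional species limits.

    ``included_species`` restricts a crop to listed epithets (e.g. cassava is
    only *Manihot esculenta*); ``excluded_species`` carves out listed epithets
    (e.g. the wild *Zea* taxa).
    """

    crop_label: str
    genera: tuple[str, ...]
    included_species: Optional[tuple[str, ...]] = None
    excluded_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.genera:
            raise ValueError(f"rule {self.crop_label!r} lists no genera")
        if self.included_species is not None:
            overlap = set(self.included_species) & set(self.excluded_species)
            if overlap:
                raise ValueError(
                    f"rule {self.crop_label!r}: species both included and "
                    f"excluded: {sorted(overlap)}"
                )


@dataclass(frozen=True)
class TreatyContext:
    """Treaty membership and Article 15 collections used by the coverage rule."""

    contracting_parties: frozenset[str]
    article15_institutes: frozenset[str]
    rules: tuple[Annex1Rule, ...]


@dataclass(frozen=True)
class DistinctEstimate:
    """Per-genus output of the FAO distinct-accession rule."""

    genus: str
    n_indigenous_national: int
    n_iarc: int

    @property
    def n_distinct(self) -> int:
        return self.n_indigenous_national + self.n_iarc


@dataclass(frozen=True)
class TreatyCoverage:
    """Per-genus output of the two-component Treaty coverage rule.

    ``attribution`` maps each contributing institute to the single component
    it was counted under ("annex1_cp" or "article15").
    """

    genus: str
    n_annex1_in_cp: int
    n_article15: int
    attribution: Mapping[str, str] = field(default_factory=dict)

    @property
    def n_covered(self) -> int:
        return self.n_annex1_in_cp + self.n_article15


def load_annex1_rules(path: str | Path | None = None) -> tuple[Annex1Rule, ...]:
    """Load Annex 1 rules from YAML; defaults to the packaged curated set."""
    if path is None:
        text = resources.files("vaultgap.data").joinpath("annex1_rules.yaml").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    entries = yaml.safe_load(text) or []
    rules = []
    for entry in entries:
        inc = entry.get("included_species")
        rules.append(
            Annex1Rule(
                crop_label=entry["crop"],
                genera=tuple(entry["genera"]),
                included_species=None if inc is None else tuple(inc),
                excluded_species=tuple(entry.get("excluded_species", ())),
            )
        )
    return tuple(rules)


def match_annex1(
    genus: str, species_epithet: str, rules: Sequence[Annex1Rule]
) -> bool:
    """True iff (genus, species) falls under some Annex 1 rule.

    An empty epithet matches only rules without an ``included_species``
    restriction, and is never blocked by ``excluded_species`` (an exclusion
    names a specific taxon; an unidentified one cannot be that taxon).
    """
    epithet = species_epithet.strip()
    for rule in rules:
        if genus not in rule.genera:
            continue
        if rule.included_species is not None:
            if not epithet or epithet not in rule.included_species:
                continue
        if epithet and epithet in rule.excluded_species:
            continue
        return True
    return False


def estimate_distinct(
    world: WorldCollections,
    genus: str,
    unknown_origin_policy: str = "non_indigenous",
) -> DistinctEstimate:
    """Apply the FAO distinct-accession counting rule to one genus.

    Per institute the accession-level path is preferred; the genebank-level
    summary path (``n_indigenous`` for component (a), ``n_total`` for IARC
    component (b)) is used only for institutes without accession records of
    the genus. When both are available the summary is cross-checked against
    the accession-level count and a disagreement is logged.

    ``unknown_origin_policy`` controls records with UNKNOWN origin:
    ``non_indigenous`` (default — they never count as indigenous),
    ``indigenous`` (they count as indigenous at non-IARC institutes), or
    ``drop`` (they are removed before either component is counted).
    """
    if unknown_origin_policy not in UNKNOWN_ORIGIN_POLICIES:
        raise ValueError(f"unknown_origin_policy must be one of {UNKNOWN_ORIGIN_POLICIES}")

    acc = world.accessions_frame()
    acc = acc[acc["genus"] == genus]
    if unknown_origin_policy == "drop":
        acc = acc[acc["origin_country"] != UNKNOWN]

    registry = world.registry_map
    n_indig = 0
    n_iarc = 0
    acc_counts: dict[str, tuple[int, int]] = {}  # code -> (total, indigenous)
    if not acc.empty:
        for code, sub in acc.groupby("institute_code"):
            inst = registry[code]
            if inst.inst_type == "international_IARC":
                n_iarc += len(sub)
                acc_counts[code] = (len(sub), 0)
            else:
                indigenous = (sub["origin_country"] == inst.country).sum()
                if unknown_origin_policy == "indigenous":
                    indigenous += (sub["origin_country"] == UNKNOWN).sum()
                n_indig += int(indigenous)
                acc_counts[code] = (len(sub), int(indigenous))

    has_accessions = set(acc_counts)
    seen_any = bool(acc_counts)
    for h in world.holdings:
        if h.genus != genus:
            continue
        seen_any = True
        inst = registry[h.institute_code]
        if h.institute_code in has_accessions:
            total, indigenous = acc_counts[h.institute_code]
            expected = total if inst.inst_type == "international_IARC" else indigenous
            reported = h.n_total if inst.inst_type == "international_IARC" else h.n_indigenous
            if reported is not None and reported != expected:
                logger.warning(
                    "summary for %s/%s disagrees with accession-level count "
                    "(%s vs %s); accession path wins",
                    h.institute_code, genus, reported, expected,
                )
            continue
        if inst.inst_type == "international_IARC":
            n_iarc += h.n_total
        elif h.n_indigenous is not None:
            n_indig += h.n_indigenous

    if not seen_any:
        logger.info("genus %s absent from world; zero-count estimate", genus)
    return DistinctEstimate(genus=genus, n_indigenous_national=n_indig, n_iarc=n_iarc)


def treaty_coverage(
    world: WorldCollections, genus: str, ctx: TreatyContext
) -> TreatyCoverage:
    """Count accessions of one genus covered by the Treaty's two components.

    Component 1 counts accession-level records matching the Annex 1 rules
    (species exceptions applied) at institutes located in Contracting-Party
    countries, excluding Article 15 institutes. Component 2 counts all
    accessions at Article 15 institutes with no species filter. Each
    institute contributes to at most one component, so nothing is counted
    twice. Institutes with only genebank-level summaries contribute nothing:
    the species-level exceptions require accession-level records.
    """
    registry = world.registry_map
    for code in ctx.article15_institutes:
        if code not in registry:
            raise KeyError(f"Article 15 institute {code!r} not in registry")

    acc = world.accessions_frame()
    acc = acc[acc["genus"] == genus]
    n_annex1 = 0
    n_art15 = 0
    attribution: dict[str, str] = {}
    if not acc.empty:
        for code, sub in acc.groupby("institute_code"):
            inst = registry[code]
            if code in ctx.article15_institutes:
                n_art15 += len(sub)
                attribution[code] = "article15"
                continue
            if inst.country not in ctx.contracting_parties:
                continue
            matched = sum(
                match_annex1(genus, sp, ctx.rules)
                for sp in sub["species_epithet"]
            )
            if matched:
                n_annex1 += int(matched)
                attribution[code] = "annex1_cp"
    return TreatyCoverage(
        genus=genus,
        n_annex1_in_cp=n_annex1,
        n_article15=n_art15,
        attribution=attribution,
    )
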