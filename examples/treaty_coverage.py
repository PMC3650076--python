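"""ITPGRFA Multilateral-System coverage with Annex 1 species exceptions.

Counts maize accessions covered by the Treaty in a small world: Annex 1
material at institutes in Contracting-Party countries (the wild relative
*Zea perennis* is excluded by the Annex 1 rules, and non-party holdings do
not count), plus everything in Article 15 in-trust collections — where the
species filter does not apply and nothing is counted twice.
"""

from vaultgap.estimators import TreatyContext, load_annex1_rules, treaty_coverage
from vaultgap.model import AccessionRecord, InstitutionRecord, assemble_world

registry = [
    InstitutionRecord("MEX001", "MEX", "national"),      # Contracting Party
    InstitutionRecord("USA001", "USA", "national"),      # not a Party here
    InstitutionRecord("CIMMYT", "MEX", "international_IARC", article15=True),
]
accessions = (
    [AccessionRecord("MEX001", f"m{i}", "Zea", "mays", "MEX") for i in range(4)]
    + [AccessionRecord("MEX001", "w0", "Zea", "perennis", "MEX")]
    + [AccessionRecord("USA001", f"u{i}", "Zea", "mays", "USA") for i in range(3)]
    + [AccessionRecord("CIMMYT", f"c{i}", "Zea", "perennis", "MEX") for i in range(2)]
)
world, _ = assemble_world(accessions, [], registry, [])

ctx = TreatyContext(
    contracting_parties=frozenset({"MEX"}),
    article15_institutes=frozenset({"CIMMYT"}),
    rules=load_annex1_rules(),
)
cov = treaty_coverage(world, "Zea", ctx)
print(f"Annex 1 in Contracting Parties: {cov.n_annex1_in_cp}")
print(f"Article 15 in-trust holdings:   {cov.n_article15}")
print(f"covered by the Treaty:          {cov.n_covered} of {len(accessions)} records")
print(f"per-institute attribution:      {dict(cov.attribution)}")
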