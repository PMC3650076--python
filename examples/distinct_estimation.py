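"""The FAO distinct-accession counting rule on a five-line toy world.

A Norwegian national genebank holds 3 barley accessions of Norwegian origin
(indigenous -> assumed distinct) and 2 of Ethiopian origin (assumed to be
duplicates of material conserved in Ethiopia); an international center (IARC)
holds 5 (in-trust collections count in full). The rule yields 3 + 5 = 8
distinct accessions out of 10 records.
"""

from vaultgap.estimators import estimate_distinct
from vaultgap.model import AccessionRecord, InstitutionRecord, assemble_world

registry = [
    InstitutionRecord("NOR001", "NOR", "national"),
    InstitutionRecord("IRRI", "PHL", "international_IARC", article15=True),
]
accessions = (
    [AccessionRecord("NOR001", f"N{i}", "Hordeum", "vulgare", "NOR") for i in range(3)]
    + [AccessionRecord("NOR001", f"E{i}", "Hordeum", "vulgare", "ETH") for i in range(2)]
    + [AccessionRecord("IRRI", f"I{i}", "Hordeum", "vulgare", "ETH") for i in range(5)]
)
world, _ = assemble_world(accessions, [], registry, [])

est = estimate_distinct(world, "Hordeum")
print(f"records in world:        {len(world.accessions)}")
print(f"indigenous at national:  {est.n_indigenous_national}")
print(f"held in trust by IARCs:  {est.n_iarc}")
print(f"estimated distinct:      {est.n_distinct}")
print("\nThe 2 foreign-origin accessions at the national bank are treated as")
print("duplicates of material conserved in their origin country.")
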