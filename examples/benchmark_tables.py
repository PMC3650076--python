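"""Crop-group aggregation and backup shares on the published benchmark rows.

Loads the packaged per-genus benchmark fixture (40 genera across six crop
groups and five database framings), sums it into group rows, and computes
the share of estimated distinct accessions already backed up in the Seed
Vault for the four largest cereals.
"""

from vaultgap.coverage import aggregate_groups, backup_share, rows_to_frame
from vaultgap.fixtures import fixture_table1

rows = fixture_table1()
groups = aggregate_groups(rows)
print(rows_to_frame(groups).to_string(index=False))

print("\nVault backup share of estimated distinct accessions:")
for genus in ("Triticum", "Sorghum", "Oryza", "Zea"):
    row = next(r for r in rows if r.genus == genus)
    share = backup_share(row.sgsv, row.distinct)
    print(f"  {genus:10s} {row.sgsv:>9,} / {row.distinct:>9,}  = {share}%")
print("\nShares above 50% mean more than half the estimated distinct")
print("holdings of that genus already have a safety duplicate in the vault.")
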