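"""Institutional backup profiles: the ten largest collections per food crop.

Rebuilds the published top-ten-holder table as a world of institutions with
holdings and deposits, profiles each of the 29 food-crop genera, and prints
how many of the ten largest collections are backed up in the vault and how
many are at least covered by a signed deposit agreement.
"""

from vaultgap.coverage import format_share, profile_genus, summarize_profiles
from vaultgap.fixtures import fixture_table2, table2_world

world = table2_world()
profiles = [profile_genus(world, row.genus) for row in fixture_table2()]

barley = next(p for p in profiles if p.genus == "Hordeum")
print("Hordeum (barley), ten largest collections:")
for e in barley.entries:
    print(f"  {e.institute_code:10s} {e.country}  holdings={e.holdings_count:>6,}"
          f"  backed_up={format_share(e.backup_share_pct):>3s}%")
print(f"  -> {barley.n_in_sgsv} in the vault, {barley.n_under_sda} under agreement")

avg_sgsv, avg_sda = summarize_profiles(profiles)
print(f"\nacross all 29 genera: on average {avg_sgsv} of the ten largest")
print(f"collections are backed up and {avg_sda} are covered by an agreement")
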