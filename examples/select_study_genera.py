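"""Study-genus selection: narrow 206 candidate genera down to 156.

Runs the four-stage cascade (name cleanup, non-PGRFA filter, >1000-accession
threshold, Seed-Vault-presence filter) on the packaged scenario encoding the
published genus lists. The final count, 156, is the number of crop genera
the gap analysis benchmarks.
"""

from vaultgap.fixtures import selection_fixture
from vaultgap.taxonomy import select_study_genera

holdings, deposits = selection_fixture()
retained, audit = select_study_genera(holdings, deposits)

print(audit.to_frame().to_string(index=False, max_colwidth=40))
print(f"\nretained study genera: {len(retained)}")
print("(each removed genus is recorded with the stage that removed it)")
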