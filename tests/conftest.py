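"""Shared fixtures and independent brute-force oracles.

The oracles re-derive the two counting rules with plain record-by-record
loops, independently of the pandas-based implementations they check.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from vaultgap.estimators import TreatyContext, match_annex1
from vaultgap.model import (
    UNKNOWN,
    AccessionRecord,
    DepositRecord,
    HoldingsRecord,
    InstitutionRecord,
    WorldCollections,
    assemble_world,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def oracle_distinct(
    world: WorldCollections, genus: str, policy: str = "non_indigenous"
) -> int:
    """Brute-force FAO distinct count: two clauses, checked record by record."""
    registry = {r.institute_code: r for r in world.registry}
    records = [a for a in world.accessions if a.genus == genus]
    if policy == "drop":
        records = [a for a in records if a.origin_country != UNKNOWN]
    count = 0
    institutes_with_records = {a.institute_code for a in records}
    for a in records:
        inst = registry[a.institute_code]
        if inst.inst_type == "international_IARC":
            count += 1
        elif a.origin_country == inst.country:
            count += 1
        elif policy == "indigenous" and a.origin_country == UNKNOWN:
            count += 1
    for h in world.holdings:
        if h.genus != genus or h.institute_code in institutes_with_records:
            continue
        inst = registry[h.institute_code]
        if inst.inst_type == "international_IARC":
            count += h.n_total
        elif h.n_indigenous is not None:
            count += h.n_indigenous
    return count


def oracle_treaty(world: WorldCollections, genus: str, ctx: TreatyContext) -> int:
    """Brute-force Treaty count: Annex 1 in Contracting Parties + Article 15."""
    registry = {r.institute_code: r for r in world.registry}
    count = 0
    for a in world.accessions:
        if a.genus != genus:
            continue
        if a.institute_code in ctx.article15_institutes:
            count += 1
            continue
        inst = registry[a.institute_code]
        if inst.country in ctx.contracting_parties and match_annex1(
            genus, a.species_epithet, ctx.rules
        ):
            count += 1
    return count


@pytest.fixture
def toy_world() -> WorldCollections:
    """One national bank (NOR), one IARC; a mix of origins for two genera."""
    registry = [
        InstitutionRecord("NOR001", "NOR", "national"),
        InstitutionRecord("IARC01", "PHL", "international_IARC", article15=True),
    ]
    accessions = (
        [AccessionRecord("NOR001", f"N{i}", "Hordeum", "vulgare", "NOR") for i in range(3)]
        + [AccessionRecord("NOR001", f"E{i}", "Hordeum", "vulgare", "ETH") for i in range(2)]
        + [AccessionRecord("IARC01", f"I{i}", "Hordeum", "vulgare", "ETH") for i in range(5)]
        + [AccessionRecord("NOR001", "U0", "Avena", "sativa", UNKNOWN)]
    )
    world, _ = assemble_world(accessions, [], registry, [])
    return world
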