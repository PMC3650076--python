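"""Genus normalization, seed-storage classification and study-genus selection.

The selection cascade reproduces how a global gap analysis narrows the full
genus list reported by the genebank registries down to the set it can
meaningfully benchmark against a seed vault:

1. name cleanup — trim/title-case raw genus strings and merge synonyms;
2. drop a configured list of non-PGRFA genera (model organisms, forestry and
   ornamental genera that are not plant genetic resources for food and
   agriculture);
3. keep genera whose global holdings exceed a minimum accession count
   (strictly more than 1000 by default);
4. optionally keep only genera already present in the Seed Vault deposit
   records, a study-specific proxy for "commonly stored ex situ as orthodox
   seed".

Every removal is recorded, with its stage, in a :class:`SelectionAudit`.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import DepositRecord, HoldingsRecord

SEED_BEHAVIORS = ("orthodox", "intermediate", "recalcitrant", "unknown")

#: Ties in seed-behavior evidence break toward the less storable class, so a
#: genus is only treated as seed-bankable on positive evidence.
_BEHAVIOR_PESSIMISM = {"recalcitrant": 0, "intermediate": 1, "orthodox": 2}


@dataclass(frozen=True)
class GenusProfile:
    """Canonical genus plus its crop group, seed behavior and PGRFA status."""

    canonical: str
    crop_group: str = "Other"
    seed_behavior: str = "unknown"
    is_pgrfa: bool = True


@dataclass(frozen=True)
class SelectionParams:
    """Knobs of the study-genus selection cascade."""

    min_accessions: int = 1000  # strict 'greater than'
    non_pgrfa_exclusions: tuple[str, ...] = ()
    require_sgsv_presence: bool = True

    def __post_init__(self) -> None:
        if self.min_accessions < 0:
            raise ValueError("min_accessions must be >= 0")


@dataclass
class SelectionAudit:
    """Stage-by-stage account of the selection cascade."""

    n_raw: int = 0
    n_after_name_cleanup: int = 0
    n_after_pgrfa_filter: int = 0
    n_after_threshold: int = 0
    n_after_sgsv_filter: int = 0
    removed: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("raw", self.n_raw, ""),
            ("name_cleanup", self.n_after_name_cleanup,
             ";".join(self.removed.get("name_cleanup", []))),
            ("pgrfa_filter", self.n_after_pgrfa_filter,
             ";".join(self.removed.get("pgrfa_filter", []))),
            ("threshold", self.n_after_threshold,
             ";".join(self.removed.get("threshold", []))),
            ("sgsv_filter", self.n_after_sgsv_filter,
             ";".join(self.removed.get("sgsv_filter", []))),
        ]
        return pd.DataFrame(rows, columns=["stage", "n_retained", "removed"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_synonym_map() -> dict[str, str]:
    """Synonym map shipped with the package (raw name -> canonical genus)."""
    with resources.files("vaultgap.data").joinpath("synonyms.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return {row["raw"]: row["canonical"] for row in csv.DictReader(fh)}


def default_crop_group_scheme() -> dict[str, str]:
    """Genus -> crop-group mapping for the benchmark genera."""
    with resources.files("vaultgap.data").joinpath("table1.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        return {
            row["genus"]: row["crop_group"]
            for row in csv.DictReader(fh, delimiter="\t")
        }


def default_non_pgrfa() -> tuple[str, ...]:
    text = resources.files("vaultgap.data").joinpath("non_pgrfa.txt").read_text()
    return tuple(line.strip() for line in text.splitlines() if line.strip())


def normalize_genus(raw: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Trim, title-case and synonym-map a raw genus string.

    Unknown names pass through unchanged (after cleanup); the function is
    idempotent and deterministic.
    """
    if not raw or not raw.strip():
        raise ValueError("genus string must be non-empty")
    name = raw.strip().title()
    if synonym_map:
        # Synonyms may be recorded under raw or cleaned spellings.
        name = synonym_map.get(raw.strip(), synonym_map.get(name, name))
    return name


def classify_seed_behavior(
    genus: str, species_behavior_table: pd.DataFrame
) -> str:
    """Majority seed-storage behavior over a genus's species entries.

    The table needs columns ``genus``, ``species`` and ``behavior``. Ties
    break toward the less storable class (recalcitrant over intermediate over
    orthodox); a genus without evidence is ``unknown``.
    """
    sub = species_behavior_table[species_behavior_table["genus"] == genus]
    if sub.empty:
        return "unknown"
    counts = sub["behavior"].value_counts()
    best = max(
        counts.items(),
        key=lambda kv: (kv[1], -_BEHAVIOR_PESSIMISM.get(kv[0], 3)),
    )
    return best[0]


def assign_crop_group(genus: str, scheme: Mapping[str, str] | None = None) -> str:
    """Crop-group label for a canonical genus; ``Other`` when unmapped."""
    if scheme is None:
        scheme = default_crop_group_scheme()
    return scheme.get(genus, "Other")


def select_study_genera(
    holdings: Iterable[HoldingsRecord],
    deposits: Iterable[DepositRecord],
    params: SelectionParams | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> tuple[set[str], SelectionAudit]:
    """Run the four-stage selection cascade; return retained genera + audit.

    Holdings are aggregated to canonical-genus totals before the threshold is
    applied. Stage order is fixed: name cleanup -> non-PGRFA filter ->
    accession threshold (strict ``>``) -> Seed-Vault-presence filter.
    """
    params = params or SelectionParams(non_pgrfa_exclusions=default_non_pgrfa())
    if synonym_map is None:
        synonym_map = default_synonym_map()

    holdings = list(holdings)
    raw_names = {h.genus for h in holdings}
    audit = SelectionAudit(n_raw=len(raw_names))

    # stage 1: cleanup/synonyms. For each canonical group keep one raw
    # representative (the spelling equal to its canonical form if present)
    # so the audit's removal count equals the drop in set size.
    groups: dict[str, list[str]] = defaultdict(list)
    for name in sorted(raw_names):
        groups[normalize_genus(name, synonym_map)].append(name)
    removed_cleanup: list[str] = []
    for canon, members in groups.items():
        keep = canon if canon in members else members[0]
        removed_cleanup.extend(m for m in members if m != keep)
    canonical = set(groups)
    audit.n_after_name_cleanup = len(canonical)
    audit.removed["name_cleanup"] = sorted(removed_cleanup)

    # stage 2: non-PGRFA exclusions
    exclusions = {normalize_genus(g, synonym_map) for g in params.non_pgrfa_exclusions}
    removed_pgrfa = sorted(canonical & exclusions)
    after_pgrfa = canonical - exclusions
    audit.n_after_pgrfa_filter = len(after_pgrfa)
    audit.removed["pgrfa_filter"] = removed_pgrfa

    # stage 3: strict accession threshold on canonical-genus totals
    totals: dict[str, int] = defaultdict(int)
    for h in holdings:
        totals[normalize_genus(h.genus, synonym_map)] += h.n_total
    after_threshold = {g for g in after_pgrfa if totals[g] > params.min_accessions}
    audit.n_after_threshold = len(after_threshold)
    audit.removed["threshold"] = sorted(after_pgrfa - after_threshold)

    # stage 4: Seed-Vault-presence proxy
    if params.require_sgsv_presence:
        in_vault = {
            normalize_genus(d.genus, synonym_map)
            for d in deposits
            if d.n_deposited > 0
        }
        retained = after_threshold & in_vault
    else:
        retained = set(after_threshold)
    audit.n_after_sgsv_filter = len(retained)
    audit.removed["sgsv_filter"] = sorted(after_threshold - retained)

    return retained, audit
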