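"""Benchmark tables, backup-share percentages and institutional profiles.

This module assembles the reporting layer: per-genus benchmark rows across
the three database framings (genebank-level totals, accession-level totals,
distinct estimate, Treaty coverage, Seed Vault deposits), crop-group
aggregates, and top-N institutional profiles showing how much of each large
collection is already backed up.

Percentages are rounded half-away-from-zero to integers and summary averages
to one decimal, matching the conventions of published genebank statistics.
Shares above 100% are reported as-is: a depositor may have sent more samples
than the accession-level database currently records for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .estimators import DistinctEstimate, TreatyCoverage
from .model import HoldingsRecord, WorldCollections
from .taxonomy import assign_crop_group

#: Presentation order of crop groups in benchmark tables.
GROUP_ORDER = (
    "Cereals",
    "Food Legumes",
    "Forage Crops",
    "Roots and Tubers",
    "Vegetables",
    "Oil Crops",
    "Fiber Crops",
    "Sugar Crops",
    "Other",
)


@dataclass(frozen=True)
class CoverageRow:
    """Per-genus benchmark counts across the database framings."""

    genus: str
    crop_group: str
    wiews_total: int
    genesys_total: int
    distinct: int
    treaty: int
    sgsv: int


@dataclass(frozen=True)
class ReportingOptions:
    top_n: int = 10

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass(frozen=True)
class TopHolderEntry:
    """One of the N largest collections of a genus and its backup status."""

    institute_code: str
    country: str
    holdings_count: int
    deposited_count: int
    backup_share_pct: Optional[int]

    @property
    def in_sgsv(self) -> bool:
        return self.deposited_count > 0

    # A nonzero deposit implies a signed deposit agreement even when the
    # registry flag is absent; the flag is carried separately by the profile.


@dataclass
class GenusProfileSummary:
    """Ranked top-N holders of a genus with backup summary counts."""

    genus: str
    entries: list[TopHolderEntry]
    n_in_sgsv: int
    n_under_sda: int


def _round_half_away(value: Decimal, exponent: str) -> Decimal:
    return value.quantize(Decimal(exponent), rounding=ROUND_HALF_UP)


def backup_share(
    numerator: int, denominator: int, opts: ReportingOptions | None = None
) -> Optional[int]:
    """Integer percent ``round(100*numerator/denominator)``, half away from zero.

    A zero denominator yields ``None`` (rendered ``na``); values above 100
    are permitted.
    """
    if denominator < 0:
        raise ValueError("denominator must be >= 0")
    if denominator == 0:
        return None
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return int(_round_half_away(pct, "1"))


def format_share(share: Optional[int]) -> str:
    return "na" if share is None else str(share)


def build_coverage_rows(
    world: WorldCollections,
    genus_set: Iterable[str],
    distinct_estimates: Mapping[str, DistinctEstimate],
    treaty_coverages: Mapping[str, TreatyCoverage],
    genesys_world: WorldCollections | None = None,
    scheme: Mapping[str, str] | None = None,
) -> list[CoverageRow]:
    """One benchmark row per genus, ordered by group then descending size.

    ``world`` supplies the genebank-level totals (holdings) and the deposit
    records; ``genesys_world`` supplies the accession-level totals and
    defaults to ``world`` itself when the two framings share one source.
    """
    genesys_world = genesys_world or world
    holdings = world.holdings_frame()
    deposits = world.deposits_frame()
    genesys = genesys_world.accessions_frame()

    rows = []
    for genus in genus_set:
        wiews_total = int(holdings.loc[holdings["genus"] == genus, "n_total"].sum())
        genesys_total = int((genesys["genus"] == genus).sum())
        sgsv = int(deposits.loc[deposits["genus"] == genus, "n_deposited"].sum())
        est = distinct_estimates.get(genus)
        cov = treaty_coverages.get(genus)
        rows.append(
            CoverageRow(
                genus=genus,
                crop_group=assign_crop_group(genus, scheme),
                wiews_total=wiews_total,
                genesys_total=genesys_total,
                distinct=est.n_distinct if est else 0,
                treaty=cov.n_covered if cov else 0,
                sgsv=sgsv,
            )
        )

    order = {g: i for i, g in enumerate(GROUP_ORDER)}
    rows.sort(
        key=lambda r: (
            order.get(r.crop_group, len(GROUP_ORDER)),
            r.crop_group,
            -r.wiews_total,
            r.genus,
        )
    )
    return rows


def aggregate_groups(
    rows: Sequence[CoverageRow], scheme: Mapping[str, str] | None = None
) -> list[CoverageRow]:
    """Exact column sums per crop group, with a grand-total row appended.

    Rows already carry their group label; ``scheme`` can override it.
    """
    groups: dict[str, list[CoverageRow]] = {}
    for row in rows:
        group = scheme.get(row.genus, row.crop_group) if scheme else row.crop_group
        groups.setdefault(group, []).append(row)

    order = {g: i for i, g in enumerate(GROUP_ORDER)}
    out = []
    for group in sorted(groups, key=lambda g: (order.get(g, len(GROUP_ORDER)), g)):
        members = groups[group]
        out.append(
            CoverageRow(
                genus=group,
                crop_group=group,
                wiews_total=sum(r.wiews_total for r in members),
                genesys_total=sum(r.genesys_total for r in members),
                distinct=sum(r.distinct for r in members),
                treaty=sum(r.treaty for r in members),
                sgsv=sum(r.sgsv for r in members),
            )
        )
    out.append(
        CoverageRow(
            genus="Total",
            crop_group="All",
            wiews_total=sum(r.wiews_total for r in rows),
            genesys_total=sum(r.genesys_total for r in rows),
            distinct=sum(r.distinct for r in rows),
            treaty=sum(r.treaty for r in rows),
            sgsv=sum(r.sgsv for r in rows),
        )
    )
    return out


def rows_to_frame(rows: Sequence[CoverageRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.genus, r.crop_group, r.wiews_total, r.genesys_total, r.distinct,
             r.treaty, r.sgsv)
            for r in rows
        ],
        columns=["genus", "crop_group", "wiews_total", "genesys_total",
                 "distinct", "treaty", "sgsv"],
    )


def rank_holders(
    holdings: Iterable[HoldingsRecord],
    genus: str,
    opts: ReportingOptions | None = None,
) -> list[tuple[str, int]]:
    """The N largest holders of a genus: descending count, ties by code."""
    opts = opts or ReportingOptions()
    totals: dict[str, int] = {}
    for h in holdings:
        if h.genus == genus:
            totals[h.institute_code] = totals.get(h.institute_code, 0) + h.n_total
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[: opts.top_n]


def profile_genus(
    world: WorldCollections, genus: str, opts: ReportingOptions | None = None
) -> GenusProfileSummary:
    """Backup profile of the N largest collections of one genus.

    ``n_in_sgsv`` counts entries with a nonzero deposit; ``n_under_sda``
    counts entries whose institute either has a signed deposit agreement on
    record or has actually deposited (a deposit implies an agreement — the
    converse is not assumed).
    """
    opts = opts or ReportingOptions()
    deposits = {(d.depositor_code, d.genus): d.n_deposited for d in world.deposits}
    registry = world.registry_map

    entries = []
    for code, count in rank_holders(world.holdings, genus, opts):
        inst = registry[code]
        deposited = deposits.get((code, genus), 0)
        entries.append(
            TopHolderEntry(
                institute_code=code,
                country=inst.country,
                holdings_count=count,
                deposited_count=deposited,
                backup_share_pct=backup_share(deposited, count),
            )
        )
    n_in_sgsv = sum(1 for e in entries if e.deposited_count > 0)
    n_under_sda = sum(
        1
        for e in entries
        if e.deposited_count > 0 or registry[e.institute_code].sda_signed
    )
    return GenusProfileSummary(
        genus=genus, entries=entries, n_in_sgsv=n_in_sgsv, n_under_sda=n_under_sda
    )


def summarize_profiles(
    summaries: Sequence[GenusProfileSummary] | Sequence[tuple[int, int]],
    opts: ReportingOptions | None = None,
) -> tuple[float, float]:
    """Mean (backed-up, under-agreement) counts over genera, to one decimal.

    Accepts either :class:`GenusProfileSummary` objects or bare
    ``(n_in_sgsv, n_under_sda)`` pairs.
    """
    if not summaries:
        raise ValueError("cannot summarize an empty profile list")
    pairs = [
        (s.n_in_sgsv, s.n_under_sda) if isinstance(s, GenusProfileSummary) else s
        for s in summaries
    ]
    n = len(pairs)
    avg_sgsv = Decimal(sum(p[0] for p in pairs)) / n
    avg_sda = Decimal(sum(p[1] for p in pairs)) / n
    return (
        float(_round_half_away(avg_sgsv, "0.1")),
        float(_round_half_away(avg_sda, "0.1")),
    )


def profiles_to_frame(summaries: Sequence[GenusProfileSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        holders = ", ".join(
            f"{e.institute_code}:{e.country} ({format_share(e.backup_share_pct)})"
            for e in s.entries
        )
        rows.append((s.genus, holders, s.n_in_sgsv, s.n_under_sda))
    return pd.DataFrame(
        rows, columns=["genus", "top_holders", "n_in_sgsv", "n_under_sda"]
    )
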