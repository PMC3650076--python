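"""End-to-end orchestration: read tables, run estimators, write a report bundle.

The bundle is four TSVs plus a run log: per-genus coverage rows, crop-group
aggregates, top-N institutional profiles (with an ``Average`` summary row),
and the selection audit. Outputs are deterministic given the inputs; every
file starts with a header comment carrying the package version and a hash of
the run configuration. Files are written to a temporary name and atomically
renamed, so a failed run never leaves partial outputs behind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .coverage import (
    ReportingOptions,
    aggregate_groups,
    build_coverage_rows,
    profile_genus,
    profiles_to_frame,
    rows_to_frame,
    summarize_profiles,
)
from .estimators import TreatyContext, estimate_distinct, load_annex1_rules, treaty_coverage
from .model import (
    WorldCollections,
    assemble_world,
    read_deposits,
    read_holdings_summary,
    read_institution_registry,
    read_passport_table,
)
from .taxonomy import SelectionParams, default_non_pgrfa, select_study_genera

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and options for one pipeline run."""

    passport_path: Optional[str] = None
    registry_path: Optional[str] = None
    holdings_path: Optional[str] = None
    deposits_path: Optional[str] = None
    annex1_rules_path: Optional[str] = None
    contracting_parties: tuple[str, ...] = ()
    out_dir: str = "vaultgap-report"
    delimiter: str = ","
    min_accessions: int = 1000
    require_sgsv_presence: bool = True
    top_n: int = 10
    log_level: str = "INFO"
    seed: int = 0

    def config_hash(self) -> str:
        # hash analysis-relevant settings only, not where outputs land
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")
        fields.pop("log_level")
        blob = repr(sorted(fields.items())).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _write_tsv(frame: pd.DataFrame, path: Path, header_comment: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(header_comment)
        frame.to_csv(fh, sep="\t", index=False)
    os.replace(tmp, path)


def run_pipeline(
    config: RunConfig, world: WorldCollections | None = None
) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    ``world`` can be passed directly (e.g. a synthetic or fixture world); the
    table paths in ``config`` are read otherwise. Returns the bundle paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("vaultgap")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        return _run(config, world, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(
    config: RunConfig, world: WorldCollections | None, out_dir: Path
) -> dict[str, Path]:
    if world is None:
        stage = "read"
        accessions = (
            read_passport_table(config.passport_path, config.delimiter)
            if config.passport_path
            else []
        )
        registry = (
            read_institution_registry(config.registry_path, config.delimiter)
            if config.registry_path
            else []
        )
        holdings = (
            read_holdings_summary(config.holdings_path, config.delimiter)
            if config.holdings_path
            else []
        )
        deposits = (
            read_deposits(config.deposits_path, config.delimiter)
            if config.deposits_path
            else []
        )
        world, report = assemble_world(accessions, holdings, registry, deposits)
        logger.info(
            "assembled world: %d accessions, %d holdings rows, %d institutions, "
            "%d deposit rows",
            report.n_accessions, report.n_holdings, report.n_institutions,
            report.n_deposits,
        )

    params = SelectionParams(
        min_accessions=config.min_accessions,
        non_pgrfa_exclusions=default_non_pgrfa(),
        require_sgsv_presence=config.require_sgsv_presence,
    )
    genera, audit = select_study_genera(world.holdings, world.deposits, params)
    logger.info(
        "selection cascade: raw %d -> cleanup %d -> PGRFA %d -> threshold %d "
        "-> vault presence %d",
        audit.n_raw, audit.n_after_name_cleanup, audit.n_after_pgrfa_filter,
        audit.n_after_threshold, audit.n_after_sgsv_filter,
    )

    rules = load_annex1_rules(config.annex1_rules_path)
    article15 = frozenset(
        r.institute_code for r in world.registry if r.article15
    )
    parties = frozenset(config.contracting_parties) or frozenset(
        r.country for r in world.registry
    )
    ctx = TreatyContext(
        contracting_parties=parties,
        article15_institutes=article15,
        rules=rules,
    )

    genus_order = sorted(genera)
    distinct = {g: estimate_distinct(world, g) for g in genus_order}
    treaty = {g: treaty_coverage(world, g, ctx) for g in genus_order}
    rows = build_coverage_rows(world, genus_order, distinct, treaty)
    groups = aggregate_groups(rows)

    opts = ReportingOptions(top_n=config.top_n)
    profiles = [profile_genus(world, g, opts) for g in genus_order]
    profile_frame = profiles_to_frame(profiles)
    if profiles:
        avg_sgsv, avg_sda = summarize_profiles(profiles, opts)
        profile_frame.loc[len(profile_frame)] = ["Average", "", avg_sgsv, avg_sda]
        logger.info(
            "top-%d profile averages: %.1f backed up, %.1f under agreement",
            config.top_n, avg_sgsv, avg_sda,
        )

    header = f"# vaultgap {__version__} config={config.config_hash()}\n"
    paths = {
        "coverage": out_dir / "coverage.tsv",
        "groups": out_dir / "groups.tsv",
        "profiles": out_dir / "profiles.tsv",
        "selection_audit": out_dir / "selection_audit.tsv",
        "log": out_dir / "run.log",
    }
    _write_tsv(rows_to_frame(rows), paths["coverage"], header)
    _write_tsv(rows_to_frame(groups), paths["groups"], header)
    _write_tsv(profile_frame, paths["profiles"], header)
    _write_tsv(audit.to_frame(), paths["selection_audit"], header)
    return paths
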