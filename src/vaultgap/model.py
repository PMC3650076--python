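"""Domain model and table I/O for passport, registry, holdings and deposit data.

The pipeline consumes five delimited table kinds that mirror how the global
genebank information systems are organised:

* accession-level passport records (who holds it, what taxon, where it
  originated), using MCPD v2 descriptor names (INSTCODE, ACCENUMB, GENUS,
  SPECIES, ORIGCTY) as accepted column aliases;
* an institution registry (WIEWS-style INSTCODE, country, institution type,
  ITPGRFA Article 15 flag, Standard Deposit Agreement flag, depositor flag);
* institution x genus holdings summaries (genebank-level counts);
* safety-deposit records (depositor, genus, number of duplicated samples);
* rule/config tables handled by :mod:`vaultgap.taxonomy` and
  :mod:`vaultgap.estimators`.

Country codes are ISO 3166-1 alpha-3 internally. Alpha-2 input is translated
via a shipped table; anything unmappable becomes the ``UNKNOWN`` sentinel with
a logged warning. A missing origin country is never silently equated with the
host country — the distinct-accession estimator depends on that distinction.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing or unresolvable origin country.
UNKNOWN = "UNKNOWN"

INST_TYPES = frozenset(
    {"national", "subnational", "regional", "international_IARC", "other"}
)

_ALPHA3_RE = re.compile(r"^[A-Z]{3}$")

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}


class SchemaError(ValueError):
    """A table is missing a mandatory column or contains an invalid token."""


class IntegrityError(ValueError):
    """Records violate a uniqueness or referential-integrity constraint."""


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class AccessionRecord:
    """One passport record: a uniquely identified sample in one genebank."""

    institute_code: str
    accession_id: str
    genus: str
    species_epithet: str = ""
    origin_country: str = UNKNOWN


@dataclass(frozen=True)
class InstitutionRecord:
    """A genebank or collection-holding institution."""

    institute_code: str
    country: str
    inst_type: str
    article15: bool = False
    sda_signed: bool = False
    sgsv_depositor: bool = False


@dataclass(frozen=True)
class HoldingsRecord:
    """Genebank-level summary: accessions of one genus at one institution.

    ``n_indigenous`` is the number of those accessions whose recorded origin
    is the institution's own country; it may be absent (``None``), which is
    distinct from zero.
    """

    institute_code: str
    genus: str
    n_total: int
    n_indigenous: Optional[int] = None


@dataclass(frozen=True)
class DepositRecord:
    """Safety-duplicate samples of one genus sent to the Seed Vault."""

    depositor_code: str
    genus: str
    n_deposited: int


@dataclass
class IntegrityReport:
    """Per-source record counts for an assembled world."""

    n_accessions: int = 0
    n_holdings: int = 0
    n_institutions: int = 0
    n_deposits: int = 0


@dataclass
class WorldCollections:
    """The merged view of the four data sources downstream stages query."""

    accessions: tuple[AccessionRecord, ...] = ()
    holdings: tuple[HoldingsRecord, ...] = ()
    registry: tuple[InstitutionRecord, ...] = ()
    deposits: tuple[DepositRecord, ...] = ()
    _registry_map: dict[str, InstitutionRecord] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.accessions = tuple(self.accessions)
        self.holdings = tuple(self.holdings)
        self.registry = tuple(self.registry)
        self.deposits = tuple(self.deposits)
        self._registry_map = {r.institute_code: r for r in self.registry}

    @property
    def registry_map(self) -> Mapping[str, InstitutionRecord]:
        return self._registry_map

    def accessions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (a.institute_code, a.accession_id, a.genus, a.species_epithet,
                 a.origin_country)
                for a in self.accessions
            ],
            columns=["institute_code", "accession_id", "genus",
                     "species_epithet", "origin_country"],
        )

    def holdings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (h.institute_code, h.genus, h.n_total, h.n_indigenous)
                for h in self.holdings
            ],
            columns=["institute_code", "genus", "n_total", "n_indigenous"],
        )

    def registry_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.institute_code, r.country, r.inst_type, r.article15,
                 r.sda_signed, r.sgsv_depositor)
                for r in self.registry
            ],
            columns=["institute_code", "country", "inst_type", "article15",
                     "sda_signed", "sgsv_depositor"],
        )

    def deposits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(d.depositor_code, d.genus, d.n_deposited) for d in self.deposits],
            columns=["depositor_code", "genus", "n_deposited"],
        )


# ---------------------------------------------------------------------------
# country handling


@lru_cache(maxsize=1)
def _alpha2_to_alpha3() -> dict[str, str]:
    with resources.files("vaultgap.data").joinpath("country_codes.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return {row["alpha2"]: row["alpha3"] for row in csv.DictReader(fh)}


def normalize_country(code: str, alpha2_map: Mapping[str, str] | None = None) -> str:
    """Return an upper-case alpha-3 code, or ``UNKNOWN``.

    Accepts alpha-3 directly and alpha-2 through the translation table.
    """
    token = (code or "").strip().upper()
    if not token or token == UNKNOWN:
        return UNKNOWN
    if _ALPHA3_RE.match(token):
        return token
    mapping = alpha2_map if alpha2_map is not None else _alpha2_to_alpha3()
    if token in mapping:
        return mapping[token]
    logger.warning("unmappable country code %r mapped to UNKNOWN", code)
    return UNKNOWN


def _parse_bool(token: str, column: str) -> bool:
    low = str(token).strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise SchemaError(f"cannot parse boolean token {token!r} in column {column!r}")


# ---------------------------------------------------------------------------
# readers

_PASSPORT_ALIASES = {
    "instcode": "institute_code",
    "accenumb": "accession_id",
    "genus": "genus",
    "species": "species_epithet",
    "origcty": "origin_country",
    "institute_code": "institute_code",
    "accession_id": "accession_id",
    "species_epithet": "species_epithet",
    "origin_country": "origin_country",
}


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], kind: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{kind} table is missing mandatory column {col!r}")


def read_passport_table(
    path: str | Path, delimiter: str = ","
) -> list[AccessionRecord]:
    """Read accession-level passport records (MCPD aliases accepted)."""
    df = _read_table(path, delimiter)
    df = df.rename(columns={c: _PASSPORT_ALIASES.get(c.lower(), c) for c in df.columns})
    _require_columns(
        df, ["institute_code", "accession_id", "genus", "origin_country"], "passport"
    )
    if "species_epithet" not in df.columns:
        df["species_epithet"] = ""

    empty_genus = df.index[df["genus"].str.strip() == ""]
    if len(empty_genus):
        raise SchemaError(
            f"passport rows with empty genus: rows {list(empty_genus + 2)}"
        )
    dup = df.duplicated(subset=["institute_code", "accession_id"], keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, ["institute_code", "accession_id"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise IntegrityError(
            "duplicate (institute_code, accession_id) pairs: "
            + ", ".join(f"{i}/{a}" for i, a in offenders)
        )
    return [
        AccessionRecord(
            institute_code=row.institute_code.strip(),
            accession_id=row.accession_id.strip(),
            genus=row.genus.strip(),
            species_epithet=row.species_epithet.strip(),
            origin_country=normalize_country(row.origin_country),
        )
        for row in df.itertuples(index=False)
    ]


def read_institution_registry(
    path: str | Path, delimiter: str = ","
) -> list[InstitutionRecord]:
    """Read the institution registry.

    An ``article15`` flag on a non-IARC institution is accepted but logged as
    a warning: Article 15 agreements are signed with international centers,
    and anything else in the data is almost certainly a recording artefact.
    """
    df = _read_table(path, delimiter)
    _require_columns(
        df,
        ["institute_code", "country", "inst_type", "article15", "sda_signed",
         "sgsv_depositor"],
        "registry",
    )
    dup = df.duplicated(subset=["institute_code"], keep=False)
    if dup.any():
        codes = sorted(df.loc[dup, "institute_code"].unique())
        raise IntegrityError(f"duplicate institute codes: {codes}")
    records = []
    for row in df.itertuples(index=False):
        inst_type = row.inst_type.strip()
        if inst_type not in INST_TYPES:
            raise SchemaError(f"unknown inst_type token {inst_type!r}")
        rec = InstitutionRecord(
            institute_code=row.institute_code.strip(),
            country=normalize_country(row.country),
            inst_type=inst_type,
            article15=_parse_bool(row.article15, "article15"),
            sda_signed=_parse_bool(row.sda_signed, "sda_signed"),
            sgsv_depositor=_parse_bool(row.sgsv_depositor, "sgsv_depositor"),
        )
        if rec.article15 and rec.inst_type != "international_IARC":
            logger.warning(
                "institute %s has article15=true but inst_type=%s",
                rec.institute_code, rec.inst_type,
            )
        records.append(rec)
    return records


def _parse_count(token: str, column: str) -> int:
    try:
        value = int(str(token).strip())
    except ValueError as exc:
        raise SchemaError(f"cannot parse count {token!r} in column {column!r}") from exc
    if value < 0:
        raise ValueError(f"negative count {value} in column {column!r}")
    return value


def read_holdings_summary(
    path: str | Path, delimiter: str = ","
) -> list[HoldingsRecord]:
    """Read institution x genus holdings summaries.

    A blank ``n_indigenous`` cell is preserved as absent, not coerced to zero.
    """
    df = _read_table(path, delimiter)
    _require_columns(df, ["institute_code", "genus", "n_total"], "holdings")
    has_indig = "n_indigenous" in df.columns
    records = []
    for row in df.itertuples(index=False):
        n_total = _parse_count(row.n_total, "n_total")
        n_indig: Optional[int] = None
        if has_indig and str(row.n_indigenous).strip() != "":
            n_indig = _parse_count(row.n_indigenous, "n_indigenous")
            if n_indig > n_total:
                raise IntegrityError(
                    f"n_indigenous {n_indig} > n_total {n_total} for "
                    f"{row.institute_code}/{row.genus}"
                )
        records.append(
            HoldingsRecord(
                institute_code=row.institute_code.strip(),
                genus=row.genus.strip(),
                n_total=n_total,
                n_indigenous=n_indig,
            )
        )
    return records


def read_deposits(path: str | Path, delimiter: str = ",") -> list[DepositRecord]:
    """Read safety-deposit records (one row per depositor x genus)."""
    df = _read_table(path, delimiter)
    _require_columns(df, ["depositor_code", "genus", "n_deposited"], "deposits")
    dup = df.duplicated(subset=["depositor_code", "genus"], keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, ["depositor_code", "genus"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise IntegrityError(
            "duplicate (depositor_code, genus) pairs: "
            + ", ".join(f"{c}/{g}" for c, g in offenders)
        )
    return [
        DepositRecord(
            depositor_code=row.depositor_code.strip(),
            genus=row.genus.strip(),
            n_deposited=_parse_count(row.n_deposited, "n_deposited"),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)


def write_passport_table(
    records: Iterable[AccessionRecord], path: str | Path, delimiter: str = ","
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["INSTCODE", "ACCENUMB", "GENUS", "SPECIES", "ORIGCTY"])
        for r in records:
            origin = "" if r.origin_country == UNKNOWN else r.origin_country
            w.writerow([r.institute_code, r.accession_id, r.genus,
                        r.species_epithet, origin])


def write_institution_registry(
    records: Iterable[InstitutionRecord], path: str | Path, delimiter: str = ","
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["institute_code", "country", "inst_type", "article15",
                    "sda_signed", "sgsv_depositor"])
        for r in records:
            w.writerow([r.institute_code, r.country, r.inst_type,
                        int(r.article15), int(r.sda_signed), int(r.sgsv_depositor)])


def write_holdings_summary(
    records: Iterable[HoldingsRecord], path: str | Path, delimiter: str = ","
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["institute_code", "genus", "n_total", "n_indigenous"])
        for r in records:
            w.writerow([r.institute_code, r.genus, r.n_total,
                        "" if r.n_indigenous is None else r.n_indigenous])


def write_deposits(
    records: Iterable[DepositRecord], path: str | Path, delimiter: str = ","
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["depositor_code", "genus", "n_deposited"])
        for r in records:
            w.writerow([r.depositor_code, r.genus, r.n_deposited])


# ---------------------------------------------------------------------------
# assembly


def assemble_world(
    accessions: Iterable[AccessionRecord],
    holdings: Iterable[HoldingsRecord],
    registry: Iterable[InstitutionRecord],
    deposits: Iterable[DepositRecord],
) -> tuple[WorldCollections, IntegrityReport]:
    """Merge the four sources, enforcing referential integrity.

    Every institute code referenced anywhere must resolve in the registry;
    unresolved codes raise :class:`IntegrityError` naming the offenders. The
    returned report carries the per-source record counts (assembly never drops
    or fabricates records).
    """
    world = WorldCollections(
        accessions=tuple(accessions),
        holdings=tuple(holdings),
        registry=tuple(registry),
        deposits=tuple(deposits),
    )
    known = set(world.registry_map)
    referenced = (
        {a.institute_code for a in world.accessions}
        | {h.institute_code for h in world.holdings}
        | {d.depositor_code for d in world.deposits}
    )
    unresolved = sorted(referenced - known)
    if unresolved:
        raise IntegrityError(f"unresolved institute codes: {unresolved}")
    report = IntegrityReport(
        n_accessions=len(world.accessions),
        n_holdings=len(world.holdings),
        n_institutions=len(world.registry),
        n_deposits=len(world.deposits),
    )
    return world, report
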