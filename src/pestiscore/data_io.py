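"""Reading, validation and harmonization of monitoring and standards tables.

All concentrations are carried internally in μg/L. Input rows that fail type
or invariant validation are collected into a rejects report rather than being
silently dropped; harmonization exclusions (mixtures, pre-2010 records,
non-detects without a usable censoring limit) carry machine-readable reasons.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class SchemaError(ValueError):
    """An input table is missing a required column or is unreadable."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class ConcentrationRecord:
    """One site-level mean concentration (or non-detect) of one pesticide.

    ``concentration``, ``lod`` and ``loq`` are in μg/L. ``detected`` is True
    for quantified values; non-detects carry only a detection (LOD) or
    quantification (LOQ) limit.
    """

    country: str
    water_body: str  # "surface" | "ground"
    site_id: str
    pesticide_cas: str
    pesticide_name: str = ""
    concentration: float | None = None
    detected: bool = True
    lod: float | None = None
    loq: float | None = None
    year_start: int = 2010
    year_end: int | None = None
    region: str | None = None
    source_id: str = ""
    is_mixture: bool = False


@dataclass(slots=True)
class WQSRecord:
    """A water-quality-standard value for (jurisdiction, pesticide, medium)."""

    jurisdiction: str
    pesticide_cas: str
    medium: str  # "surface" | "ground" | "drinking"
    value: float  # μg/L, > 0 so log-transformable
    system_id: str = "default"


@dataclass(slots=True)
class UsageRecord:
    """Annual pesticide use (tonnes) and agricultural land (km²) of a country."""

    country: str
    year: int
    pesticide_use: float
    agricultural_land: float


@dataclass(slots=True)
class RejectedRow:
    row_index: int
    reason: str
    row: dict = field(default_factory=dict)


@dataclass(slots=True)
class HarmonizeResult:
    kept: list[ConcentrationRecord]
    excluded: list[tuple[ConcentrationRecord, str]]


# ---------------------------------------------------------------------------
# units, CAS numbers, country codes
# ---------------------------------------------------------------------------

#: accepted concentration units → multiplicative factor to μg/L
#: (ppb ≡ μg/L and ppm ≡ mg/L assuming water density 1 kg/L)
UNIT_TO_UG_L: dict[str, float] = {
    "ug/l": 1.0,
    "µg/l": 1.0,
    "μg/l": 1.0,
    "mg/l": 1e3,
    "ng/l": 1e-3,
    "g/l": 1e6,
    "ppb": 1.0,
    "ppm": 1e3,
}

_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


def normalize_cas(cas: str) -> str:
    """Strip whitespace from a CAS registry number string."""
    return re.sub(r"\s+", "", str(cas))


def cas_checksum_ok(cas: str) -> bool:
    """Validate the CAS registry check digit (weighted digit sum mod 10)."""
    cas = normalize_cas(cas)
    if not _CAS_RE.match(cas):
        return False
    digits = cas.replace("-", "")
    body, check = digits[:-1], int(digits[-1])
    total = sum((i + 1) * int(d) for i, d in enumerate(reversed(body)))
    return total % 10 == check


def validate_cas(cas: str) -> str:
    """Normalize a CAS string; an invalid check digit warns but keeps the record."""
    cas = normalize_cas(cas)
    if not cas_checksum_ok(cas):
        warnings.warn(f"CAS number {cas!r} fails syntax or check-digit validation",
                      stacklevel=2)
    return cas


#: free-text country name → ISO-3166-1 alpha-3 (monitoring literature and
#: FAOSTAT-style exports use names; scores are keyed by alpha-3 codes)
COUNTRY_ALIASES: dict[str, str] = {
    "albania": "ALB", "argentina": "ARG", "australia": "AUS", "austria": "AUT",
    "belgium": "BEL", "brazil": "BRA", "canada": "CAN", "china": "CHN",
    "colombia": "COL", "czech republic": "CZE", "czechia": "CZE",
    "denmark": "DNK", "egypt": "EGY", "finland": "FIN", "france": "FRA",
    "germany": "DEU", "ghana": "GHA", "greece": "GRC", "india": "IND",
    "ireland": "IRL", "israel": "ISR", "italy": "ITA", "japan": "JPN",
    "kenya": "KEN", "mexico": "MEX", "netherlands": "NLD",
    "new zealand": "NZL", "nigeria": "NGA", "norway": "NOR", "poland": "POL",
    "portugal": "PRT", "russia": "RUS", "south africa": "ZAF",
    "south korea": "KOR", "spain": "ESP", "sweden": "SWE",
    "switzerland": "CHE", "thailand": "THA", "turkey": "TUR",
    "türkiye": "TUR", "uk": "GBR", "united kingdom": "GBR",
    "united states": "USA", "united states of america": "USA", "usa": "USA",
    "viet nam": "VNM", "vietnam": "VNM",
}

_ISO3_RE = re.compile(r"^[A-Za-z]{3}$")


def normalize_country(name: str) -> str | None:
    """Map a free-text country name or alpha-3 code to ISO-3166-1 alpha-3.

    Returns None for values that are neither a known alias nor shaped like an
    alpha-3 code.
    """
    name = str(name).strip()
    alias = COUNTRY_ALIASES.get(name.lower())
    if alias:
        return alias
    if _ISO3_RE.match(name):
        return name.upper()
    return None


_WATER_BODY_ALIASES = {
    "surface": "surface", "surface water": "surface",
    "surface freshwater": "surface", "sw": "surface",
    "ground": "ground", "groundwater": "ground", "ground water": "ground",
    "gw": "ground",
}

_MEDIUM_ALIASES = {
    "surface": "surface", "surface water": "surface", "sw": "surface",
    "ground": "ground", "groundwater": "ground", "gw": "ground",
    "drinking": "drinking", "drinking water": "drinking",
    "drinking_water": "drinking", "dw": "drinking",
}

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_float(value, name: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"unparseable {name} {s!r}") from None


def _parse_int(value, name: str) -> int | None:
    f = _parse_float(value, name)
    if f is None:
        return None
    if f != int(f):
        raise ValueError(f"non-integer {name} {value!r}")
    return int(f)


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip().lower()
    if not s:
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"unparseable flag {value!r}")


def _load_table(path, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty input file: {path}") from None
    if dialect:
        df = df.rename(columns={actual: canon for canon, actual in dialect.items()})
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col} (in {path})")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

CONCENTRATION_COLUMNS = [
    "country", "region", "water_body", "site_id", "pesticide_cas",
    "pesticide_name", "concentration", "unit", "detected", "lod", "loq",
    "year_start", "year_end", "source_id",
]


def read_concentration_table(
    path, dialect: Mapping[str, str] | None = None
) -> tuple[list[ConcentrationRecord], list[RejectedRow]]:
    """Read a monitoring CSV into ConcentrationRecords, converting units to μg/L.

    ``dialect`` maps canonical column names to the names used in the file.
    Rows failing validation become :class:`RejectedRow` entries with a reason;
    a missing required column raises :class:`SchemaError`.
    """
    df = _load_table(path, dialect)
    if "year_start" not in df.columns and "year" in df.columns:
        df = df.rename(columns={"year": "year_start"})
    _require(df, ["country", "water_body", "site_id", "pesticide_cas", "unit",
                  "year_start"], path)

    records: list[ConcentrationRecord] = []
    rejects: list[RejectedRow] = []
    for idx, row in enumerate(df.to_dict("records")):
        try:
            records.append(_parse_concentration_row(row))
        except ValueError as err:
            rejects.append(RejectedRow(idx, str(err), row))
    return records, rejects


def _get(row: dict, key: str):
    v = row.get(key)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def _parse_concentration_row(row: dict) -> ConcentrationRecord:
    country = normalize_country(_get(row, "country") or "")
    if country is None:
        raise ValueError(f"unknown country {_get(row, 'country')!r}")

    wb_raw = (_get(row, "water_body") or "").lower()
    water_body = _WATER_BODY_ALIASES.get(wb_raw)
    if water_body is None:
        raise ValueError(f"unknown water_body {wb_raw!r}")

    site_id = _get(row, "site_id")
    if not site_id:
        raise ValueError("missing site_id")

    unit_raw = (_get(row, "unit") or "").lower()
    factor = UNIT_TO_UG_L.get(unit_raw)
    if factor is None:
        raise ValueError(f"unknown unit {unit_raw!r}")

    concentration = _parse_float(_get(row, "concentration"), "concentration")
    lod = _parse_float(_get(row, "lod"), "lod")
    loq = _parse_float(_get(row, "loq"), "loq")
    if concentration is not None and concentration < 0:
        raise ValueError("negative concentration")
    for name, v in (("lod", lod), ("loq", loq)):
        if v is not None and v <= 0:
            raise ValueError(f"non-positive {name}")

    detected = _parse_bool(_get(row, "detected"))
    if detected is None:
        detected = concentration is not None
    if detected and concentration is None:
        raise ValueError("detected without concentration")

    year_start = _parse_int(_get(row, "year_start"), "year_start")
    if year_start is None:
        raise ValueError("missing year_start")
    year_end = _parse_int(_get(row, "year_end"), "year_end")

    cas = _get(row, "pesticide_cas")
    if not cas:
        raise ValueError("missing pesticide_cas")
    cas = validate_cas(cas)

    is_mixture = _parse_bool(_get(row, "is_mixture")) or False

    return ConcentrationRecord(
        country=country,
        water_body=water_body,
        site_id=site_id,
        pesticide_cas=cas,
        pesticide_name=_get(row, "pesticide_name") or "",
        concentration=None if concentration is None else concentration * factor,
        detected=detected,
        lod=None if lod is None else lod * factor,
        loq=None if loq is None else loq * factor,
        year_start=year_start,
        year_end=year_end if year_end is not None else year_start,
        region=_get(row, "region"),
        source_id=_get(row, "source_id") or "",
        is_mixture=is_mixture,
    )


def read_wqs_table(
    path, dialect: Mapping[str, str] | None = None
) -> tuple[list[WQSRecord], list[RejectedRow]]:
    """Read a water-quality-standard CSV (values converted to μg/L)."""
    df = _load_table(path, dialect)
    _require(df, ["jurisdiction", "pesticide_cas", "medium", "value", "unit"], path)
    records: list[WQSRecord] = []
    rejects: list[RejectedRow] = []
    for idx, row in enumerate(df.to_dict("records")):
        try:
            jur = _get(row, "jurisdiction")
            if not jur:
                raise ValueError("missing jurisdiction")
            jur_norm = normalize_country(jur) or jur.strip().upper()
            medium = _MEDIUM_ALIASES.get((_get(row, "medium") or "").lower())
            if medium is None:
                raise ValueError(f"unknown medium {_get(row, 'medium')!r}")
            factor = UNIT_TO_UG_L.get((_get(row, "unit") or "").lower())
            if factor is None:
                raise ValueError(f"unknown unit {_get(row, 'unit')!r}")
            value = _parse_float(_get(row, "value"), "value")
            if value is None or value <= 0:
                raise ValueError("non-positive standard value")
            cas = validate_cas(_get(row, "pesticide_cas") or "")
            records.append(WQSRecord(
                jurisdiction=jur_norm,
                pesticide_cas=cas,
                medium=medium,
                value=value * factor,
                system_id=_get(row, "system_id") or "default",
            ))
        except ValueError as err:
            rejects.append(RejectedRow(idx, str(err), row))
    return records, rejects


def read_usage_table(
    path, dialect: Mapping[str, str] | None = None
) -> tuple[list[UsageRecord], list[RejectedRow]]:
    """Read a FAOSTAT-style usage CSV; land accepted in km² or ha (1 km² = 100 ha)."""
    df = _load_table(path, dialect)
    _require(df, ["country", "year", "pesticide_use_t"], path)
    if "agri_land_km2" not in df.columns and "agri_land_ha" not in df.columns:
        raise SchemaError(f"missing required column: agri_land_km2 (in {path})")
    records: list[UsageRecord] = []
    rejects: list[RejectedRow] = []
    for idx, row in enumerate(df.to_dict("records")):
        try:
            country = normalize_country(_get(row, "country") or "")
            if country is None:
                raise ValueError(f"unknown country {_get(row, 'country')!r}")
            year = _parse_int(_get(row, "year"), "year")
            if year is None:
                raise ValueError("missing year")
            use = _parse_float(_get(row, "pesticide_use_t"), "pesticide_use_t")
            if use is None or use < 0:
                raise ValueError("missing or negative pesticide_use_t")
            if _get(row, "agri_land_km2") is not None:
                land = _parse_float(_get(row, "agri_land_km2"), "agri_land_km2")
            else:
                land_ha = _parse_float(_get(row, "agri_land_ha"), "agri_land_ha")
                land = None if land_ha is None else land_ha / 100.0
            if land is None or land <= 0:
                raise ValueError("missing or non-positive agricultural land")
            records.append(UsageRecord(country, year, use, land))
        except ValueError as err:
            rejects.append(RejectedRow(idx, str(err), row))
    return records, rejects


def read_panel(path) -> list[str]:
    """Read a pesticide panel file: one CAS number per line, '#' comments allowed."""
    panel = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            panel.append(normalize_cas(line))
    return panel


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

_MIXTURE_NAME = re.compile(r"^\s*(?:[∑Σ]|sum\b|total\b)", re.IGNORECASE)


def harmonize_records(records: Iterable[ConcentrationRecord]) -> HarmonizeResult:
    """Apply the study's inclusion rules, partitioning records into kept/excluded.

    Exclusions (with machine-readable reasons):

    - ``mixture``: mixture totals such as ΣDDTs, whose component shares are
      unknown (flagged explicitly or recognized from the name);
    - ``pre-2010``: sampling started before 2010;
    - ``nondetect without LOD/LOQ``: non-detects with no usable censoring limit.

    Idempotent: harmonizing the kept list again keeps everything.
    """
    kept: list[ConcentrationRecord] = []
    excluded: list[tuple[ConcentrationRecord, str]] = []
    for rec in records:
        if rec.is_mixture or _MIXTURE_NAME.match(rec.pesticide_name or ""):
            excluded.append((rec, "mixture"))
        elif rec.year_start < 2010:
            excluded.append((rec, "pre-2010"))
        elif not rec.detected and rec.lod is None and rec.loq is None:
            excluded.append((rec, "nondetect without LOD/LOQ"))
        else:
            kept.append(rec)
    return HarmonizeResult(kept=kept, excluded=excluded)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_SORT_PREFERENCE = ("group_id", "country", "jurisdiction", "pesticide_cas")


def write_results_table(rows: pd.DataFrame, path) -> None:
    """Write a result table as CSV with deterministic column and row order.

    Rows are sorted ascending by the table's group key (country / jurisdiction
    code) with a stable sort, so repeated runs are byte-identical.
    """
    if rows.shape[1] == 0:
        raise ValueError("refusing to write a table with an empty schema")
    key = next((c for c in _SORT_PREFERENCE if c in rows.columns), rows.columns[0])
    out = rows.sort_values(key, kind="mergesort")
    out.to_csv(path, index=False)


def write_rejects_report(rejects: Sequence[RejectedRow], path) -> None:
    """Write the rejects report: original row index plus reason string."""
    df = pd.DataFrame(
        [{"row_index": r.row_index, "reason": r.reason} for r in rejects],
        columns=["row_index", "reason"],
    )
    df.to_csv(path, index=False)


def records_to_frame(records: Iterable[ConcentrationRecord]) -> pd.DataFrame:
    """Flatten ConcentrationRecords into a DataFrame (writer-compatible schema)."""
    cols = CONCENTRATION_COLUMNS
    rows = []
    for r in records:
        rows.append({
            "country": r.country, "region": r.region, "water_body": r.water_body,
            "site_id": r.site_id, "pesticide_cas": r.pesticide_cas,
            "pesticide_name": r.pesticide_name, "concentration": r.concentration,
            "unit": "ug/L", "detected": r.detected, "lod": r.lod, "loq": r.loq,
            "year_start": r.year_start, "year_end": r.year_end,
            "source_id": r.source_id, "is_mixture": r.is_mixture,
        })
    return pd.DataFrame(rows, columns=cols + ["is_mixture"])


def write_concentration_table(records: Iterable[ConcentrationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# packaged defaults
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("pestiscore.data").joinpath(name)


def default_panel() -> list[str]:
    """The default 30-pesticide regulation panel shipped with the package."""
    return read_panel(_data_path("panel30.txt"))


def default_who_guidelines() -> dict[str, float]:
    """WHO drinking-water guideline values (μg/L) for the five screened pesticides."""
    df = pd.read_csv(_data_path("who_guidelines.csv"), dtype={"pesticide_cas": str})
    out = {}
    for _, row in df.iterrows():
        factor = UNIT_TO_UG_L[str(row["unit"]).lower()]
        out[normalize_cas(row["pesticide_cas"])] = float(row["value"]) * factor
    return out


def default_rfd_table() -> dict[str, float]:
    """Chronic oral reference doses (mg/(kg·day)) for commonly screened pesticides."""
    df = pd.read_csv(_data_path("rfd_defaults.csv"), dtype={"pesticide_cas": str})
    return {
        normalize_cas(row["pesticide_cas"]): float(row["rfd_mg_per_kg_day"])
        for _, row in df.iterrows()
    }
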