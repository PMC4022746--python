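"""Domain types and CSV I/O for athlete body-composition records.

An :class:`AthleteRecord` carries one athlete's raw anthropometry (weight,
height, seven skinfolds, five circumferences) and, optionally, a tabulated
whole-body DXA scan broken down by region.  Records are keyed by sex and by
one of the 21 sports represented in the study design this package emulates.

The module also ships a packaged transcription of the study's per-sport,
per-sex sample-size table (:func:`load_table1`) used as the default design
for the synthetic-data generator and for sample-size bookkeeping
(:func:`count_measured`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "Sex",
    "Sport",
    "SkinfoldSet",
    "CircumferenceSet",
    "RegionTissues",
    "DxaScan",
    "AthleteRecord",
    "ParseError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "records_to_frame",
    "load_table1",
    "count_measured",
    "tabulate_counts",
    "normalize_sport",
]


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. non-positive height)."""


class ParseError(ValueError):
    """A CSV cell could not be parsed; the message names row and column."""


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Sport(str, enum.Enum):
    ARCHERY_SHOOTING = "archery_shooting"
    ATHLETICS = "athletics"
    BASKETBALL = "basketball"
    FENCING = "fencing"
    GYMNASTICS = "gymnastics"
    HANDBALL = "handball"
    HOCKEY_RINK = "hockey_rink"
    KORFBALL = "korfball"
    MODERN_PENTATHLON = "modern_pentathlon"
    MOTORSPORT = "motorsport"
    OTHER_COMBAT = "other_combat"
    ROWING = "rowing"
    RUGBY = "rugby"
    SAILING = "sailing"
    SOCCER = "soccer"
    SURF = "surf"
    SWIMMING = "swimming"
    TENNIS = "tennis"
    TRIATHLON = "triathlon"
    VOLLEYBALL = "volleyball"
    WRESTLING_JUDO = "wrestling_judo"


# Case-insensitive aliases for the free-text sport labels found in source
# tables (footnote markers stripped by the normalizer before lookup).
_SPORT_ALIASES = {
    "archery and shooting": Sport.ARCHERY_SHOOTING,
    "hockey rink": Sport.HOCKEY_RINK,
    "rink hockey": Sport.HOCKEY_RINK,
    "modern pentathlon": Sport.MODERN_PENTATHLON,
    "other combat sports": Sport.OTHER_COMBAT,
    "other combat": Sport.OTHER_COMBAT,
    "wrestling and judo": Sport.WRESTLING_JUDO,
}


def normalize_sport(label: str) -> Sport:
    """Map a free-text sport label onto the 21-level sport enum.

    Matching is case-insensitive and tolerates spaces in place of
    underscores; trailing footnote markers (``*``, ``#``, digits after a
    letter run) are stripped.
    """
    key = str(label).strip().lower().rstrip("*#^ ")
    if key in _SPORT_ALIASES:
        return _SPORT_ALIASES[key]
    canonical = key.replace(" ", "_").replace("-", "_")
    try:
        return Sport(canonical)
    except ValueError:
        raise ValidationError(f"unknown sport label: {label!r}") from None


def _require_positive(name: str, value: float) -> None:
    if not (value > 0) or not math.isfinite(value):
        raise ValidationError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class SkinfoldSet:
    """Seven caliper skinfold thicknesses, millimetres."""

    triceps: float
    subscapular: float
    biceps: float
    suprailiac: float
    abdominal: float
    thigh: float
    medial_calf: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f"skinfold {f.name}", getattr(self, f.name))


@dataclass(frozen=True)
class CircumferenceSet:
    """Five limb/torso circumferences, centimetres."""

    hip: float
    arm: float
    midthigh: float
    calf: float
    abdominal: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f"circumference {f.name}", getattr(self, f.name))


@dataclass(frozen=True)
class RegionTissues:
    """Tissue masses for one DXA region: bone mineral content (g),
    fat mass (kg) and lean soft tissue (kg)."""

    bmc_g: float
    fm_kg: float
    lst_kg: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or not math.isfinite(v):
                raise ValidationError(f"DXA {f.name} must be >= 0, got {v!r}")

    def __add__(self, other: "RegionTissues") -> "RegionTissues":
        return RegionTissues(
            self.bmc_g + other.bmc_g, self.fm_kg + other.fm_kg, self.lst_kg + other.lst_kg
        )


@dataclass(frozen=True)
class DxaScan:
    """A tabulated whole-body DXA scan.

    ``whole``, ``subtotal`` (whole minus head), ``trunk`` and
    ``appendicular`` (arms + legs) region breakdowns plus whole-body areal
    bone mineral density.  The optional ``arms``/``legs``/``head`` parts, when
    present, feed the appendicular and subtotal aggregates.
    """

    whole: RegionTissues
    subtotal: RegionTissues
    trunk: RegionTissues
    appendicular: RegionTissues
    bmd: float  # whole-body BMD, g/cm^2
    arms: Optional[RegionTissues] = None
    legs: Optional[RegionTissues] = None
    head: Optional[RegionTissues] = None

    def __post_init__(self) -> None:
        _require_positive("bmd", self.bmd)


@dataclass(frozen=True)
class AthleteRecord:
    id: str
    sex: Sex
    sport: Sport
    age: float
    weight: float  # kg
    height: float  # cm
    skinfolds: Optional[SkinfoldSet] = None
    circumferences: Optional[CircumferenceSet] = None
    dxa: Optional[DxaScan] = None

    def __post_init__(self) -> None:
        _require_positive("weight", self.weight)
        _require_positive("height", self.height)
        if self.age < 0 or not math.isfinite(self.age):
            raise ValidationError(f"age must be >= 0, got {self.age!r}")


# ---------------------------------------------------------------------------
# CSV layout

_SKF_COLS = {
    "triceps": "skf_triceps",
    "subscapular": "skf_subscapular",
    "biceps": "skf_biceps",
    "suprailiac": "skf_suprailiac",
    "abdominal": "skf_abdominal",
    "thigh": "skf_thigh",
    "medial_calf": "skf_medial_calf",
}
_CIRC_COLS = {
    "hip": "circ_hip",
    "arm": "circ_arm",
    "midthigh": "circ_midthigh",
    "calf": "circ_calf",
    "abdominal": "circ_abdominal",
}
_DXA_REGIONS = ("whole", "subtotal", "trunk", "appendicular")
_DXA_PARTS = ("arms", "legs", "head")
_DXA_TISSUES = ("bmc_g", "fm_kg", "lst_kg")


def _dxa_col(region: str, tissue: str) -> str:
    return f"dxa_{region}_{tissue}"


def csv_columns() -> list[str]:
    """Canonical column order of the dataset CSV format."""
    cols = ["id", "sex", "sport", "age", "weight_kg", "height_cm"]
    cols += list(_SKF_COLS.values())
    cols += list(_CIRC_COLS.values())
    for region in _DXA_REGIONS + _DXA_PARTS:
        cols += [_dxa_col(region, t) for t in _DXA_TISSUES]
    cols.append("dxa_wb_bmd")
    return cols


def _cell(row: pd.Series, col: str, rowno: int) -> Optional[float]:
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or (isinstance(v, str) and not v.strip()):
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise ParseError(f"row {rowno}, column {col!r}: cannot parse {v!r} as a number") from None


def _block(row: pd.Series, mapping: Mapping[str, str], rowno: int) -> Optional[dict]:
    vals = {field: _cell(row, col, rowno) for field, col in mapping.items()}
    present = [v for v in vals.values() if v is not None]
    if not present:
        return None
    missing = [mapping[k] for k, v in vals.items() if v is None]
    if missing:
        raise ParseError(f"row {rowno}: partially filled measurement block, missing {missing}")
    return vals


def _region_from_row(row: pd.Series, region: str, rowno: int) -> Optional[RegionTissues]:
    vals = _block(row, {t: _dxa_col(region, t) for t in _DXA_TISSUES}, rowno)
    return None if vals is None else RegionTissues(**vals)


def read_dataset(path, schema: Optional[Mapping[str, str]] = None) -> list[AthleteRecord]:
    """Read a dataset CSV into a list of :class:`AthleteRecord`.

    Parameters
    ----------
    path : str or path-like
        Comma-separated UTF-8 file with one header row; missing optional
        measurement blocks are encoded as empty cells.
    schema : mapping, optional
        Maps canonical column names (see :func:`csv_columns`) to the header
        names actually used in the file.
    """
    df = pd.read_csv(path, dtype=str)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    records: list[AthleteRecord] = []
    for i, (_, row) in enumerate(df.iterrows()):
        rowno = i + 2  # 1-based with header
        try:
            sex = Sex(str(row["sex"]).strip().lower())
        except (KeyError, ValueError):
            raise ParseError(f"row {rowno}: invalid or missing sex {row.get('sex')!r}") from None
        sport = normalize_sport(row["sport"])
        age = _cell(row, "age", rowno)
        weight = _cell(row, "weight_kg", rowno)
        height = _cell(row, "height_cm", rowno)
        if weight is None or height is None:
            raise ParseError(f"row {rowno}: weight_kg and height_cm are required")
        skf = _block(row, _SKF_COLS, rowno)
        circ = _block(row, _CIRC_COLS, rowno)
        dxa = None
        regions = {r: _region_from_row(row, r, rowno) for r in _DXA_REGIONS + _DXA_PARTS}
        bmd = _cell(row, "dxa_wb_bmd", rowno)
        if any(regions[r] is not None for r in _DXA_REGIONS) or bmd is not None:
            core = {r: regions[r] for r in _DXA_REGIONS}
            missing = [r for r, v in core.items() if v is None]
            if missing or bmd is None:
                raise ParseError(
                    f"row {rowno}: incomplete DXA block, missing regions {missing}"
                    + ("" if bmd is not None else " and dxa_wb_bmd")
                )
            dxa = DxaScan(
                whole=core["whole"],
                subtotal=core["subtotal"],
                trunk=core["trunk"],
                appendicular=core["appendicular"],
                bmd=bmd,
                arms=regions["arms"],
                legs=regions["legs"],
                head=regions["head"],
            )
        records.append(
            AthleteRecord(
                id=str(row["id"]),
                sex=sex,
                sport=sport,
                age=0.0 if age is None else age,
                weight=weight,
                height=height,
                skinfolds=None if skf is None else SkinfoldSet(**skf),
                circumferences=None if circ is None else CircumferenceSet(**circ),
                dxa=dxa,
            )
        )
    return records


def _record_to_row(r: AthleteRecord) -> dict:
    row: dict = {
        "id": r.id,
        "sex": r.sex.value,
        "sport": r.sport.value,
        "age": r.age,
        "weight_kg": r.weight,
        "height_cm": r.height,
    }
    if r.skinfolds is not None:
        for field, col in _SKF_COLS.items():
            row[col] = getattr(r.skinfolds, field)
    if r.circumferences is not None:
        for field, col in _CIRC_COLS.items():
            row[col] = getattr(r.circumferences, field)
    if r.dxa is not None:
        for region in _DXA_REGIONS + _DXA_PARTS:
            part = getattr(r.dxa, region) if region in _DXA_PARTS else getattr(r.dxa, region)
            if part is None:
                continue
            for t in _DXA_TISSUES:
                row[_dxa_col(region, t)] = getattr(part, t)
        row["dxa_wb_bmd"] = r.dxa.bmd
    return row


def records_to_frame(records: Iterable[AthleteRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame in the canonical CSV column order."""
    rows = [_record_to_row(r) for r in records]
    df = pd.DataFrame(rows, columns=csv_columns())
    return df


def write_dataset(records: Sequence[AthleteRecord], path) -> None:
    """Write records as CSV; absent optional blocks become empty cells."""
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Study-design sample-size fixture

_COUNT_COLUMNS = {
    "common": "n_common",
    "weight_height": "n_weight_height",
    "skinfold_circumference": "n_skinfold_circumference",
    "dxa": "n_dxa",
}


class MeasuredCounts(NamedTuple):
    total: int
    female: int
    male: int


def load_table1() -> pd.DataFrame:
    """Packaged per-sport, per-sex sample sizes of the reference study.

    Columns: sport, sex, n_common, n_weight_height,
    n_skinfold_circumference, n_dxa.  Every (sport, sex) pair is present.
    """
    with resources.files("athleref.data").joinpath("table1_sample_sizes.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    return df


def count_measured(fixture: pd.DataFrame, measurement_class: str) -> MeasuredCounts:
    """Sum one sample-size column of the design fixture over all sports.

    Returns ``(total, female, male)`` for the requested measurement class
    (``weight_height``, ``skinfold_circumference``, ``dxa`` or ``common``).
    """
    try:
        col = _COUNT_COLUMNS[measurement_class]
    except KeyError:
        raise ValueError(
            f"unknown measurement_class {measurement_class!r}; "
            f"expected one of {sorted(_COUNT_COLUMNS)}"
        ) from None
    by_sex = fixture.groupby("sex")[col].sum()
    female = int(by_sex.get("female", 0))
    male = int(by_sex.get("male", 0))
    return MeasuredCounts(female + male, female, male)


def tabulate_counts(records: Iterable[AthleteRecord]) -> pd.DataFrame:
    """Tabulate a record collection into the fixture's sample-size layout."""
    rows = []
    for sport in Sport:
        for sex in Sex:
            cell = [
                r for r in records if r.sport is sport and r.sex is sex
            ]
            n_wh = len(cell)
            n_skf = sum(1 for r in cell if r.skinfolds is not None)
            n_dxa = sum(1 for r in cell if r.dxa is not None)
            n_common = sum(1 for r in cell if r.skinfolds is not None and r.dxa is not None)
            rows.append(
                {
                    "sport": sport.value,
                    "sex": sex.value,
                    "n_common": n_common,
                    "n_weight_height": n_wh,
                    "n_skinfold_circumference": n_skf,
                    "n_dxa": n_dxa,
                }
            )
    return pd.DataFrame(rows)
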