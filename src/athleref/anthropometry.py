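"""Derived anthropometric and DXA body-composition variables.

Implements the standard field formulas: skinfold sums (7-site, appendicular,
trunk, arm, leg), skinfold-corrected muscle circumferences
(circumference − π·skinfold, with the skinfold converted mm → cm so the
correction lives on the circumference scale), BMI, and the DXA quantities —
fat-free mass FFM = LST + BMC, percent fat, and the height-normalized
indices FMI, FFMI and ALSTI (mass / height², kg/m²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import (
    AthleteRecord,
    DxaScan,
    SkinfoldSet,
    ValidationError,
    records_to_frame,
)

__all__ = [
    "sum_skinfolds",
    "muscle_circumference",
    "bmi",
    "height_index",
    "derive_dxa",
    "DerivedAnthropometry",
    "DerivedDxa",
    "derive_frame",
    "OUTCOME_CATALOGUE",
    "LOG_SCALE_OUTCOMES",
    "is_log_scale",
]

_SELECTIONS = {
    "seven": ("triceps", "subscapular", "biceps", "suprailiac", "abdominal", "thigh", "medial_calf"),
    "appendicular": ("triceps", "biceps", "thigh", "medial_calf"),
    "trunk": ("subscapular", "suprailiac", "abdominal"),
    "arm": ("triceps", "biceps"),
    "leg": ("thigh", "medial_calf"),
}


def sum_skinfolds(s: SkinfoldSet, selection: str = "seven") -> float:
    """Sum of skinfold thicknesses (mm) over a named site selection.

    ``seven`` is all sites; ``appendicular`` = triceps + biceps + thigh +
    medial calf; ``trunk`` = subscapular + suprailiac + abdominal;
    ``arm`` = triceps + biceps; ``leg`` = thigh + medial calf.
    """
    try:
        sites = _SELECTIONS[selection]
    except KeyError:
        raise ValueError(f"unknown selection {selection!r}; expected one of {sorted(_SELECTIONS)}") from None
    return float(sum(getattr(s, site) for site in sites))


def muscle_circumference(circumference: float, skinfold: float) -> float:
    """Skinfold-corrected muscle circumference, cm.

    circumference (cm) − π · skinfold, with the skinfold (mm) converted to
    cm first so both terms share a unit.
    """
    if not circumference > 0:
        raise ValidationError(f"circumference must be > 0, got {circumference!r}")
    if skinfold < 0:
        raise ValidationError(f"skinfold must be >= 0, got {skinfold!r}")
    mc = circumference - math.pi * (skinfold / 10.0)
    if mc <= 0:
        raise ValidationError(
            f"muscle circumference {mc:.2f} cm <= 0 for circumference "
            f"{circumference} cm and skinfold {skinfold} mm"
        )
    return mc


def bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m², from weight in kg and height in cm."""
    return height_index(weight, height)


def height_index(mass: float, height: float) -> float:
    """mass / height² in kg/m²; used for BMI, FMI, FFMI and ALSTI."""
    if not mass > 0:
        raise ValidationError(f"mass must be > 0, got {mass!r}")
    if not height > 0:
        raise ValidationError(f"height must be > 0, got {height!r}")
    return mass / (height / 100.0) ** 2


@dataclass(frozen=True)
class DerivedAnthropometry:
    bmi: float
    sum7: float
    sum_appendicular: float
    sum_trunk: float
    sum_arm: float
    sum_leg: float
    arm_mc: Optional[float] = None
    thigh_mc: Optional[float] = None
    calf_mc: Optional[float] = None


@dataclass(frozen=True)
class RegionDerived:
    ffm_kg: float
    pct_fm: Optional[float]  # None when fm + ffm = 0 (undefined)


@dataclass(frozen=True)
class DerivedDxa:
    regions: dict  # region name -> RegionDerived
    fmi: float
    ffmi: float
    alst: float
    alsti: float


def _region_derived(fm_kg: float, lst_kg: float, bmc_g: float) -> RegionDerived:
    ffm = lst_kg + bmc_g / 1000.0
    denom = fm_kg + ffm
    pct = None if denom == 0 else 100.0 * fm_kg / denom
    return RegionDerived(ffm_kg=ffm, pct_fm=pct)


def derive_dxa(scan: DxaScan, height: float) -> DerivedDxa:
    """All derived DXA variables for one scan.

    Per region: FFM = LST + BMC (BMC stored in g, converted to kg) and
    %FM = 100·FM/(FM + FFM).  Whole-body FMI and FFMI, appendicular lean
    soft tissue (ALST) and its height index (ALSTI).  A region with
    FM + FFM = 0 yields an explicitly undefined percent fat (None).
    """
    if not height > 0:
        raise ValidationError(f"height must be > 0, got {height!r}")
    regions = {}
    for name in ("whole", "subtotal", "trunk", "appendicular"):
        part = getattr(scan, name)
        regions[name] = _region_derived(part.fm_kg, part.lst_kg, part.bmc_g)
    whole = scan.whole
    whole_ffm = regions["whole"].ffm_kg
    return DerivedDxa(
        regions=regions,
        fmi=height_index(whole.fm_kg, height) if whole.fm_kg > 0 else 0.0,
        ffmi=height_index(whole_ffm, height),
        alst=scan.appendicular.lst_kg,
        alsti=height_index(scan.appendicular.lst_kg, height),
    )


# ---------------------------------------------------------------------------
# Outcome catalogue: the 16 anthropometry + 24 DXA reference variables.
# Each entry: column name -> (description, units, log_scale flag).

OUTCOME_CATALOGUE: dict[str, tuple[str, str, bool]] = {
    # anthropometry (16)
    "weight_kg": ("body weight", "kg", False),
    "height_cm": ("height", "cm", False),
    "bmi": ("body mass index", "kg/m^2", False),
    "sum7_skf": ("sum of 7 skinfolds", "mm", False),
    "sum_appendicular_skf": ("sum of appendicular skinfolds", "mm", False),
    "sum_arm_skf": ("sum of arm skinfolds", "mm", False),
    "sum_leg_skf": ("sum of leg skinfolds", "mm", False),
    "sum_trunk_skf": ("sum of trunk skinfolds", "mm", False),
    "circ_arm": ("arm circumference", "cm", False),
    "arm_mc": ("arm muscle circumference", "cm", False),
    "circ_midthigh": ("midthigh circumference", "cm", False),
    "thigh_mc": ("thigh muscle circumference", "cm", False),
    "circ_calf": ("calf circumference", "cm", False),
    "calf_mc": ("calf muscle circumference", "cm", False),
    "circ_abdominal": ("abdominal circumference", "cm", False),
    "circ_hip": ("hip circumference", "cm", False),
    # DXA (24)
    "wb_bmc_g": ("whole-body bone mineral content", "g", False),
    "wb_bmd": ("whole-body bone mineral density", "g/cm^2", True),
    "wb_fm_kg": ("whole-body fat mass", "kg", True),
    "wb_fmi": ("whole-body fat mass index", "kg/m^2", True),
    "wb_pct_fm": ("whole-body percent fat mass", "%", True),
    "wb_ffm_kg": ("whole-body fat-free mass", "kg", False),
    "wb_ffmi": ("whole-body fat-free mass index", "kg/m^2", True),
    "wb_lst_kg": ("whole-body lean soft tissue", "kg", False),
    "subtotal_bmc_kg": ("subtotal bone mineral content", "kg", False),
    "subtotal_fm_kg": ("subtotal fat mass", "kg", True),
    "subtotal_pct_fm": ("subtotal percent fat mass", "%", True),
    "subtotal_ffm_kg": ("subtotal fat-free mass", "kg", False),
    "subtotal_lst_kg": ("subtotal lean soft tissue", "kg", False),
    "appendicular_bmc_kg": ("appendicular bone mineral content", "kg", False),
    "appendicular_fm_kg": ("appendicular fat mass", "kg", True),
    "appendicular_pct_fm": ("appendicular percent fat mass", "%", True),
    "appendicular_ffm_kg": ("appendicular fat-free mass", "kg", False),
    "appendicular_lst_kg": ("appendicular lean soft tissue", "kg", False),
    "alsti": ("appendicular lean soft tissue index", "kg/m^2", True),
    "trunk_bmc_kg": ("trunk bone mineral content", "kg", False),
    "trunk_fm_kg": ("trunk fat mass", "kg", True),
    "trunk_pct_fm": ("trunk percent fat mass", "%", True),
    "trunk_ffm_kg": ("trunk fat-free mass", "kg", False),
    "trunk_lst_kg": ("trunk lean soft tissue", "kg", False),
}

ANTHROPOMETRY_OUTCOMES = tuple(list(OUTCOME_CATALOGUE)[:16])
DXA_OUTCOMES = tuple(list(OUTCOME_CATALOGUE)[16:])
LOG_SCALE_OUTCOMES = frozenset(k for k, (_, _, lg) in OUTCOME_CATALOGUE.items() if lg)


def is_log_scale(outcome: str) -> bool:
    """Whether a catalogue outcome is analysed on the log scale.

    The strongly right-skewed outcomes — BMD, absolute and percent fat mass
    (all regions), FMI, FFMI and ALSTI — are log-transformed before the
    percentile model is fitted and back-transformed afterwards.
    """
    return outcome in LOG_SCALE_OUTCOMES


def derive_frame(records: Iterable[AthleteRecord]) -> pd.DataFrame:
    """Flatten records and append every derivable catalogue outcome.

    Columns for outcomes whose source measurements are absent in a record
    are left as NaN for that row.
    """
    recs = list(records)
    df = records_to_frame(recs)
    derived_rows = []
    for r in recs:
        d: dict[str, float] = {"bmi": bmi(r.weight, r.height)}
        if r.skinfolds is not None:
            d["sum7_skf"] = sum_skinfolds(r.skinfolds, "seven")
            d["sum_appendicular_skf"] = sum_skinfolds(r.skinfolds, "appendicular")
            d["sum_trunk_skf"] = sum_skinfolds(r.skinfolds, "trunk")
            d["sum_arm_skf"] = sum_skinfolds(r.skinfolds, "arm")
            d["sum_leg_skf"] = sum_skinfolds(r.skinfolds, "leg")
            if r.circumferences is not None:
                # arm MC pairs the triceps skinfold; thigh MC the thigh
                # skinfold with the midthigh circumference; calf MC the
                # medial-calf skinfold.
                d["arm_mc"] = muscle_circumference(r.circumferences.arm, r.skinfolds.triceps)
                d["thigh_mc"] = muscle_circumference(r.circumferences.midthigh, r.skinfolds.thigh)
                d["calf_mc"] = muscle_circumference(r.circumferences.calf, r.skinfolds.medial_calf)
        if r.dxa is not None:
            dx = derive_dxa(r.dxa, r.height)
            d["wb_bmc_g"] = r.dxa.whole.bmc_g
            d["wb_bmd"] = r.dxa.bmd
            d["wb_fm_kg"] = r.dxa.whole.fm_kg
            d["wb_fmi"] = dx.fmi
            d["wb_pct_fm"] = dx.regions["whole"].pct_fm
            d["wb_ffm_kg"] = dx.regions["whole"].ffm_kg
            d["wb_ffmi"] = dx.ffmi
            d["wb_lst_kg"] = r.dxa.whole.lst_kg
            for region in ("subtotal", "trunk", "appendicular"):
                part = getattr(r.dxa, region)
                d[f"{region}_bmc_kg"] = part.bmc_g / 1000.0
                d[f"{region}_fm_kg"] = part.fm_kg
                d[f"{region}_pct_fm"] = dx.regions[region].pct_fm
                d[f"{region}_ffm_kg"] = dx.regions[region].ffm_kg
                d[f"{region}_lst_kg"] = part.lst_kg
            d["alsti"] = dx.alsti
        derived_rows.append(d)
    derived = pd.DataFrame(derived_rows, columns=[c for c in OUTCOME_CATALOGUE if c not in df.columns])
    return pd.concat([df.reset_index(drop=True), derived.reset_index(drop=True)], axis=1)
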