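"""Synthetic athlete datasets with the statistical structure the
empirical-Bayes analysis assumes.

Each outcome is generated hierarchically: per (sport, sex) cell a latent
(mean, precision) pair is drawn from that outcome's normal–gamma
hyperprior, then the cell's athletes receive independent Gaussian values.
Right-skewed outcomes (BMD and the fat-mass family) are generated on the
log scale and exponentiated, mirroring the analysis model.  DXA values are
built part-wise (arms, legs, trunk, head per tissue) and aggregated, so the
additivity identities — appendicular = arms + legs, subtotal = whole −
head, FFM = LST + BMC — hold exactly.

Cell sample sizes default to the packaged study design (21 sports × 2
sexes with many cells below the n ≥ 8 reporting gate), so a default
simulation exercises the same sharing and reporting rules as the original
analysis.  The default outcome hyperparameters emulate the study's
descriptive statistics (grand means and within-/between-sport spreads).

The module also hosts the validation harnesses: hyperparameter-recovery
and joint-coverage experiments for the full estimation pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    FitError,
    Hyperparams,
    Posterior,
    ResolutionError,
    fit_hyperparams,
    hpd_region,
    posterior_update,
    simultaneous_cis,
    summarize_group,
)
from .records import (
    AthleteRecord,
    CircumferenceSet,
    DxaScan,
    RegionTissues,
    Sex,
    SkinfoldSet,
    Sport,
    load_table1,
)

__all__ = [
    "OutcomeSpec",
    "SimConfig",
    "default_sim_config",
    "simulate_dataset",
    "simulate_groups",
    "draw_sizes_from_table1",
    "recovery_experiment",
    "coverage_experiment",
]


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative spec for one primitive outcome: per-sex normal–gamma
    hyperparameters and whether generation happens on the log scale."""

    female: Hyperparams
    male: Hyperparams
    log_scale: bool = False

    def for_sex(self, sex: Sex) -> Hyperparams:
        return self.female if sex is Sex.FEMALE else self.male


def _hp(mean: float, within_sd: float, between_sd: float, alpha0: float = 4.0) -> Hyperparams:
    """Hyperparameters matching a target within-group SD and between-group
    SD of means: E[sigma^2] = beta0/(alpha0-1) = within_sd^2 and
    Var[mu] ~ within_sd^2/kappa0 = between_sd^2."""
    w2 = within_sd**2
    return Hyperparams(
        mu0=mean, kappa0=w2 / between_sd**2, alpha0=alpha0, beta0=w2 * (alpha0 - 1.0)
    )


def _log_hp(typical: float, within_cv: float, between_cv: float) -> Hyperparams:
    """Log-scale hyperparameters for a multiplicative outcome with a
    typical value and approximate within/between coefficients of
    variation."""
    return _hp(math.log(typical), within_cv, between_cv)


# Primitive outcomes of the generator: basic anthropometry and the DXA
# tissue parts from which every aggregate is built.  Values emulate the
# study population's descriptive statistics.
_DEFAULT_SPECS: dict[str, OutcomeSpec] = {
    "height_cm": OutcomeSpec(_hp(167.8, 6.0, 4.5), _hp(179.3, 6.5, 6.0)),
    "weight_kg": OutcomeSpec(_hp(61.5, 6.5, 4.0), _hp(76.1, 8.5, 7.0)),
    # skinfolds, mm
    "skf_triceps": OutcomeSpec(_hp(17.0, 4.5, 3.0), _hp(9.0, 3.5, 2.0)),
    "skf_subscapular": OutcomeSpec(_hp(13.0, 4.0, 2.5), _hp(10.0, 3.0, 2.0)),
    "skf_biceps": OutcomeSpec(_hp(9.0, 3.0, 2.0), _hp(5.0, 1.8, 1.0)),
    "skf_suprailiac": OutcomeSpec(_hp(14.0, 4.5, 3.0), _hp(9.0, 3.5, 2.0)),
    "skf_abdominal": OutcomeSpec(_hp(20.0, 6.0, 4.0), _hp(14.0, 5.0, 3.0)),
    "skf_thigh": OutcomeSpec(_hp(24.0, 6.0, 4.0), _hp(12.0, 4.5, 3.0)),
    "skf_medial_calf": OutcomeSpec(_hp(13.0, 4.0, 3.0), _hp(7.0, 2.8, 1.8)),
    # circumferences, cm
    "circ_hip": OutcomeSpec(_hp(95.0, 4.5, 2.5), _hp(97.0, 4.5, 2.5)),
    "circ_arm": OutcomeSpec(_hp(26.0, 2.0, 1.2), _hp(31.0, 2.5, 1.5)),
    "circ_midthigh": OutcomeSpec(_hp(55.0, 4.0, 2.0), _hp(56.0, 4.0, 2.0)),
    "circ_calf": OutcomeSpec(_hp(35.0, 2.5, 1.5), _hp(37.0, 2.5, 1.5)),
    "circ_abdominal": OutcomeSpec(_hp(72.0, 5.0, 3.0), _hp(80.0, 6.0, 3.0)),
    # DXA lean soft tissue parts, kg
    "lst_arms": OutcomeSpec(_hp(4.4, 0.6, 0.5), _hp(7.5, 0.9, 0.8)),
    "lst_legs": OutcomeSpec(_hp(15.2, 1.7, 1.3), _hp(21.2, 2.2, 1.8)),
    "lst_trunk": OutcomeSpec(_hp(21.5, 2.2, 1.6), _hp(29.5, 2.8, 2.2)),
    "lst_head": OutcomeSpec(_hp(3.1, 0.25, 0.15), _hp(3.4, 0.28, 0.16)),
    # DXA bone mineral content parts, g
    "bmc_arms": OutcomeSpec(_hp(330.0, 45.0, 35.0), _hp(460.0, 60.0, 45.0)),
    "bmc_legs": OutcomeSpec(_hp(870.0, 110.0, 80.0), _hp(1150.0, 140.0, 100.0)),
    "bmc_trunk": OutcomeSpec(_hp(700.0, 90.0, 65.0), _hp(890.0, 110.0, 80.0)),
    "bmc_head": OutcomeSpec(_hp(450.0, 50.0, 30.0), _hp(520.0, 55.0, 35.0)),
    # DXA fat-mass parts (kg) and whole-body BMD: right-skewed, log scale
    "fm_arms": OutcomeSpec(_log_hp(1.7, 0.30, 0.20), _log_hp(1.1, 0.32, 0.22), log_scale=True),
    "fm_legs": OutcomeSpec(_log_hp(5.8, 0.28, 0.18), _log_hp(3.9, 0.30, 0.20), log_scale=True),
    "fm_trunk": OutcomeSpec(_log_hp(6.2, 0.32, 0.20), _log_hp(5.0, 0.35, 0.22), log_scale=True),
    "fm_head": OutcomeSpec(_log_hp(0.9, 0.15, 0.08), _log_hp(0.9, 0.15, 0.08), log_scale=True),
    "wb_bmd": OutcomeSpec(_log_hp(1.177, 0.06, 0.045), _log_hp(1.291, 0.06, 0.05), log_scale=True),
}


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification for a synthetic athlete dataset.

    ``cells`` follows the packaged design fixture layout (sport, sex,
    n_common, n_weight_height, n_skinfold_circumference, n_dxa);
    ``outcomes`` maps primitive outcome names to :class:`OutcomeSpec`;
    ``dxa_consistent=True`` generates DXA tissue parts and aggregates them
    so the additivity identities hold exactly.
    """

    cells: pd.DataFrame = dc_field(repr=False)
    outcomes: dict = dc_field(repr=False)
    seed: int = 0
    dxa_consistent: bool = True
    age_range: tuple[float, float] = (16.0, 35.0)

    def __post_init__(self) -> None:
        needed = {"sport", "sex", "n_common", "n_weight_height", "n_skinfold_circumference", "n_dxa"}
        missing = needed - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells table missing columns: {sorted(missing)}")
        counts = self.cells[[c for c in self.cells.columns if c.startswith("n_")]]
        if (counts.to_numpy() < 0).any():
            raise ValueError("cell sample sizes must be >= 0")


def default_sim_config(seed: int = 0, cells: Optional[pd.DataFrame] = None) -> SimConfig:
    """Default configuration: study-design cell sizes, emulated outcome
    hyperparameters, exact DXA additivity."""
    return SimConfig(
        cells=load_table1() if cells is None else cells,
        outcomes=dict(_DEFAULT_SPECS),
        seed=seed,
    )


def _draw_group_values(h: Hyperparams, n: int, rng: np.random.Generator, log_scale: bool,
                       floor_frac: float = 0.05) -> np.ndarray:
    """Draw (mu, tau) from the hyperprior, then n Gaussian values.

    Gaussian (non-log) outcomes are physical magnitudes; the rare draw at
    or below ``floor_frac`` times the prior mean is redrawn to keep the
    positivity invariants of the record types.
    """
    tau = rng.gamma(shape=h.alpha0, scale=1.0 / h.beta0)
    mu = rng.normal(h.mu0, 1.0 / math.sqrt(h.kappa0 * tau))
    x = rng.normal(mu, 1.0 / math.sqrt(tau), size=n)
    if log_scale:
        return np.exp(x)
    floor = floor_frac * abs(h.mu0)
    for _ in range(100):
        bad = x <= floor
        if not bad.any():
            break
        x[bad] = rng.normal(mu, 1.0 / math.sqrt(tau), size=int(bad.sum()))
    return np.maximum(x, floor + 1e-9)


def simulate_dataset(config: SimConfig) -> list[AthleteRecord]:
    """Generate a full athlete dataset from a :class:`SimConfig`.

    Per cell, ``n_weight_height`` athletes are created; the skinfold/
    circumference and DXA blocks are assigned to subsets of the requested
    sizes with an overlap as close to ``n_common`` as the sizes allow.
    Reproducible: a fixed config (including seed) yields an identical
    dataset.
    """
    rng = np.random.default_rng(config.seed)
    records: list[AthleteRecord] = []
    cells = config.cells.sort_values(["sport", "sex"]).reset_index(drop=True)
    for _, cell in cells.iterrows():
        sport = Sport(cell["sport"])
        sex = Sex(cell["sex"])
        n = int(cell["n_weight_height"])
        if n == 0:
            continue
        n_skf = min(int(cell["n_skinfold_circumference"]), n)
        n_dxa = min(int(cell["n_dxa"]), n)
        overlap = int(np.clip(int(cell["n_common"]), max(n_skf + n_dxa - n, 0), min(n_skf, n_dxa)))
        draws: dict[str, np.ndarray] = {}
        for name, spec in config.outcomes.items():
            draws[name] = _draw_group_values(spec.for_sex(sex), n, rng, spec.log_scale)
        ages = rng.uniform(*config.age_range, size=n)
        # block assignment: [both] [skf only] [dxa only] [neither]
        has_skf = np.zeros(n, bool)
        has_dxa = np.zeros(n, bool)
        has_skf[:overlap] = True
        has_dxa[:overlap] = True
        has_skf[overlap : overlap + (n_skf - overlap)] = True
        start = overlap + (n_skf - overlap)
        has_dxa[start : start + (n_dxa - overlap)] = True
        for i in range(n):
            skinfolds = circumferences = dxa = None
            if has_skf[i]:
                skinfolds = SkinfoldSet(
                    triceps=draws["skf_triceps"][i],
                    subscapular=draws["skf_subscapular"][i],
                    biceps=draws["skf_biceps"][i],
                    suprailiac=draws["skf_suprailiac"][i],
                    abdominal=draws["skf_abdominal"][i],
                    thigh=draws["skf_thigh"][i],
                    medial_calf=draws["skf_medial_calf"][i],
                )
                circumferences = CircumferenceSet(
                    hip=draws["circ_hip"][i],
                    arm=draws["circ_arm"][i],
                    midthigh=draws["circ_midthigh"][i],
                    calf=draws["circ_calf"][i],
                    abdominal=draws["circ_abdominal"][i],
                )
            if has_dxa[i]:
                parts = {
                    part: RegionTissues(
                        bmc_g=draws[f"bmc_{part}"][i],
                        fm_kg=draws[f"fm_{part}"][i],
                        lst_kg=draws[f"lst_{part}"][i],
                    )
                    for part in ("arms", "legs", "trunk", "head")
                }
                appendicular = parts["arms"] + parts["legs"]
                subtotal = appendicular + parts["trunk"]
                whole = subtotal + parts["head"]
                dxa = DxaScan(
                    whole=whole,
                    subtotal=subtotal,
                    trunk=parts["trunk"],
                    appendicular=appendicular,
                    bmd=draws["wb_bmd"][i],
                    arms=parts["arms"],
                    legs=parts["legs"],
                    head=parts["head"],
                )
            records.append(
                AthleteRecord(
                    id=f"{sport.value}-{sex.value}-{i + 1:03d}",
                    sex=sex,
                    sport=sport,
                    age=float(ages[i]),
                    weight=float(draws["weight_kg"][i]),
                    height=float(draws["height_cm"][i]),
                    skinfolds=skinfolds,
                    circumferences=circumferences,
                    dxa=dxa,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Validation harnesses


def simulate_groups(h: Hyperparams, sizes: Sequence[int], rng: np.random.Generator):
    """Draw one grouped dataset from the hierarchical model.

    Returns ``(summaries, truths)`` where ``truths`` is the list of latent
    (mu, tau) pairs drawn per group.
    """
    summaries = []
    truths = []
    for g, n in enumerate(sizes):
        tau = rng.gamma(shape=h.alpha0, scale=1.0 / h.beta0)
        mu = rng.normal(h.mu0, 1.0 / math.sqrt(h.kappa0 * tau))
        x = rng.normal(mu, 1.0 / math.sqrt(tau), size=int(n))
        summaries.append(summarize_group(x, group=g))
        truths.append((mu, tau))
    return summaries, truths


def draw_sizes_from_table1(
    n_groups: int, rng: np.random.Generator, min_n: int = 2, column: str = "n_weight_height"
) -> np.ndarray:
    """Sample group sizes with replacement from the study-design fixture,
    restricted to cells with at least ``min_n`` athletes."""
    pool = load_table1()[column].to_numpy()
    pool = pool[pool >= min_n]
    return rng.choice(pool, size=n_groups, replace=True)


def recovery_experiment(
    true_params: Hyperparams,
    n_groups: int,
    n_per_group: int,
    replicates: int,
    seed: int = 0,
) -> dict:
    """Repeatedly simulate and refit; summarize hyperparameter recovery.

    For kappa0, alpha0 and beta0 the per-replicate error is the relative
    error |estimate - truth| / truth; for mu0 (whose truth may be zero) the
    error is normalized by the prior SD of the group mean,
    sqrt(beta0 / ((alpha0 - 1) * kappa0)).  Fit failures are counted and
    excluded, never fatal.

    Returns a dict with the per-replicate error frame, per-parameter
    median relative errors, and the failure count.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    mu_scale = math.sqrt(true_params.beta0 / ((true_params.alpha0 - 1.0) * true_params.kappa0))
    rows = []
    failures = 0
    for _ in range(replicates):
        summaries, _ = simulate_groups(true_params, [n_per_group] * n_groups, rng)
        try:
            est = fit_hyperparams(summaries)
        except (FitError, Exception) as exc:  # noqa: BLE001 - recorded, not fatal
            if not isinstance(exc, (FitError, ValueError)):
                raise
            failures += 1
            continue
        rows.append(
            {
                "mu0": abs(est.mu0 - true_params.mu0) / mu_scale,
                "kappa0": abs(est.kappa0 - true_params.kappa0) / true_params.kappa0,
                "alpha0": abs(est.alpha0 - true_params.alpha0) / true_params.alpha0,
                "beta0": abs(est.beta0 - true_params.beta0) / true_params.beta0,
            }
        )
    errors = pd.DataFrame(rows)
    median = errors.median().to_dict() if len(errors) else {}
    return {"errors": errors, "median_relative_error": median, "n_failures": failures}


def coverage_experiment(
    true_params: Hyperparams,
    sizes: Sequence[int],
    replicates: int,
    level: float = 0.95,
    seed: int = 0,
    grid: tuple[int, int] = (100, 100),
    span_sds: float = 6.0,
    percentiles: Sequence[float] = (5.0, 25.0, 50.0, 75.0, 95.0),
    variance_estimator: str = "posterior_mean",
) -> dict:
    """Joint coverage of the HPD region and the simultaneous CIs.

    Per replicate: simulate groups from ``true_params``, refit the
    hyperparameters (full empirical-Bayes pipeline), and for every group
    with n >= 2 record (a) whether the latent (mu, tau) lies inside the
    level-``level`` HPD region and (b) whether all true Gaussian
    percentiles mu + z_p/sqrt(tau) fall inside their simultaneous
    intervals.  Returns both coverage proportions with binomial standard
    errors.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    z = stats.norm.ppf(np.asarray(percentiles, float) / 100.0)
    n_eval = 0
    region_hits = 0
    ci_hits = 0
    fit_failures = 0
    region_failures = 0
    for _ in range(replicates):
        summaries, truths = simulate_groups(true_params, sizes, rng)
        try:
            h = fit_hyperparams(summaries)
        except (FitError, ValueError):
            fit_failures += 1
            continue
        for s, (mu, tau) in zip(summaries, truths):
            if s.n < 2:
                continue
            post = posterior_update(h, s)
            try:
                region = hpd_region(post, level=level, grid=grid, span_sds=span_sds)
            except ResolutionError:
                region_failures += 1
                continue
            n_eval += 1
            if region.contains(mu, tau):
                region_hits += 1
            cis = simultaneous_cis(region, percentiles)
            true_q = mu + z / math.sqrt(tau)
            if all(lo <= q <= hi for (_, lo, hi), q in zip(cis, true_q)):
                ci_hits += 1
    def _prop(hits: int) -> tuple[float, float]:
        if n_eval == 0:
            return float("nan"), float("nan")
        p = hits / n_eval
        return p, math.sqrt(p * (1.0 - p) / n_eval)

    region_cov, region_se = _prop(region_hits)
    ci_cov, ci_se = _prop(ci_hits)
    return {
        "level": level,
        "n_groups_evaluated": n_eval,
        "region_coverage": region_cov,
        "region_se": region_se,
        "ci_coverage": ci_cov,
        "ci_se": ci_se,
        "n_fit_failures": fit_failures,
        "n_region_failures": region_failures,
    }
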