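"""Empirical-Bayes normal–gamma reference percentiles.

Within a group (one sport, one sex), outcome values are modelled as
Gaussian with unknown mean ``mu`` and precision ``tau``.  Across groups the
pair ``(mu, tau)`` is drawn from a conjugate normal–gamma prior

    tau ~ Gamma(alpha0, rate=beta0),   mu | tau ~ N(mu0, 1/(kappa0 * tau)),

whose hyperparameters are estimated by maximising the marginal likelihood
of all groups (empirical Bayes).  Small groups are thereby shrunk toward
the pooled behaviour of the other groups, with ``kappa0`` acting as the
effective prior weight measured in persons.

Per group, the conjugate posterior is again normal–gamma; reference
percentiles (5/25/50/75/95) follow from the plug-in Gaussian quantile
``mu_n + z_p * sigma_hat``, and *simultaneous* confidence intervals are
obtained by extremising the quantile function over a joint
highest-posterior-density (HPD) region for ``(mu, tau)``.

Right-skewed outcomes are log-transformed before fitting and the resulting
percentile points and interval endpoints are exponentiated back, which is
exact for quantiles (monotone transform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, polygamma, psi
from sklearn.base import BaseEstimator

from .anthropometry import is_log_scale

__all__ = [
    "GroupSummary",
    "Hyperparams",
    "Posterior",
    "JointRegion",
    "PercentileEstimate",
    "ReferenceTable",
    "SharingRuleError",
    "FitError",
    "ResolutionError",
    "summarize_group",
    "log_marginal",
    "fit_hyperparams",
    "posterior_update",
    "point_percentiles",
    "hpd_region",
    "simultaneous_cis",
    "build_reference_table",
    "locate_in_reference",
    "LocateResult",
    "NormalGammaReferenceModel",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0)


class SharingRuleError(ValueError):
    """A group (or dataset) has too few observations to share information."""


class FitError(RuntimeError):
    """Hyperparameter maximum-likelihood estimation failed."""


class ResolutionError(RuntimeError):
    """The HPD grid cannot represent the requested probability mass."""


# ---------------------------------------------------------------------------
# Sufficient statistics and hyperparameters


@dataclass(frozen=True)
class GroupSummary:
    """Gaussian sufficient statistics for one group.

    ``ss`` is the sum of squared deviations about the group mean; for
    ``n <= 1`` it is zero and for ``n == 0`` the mean is NaN.
    """

    group: object
    n: int
    mean: float
    ss: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.ss < -1e-12:
            raise ValueError("ss must be >= 0")
        if self.n <= 1 and abs(self.ss) > 1e-9:
            raise ValueError("ss must be 0 when n <= 1")


def summarize_group(values: Iterable[float], group: object = None) -> GroupSummary:
    """Two-pass sufficient statistics (n, mean, centred sum of squares)."""
    x = np.asarray(list(values), dtype=float)
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = int(x.size)
    if n == 0:
        return GroupSummary(group=group, n=0, mean=float("nan"), ss=0.0)
    mean = float(x.mean())
    ss = float(np.sum((x - mean) ** 2))
    if n == 1:
        ss = 0.0
    return GroupSummary(group=group, n=n, mean=mean, ss=ss)


@dataclass(frozen=True)
class Hyperparams:
    """Normal–gamma prior: mu0 (location), kappa0 (pseudo-observations for
    the mean), alpha0 (shape) and beta0 (rate, outcome units²)."""

    mu0: float
    kappa0: float
    alpha0: float
    beta0: float

    def __post_init__(self) -> None:
        for name in ("kappa0", "alpha0", "beta0"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not math.isfinite(self.mu0):
            raise ValueError("mu0 must be finite")


@dataclass(frozen=True)
class Posterior:
    """Conjugate normal–gamma posterior for one group."""

    group: object
    n: int
    mu_n: float
    kappa_n: float
    alpha_n: float
    beta_n: float


# ---------------------------------------------------------------------------
# Marginal likelihood and empirical-Bayes fit


def _summaries_to_arrays(summaries: Iterable[GroupSummary]):
    s = list(summaries)
    n = np.array([g.n for g in s], dtype=float)
    mean = np.array([g.mean for g in s], dtype=float)
    ss = np.array([g.ss for g in s], dtype=float)
    return n, mean, ss


def _log_marginal_arrays(mu0, kappa0, alpha0, beta0, n, mean, ss) -> float:
    """Closed-form sum of per-group log marginal likelihoods.

    Integrating (mu, tau) out of the Gaussian likelihood under the
    normal–gamma prior gives, per group,

        log Gamma(alpha_n) - log Gamma(alpha0) + alpha0*log(beta0)
        - alpha_n*log(beta_n) + (log(kappa0) - log(kappa_n))/2
        - (n/2)*log(2*pi),

    with the conjugate-updated (kappa_n, alpha_n, beta_n).  Empty groups
    contribute zero.
    """
    mask = n > 0
    if not np.any(mask):
        return 0.0
    n = n[mask]
    mean = mean[mask]
    ss = ss[mask]
    kappa_n = kappa0 + n
    alpha_n = alpha0 + n / 2.0
    beta_n = beta0 + ss / 2.0 + kappa0 * n * (mean - mu0) ** 2 / (2.0 * kappa_n)
    per_group = (
        gammaln(alpha_n)
        - gammaln(alpha0)
        + alpha0 * np.log(beta0)
        - alpha_n * np.log(beta_n)
        + 0.5 * (np.log(kappa0) - np.log(kappa_n))
        - (n / 2.0) * np.log(2.0 * np.pi)
    )
    return float(np.sum(per_group))


def log_marginal(h: Hyperparams, summaries: Iterable[GroupSummary]) -> float:
    """Log marginal likelihood of grouped data under a normal–gamma prior."""
    n, mean, ss = _summaries_to_arrays(summaries)
    return _log_marginal_arrays(h.mu0, h.kappa0, h.alpha0, h.beta0, n, mean, ss)


def _moment_init(n, mean, ss) -> np.ndarray:
    """Method-of-moments starting point on the optimisation scale
    (mu0, log kappa0, log alpha0, log beta0)."""
    obs = n >= 1
    mu0 = float(np.average(mean[obs], weights=n[obs]))
    multi = n >= 2
    s2 = ss[multi] / (n[multi] - 1.0)
    m = float(np.mean(s2))
    if m <= 0:
        m = 1e-6
    v = float(np.var(s2)) if s2.size >= 2 else (m / 2.0) ** 2
    v = max(v, 1e-12 * m * m)
    alpha0 = float(np.clip(2.0 + m * m / v, 1.2, 50.0))
    beta0 = m * (alpha0 - 1.0)
    var_means = float(np.var(mean[obs])) if obs.sum() >= 2 else m
    n_bar = float(np.mean(n[obs]))
    between = max(var_means - m / n_bar, m * 1e-3)
    kappa0 = float(np.clip(m / between, 1e-3, 1e3))
    return np.array([mu0, math.log(kappa0), math.log(alpha0), math.log(beta0)])


def fit_hyperparams(
    summaries: Iterable[GroupSummary],
    options: Optional[Mapping] = None,
) -> Hyperparams:
    """Maximum marginal-likelihood (empirical-Bayes) hyperparameters.

    Optimises ``(mu0, log kappa0, log alpha0, log beta0)`` with a
    derivative-free Nelder–Mead simplex started from method-of-moments
    values; the log scale enforces positivity.  The initial simplex uses
    absolute steps whose sizes depend only on shift-invariant data features,
    so translating every observation by a constant translates the fitted
    ``mu0`` by exactly that constant.

    The shape and weight parameters are kept in a wide box
    (``alpha0 <= 500``, ``1e-6 <= kappa0 <= 1e6``) via a smooth quadratic
    penalty: with few groups the marginal likelihood can increase
    monotonically toward the degenerate equal-variance limit
    ``alpha0 -> inf`` (an improper boundary MLE), and the cap makes that
    limit a well-defined fitted point, exactly as shape caps do in
    variance-moderation software.

    Raises
    ------
    SharingRuleError
        Fewer than 2 observed groups, or no group with n >= 2.
    FitError
        Degenerate data (zero spread) or optimizer non-convergence.
    """
    opts = dict(options or {})
    fatol = opts.pop("fatol", 1e-8)
    xatol = opts.pop("xatol", 1e-8)
    maxiter = opts.pop("maxiter", 5000)
    if opts:
        raise TypeError(f"unknown optimizer options: {sorted(opts)}")

    n, mean, ss = _summaries_to_arrays(summaries)
    if np.sum(n >= 1) < 2:
        raise SharingRuleError("need at least 2 groups with n >= 1 to fit hyperparameters")
    if np.sum(n >= 2) < 1:
        raise SharingRuleError("need at least one group with n >= 2 (beta0 unidentifiable)")
    total_spread = float(np.sum(ss)) + (float(np.var(mean[n >= 1])) if np.sum(n >= 1) > 1 else 0.0)
    if total_spread <= 0:
        raise FitError("degenerate data: all observed values are identical")

    x0 = _moment_init(n, mean, ss)

    lo = np.array([-np.inf, math.log(1e-6), math.log(1.02), -250.0])
    hi = np.array([np.inf, math.log(1e6), math.log(500.0), 250.0])

    def neg_loglik(theta: np.ndarray) -> float:
        clipped = np.clip(theta, lo, hi)
        penalty = 1e4 * float(np.sum((theta - clipped) ** 2))
        mu0, lk, la, lb = clipped
        val = _log_marginal_arrays(mu0, math.exp(lk), math.exp(la), math.exp(lb), n, mean, ss)
        return np.inf if not np.isfinite(val) else -val + penalty

    # absolute-step initial simplex: the mu0 step scales with the pooled
    # within-group SD (shift-invariant), log-parameter steps are fixed
    pooled_sd = math.sqrt(max(float(np.sum(ss)) / max(float(np.sum(n[n >= 2] - 1)), 1.0), 1e-12))
    steps = np.array([max(0.5 * pooled_sd, 1e-3), 0.35, 0.35, 0.35])
    simplex = np.vstack([x0] + [x0 + steps[i] * np.eye(4)[i] for i in range(4)])

    res = optimize.minimize(
        neg_loglik,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "fatol": fatol,
            "xatol": xatol,
            "maxiter": maxiter,
            "maxfev": 4 * maxiter,
        },
    )
    if not res.success or not np.isfinite(res.fun):
        raise FitError(
            f"hyperparameter fit did not converge: {res.message} "
            f"(nit={res.nit}, nfev={res.nfev}, f={res.fun!r})"
        )
    mu0, lk, la, lb = np.clip(res.x, lo, hi)
    return Hyperparams(mu0=float(mu0), kappa0=math.exp(lk), alpha0=math.exp(la), beta0=math.exp(lb))


# ---------------------------------------------------------------------------
# Conjugate posterior and percentile point estimates


def posterior_update(h: Hyperparams, s: GroupSummary) -> Posterior:
    """Conjugate normal–gamma update for one group (requires n >= 2).

    The n >= 2 sharing rule mirrors the reference analysis: information is
    borrowed across groups only where at least two athletes were measured.
    """
    if s.n < 2:
        raise SharingRuleError(
            f"group {s.group!r} has n={s.n} < 2; the sharing rule requires at "
            "least two measured athletes"
        )
    kappa_n = h.kappa0 + s.n
    mu_n = (h.kappa0 * h.mu0 + s.n * s.mean) / kappa_n
    alpha_n = h.alpha0 + s.n / 2.0
    beta_n = h.beta0 + s.ss / 2.0 + h.kappa0 * s.n * (s.mean - h.mu0) ** 2 / (2.0 * kappa_n)
    return Posterior(group=s.group, n=s.n, mu_n=mu_n, kappa_n=kappa_n, alpha_n=alpha_n, beta_n=beta_n)


def _sigma_hat(post: Posterior, variance_estimator: str) -> float:
    if variance_estimator == "posterior_mean":
        if post.alpha_n <= 1:
            raise ValueError(
                f"alpha_n={post.alpha_n:.3g} <= 1: the posterior-mean variance is "
                "undefined; use a larger group or a stronger prior (or the "
                "'inverse_mean_precision' estimator)"
            )
        return math.sqrt(post.beta_n / (post.alpha_n - 1.0))
    if variance_estimator == "inverse_mean_precision":
        return math.sqrt(post.beta_n / post.alpha_n)
    raise ValueError(f"unknown variance_estimator {variance_estimator!r}")


def point_percentiles(
    post: Posterior,
    probs: Sequence[float] = DEFAULT_PERCENTILES,
    variance_estimator: str = "posterior_mean",
) -> list[tuple[float, float]]:
    """Plug-in Gaussian percentile points mu_n + z_p * sigma_hat.

    ``sigma_hat**2`` defaults to the posterior mean of the variance,
    beta_n/(alpha_n - 1); ``inverse_mean_precision`` uses beta_n/alpha_n.
    Ranks are given in percent (e.g. 5, 25, 50, 75, 95).
    """
    sigma = _sigma_hat(post, variance_estimator)
    out = []
    for p in probs:
        if not 0 < p < 100:
            raise ValueError(f"percentile rank must be in (0, 100), got {p}")
        z = stats.norm.ppf(p / 100.0)
        out.append((float(p), post.mu_n + z * sigma))
    return out


# ---------------------------------------------------------------------------
# Joint HPD region and simultaneous CIs


@dataclass(frozen=True)
class JointRegion:
    """Grid representation of an HPD set for (mean, precision).

    The grid lives on (mu, log tau); ``mask`` flags cells whose posterior
    density reaches ``log_threshold``, and ``contained_mass`` is the
    probability the flagged cells enclose (midpoint rule).
    """

    post: Posterior
    level: float
    mu: np.ndarray  # (n_mu,)
    log_tau: np.ndarray  # (n_tau,)
    log_density: np.ndarray  # (n_mu, n_tau), density of (mu, log tau)
    log_threshold: float
    mask: np.ndarray  # (n_mu, n_tau) boolean
    contained_mass: float

    def log_density_at(self, mu, tau):
        """Analytic log density of the posterior in (mu, log tau) coords."""
        return _ng_logpdf_mu_logtau(self.post, np.asarray(mu, float), np.log(np.asarray(tau, float)))

    def contains(self, mu: float, tau: float) -> bool:
        """Whether the point (mu, tau) lies inside the HPD set."""
        return bool(self.log_density_at(mu, tau) >= self.log_threshold)


def _ng_logpdf_mu_logtau(post: Posterior, mu, log_tau):
    """Log density of the normal–gamma posterior in (mu, u=log tau)
    coordinates (includes the Jacobian tau)."""
    tau = np.exp(log_tau)
    return (
        0.5 * (math.log(post.kappa_n) - math.log(2.0 * math.pi))
        + post.alpha_n * math.log(post.beta_n)
        - gammaln(post.alpha_n)
        + (post.alpha_n + 0.5) * log_tau
        - tau * (post.beta_n + post.kappa_n * (mu - post.mu_n) ** 2 / 2.0)
    )


def _marginal_scales(post: Posterior) -> tuple[float, float, float, float]:
    """Centres and SDs of the marginal posteriors of mu and log tau."""
    df = 2.0 * post.alpha_n
    scale = math.sqrt(post.beta_n / (post.alpha_n * post.kappa_n))
    mu_sd = scale * math.sqrt(df / (df - 2.0)) if df > 2.0 else 3.0 * scale
    lt_mean = psi(post.alpha_n) - math.log(post.beta_n)
    lt_sd = math.sqrt(float(polygamma(1, post.alpha_n)))
    return post.mu_n, mu_sd, lt_mean, lt_sd


def hpd_region(
    post: Posterior,
    level: float = 0.95,
    grid: tuple[int, int] = (200, 200),
    span_sds: float = 6.0,
    mass_tol: float = 0.005,
) -> JointRegion:
    """Highest-posterior-density set for (mean, precision) on a grid.

    The grid spans ``span_sds`` marginal posterior SDs around the centre in
    each of (mu, log tau); cells are sorted by density and accumulated until
    ``level`` mass is enclosed.  Raises :class:`ResolutionError` if the grid
    cannot represent the requested mass to within ``mass_tol``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    n_mu, n_lt = grid
    if n_mu < 50 or n_lt < 50:
        raise ValueError("grid resolution must be at least 50x50")
    mu_c, mu_sd, lt_c, lt_sd = _marginal_scales(post)
    mu = np.linspace(mu_c - span_sds * mu_sd, mu_c + span_sds * mu_sd, n_mu)
    lt = np.linspace(lt_c - span_sds * lt_sd, lt_c + span_sds * lt_sd, n_lt)
    cell = (mu[1] - mu[0]) * (lt[1] - lt[0])
    logd = _ng_logpdf_mu_logtau(post, mu[:, None], lt[None, :])
    d = np.exp(logd)
    masses = d.ravel() * cell
    order = np.argsort(masses)[::-1]
    cum = np.cumsum(masses[order])
    total = cum[-1]
    if total < level:
        raise ResolutionError(
            f"grid encloses only {total:.4f} total mass < level {level}; "
            "increase span_sds or grid resolution"
        )
    k = int(np.searchsorted(cum, level))
    contained = float(cum[k])
    if contained - level > mass_tol:
        raise ResolutionError(
            f"grid too coarse: smallest enclosing mass {contained:.4f} exceeds "
            f"level {level} by more than {mass_tol}"
        )
    log_threshold = float(logd.ravel()[order[k]])
    mask = logd >= log_threshold
    return JointRegion(
        post=post,
        level=level,
        mu=mu,
        log_tau=lt,
        log_density=logd,
        log_threshold=log_threshold,
        mask=mask,
        contained_mass=contained,
    )


def simultaneous_cis(
    region: JointRegion, probs: Sequence[float] = DEFAULT_PERCENTILES
) -> list[tuple[float, float, float]]:
    """Simultaneous CI bounds for Gaussian percentiles.

    For each rank p, the bound pair is the minimum and maximum of
    ``mu + z_p / sqrt(tau)`` over every grid point inside the joint HPD
    region; because all ranks share one region, the intervals hold
    simultaneously at the region's level.
    """
    if not region.mask.any():
        raise RuntimeError("empty HPD region")
    ii, jj = np.nonzero(region.mask)
    mu = region.mu[ii]
    inv_sqrt_tau = np.exp(-0.5 * region.log_tau[jj])
    out = []
    for p in probs:
        z = stats.norm.ppf(float(p) / 100.0)
        q = mu + z * inv_sqrt_tau
        out.append((float(p), float(q.min()), float(q.max())))
    return out


# ---------------------------------------------------------------------------
# Reference tables


@dataclass(frozen=True)
class PercentileEstimate:
    p: float
    point: float
    lo: float
    hi: float
    reported: bool


@dataclass(frozen=True)
class ReferenceTable:
    """Per-group percentile estimates for one outcome and sex.

    ``estimates`` is a long DataFrame (sport, n, p, point, lo, hi,
    reported); groups with n below the sharing threshold are absent, and
    groups with n below the reporting threshold carry ``reported=False``.
    ``prior_weight`` is kappa0, the prior's effective weight in persons.
    """

    outcome: str
    sex: Optional[str]
    log_scale: bool
    hyperparams: Hyperparams
    estimates: pd.DataFrame = field(repr=False)

    @property
    def prior_weight(self) -> float:
        return self.hyperparams.kappa0

    def row(self, group) -> dict[float, float]:
        """Percentile rank -> point mapping for one group."""
        sub = self.estimates[self.estimates["sport"] == group]
        if sub.empty:
            raise KeyError(f"group {group!r} not in table")
        return dict(zip(sub["p"], sub["point"]))


def build_reference_table(
    data: pd.DataFrame,
    outcome: str,
    sex: Optional[str] = None,
    *,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    log_scale: Optional[bool] = None,
    min_share: int = 2,
    min_report: int = 8,
    level: float = 0.95,
    grid: tuple[int, int] = (200, 200),
    span_sds: float = 6.0,
    variance_estimator: str = "posterior_mean",
    group_col: str = "sport",
) -> ReferenceTable:
    """Fit the empirical-Bayes model and tabulate reference percentiles.

    Parameters
    ----------
    data : DataFrame
        Must contain ``group_col`` and ``outcome`` columns (and ``sex`` if a
        sex filter is given); NaN outcome values are treated as unmeasured.
    outcome : str
        Column to analyse.  When ``log_scale`` is None the catalogue decides
        whether the outcome is modelled on the log scale.
    sex : str, optional
        Restrict to one sex before fitting ("female"/"male").

    The pipeline: optional log transform; per-group sufficient statistics;
    empirical-Bayes hyperparameter fit over all observed groups; for every
    group with ``n >= min_share`` a conjugate posterior, plug-in percentile
    points, an HPD region at ``level`` and simultaneous CIs; back-transform
    for log-scale outcomes; ``reported=False`` where ``n < min_report``.
    """
    if min_share < 2:
        raise ValueError("min_share must be >= 2")
    if min_report < min_share:
        raise ValueError("min_report must be >= min_share")
    df = data
    if sex is not None:
        df = df[df["sex"].astype(str) == str(sex)]
    use_log = is_log_scale(outcome) if log_scale is None else bool(log_scale)
    values = pd.to_numeric(df[outcome], errors="coerce")
    measured = df.loc[values.notna()].assign(_value=values[values.notna()].astype(float))
    if use_log:
        if (measured["_value"] <= 0).any():
            raise ValueError(
                f"outcome {outcome!r} is analysed on the log scale but has "
                "non-positive values"
            )
        measured = measured.assign(_value=np.log(measured["_value"]))
    summaries = [
        summarize_group(g["_value"].to_numpy(), group=name)
        for name, g in measured.groupby(group_col, observed=True)
    ]
    if sum(1 for s in summaries if s.n >= 1) < 2:
        raise SharingRuleError(
            f"outcome {outcome!r}: fewer than 2 groups with measured values; "
            "cannot share information across groups"
        )
    h = fit_hyperparams(summaries)
    rows = []
    for s in summaries:
        if s.n < min_share:
            continue
        post = posterior_update(h, s)
        points = dict(point_percentiles(post, percentiles, variance_estimator))
        region = hpd_region(post, level=level, grid=grid, span_sds=span_sds)
        cis = {p: (lo, hi) for p, lo, hi in simultaneous_cis(region, percentiles)}
        for p in percentiles:
            point, (lo, hi) = points[p], cis[p]
            if use_log:
                point, lo, hi = math.exp(point), math.exp(lo), math.exp(hi)
            rows.append(
                {
                    "sport": s.group,
                    "n": s.n,
                    "p": float(p),
                    "point": point,
                    "lo": lo,
                    "hi": hi,
                    "reported": s.n >= min_report,
                }
            )
    estimates = pd.DataFrame(
        rows, columns=["sport", "n", "p", "point", "lo", "hi", "reported"]
    )
    return ReferenceTable(
        outcome=outcome, sex=sex, log_scale=use_log, hyperparams=h, estimates=estimates
    )


@dataclass(frozen=True)
class LocateResult:
    """Where a measurement sits in a group's reference percentiles.

    ``band`` is "<5"-style text below/above the tabulated range or
    "p25-p50"-style inside it; ``nearest`` is the tabulated rank whose point
    estimate is closest on the outcome scale (None outside the range).
    """

    band: str
    bracket: Optional[tuple[float, float]]
    nearest: Optional[float]


def locate_in_reference(value: float, table_row: Mapping[float, float]) -> LocateResult:
    """Classify a measurement against one group's percentile points.

    ``table_row`` maps percentile rank to point estimate and must be
    monotone nondecreasing in rank.
    """
    ranks = sorted(float(p) for p in table_row)
    points = [float(table_row[p]) for p in ranks]
    if len(ranks) < 2:
        raise ValueError("need at least two percentile points")
    if any(b < a for a, b in zip(points, points[1:])):
        raise ValueError("percentile points must be monotone nondecreasing in rank")
    fmt = lambda p: f"{p:g}"
    if value < points[0]:
        return LocateResult(band=f"<{fmt(ranks[0])}", bracket=None, nearest=None)
    if value > points[-1]:
        return LocateResult(band=f">{fmt(ranks[-1])}", bracket=None, nearest=None)
    for (p_lo, x_lo), (p_hi, x_hi) in zip(zip(ranks, points), zip(ranks[1:], points[1:])):
        if x_lo <= value <= x_hi:
            nearest = p_lo if abs(value - x_lo) <= abs(value - x_hi) else p_hi
            return LocateResult(
                band=f"p{fmt(p_lo)}-p{fmt(p_hi)}", bracket=(p_lo, p_hi), nearest=nearest
            )
    raise AssertionError("unreachable: value within range must fall in a bracket")


# ---------------------------------------------------------------------------
# scikit-learn style estimator


class NormalGammaReferenceModel(BaseEstimator):
    """Empirical-Bayes normal–gamma reference-percentile estimator.

    Fit on a vector of outcome values ``X`` with group labels ``y``
    (sport identifiers); exposes per-group reference percentiles with
    simultaneous confidence intervals and classifies new measurements
    against them.

    Parameters
    ----------
    percentiles : sequence of float
        Reference ranks in percent (default 5/25/50/75/95).
    log_scale : bool
        Model values on the natural-log scale and back-transform results.
    min_share, min_report : int
        Sharing (posterior computed) and reporting (estimates displayed)
        sample-size gates.
    level : float
        Joint HPD / simultaneous CI level.
    grid : (int, int)
        HPD grid resolution over (mean, log precision).
    span_sds : float
        Half-width of the HPD grid in marginal posterior SDs.
    variance_estimator : str
        "posterior_mean" (beta_n/(alpha_n-1)) or "inverse_mean_precision"
        (beta_n/alpha_n) for the plug-in within-group variance.

    Attributes
    ----------
    hyperparams_ : Hyperparams
        Fitted empirical-Bayes prior.
    posteriors_ : dict
        Group label -> :class:`Posterior` for groups passing ``min_share``.
    reference_ : DataFrame
        Long-format table (sport, n, p, point, lo, hi, reported).
    prior_weight_ : float
        kappa0, the prior's effective weight in persons.
    """

    def __init__(
        self,
        percentiles: Sequence[float] = DEFAULT_PERCENTILES,
        log_scale: bool = False,
        min_share: int = 2,
        min_report: int = 8,
        level: float = 0.95,
        grid: tuple[int, int] = (200, 200),
        span_sds: float = 6.0,
        variance_estimator: str = "posterior_mean",
    ):
        self.percentiles = percentiles
        self.log_scale = log_scale
        self.min_share = min_share
        self.min_report = min_report
        self.level = level
        self.grid = grid
        self.span_sds = span_sds
        self.variance_estimator = variance_estimator

    def fit(self, X, y):
        """Fit on outcome values X (n_samples,) with group labels y."""
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y).reshape(-1)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same length")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        data = pd.DataFrame({"sport": y, "_outcome": X})
        table = build_reference_table(
            data,
            "_outcome",
            percentiles=self.percentiles,
            log_scale=self.log_scale,
            min_share=self.min_share,
            min_report=self.min_report,
            level=self.level,
            grid=self.grid,
            span_sds=self.span_sds,
            variance_estimator=self.variance_estimator,
        )
        self.table_ = table
        self.hyperparams_ = table.hyperparams
        self.reference_ = table.estimates
        self.prior_weight_ = table.prior_weight
        vals = np.log(X) if self.log_scale else X
        self.posteriors_ = {}
        for g in pd.unique(y):
            s = summarize_group(vals[y == g], group=g)
            if s.n >= self.min_share:
                self.posteriors_[g] = posterior_update(self.hyperparams_, s)
        self.n_features_in_ = 1
        return self

    def predict(self, X, groups):
        """Nearest reference rank for each (value, group) pair.

        Returns NaN where the value falls outside the tabulated range or
        the group has no reference row.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "reference_")
        X = np.asarray(X, dtype=float).reshape(-1)
        groups = np.asarray(groups).reshape(-1)
        out = np.full(X.shape, np.nan)
        for i, (v, g) in enumerate(zip(X, groups)):
            try:
                res = locate_in_reference(v, self.table_.row(g))
            except KeyError:
                continue
            if res.nearest is not None:
                out[i] = res.nearest
        return out

    def locate(self, value: float, group) -> LocateResult:
        """Full band/bracket/nearest classification for one measurement."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "reference_")
        return locate_in_reference(value, self.table_.row(group))
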