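"""Two-step three-state chemical-denaturation analysis.

The unfolding of serum albumin by urea proceeds through a populated
intermediate, N = I = U, and each step is analyzed as an independent
two-state equilibrium.  The workflow is

1. fit linear state baselines yN, yI, yU over user-supplied pre-,
   intermediate- and post-transition windows (``fit_baselines``);
2. convert the signal inside each transition zone into a fraction via the
   baseline chords, f_I = (y1 - yN)/(yI - yN), f_U = (y2 - yI)/(yU - yI)
   (``state_fractions``);
3. either transform fractions in the band [0.05, 0.95] to per-point free
   energies dG = -RT ln(f/(1-f)) and fit the linear extrapolation model
   dG(u) = dG_H2O - m*u by OLS (``fit_lem``), or fit the logistic
   f(u) = 1/(1 + exp((dG_H2O - m*u)/(RT))) directly in fraction space
   (``fit_nonlinear``);
4. compare ligand-free and ligand-bound totals to get the stabilization
   ddG_H2O (``compare_stability``).

Baselines are extrapolated as fitted lines, not plateau constants, into the
transition zones; sloped native baselines are the norm for albumin
fluorescence.  Transition-1 fractions live on the open interval between the
native and intermediate windows, transition-2 fractions between the
intermediate and unfolded windows; the intermediate baseline serves as the
native side of I = U.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .constants import DEFAULT_REGIONS, R_GAS, T_DEFAULT_K
from .exceptions import (
    DataValidationError,
    DegenerateBaselineError,
    FitConvergenceError,
    InsufficientDataError,
)
from .io_spectra import UnfoldingProfile

#: Fractions outside this band are excluded from the per-point dG transform
#: (the log-ratio diverges at 0 and 1).
FRACTION_BAND = (0.05, 0.95)

#: Reporting range for computed fractions; points outside are clamped and flagged.
FRACTION_REPORT_RANGE = (-0.05, 1.05)


class Transition(str, enum.Enum):
    N_TO_I = "N_to_I"
    I_TO_U = "I_to_U"


class FitMethod(str, enum.Enum):
    LINEAR_LEM = "linear_LEM"
    NONLINEAR = "nonlinear"


@dataclass(frozen=True)
class BaselineSet:
    """Linear baselines of the N, I and U states over their windows.

    Regions are (min_M, max_M) denaturant windows, ordered N < I < U and
    non-overlapping; lines are (intercept, slope) of signal vs denaturant.
    ``cov_n/i/u`` hold the OLS parameter covariance of each line as
    (var_intercept, var_slope, cov_intercept_slope); ``noise_sd_rel`` is the
    pooled relative residual standard deviation across the three windows
    (an estimate of the multiplicative measurement noise).  Both feed the
    error propagation of the downstream fraction transforms.
    """

    region_n: tuple[float, float]
    region_i: tuple[float, float]
    region_u: tuple[float, float]
    line_n: tuple[float, float]
    line_i: tuple[float, float]
    line_u: tuple[float, float]
    cov_n: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cov_i: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cov_u: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd_rel: float = 0.0

    def __post_init__(self) -> None:
        regions = [tuple(map(float, r)) for r in
                   (self.region_n, self.region_i, self.region_u)]
        for (lo, hi), name in zip(regions, "NIU"):
            if not lo < hi:
                raise DataValidationError(f"region {name}: min must be < max")
        if not (regions[0][1] <= regions[1][0] and regions[1][1] <= regions[2][0]):
            raise DataValidationError("baseline windows must be ordered N < I < U "
                                      "and non-overlapping")
        object.__setattr__(self, "region_n", regions[0])
        object.__setattr__(self, "region_i", regions[1])
        object.__setattr__(self, "region_u", regions[2])
        for name in ("line_n", "line_i", "line_u", "cov_n", "cov_i", "cov_u"):
            object.__setattr__(self, name, tuple(map(float, getattr(self, name))))

    def y_n(self, u: np.ndarray) -> np.ndarray:
        return self.line_n[0] + self.line_n[1] * np.asarray(u, dtype=float)

    def y_i(self, u: np.ndarray) -> np.ndarray:
        return self.line_i[0] + self.line_i[1] * np.asarray(u, dtype=float)

    def y_u(self, u: np.ndarray) -> np.ndarray:
        return self.line_u[0] + self.line_u[1] * np.asarray(u, dtype=float)

    @staticmethod
    def _prediction_cov(cov: tuple[float, float, float],
                        u: np.ndarray) -> np.ndarray:
        """Covariance matrix of the extrapolated line values at ``u``."""
        var_a, var_b, cov_ab = cov
        u = np.asarray(u, dtype=float)
        return (var_a + np.outer(u, u) * var_b
                + np.add.outer(u, u) * cov_ab)


@dataclass(frozen=True)
class StateFractions:
    """Per-point state fraction over one transition zone.

    ``flagged`` indexes points whose raw fraction fell outside the reporting
    range [-0.05, 1.05] before clamping.
    """

    transition: Transition
    denaturant_M: tuple[float, ...]
    fraction: tuple[float, ...]
    flagged: tuple[int, ...]
    temperature_K: float = T_DEFAULT_K
    #: optional covariance of the fractions (measurement noise plus shared
    #: baseline-extrapolation error); used for fit standard errors
    fraction_cov: Optional[np.ndarray] = field(default=None, repr=False,
                                               compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "transition", Transition(self.transition))
        object.__setattr__(self, "denaturant_M", tuple(map(float, self.denaturant_M)))
        object.__setattr__(self, "fraction", tuple(map(float, self.fraction)))
        object.__setattr__(self, "flagged", tuple(map(int, self.flagged)))


@dataclass(frozen=True)
class FreeEnergySeries:
    """Per-point unfolding free energies over one transition zone (J/mol)."""

    transition: Transition
    denaturant_M: tuple[float, ...]
    dg_J_per_mol: tuple[float, ...]
    n_excluded: int
    temperature_K: float = T_DEFAULT_K
    dg_cov: Optional[np.ndarray] = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class TransitionFit:
    """dG_H2O (J/mol), m-value (J/mol/M) and midpoint of one transition.

    ``midpoint_M`` is derived exactly as dG_H2O/m.
    """

    dg_h2o_J_per_mol: float
    m_J_per_mol_per_M: float
    stderr_dg: float
    stderr_m: float
    method: FitMethod
    transition: Transition
    n_points: int = 0
    r_squared: float = float("nan")
    midpoint_M: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", FitMethod(self.method))
        object.__setattr__(self, "transition", Transition(self.transition))
        object.__setattr__(self, "midpoint_M",
                           self.dg_h2o_J_per_mol / self.m_J_per_mol_per_M)


@dataclass(frozen=True)
class UnfoldingFitSet:
    """All transition fits obtained from one profile."""

    fits: tuple[TransitionFit, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "fits", tuple(self.fits))

    def get(self, method: FitMethod | str, transition: Transition | str) -> TransitionFit:
        method, transition = FitMethod(method), Transition(transition)
        for f in self.fits:
            if f.method == method and f.transition == transition:
                return f
        raise KeyError(f"no fit for {method.value}/{transition.value}")

    def pair(self, method: FitMethod | str) -> tuple[TransitionFit, TransitionFit]:
        return (self.get(method, Transition.N_TO_I), self.get(method, Transition.I_TO_U))


@dataclass(frozen=True)
class StabilityComparison:
    """Ligand-induced stabilization: totals over both transitions and their
    difference, ddG_H2O = total_complex - total_apo (exact arithmetic)."""

    total_dg_h2o_apo_J_per_mol: float
    total_dg_h2o_complex_J_per_mol: float
    per_transition_ddg_J_per_mol: dict[str, float]
    method: FitMethod
    ddg_h2o_J_per_mol: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", FitMethod(self.method))
        object.__setattr__(
            self, "ddg_h2o_J_per_mol",
            self.total_dg_h2o_complex_J_per_mol - self.total_dg_h2o_apo_J_per_mol,
        )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class LinearExtrapolationRegression(RegressorMixin, BaseEstimator):
    """OLS of per-point dG on denaturant concentration (the LEM line).

    fit(X, y): X is the (n, 1) denaturant column (mol/L), y the per-point
    free energies (J/mol).  Attributes: ``dg_h2o_`` (intercept, J/mol),
    ``m_`` (= -slope, J/mol/M), ``midpoint_``, ``stderr_dg_``, ``stderr_m_``,
    ``r_squared_``.
    """

    def fit(self, X, y):
        X = check_array(X, ensure_2d=True)
        y = np.asarray(y, dtype=float)
        u = X[:, 0]
        if u.size < 3:
            raise InsufficientDataError("need >= 3 per-point dG values for the LEM fit")
        res = stats.linregress(u, y)
        self.dg_h2o_ = float(res.intercept)
        self.m_ = -float(res.slope)
        self.midpoint_ = self.dg_h2o_ / self.m_
        self.stderr_dg_ = float(res.intercept_stderr)
        self.stderr_m_ = float(res.stderr)
        self.r_squared_ = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "dg_h2o_")
        X = check_array(X, ensure_2d=True)
        return self.dg_h2o_ - self.m_ * X[:, 0]


def _logistic_fraction(u: np.ndarray, dg: float, m: float, rt: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((dg - m * u) / rt))


class TwoStateDenaturationCurve(RegressorMixin, BaseEstimator):
    """Nonlinear two-state fit of fraction denatured vs denaturant.

    Model: f(u) = 1/(1 + exp((dG_H2O - m*u)/(R T))), fitted by
    least squares in fraction space.  Initialization comes from an internal
    LEM fit on the in-band points when possible, followed by a coarse
    restart grid if the optimizer fails.

    Attributes: ``dg_h2o_``, ``m_``, ``midpoint_``, ``stderr_dg_``,
    ``stderr_m_``, ``n_iter_restarts_``.
    """

    def __init__(self, temperature_K: float = T_DEFAULT_K, max_restarts: int = 24):
        self.temperature_K = temperature_K
        self.max_restarts = max_restarts

    def _initial_guesses(self, u: np.ndarray, f: np.ndarray, rt: float):
        guesses = []
        band = (f >= FRACTION_BAND[0]) & (f <= FRACTION_BAND[1])
        if np.count_nonzero(band) >= 3:
            dg_pts = -rt * np.log(f[band] / (1.0 - f[band]))
            try:
                lem = LinearExtrapolationRegression().fit(
                    u[band].reshape(-1, 1), dg_pts)
                if lem.m_ > 0 and lem.dg_h2o_ > 0:
                    guesses.append((lem.dg_h2o_, lem.m_))
            except InsufficientDataError:
                pass
        span = max(u.max() - u.min(), 1e-6)
        for mid_frac in (0.25, 0.5, 0.75):
            mid = u.min() + mid_frac * span
            for m0 in (rt / span, 4 * rt / span, 12 * rt / span):
                guesses.append((m0 * mid, m0))
        return guesses[: self.max_restarts]

    def fit(self, X, y):
        X = check_array(X, ensure_2d=True)
        f = np.asarray(y, dtype=float)
        u = X[:, 0]
        if u.size < 4:
            raise InsufficientDataError("need >= 4 fraction points for the nonlinear fit")
        if np.ptp(f) < 0.05:
            raise FitConvergenceError(
                "fraction data nearly constant: transition parameters are "
                "non-identifiable"
            )
        rt = R_GAS * self.temperature_K
        model = lambda x, dg, m: _logistic_fraction(x, dg, m, rt)  # noqa: E731
        best = None
        tried = 0
        for p0 in self._initial_guesses(u, f, rt):
            tried += 1
            try:
                popt, pcov = curve_fit(model, u, f, p0=p0, maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            resid = float(np.sum((model(u, *popt) - f) ** 2))
            if best is None or resid < best[2]:
                best = (popt, pcov, resid)
            if resid < 1e-20:
                break
        if best is None:
            raise FitConvergenceError(
                f"nonlinear two-state fit failed to converge after {tried} restarts"
            )
        (dg, m), pcov, resid = best
        if m <= 0 or dg <= 0:
            raise FitConvergenceError(
                f"nonlinear fit converged to a non-physical optimum "
                f"(dG_H2O={dg:.3g} J/mol, m={m:.3g} J/mol/M)"
            )
        self.dg_h2o_ = float(dg)
        self.m_ = float(m)
        self.midpoint_ = self.dg_h2o_ / self.m_
        with np.errstate(invalid="ignore"):
            errs = np.sqrt(np.diag(pcov))
        self.stderr_dg_ = float(errs[0])
        self.stderr_m_ = float(errs[1])
        self.residual_ss_ = resid
        self.n_iter_restarts_ = tried
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "dg_h2o_")
        X = check_array(X, ensure_2d=True)
        return _logistic_fraction(X[:, 0], self.dg_h2o_, self.m_,
                                  R_GAS * self.temperature_K)


# ---------------------------------------------------------------------------
# functional pipeline
# ---------------------------------------------------------------------------

def fit_baselines(
    profile: UnfoldingProfile,
    regions: Sequence[tuple[float, float]] = DEFAULT_REGIONS,
) -> BaselineSet:
    """Independent OLS baselines over the N, I and U windows.

    Each window must hold >= 2 data points; a two-point window gives the
    exact line through them.
    """
    regions = tuple(tuple(map(float, r)) for r in regions)
    u, y = profile.denaturant_M, profile.signal
    lines, covs = [], []
    ss_rel, dof = 0.0, 0
    for (lo, hi), name in zip(regions, ("N", "I", "U")):
        mask = (u >= lo) & (u <= hi)
        n = int(np.count_nonzero(mask))
        if n < 2:
            raise InsufficientDataError(
                f"baseline region {name} [{lo:g}, {hi:g}] M holds {n} point(s); "
                "need >= 2"
            )
        if np.ptp(u[mask]) == 0:
            raise InsufficientDataError(
                f"baseline region {name}: all points at one denaturant value")
        uw, yw = u[mask], y[mask]
        if np.ptp(yw) == 0:  # exactly flat: slope 0 without OLS noise
            a, b = float(yw[0]), 0.0
        else:
            res = stats.linregress(uw, yw)
            a, b = float(res.intercept), float(res.slope)
        lines.append((a, b))
        resid = yw - (a + b * uw)
        if n > 2:
            s2 = float(np.sum(resid**2)) / (n - 2)
            sxx = float(np.sum((uw - uw.mean()) ** 2))
            var_b = s2 / sxx
            var_a = s2 * (1.0 / n + uw.mean() ** 2 / sxx)
            cov_ab = -uw.mean() * var_b
            covs.append((var_a, var_b, cov_ab))
            with np.errstate(divide="ignore", invalid="ignore"):
                pred = a + b * uw
                rel = np.where(np.abs(pred) > 0, resid / pred, 0.0)
            ss_rel += float(np.sum(rel**2))
            dof += n - 2
        else:
            covs.append((0.0, 0.0, 0.0))
    noise_sd_rel = float(np.sqrt(ss_rel / dof)) if dof > 0 else 0.0
    return BaselineSet(
        region_n=regions[0], region_i=regions[1], region_u=regions[2],
        line_n=lines[0], line_i=lines[1], line_u=lines[2],
        cov_n=covs[0], cov_i=covs[1], cov_u=covs[2],
        noise_sd_rel=noise_sd_rel,
    )


def _zone_fraction(
    u: np.ndarray, y: np.ndarray, lo: float, hi: float,
    y_native: np.ndarray, y_denatured: np.ndarray,
    cov_native: tuple[float, float, float],
    cov_denatured: tuple[float, float, float],
    noise_sd_rel: float,
    transition: Transition, temperature_K: float,
) -> StateFractions:
    mask = (u > lo) & (u < hi)
    if not np.any(mask):
        raise InsufficientDataError(
            f"no data points in the {transition.value} transition zone "
            f"({lo:g}, {hi:g}) M"
        )
    denom = y_denatured[mask] - y_native[mask]
    scale = np.maximum(np.abs(y_native[mask]), 1.0)
    if np.any(np.abs(denom) < 1e-12 * scale):
        raise DegenerateBaselineError(
            f"state baselines coincide inside the {transition.value} zone"
        )
    f = (y[mask] - y_native[mask]) / denom
    lo_r, hi_r = FRACTION_REPORT_RANGE
    flagged = tuple(int(i) for i in np.nonzero((f < lo_r) | (f > hi_r))[0])
    f = np.clip(f, lo_r, hi_r)
    # error propagation: measurement noise (diagonal) plus the shared,
    # fully correlated uncertainty of the two extrapolated baselines
    uz = u[mask]
    sigma_y = noise_sd_rel * np.abs(y[mask])
    k_nat = BaselineSet._prediction_cov(cov_native, uz)
    k_den = BaselineSet._prediction_cov(cov_denatured, uz)
    grad_nat = (f - 1.0) / denom
    grad_den = -f / denom
    cov = (np.diag((sigma_y / denom) ** 2)
           + np.outer(grad_nat, grad_nat) * k_nat
           + np.outer(grad_den, grad_den) * k_den)
    return StateFractions(
        transition=transition,
        denaturant_M=tuple(uz),
        fraction=tuple(f),
        flagged=flagged,
        temperature_K=temperature_K,
        fraction_cov=cov,
    )


def state_fractions(
    profile: UnfoldingProfile, baselines: BaselineSet
) -> tuple[StateFractions, StateFractions]:
    """Baseline-chord fractions for both transitions.

    Transition 1 (N=I) spans the open interval between the native and
    intermediate windows, transition 2 (I=U) between the intermediate and
    unfolded windows; baselines are evaluated (extrapolated) at each point.
    """
    u, y = profile.denaturant_M, profile.signal
    f1 = _zone_fraction(
        u, y, baselines.region_n[1], baselines.region_i[0],
        baselines.y_n(u), baselines.y_i(u),
        baselines.cov_n, baselines.cov_i, baselines.noise_sd_rel,
        Transition.N_TO_I, profile.temperature_K,
    )
    f2 = _zone_fraction(
        u, y, baselines.region_i[1], baselines.region_u[0],
        baselines.y_i(u), baselines.y_u(u),
        baselines.cov_i, baselines.cov_u, baselines.noise_sd_rel,
        Transition.I_TO_U, profile.temperature_K,
    )
    return f1, f2


def per_point_dg(
    fractions: StateFractions, temperature_K: Optional[float] = None
) -> FreeEnergySeries:
    """Per-point free energies dG = -RT ln(f/(1-f)) for in-band fractions.

    Only points with f in [0.05, 0.95] are transformed; the count of
    excluded points is reported.
    """
    t = fractions.temperature_K if temperature_K is None else temperature_K
    f = np.asarray(fractions.fraction)
    u = np.asarray(fractions.denaturant_M)
    band = (f >= FRACTION_BAND[0]) & (f <= FRACTION_BAND[1])
    n_excl = int(np.count_nonzero(~band))
    if not np.any(band):
        raise InsufficientDataError(
            f"no fractions inside the band {FRACTION_BAND} for "
            f"{fractions.transition.value}"
        )
    fb = f[band]
    dg = -R_GAS * t * np.log(fb / (1.0 - fb))
    dg_cov = None
    if fractions.fraction_cov is not None:
        jac = -R_GAS * t / (fb * (1.0 - fb))  # d(dG)/df
        sub = fractions.fraction_cov[np.ix_(band.nonzero()[0], band.nonzero()[0])]
        dg_cov = np.outer(jac, jac) * sub
    return FreeEnergySeries(
        transition=fractions.transition,
        denaturant_M=tuple(u[band]),
        dg_J_per_mol=tuple(dg),
        n_excluded=n_excl,
        temperature_K=t,
        dg_cov=dg_cov,
    )


def _sandwich_cov(design: np.ndarray, cov_y: np.ndarray) -> np.ndarray:
    """Covariance of a least-squares estimate under correlated errors:
    (X'X)^-1 X' Cov(y) X (X'X)^-1."""
    pinv = np.linalg.pinv(design.T @ design) @ design.T
    return pinv @ cov_y @ pinv.T


def fit_lem(dg_series: FreeEnergySeries) -> TransitionFit:
    """Linear extrapolation fit: dG(u) = dG_H2O - m*u by OLS.

    Standard errors use the propagated per-point dG covariance when the
    series carries one (it accounts for the shared baseline uncertainty);
    otherwise the ordinary OLS errors are reported.
    """
    u = np.asarray(dg_series.denaturant_M)
    est = LinearExtrapolationRegression().fit(
        u.reshape(-1, 1), np.asarray(dg_series.dg_J_per_mol))
    stderr_dg, stderr_m = est.stderr_dg_, est.stderr_m_
    if dg_series.dg_cov is not None:
        design = np.column_stack([np.ones_like(u), u])
        cov = _sandwich_cov(design, dg_series.dg_cov)
        stderr_dg = float(np.sqrt(max(cov[0, 0], 0.0)))
        stderr_m = float(np.sqrt(max(cov[1, 1], 0.0)))
    return TransitionFit(
        dg_h2o_J_per_mol=est.dg_h2o_,
        m_J_per_mol_per_M=est.m_,
        stderr_dg=stderr_dg,
        stderr_m=stderr_m,
        method=FitMethod.LINEAR_LEM,
        transition=dg_series.transition,
        n_points=u.size,
        r_squared=est.r_squared_,
    )


def fit_nonlinear(
    fractions: StateFractions, temperature_K: Optional[float] = None
) -> TransitionFit:
    """Nonlinear two-state fit of the fraction-vs-denaturant curve.

    Standard errors use the fraction covariance when available (sandwich
    estimator with the model Jacobian at the optimum); otherwise the
    optimizer's own covariance is reported.
    """
    t = fractions.temperature_K if temperature_K is None else temperature_K
    u = np.asarray(fractions.denaturant_M)
    est = TwoStateDenaturationCurve(temperature_K=t).fit(
        u.reshape(-1, 1), np.asarray(fractions.fraction))
    stderr_dg, stderr_m = est.stderr_dg_, est.stderr_m_
    if fractions.fraction_cov is not None:
        rt = R_GAS * t
        f_hat = _logistic_fraction(u, est.dg_h2o_, est.m_, rt)
        w = f_hat * (1.0 - f_hat) / rt
        jac = np.column_stack([-w, w * u])  # d f / d(dG_H2O, m)
        cov = _sandwich_cov(jac, fractions.fraction_cov)
        stderr_dg = float(np.sqrt(max(cov[0, 0], 0.0)))
        stderr_m = float(np.sqrt(max(cov[1, 1], 0.0)))
    return TransitionFit(
        dg_h2o_J_per_mol=est.dg_h2o_,
        m_J_per_mol_per_M=est.m_,
        stderr_dg=stderr_dg,
        stderr_m=stderr_m,
        method=FitMethod.NONLINEAR,
        transition=fractions.transition,
        n_points=u.size,
    )


def analyze_profile(
    profile: UnfoldingProfile,
    regions: Sequence[tuple[float, float]] = DEFAULT_REGIONS,
    method: str = "both",
    temperature_K: Optional[float] = None,
) -> UnfoldingFitSet:
    """Full pipeline: baselines -> fractions -> LEM and/or nonlinear fits."""
    if method not in ("linear_LEM", "nonlinear", "both"):
        raise DataValidationError(f"unknown method {method!r}")
    baselines = fit_baselines(profile, regions)
    fits: list[TransitionFit] = []
    for fr in state_fractions(profile, baselines):
        if method in ("linear_LEM", "both"):
            fits.append(fit_lem(per_point_dg(fr, temperature_K)))
        if method in ("nonlinear", "both"):
            fits.append(fit_nonlinear(fr, temperature_K))
    return UnfoldingFitSet(fits=tuple(fits), label=profile.label)


class ThreeStateUnfoldingAnalysis(BaseEstimator):
    """Estimator wrapper for the full three-state pipeline.

    fit(X, y): X is the (n, 1) denaturant column (mol/L), y the signal.
    After fitting, ``baselines_`` holds the :class:`BaselineSet`,
    ``fractions_`` the two :class:`StateFractions`, and ``fit_set_`` the
    :class:`UnfoldingFitSet` with one :class:`TransitionFit` per transition
    and method.
    """

    def __init__(self, regions: tuple = DEFAULT_REGIONS, method: str = "both",
                 temperature_K: float = T_DEFAULT_K):
        self.regions = regions
        self.method = method
        self.temperature_K = temperature_K

    def fit(self, X, y):
        X = check_array(X, ensure_2d=True)
        profile = UnfoldingProfile(X[:, 0], np.asarray(y, dtype=float),
                                   temperature_K=self.temperature_K)
        self.baselines_ = fit_baselines(profile, self.regions)
        self.fractions_ = state_fractions(profile, self.baselines_)
        self.fit_set_ = analyze_profile(profile, self.regions, self.method,
                                        self.temperature_K)
        self.n_features_in_ = 1
        return self


def compare_stability(
    apo: Sequence[TransitionFit], complex_: Sequence[TransitionFit]
) -> StabilityComparison:
    """Ligand-induced stabilization from two pairs of transition fits.

    Both sides must contain one fit per transition obtained with the same
    method; totals are the sums of the two dG_H2O per side.
    """
    if len(apo) != 2 or len(complex_) != 2:
        raise DataValidationError("each side needs exactly two transition fits")
    methods = {f.method for f in (*apo, *complex_)}
    if len(methods) != 1:
        raise DataValidationError(
            "apo and complex fits mix methods: " +
            ", ".join(sorted(m.value for m in methods))
        )
    def by_transition(fits):
        d = {f.transition: f for f in fits}
        if set(d) != {Transition.N_TO_I, Transition.I_TO_U}:
            raise DataValidationError("each side needs one fit per transition")
        return d
    a, c = by_transition(apo), by_transition(complex_)
    per_transition = {
        t.value: c[t].dg_h2o_J_per_mol - a[t].dg_h2o_J_per_mol
        for t in (Transition.N_TO_I, Transition.I_TO_U)
    }
    return StabilityComparison(
        total_dg_h2o_apo_J_per_mol=sum(f.dg_h2o_J_per_mol for f in apo),
        total_dg_h2o_complex_J_per_mol=sum(f.dg_h2o_J_per_mol for f in complex_),
        per_transition_ddg_J_per_mol=per_transition,
        method=methods.pop(),
    )
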