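"""Association constant and site number from the double-logarithmic plot.

For a quencher binding at n equivalent sites the quench ratio follows
(F0 - F)/F = Ka * [Q]**n, so the double-log plot

    log10((F0 - F)/F) = log10(Ka) + n * log10([Q])

is a straight line whose slope is the site number n and whose intercept is
log10 Ka.  Base-10 logarithms are used throughout (the plot is drawn in
decades).  The regression is unweighted OLS in log space, matching the
classical least-squares treatment; [Q] is the total added ligand
concentration (no free-ligand iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .constants import T_DEFAULT_K
from .exceptions import DataValidationError, InsufficientDataError
from .io_spectra import TitrationSeries

#: Site numbers outside this open interval are flagged as implausible.
N_SITES_SANITY_BAND = (0.0, 4.0)


@dataclass(frozen=True)
class BindingFit:
    """Double-log binding fit: association constant and site number."""

    log10_ka: float
    n_sites: float
    stderr_log10_ka: float
    stderr_n: float
    r_squared: float
    temperature_K: float = T_DEFAULT_K
    n_excluded: int = 0
    label: str = ""
    warnings: tuple[str, ...] = ()
    ka_assoc_per_M: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ka_assoc_per_M", 10.0**self.log10_ka)
        warnings = tuple(self.warnings)
        lo, hi = N_SITES_SANITY_BAND
        if not lo < self.n_sites < hi:
            warnings += (f"n_sites={self.n_sites:.3g} outside sanity band {N_SITES_SANITY_BAND}",)
        object.__setattr__(self, "warnings", warnings)


class DoubleLogBindingRegression(RegressorMixin, BaseEstimator):
    """OLS of log10(quench ratio) on log10([Q]).

    fit(X, y) takes X as the (n, 1) column of ligand concentrations (mol/L,
    all > 0) and y as the quench ratio (F0 - F)/F (all > 0).

    Attributes after fit: ``log10_ka_``, ``ka_``, ``n_sites_``,
    ``stderr_log10_ka_``, ``stderr_n_``, ``r_squared_``.
    """

    def fit(self, X, y):
        X = check_array(X, ensure_2d=True)
        y = np.asarray(y, dtype=float)
        if X.shape[1] != 1:
            raise DataValidationError("X must have a single column ([Q] in mol/L)")
        q = X[:, 0]
        if np.any(q <= 0) or np.any(y <= 0):
            raise DataValidationError("double-log fit requires [Q] > 0 and quench ratio > 0")
        if q.size < 3:
            raise InsufficientDataError("need at least 3 points for the double-log fit")
        res = stats.linregress(np.log10(q), np.log10(y))
        self.n_sites_ = float(res.slope)
        self.log10_ka_ = float(res.intercept)
        self.ka_ = 10.0**self.log10_ka_
        self.stderr_n_ = float(res.stderr)
        self.stderr_log10_ka_ = float(res.intercept_stderr)
        self.r_squared_ = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Predicted quench ratio (F0 - F)/F at the given concentrations."""
        check_is_fitted(self, "ka_")
        X = check_array(X, ensure_2d=True)
        return self.ka_ * X[:, 0] ** self.n_sites_


def fit_double_log(series: TitrationSeries) -> BindingFit:
    """Fit Ka and n from one titration via the double-logarithmic transform.

    Points with F >= F0 (no positive quench) are excluded and counted; fewer
    than 3 usable points is an error that reports the exclusion count.
    """
    q = series.ligand_conc_M[1:]
    f = series.intensity[1:]
    usable = f < series.f0
    n_excluded = int(np.count_nonzero(~usable))
    if np.count_nonzero(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 points with positive quench; "
            f"{n_excluded} of {q.size} points excluded (F >= F0)"
        )
    ratio = (series.f0 - f[usable]) / f[usable]
    est = DoubleLogBindingRegression().fit(q[usable].reshape(-1, 1), ratio)
    return BindingFit(
        log10_ka=est.log10_ka_,
        n_sites=est.n_sites_,
        stderr_log10_ka=est.stderr_log10_ka_,
        stderr_n=est.stderr_n_,
        r_squared=est.r_squared_,
        temperature_K=series.temperature_K,
        n_excluded=n_excluded,
        label=series.label,
    )
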