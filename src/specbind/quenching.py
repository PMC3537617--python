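"""Stern-Volmer quenching analysis.

The Stern-Volmer relation, F0/F = 1 + Ksv*[Q], is fitted by ordinary least
squares with a *free* intercept: a unit-pinned intercept would hide baseline
errors, so the fitted intercept is reported and a warning is attached when it
deviates from 1 by more than 5%.  The bimolecular quenching rate constant is
kq = Ksv/tau0 with tau0 the unquenched fluorophore lifetime (5 ns for serum
albumin by default).

Mechanism classification follows the standard two-pronged diagnostic: kq far
above the diffusion-collision ceiling (~1e10 M^-1 s^-1) together with Ksv
falling as temperature rises indicates static quenching (ground-state complex
formation); kq at or below the ceiling with Ksv rising with temperature
indicates dynamic (collisional) quenching; anything else is indeterminate.

A specificity check across protein concentrations guards against the
colloid-aggregation artifact: promiscuous sequestration of protein by ligand
aggregates makes the apparent Ksv collapse as protein concentration rises.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .constants import COLLISIONAL_LIMIT_PER_M_PER_S, TAU0_DEFAULT_S
from .exceptions import DataValidationError, InsufficientDataError
from .io_spectra import TitrationSeries


class Mechanism(str, enum.Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class QuenchFit:
    """Stern-Volmer fit of one titration.

    ``kq_per_M_per_s`` is derived, not stored: it is always exactly
    Ksv/tau0.  ``intercept`` is the freely fitted intercept of the
    F0/F vs [Q] line (1 for ideal data).
    """

    ksv_per_M: float
    ksv_stderr: float
    tau0_s: float
    r_squared: float
    temperature_K: float
    intercept: float = 1.0
    intercept_stderr: float = 0.0
    protein_conc_M: float = 5e-6
    label: str = ""
    mechanism: Mechanism = Mechanism.INDETERMINATE
    warnings: tuple[str, ...] = ()
    kq_per_M_per_s: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.tau0_s > 0:
            raise DataValidationError("tau0_s must be > 0")
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        object.__setattr__(self, "warnings", tuple(self.warnings))
        object.__setattr__(self, "kq_per_M_per_s", self.ksv_per_M / self.tau0_s)


@dataclass(frozen=True)
class MechanismReport:
    """Outcome of the temperature-trend mechanism classification, with the
    decision rule and threshold recorded."""

    mechanism: Mechanism
    collisional_limit_per_M_per_s: float
    temperatures_K: tuple[float, ...]
    ksv_per_M: tuple[float, ...]
    kq_per_M_per_s: tuple[float, ...]
    rule: str = (
        "static if all kq > limit and Ksv non-increasing with T; "
        "dynamic if all kq <= limit and Ksv non-decreasing with T; "
        "indeterminate otherwise"
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        object.__setattr__(self, "temperatures_K", tuple(self.temperatures_K))
        object.__setattr__(self, "ksv_per_M", tuple(self.ksv_per_M))
        object.__setattr__(self, "kq_per_M_per_s", tuple(self.kq_per_M_per_s))


@dataclass(frozen=True)
class SpecificityReport:
    """Ksv stability across protein concentrations (colloid-artifact check)."""

    protein_conc_M: tuple[float, ...]
    ksv_per_M: tuple[float, ...]
    max_rel_spread: float
    max_rel_drop: float
    passed: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein_conc_M", tuple(self.protein_conc_M))
        object.__setattr__(self, "ksv_per_M", tuple(self.ksv_per_M))


class SternVolmerRegression(RegressorMixin, BaseEstimator):
    """Least-squares Stern-Volmer line, y = intercept + Ksv*[Q].

    Parameters
    ----------
    tau0_s : float
        Unquenched fluorophore lifetime in seconds; kq_ = ksv_/tau0_s.
    intercept_warning_tol : float
        |intercept - 1| above which a baseline warning is recorded.

    Attributes (after fit)
    ----------------------
    ksv_ : slope in M^-1;  intercept_ : fitted intercept;
    ksv_stderr_, intercept_stderr_ : OLS standard errors;
    r_squared_ : coefficient of determination of the line;
    kq_ : bimolecular quenching rate constant, M^-1 s^-1;
    warnings_ : tuple of diagnostic strings.
    """

    def __init__(self, tau0_s: float = TAU0_DEFAULT_S,
                 intercept_warning_tol: float = 0.05):
        self.tau0_s = tau0_s
        self.intercept_warning_tol = intercept_warning_tol

    def fit(self, X, y):
        X = check_array(X, ensure_2d=True)
        y = np.asarray(y, dtype=float)
        if X.shape[1] != 1:
            raise DataValidationError("X must have a single column ([Q] in mol/L)")
        q = X[:, 0]
        if np.count_nonzero(q > 0) < 3:
            raise InsufficientDataError(
                "need at least 3 nonzero-concentration points for a Stern-Volmer fit"
            )
        res = stats.linregress(q, y)
        self.ksv_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.ksv_stderr_ = float(res.stderr)
        self.intercept_stderr_ = float(res.intercept_stderr)
        self.r_squared_ = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
        self.kq_ = self.ksv_ / self.tau0_s
        warnings = []
        if abs(self.intercept_ - 1.0) > self.intercept_warning_tol:
            warnings.append(
                f"fitted intercept {self.intercept_:.4g} deviates from 1 "
                f"by more than {self.intercept_warning_tol:g}"
            )
        if self.ksv_ <= 0 or self.ksv_stderr_ >= abs(self.ksv_):
            warnings.append("no clear quenching: slope is non-positive or "
                            "dominated by its standard error")
        self.warnings_ = tuple(warnings)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "ksv_")
        X = check_array(X, ensure_2d=True)
        return self.intercept_ + self.ksv_ * X[:, 0]


def fit_stern_volmer(series: TitrationSeries, tau0_s: float = TAU0_DEFAULT_S) -> QuenchFit:
    """Fit the Stern-Volmer line F0/F vs [Q] for one titration.

    ``intensity[0]`` is taken as F0; the zero-concentration point (y = 1)
    participates in the regression.  Mechanism on a single titration is
    reported as indeterminate - use :func:`classify_mechanism` on a
    temperature series.
    """
    q = series.ligand_conc_M
    y = series.f0 / series.intensity
    warnings: list[str] = []
    if np.any(series.intensity >= series.f0 * 1.05):
        warnings.append("intensity exceeds F0 by >5% at some points (anti-quench)")
    est = SternVolmerRegression(tau0_s=tau0_s).fit(q.reshape(-1, 1), y)
    return QuenchFit(
        ksv_per_M=est.ksv_,
        ksv_stderr=est.ksv_stderr_,
        tau0_s=tau0_s,
        r_squared=est.r_squared_,
        temperature_K=series.temperature_K,
        intercept=est.intercept_,
        intercept_stderr=est.intercept_stderr_,
        protein_conc_M=series.protein_conc_M,
        label=series.label,
        mechanism=Mechanism.INDETERMINATE,
        warnings=tuple(warnings) + est.warnings_,
    )


def classify_mechanism_report(
    fits: Sequence[QuenchFit],
    collisional_limit_per_M_per_s: float = COLLISIONAL_LIMIT_PER_M_PER_S,
) -> MechanismReport:
    """Classify static vs dynamic quenching from fits ordered by temperature."""
    if len(fits) < 1:
        raise InsufficientDataError("need at least one Stern-Volmer fit")
    temps = [f.temperature_K for f in fits]
    if len(set(temps)) != len(temps):
        raise DataValidationError("duplicate temperatures in mechanism classification")
    order = np.argsort(temps)
    fits = [fits[i] for i in order]
    temps = [f.temperature_K for f in fits]
    ksv = [f.ksv_per_M for f in fits]
    kq = [f.kq_per_M_per_s for f in fits]
    non_increasing = all(b <= a for a, b in zip(ksv, ksv[1:]))
    non_decreasing = all(b >= a for a, b in zip(ksv, ksv[1:]))
    if all(k > collisional_limit_per_M_per_s for k in kq) and non_increasing:
        mech = Mechanism.STATIC
    elif all(k <= collisional_limit_per_M_per_s for k in kq) and non_decreasing:
        mech = Mechanism.DYNAMIC
    else:
        mech = Mechanism.INDETERMINATE
    return MechanismReport(
        mechanism=mech,
        collisional_limit_per_M_per_s=collisional_limit_per_M_per_s,
        temperatures_K=tuple(temps),
        ksv_per_M=tuple(ksv),
        kq_per_M_per_s=tuple(kq),
    )


def classify_mechanism(
    fits: Sequence[QuenchFit],
    collisional_limit_per_M_per_s: float = COLLISIONAL_LIMIT_PER_M_PER_S,
) -> Mechanism:
    """Mechanism enum only; see :func:`classify_mechanism_report`."""
    return classify_mechanism_report(fits, collisional_limit_per_M_per_s).mechanism


def specificity_check(
    fits: Sequence[QuenchFit], max_rel_drop: float = 0.5
) -> SpecificityReport:
    """Check that Ksv does not collapse with rising protein concentration.

    Passes when the maximum pairwise relative spread of Ksv, normalized by
    the largest Ksv, stays below ``max_rel_drop``.
    """
    if len(fits) < 2:
        raise InsufficientDataError(
            "need fits at >= 2 distinct protein concentrations"
        )
    concs = [f.protein_conc_M for f in fits]
    if len(set(concs)) != len(concs):
        raise DataValidationError("duplicate protein concentrations")
    order = np.argsort(concs)
    fits = [fits[i] for i in order]
    ksv = np.array([f.ksv_per_M for f in fits])
    spread = float((ksv.max() - ksv.min()) / ksv.max())
    return SpecificityReport(
        protein_conc_M=tuple(f.protein_conc_M for f in fits),
        ksv_per_M=tuple(ksv),
        max_rel_spread=spread,
        max_rel_drop=max_rel_drop,
        passed=spread < max_rel_drop,
    )
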