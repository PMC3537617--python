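"""van't Hoff thermodynamics and residence-time kinetics of a binding
equilibrium.

The integrated van't Hoff relation, ln Ka = -dH/(R T) + dS/R, is fitted by
OLS of ln Ka on 1/T: dH = -R * slope, dS = R * intercept.  dG(T) is then
reported from dH - T*dS (the classical substitution route); -RT ln Ka is also
computed at every input temperature as a diagnostic, since with a finite
temperature series the two routes need not coincide.

Kinetics: with a diffusion-limited forward rate kf (Smoluchowski,
kf = 4 pi r D N_A * 1000 in M^-1 s^-1 for r in m and D in m^2/s), the
dissociation rate is kb = kf/Ka and the residence time of the complex is
tau = 1/kb = Ka/kf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .constants import N_AVOGADRO, R_GAS
from .exceptions import DataValidationError, InsufficientDataError


@dataclass(frozen=True)
class ThermoResult:
    """van't Hoff fit: binding enthalpy, entropy and free energy.

    ``dg_J_per_mol_at`` holds dH - T*dS at each input temperature;
    ``dg_from_lnka_at`` holds the -RT ln Ka diagnostic at the same
    temperatures.  Standard errors are NaN for a two-point (exact-line) fit.
    """

    dh_J_per_mol: float
    ds_J_per_mol_K: float
    stderr_dh: float
    stderr_ds: float
    r_squared: float
    dg_J_per_mol_at: dict[float, float]
    dg_from_lnka_at: dict[float, float]
    r_gas: float = R_GAS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "dg_J_per_mol_at",
            {float(t): float(g) for t, g in self.dg_J_per_mol_at.items()},
        )
        object.__setattr__(
            self, "dg_from_lnka_at",
            {float(t): float(g) for t, g in self.dg_from_lnka_at.items()},
        )


@dataclass(frozen=True)
class KineticResult:
    """Diffusion-limited kinetic decomposition of a binding constant.

    Derived fields: kb = kf/Ka and residence_time = 1/kb, stored exactly.
    """

    ka_assoc_per_M: float
    kf_per_M_per_s: float
    d_m2_per_s: float = float("nan")
    r_m: float = float("nan")
    kb_per_s: float = field(init=False)
    residence_time_s: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.ka_assoc_per_M > 0 or not self.kf_per_M_per_s > 0:
            raise DataValidationError("Ka and kf must be > 0")
        kb = self.kf_per_M_per_s / self.ka_assoc_per_M
        object.__setattr__(self, "kb_per_s", kb)
        object.__setattr__(self, "residence_time_s", 1.0 / kb)


class VantHoffRegression(RegressorMixin, BaseEstimator):
    """OLS of ln Ka on 1/T.

    fit(X, y): X is the (n, 1) column of absolute temperatures (K) and y the
    association constants (M^-1).  Attributes after fit: ``dh_`` (J/mol),
    ``ds_`` (J/mol/K), ``stderr_dh_``, ``stderr_ds_`` (NaN for n = 2),
    ``r_squared_``.  ``predict(X)`` returns Ka at the given temperatures.
    """

    def fit(self, X, y):
        X = check_array(X, ensure_2d=True)
        y = np.asarray(y, dtype=float)
        if X.shape[1] != 1:
            raise DataValidationError("X must have a single column (T in K)")
        temps = X[:, 0]
        if temps.size < 2:
            raise InsufficientDataError("need Ka at >= 2 temperatures")
        if len(set(temps.tolist())) != temps.size:
            raise DataValidationError("duplicate temperatures in van't Hoff fit")
        if np.any(temps <= 0) or np.any(y <= 0):
            raise DataValidationError("temperatures and Ka must be > 0")
        res = stats.linregress(1.0 / temps, np.log(y))
        self.dh_ = -R_GAS * float(res.slope)
        self.ds_ = R_GAS * float(res.intercept)
        if temps.size == 2:  # exact line: no residual degrees of freedom
            self.stderr_dh_ = float("nan")
            self.stderr_ds_ = float("nan")
        else:
            self.stderr_dh_ = R_GAS * float(res.stderr)
            self.stderr_ds_ = R_GAS * float(res.intercept_stderr)
        self.r_squared_ = float(res.rvalue**2)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "dh_")
        X = check_array(X, ensure_2d=True)
        t = X[:, 0]
        return np.exp(-self.dh_ / (R_GAS * t) + self.ds_ / R_GAS)


def fit_vant_hoff(points: Sequence[tuple[float, float]]) -> ThermoResult:
    """van't Hoff fit from (temperature_K, Ka) pairs."""
    pts = [(float(t), float(k)) for t, k in points]
    temps = np.array([t for t, _ in pts])
    kas = np.array([k for _, k in pts])
    est = VantHoffRegression().fit(temps.reshape(-1, 1), kas)
    return ThermoResult(
        dh_J_per_mol=est.dh_,
        ds_J_per_mol_K=est.ds_,
        stderr_dh=est.stderr_dh_,
        stderr_ds=est.stderr_ds_,
        r_squared=est.r_squared_,
        dg_J_per_mol_at={t: est.dh_ - t * est.ds_ for t in temps},
        dg_from_lnka_at={t: -R_GAS * t * np.log(k) for t, k in pts},
    )


def diffusion_limited_kf(d_m2_per_s: float = 1e-9, r_m: float = 4e-10) -> float:
    """Smoluchowski diffusion-limited association rate, M^-1 s^-1.

    kf = 4 pi r D N_A * 1000, with the factor 1000 converting m^3/mol/s to
    L/mol/s.  Defaults (D = 1e-9 m^2/s, i.e. 1e-5 cm^2/s; r = 0.4 nm) give
    about 3.0e9 M^-1 s^-1.
    """
    if d_m2_per_s < 0 or r_m < 0:
        raise DataValidationError("D and r must be >= 0")
    return 4.0 * np.pi * r_m * d_m2_per_s * N_AVOGADRO * 1000.0


def residence_time(ka_assoc_per_M: float, kf_per_M_per_s: float,
                   d_m2_per_s: float = float("nan"),
                   r_m: float = float("nan")) -> KineticResult:
    """Residence time of the complex: kb = kf/Ka, tau = 1/kb = Ka/kf."""
    return KineticResult(
        ka_assoc_per_M=float(ka_assoc_per_M),
        kf_per_M_per_s=float(kf_per_M_per_s),
        d_m2_per_s=d_m2_per_s,
        r_m=r_m,
    )
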