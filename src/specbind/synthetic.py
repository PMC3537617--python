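"""Synthetic-data generators with known ground truth.

Every analysis stage in the package (Stern-Volmer, double-log binding,
van't Hoff, three-state denaturation) has a generator here that produces its
input from exactly the model the estimator fits, so parameter-recovery tests
isolate estimator correctness from model misfit.

Quench titrations follow the empirical saturable form

    F([Q]) = F0 / (1 + Ka * [Q]**n)

which makes F0/F - 1 exactly linear in [Q] when n = 1 (the Stern-Volmer
limit) and makes the double-logarithmic plot log10((F0-F)/F) vs log10([Q])
exactly linear for every n.  Noise is multiplicative lognormal with a given
coefficient of variation: fluorescence error scales with intensity and the
log transforms stay defined because intensities remain positive.

Denaturation profiles offer two compositions of the three-state scheme
N = I = U (see :func:`generate_unfolding`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import DEFAULT_REGIONS, R_GAS, T_DEFAULT_K
from .exceptions import DataValidationError
from .io_spectra import TitrationSeries, UnfoldingProfile

#: 0-20 uM in 1 uM steps: 0-20 uL additions of a 2.7 mM stock into 3 mL.
DEFAULT_QUENCH_GRID_M = np.linspace(0.0, 20e-6, 21)

#: 0-9 M urea in 0.25 M steps, spanning both unfolding transitions.
DEFAULT_UREA_GRID_M = np.arange(0.0, 9.0 + 1e-9, 0.25)


@dataclass(frozen=True)
class QuenchTruth:
    """Ground-truth parameters for a synthetic quench titration."""

    ka_assoc_per_M: float
    n_sites: float = 1.0
    f0: float = 1000.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ka_assoc_per_M > 0:
            raise DataValidationError("ka_assoc_per_M must be > 0")
        if not self.n_sites > 0:
            raise DataValidationError("n_sites must be > 0")
        if not self.f0 > 0:
            raise DataValidationError("f0 must be > 0")
        if not 0 <= self.noise_cv < 0.2:
            raise DataValidationError("noise_cv must be in [0, 0.2)")


@dataclass(frozen=True)
class UnfoldTruth:
    """Ground truth for a two-step three-state denaturation profile.

    Free energies are in J/mol (water values), m-values in J/mol/M;
    ``baselines`` are (intercept, slope) pairs of signal vs denaturant for
    the N, I and U states.  The N=I midpoint (dg1/m1) must precede the
    I=U midpoint (dg2/m2).
    """

    dg1_J_per_mol: float
    m1_J_per_mol_per_M: float
    dg2_J_per_mol: float
    m2_J_per_mol_per_M: float
    baselines: tuple[tuple[float, float], ...] = ((1.0, 0.0), (0.55, 0.0), (0.15, 0.0))
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dg1_J_per_mol", "m1_J_per_mol_per_M",
                     "dg2_J_per_mol", "m2_J_per_mol_per_M"):
            if not getattr(self, name) > 0:
                raise DataValidationError(f"{name} must be > 0")
        if len(self.baselines) != 3 or any(len(b) != 2 for b in self.baselines):
            raise DataValidationError("baselines must be three (intercept, slope) pairs")
        if not 0 <= self.noise_cv < 0.2:
            raise DataValidationError("noise_cv must be in [0, 0.2)")
        if not self.midpoint1_M < self.midpoint2_M:
            raise DataValidationError(
                "transition-1 midpoint must precede transition-2 midpoint"
            )
        object.__setattr__(
            self, "baselines", tuple((float(a), float(b)) for a, b in self.baselines)
        )

    @property
    def midpoint1_M(self) -> float:
        return self.dg1_J_per_mol / self.m1_J_per_mol_per_M

    @property
    def midpoint2_M(self) -> float:
        return self.dg2_J_per_mol / self.m2_J_per_mol_per_M


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_quench(
    truth: QuenchTruth,
    conc_grid_M: Optional[Sequence[float]] = None,
    temperature_K: float = T_DEFAULT_K,
    protein_conc_M: float = 5e-6,
    label: str = "",
    rng: Optional[np.random.Generator] = None,
) -> TitrationSeries:
    """Simulate one quench titration from the saturable binding model.

    ``intensity[0]`` equals F0 exactly (noise is applied only to the points
    with ligand present); output is deterministic for a given seed.
    """
    conc = np.asarray(DEFAULT_QUENCH_GRID_M if conc_grid_M is None else conc_grid_M,
                      dtype=float)
    if np.any(conc < 0):
        raise DataValidationError("ligand concentrations must be >= 0")
    if conc[0] != 0 or not np.all(np.diff(conc) > 0):
        raise DataValidationError("conc grid must start at 0 and increase strictly")
    q = conc[1:]
    intensity = np.empty_like(conc)
    intensity[0] = truth.f0
    intensity[1:] = truth.f0 / (1.0 + truth.ka_assoc_per_M * q**truth.n_sites)
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    intensity[1:] *= _lognormal_factors(rng, truth.noise_cv, q.size)
    return TitrationSeries(conc, intensity, temperature_K=temperature_K,
                           protein_conc_M=protein_conc_M, label=label)


def vant_hoff_ka(dh_J_per_mol: float, ds_J_per_mol_K: float, temperature_K: float) -> float:
    """Association constant implied by the integrated van't Hoff relation,
    Ka(T) = exp(-dH/(R T) + dS/R)."""
    return float(np.exp(-dh_J_per_mol / (R_GAS * temperature_K) + ds_J_per_mol_K / R_GAS))


def generate_temperature_series(
    dh_J_per_mol: float,
    ds_J_per_mol_K: float,
    temps_K: Sequence[float],
    base: QuenchTruth,
    conc_grid_M: Optional[Sequence[float]] = None,
    protein_conc_M: float = 5e-6,
) -> list[TitrationSeries]:
    """One titration per temperature; the underlying Ka(T) obeys the van't
    Hoff relation exactly before noise.  ``base`` supplies F0, n, noise and
    seed (its ka is ignored)."""
    temps = [float(t) for t in temps_K]
    if any(t <= 0 for t in temps):
        raise DataValidationError("temperatures must be > 0")
    rng = np.random.default_rng(base.seed)
    out = []
    for t in temps:
        truth_t = QuenchTruth(
            ka_assoc_per_M=vant_hoff_ka(dh_J_per_mol, ds_J_per_mol_K, t),
            n_sites=base.n_sites, f0=base.f0,
            noise_cv=base.noise_cv, seed=base.seed,
        )
        out.append(
            generate_quench(truth_t, conc_grid_M, temperature_K=t,
                            protein_conc_M=protein_conc_M,
                            label=f"T={t:g}K", rng=rng)
        )
    return out


def three_state_populations(
    truth: UnfoldTruth,
    denaturant_M: np.ndarray,
    temperature_K: float = T_DEFAULT_K,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equilibrium populations (pN, pI, pU) of the sequential scheme.

    Each step follows the linear extrapolation model dG_i(u) = dG_i - m_i*u;
    K1 = exp(-dG1/RT), K2 = exp(-dG2/RT); pN = 1/(1 + K1 + K1 K2),
    pI = K1 pN, pU = K1 K2 pN.
    """
    u = np.asarray(denaturant_M, dtype=float)
    rt = R_GAS * temperature_K
    k1 = np.exp(-(truth.dg1_J_per_mol - truth.m1_J_per_mol_per_M * u) / rt)
    k2 = np.exp(-(truth.dg2_J_per_mol - truth.m2_J_per_mol_per_M * u) / rt)
    p_n = 1.0 / (1.0 + k1 + k1 * k2)
    return p_n, k1 * p_n, k1 * k2 * p_n


def _two_state_fraction(dg: float, m: float, u: np.ndarray, rt: float) -> np.ndarray:
    # fraction denatured of an isolated two-state step under the LEM
    return 1.0 / (1.0 + np.exp((dg - m * u) / rt))


def generate_unfolding(
    truth: UnfoldTruth,
    denat_grid_M: Optional[Sequence[float]] = None,
    temperature_K: float = T_DEFAULT_K,
    composition: str = "sequential",
    regions: tuple = DEFAULT_REGIONS,
    label: str = "",
) -> UnfoldingProfile:
    """Simulate a three-state denaturation profile with linear state baselines.

    Two compositions of the observable are available:

    ``"sequential"``
        Signal = pN*bN(u) + pI*bI(u) + pU*bU(u) with populations from the
        sequential three-state partition function.  Thermodynamically
        consistent; when the transitions overlap, the classical
        baseline-fraction analysis of such data is intrinsically biased.

    ``"two_state_zones"``
        Emulates the classical analysis assumption that each segment of the
        profile reflects a single two-state step: inside the N/I/U windows
        of ``regions`` the signal lies exactly on the state baseline, and in
        each inter-window transition zone it interpolates between the two
        flanking baselines with the isolated two-state fraction.  This
        composition is exactly invertible by the baseline-fraction pipeline
        regardless of midpoint separation (it may be discontinuous at zone
        boundaries when transitions overlap).

    A grid that does not span both midpoints is flagged in the label, not an
    error.
    """
    u = np.asarray(DEFAULT_UREA_GRID_M if denat_grid_M is None else denat_grid_M,
                   dtype=float)
    rt = R_GAS * temperature_K
    (bn0, bn1), (bi0, bi1), (bu0, bu1) = truth.baselines
    b_n = bn0 + bn1 * u
    b_i = bi0 + bi1 * u
    b_u = bu0 + bu1 * u

    if composition == "sequential":
        p_n, p_i, p_u = three_state_populations(truth, u, temperature_K)
        signal = p_n * b_n + p_i * b_i + p_u * b_u
    elif composition == "two_state_zones":
        (n_lo, n_hi), (i_lo, i_hi), (u_lo, _u_hi) = regions
        f1 = _two_state_fraction(truth.dg1_J_per_mol, truth.m1_J_per_mol_per_M, u, rt)
        f2 = _two_state_fraction(truth.dg2_J_per_mol, truth.m2_J_per_mol_per_M, u, rt)
        signal = np.where(u <= n_hi, b_n,
                  np.where(u < i_lo, b_n + (b_i - b_n) * f1,
                   np.where(u <= i_hi, b_i,
                    np.where(u < u_lo, b_i + (b_u - b_i) * f2, b_u))))
    else:
        raise DataValidationError(f"unknown composition: {composition!r}")

    if not (u.min() <= truth.midpoint1_M and u.max() >= truth.midpoint2_M):
        label = (label + " [warning: grid does not span both midpoints]").strip()

    rng = np.random.default_rng(truth.seed)
    signal = signal * _lognormal_factors(rng, truth.noise_cv, u.size)
    return UnfoldingProfile(u, signal, temperature_K=temperature_K, label=label)


def generate_scattering(
    conc_grid_M: Sequence[float],
    cmc_like_threshold_M: Optional[float] = None,
    seed: int = 0,
    base_intensity: float = 50.0,
    rise_slope_per_M: Optional[float] = None,
    noise_cv: float = 0.02,
) -> TitrationSeries:
    """Rayleigh-scattering intensity vs ligand concentration.

    Flat low signal below an aggregation threshold, steep linear rise above;
    ``cmc_like_threshold_M=None`` means no aggregation over the grid.
    """
    conc = np.asarray(conc_grid_M, dtype=float)
    if not np.all(np.diff(conc) > 0):
        raise DataValidationError("conc grid must be strictly increasing")
    signal = np.full(conc.size, base_intensity)
    if cmc_like_threshold_M is not None:
        if rise_slope_per_M is None:
            rise_slope_per_M = 5e5 * base_intensity
        above = conc > cmc_like_threshold_M
        signal = signal + np.where(above, (conc - cmc_like_threshold_M) * rise_slope_per_M, 0.0)
    rng = np.random.default_rng(seed)
    noisy = signal * _lognormal_factors(rng, noise_cv, conc.size)
    # first point is conventionally ligand-free for a TitrationSeries
    if conc[0] != 0:
        raise DataValidationError("scattering grid must start at 0")
    return TitrationSeries(conc, noisy, label="scattering@350nm")
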