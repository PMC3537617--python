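"""Circular-dichroism conversions and near-UV shape diagnostics.

Raw CD in millidegrees is converted to mean residue ellipticity

    [theta](lambda) = CD_mdeg(lambda) / (10 * n_residues * l_cm * C_M)

in deg cm^2 dmol^-1, where n_residues is the number of amino acid residues
(583 for bovine serum albumin), l the cell path length in cm and C the molar
protein concentration.  The factor-of-10 divisor is the standard
molar-concentration convention that returns deg cm^2 dmol^-1 from those
units; it is covered by a unit test so an alternative convention is a
one-line change.

The near-UV tertiary-structure diagnostic is the ellipticity ratio between
two wavelengths (268/262 nm by default), read at the nearest grid points
without interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataValidationError
from .io_spectra import SignalKind, Spectrum


@dataclass(frozen=True)
class MREParams:
    """Parameters of the mean-residue-ellipticity conversion."""

    n_residues: int = 583
    path_cm: float = 0.1
    protein_conc_M: float = 5e-6

    def __post_init__(self) -> None:
        if not (self.n_residues > 0 and self.path_cm > 0 and self.protein_conc_M > 0):
            raise DataValidationError("all MRE parameters must be positive")


def to_mre(spectrum: Spectrum, params: MREParams) -> Spectrum:
    """Convert a millidegree CD spectrum to mean residue ellipticity."""
    if spectrum.signal_kind is not SignalKind.CD_MILLIDEG:
        raise TypeError(
            f"to_mre expects a {SignalKind.CD_MILLIDEG.value} spectrum, "
            f"got {spectrum.signal_kind.value}"
        )
    divisor = 10.0 * params.n_residues * params.path_cm * params.protein_conc_M
    return Spectrum(
        spectrum.wavelength_nm.copy(),
        spectrum.signal / divisor,
        SignalKind.CD_MRE,
        label=spectrum.label,
    )


def ellipticity_ratio(
    spectrum: Spectrum, num_nm: float = 268.0, den_nm: float = 262.0,
    max_offset_nm: float = 0.5,
) -> float:
    """Ratio of ellipticities at two wavelengths (nearest grid points).

    No interpolation: the nearest grid point must lie within
    ``max_offset_nm`` of each requested wavelength.
    """
    wl = spectrum.wavelength_nm
    values = []
    for target in (num_nm, den_nm):
        idx = int(np.argmin(np.abs(wl - target)))
        if abs(wl[idx] - target) > max_offset_nm:
            raise DataValidationError(
                f"no grid point within {max_offset_nm:g} nm of {target:g} nm"
            )
        values.append(float(spectrum.signal[idx]))
    num, den = values
    if abs(den) < 1e-12:
        raise DataValidationError(f"ellipticity at {den_nm:g} nm is degenerate (~0)")
    return num / den
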