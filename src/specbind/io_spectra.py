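"""Delimited-text I/O and the core spectroscopic data containers.

Data tables are plain CSV/TSV with a required header row and optional
``# key: value`` comment lines carrying metadata (temperature, protein
concentration, label, signal kind).  Explicit keyword arguments to the
readers override file metadata, mirroring command-line flags winning over
embedded comments.  All concentrations are held in mol/L internally; the
readers accept ``conc_unit`` in {"M", "mM", "uM"} and convert on ingest.

No interpolation is ever performed here: spectra with mismatched wavelength
grids are an error, never silently resampled.
"""

from __future__ import annotations

import dataclasses
import enum
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._serial import record_from_dict, record_to_dict
from .constants import T_DEFAULT_K
from .exceptions import (
    DataValidationError,
    FormatError,
    GridAlignmentError,
    SpecbindError,
)

CONC_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6}


class SignalKind(str, enum.Enum):
    FLUORESCENCE = "fluorescence"
    CD_MILLIDEG = "cd_millideg"
    CD_MRE = "cd_mre"
    SCATTERING = "scattering"


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataValidationError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise DataValidationError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise DataValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-resolved signal (fluorescence, CD millidegrees, MRE or
    Rayleigh scattering)."""

    wavelength_nm: np.ndarray
    signal: np.ndarray
    signal_kind: SignalKind
    label: str = ""

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelength_nm, "wavelength_nm")
        sig = _as_float_array(self.signal, "signal")
        if wl.size != sig.size:
            raise DataValidationError("wavelength and signal lengths differ")
        if not np.all(np.diff(wl) > 0):
            raise DataValidationError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "signal_kind", SignalKind(self.signal_kind))
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "signal", sig)


@dataclass(frozen=True)
class TitrationSeries:
    """Ligand concentrations with paired fluorescence intensities at a fixed
    emission wavelength; ``intensity[0]`` is the ligand-free intensity F0."""

    ligand_conc_M: np.ndarray
    intensity: np.ndarray
    temperature_K: float = T_DEFAULT_K
    protein_conc_M: float = 5e-6
    label: str = ""

    def __post_init__(self) -> None:
        conc = _as_float_array(self.ligand_conc_M, "ligand_conc_M")
        inten = _as_float_array(self.intensity, "intensity")
        if conc.size != inten.size:
            raise DataValidationError("concentration and intensity lengths differ")
        if conc[0] != 0.0:
            raise DataValidationError("first ligand concentration must be 0 (F0 point)")
        if np.any(conc < 0):
            raise DataValidationError("ligand concentrations must be >= 0")
        if not np.all(np.diff(conc) > 0):
            dup = np.nonzero(np.diff(conc) <= 0)[0][0] + 1
            raise DataValidationError(
                f"ligand concentrations must be strictly increasing (row {dup})"
            )
        bad = np.nonzero(inten <= 0)[0]
        if bad.size:
            raise DataValidationError(f"non-positive intensity at row {bad[0]}")
        if not self.temperature_K > 0:
            raise DataValidationError("temperature_K must be > 0")
        if not self.protein_conc_M > 0:
            raise DataValidationError("protein_conc_M must be > 0")
        object.__setattr__(self, "ligand_conc_M", conc)
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "temperature_K", float(self.temperature_K))
        object.__setattr__(self, "protein_conc_M", float(self.protein_conc_M))

    @property
    def f0(self) -> float:
        """Fluorescence intensity in the absence of quencher."""
        return float(self.intensity[0])


@dataclass(frozen=True)
class UnfoldingProfile:
    """Denaturant concentration versus signal (fluorescence at a fixed
    emission wavelength) for an equilibrium unfolding experiment."""

    denaturant_M: np.ndarray
    signal: np.ndarray
    temperature_K: float = T_DEFAULT_K
    label: str = ""

    def __post_init__(self) -> None:
        den = _as_float_array(self.denaturant_M, "denaturant_M")
        sig = _as_float_array(self.signal, "signal")
        if den.size != sig.size:
            raise DataValidationError("denaturant and signal lengths differ")
        if np.any(den < 0):
            raise DataValidationError("denaturant concentrations must be >= 0")
        if np.any(np.diff(den) < 0):
            raise DataValidationError("denaturant concentrations must be non-decreasing")
        object.__setattr__(self, "denaturant_M", den)
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "temperature_K", float(self.temperature_K))


# ---------------------------------------------------------------------------
# delimited-text tables
# ---------------------------------------------------------------------------

def _parse_table(path: str | Path, delimiter: Optional[str]) -> tuple[dict, pd.DataFrame]:
    """Read a CSV/TSV table, returning (# key: value) metadata and the frame.

    Delimiter: explicit argument wins; otherwise tab is auto-detected from the
    header line, with comma as the default.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    text = path.read_text()
    meta: dict[str, str] = {}
    data_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        if stripped:
            data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no data rows")
    if delimiter is None:
        delimiter = "\t" if "\t" in data_lines[0] else ","
    try:
        frame = pd.read_csv(io.StringIO("\n".join(data_lines)), sep=delimiter,
                            float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: could not parse table ({exc})") from exc
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns, got {frame.shape[1]}")
    return meta, frame


def _numeric_column(frame: pd.DataFrame, idx: int, path: Any) -> np.ndarray:
    col = pd.to_numeric(frame.iloc[:, idx], errors="coerce")
    if col.isna().any():
        row = int(col.isna().idxmax())
        raise FormatError(f"{path}: non-numeric value in column "
                          f"'{frame.columns[idx]}' at data row {row}")
    return col.to_numpy(dtype=float)


def read_titration(
    path: str | Path,
    delimiter: Optional[str] = None,
    conc_unit: str = "M",
    temperature_K: Optional[float] = None,
    protein_conc_M: Optional[float] = None,
    label: Optional[str] = None,
) -> TitrationSeries:
    """Read a quench-titration table (ligand concentration, intensity).

    Metadata may be embedded as ``# temperature_K: 298`` comment lines;
    explicit arguments override embedded values.  Rows are sorted by
    concentration on ingest.
    """
    if conc_unit not in CONC_UNIT_FACTORS:
        raise FormatError(f"unknown concentration unit: {conc_unit!r}")
    meta, frame = _parse_table(path, delimiter)
    conc = _numeric_column(frame, 0, path) * CONC_UNIT_FACTORS[conc_unit]
    inten = _numeric_column(frame, 1, path)
    order = np.argsort(conc, kind="stable")
    conc, inten = conc[order], inten[order]
    temp = temperature_K if temperature_K is not None else float(meta.get("temperature_K", T_DEFAULT_K))
    prot = protein_conc_M if protein_conc_M is not None else float(meta.get("protein_conc_M", 5e-6))
    lab = label if label is not None else meta.get("label", Path(path).stem)
    return TitrationSeries(conc, inten, temperature_K=temp, protein_conc_M=prot, label=lab)


def read_unfolding(
    path: str | Path,
    delimiter: Optional[str] = None,
    conc_unit: str = "M",
    temperature_K: Optional[float] = None,
    label: Optional[str] = None,
) -> UnfoldingProfile:
    """Read a denaturation table (denaturant concentration, signal)."""
    if conc_unit not in CONC_UNIT_FACTORS:
        raise FormatError(f"unknown concentration unit: {conc_unit!r}")
    meta, frame = _parse_table(path, delimiter)
    den = _numeric_column(frame, 0, path) * CONC_UNIT_FACTORS[conc_unit]
    sig = _numeric_column(frame, 1, path)
    order = np.argsort(den, kind="stable")
    temp = temperature_K if temperature_K is not None else float(meta.get("temperature_K", T_DEFAULT_K))
    lab = label if label is not None else meta.get("label", Path(path).stem)
    return UnfoldingProfile(den[order], sig[order], temperature_K=temp, label=lab)


def read_spectrum(
    path: str | Path,
    delimiter: Optional[str] = None,
    signal_kind: Optional[str | SignalKind] = None,
    label: Optional[str] = None,
) -> Spectrum:
    """Read a wavelength-vs-signal table."""
    meta, frame = _parse_table(path, delimiter)
    wl = _numeric_column(frame, 0, path)
    sig = _numeric_column(frame, 1, path)
    order = np.argsort(wl, kind="stable")
    kind = signal_kind if signal_kind is not None else meta.get("signal_kind")
    if kind is None:
        raise FormatError(f"{path}: signal_kind neither embedded nor supplied")
    lab = label if label is not None else meta.get("label", Path(path).stem)
    return Spectrum(wl[order], sig[order], SignalKind(kind), label=lab)


def _write_table(path: str | Path, meta: dict, columns: dict[str, np.ndarray]) -> None:
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    names = list(columns)
    lines.append(",".join(names))
    arrays = [np.asarray(columns[n], dtype=float) for n in names]
    for row in zip(*arrays):
        lines.append(",".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    _write_table(
        path,
        {"temperature_K": f"{series.temperature_K:.17g}",
         "protein_conc_M": f"{series.protein_conc_M:.17g}",
         "label": series.label},
        {"ligand_conc_M": series.ligand_conc_M, "intensity": series.intensity},
    )


def write_unfolding(profile: UnfoldingProfile, path: str | Path) -> None:
    _write_table(
        path,
        {"temperature_K": f"{profile.temperature_K:.17g}", "label": profile.label},
        {"denaturant_M": profile.denaturant_M, "signal": profile.signal},
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    _write_table(
        path,
        {"signal_kind": spectrum.signal_kind.value, "label": spectrum.label},
        {"wavelength_nm": spectrum.wavelength_nm, "signal": spectrum.signal},
    )


# ---------------------------------------------------------------------------
# background subtraction
# ---------------------------------------------------------------------------

def subtract_background(sample: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise subtraction of a free-ligand background spectrum.

    The wavelength grids must be identical; no interpolation is performed.
    """
    if sample.wavelength_nm.size != background.wavelength_nm.size or not np.array_equal(
        sample.wavelength_nm, background.wavelength_nm
    ):
        raise GridAlignmentError("sample and background wavelength grids differ")
    return Spectrum(
        sample.wavelength_nm.copy(),
        sample.signal - background.signal,
        sample.signal_kind,
        label=sample.label,
    )


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

def _result_registry() -> dict[str, type]:
    # imported lazily: the result dataclasses live in the analysis modules
    from .binding import BindingFit
    from .quenching import MechanismReport, QuenchFit, SpecificityReport
    from .thermo import KineticResult, ThermoResult
    from .unfolding import BaselineSet, StabilityComparison, TransitionFit, UnfoldingFitSet

    return {
        cls.__name__: cls
        for cls in (
            QuenchFit, MechanismReport, SpecificityReport, BindingFit,
            ThermoResult, KineticResult, BaselineSet, TransitionFit,
            UnfoldingFitSet, StabilityComparison,
        )
    }


def write_result(record: Any, path: str | Path, provenance: Optional[dict] = None) -> None:
    """Serialize a result dataclass to a structured JSON file.

    The file carries the record type, every field (units are embedded in the
    field names), the package version and optional provenance (input files,
    seed, parameters).  Numeric output keeps full float precision.
    """
    if not dataclasses.is_dataclass(record) or isinstance(record, type):
        raise SpecbindError(f"not a result record: {record!r}")
    name = type(record).__name__
    if name not in _result_registry():
        raise SpecbindError(f"unknown result type: {name}")
    payload = {
        "record_type": name,
        "specbind_version": __version__,
        "provenance": provenance or {},
        "fields": record_to_dict(record),
    }
    path = Path(path)
    if str(path) == "":
        raise OSError("empty output path")
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_result(path: str | Path) -> Any:
    """Read back a JSON result file written by :func:`write_result`."""
    payload = json.loads(Path(path).read_text())
    try:
        cls = _result_registry()[payload["record_type"]]
    except KeyError as exc:
        raise FormatError(f"{path}: unknown record type") from exc
    return record_from_dict(cls, payload["fields"])
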