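"""Reproducible multi-stage pipeline: simulate -> fit -> compare.

A run is described by a single YAML/JSON config document with a ``version``
field, a ``seed`` (mandatory whenever any stochastic simulation stage is
present), an ``output_dir`` and an ordered list of stages.  Stages consume
files produced by earlier stages (a missing input is a dependency error) and
every artifact is recorded, with its SHA-256 hash, in a manifest written at
the end of the run.  Identical config + seed give byte-identical JSON
artifacts and manifest hashes.

Logging goes to stderr; set ``log_format: json`` for machine-readable
JSON-lines records (warnings such as intercept deviations and excluded
points are logged per stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .binding import fit_double_log
from .constants import DEFAULT_REGIONS
from .cd import MREParams, to_mre
from .exceptions import ConfigError, DependencyError
from .io_spectra import (
    read_result,
    read_spectrum,
    read_titration,
    read_unfolding,
    write_result,
    write_spectrum,
    write_titration,
    write_unfolding,
)
from .quenching import classify_mechanism_report, fit_stern_volmer, specificity_check
from .synthetic import (
    QuenchTruth,
    UnfoldTruth,
    generate_quench,
    generate_scattering,
    generate_temperature_series,
    generate_unfolding,
)
from .thermo import diffusion_limited_kf, fit_vant_hoff, residence_time
from .unfolding import analyze_profile, compare_stability

logger = logging.getLogger("specbind")

KNOWN_STAGES = (
    "simulate", "fit-sv", "classify", "specificity", "fit-binding",
    "vant-hoff", "residence", "fit-unfolding", "compare", "mre",
)


class StageSpec(BaseModel):
    stage: str
    params: dict = Field(default_factory=dict)
    input: Optional[str] = None
    inputs: list[str] = Field(default_factory=list)
    output: Optional[str] = None
    outputs: list[str] = Field(default_factory=list)

    def input_names(self) -> list[str]:
        return ([self.input] if self.input else []) + list(self.inputs)

    def output_names(self) -> list[str]:
        return ([self.output] if self.output else []) + list(self.outputs)


class RunConfig(BaseModel):
    version: int = 1
    seed: Optional[int] = None
    output_dir: str = "specbind_out"
    log_level: str = "INFO"
    log_format: str = "text"
    stages: list[StageSpec] = Field(default_factory=list)


class _JsonLineFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        return json.dumps(
            {"level": record.levelname, "stage": getattr(record, "stage", None),
             "message": record.getMessage()},
            sort_keys=True,
        )


def load_config(path: str | Path, overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML/JSON config file; ``overrides`` (e.g. CLI flags) win."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: invalid config: {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stochastic(stage: StageSpec) -> bool:
    if stage.stage != "simulate":
        return False
    if stage.params.get("kind") == "scatter":
        return True
    return float(stage.params.get("noise_cv", 0.0)) > 0


def run_pipeline(config: RunConfig, base_dir: str | Path = ".") -> dict:
    """Execute the configured stages in order and return the manifest."""
    for stage in config.stages:
        if stage.stage not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage: {stage.stage!r}")
    if any(_stochastic(s) for s in config.stages) and config.seed is None:
        raise ConfigError("config has stochastic simulate stages but no seed")

    handler = logging.StreamHandler(sys.stderr)
    if config.log_format == "json":
        handler.setFormatter(_JsonLineFormatter())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers = [handler]
    logger.setLevel(config.log_level.upper())

    out_dir = Path(base_dir) / config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    produced: set[str] = set()
    manifest_stages = []

    for i, stage in enumerate(config.stages):
        in_paths = []
        for name in stage.input_names():
            p = out_dir / name
            if name in produced and p.is_file():
                in_paths.append(p)
            elif Path(name).is_file():
                in_paths.append(Path(name))
            else:
                raise DependencyError(
                    f"stage {i} ({stage.stage}): input {name!r} was not produced "
                    "by an earlier stage and does not exist"
                )
        out_paths = [out_dir / name for name in stage.output_names()]
        all_outputs = _STAGE_HANDLERS[stage.stage](stage, in_paths, out_paths,
                                                   config.seed)
        produced.update(all_outputs)
        logger.info("stage %s done: %s -> %s", stage.stage,
                    stage.input_names(), all_outputs, extra={"stage": stage.stage})
        manifest_stages.append({
            "stage": stage.stage,
            "params": stage.params,
            "inputs": stage.input_names(),
            "outputs": sorted(all_outputs),
            "sha256": {n: _sha256(out_dir / n) for n in sorted(all_outputs)},
        })

    manifest = {
        "specbind_version": __version__,
        "config_version": config.version,
        "seed": config.seed,
        "output_dir": str(config.output_dir),
        "stages": manifest_stages,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stage handlers: (stage, input paths, output paths, seed) -> produced names
# ---------------------------------------------------------------------------

def _require_outputs(stage: StageSpec, out_paths: list[Path], n: int) -> None:
    if len(out_paths) != n:
        raise ConfigError(f"stage {stage.stage}: expected {n} output name(s)")


def _stage_simulate(stage: StageSpec, ins: list[Path], outs: list[Path],
                    seed: Optional[int]) -> list[str]:
    p = dict(stage.params)
    kind = p.pop("kind", None)
    if kind is None:
        raise ConfigError("simulate stage needs params.kind")
    eff_seed = int(p.pop("seed", seed if seed is not None else 0))
    if kind == "quench":
        _require_outputs(stage, outs, 1)
        truth = QuenchTruth(
            ka_assoc_per_M=float(p.pop("ka_assoc_per_M")),
            n_sites=float(p.pop("n_sites", 1.0)),
            f0=float(p.pop("f0", 1000.0)),
            noise_cv=float(p.pop("noise_cv", 0.0)),
            seed=eff_seed,
        )
        series = generate_quench(truth, p.pop("conc_grid_M", None),
                                 temperature_K=float(p.pop("temperature_K", 298.0)),
                                 protein_conc_M=float(p.pop("protein_conc_M", 5e-6)))
        write_titration(series, outs[0])
    elif kind == "tempseries":
        _require_outputs(stage, outs, 1)
        base = QuenchTruth(
            ka_assoc_per_M=1.0 if "ka_assoc_per_M" not in p else float(p.pop("ka_assoc_per_M")),
            n_sites=float(p.pop("n_sites", 1.0)),
            f0=float(p.pop("f0", 1000.0)),
            noise_cv=float(p.pop("noise_cv", 0.0)),
            seed=eff_seed,
        )
        temps = [float(t) for t in p.pop("temps_K")]
        series = generate_temperature_series(
            float(p.pop("dh_J_per_mol")), float(p.pop("ds_J_per_mol_K")),
            temps, base, p.pop("conc_grid_M", None),
            protein_conc_M=float(p.pop("protein_conc_M", 5e-6)))
        template = outs[0].name
        if "{T}" not in template:
            raise ConfigError("tempseries output name must contain '{T}'")
        extra = []
        for s in series:
            name = template.replace("{T}", f"{s.temperature_K:g}")
            write_titration(s, outs[0].parent / name)
            extra.append(name)
        return extra
    elif kind == "unfold":
        _require_outputs(stage, outs, 1)
        truth = UnfoldTruth(
            dg1_J_per_mol=float(p.pop("dg1_J_per_mol")),
            m1_J_per_mol_per_M=float(p.pop("m1_J_per_mol_per_M")),
            dg2_J_per_mol=float(p.pop("dg2_J_per_mol")),
            m2_J_per_mol_per_M=float(p.pop("m2_J_per_mol_per_M")),
            baselines=tuple(tuple(b) for b in p.pop(
                "baselines", ((1.0, 0.0), (0.55, 0.0), (0.15, 0.0)))),
            noise_cv=float(p.pop("noise_cv", 0.0)),
            seed=eff_seed,
        )
        profile = generate_unfolding(
            truth, p.pop("denat_grid_M", None),
            temperature_K=float(p.pop("temperature_K", 298.0)),
            composition=p.pop("composition", "sequential"))
        write_unfolding(profile, outs[0])
    elif kind == "scatter":
        _require_outputs(stage, outs, 1)
        series = generate_scattering(
            p.pop("conc_grid_M"),
            cmc_like_threshold_M=p.pop("cmc_like_threshold_M", None),
            seed=eff_seed,
            noise_cv=float(p.pop("noise_cv", 0.02)),
        )
        write_titration(series, outs[0])
    else:
        raise ConfigError(f"unknown simulate kind: {kind!r}")
    return [outs[0].name]


def _stage_fit_sv(stage, ins, outs, seed):
    _require_outputs(stage, outs, len(ins))
    for src, dst in zip(ins, outs):
        series = read_titration(src)
        fit = fit_stern_volmer(series, tau0_s=float(stage.params.get("tau0_s", 5e-9)))
        for w in fit.warnings:
            logger.warning("%s: %s", src.name, w, extra={"stage": stage.stage})
        write_result(fit, dst, provenance={"input": src.name, "stage": stage.stage})
    return [p.name for p in outs]


def _stage_classify(stage, ins, outs, seed):
    _require_outputs(stage, outs, 1)
    fits = [read_result(p) for p in ins]
    report = classify_mechanism_report(
        fits, float(stage.params.get("collisional_limit_per_M_per_s", 1e10)))
    write_result(report, outs[0],
                 provenance={"inputs": [p.name for p in ins], "stage": stage.stage})
    return [outs[0].name]


def _stage_specificity(stage, ins, outs, seed):
    _require_outputs(stage, outs, 1)
    fits = [read_result(p) for p in ins]
    report = specificity_check(fits, float(stage.params.get("max_rel_drop", 0.5)))
    write_result(report, outs[0],
                 provenance={"inputs": [p.name for p in ins], "stage": stage.stage})
    return [outs[0].name]


def _stage_fit_binding(stage, ins, outs, seed):
    _require_outputs(stage, outs, len(ins))
    for src, dst in zip(ins, outs):
        fit = fit_double_log(read_titration(src))
        if fit.n_excluded:
            logger.warning("%s: %d points excluded (F >= F0)", src.name,
                           fit.n_excluded, extra={"stage": stage.stage})
        write_result(fit, dst, provenance={"input": src.name, "stage": stage.stage})
    return [p.name for p in outs]


def _stage_vant_hoff(stage, ins, outs, seed):
    _require_outputs(stage, outs, 1)
    if ins:
        fits = [read_result(p) for p in ins]
        points = [(f.temperature_K, f.ka_assoc_per_M) for f in fits]
    else:
        points = [(float(t), float(k)) for t, k in stage.params["points"]]
    result = fit_vant_hoff(points)
    write_result(result, outs[0],
                 provenance={"inputs": [p.name for p in ins],
                             "points": points, "stage": stage.stage})
    return [outs[0].name]


def _stage_residence(stage, ins, outs, seed):
    _require_outputs(stage, outs, 1)
    p = stage.params
    if ins:  # Ka from an upstream binding fit
        ka = read_result(ins[0]).ka_assoc_per_M
    else:
        ka = float(p["ka_assoc_per_M"])
    kf = p.get("kf_per_M_per_s", "auto")
    d = float(p.get("d_m2_per_s", 1e-9))
    r = float(p.get("r_m", 4e-10))
    if kf == "auto":
        kf = diffusion_limited_kf(d, r)
    result = residence_time(ka, float(kf), d_m2_per_s=d, r_m=r)
    write_result(result, outs[0], provenance={"stage": stage.stage,
                                              "kf_source": p.get("kf_per_M_per_s", "auto")})
    return [outs[0].name]


def _parse_regions(spec_str):
    # "0:2.2,4.8:5.2,8:9" -> ((0,2.2),(4.8,5.2),(8,9))
    parts = spec_str.split(",")
    if len(parts) != 3:
        raise ConfigError("regions must be three lo:hi windows")
    return tuple(tuple(float(x) for x in part.split(":")) for part in parts)


def _stage_fit_unfolding(stage, ins, outs, seed):
    _require_outputs(stage, outs, len(ins))
    p = stage.params
    regions = p.get("regions", DEFAULT_REGIONS)
    if isinstance(regions, str):
        regions = _parse_regions(regions)
    else:
        regions = tuple(tuple(float(x) for x in r) for r in regions)
    for src, dst in zip(ins, outs):
        profile = read_unfolding(src)
        fit_set = analyze_profile(profile, regions, p.get("method", "both"))
        write_result(fit_set, dst,
                     provenance={"input": src.name, "regions": [list(r) for r in regions],
                                 "stage": stage.stage})
    return [p.name for p in outs]


def _stage_compare(stage, ins, outs, seed):
    _require_outputs(stage, outs, 1)
    if len(ins) != 2:
        raise ConfigError("compare stage needs exactly two inputs (apo, complex)")
    method = stage.params.get("method", "nonlinear")
    apo, cplx = (read_result(p) for p in ins)
    comparison = compare_stability(apo.pair(method), cplx.pair(method))
    write_result(comparison, outs[0],
                 provenance={"apo": ins[0].name, "complex": ins[1].name,
                             "stage": stage.stage})
    return [outs[0].name]


def _stage_mre(stage, ins, outs, seed):
    _require_outputs(stage, outs, len(ins))
    p = stage.params
    params = MREParams(n_residues=int(p.get("n_residues", 583)),
                       path_cm=float(p.get("path_cm", 0.1)),
                       protein_conc_M=float(p.get("protein_conc_M", 5e-6)))
    for src, dst in zip(ins, outs):
        write_spectrum(to_mre(read_spectrum(src), params), dst)
    return [p.name for p in outs]


_STAGE_HANDLERS = {
    "simulate": _stage_simulate,
    "fit-sv": _stage_fit_sv,
    "classify": _stage_classify,
    "specificity": _stage_specificity,
    "fit-binding": _stage_fit_binding,
    "vant-hoff": _stage_vant_hoff,
    "residence": _stage_residence,
    "fit-unfolding": _stage_fit_unfolding,
    "compare": _stage_compare,
    "mre": _stage_mre,
}
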