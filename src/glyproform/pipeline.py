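"""End-to-end pipeline: XIC tables -> site profiles -> proteoform profile ->
constructed spectrum -> comparison against an experimental spectrum.

Mirrors the hybrid workflow of integrating peptide-centric quantification
with native MS: the peptide-level occupancies predict the intact proteoform
distribution, which is rendered as an in-silico spectrum and correlated with
the measured one.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import io as gio
from .compare_validate import ComparisonResult, compare_spectra
from .glycan_algebra import SolverConfig
from .mass_core import backbone_mass as compute_backbone_mass
from .proteoform_builder import (
    BuilderConfig,
    ProteoformProfile,
    apply_cutoff,
    convolve,
    modal_proteoform,
)
from .site_profiles import average_runs, normalize_site
from .spectrum_tools import (
    ChargeEnvelope,
    PeakShapeConfig,
    Spectrum,
    annotate_differences,
    deconvolute_spectrum,
    simulate_spectrum,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "read_pipeline_config"]

logger = logging.getLogger("glyproform")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs; strictly validated on read."""

    output_dir: Path
    backbone_mass: float | None = None
    assembly_config: Path | None = None
    xic_table: Path | None = None
    site_profiles: Path | None = None
    experimental_spectrum: Path | None = None
    builder: BuilderConfig = field(default_factory=BuilderConfig)
    envelope: ChargeEnvelope = field(
        default_factory=lambda: ChargeEnvelope(21, 26, 24.0, 1.5)
    )
    peak_shape: PeakShapeConfig = field(default_factory=PeakShapeConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    comparison_axis: str = "zero_charge"  # or "mz"
    comparison_grid_step: float | None = None
    match_tolerance: float = 3.0
    min_rel_intensity: float = 0.01
    baseline_subtract: bool = False
    grid_step: float = 0.05
    log_level: str = "INFO"


_TOP_KEYS = {
    "output_dir",
    "backbone_mass",
    "assembly_config",
    "xic_table",
    "site_profiles",
    "experimental_spectrum",
    "builder",
    "envelope",
    "peak_shape",
    "solver",
    "comparison_axis",
    "comparison_grid_step",
    "match_tolerance",
    "min_rel_intensity",
    "baseline_subtract",
    "grid_step",
    "log_level",
}


def read_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config (YAML/JSON); unknown keys are rejected and
    relative paths resolve against the config file."""
    import yaml

    path = Path(path)
    doc: Mapping[str, Any] = yaml.safe_load(path.read_text()) or {}
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    base = path.parent

    def _path(key: str) -> Path | None:
        return (base / doc[key]) if key in doc and doc[key] is not None else None

    kwargs: dict[str, Any] = {
        "output_dir": base / doc.get("output_dir", "out"),
        "assembly_config": _path("assembly_config"),
        "xic_table": _path("xic_table"),
        "site_profiles": _path("site_profiles"),
        "experimental_spectrum": _path("experimental_spectrum"),
    }
    if "backbone_mass" in doc and doc["backbone_mass"] is not None:
        kwargs["backbone_mass"] = float(doc["backbone_mass"])
    if "builder" in doc:
        kwargs["builder"] = BuilderConfig(**doc["builder"])
    if "envelope" in doc:
        kwargs["envelope"] = ChargeEnvelope(**doc["envelope"])
    if "peak_shape" in doc:
        kwargs["peak_shape"] = PeakShapeConfig(**doc["peak_shape"])
    if "solver" in doc:
        kwargs["solver"] = SolverConfig(**doc["solver"])
    for key in (
        "comparison_axis",
        "comparison_grid_step",
        "match_tolerance",
        "min_rel_intensity",
        "baseline_subtract",
        "grid_step",
        "log_level",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    for key in ("xic_table", "site_profiles", "experimental_spectrum", "assembly_config"):
        p = kwargs.get(key)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{path}: referenced file missing: {p}")
    return PipelineConfig(**kwargs)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("mass_core")
def _resolve_backbone(config: PipelineConfig) -> float:
    if config.assembly_config is not None:
        assembly = gio.read_assembly_config(config.assembly_config)
        return compute_backbone_mass(assembly)
    if config.backbone_mass is None:
        raise ValueError("need backbone_mass or assembly_config")
    return config.backbone_mass


@_stage("site_profiles")
def _resolve_site_profiles(config: PipelineConfig):
    if config.site_profiles is not None:
        return gio.read_site_profiles(config.site_profiles)
    if config.xic_table is None:
        raise ValueError("need xic_table or site_profiles")
    records = gio.read_xic_table(config.xic_table)
    by_site_run = defaultdict(list)
    for r in records:
        by_site_run[(r.site_id, r.run_id)].append(r)
    by_site = defaultdict(list)
    for (site, _run), recs in by_site_run.items():
        by_site[site].append(normalize_site(recs))
    return [average_runs(per_run) for per_run in by_site.values()]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle into ``output_dir``.

    Outputs: ``proteoforms.tsv`` (retained species), ``differences.tsv``
    (annotated mass deltas), ``constructed_spectrum.csv``,
    ``comparison.json`` (when an experimental spectrum is given) and
    ``run_log.json`` with all effective parameters.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    backbone = _resolve_backbone(config)
    logger.info("backbone mass: %.2f Da", backbone)
    profiles = _resolve_site_profiles(config)
    logger.info("site profiles: %d sites", len(profiles))

    try:
        full = convolve(backbone, profiles, config.builder)
        retained = apply_cutoff(full, config.builder.cutoff_fraction)
        modal = modal_proteoform(full)
    except Exception as exc:
        raise PipelineError("proteoform_builder", exc) from exc
    logger.info(
        "proteoforms: %d species, %d above cutoff; modal %s at %.2f Da",
        len(full.species),
        len(retained.species),
        modal.composition,
        modal.mass,
    )

    try:
        constructed = simulate_spectrum(
            full,
            config.envelope,
            config.peak_shape,
            grid_step=config.grid_step,
        )
    except Exception as exc:
        raise PipelineError("spectrum_tools", exc) from exc

    gio.write_proteoform_table(retained, out / "proteoforms.tsv")
    gio.write_spectrum_csv(constructed, out / "constructed_spectrum.csv")

    diffs = (
        annotate_differences([s.mass for s in retained.species], config.solver)
        if len(retained.species) >= 2
        else []
    )
    with (out / "differences.tsv").open("w") as fh:
        fh.write("mass_low\tmass_high\tdelta\tlabel\n")
        for lo, hi, delta, label in diffs:
            fh.write(f"{lo:.2f}\t{hi:.2f}\t{delta:.2f}\t{label}\n")

    report: dict[str, Any] = {
        "backbone_mass": backbone,
        "n_sites": len(profiles),
        "n_species": len(full.species),
        "n_species_above_cutoff": len(retained.species),
        "modal_composition": str(modal.composition),
        "modal_mass": modal.mass,
        "modal_abundance": modal.abundance,
    }

    if config.experimental_spectrum is not None:
        try:
            experimental = gio.read_spectrum_csv(config.experimental_spectrum)
            comparison = _compare(config, full, constructed, experimental)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("compare_validate", exc) from exc
        gio.write_comparison_json(comparison, out / "comparison.json")
        report["pearson_r"] = comparison.pearson_r
        report["n_matched"] = len(comparison.matched)
        report["n_unmatched_experimental"] = len(comparison.unmatched_experimental)

    run_log = {
        "effective_config": _jsonable(config),
        "report": report,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return report


def _compare(
    config: PipelineConfig,
    profile: ProteoformProfile,
    constructed: Spectrum,
    experimental: Spectrum,
) -> ComparisonResult:
    if config.comparison_axis == "zero_charge" and experimental.axis_kind == "mz":
        charges = [int(z) for z in config.envelope.charges]
        lo = profile.masses.min() - 200.0
        hi = profile.masses.max() + 200.0
        mass_grid = np.arange(lo, hi, 1.0)
        experimental = deconvolute_spectrum(experimental, charges, mass_grid)
        constructed = deconvolute_spectrum(constructed, charges, mass_grid)
    return compare_spectra(
        experimental,
        constructed,
        grid_step=config.comparison_grid_step,
        tol_mass=config.match_tolerance,
        min_rel_intensity=config.min_rel_intensity,
        baseline_subtract=config.baseline_subtract,
        solver=config.solver,
    )


def _jsonable(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
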