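"""End-to-end orchestration: phantom -> tractography -> sectioning &
deformation -> reconstruction -> evaluation, with a manifest recording
every emitted file.  Fully deterministic under a fixed master seed:
stage seeds fan out through named substreams, so adding a stage never
perturbs earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io, overlap, reconstruction, tractography
from ._rng import child_seed
from .errors import ConfigurationError
from .phantom import PhantomConfig, build_phantom, deform_stack, simulate_sectioning
from .reconstruction import ReconConfig
from .tractography import TrackingParams

SIDES = ("left", "right")


@dataclass
class SectionConfig:
    """Sectioning + deformation settings for the synthetic histology."""

    section_thickness_mm: float = 0.25
    retention_interval: int = 4
    deform_amplitude_mm: float = 3.0
    deform_smoothness_mm: float = 6.0

    def validate(self) -> None:
        if self.section_thickness_mm <= 0:
            raise ConfigurationError("section_thickness_mm must be positive")
        if self.retention_interval < 1:
            raise ConfigurationError("retention_interval must be >= 1")
        if self.deform_amplitude_mm < 0:
            raise ConfigurationError("deform_amplitude_mm must be >= 0")


@dataclass
class EvalConfig:
    n_thresholds: int = 100
    threshold_upper: float = 0.0035  # 0.35% of accepted streamlines
    roi_band_voxels: int = 3  # dilation of each ROI for TN counting
    dilation_margin_mm: float = 5.0
    optimal_roi: str = "peduncle"  # ROI whose max-SI threshold defines "optimal"

    def validate(self) -> None:
        if self.n_thresholds < 2:
            raise ConfigurationError("n_thresholds must be >= 2")
        if self.threshold_upper <= 0:
            raise ConfigurationError("threshold_upper must be positive")

    def thresholds(self) -> np.ndarray:
        return np.linspace(0.0, self.threshold_upper, self.n_thresholds)


@dataclass
class RunConfig:
    phantom: PhantomConfig = dc_field(default_factory=PhantomConfig)
    tracking: TrackingParams = dc_field(default_factory=TrackingParams)
    recon: ReconConfig = dc_field(default_factory=ReconConfig)
    section: SectionConfig = dc_field(default_factory=SectionConfig)
    evaluation: EvalConfig = dc_field(default_factory=EvalConfig)
    output_dir: str = "run_output"
    master_seed: int = 0

    def validate(self) -> None:
        self.phantom.validate()
        self.tracking.validate()
        self.recon.validate()
        self.section.validate()
        self.evaluation.validate()

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"]["grid_shape"] = list(d["phantom"]["grid_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "phantom": PhantomConfig,
            "tracking": TrackingParams,
            "recon": ReconConfig,
            "section": SectionConfig,
            "evaluation": EvalConfig,
        }
        kwargs = {}
        for key, typ in sub.items():
            if key in d:
                val = d.pop(key)
                if key == "phantom" and "grid_shape" in val:
                    val = dict(val)
                    val["grid_shape"] = tuple(val["grid_shape"])
                kwargs[key] = typ(**val)
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = dc_field(default_factory=dict)

    def record(self, stage: str, status: str, outputs: list, seconds: float) -> None:
        self.stages[stage] = {
            "status": status,
            "outputs": [str(p) for p in outputs],
            "wall_seconds": round(float(seconds), 3),
        }

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "version": self.version,
                "stages": self.stages}

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))
        return path


def evaluate_side(phantom, cmap, side: str, cfg: EvalConfig) -> overlap.OverlapReport:
    """ROC/SI sweep plus FN dilation profiles for one tract side."""
    return _evaluate(phantom, cmap, phantom.reference_mask(side), side, cfg)


def _evaluate(phantom, cmap, ref, side, cfg: EvalConfig) -> overlap.OverlapReport:
    from scipy import ndimage

    regions = dict(phantom.roi_masks(side))
    regions["tract"] = ref
    roi_masks = {
        name: ndimage.binary_dilation(region, iterations=cfg.roi_band_voxels)
        for name, region in regions.items()
    }
    report = overlap.roc_and_si_curves(cmap, ref, roi_masks, cfg.thresholds())
    opt = report.summary[cfg.optimal_roi]["optimal_threshold"]
    pred = tractography.threshold_map(cmap, opt)
    for name, region in regions.items():
        report.dilation[name] = overlap.fn_dilation_profile(
            pred, ref, region, phantom.voxel_size_mm, cfg.dilation_margin_mm)
    return report


def _plot_report(report: overlap.OverlapReport, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "tractconcord"
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for roi, sub in report.rows.groupby("roi"):
        axes[0].plot(sub["FPR"], sub["TPR"], marker=".", label=roi)
        axes[1].plot(sub["threshold"] * 100, sub["SI"], label=roi)
    axes[0].set_xlabel("FPR")
    axes[0].set_ylabel("TPR")
    axes[0].set_title("ROC")
    axes[1].set_xlabel("threshold (% of streamlines)")
    axes[1].set_ylabel("Dice SI")
    axes[1].set_title("SI vs threshold")
    for roi, df in report.dilation.items():
        axes[2].plot(df["margin_mm"], df["covered_fraction"], label=roi)
    axes[2].set_xlabel("dilation margin (mm)")
    axes[2].set_ylabel("reference covered")
    axes[2].set_title("FN dilation profile")
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return path


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, persisting every intermediate.

    Raises on the first failing stage after writing a partial manifest;
    two runs with an identical config produce byte-identical reports.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)
    manifest_path = out / "manifest.json"
    config.to_yaml(out / "run.yaml")

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception:
            manifest.record(name, "failed", [], time.perf_counter() - t0)
            manifest.write(manifest_path)
            raise
        manifest.record(name, "ok", outputs, time.perf_counter() - t0)
        manifest.write(manifest_path)
        return outputs

    state = {}

    def do_phantom():
        pcfg = PhantomConfig(**{**asdict(config.phantom),
                                "rng_seed": child_seed(config.master_seed, "phantom")})
        state["phantom"] = build_phantom(pcfg)
        return [io.write_phantom(out / "phantom", state["phantom"])]

    def do_track():
        outputs = []
        state["maps"] = {}
        for side in SIDES:
            params = TrackingParams(**{
                **asdict(config.tracking),
                "rng_seed": child_seed(config.master_seed, f"track-{side}"),
            })
            cmap = tractography.run_tractography(state["phantom"], params, side=side)
            state["maps"][side] = cmap
            outputs.append(io.write_connectivity_map(
                out / f"connectivity_{side}.nii", cmap))
        return outputs

    def do_section():
        ph = state["phantom"]
        stack = simulate_sectioning(
            ph.intensity_volume, ph.voxel_size_mm,
            config.section.section_thickness_mm, config.section.retention_interval)
        stack = deform_stack(
            stack, config.section.deform_amplitude_mm,
            config.section.deform_smoothness_mm,
            seed=child_seed(config.master_seed, "deform"))
        state["stack"] = stack
        return [io.write_stack(out / "stack", stack)]

    def do_recon():
        ph = state["phantom"]
        result = reconstruction.refine_nonlinear(
            state["stack"], ph.intensity_volume, config.recon,
            reference_voxel_size_mm=ph.voxel_size_mm)
        state["recon"] = result
        vol_path = io.write_volume(
            out / "reconstructed.nii", result.volume,
            (state["stack"].in_plane_spacing_mm,) * 2 + (state["stack"].slice_spacing_mm,))
        metrics = reconstruction.reconstruction_error(
            result, state["stack"], ph.intensity_volume,
            reference_voxel_size_mm=ph.voxel_size_mm)
        metrics_path = out / "recon_metrics.json"
        metrics_path.write_text(json.dumps(metrics, sort_keys=True, indent=1))
        fields_path = out / "recon_fields.npz"
        np.savez(fields_path,
                 **{f"u_{i:04d}": f.u for i, f in enumerate(result.fields)})
        return [vol_path, metrics_path, fields_path]

    def do_evaluate():
        ph = state["phantom"]
        outputs = []
        reports = []
        for side in SIDES:
            rep = _evaluate(ph, state["maps"][side], ph.reference_mask(side),
                            side, config.evaluation)
            reports.append(rep)
            outputs.extend(io.write_report(out / f"report_{side}", rep))
            outputs.append(_plot_report(rep, out / f"report_{side}.svg"))
        averaged = overlap.average_reports(reports)
        outputs.extend(io.write_report(out / "report_averaged", averaged))
        outputs.append(_plot_report(averaged, out / "report_averaged.svg"))
        return outputs

    stage("phantom", do_phantom)
    stage("track", do_track)
    stage("section", do_section)
    stage("recon", do_recon)
    stage("evaluate", do_evaluate)
    return manifest
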