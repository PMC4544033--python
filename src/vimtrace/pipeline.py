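"""End-to-end pipeline: simulate -> segment -> quantify -> report.

Configuration is a single YAML-able mapping with one block per stage;
unknown keys are rejected so typos cannot silently fall back to
defaults.  Every run writes a manifest (config hash, root seed, package
versions, per-field failure count) sufficient to reconstruct it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fibers import segment_fibers
from .nuclei import NucleiParams, segment_nuclei
from .quantify import normalize_to_control, segments_per_cell_table
from .simulate import FieldImage, GroundTruth, SimulationConfig, generate_field

log = logging.getLogger("vimtrace")

__all__ = ["PipelineConfig", "run_pipeline", "process_field", "simulate_conditions"]


@dataclass
class ConditionSpec:
    condition: str
    multiplier: float = 1.0
    time_h: float = 0.0
    dose_nM: float = 0.0


@dataclass
class SegmentParams:
    scales: tuple = (1.0, 2.0, 3.0)
    min_object_px: int = 30
    spur_prune_px: int = 3
    min_segment_length: float = 1.0  # um
    noise_floor_sigmas: float = 6.0


@dataclass
class QuantifyParams:
    min_cells: int = 100
    control_key: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "vimtrace_out"
    input_dir: str | None = None  # if set, read TIFFs instead of simulating
    n_fields: int = 5
    base: SimulationConfig = field(default_factory=SimulationConfig)
    conditions: list = field(default_factory=lambda: [ConditionSpec("control")])
    segment: SegmentParams = field(default_factory=SegmentParams)
    nuclei: NucleiParams = field(default_factory=NucleiParams)
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    write_overlays: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)

        def build(klass, sub):
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - known
            if unknown:
                raise KeyError(
                    f"unknown {klass.__name__} keys: {sorted(unknown)}")
            # YAML gives lists where dataclasses expect tuples
            kwargs = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in sub.items()}
            return klass(**kwargs)

        sub_builders = {
            "base": lambda v: build(SimulationConfig, v),
            "segment": lambda v: build(SegmentParams, v),
            "nuclei": lambda v: build(NucleiParams, v),
            "quantify": lambda v: build(QuantifyParams, v),
            "conditions": lambda v: [build(ConditionSpec, c) for c in v],
        }
        kwargs = {}
        for k, v in d.items():
            if k in sub_builders:
                kwargs[k] = sub_builders[k](v)
            else:
                kwargs[k] = v
        return build_top(cls, kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_top(klass, kwargs):
    known = {f.name for f in dataclasses.fields(klass)}
    unknown = set(kwargs) - known
    if unknown:
        raise KeyError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
    return klass(**kwargs)


def _write_overlay(img: FieldImage, graph, nres, path: Path) -> None:
    """QC overlay: fiber channel with skeleton and nucleus outlines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img.fiber_channel, cmap="gray",
              vmax=np.percentile(img.fiber_channel, 99.5))
    sk = np.ma.masked_where(~graph.skeleton, graph.skeleton)
    ax.imshow(sk, cmap="autumn", alpha=0.9, interpolation="nearest")
    ax.contour(nres.labels > 0, levels=[0.5], colors="cyan", linewidths=0.6)
    ax.set_axis_off()
    fig.tight_layout(pad=0)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def process_field(img: FieldImage, seg: SegmentParams,
                  nuc: NucleiParams, overlay_path: Path | None = None) -> dict:
    """Measure one field: fiber segments and nuclei."""
    segs, _graph, _mask = segment_fibers(
        img.fiber_channel, pixel_size=img.pixel_size, scales=seg.scales,
        min_object_px=seg.min_object_px, spur_prune_px=seg.spur_prune_px,
        min_segment_length=seg.min_segment_length,
        noise_floor_sigmas=seg.noise_floor_sigmas)
    nres = segment_nuclei(img.nuclear_channel, pixel_size=img.pixel_size,
                          params=nuc)
    if overlay_path is not None:
        _write_overlay(img, _graph, nres, overlay_path)
    return {
        "condition": img.metadata.get("condition", "?"),
        "time_h": float(img.metadata.get("time_h", 0.0)),
        "dose_nM": float(img.metadata.get("dose_nM", 0.0)),
        "field": img.metadata.get("field", 0),
        "n_segments": segs.total_count,
        "n_nuclei": nres.nuclei_count,
    }


def simulate_conditions(cfg: PipelineConfig, out_fields: Path | None = None):
    """Generate all configured condition field sets.

    Yields (FieldImage, GroundTruth) pairs; when ``out_fields`` is given,
    each field is also written as a two-page TIFF with a JSON sidecar of
    its ground truth.
    """
    n_total = len(cfg.conditions) * cfg.n_fields
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_total) % (2**31 - 1)
    i = 0
    for spec in cfg.conditions:
        fcfg = cfg.base.with_(
            fibers_per_cell=cfg.base.fibers_per_cell * spec.multiplier)
        for f in range(cfg.n_fields):
            img, gt = generate_field(fcfg, seed=int(seeds[i]))
            i += 1
            img.metadata.update({
                "condition": spec.condition, "time_h": spec.time_h,
                "dose_nM": spec.dose_nM, "field": f,
            })
            if out_fields is not None:
                stem = f"{spec.condition}_t{spec.time_h:g}_d{spec.dose_nM:g}_f{f:03d}"
                img.save(out_fields / f"{stem}.tif")
                gt.to_json(out_fields / f"{stem}.truth.json")
            yield img, gt


def _iter_input_fields(input_dir: Path):
    for path in sorted(input_dir.glob("*.tif")):
        yield path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline per the configuration.

    Returns a results bundle: per-field table, per-condition
    measurements, normalized series (when a control key is configured)
    and the manifest.  All tables are also written under ``out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    overlays_dir = None
    if cfg.write_overlays:
        overlays_dir = out / "overlays"
        overlays_dir.mkdir(exist_ok=True)

    def _overlay_path(stem):
        return overlays_dir / f"{stem}.png" if overlays_dir else None

    rows = []
    n_failures = 0

    if cfg.input_dir:
        sources = list(_iter_input_fields(Path(cfg.input_dir)))
        if not sources:
            raise ValueError(f"no TIFF fields found in {cfg.input_dir}")
        for path in sources:
            try:
                img = FieldImage.load(path)
                rows.append(process_field(img, cfg.segment, cfg.nuclei,
                                          _overlay_path(path.stem)))
            except Exception as err:  # noqa: BLE001 - per-field isolation
                n_failures += 1
                log.warning("field %s failed: %s", path.name, err)
    else:
        fields_dir = out / "fields"
        fields_dir.mkdir(exist_ok=True)
        for i, (img, _gt) in enumerate(
                simulate_conditions(cfg, out_fields=fields_dir)):
            stem = "{}_f{:03d}".format(img.metadata.get("condition", "field"), i)
            rows.append(process_field(img, cfg.segment, cfg.nuclei,
                                      _overlay_path(stem)))

    if not rows:
        raise ValueError("no fields were processed successfully")
    field_table = pd.DataFrame(rows)
    field_table.to_csv(out / "fields.csv", index=False)

    measurements = segments_per_cell_table(
        field_table, min_cells=cfg.quantify.min_cells)
    mtable = pd.DataFrame([{
        "condition": m.condition, "time_h": m.time_h, "dose_nM": m.dose_nM,
        "n_fields": m.n_fields, "total_segments": m.total_segments,
        "total_nuclei": m.total_nuclei,
        "segments_per_cell": m.segments_per_cell,
    } for m in measurements])
    series = None
    if cfg.quantify.control_key:
        series = normalize_to_control(measurements, cfg.quantify.control_key)
        mtable = mtable.merge(
            series.table[["condition", "time_h", "dose_nM", "relative_value"]],
            on=["condition", "time_h", "dose_nM"], how="left")
    mtable.to_csv(out / "measurements.csv", index=False)

    manifest = {
        "package": "vimtrace",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "n_fields_processed": len(rows),
        "n_failures": n_failures,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "field_table": field_table,
        "measurements": measurements,
        "measurement_table": mtable,
        "normalized": series,
        "manifest": manifest,
    }
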