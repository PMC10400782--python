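"""End-to-end orchestration: snapshots -> voids -> descriptors -> models.

The pipeline mirrors how the analysis is run on MD output: sample frames,
remove the solute, extract the host void, surface it, compute descriptors,
aggregate over frames, and (when a feature/target table is supplied) fit the
standardized linear models.  Frames that fail extraction are logged and
skipped; the run aborts (nonzero status) only when more than half the
frames fail.  A manifest capturing the effective configuration, per-frame
status and seeds is always written, on success and on failure alike.
"""

from __future__ import annotations

import glob as _glob
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .extraction import (
    DEFAULT_BOTTLENECK_RADIUS,
    DEFAULT_PROBE_RADIUS,
    ExtractionParameters,
    compute_probe_spheres,
    merge_probes,
    select_host_void,
    voids_to_dict,
)
from .io import read_configuration, write_json
from .shape import (
    DEFAULT_ALPHA_FACTOR,
    DEFAULT_BRANCH_THRESHOLD,
    VoidDescriptors,
    aggregate_frames,
    build_surface,
    detect_branches,
    summarize_descriptors,
)
from .synthetic import SolvatedConfiguration

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults are the standard parameters."""

    inputs: list[str] = field(default_factory=list)  # paths or globs
    input_format: str | None = None
    solute_selector: str | None = None
    box: tuple[float, float, float] | None = None
    probe_radius: float = DEFAULT_PROBE_RADIUS
    bottleneck_radius: float = DEFAULT_BOTTLENECK_RADIUS
    branch_threshold: float = DEFAULT_BRANCH_THRESHOLD
    dc: float | None = None  # density-peak bandwidth; None -> threshold / 2
    alpha_factor: float = DEFAULT_ALPHA_FACTOR
    stride: int = 1
    max_frames: int | None = None
    random_frames: bool = False  # random sample instead of uniform stride
    seed: int = 0
    out_dir: str = "voidshape_out"
    sd_ddof: int = 0  # standardization convention (0 = population sd)
    criterion: str = "loo_mse"
    row_mask: list[str] | None = None  # entity subset for fits

    def __post_init__(self):
        if self.probe_radius <= 0 or self.bottleneck_radius <= 0:
            raise ValueError("radii must be positive")
        if self.branch_threshold <= 0:
            raise ValueError("branch_threshold must be positive")

    def extraction_params(self) -> ExtractionParameters:
        return ExtractionParameters(probe_radius=self.probe_radius,
                                    bottleneck_radius=self.bottleneck_radius)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(data.get("box"), list):
            data["box"] = tuple(data["box"])
        return cls(**data)


@dataclass
class RunManifest:
    """Record of one pipeline run; written before exit in every outcome."""

    config: dict
    frames: list[dict] = field(default_factory=list)
    n_failed: int = 0
    ok: bool = False
    version: str = __version__
    wall_clock_s: float = 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def describe_frame(
    config: SolvatedConfiguration,
    params: ExtractionParameters,
    branch_threshold: float = DEFAULT_BRANCH_THRESHOLD,
    dc: float | None = None,
    alpha_factor: float = DEFAULT_ALPHA_FACTOR,
) -> tuple[VoidDescriptors, dict]:
    """Descriptors of the host void of one frame (plus void metadata)."""
    if config.n_solute == 0:
        raise ValueError("frame has no solute; cannot identify a host void")
    graph = compute_probe_spheres(config.without_solute(), params)
    voids = merge_probes(graph, params)
    host = select_host_void(voids, config.solute_pos, config.solute_radii,
                            graph)
    if host is None:
        raise ValueError("no void overlaps the solute")
    surface = build_surface(host, graph, probe_radius=params.probe_radius,
                            alpha_factor=alpha_factor)
    branches = detect_branches(surface, config.solute_pos,
                               config.solute_radii,
                               threshold=branch_threshold, dc=dc,
                               box=config.box)
    desc = summarize_descriptors(surface, branches, config.n_heavy())
    meta = voids_to_dict(voids, graph)
    return desc, meta


def _select_frames(paths: list[str], cfg: PipelineConfig) -> list[str]:
    expanded: list[str] = []
    for p in paths:
        hits = sorted(_glob.glob(p))
        expanded.extend(hits if hits else ([p] if Path(p).exists() else []))
    if not expanded:
        raise FileNotFoundError(f"no input frames match {paths}")
    if cfg.random_frames:
        rng = np.random.default_rng(cfg.seed)
        k = min(cfg.max_frames or len(expanded), len(expanded))
        pick = sorted(rng.choice(len(expanded), size=k, replace=False))
        return [expanded[i] for i in pick]
    picked = expanded[:: max(cfg.stride, 1)]
    if cfg.max_frames:
        picked = picked[: cfg.max_frames]
    return picked


def run_pipeline(cfg: PipelineConfig,
                 frames: list[SolvatedConfiguration] | None = None
                 ) -> RunManifest:
    """Run extract -> describe -> aggregate over frames and write outputs.

    ``frames`` may supply in-memory configurations (e.g. phantoms); when
    None, ``cfg.inputs`` is globbed and read from disk.  Outputs under
    ``cfg.out_dir``: per-frame ``descriptors.csv``, ``aggregate.csv``, the
    run ``manifest.json``.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg))
    params = cfg.extraction_params()

    if frames is None:
        paths = _select_frames(cfg.inputs, cfg)
        loaded: list[tuple[str, SolvatedConfiguration | None, str]] = []
        for i, p in enumerate(paths):
            try:
                loaded.append((p, read_configuration(
                    p, fmt=cfg.input_format,
                    solute_selector=cfg.solute_selector, box=cfg.box,
                    frame_id=i), ""))
            except Exception as exc:
                loaded.append((p, None, str(exc)))
    else:
        loaded = [(f"frame[{f.frame_id}]", f, "") for f in frames]

    rows = []
    descs = []
    try:
        for name, conf, err in loaded:
            if conf is None:
                manifest.frames.append({"frame": name, "status": "read-error",
                                        "error": err})
                manifest.n_failed += 1
                logger.warning("skipping %s: %s", name, err)
                continue
            try:
                desc, _ = describe_frame(
                    conf, params, branch_threshold=cfg.branch_threshold,
                    dc=cfg.dc, alpha_factor=cfg.alpha_factor)
            except Exception as exc:
                manifest.frames.append({"frame": name, "status": "failed",
                                        "error": str(exc)})
                manifest.n_failed += 1
                logger.warning("frame %s failed: %s", name, exc)
                continue
            manifest.frames.append({"frame": name, "status": "ok"})
            row = {"frame_id": conf.frame_id}
            row.update(desc.as_dict())
            rows.append(row)
            descs.append(desc)

        if rows:
            pd.DataFrame(rows).to_csv(out / "descriptors.csv", index=False)
            agg = aggregate_frames(descs)
            agg.to_csv(out / "aggregate.csv")
        manifest.ok = manifest.n_failed <= len(loaded) / 2 and bool(rows)
    finally:
        manifest.wall_clock_s = round(time.time() - t0, 3)
        write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
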