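"""Config-driven orchestration of the full mapping pipeline.

Stages run in a fixed order — slide -> ring -> register -> fuse -> stats —
each consuming the previous stage's outputs. A run writes per-stage
artifacts under the configured output directory plus a ``manifest.json``
listing every file with its SHA-256 checksum; identical config + seed
reproduce identical CSV/JSON bytes (PNG/NIfTI outputs are written with
deterministic encoders as well).

Inputs are either real slides (paths + mpp) or a generated phantom heart;
ring layouts and landmark files are optional — absent, each slide is
treated as an already-assembled, already-registered ring.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import fusion, phantom, register, ring, stats
from .density import DensityMap, HeatmapStyle, compute_density_map, render_heatmap
from .fiber_detect import DEFAULT_HSV_RANGE, FiberMask, HsvRange, classify_fibers
from .slide_io import SlideImage, effective_mpp, load_slide, save_png
from .tissue_mask import MaskParams, TissueMask, compute_tissue_mask

__all__ = ["PipelineConfig", "ConfigError", "MissingInputError", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("nervemap")

ALL_STAGES = ("slide", "ring", "register", "fuse", "stats")


class ConfigError(ValueError):
    """Invalid pipeline configuration (reported with the field path)."""


class MissingInputError(FileNotFoundError):
    """A requested stage's inputs are not available."""


@dataclass
class PipelineConfig:
    output_dir: str = "nervemap_out"
    downscale: int = 16
    window_mm2: float = 1.0
    dz_mm: float = 4.0
    seed: int = 0
    mpp: float | None = None
    slides: list[dict] = field(default_factory=list)  # [{path, mpp?, slice_index?}]
    phantom: dict | None = None  # {n_slices, gradient | (fraction_lo, fraction_hi), canvas, ...}
    layouts: list[str] = field(default_factory=list)  # ring layout JSON paths
    landmarks: dict[str, str] = field(default_factory=dict)  # ring_id -> landmark CSV
    reference_volume: str | None = None
    tissue_mask: dict = field(default_factory=dict)
    fiber_hsv: dict | None = None
    heatmap: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    tps_lambda: float = 0.0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.downscale < 1:
            raise ConfigError("downscale: must be >= 1")
        if self.window_mm2 <= 0:
            raise ConfigError("window_mm2: must be > 0")
        if self.dz_mm <= 0:
            raise ConfigError("dz_mm: must be > 0")
        if self.phantom is None and not self.slides:
            raise ConfigError("slides: need either slide paths or a phantom section")
        for i, s in enumerate(self.slides):
            if "path" not in s:
                raise ConfigError(f"slides[{i}].path: required")

    def mask_params(self) -> MaskParams:
        try:
            return MaskParams(**self.tissue_mask)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"tissue_mask: {e}") from e

    def hsv_range(self) -> HsvRange:
        if self.fiber_hsv is None:
            log.info("fiber_hsv not configured; using default range H(0,80) S(12,125) V(31,162)")
            return DEFAULT_HSV_RANGE
        try:
            return HsvRange(
                h=tuple(self.fiber_hsv.get("h", (0, 80))),
                s=tuple(self.fiber_hsv.get("s", (12, 125))),
                v=tuple(self.fiber_hsv.get("v", (31, 162))),
            )
        except (TypeError, ValueError) as e:
            raise ConfigError(f"fiber_hsv: {e}") from e

    def heatmap_style(self) -> HeatmapStyle:
        try:
            kwargs = dict(self.heatmap)
            if "bin_edges" in kwargs:
                kwargs["bin_edges"] = tuple(kwargs["bin_edges"])
            if "palette" in kwargs:
                kwargs["palette"] = tuple(tuple(c) for c in kwargs["palette"])
            return HeatmapStyle(**kwargs)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"heatmap: {e}") from e


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class _SlideResult:
    slide: SlideImage
    tissue: TissueMask
    fibers: FiberMask
    density: DensityMap
    slice_index: int


def _load_inputs(cfg: PipelineConfig) -> list[tuple[SlideImage, int]]:
    if cfg.phantom is not None:
        p = dict(cfg.phantom)
        n = int(p.get("n_slices", 8))
        if "gradient" in p:
            gradient = np.asarray(p["gradient"], dtype=float)
        else:
            lo = float(p.get("fraction_lo", 0.01))
            hi = float(p.get("fraction_hi", 0.10))
            gradient = np.linspace(lo, hi, n)
        template = phantom.PhantomSpec(
            canvas=tuple(p.get("canvas", (400, 400))),
            mpp_eff=float(p.get("mpp_eff", 8.0)),
            geometry=p.get("geometry", "annulus"),
            radii=tuple(p.get("radii", (60.0, 140.0))),
        )
        slides, _ref, _truth = phantom.make_phantom_heart(
            n, gradient, spec_template=template, seed=cfg.seed, dz_mm=cfg.dz_mm,
            mode=p.get("mode", "sector"),
            background_fraction=float(p.get("background_fraction", 0.002)),
            hot_fraction=float(p.get("hot_fraction", 0.5)),
        )
        return [(s, i + 1) for i, (s, _t) in enumerate(slides)]
    out = []
    for i, entry in enumerate(cfg.slides):
        path = entry["path"]
        if not os.path.exists(path):
            raise MissingInputError(f"slide not found: {path}")
        slide = load_slide(path, downscale=cfg.downscale, mpp=entry.get("mpp", cfg.mpp))
        out.append((slide, int(entry.get("slice_index", i + 1))))
    return out


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] | list[str] = ALL_STAGES) -> dict:
    """Execute the requested stages in order and write a manifest.

    Returns the manifest dict: per-stage file lists with SHA-256
    checksums. Raises ConfigError / MissingInputError for bad configs or
    absent stage inputs.
    """
    stages = tuple(s for s in ALL_STAGES if s in set(stages))
    if not stages:
        raise ConfigError("stages: none recognised")
    os.makedirs(cfg.output_dir, exist_ok=True)
    manifest: dict[str, Any] = {"config": {"seed": cfg.seed, "downscale": cfg.downscale,
                                           "window_mm2": cfg.window_mm2, "dz_mm": cfg.dz_mm},
                                "stages": {}}
    written: dict[str, list[str]] = {s: [] for s in stages}

    mask_params = cfg.mask_params()
    hsv_range = cfg.hsv_range()
    style = cfg.heatmap_style()

    results: list[_SlideResult] = []
    if "slide" in stages:
        for slide, idx in _load_inputs(cfg):
            tissue = compute_tissue_mask(slide, mask_params)
            fibers = classify_fibers(slide, tissue, hsv_range)
            density = compute_density_map(
                fibers, window_mm2=cfg.window_mm2, tissue=tissue.mask
            )
            results.append(_SlideResult(slide, tissue, fibers, density, idx))
            stem = os.path.join(cfg.output_dir, f"slice{idx:03d}")
            save_png(slide, stem + "_slide.png")
            heat = render_heatmap(slide, density, style)
            save_png(SlideImage(heat[:, :, :3], slide.mpp_base, slide.downscale, slide.source_id),
                     stem + "_heatmap.png")
            np.savetxt(stem + "_density.csv", density.grid, delimiter=",", fmt="%.8g")
            written["slide"] += [stem + "_slide.png", stem + "_heatmap.png", stem + "_density.csv"]
            log.info("slide %d: %d fibre px, density grid %s", idx, fibers.count, density.shape)
    else:
        raise MissingInputError(
            "missing inputs: later stages require the 'slide' stage in the same run"
        )

    # ring stage: assemble layouts when provided; otherwise each slide is
    # already a complete ring
    composites: list[tuple[int, ring.RingComposite]] = []
    if "ring" in stages:
        if cfg.layouts:
            by_id = {r.slide.source_id: r for r in results}
            for lp in cfg.layouts:
                if not os.path.exists(lp):
                    raise MissingInputError(f"layout not found: {lp}")
                with open(lp) as fh:
                    layout = ring.FragmentLayout.from_json(fh.read())
                frags = {}
                for pl in layout.fragments:
                    if pl.fragment_id not in by_id:
                        raise MissingInputError(
                            f"layout {layout.ring_id!r} references unprocessed slide "
                            f"{pl.fragment_id!r}"
                        )
                    r = by_id[pl.fragment_id]
                    frags[pl.fragment_id] = ring.Fragment(
                        image=r.slide.pixels, fiber=r.fibers.mask, tissue=r.tissue.mask
                    )
                mpp = effective_mpp(next(iter(by_id.values())).slide)
                comp = ring.assemble_ring(frags, layout, window_mm2=cfg.window_mm2, mpp_eff=mpp)
                comp = ring.refine_boundaries(comp)
                composites.append((len(composites) + 1, comp))
        else:
            for r in results:
                comp = ring.RingComposite(
                    ring_id=r.slide.source_id,
                    image=r.slide.pixels,
                    tissue=r.tissue.mask,
                    fiber=r.fibers.mask,
                    provenance=np.where(r.tissue.mask, 0, -1).astype(np.int32),
                    fragment_ids=[r.slide.source_id],
                    density=r.density,
                    mpp_eff=effective_mpp(r.slide),
                    window_mm2=cfg.window_mm2,
                )
                composites.append((r.slice_index, comp))
        for idx, comp in composites:
            stem = os.path.join(cfg.output_dir, f"ring{idx:03d}")
            save_png(SlideImage(comp.image, 1.0, 1, comp.ring_id), stem + "_composite.png")
            np.savetxt(stem + "_density.csv", comp.density.grid, delimiter=",", fmt="%.8g")
            written["ring"] += [stem + "_composite.png", stem + "_density.csv"]

    # register stage: landmark-driven rigid + TPS onto the reference frame
    registered: list[tuple[int, ring.RingComposite]] = []
    if "register" in stages:
        if not composites:
            raise MissingInputError("missing inputs: 'register' requires ring composites")
        for idx, comp in composites:
            lm_path = cfg.landmarks.get(comp.ring_id)
            if lm_path is None:
                registered.append((idx, comp))  # already in the reference frame
                continue
            if not os.path.exists(lm_path):
                raise MissingInputError(f"landmark file not found: {lm_path}")
            pairs = register.load_landmarks_csv(lm_path)
            rigid = register.fit_rigid(pairs, allow_scale=True)
            moved = register.LandmarkPairs(register.transform_points(rigid, pairs.source),
                                           pairs.target)
            tps = register.fit_tps(moved, lam=cfg.tps_lambda)
            shape = comp.tissue.shape
            def _warp(arr, fill=0.0):
                a = register.apply_transform(arr, rigid, shape, "nearest", fill)
                return register.apply_transform(a, tps, shape, "nearest", fill)
            fiber = _warp(comp.fiber) > 0.5
            tissue = _warp(comp.tissue) > 0.5
            density = compute_density_map(
                FiberMask(fiber, comp.ring_id, comp.mpp_eff),
                window_mm2=cfg.window_mm2, tissue=tissue,
            )
            registered.append((idx, ring.RingComposite(
                ring_id=comp.ring_id, image=comp.image, tissue=tissue, fiber=fiber,
                provenance=np.where(tissue, 0, -1).astype(np.int32),
                fragment_ids=comp.fragment_ids, density=density,
                mpp_eff=comp.mpp_eff, window_mm2=cfg.window_mm2,
            )))
        for idx, comp in registered:
            stem = os.path.join(cfg.output_dir, f"registered{idx:03d}")
            np.savetxt(stem + "_density.csv", comp.density.grid, delimiter=",", fmt="%.8g")
            written["register"].append(stem + "_density.csv")

    # fuse stage: stack registered density grids apex -> base
    volume = None
    if "fuse" in stages:
        source = registered or composites
        if not source:
            raise MissingInputError("missing inputs: 'fuse' requires registered rings")
        source = sorted(source, key=lambda t: t[0])
        grids = [c.density.grid for _i, c in source]
        in_plane = source[0][1].density.window_px * source[0][1].mpp_eff / 1000.0
        volume = fusion.build_volume(
            grids, dz=cfg.dz_mm, in_plane_spacing=in_plane,
            provenance=[c.ring_id for _i, c in source],
        )
        vol_path = os.path.join(cfg.output_dir, "density_volume.nii")
        fusion.save_nifti(volume, vol_path)
        written["fuse"] += [vol_path, os.path.join(cfg.output_dir, "density_volume_provenance.json")]

    # stats stage: apex -> base profile
    if "stats" in stages:
        source = registered or composites
        if not source:
            raise MissingInputError("missing inputs: 'stats' requires density outputs")
        fibers_by_idx = {r.slice_index: r.fibers for r in results}
        entries = []
        for idx, comp in sorted(source, key=lambda t: t[0]):
            fm = FiberMask(comp.fiber, comp.ring_id, comp.mpp_eff)
            entries.append((idx, comp.density, fm))
        sopt = cfg.stats
        region_spec = {k: tuple(v) for k, v in sopt.get("regions", {}).items()} or None
        table = stats.innervation_profile(
            entries,
            region_spec=region_spec,
            threshold=float(sopt.get("hotspot_threshold", stats.DEFAULT_HOTSPOT_THRESHOLD)),
            adjacency=sopt.get("adjacency", "queen"),
        )
        csv_path = os.path.join(cfg.output_dir, "profile.csv")
        json_path = os.path.join(cfg.output_dir, "profile.json")
        table.to_csv(csv_path)
        table.to_json(json_path)
        written["stats"] += [csv_path, json_path]
        plot_path = _plot_profile(table, os.path.join(cfg.output_dir, "profile.png"))
        written["stats"].append(plot_path)

    for stage in stages:
        manifest["stages"][stage] = [
            {"path": os.path.relpath(p, cfg.output_dir), "sha256": _sha256(p)}
            for p in written[stage]
        ]
    man_path = os.path.join(cfg.output_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _plot_profile(table: stats.ProfileTable, path: str) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.slices
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    for ax, metric, label in zip(
        axes.ravel(),
        ("entropy", "morans_i", "nnd_mean", "hotspot_volume_px"),
        ("Shannon entropy", "Moran's I", "mean NND (px)", "hotspot volume (px)"),
    ):
        ax.plot(df["slice_index"], df[metric], "o-")
        ax.set_ylabel(label)
        ax.set_xlabel("slice (1 = apex)")
    fig.suptitle("Apex → base innervation profile")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
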