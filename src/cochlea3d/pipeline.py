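"""Configuration-driven end-to-end reconstruction runner.

Wires the stages of the reconstruction together: phantom generation (or real
input loading) -> per-slice hierarchical segmentation -> rigid slice
registration -> two-scala point-cloud assembly -> mirrored-GMM centerline
fit -> b-spline resampling -> rotation-minimizing frames and area-ratio
scale profile -> contour sweeps -> surface lofts -> mesh export.  Every
intermediate is serialized so stages can be inspected and re-run; a run
manifest records the configuration, stage timings, output files and mesh
validation reports.  A single global seed fans out to per-stage seeds so
identical configurations reproduce identical numeric outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import centerline as cl
from . import phantom as ph
from . import projection as pj
from . import segmentation as seg
from . import surface as sf

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "RunManifest",
    "run_reconstruction",
    "read_image_stack",
    "write_outputs",
    "stage_seed",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the global seed."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a reconstruction run needs; YAML-serializable.

    Either ``phantom`` (helix parameters for synthetic input generation) or
    ``inputs`` (paths to a point-cloud file and an annotation JSON, plus an
    optional image-stack directory) must be present.
    """

    phantom: dict | None = None
    inputs: dict | None = None
    # synthetic section rendering
    section_image_size: tuple[int, int] = (256, 256)
    section_pixel_spacing: float = 0.016
    section_noise_sigma: float = 0.02
    n_sections: int = 3
    # cloud sampling
    n_per_scala: int = 4000
    cloud_noise_rel: float = 0.25  # x tube_radius
    # centerline fit
    n_pairs: int = 64
    n_stations: int = 200
    init_variance: float = 0.1
    local_affine_regularization: float = 1.0
    fit_tolerance: float = 1e-7
    max_iterations: int = 50
    update_variances: bool = False
    helix_init: dict | None = None  # defaults to the phantom spec
    # smoothing spline residual budget ~ n_vertices x (per-mean position
    # uncertainty)^2; an interpolating spline would chase the component
    # noise instead of the medial axis
    spline_smoothing: float = 0.01
    # scaling and sweeping
    scale_labels: tuple[str, ...] = ("scala_vestibuli", "scala_tympani")
    sweep: list | None = None
    # run control
    output_dir: str = "recon_out"
    mesh_formats: tuple[str, ...] = ("obj",)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.phantom is None and self.inputs is None:
            raise ValueError("config needs either a phantom spec or real "
                             "input paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def helix_spec(self) -> ph.HelixSpec:
        params = dict(self.phantom or {})
        for key in ("center", "axis"):
            if key in params:
                params[key] = tuple(params[key])
        return ph.HelixSpec(**params)

    def init_spec(self) -> ph.HelixSpec:
        if self.helix_init is None:
            return self.helix_spec()
        params = dict(self.helix_init)
        for key in ("center", "axis"):
            if key in params:
                params[key] = tuple(params[key])
        return ph.HelixSpec(**params)

    def default_sweep(self) -> list[dict]:
        return [
            {"label": "scala_vestibuli", "centerline": "sv",
             "anchor": "centroid", "cap": True},
            {"label": "scala_tympani", "centerline": "st",
             "anchor": "centroid", "cap": True},
            {"label": "scala_media", "centerline": "average",
             "anchor": "auto", "cap": True},
        ]


@dataclass
class RunManifest:
    config: dict
    versions: dict
    stages: list = field(default_factory=list)  # {name, seconds, files}
    registration: list = field(default_factory=list)
    scale_profile: dict | None = None
    mesh_reports: dict = field(default_factory=dict)
    error: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


# ---------------------------------------------------------------------------
# Stack / output I/O
# ---------------------------------------------------------------------------

def read_image_stack(path) -> list[seg.ImageSlice]:
    """Read a directory of numbered TIFF/PNG slices plus its JSON sidecar.

    Files are ordered by the integer embedded in their names (1, 2, 10 — not
    lexicographic); intensities are rescaled to [0, 1] by bit depth; mixed
    bit depths are an error.  The sidecar ``stack_meta.json`` must provide
    ``pixel_spacing``.
    """
    path = Path(path)
    sidecar = path / "stack_meta.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing stack sidecar: expected {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    spacing = float(meta["pixel_spacing"])
    files = sorted(
        [p for p in path.iterdir()
         if p.suffix.lower() in (".tif", ".tiff", ".png", ".dcm")],
        key=ph.numeric_sort_key)
    if not files:
        raise FileNotFoundError(f"no TIFF/PNG/DICOM slices in {path}")
    slices = []
    depth = None
    for i, f in enumerate(files):
        if f.suffix.lower() == ".dcm":
            px, bits = _load_dicom(f)
        else:
            px, bits = ph.load_image(f)
        if depth is None:
            depth = bits
        elif bits != depth:
            raise ValueError(f"mixed bit depths in stack: {f} is {bits}-bit, "
                             f"expected {depth}-bit")
        slices.append(seg.ImageSlice(pixels=px, pixel_spacing=spacing,
                                     index=i))
    return slices


def _load_dicom(path) -> tuple[np.ndarray, int]:
    """Read one DICOM frame; requires the optional pydicom dependency."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError(
            "reading DICOM stacks requires pydicom (pip install "
            "cochlea3d[dicom])") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    bits = int(getattr(ds, "BitsStored", 16))
    return arr / float(2 ** bits - 1), bits


def write_outputs(meshes: list[sf.SurfaceMesh],
                  centerline: cl.Centerline | None,
                  manifest: RunManifest, out_dir,
                  mesh_formats=("obj",)) -> list[Path]:
    """Serialize meshes, the centerline and the manifest; returns the files."""
    out_dir = Path(out_dir)
    probe = out_dir if out_dir.exists() else out_dir.parent
    if probe.exists() and not os.access(probe, os.W_OK):
        raise PermissionError(f"output directory not writable: {out_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for mesh in meshes:
        for fmt in mesh_formats:
            files.append(sf.export_mesh(mesh, out_dir / f"{mesh.label}.{fmt}"))
    if meshes:
        files.append(sf.export_combined_obj(meshes, out_dir / "combined.obj"))
    if centerline is not None:
        f = out_dir / "centerline.json"
        centerline.to_json(f)
        files.append(f)
        f = out_dir / "centerline.ply"
        centerline.to_ply(f)
        files.append(f)
    f = out_dir / "manifest.json"
    manifest.to_json(f)
    files.append(f)
    return files


# ---------------------------------------------------------------------------
# Phantom input synthesis
# ---------------------------------------------------------------------------

def _phantom_section_spec(config: PipelineConfig, spec: ph.HelixSpec,
                          shift=(0.0, 0.0), angle: float = 0.0,
                          seed: int = 0, with_media: bool = True
                          ) -> ph.SectionSpec:
    """A cross-section with the two scala disks (and a scala-media blob),
    optionally rigidly displaced to emulate slice-to-slice misalignment."""
    h, w = config.section_image_size
    sp = config.section_pixel_spacing
    cx, cy = w / 2.0, h / 2.0
    r_px = spec.tube_radius / sp
    half_sep = 0.5 * spec.scala_separation / sp

    def place(x, y):
        dx, dy = x - cx, y - cy
        c, s = np.cos(angle), np.sin(angle)
        return (cx + c * dx - s * dy + shift[0],
                cy + s * dx + c * dy + shift[1])

    structures = [
        ("scala_vestibuli", ph.Disk(place(cx - half_sep, cy), r_px)),
        ("scala_tympani", ph.Disk(place(cx + half_sep, cy), r_px)),
    ]
    if with_media:
        mx, my = place(cx, cy - half_sep - 0.9 * r_px)
        structures.append(
            ("scala_media", ph.Ellipse((mx, my), (0.45 * r_px, 0.3 * r_px),
                                       angle)))
    return ph.SectionSpec(
        image_size=(h, w), pixel_spacing=sp, structures=structures,
        noise_sigma=config.section_noise_sigma, seed=seed)


def default_plan(config: PipelineConfig, spec: ph.HelixSpec,
                 with_media: bool = True) -> list[seg.SegmentationStage]:
    """Coarse-to-fine plan for the phantom sections: Hough for the two big
    scala lumina (level-set refined), then a level set for the media blob."""
    h, w = config.section_image_size
    sp = config.section_pixel_spacing
    r_px = spec.tube_radius / sp
    half_sep = 0.5 * spec.scala_separation / sp
    stages = [seg.SegmentationStage(
        labels=("scala_vestibuli", "scala_tympani"),
        strategy="hough",
        params={
            "radius_range": (max(int(0.6 * r_px), 3), int(1.5 * r_px)),
            "prior_centers": {
                "scala_vestibuli": (w / 2.0 - half_sep, h / 2.0),
                "scala_tympani": (w / 2.0 + half_sep, h / 2.0),
            },
            "refine_level_set": True,
            "iterations": 60,
            "margin": int(2.5 * r_px),
            "smoothing_sigma": 1.0,
        })]
    if with_media:
        stages.append(seg.SegmentationStage(
            labels=("scala_media",), strategy="level_set",
            params={"iterations": 60, "smoothing_weight": 1.0,
                    "smoothing_sigma": 1.0}))
    return stages


# ---------------------------------------------------------------------------
# The runner
# ---------------------------------------------------------------------------

def run_reconstruction(config: PipelineConfig) -> RunManifest:
    """Execute the full reconstruction; returns the run manifest.

    Any stage failure aborts the run with the stage name and cause recorded
    in the manifest (written to the output directory); outputs of completed
    stages are retained.
    """
    import cochlea3d

    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        versions={"cochlea3d": cochlea3d.__version__,
                  "numpy": np.__version__},
    )
    state: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            files = fn() or []
        except Exception as exc:  # noqa: BLE001 - abort with context
            manifest.error = {"stage": name, "cause": str(exc)}
            manifest.to_json(out_dir / "manifest.json")
            raise PipelineError(name, str(exc)) from exc
        manifest.stages.append({
            "name": name,
            "seconds": round(time.perf_counter() - t0, 3),
            "files": [str(f) for f in files],
        })

    run_stage("inputs", lambda: _stage_inputs(config, state, out_dir))
    run_stage("segmentation",
              lambda: _stage_segmentation(config, state, out_dir))
    run_stage("registration",
              lambda: _stage_registration(config, state, out_dir, manifest))
    run_stage("fit", lambda: _stage_fit(config, state, out_dir))
    run_stage("centerline", lambda: _stage_centerline(config, state, out_dir))
    run_stage("frames_scale",
              lambda: _stage_frames_scale(config, state, manifest))
    run_stage("sweep", lambda: _stage_sweep(config, state, out_dir))
    run_stage("loft", lambda: _stage_loft(config, state, manifest))
    run_stage("export", lambda: write_outputs(
        state["meshes"], state["centerlines"]["average"], manifest, out_dir,
        config.mesh_formats))
    return manifest


def _stage_inputs(config: PipelineConfig, state: dict, out_dir: Path):
    files = []
    if config.phantom is not None:
        spec = config.helix_spec()
        state["spec"] = spec
        cloud, mid = ph.generate_scala_cloud(
            spec, config.n_per_scala,
            noise_sigma=config.cloud_noise_rel * spec.tube_radius,
            seed=stage_seed(config.seed, "cloud"))
        state["cloud"], state["mid_curve"] = cloud, mid
        f = out_dir / "cloud.csv"
        ph.save_cloud_csv(cloud, f)
        files.append(f)
        # "histology" sections with per-slice rigid offsets, plus clean
        # base/apex reference sections for the scale profile
        sections = []
        for i in range(config.n_sections):
            sec = _phantom_section_spec(
                config, spec, shift=(0.9 * i, -0.6 * i),
                angle=np.deg2rad(1.5 * i),
                seed=stage_seed(config.seed, f"section{i}"))
            img, gt, masks = ph.render_section(sec)
            f = out_dir / f"section_{i:02d}.png"
            ph.save_image(img, f, bit_depth=8)
            files.append(f)
            sections.append(seg.ImageSlice(
                pixels=img, pixel_spacing=config.section_pixel_spacing,
                index=i))
        state["sections"] = sections
        for tag in ("base", "apex"):
            sec = _phantom_section_spec(
                config, spec, seed=stage_seed(config.seed, f"mct_{tag}"),
                with_media=False)
            img, _, _ = ph.render_section(sec)
            state[f"mct_{tag}"] = seg.ImageSlice(
                pixels=img, pixel_spacing=config.section_pixel_spacing,
                index=0)
            f = out_dir / f"mct_{tag}.png"
            ph.save_image(img, f, bit_depth=8)
            files.append(f)
    else:
        inputs = config.inputs or {}
        state["spec"] = config.init_spec()
        state["cloud"] = ph.load_cloud_csv(inputs["cloud_path"])
        state["annotation"] = pj.AnnotationSet.from_json(
            inputs["annotation_json"])
        if "stack_dir" in inputs:
            state["stack"] = read_image_stack(inputs["stack_dir"])
    return files


def _stage_segmentation(config: PipelineConfig, state: dict, out_dir: Path):
    if "sections" not in state:
        return []  # real-input runs consume a supplied annotation
    spec = state["spec"]
    plan = default_plan(config, spec)
    annos = []
    files = []
    for sl in state["sections"]:
        anno = seg.hierarchical_segment(sl, plan)
        annos.append(anno)
        f = out_dir / f"annotation_{sl.index:02d}.json"
        anno.to_json(f)
        files.append(f)
    state["annotations"] = annos
    mct_plan = default_plan(config, spec, with_media=False)
    for tag in ("base", "apex"):
        anno = seg.hierarchical_segment(state[f"mct_{tag}"], mct_plan)
        state[f"mct_{tag}_anno"] = anno
        f = out_dir / f"mct_{tag}_annotation.json"
        anno.to_json(f)
        files.append(f)
    return files


def _stage_registration(config: PipelineConfig, state: dict, out_dir: Path,
                        manifest: RunManifest):
    if "annotations" not in state:
        return []
    annos = state["annotations"]
    ref = annos[0]
    files = []
    for anno in annos[1:]:
        xf = seg.register_slices(ref, anno, labels=list(config.scale_labels))
        manifest.registration.append({
            "slice_id": anno.slice_id,
            "rotation_deg": float(np.rad2deg(xf.rotation_angle)),
            "translation": [float(xf.translation[0]),
                            float(xf.translation[1])],
        })
        registered = pj.AnnotationSet(
            slice_id=anno.slice_id + "-registered",
            pixel_spacing=anno.pixel_spacing,
            contours=[pj.Contour2D(c.label, xf.apply(c.points), c.closed)
                      for c in anno.contours])
        f = out_dir / f"annotation_{anno.slice_id}-registered.json"
        registered.to_json(f)
        files.append(f)
    state["annotation"] = ref
    return files


def _stage_fit(config: PipelineConfig, state: dict, out_dir: Path):
    model = cl.init_mirrored_gmm(config.init_spec() if config.phantom
                                 else state["spec"],
                                 n_pairs=config.n_pairs,
                                 variance=config.init_variance)
    fit_cfg = cl.FitConfig(
        max_iterations=config.max_iterations,
        tolerance=config.fit_tolerance,
        local_affine_regularization=config.local_affine_regularization,
        update_variances=config.update_variances,
        seed=stage_seed(config.seed, "fit"))
    fitted, trace = cl.fit_gmm(model, state["cloud"], fit_cfg)
    state["model"], state["trace"] = fitted, trace
    f = out_dir / "gmm_fit.json"
    with open(f, "w") as fh:
        json.dump({
            "means_sv": fitted.means_sv.tolist(),
            "means_st": fitted.means_st.tolist(),
            "variance": fitted.variance,
            "log_likelihood_trace": trace.tolist(),
        }, fh, indent=1)
    return [f]


def _stage_centerline(config: PipelineConfig, state: dict, out_dir: Path):
    sv, st = cl.extract_scala_centerlines(state["model"])
    # the outermost components stop short of the tube ends (one-sided
    # responsibility windows); extend each scala polyline to the data extent
    spec = state["spec"]
    noise = config.cloud_noise_rel * spec.tube_radius
    capture = spec.tube_radius + 3.0 * noise
    cloud = state["cloud"]
    sv = cl.extend_polyline_to_data(sv, cloud.subset("SV"), noise,
                                    capture_radius=capture)
    st = cl.extend_polyline_to_data(st, cloud.subset("ST"), noise,
                                    capture_radius=capture)
    if len(sv) == len(st):
        mid = cl.average_centerlines(sv, st)
    else:
        # an end extended on one scala only: average the un-extended fits
        sv0, st0 = cl.extract_scala_centerlines(state["model"])
        mid = cl.average_centerlines(sv0, st0)
    lines = {
        "sv": cl.build_centerline(sv, config.n_stations,
                                  config.spline_smoothing),
        "st": cl.build_centerline(st, config.n_stations,
                                  config.spline_smoothing),
        "average": cl.build_centerline(mid, config.n_stations,
                                       config.spline_smoothing),
    }
    state["centerlines"] = lines
    files = []
    for name, line in lines.items():
        f = out_dir / f"centerline_{name}.json"
        line.to_json(f)
        files.append(f)
    return files


def _stage_frames_scale(config: PipelineConfig, state: dict,
                        manifest: RunManifest):
    spec = state["spec"]
    ref_dir = np.asarray(spec.axis, dtype=float)
    state["frames"] = {name: pj.build_frames(line, ref_dir)
                       for name, line in state["centerlines"].items()}
    anno = state["annotation"]
    hist_areas = {c.label: pj.contour_area(c) for c in anno.contours
                  if c.closed}
    if "mct_base_anno" in state:
        base_areas = {c.label: pj.contour_area(c)
                      for c in state["mct_base_anno"].contours}
        apex_areas = {c.label: pj.contour_area(c)
                      for c in state["mct_apex_anno"].contours}
    else:
        base_areas = apex_areas = hist_areas  # identity scaling fallback
    profiles = {}
    for name, line in state["centerlines"].items():
        profiles[name] = pj.estimate_scale_profile(
            {k: hist_areas[k] for k in config.scale_labels},
            base_areas, apex_areas, line)
    state["profiles"] = profiles
    p = profiles["average"]
    manifest.scale_profile = {"s_max": p.s_max, "s_min": p.s_min}
    return []


def _stage_sweep(config: PipelineConfig, state: dict, out_dir: Path):
    anno = state["annotation"]
    sweep_specs = config.sweep or config.default_sweep()
    curves = []
    files = []
    for sw in sweep_specs:
        label = sw["label"]
        if label not in anno:
            continue
        contour = anno[label]
        line_key = sw.get("centerline", "average")
        line = state["centerlines"][line_key]
        frames = state["frames"][line_key]
        profile = state["profiles"][line_key]
        anchor_cfg = sw.get("anchor", "auto")
        if anchor_cfg == "centroid":
            anchor = contour.centroid()
        elif anchor_cfg == "auto":
            anchor = pj.default_anchor(anno)
        else:
            anchor = np.asarray(anchor_cfg, dtype=float)
        curve = pj.sweep_structure(contour, line, frames, profile,
                                   in_plane_offset=anchor)
        curves.append((curve, bool(sw.get("cap", True))))
        f = out_dir / f"rings_{label}.ply"
        curve.to_ply(f)
        files.append(f)
    if not curves:
        raise ValueError("no sweep structure present in the annotation")
    state["curves"] = curves
    return files


def _stage_loft(config: PipelineConfig, state: dict, manifest: RunManifest):
    meshes = []
    for curve, cap in state["curves"]:
        if curve.closed_ring:
            mesh = sf.loft_rings(curve, cap_ends=cap)
        else:
            mesh = sf.loft_strip(curve)
        report = sf.validate_mesh(mesh)
        manifest.mesh_reports[curve.label] = dataclasses.asdict(report)
        meshes.append(mesh)
    state["meshes"] = meshes
    return []
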