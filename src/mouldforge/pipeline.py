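"""End-to-end pipeline: oriented case -> replica + mould + slice outlines.

One call produces everything needed for a case: ``replica.stl`` (the
print-ready smoothed tumour), ``mould.stl`` and ``mould.scad`` (the
assembled slicing mould and its CSG description), ``slices/slab_NN.svg``
(real-size annotated outlines) with ``slices/index.json`` (slab-to-image
plane map and the fixed co-registration angle), and ``report.json``
echoing every tunable parameter for reproducibility.

The run is deterministic for identical inputs and configuration; wall
time is logged and compared against a two-minute soft budget (logged,
never asserted).
"""

from __future__ import annotations

import json
import logging
import shutil
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from mouldforge.imaging_io import SegmentationCase, write_mesh
from mouldforge.mould_design import (
    MouldSpec,
    build_mould,
    knife_path_clearance,
    plan_slits,
)
from mouldforge.orientation import orient_case
from mouldforge.slice_mapping import (
    annotate_outline,
    cavalieri_volume,
    export_outlines_svg,
    extract_outlines,
    map_slice_to_image,
)
from mouldforge.tumour_modelling import (
    convex_hull,
    laplacian_smooth,
    marching_cubes,
    mesh_volume,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "run_bilateral",
           "PipelineError"]

log = logging.getLogger("mouldforge")

# pass-through print settings recorded in the report (informational only)
PRINT_METADATA = {"infill_percent": 20, "layer_height_mm": 0.3}

SOFT_RUNTIME_BUDGET_S = 120.0

_PIPELINE_KEYS = {
    "voxel_size_mm": 1.0,
    "crop_margin_mm": 5.0,
    "manual_rotation_deg": None,
    "smoothing_lambda": 1.0,
    "smoothing_iterations": 3,
    "outline_mode": "midplane",
    "write_qc_raw_mesh": False,
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything tunable about a run (MouldSpec plus pipeline knobs)."""

    mould: MouldSpec = field(default_factory=MouldSpec)
    voxel_size_mm: float = 1.0
    crop_margin_mm: float = 5.0
    manual_rotation_deg: Optional[float] = None
    smoothing_lambda: float = 1.0
    smoothing_iterations: int = 3
    outline_mode: str = "midplane"
    write_qc_raw_mesh: bool = False

    @classmethod
    def from_sources(cls, config_file: Optional[dict] = None,
                     cli_overrides: Optional[dict] = None
                     ) -> "PipelineConfig":
        """Merge defaults < config file < CLI flags (later wins)."""
        mould_fields = set(MouldSpec().to_dict())
        merged_pipe = dict(_PIPELINE_KEYS)
        merged_mould = MouldSpec().to_dict()
        for src in (config_file or {}), (cli_overrides or {}):
            for k, v in src.items():
                if v is None:
                    continue
                if k in mould_fields:
                    merged_mould[k] = v
                elif k in merged_pipe:
                    merged_pipe[k] = v
                else:
                    raise ValueError(f"unknown configuration key {k!r}")
        return cls(mould=MouldSpec(**merged_mould), **merged_pipe)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mould"] = self.mould.to_dict()
        return d


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    case_id: str
    input_summary: dict
    parameters: dict
    tumour_volume_mm3: float
    tumour_x_extent_mm: list
    slit_positions_mm: list
    slab_plane_map: list
    coregistration_angle_deg: float
    cavalieri_volume_mm3: float
    knife_paths: list
    print_metadata: dict
    warnings: list
    timings_s: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def run_pipeline(case: SegmentationCase, config: PipelineConfig,
                 out_dir) -> RunReport:
    """Run segmentation -> orientation -> modelling -> mould -> outlines.

    Writes all artefacts into ``out_dir``; on a stage failure, partial
    outputs are removed and a :class:`PipelineError` names the stage.
    """
    out_dir = Path(out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    timings: dict = {}
    caught: list[str] = []

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t, 3)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                    _cleanup()
                    raise PipelineError(name, str(exc)) from exc
                log.info("stage %s: %.2f s", name, timings[name])

        return _Ctx()

    def _cleanup():
        if created and out_dir.exists():
            shutil.rmtree(out_dir, ignore_errors=True)
        else:
            for p in out_dir.glob("*"):
                if p.name in ("mould.scad", "mould.stl", "replica.stl",
                              "report.json", "qc_raw_mesh.stl"):
                    p.unlink(missing_ok=True)
                elif p.name == "slices":
                    shutil.rmtree(p, ignore_errors=True)

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        with _stage("orientation"):
            oriented = orient_case(
                case,
                manual_rotation_deg=config.manual_rotation_deg,
                crop_margin_mm=config.crop_margin_mm,
            )

        with _stage("tumour_modelling"):
            raw = marching_cubes(oriented)
            replica = laplacian_smooth(
                raw, lam=config.smoothing_lambda,
                iterations=config.smoothing_iterations,
            )
            hull = convex_hull(replica)
            volume = mesh_volume(replica)
            log.info("replica volume %.1f cm³ (defaults logged: λ=%g, "
                     "%d smoothing iterations, crop margin %g mm)",
                     volume / 1000.0, config.smoothing_lambda,
                     config.smoothing_iterations, config.crop_margin_mm)

        with _stage("mould_design"):
            x_extent = oriented.x_extent_mm()
            plan = plan_slits(x_extent, config.mould)
            assembly = build_mould(oriented, replica, hull, config.mould,
                                   plan=plan)
            knife = knife_path_clearance(assembly)

        with _stage("slice_mapping"):
            outlines = extract_outlines(oriented, plan, config.mould,
                                        mode=config.outline_mode)
            for o in outlines:
                annotate_outline(o, oriented, config.mould)
            maps = [map_slice_to_image(o, oriented) for o in outlines]
            angle = maps[0].angle_deg if maps else 0.0

        with _stage("export"):
            write_mesh(replica, out_dir / "replica.stl")
            write_mesh(assembly.assembled, out_dir / "mould.stl")
            (out_dir / "mould.scad").write_text(assembly.scad_script)
            if config.write_qc_raw_mesh:
                write_mesh(raw, out_dir / "qc_raw_mesh.stl")
            slices_dir = out_dir / "slices"
            export_outlines_svg(outlines, slices_dir)
            index = {
                "coregistration_angle_deg": angle,
                "slabs": [
                    {
                        "slab_index": o.slab_index,
                        "x_interval_mm": list(o.x_interval_mm),
                        "patient_plane": o.patient_plane,
                        "empty": o.empty,
                        "area_mm2": round(o.area_mm2, 3),
                    }
                    for o in outlines
                ],
            }
            (slices_dir / "index.json").write_text(
                json.dumps(index, indent=2, sort_keys=True))

        caught = sorted({str(w.message) for w in wrec})

    total = time.perf_counter() - t0
    timings["total"] = round(total, 3)
    if total > SOFT_RUNTIME_BUDGET_S:
        log.warning("pipeline took %.1f s, above the %.0f s soft budget",
                    total, SOFT_RUNTIME_BUDGET_S)
    else:
        log.info("pipeline completed in %.1f s (soft budget %.0f s)",
                 total, SOFT_RUNTIME_BUDGET_S)

    img = case.image
    report = RunReport(
        case_id=case.case_id,
        input_summary={
            "modality": img.modality,
            "spacing_mm": [round(float(s), 4) for s in img.spacing],
            "shape": list(img.shape),
            "has_base_roi": case.base is not None,
        },
        parameters=config.to_dict(),
        tumour_volume_mm3=round(volume, 2),
        tumour_x_extent_mm=[round(x_extent[0], 2), round(x_extent[1], 2)],
        slit_positions_mm=[round(float(x), 3) for x in plan.slit_x_mm],
        slab_plane_map=[
            {"slab_index": o.slab_index, "patient_plane": o.patient_plane}
            for o in outlines
        ],
        coregistration_angle_deg=round(float(angle), 3),
        cavalieri_volume_mm3=round(cavalieri_volume(outlines), 2),
        knife_paths=knife,
        print_metadata=dict(PRINT_METADATA),
        warnings=caught,
        timings_s=timings,
    )
    (out_dir / "report.json").write_text(report.to_json())
    return report


def run_bilateral(cases, config: PipelineConfig, out_dir) -> list:
    """Run two (or more) lesions independently into sub-directories.

    Each lesion gets its own sub-directory named by its ``case_id``;
    a failure in one does not stop the others.  Returns a list of
    ``{"case_id", "report", "error"}`` dicts.
    """
    out_dir = Path(out_dir)
    results = []
    for case in cases:
        sub = out_dir / case.case_id
        try:
            report = run_pipeline(case, config, sub)
            results.append({"case_id": case.case_id, "report": report,
                            "error": None})
        except Exception as exc:  # keep the other lesion running
            log.error("lesion %s failed: %s", case.case_id, exc)
            results.append({"case_id": case.case_id, "report": None,
                            "error": str(exc)})
    return results
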