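"""Standard-format I/O and the two end-to-end pipelines.

Images travel as multi-frame TIFF with pixel size and frame interval in the
shaped metadata; traces, granule tables and histograms as CSV with documented
column schemas; fit and test reports as JSON; run configuration as YAML or
JSON.  ``run_pipeline`` ties the stages into the two standard workflows
(image -> morphometry report; traces -> kinetics report) and writes the fully
resolved configuration next to every output so any number in a report can be
reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import GranuleKitError, ParameterError, TraceFormatError
from .image import AXES, ImageStack
from .photokinetics import RecoveryTrace, fit_frap_session

log = logging.getLogger(__name__)

TRACE_COLUMNS = ("time_s", "roi_id", "role", "intensity")
TRACE_ROLES = ("bleach", "reference", "background", "region", "control")
FLOAT_FORMAT = "%.9g"  # fixed formatting keeps repeated runs byte-identical


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------
def write_image(stack: ImageStack, path) -> None:
    """Write an ImageStack as multi-frame TIFF with calibration metadata."""
    tifffile.imwrite(
        str(path),
        np.asarray(stack.data, dtype=np.float32),
        metadata={
            "axes": AXES,
            "pixel_size_nm": stack.pixel_size_nm,
            "frame_interval_s": stack.frame_interval_s,
        },
    )


def read_image(path) -> ImageStack:
    """Read a TIFF into the (t, z, c, y, x) container.

    Missing axes are inserted with length 1.  Pixel size defaults to
    1 nm/px (with a warning) when the file carries no calibration.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except Exception as exc:
        raise GranuleKitError(f"cannot read TIFF {path}: {exc}") from exc
    if not np.issubdtype(np.asarray(data).dtype, np.number):
        raise GranuleKitError(f"non-numeric data in {path}")

    axes = axes.replace("S", "C").replace("Q", "T").replace("I", "T")
    keep, labels = [], []
    for i, ax in enumerate(axes):
        if ax in AXES and ax not in labels:
            keep.append(i)
            labels.append(ax)
        elif data.shape[i] == 1:
            continue
        else:
            raise GranuleKitError(f"unsupported axis {ax!r} in {path}")
    data = data.squeeze(axis=tuple(i for i in range(data.ndim) if i not in keep))

    pixel_size = meta.get("pixel_size_nm")
    if pixel_size is None:
        warnings.warn(f"{path.name}: no pixel size metadata; defaulting to 1 nm/px",
                      stacklevel=2)
        pixel_size = 1.0
    frame_interval = meta.get("frame_interval_s", 1.0)
    return ImageStack.from_array(
        data, axes="".join(labels),
        pixel_size_nm=float(pixel_size), frame_interval_s=float(frame_interval),
    )


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------
def write_traces(traces, path) -> None:
    """Write RecoveryTraces as long-format CSV (time_s, roi_id, role, intensity)."""
    rows = []
    for i, tr in enumerate(traces):
        roi_id = tr.label or f"roi{i}"
        for role, arr in (
            ("bleach", tr.roi_intensity),
            ("reference", tr.reference_intensity),
            ("background", tr.background_intensity),
        ):
            if arr is None:
                continue
            for t, v in zip(tr.time_s, arr):
                rows.append((t, roi_id, role, v))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_traces(path, n_pre: int = 5) -> list:
    """Read a trace CSV back into RecoveryTraces, one per roi_id.

    Validates the column schema, duplicate (time, roi, role) rows, and time
    grid uniformity (reported with the offending row index).
    """
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise TraceFormatError(f"{path}: missing columns {sorted(missing)}")
    bad_roles = set(df["role"]) - set(TRACE_ROLES)
    if bad_roles:
        raise TraceFormatError(f"{path}: unknown roles {sorted(bad_roles)}")
    dup = df.duplicated(subset=["time_s", "roi_id", "role"])
    if dup.any():
        raise TraceFormatError(
            f"{path}: duplicated (time, roi, role) at row {int(np.nonzero(dup.values)[0][0])}"
        )

    traces = []
    for roi_id, grp in df.groupby("roi_id", sort=True):
        parts = {}
        for role, sub in grp.groupby("role"):
            sub = sub.sort_values("time_s")
            parts[role] = (sub["time_s"].to_numpy(), sub["intensity"].to_numpy(),
                           sub.index.to_numpy())
        main_role = "bleach" if "bleach" in parts else "region"
        if main_role not in parts:
            raise TraceFormatError(f"{path}: roi {roi_id} has no bleach/region rows")
        t, v, idx = parts[main_role]
        dt = np.diff(t)
        if len(dt) and (np.any(dt <= 0) or
                        np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0)):
            bad = int(idx[int(np.argmax(np.abs(dt - dt[0]))) + 1])
            raise TraceFormatError(f"{path}: non-uniform time grid at row {bad}")
        traces.append(RecoveryTrace(
            t, v,
            reference_intensity=parts.get("reference", (None, None, None))[1],
            background_intensity=parts.get("background", (None, None, None))[1],
            n_pre=n_pre, label=str(roi_id),
        ))
    return traces


def write_records(records, path) -> None:
    """Write GranuleRecords as CSV with a stable column schema."""
    rows = [{
        "id": r.id, "channel": r.channel,
        "centroid_z": r.centroid[0], "centroid_y": r.centroid[1],
        "centroid_x": r.centroid[2],
        "area_nm2": r.area_nm2,
        "equivalent_diameter_nm": r.equivalent_diameter_nm,
        "total_intensity": r.total_intensity,
        "mean_intensity_per_area": r.mean_intensity_per_area,
        "class_label": r.class_label,
        "hollow_dip_ratio": r.hollow_dip_ratio,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise GranuleKitError(f"config references missing file: {path}")
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=True))


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------
MORPHOMETRY_DEFAULTS = {
    "channel": 0, "threshold_k": 3.0, "min_area_nm2": 0.0,
    "granule_measure": "mean", "reference_kind": "intergranular",
    "n_reference_rois": 0, "reference_roi_radius_px": 6.0,
}
KINETICS_DEFAULTS = {"mode": "full_scale", "n_pre": 5}


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute one configured pipeline and write its report bundle.

    ``config['pipeline']`` selects ``morphometry`` (image -> granule table,
    optional enrichment) or ``frap`` (traces -> averaged fit).  Inputs come
    from ``config['input']`` (a file path) or ``config['simulate']`` (a
    parameter block passed to the matching generator).  The effective,
    fully-resolved configuration is written alongside the outputs; every
    random quantity derives from ``config['seed']``.
    """
    from . import morphometry, simulate  # local import keeps startup light

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kind = config.get("pipeline")
    seed = int(config.get("seed", 0))
    resolved = {"pipeline": kind, "seed": seed}
    outputs = {}

    if kind == "morphometry":
        params = {**MORPHOMETRY_DEFAULTS, **config.get("params", {})}
        resolved["params"] = params
        if "input" in config:
            stack = read_image(config["input"])
            resolved["input"] = str(config["input"])
            truths = None
        elif "simulate" in config:
            sim = dict(config["simulate"])
            resolved["simulate"] = sim
            cfg = simulate.SimulationConfig(seed=seed, **sim.get("config", {}))
            truths = simulate.place_granules(
                cfg, n=sim.get("n_granules", 20),
                radius_nm=sim.get("radius_nm", 300.0),
                enrichment=sim.get("enrichment", 10.0),
                shape=tuple(sim.get("shape", (512, 512))),
            )
            stack, truths = simulate.simulate_granule_image(
                cfg, truths, background_level=sim.get("background_level", 200.0),
                shape=tuple(sim.get("shape", (512, 512))),
            )
        else:
            raise ParameterError("morphometry pipeline needs 'input' or 'simulate'")

        records = morphometry.segment_granules(
            stack, channel=params["channel"], threshold_k=params["threshold_k"],
            min_area_nm2=params["min_area_nm2"],
        )
        write_records(records, out_dir / "granules.csv")
        outputs["granules"] = records

        if params["n_reference_rois"] > 0 and records:
            rng = np.random.default_rng(seed + 1)
            shape = stack.shape_yx
            occupied = morphometry.records_to_mask(records, shape)
            occupied = np.asarray(occupied)
            rois, attempts = [], 0
            rad = params["reference_roi_radius_px"]
            while len(rois) < params["n_reference_rois"] and attempts < 10000:
                attempts += 1
                cy = rng.uniform(rad, shape[0] - 1 - rad)
                cx = rng.uniform(rad, shape[1] - 1 - rad)
                roi = morphometry.disk_roi(shape, (cy, cx), rad)
                if not (roi & occupied).any():
                    rois.append(roi)
            enr = morphometry.fold_enrichment(
                stack, records, rois,
                reference_kind=params["reference_kind"],
                granule_measure=params["granule_measure"],
            )
            (out_dir / "enrichment.json").write_text(
                json.dumps(_asdict(enr), indent=2, sort_keys=True))
            outputs["enrichment"] = enr

    elif kind == "frap":
        params = {**KINETICS_DEFAULTS, **config.get("params", {})}
        resolved["params"] = params
        if "input" in config:
            traces = read_traces(config["input"], n_pre=params["n_pre"])
            resolved["input"] = str(config["input"])
        elif "simulate" in config:
            sim = dict(config["simulate"])
            resolved["simulate"] = sim
            truth = simulate.KineticTruth(**sim.get("truth", {}))
            n_traces = int(sim.get("n_traces", 10))
            duration = float(sim.get("duration_s", 240.0))
            traces = []
            for i in range(n_traces):
                cfg = simulate.SimulationConfig(
                    seed=seed + i, **sim.get("config", {}))
                traces.append(simulate.simulate_frap_trace(
                    truth, cfg, duration, label=f"trace{i}"))
        else:
            raise ParameterError("frap pipeline needs 'input' or 'simulate'")

        write_traces(traces, out_dir / "traces.csv")
        fit = fit_frap_session(traces, mode=params["mode"])
        (out_dir / "fit.json").write_text(
            json.dumps(_asdict(fit), indent=2, sort_keys=True))
        outputs["fit"] = fit

    else:
        raise ParameterError(f"unknown pipeline {kind!r}")

    save_config(resolved, out_dir / "resolved_config.yaml")
    log.info("pipeline %s complete; outputs in %s (seed=%d)", kind, out_dir, seed)
    return outputs
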