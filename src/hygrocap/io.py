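"""File readers/writers and run configuration.

All user-facing tables are delimited text with headers; angles are in
degrees, curvature in 1/length of the trace unit, and circumferential
position ``s`` is always measured from the split region.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .laminate import ModelParams
from .mfa import AzimuthMap, CellROI
from .morphometry import SectionThicknessPair, SegmentSeries, SegmentTrace
from .profile import CurvatureProfile, ThicknessProfile
from .synthetic import NoiseSpec, ProfileSpec

__all__ = [
    "read_profile",
    "write_profile",
    "read_curvature",
    "write_curvature",
    "read_traces",
    "write_traces",
    "read_thickness_pair",
    "write_thickness_pair",
    "read_azimuth_map",
    "write_azimuth_map",
    "read_rois",
    "write_rois",
    "RunConfig",
    "read_config",
]


def _load_grid(path) -> np.ndarray:
    """Load a single 2-D grid from .npy or single-channel TIFF."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    return np.load(path)


def read_azimuth_map(azimuth_path, retardance_path=None) -> AzimuthMap:
    """Read an azimuth/retardance map pair.

    Either a single ``.npz`` archive with arrays ``azimuth`` and
    ``retardance``, or two single-channel files (``.npy`` or TIFF).
    """
    path = Path(azimuth_path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return AzimuthMap(azimuth=data["azimuth"], retardance=data["retardance"])
    if retardance_path is None:
        raise ValueError("retardance file required unless a .npz archive is given")
    return AzimuthMap(azimuth=_load_grid(path), retardance=_load_grid(retardance_path))


def write_azimuth_map(amap: AzimuthMap, path) -> None:
    np.savez(path, azimuth=amap.azimuth, retardance=amap.retardance)


def read_rois(labels_path, table_path) -> list[CellROI]:
    """Read cell ROIs: a labelled mask plus a table cell_id,label,cell_axis_deg."""
    labels = _load_grid(labels_path) if Path(labels_path).suffix != ".npz" else None
    if labels is None:
        with np.load(labels_path) as data:
            labels = data["labels"]
    labels = np.asarray(labels)
    table = _read_table(table_path, {"cell_id", "label", "cell_axis_deg"})
    rois = []
    for _, row in table.iterrows():
        mask = labels == int(row["label"])
        if not mask.any():
            raise ValueError(f"{table_path}: label {row['label']} absent from mask")
        rois.append(
            CellROI(
                mask=mask,
                cell_axis_deg=float(row["cell_axis_deg"]),
                cell_id=str(row["cell_id"]),
            )
        )
    return rois


def write_rois(rois: list[CellROI], labels_path, table_path) -> None:
    shape = rois[0].mask.shape
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    for i, roi in enumerate(rois, start=1):
        labels[roi.mask] = i
        rows.append((roi.cell_id or f"cell{i}", i, roi.cell_axis_deg))
    np.savez(labels_path, labels=labels)
    pd.DataFrame(rows, columns=["cell_id", "label", "cell_axis_deg"]).to_csv(
        table_path, index=False, float_format="%.12g"
    )


def _read_table(path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: cannot parse delimited table: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    bad = df[list(required)].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        # +2: header line plus 1-based counting
        raise ValueError(f"{path}: malformed row at line {row + 2}")
    return df


def read_profile(path) -> ThicknessProfile:
    """Read a thickness-profile table with columns s, X_M, X_L, X_T."""
    df = _read_table(path, {"s", "X_M", "X_L", "X_T"})
    try:
        return ThicknessProfile(
            s=df["s"].to_numpy(),
            X_M=df["X_M"].to_numpy(),
            X_L=df["X_L"].to_numpy(),
            X_T=df["X_T"].to_numpy(),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_profile(profile: ThicknessProfile, path) -> None:
    pd.DataFrame(
        {"s": profile.s, "X_M": profile.X_M, "X_L": profile.X_L, "X_T": profile.X_T}
    ).to_csv(path, index=False, float_format="%.12g")


def read_curvature(path) -> CurvatureProfile:
    """Read a curvature table with columns s, kappa, kappa_norm."""
    df = _read_table(path, {"s", "kappa", "kappa_norm"})
    return CurvatureProfile(
        s=df["s"].to_numpy(),
        kappa=df["kappa"].to_numpy(),
        kappa_norm=df["kappa_norm"].to_numpy(),
    )


def write_curvature(curv: CurvatureProfile, path) -> None:
    pd.DataFrame(
        {"s": curv.s, "kappa": curv.kappa, "kappa_norm": curv.kappa_norm}
    ).to_csv(path, index=False, float_format="%.12g")


def read_traces(traces_path, widths_path) -> SegmentSeries:
    """Read digitized segment traces plus the widths table.

    ``traces_path``: columns segment_id, point_index, x, y.
    ``widths_path``: columns segment_id, d.  Segment order follows the
    widths table (anatomical order from the split region).
    """
    pts = _read_table(traces_path, {"segment_id", "point_index", "x", "y"})
    widths = _read_table(widths_path, {"segment_id", "d"})
    traces = []
    for _, row in widths.iterrows():
        seg = pts[pts["segment_id"] == row["segment_id"]].sort_values("point_index")
        if seg.empty:
            raise ValueError(
                f"{traces_path}: no points for segment {row['segment_id']!r}"
            )
        traces.append(
            SegmentTrace(
                points=seg[["x", "y"]].to_numpy(),
                width_d=float(row["d"]),
                segment_id=str(row["segment_id"]),
            )
        )
    return SegmentSeries(traces)


def write_traces(series: SegmentSeries, traces_path, widths_path) -> None:
    rows = []
    for trace in series.traces:
        for i, (x, y) in enumerate(trace.points):
            rows.append((trace.segment_id, i, x, y))
    pd.DataFrame(rows, columns=["segment_id", "point_index", "x", "y"]).to_csv(
        traces_path, index=False, float_format="%.12g"
    )
    pd.DataFrame(
        {
            "segment_id": [t.segment_id for t in series.traces],
            "d": [t.width_d for t in series.traces],
        }
    ).to_csv(widths_path, index=False, float_format="%.12g")


def read_thickness_pair(wet_path, dry_path) -> SectionThicknessPair:
    wet = _read_table(wet_path, {"thickness"})["thickness"].to_numpy()
    dry = _read_table(dry_path, {"thickness"})["thickness"].to_numpy()
    return SectionThicknessPair(wet=wet, dry=dry)


def write_thickness_pair(pair: SectionThicknessPair, wet_path, dry_path) -> None:
    pd.DataFrame({"thickness": pair.wet}).to_csv(wet_path, index=False, float_format="%.12g")
    pd.DataFrame({"thickness": pair.dry}).to_csv(dry_path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of an end-to-end run."""

    params: ModelParams = field(default_factory=ModelParams)
    profile_spec: ProfileSpec = field(default_factory=ProfileSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_segments: int = 20
    arc_length: float = 1.0
    injected_defaults: tuple[str, ...] = ()
    config_hash: str = ""


_SCHEMA = {
    "model": {"stiffness_triplet", "nu_default", "eps_parenchyma", "total_wall_thickness"},
    "profile": {"n_stations", "knots", "residual_sd", "seed"},
    "noise": {"arc_point_sd", "mfa_noise_sd_deg", "seed"},
    "pipeline": {"n_segments", "arc_length"},
}


def _build_section(cls, raw: dict, prefix: str, injected: list[str], **convert):
    kwargs = {}
    for name in (f.name for f in dataclasses.fields(cls)):
        if name in raw:
            val = raw[name]
            kwargs[name] = convert[name](val) if name in convert else val
        else:
            injected.append(f"{prefix}.{name}")
    return cls(**kwargs)


def read_config(path) -> RunConfig:
    """Read and validate a YAML/JSON run configuration.

    Unknown keys are rejected; missing keys fall back to the packaged
    defaults and are recorded in ``injected_defaults`` so the run log
    can report them.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    for section, allowed in _SCHEMA.items():
        extra = set(raw.get(section, {}) or {}) - allowed
        if extra:
            raise ValueError(f"{path}: unknown keys in [{section}]: {sorted(extra)}")

    injected: list[str] = []
    params = _build_section(
        ModelParams,
        raw.get("model", {}) or {},
        "model",
        injected,
        stiffness_triplet=lambda v: tuple(float(x) for x in v),
    )
    prof_raw = dict(raw.get("profile", {}) or {})
    if "knots" in prof_raw:
        prof_raw["knots"] = {
            name: (float(k["s"]), (float(k["X_M"]), float(k["X_L"]), float(k["X_T"])))
            for name, k in prof_raw["knots"].items()
        }
    profile_spec = _build_section(ProfileSpec, prof_raw, "profile", injected)
    noise = _build_section(NoiseSpec, raw.get("noise", {}) or {}, "noise", injected)
    pipe = raw.get("pipeline", {}) or {}
    for key in ("n_segments", "arc_length"):
        if key not in pipe:
            injected.append(f"pipeline.{key}")
    digest = hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return RunConfig(
        params=params,
        profile_spec=profile_spec,
        noise=noise,
        n_segments=int(pipe.get("n_segments", 20)),
        arc_length=float(pipe.get("arc_length", 1.0)),
        injected_defaults=tuple(injected),
        config_hash=digest,
    )
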