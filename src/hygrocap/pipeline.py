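"""End-to-end analysis: simulate -> predict -> dissect -> measure -> compare.

Reproduces the study design on synthetic material: generate a graded
thickness profile, predict the longitudinal curvature profile from the
laminate model, synthesize dried-segment traces realizing that
prediction, re-measure them with the circle-fit procedure, and compare
measured against predicted normalized curvature.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .io import RunConfig, write_curvature, write_profile, write_traces
from .morphometry import measure_curvature_profile
from .profile import (
    NoMovementError,
    anticorrelation_stats,
    compare_profiles,
    peak_location,
    predict_curvature_profile,
)
from .synthetic import arcs_from_profile, canonical_profile

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineReport:
    peak_s_predicted: float | None
    peak_s_measured: float | None
    rmse_norm: float | None
    pearson_r: float | None
    delta_peak_s: float | None
    r2_M_vs_L: float
    r2_M_vs_T: float
    no_movement: bool


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineReport:
    """Run the full synthetic analysis described by ``config``.

    When ``out_dir`` is given, writes the profile, predicted and
    measured curvature tables, the segment traces, and a JSON run log
    recording seeds, injected defaults, the config hash and the package
    version.  Stage failures are re-raised with the stage name.
    """
    stage = "simulate"
    try:
        profile = canonical_profile(config.profile_spec)
        stats = anticorrelation_stats(profile)

        stage = "predict"
        predicted = predict_curvature_profile(profile, config.params)

        no_movement = not predicted.moves
        measured = None
        comparison = None
        if not no_movement:
            stage = "dissect"
            series = arcs_from_profile(
                predicted,
                n_segments=config.n_segments,
                arc_length=config.arc_length,
                noise=config.noise,
            )
            stage = "measure"
            try:
                measured = measure_curvature_profile(series)
            except NoMovementError:
                no_movement = True
            if measured is not None:
                stage = "compare"
                comparison = compare_profiles(predicted, measured)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = PipelineReport(
        peak_s_predicted=peak_location(predicted) if predicted.moves else None,
        peak_s_measured=peak_location(measured) if measured is not None else None,
        rmse_norm=comparison.rmse_norm if comparison else None,
        pearson_r=comparison.pearson_r if comparison else None,
        delta_peak_s=comparison.delta_peak_s if comparison else None,
        r2_M_vs_L=stats.r2_M_vs_L,
        r2_M_vs_T=stats.r2_M_vs_T,
        no_movement=no_movement,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_profile(profile, out / "profile.csv")
        write_curvature(predicted, out / "predicted_curvature.csv")
        if not no_movement:
            write_traces(series, out / "traces.csv", out / "widths.csv")
            write_curvature(measured, out / "measured_curvature.csv")
        log = {
            "version": __version__,
            "config_hash": config.config_hash,
            "injected_defaults": list(config.injected_defaults),
            "seeds": {
                "profile": config.profile_spec.seed,
                "noise": config.noise.seed,
            },
            "report": asdict(report),
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return report
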