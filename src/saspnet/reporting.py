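"""Scenario reports and the channel-perturbation arrow matrix.

The arrow matrix condenses the whole perturbation suite into one table:
for each metric (mean, amplitude, peak calcium, and Fourier mode diversity)
and each channel-alteration scenario, an arrow records whether the metric
rose, fell or stayed within tolerance of its wild-type value.  Scenarios in
which the Ca2+-dependent K+ channel is *activated* rather than blocked
(scenario-2 variants) are kept as separate columns, flagged by the ``+`` in
their clamp signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import EnsembleSeries, SummaryStats, compare_to_wt
from .perturbations import PerturbationSpec
from .spectral import (
    SpectrumResult,
    dominant_periods,
    mode_diversity,
    recurrent_module_length,
    running_average,
)

__all__ = ["ArrowTable", "build_arrow_table", "scenario_report", "ScenarioResult"]

_GLYPH = {"up": "up", "down": "down", "equal": "="}

METRICS = ("mean", "amplitude", "peak", "fourier_mode_diversity")


@dataclass(frozen=True)
class ScenarioResult:
    """Everything the reporting layer needs about one scenario."""

    spec: PerturbationSpec
    series: EnsembleSeries
    stats: SummaryStats
    spectrum: SpectrumResult


@dataclass(frozen=True)
class ArrowTable:
    """Metric-by-scenario matrix of 'up' / 'down' / '=' cells."""

    frame: pd.DataFrame  # index = METRICS, columns = scenario labels

    def cell(self, metric: str, scenario: str) -> str:
        return str(self.frame.loc[metric, scenario])

    @property
    def scenario2_columns(self) -> list[str]:
        """Columns where CaKC is clamped open rather than closed."""
        return [c for c in self.frame.columns if "+" in c]

    def to_text(self) -> str:
        return self.frame.to_string()


def build_arrow_table(
    results: dict[str, ScenarioResult],
    wt_label: str = "WT",
    rel_tol: float = 0.01,
    threshold_frac: float = 0.05,
) -> ArrowTable:
    """Assemble the arrow matrix from per-scenario results.

    Calcium metrics are compared with :func:`saspnet.ensemble.compare_to_wt`
    ('equal' within ``rel_tol`` of the wild-type value); mode diversity is
    an integer count compared exactly.
    """
    if wt_label not in results:
        raise ValueError(f"missing wild-type scenario {wt_label!r}")
    wt = results[wt_label]
    wt_div = mode_diversity(wt.spectrum, threshold_frac)
    cols = {}
    for label, res in results.items():
        if label == wt_label:
            continue
        if res.stats.window != wt.stats.window:
            raise ValueError(f"scenario {label!r} uses a different summary window")
        arrows = compare_to_wt(wt.stats, res.stats, rel_tol)
        div = mode_diversity(res.spectrum, threshold_frac)
        div_arrow = "up" if div > wt_div else ("down" if div < wt_div else "equal")
        cols[label] = [
            _GLYPH[arrows.mean],
            _GLYPH[arrows.amplitude],
            _GLYPH[arrows.peak],
            _GLYPH[div_arrow],
        ]
    frame = pd.DataFrame(cols, index=list(METRICS))
    return ArrowTable(frame)


def scenario_report(
    result: ScenarioResult,
    trace_steps: int = 60,
    threshold_frac: float = 0.05,
    envelope_windows: tuple[int, ...] = (3, 4, 8),
    module_tol: float = 1e-9,
) -> dict:
    """Self-contained per-scenario summary mirroring the figure panels.

    Returns a plain dict with a steady-state trace segment, the summary
    metrics, the dominant spectral lines, the recurrent module length of
    the raw series, and module lengths after running-average envelopes.
    """
    series = result.series
    x = np.asarray(series.values)
    report: dict = {
        "label": result.spec.label,
        "clamps": dict(result.spec.clamps),
        "n_ic": series.n_ic,
        "transient_discarded": series.transient_discarded,
        "trace": x[:trace_steps].tolist(),
        "mean": result.stats.mean,
        "amplitude": result.stats.amplitude,
        "peak": result.stats.peak,
        "interpeak_interval": result.stats.interpeak_interval,
        "dominant_periods": dominant_periods(result.spectrum, threshold_frac),
        "mode_diversity": mode_diversity(result.spectrum, threshold_frac),
        "module_length": recurrent_module_length(x, tol=module_tol),
        "spectral_lines": [
            {
                "frequency": line.frequency,
                "power": line.power,
                "period": line.period,
                "harmonic_of": line.harmonic_of,
            }
            for line in result.spectrum.dominant_modes
        ],
    }
    envelopes = {}
    for w in envelope_windows:
        if x.size >= 2 * w:
            env = running_average(x, w)
            envelopes[w] = recurrent_module_length(env, tol=module_tol)
    report["envelope_modules"] = envelopes
    return report
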