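"""Comparison-task subtraction and Bland–Altman equivalence.

Three ways of referencing the sentence-generation LI against the list
-generation comparison task are provided: (A) subtract the two
task LIs, (B) subtract the difference waves and run the peak procedure
on the result, and (C) subtract the period-of-interest means of the two
waves.  Bland–Altman limits of agreement with predetermined equivalence
bounds decide whether two LI measures are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io_formats import PipelineConfig, ValidationError
from .laterality import DifferenceWave, find_peak, li_mean_poi, li_peak

__all__ = [
    "BlandAltmanResult",
    "subtract_a",
    "subtract_b",
    "subtract_c",
    "bland_altman",
]


@dataclass
class BlandAltmanResult:
    """Limits-of-agreement summary for paired LI measures (x − y)."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean_low: float
    ci_mean_high: float
    predetermined_low: float
    predetermined_high: float
    within_limits_fraction: float
    verdict: str  # "equivalent" | "not_equivalent"


def subtract_a(li_sg: float, li_lg: float) -> float:
    """Method A: difference of the two tasks' LIs (sentence − list)."""
    return float(li_sg) - float(li_lg)


def _check_grids(dw_sg: DifferenceWave, dw_lg: DifferenceWave) -> None:
    if len(dw_sg.values) != len(dw_lg.values) or dw_sg.sample_rate != dw_lg.sample_rate:
        raise ValidationError("difference waves are on different time grids")
    if not np.allclose(dw_sg.time_s, dw_lg.time_s):
        raise ValidationError("difference waves are on different time grids")


def subtract_b(dw_sg: DifferenceWave, dw_lg: DifferenceWave, cfg: PipelineConfig) -> tuple[float, float]:
    """Method B: peak procedure on the wave-level difference (SG − LG).

    Returns ``(li, latency_s)`` from the subtracted waveform.
    """
    _check_grids(dw_sg, dw_lg)
    diff = DifferenceWave(
        task=dw_sg.task,
        time_s=dw_sg.time_s,
        values=dw_sg.values - dw_lg.values,
        n_trials=min(dw_sg.n_trials, dw_lg.n_trials),
        sample_rate=dw_sg.sample_rate,
    )
    latency = find_peak(diff, cfg)
    return li_peak(diff, latency, cfg), latency


def subtract_c(dw_sg: DifferenceWave, dw_lg: DifferenceWave, cfg: PipelineConfig) -> float:
    """Method C: difference of the period-of-interest means (SG − LG)."""
    _check_grids(dw_sg, dw_lg)
    return li_mean_poi(dw_sg, cfg) - li_mean_poi(dw_lg, cfg)


def bland_altman(x, y, cfg: PipelineConfig) -> BlandAltmanResult:
    """Bland–Altman agreement of paired measures with predetermined limits.

    Pairwise differences ``d = x − y`` give the mean difference, its sd,
    limits of agreement ``mean ± 1.96 sd`` and a t-based CI of the mean.
    The equivalence verdict follows the mean difference: ``equivalent``
    iff it lies within the predetermined limits.  The fraction of
    individual differences inside the limits is also reported so the
    stricter every-point rule can be applied by the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be paired 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("Bland–Altman needs at least 3 pairs")
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low = mean - 1.96 * sd
    loa_high = mean + 1.96 * sd
    tcrit = float(sps.t.ppf(0.5 + cfg.ci_level / 2.0, n - 1))
    half = tcrit * sd / np.sqrt(n)
    lo, hi = cfg.predetermined_loa
    within = float(np.mean((d >= lo) & (d <= hi)))
    verdict = "equivalent" if lo <= mean <= hi else "not_equivalent"
    return BlandAltmanResult(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_mean_low=mean - half,
        ci_mean_high=mean + half,
        predetermined_low=lo,
        predetermined_high=hi,
        within_limits_fraction=within,
        verdict=verdict,
    )
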