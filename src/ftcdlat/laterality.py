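"""Laterality indices from baseline-corrected epochs.

The group left-minus-right difference wave is averaged over a task's
included trials; the laterality index (LI) is the mean of that wave in
a two-second window centred on the point of maximal absolute difference
within the period of interest (peak method), or the mean of the wave
over the whole period of interest (mean method).  Per-trial LIs, read
from the same window, give a 95 % confidence interval that classifies a
participant as left-, right- or not (bilateral) lateralised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io_formats import (
    PipelineConfig,
    ProcessingError,
    ValidationError,
    sec_to_index,
)
from .preprocess import Epoch

__all__ = [
    "DifferenceWave",
    "LateralityResult",
    "mean_difference_wave",
    "find_peak",
    "li_peak",
    "trial_lis",
    "classify",
    "li_mean_poi",
    "split_half",
    "analyse_task",
    "analyse_epochs",
]


@dataclass
class DifferenceWave:
    """Mean left-minus-right curve for one task (percentage points)."""

    task: str
    time_s: np.ndarray
    values: np.ndarray
    n_trials: int
    sample_rate: int

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.time_s) != len(self.values):
            raise ValidationError("time axis and values differ in length")
        if self.n_trials < 1:
            raise ValidationError("a difference wave needs at least one trial")


@dataclass
class LateralityResult:
    """LI, peak latency, per-trial LIs, CI and category for one task."""

    task: str
    method: str  # "peak" or "mean"
    li: float
    latency_s: float
    trial_lis: np.ndarray
    ci_low: float
    ci_high: float
    category: str
    n_trials: int


def _included(epochs: list[Epoch]) -> list[Epoch]:
    eps = [ep for ep in epochs if ep.included]
    for ep in eps:
        if ep.state != "baselined":
            raise ProcessingError(
                f"laterality analysis expects baselined epochs, got {ep.state!r}"
            )
    return eps


def mean_difference_wave(epochs: list[Epoch], task: str | None = None) -> DifferenceWave:
    """Pointwise mean of per-epoch (left − right) over included trials."""
    eps = _included(epochs)
    if task is not None:
        eps = [ep for ep in eps if ep.task == task]
    else:
        tasks = {ep.task for ep in eps}
        if len(tasks) > 1:
            raise ValidationError(f"epochs span several tasks {sorted(tasks)}; pass task=")
        task = tasks.pop() if tasks else None
    if not eps:
        raise ProcessingError(f"no included epochs for task {task!r}")
    values = np.mean([ep.difference() for ep in eps], axis=0)
    first = eps[0]
    return DifferenceWave(task, first.time_s, values, len(eps), first.sample_rate)


def _poi_slice(dw: DifferenceWave, cfg: PipelineConfig) -> slice:
    a = sec_to_index(cfg.poi_s[0], dw.sample_rate)
    b = sec_to_index(cfg.poi_s[1], dw.sample_rate)
    a = max(a, 0)
    b = min(b, len(dw.values))
    if b <= a:
        raise ValidationError("period of interest is empty after clipping to the wave")
    return slice(a, b)


def find_peak(dw: DifferenceWave, cfg: PipelineConfig) -> float:
    """Latency (s) of the maximal |L−R| within the period of interest.

    Ties are broken by the earliest time.  The absolute value is used so
    that right-lateralised responses (negative difference) yield their
    true peak rather than the largest positive excursion.
    """
    sl = _poi_slice(dw, cfg)
    seg = np.abs(dw.values[sl])
    return float(dw.time_s[sl.start + int(np.argmax(seg))])


def _window_slice(latency_s: float, hw_s: float, rate: int, n: int) -> slice:
    a = sec_to_index(latency_s - hw_s, rate)
    b = sec_to_index(latency_s + hw_s, rate) + 1  # inclusive, symmetric
    return slice(max(a, 0), min(b, n))


def li_peak(dw: DifferenceWave, latency_s: float, cfg: PipelineConfig) -> float:
    """Mean of the difference wave in the 2-s window centred at the peak."""
    sl = _window_slice(latency_s, cfg.peak_window_halfwidth_s, dw.sample_rate, len(dw.values))
    return float(np.mean(dw.values[sl]))


def trial_lis(epochs: list[Epoch], latency_s: float, cfg: PipelineConfig) -> np.ndarray:
    """Per-trial LI: each trial's mean (L−R) over the group peak window.

    The window is fixed at the task's group-mean latency so that the CI
    over trials estimates the uncertainty of the group LI itself; by
    linearity, the mean of these values equals the group peak LI.
    """
    eps = _included(epochs)
    if not eps:
        raise ProcessingError("no included epochs")
    sl = _window_slice(latency_s, cfg.peak_window_halfwidth_s, eps[0].sample_rate, eps[0].n_samples)
    return np.array([float(np.mean(ep.difference()[sl])) for ep in eps])


def classify(values: np.ndarray, cfg: PipelineConfig) -> tuple[float, float, str]:
    """95 % t-interval of per-trial LIs → (ci_low, ci_high, category).

    Left-lateralised if the whole interval is above zero, right if
    below, bilateral if it spans zero.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ProcessingError("classification needs at least 2 trial LIs")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    tcrit = float(sps.t.ppf(0.5 + cfg.ci_level / 2.0, n - 1))
    half = tcrit * sd / np.sqrt(n)
    ci_low, ci_high = mean - half, mean + half
    category = "left" if ci_low > 0 else ("right" if ci_high < 0 else "bilateral")
    return ci_low, ci_high, category


def li_mean_poi(dw: DifferenceWave, cfg: PipelineConfig) -> float:
    """Mean of the difference wave over the whole period of interest."""
    return float(np.mean(dw.values[_poi_slice(dw, cfg)]))


def split_half(epochs: list[Epoch], cfg: PipelineConfig) -> tuple[float, float]:
    """Peak LIs from odd- and even-numbered trials, run independently.

    Trials are split by their original (1-based) position within the
    task; each half gets its own mean wave, peak and window.  A half
    with fewer than two included trials yields NaN.
    """
    eps = [ep for ep in epochs if ep.included]
    eps.sort(key=lambda ep: ep.trial_index)
    halves = []
    for parity in (0, 1):  # 0 → 1st, 3rd, ... ("odd" 1-based)
        half = eps[parity::2]
        if len(half) < 2:
            halves.append(float("nan"))
            continue
        dw = mean_difference_wave(half, task=half[0].task)
        latency = find_peak(dw, cfg)
        halves.append(li_peak(dw, latency, cfg))
    return halves[0], halves[1]


def analyse_task(epochs: list[Epoch], cfg: PipelineConfig, method: str = "peak") -> LateralityResult:
    """Full LI procedure for one task's epochs, peak or mean method.

    For the mean method the latency is reported as the midpoint of the
    period of interest by convention, and per-trial LIs are each trial's
    mean difference over the whole period of interest.
    """
    eps = _included(epochs)
    if not eps:
        raise ProcessingError("no included epochs for laterality analysis")
    task = eps[0].task
    dw = mean_difference_wave(eps, task=task)
    if method == "peak":
        latency = find_peak(dw, cfg)
        li = li_peak(dw, latency, cfg)
        tl = trial_lis(eps, latency, cfg)
    elif method == "mean":
        latency = (cfg.poi_s[0] + cfg.poi_s[1]) / 2.0
        li = li_mean_poi(dw, cfg)
        sl = _poi_slice(dw, cfg)
        tl = np.array([float(np.mean(ep.difference()[sl])) for ep in eps])
    else:
        raise ValidationError(f"unknown method {method!r}")
    ci_low, ci_high, category = classify(tl, cfg)
    return LateralityResult(
        task=task,
        method=method,
        li=li,
        latency_s=latency,
        trial_lis=tl,
        ci_low=ci_low,
        ci_high=ci_high,
        category=category,
        n_trials=len(eps),
    )


def analyse_epochs(epochs: list[Epoch], cfg: PipelineConfig) -> dict:
    """Analyse all tasks present: results per method, wave and split-half.

    Returns ``{task: {"peak": LateralityResult, "mean": LateralityResult,
    "wave": DifferenceWave, "split_half": (odd, even)}}``.
    """
    out: dict = {}
    tasks = sorted({ep.task for ep in epochs})
    for task in tasks:
        task_eps = [ep for ep in epochs if ep.task == task]
        included = [ep for ep in task_eps if ep.included]
        if not included:
            raise ProcessingError(f"no included epochs for task {task!r}")
        out[task] = {
            "peak": analyse_task(included, cfg, method="peak"),
            "mean": analyse_task(included, cfg, method="mean"),
            "wave": mean_difference_wave(included, task=task),
            "split_half": split_half(included, cfg),
        }
    return out
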