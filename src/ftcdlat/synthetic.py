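"""Synthetic dual-channel fTCD recordings with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: cardiac pulse modulation of velocity, a task-locked bilateral
evoked rise with a lateralised (left-minus-right) component that begins
a few seconds after stimulus onset and is sustained through the covert
generation phase, additive Gaussian noise, slow random-walk drift,
isolated single-sample spikes, and multi-sample signal dropouts.

The signal model per channel is multiplicative in the slow components::

    v(t) = base * (1 + depth * cardiac(phase(t)) + evoked(t) + drift(t)) + noise(t)

so that after normalisation to a per-channel mean of 100 the evoked
component reads directly in percentage points, which is the unit the
laterality index is expressed in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io_formats import TASK_NAMES, TASKS, RawRecording, ValidationError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "cardiac_waveform",
    "evoked_response",
    "simulate_recording",
    "simulate_cohort",
    "write_truth",
]

NATIVE_RATE_HZ = 100

# Evoked-envelope shape (seconds relative to stimulus onset): half-cosine
# rise after the onset delay, plateau through the 2-s stimulus display and
# the 10-s covert generation phase, half-cosine return to baseline.
EVOKED_RISE_S = 1.5
EVOKED_PLATEAU_END_S = 12.0
EVOKED_FALL_S = 3.0

#: per-trial mean word counts used for the simulated behavioural metadata
WORD_COUNT_MEANS = {"list": 10.0, "sentence": 9.0, "word": 4.0}

# Gamma-like systolic pulse shape: fast rise to a peak early in the
# cycle, slow diastolic decay.  The mode sits at phase 0.12.
_PULSE_MODE = 0.12


def _pulse_shape(phase: np.ndarray) -> np.ndarray:
    p = np.asarray(phase, dtype=float)
    return (p / _PULSE_MODE) * np.exp(1.0 - p / _PULSE_MODE)


# Cycle mean of the raw shape, removed so that heart-cycle averaging of the
# modulation term yields (numerically) zero.  Dense trapezoid quadrature.
_grid = np.linspace(0.0, 1.0, 200_001)
_PULSE_MEAN = float(np.trapezoid(_pulse_shape(_grid), _grid))
del _grid


def cardiac_waveform(phase) -> np.ndarray:
    """Dimensionless cardiac modulation factor at cycle phase in [0, 1).

    The waveform is periodic with zero mean over a cycle (to ~1e-6), so
    a cycle-averaged velocity equals the slow component alone.  The
    systolic peak occurs at phase 0.12, well before phase 0.25.
    """
    p = np.asarray(phase, dtype=float)
    if np.any((p < 0.0) | (p >= 1.0)):
        raise ValidationError("cardiac phase must lie in [0, 1)")
    return _pulse_shape(p) - _PULSE_MEAN


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic participant.

    Amplitude-like parameters are percentages of the per-channel base
    velocity; ``planted_li_pct`` is the left-minus-right evoked plateau
    difference per task, i.e. the laterality index the pipeline should
    recover (in percentage points).
    """

    n_trials_per_task: int = 20
    task_order: Sequence[str] | None = None
    inter_trial_interval_s: float = 30.0
    heart_rate_bpm: float = 70.0
    heart_rate_jitter_bpm: float = 3.0
    base_velocity_cms: tuple[float, float] = (55.0, 53.0)
    pulse_modulation_depth: float = 0.25
    evoked_amplitude_pct: float = 3.0
    planted_li_pct: dict = field(
        default_factory=lambda: {"list": 0.0, "sentence": 5.0, "word": 2.5}
    )
    evoked_onset_delay_s: float = 2.5
    noise_sd_pct: float = 0.8
    drift_sd_pct: float = 0.02
    spike_prob_per_trial: float = 0.05
    dropout_prob_per_trial: float = 0.03
    lead_in_s: float = 10.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_trials_per_task < 1:
            raise ValidationError("n_trials_per_task must be >= 1")
        if self.inter_trial_interval_s < 30.0 - 1e-9:
            raise ValidationError("inter_trial_interval_s must be >= 30 s (epoch length)")
        for name in ("heart_rate_bpm", "pulse_modulation_depth", "evoked_amplitude_pct"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("heart_rate_jitter_bpm", "noise_sd_pct", "drift_sd_pct"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if any(b <= 0 for b in self.base_velocity_cms):
            raise ValidationError("base velocities must be positive")
        for name in ("spike_prob_per_trial", "dropout_prob_per_trial"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.spike_prob_per_trial + self.dropout_prob_per_trial > 1.0:
            raise ValidationError("artifact probabilities must sum to <= 1")
        unknown = set(self.planted_li_pct) - set(TASKS)
        if unknown:
            raise ValidationError(f"planted_li_pct has unknown task(s): {sorted(unknown)}")
        for task in TASKS:
            self.planted_li_pct.setdefault(task, 0.0)
        if self.task_order is not None:
            order = list(self.task_order)
            if sorted(order) != sorted(list(TASKS) * self.n_trials_per_task):
                raise ValidationError(
                    "task_order must contain each task exactly n_trials_per_task times"
                )
            self.task_order = order
        if self.lead_in_s < 5.0:
            raise ValidationError("lead_in_s must be >= 5 s (pre-trigger epoch span)")


@dataclass
class SimulationTruth:
    """Planted per-trial ground truth emitted alongside a recording.

    ``trials`` has one row per emitted trigger with columns ``trial``,
    ``task``, ``trigger_sample`` (native-rate index), ``planted_li``,
    ``artifact`` (none/spike/dropout) and ``n_words`` (simulated
    behavioural word count).
    """

    trials: pd.DataFrame
    planted_li: dict

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def evoked_response(t_since_stimulus, cfg: SimulationConfig, planted_li_pct: float):
    """Evoked velocity increase (percent of base) per channel at time ``t``.

    Returns the pair ``(left, right)``.  Both channels share one smooth
    envelope: zero before the onset delay, a half-cosine rise, a plateau
    sustained through the covert-generation phase, then a half-cosine
    decay.  On the plateau the bilateral mean equals
    ``cfg.evoked_amplitude_pct`` and the left-minus-right difference
    equals ``planted_li_pct``.
    """
    env = _evoked_envelope(t_since_stimulus, cfg.evoked_onset_delay_s)
    left = (cfg.evoked_amplitude_pct + planted_li_pct / 2.0) * env
    right = (cfg.evoked_amplitude_pct - planted_li_pct / 2.0) * env
    return left, right


def _evoked_envelope(t, onset_delay: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    env = np.zeros_like(t)
    rise_end = onset_delay + EVOKED_RISE_S
    fall_end = EVOKED_PLATEAU_END_S + EVOKED_FALL_S
    rising = (t >= onset_delay) & (t < rise_end)
    env[rising] = 0.5 * (1.0 - np.cos(np.pi * (t[rising] - onset_delay) / EVOKED_RISE_S))
    env[(t >= rise_end) & (t < EVOKED_PLATEAU_END_S)] = 1.0
    falling = (t >= EVOKED_PLATEAU_END_S) & (t < fall_end)
    env[falling] = 0.5 * (1.0 + np.cos(np.pi * (t[falling] - EVOKED_PLATEAU_END_S) / EVOKED_FALL_S))
    return env


def _default_task_order(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Pseudorandom interleaving split into two runs of equal size."""
    n = cfg.n_trials_per_task
    first, second = [], []
    for task in TASKS:
        k = n // 2
        first += [task] * k
        second += [task] * (n - k)
    rng.shuffle(first)
    rng.shuffle(second)
    return first + second


def simulate_recording(cfg: SimulationConfig) -> tuple[RawRecording, SimulationTruth]:
    """Generate one participant's 100 Hz recording plus ground truth.

    The same ``cfg.rng_seed`` always yields a bit-identical recording.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    rate = NATIVE_RATE_HZ
    order = list(cfg.task_order) if cfg.task_order is not None else _default_task_order(cfg, rng)
    n_trials = len(order)
    iti = cfg.inter_trial_interval_s
    total_s = cfg.lead_in_s + (n_trials - 1) * iti + 25.0 + 5.0
    n = int(round(total_s * rate))
    times = np.arange(n) / rate

    # --- cardiac phase: beat-to-beat jitter in heart rate
    mean_beat = 60.0 / cfg.heart_rate_bpm
    n_beats = int(np.ceil(total_s / mean_beat * 1.5)) + 10
    bpm = rng.normal(cfg.heart_rate_bpm, cfg.heart_rate_jitter_bpm, n_beats)
    bpm = np.clip(bpm, 30.0, 200.0)
    durations = 60.0 / bpm
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    beat = np.searchsorted(starts, times, side="right") - 1
    phase = (times - starts[beat]) / durations[beat]
    phase = np.clip(phase, 0.0, np.nextafter(1.0, 0.0))
    cardiac = cardiac_waveform(phase)

    # --- markers and evoked component
    marker_samples = (cfg.lead_in_s + np.arange(n_trials) * iti) * rate
    marker_samples = np.round(marker_samples).astype(int)
    marker = np.zeros(n, dtype=int)
    evoked_l = np.zeros(n)
    evoked_r = np.zeros(n)
    fall_end = EVOKED_PLATEAU_END_S + EVOKED_FALL_S
    for m, task in zip(marker_samples, order):
        marker[m] = TASK_NAMES[task]
        stop = min(n, m + int(fall_end * rate) + 1)
        t_rel = (np.arange(m, stop) - m) / rate
        le, re_ = evoked_response(t_rel, cfg, cfg.planted_li_pct[task])
        evoked_l[m:stop] += le
        evoked_r[m:stop] += re_

    # --- slow drift (independent random walk per channel) and noise
    base_l, base_r = cfg.base_velocity_cms
    step = cfg.drift_sd_pct / 100.0
    drift_l = rng.normal(0.0, step, n).cumsum() if step > 0 else np.zeros(n)
    drift_r = rng.normal(0.0, step, n).cumsum() if step > 0 else np.zeros(n)
    noise_sd = cfg.noise_sd_pct / 100.0
    noise_l = rng.normal(0.0, noise_sd * base_l, n) if noise_sd > 0 else 0.0
    noise_r = rng.normal(0.0, noise_sd * base_r, n) if noise_sd > 0 else 0.0

    depth = cfg.pulse_modulation_depth
    left = base_l * (1.0 + depth * cardiac + evoked_l / 100.0 + drift_l) + noise_l
    right = base_r * (1.0 + depth * cardiac + evoked_r / 100.0 + drift_r) + noise_r

    # --- artifacts: at most one per trial, logged in the truth table
    artifacts = []
    epoch_pre = int(5.0 * rate)
    epoch_post = int(25.0 * rate)
    for m in marker_samples:
        u = rng.uniform()
        if u < cfg.spike_prob_per_trial:
            artifacts.append("spike")
            offset = int(rng.integers(-epoch_pre + 2, epoch_post - 2))
            chan = left if rng.uniform() < 0.5 else right
            base = base_l if chan is left else base_r
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            chan[m + offset] += sign * 3.0 * base
        elif u < cfg.spike_prob_per_trial + cfg.dropout_prob_per_trial:
            artifacts.append("dropout")
            dur = int(rng.uniform(0.5, 1.5) * rate)
            start = m + int(rng.integers(-epoch_pre + 1, epoch_post - dur - 1))
            chan = left if rng.uniform() < 0.5 else right
            chan[start : start + dur] = 0.0  # flat-line signal loss
        else:
            artifacts.append("none")

    n_words = [int(rng.poisson(WORD_COUNT_MEANS[task])) for task in order]

    rec = RawRecording(rate, left, right, marker)
    trials = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "task": order,
            "trigger_sample": marker_samples,
            "planted_li": [cfg.planted_li_pct[t] for t in order],
            "artifact": artifacts,
            "n_words": n_words,
        }
    )
    truth = SimulationTruth(trials=trials, planted_li=dict(cfg.planted_li_pct))
    return rec, truth


#: default between-participant sd of the planted LI, per task (pct points)
DEFAULT_LI_BETWEEN_SD = {"list": 2.0, "sentence": 2.0, "word": 1.5}
#: default cross-task correlation of a participant's planted LIs
DEFAULT_CROSS_TASK_RHO = 0.6


def simulate_cohort(
    n_participants: int,
    cfg: SimulationConfig | None = None,
    li_between_sd: dict | float | None = None,
    cross_task_rho: float = DEFAULT_CROSS_TASK_RHO,
    seed: int = 0,
) -> Iterator[tuple[str, RawRecording, SimulationTruth]]:
    """Yield ``(participant_id, recording, truth)`` for a simulated cohort.

    Each participant's planted per-task LIs are drawn around the config
    values with between-participant sd ``li_between_sd`` (a dict per task
    or one scalar; default sds 2.0/2.0/1.5 for list/sentence/word) and a
    shared trait inducing cross-task correlation ``cross_task_rho``.
    Pass ``li_between_sd=0`` for a cohort of identical planted values.
    """
    if cfg is None:
        cfg = SimulationConfig()
    if li_between_sd is None:
        sds = dict(DEFAULT_LI_BETWEEN_SD)
    elif np.isscalar(li_between_sd):
        sds = {task: float(li_between_sd) for task in TASKS}
    else:
        sds = {task: float(li_between_sd.get(task, 0.0)) for task in TASKS}
    if not 0.0 <= cross_task_rho <= 1.0:
        raise ValidationError("cross_task_rho must be in [0, 1]")
    master = np.random.default_rng(seed)
    w_shared = np.sqrt(cross_task_rho)
    w_own = np.sqrt(1.0 - cross_task_rho)
    for i in range(n_participants):
        trait = master.normal()
        planted = {}
        for task in TASKS:
            z = w_shared * trait + w_own * master.normal()
            planted[task] = cfg.planted_li_pct[task] + sds[task] * z
        pcfg = dataclasses.replace(
            cfg,
            planted_li_pct=planted,
            rng_seed=int(master.integers(2**31)),
            task_order=list(cfg.task_order) if cfg.task_order is not None else None,
        )
        rec, truth = simulate_recording(pcfg)
        yield f"p{i + 1:03d}", rec, truth


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Write the per-trial ground-truth table as CSV."""
    truth.trials.to_csv(path, index=False)
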