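"""Raw recording → cleaned, normalised, heart-cycle-integrated epochs.

The stages run in a fixed order: down-sample, segment into 30-s epochs,
de-spike at extreme quantiles, normalise each channel to a mean of 100,
replace samples by per-heart-cycle means, subtract the pre-trigger
baseline, and finally reject epochs whose normalised signal leaves the
60–140 % band.  Each epoch tracks its processing state and the ops
refuse epochs in the wrong state, so the order cannot silently be
violated.  Excluded epochs keep their data and record why they were
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io_formats import (
    PipelineConfig,
    ProcessingError,
    RawRecording,
    ValidationError,
    sec_to_index,
)

__all__ = [
    "Epoch",
    "downsample",
    "segment_epochs",
    "despike",
    "normalise",
    "integrate_heart_cycles",
    "baseline_correct",
    "reject_artifacts",
    "preprocess_recording",
    "qc_frame",
]

STATES = ("raw", "despiked", "normalised", "integrated", "baselined")

EXCLUSION_REASONS = (
    "none",
    "dropout_run",
    "artifact_out_of_range",
    "incomplete_epoch",
    "cannot_integrate",
    "behavioural",
)


@dataclass
class Epoch:
    """One trial's two-channel 30-s segment with processing state."""

    trial_index: int
    task: str
    trigger_sample: int  # index in the down-sampled recording
    sample_rate: int
    left: np.ndarray
    right: np.ndarray
    state: str = "raw"
    included: bool = True
    exclusion_reason: str = "none"
    #: per-channel offsets removed by baseline correction (left, right)
    baseline_offset: tuple[float, float] | None = None

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if len(self.left) != len(self.right):
            raise ValidationError("epoch channels differ in length")
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValidationError(f"unknown exclusion reason {self.exclusion_reason!r}")

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def time_s(self) -> np.ndarray:
        """Epoch-time axis in seconds (0 = epoch start, 5 s pre-trigger)."""
        return np.arange(self.n_samples) / self.sample_rate

    def exclude(self, reason: str) -> None:
        if reason not in EXCLUSION_REASONS:
            raise ValidationError(f"unknown exclusion reason {reason!r}")
        self.included = False
        if self.exclusion_reason == "none":
            self.exclusion_reason = reason

    def difference(self) -> np.ndarray:
        """Left-minus-right trace for this epoch."""
        return self.left - self.right


def _require_state(epochs, expected: str, op: str) -> None:
    for ep in epochs:
        if ep.state != expected:
            raise ProcessingError(
                f"{op} expects epochs in state {expected!r}, got {ep.state!r} "
                f"(trial {ep.trial_index})"
            )


def downsample(rec: RawRecording, factor: int) -> RawRecording:
    """Block-average the recording by ``factor`` (100 Hz → 25 Hz at 4).

    Each output sample is the mean of its block of ``factor`` inputs;
    a trailing remainder is discarded.  Markers are relocated to the
    block containing them.
    """
    if factor < 1:
        raise ValidationError("downsample factor must be >= 1")
    if rec.sample_rate % factor != 0:
        raise ValidationError(
            f"factor {factor} does not divide the sample rate {rec.sample_rate}"
        )
    if factor == 1:
        return rec
    n_blocks = rec.n_samples // factor
    n = n_blocks * factor
    left = rec.left[:n].reshape(n_blocks, factor).mean(axis=1)
    right = rec.right[:n].reshape(n_blocks, factor).mean(axis=1)
    # markers are isolated, so the block maximum preserves the task code
    marker = rec.marker[:n].reshape(n_blocks, factor).max(axis=1)
    return RawRecording(rec.sample_rate // factor, left, right, marker)


def segment_epochs(rec: RawRecording, cfg: PipelineConfig) -> list[Epoch]:
    """Cut one epoch per trial marker: 5 s pre- to 25 s post-trigger.

    Epochs that would overrun either end of the recording are emitted
    with NaN padding and flagged ``incomplete_epoch``.
    """
    rate = rec.sample_rate
    pre = sec_to_index(cfg.epoch_start_s, rate)
    length = sec_to_index(cfg.epoch_length_s, rate)
    epochs: list[Epoch] = []
    for trial_index, (m, task) in enumerate(rec.triggers()):
        start = m - pre
        end = start + length
        left = np.full(length, np.nan)
        right = np.full(length, np.nan)
        lo = max(start, 0)
        hi = min(end, rec.n_samples)
        left[lo - start : hi - start] = rec.left[lo:hi]
        right[lo - start : hi - start] = rec.right[lo:hi]
        ep = Epoch(trial_index, task, m, rate, left, right)
        if start < 0 or end > rec.n_samples:
            ep.exclude("incomplete_epoch")
        epochs.append(ep)
    return epochs


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open ``[start, stop)`` runs of True in a boolean mask."""
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(edges[::2], edges[1::2]))


def despike(epochs: list[Epoch], cfg: PipelineConfig) -> list[Epoch]:
    """Interpolate brief extreme excursions; exclude signal-loss runs.

    Thresholds are the per-channel empirical 0.0001 / 0.9999 quantiles
    over all epoch samples of the recording.  An extreme sample is one
    at or beyond a threshold.  Because empirical quantiles by
    construction always flag a handful of samples — and the pulse shape
    clusters extremes at systolic peaks and diastolic troughs — a run
    of two or three chance extremes occurs in most artifact-free
    recordings.  Brief excursions (shorter than ``min_loss_run_s``) are
    therefore repaired by linear interpolation between the nearest
    in-range neighbours, and only runs of at least ``min_loss_run_s``
    (default 0.25 s, far below any genuine dropout yet well above
    chance clusters) mark a period of signal loss and exclude the
    epoch (``dropout_run``).
    """
    _require_state(epochs, "raw", "despike")
    pools = {
        "left": np.concatenate([ep.left for ep in epochs]) if epochs else np.array([]),
        "right": np.concatenate([ep.right for ep in epochs]) if epochs else np.array([]),
    }
    thresholds = {}
    for chan, pool in pools.items():
        pool = pool[np.isfinite(pool)]
        if len(pool) == 0:
            raise ProcessingError("no finite samples to estimate spike thresholds from")
        thresholds[chan] = (
            float(np.quantile(pool, cfg.spike_quantile_low)),
            float(np.quantile(pool, cfg.spike_quantile_high)),
        )
    min_run = max(2, sec_to_index(cfg.min_loss_run_s, epochs[0].sample_rate) if epochs else 2)
    for ep in epochs:
        if ep.included:
            for chan in ("left", "right"):
                x = getattr(ep, chan)
                lo, hi = thresholds[chan]
                mask = (x <= lo) | (x >= hi)
                if not mask.any():
                    continue
                if mask.all():
                    raise ProcessingError(
                        f"trial {ep.trial_index}: all {chan} samples extreme; "
                        "cannot despike a degenerate epoch"
                    )
                if any(stop - start >= min_run for start, stop in _runs(mask)):
                    ep.exclude("dropout_run")
                    break
                good = np.flatnonzero(~mask)
                bad = np.flatnonzero(mask)
                x[bad] = np.interp(bad, good, x[good])
        ep.state = "despiked"
    return epochs


def normalise(epochs: list[Epoch]) -> list[Epoch]:
    """Scale each channel so its mean over included epochs is 100.

    This removes the dependence of absolute velocity on insonation
    angle and vessel diameter; values become percent of the session
    mean per channel.
    """
    _require_state(epochs, "despiked", "normalise")
    included = [ep for ep in epochs if ep.included]
    if not included:
        raise ProcessingError("no included epochs to normalise")
    for chan in ("left", "right"):
        mean = float(np.mean(np.concatenate([getattr(ep, chan) for ep in included])))
        if not np.isfinite(mean) or mean <= 0:
            raise ProcessingError(f"non-positive {chan}-channel mean ({mean}); cannot normalise")
        for ep in epochs:
            setattr(ep, chan, getattr(ep, chan) * (100.0 / mean))
    for ep in epochs:
        ep.state = "normalised"
    return epochs


def integrate_heart_cycles(epochs: list[Epoch], cfg: PipelineConfig) -> list[Epoch]:
    """Replace samples by per-cardiac-cycle means to remove pulsatility.

    Systolic peaks are detected on the mean of the two channels (the
    cardiac cycle is common to both) as local maxima with a minimum
    separation of ``min_cycle_separation_s`` and a prominence of at
    least 25 % of the epoch's peak-to-trough amplitude.  Samples within
    each peak-to-peak interval take that interval's per-channel mean;
    samples before the first (after the last) peak take the first
    (last) cycle's mean.  Epochs with fewer than three detected peaks
    cannot be integrated and are excluded.
    """
    _require_state(epochs, "normalised", "integrate_heart_cycles")
    distance = max(1, sec_to_index(cfg.min_cycle_separation_s, epochs[0].sample_rate) if epochs else 1)
    for ep in epochs:
        if ep.included:
            m = (ep.left + ep.right) / 2.0
            prominence = 0.25 * (np.max(m) - np.min(m))
            peaks, _ = find_peaks(m, distance=distance, prominence=prominence)
            if len(peaks) < 3:
                ep.exclude("cannot_integrate")
            else:
                n_cycles = len(peaks) - 1
                cycle = np.searchsorted(peaks, np.arange(ep.n_samples), side="right") - 1
                cycle = np.clip(cycle, 0, n_cycles - 1)
                counts = np.bincount(cycle, minlength=n_cycles)
                for chan in ("left", "right"):
                    x = getattr(ep, chan)
                    means = np.bincount(cycle, weights=x, minlength=n_cycles) / counts
                    setattr(ep, chan, means[cycle])
        ep.state = "integrated"
    return epochs


def baseline_correct(epochs: list[Epoch], cfg: PipelineConfig) -> list[Epoch]:
    """Subtract each channel's mean over the pre-trigger rest window.

    After correction, values are percentage-point changes from rest and
    the baseline-window mean is zero.  The removed offsets are kept on
    the epoch so later stages can recover the pre-baseline signal.
    """
    _require_state(epochs, "integrated", "baseline_correct")
    for ep in epochs:
        b0 = sec_to_index(cfg.baseline_window_s[0], ep.sample_rate)
        b1 = sec_to_index(cfg.baseline_window_s[1], ep.sample_rate)
        if ep.included:
            off_l = float(np.mean(ep.left[b0:b1]))
            off_r = float(np.mean(ep.right[b0:b1]))
            ep.left = ep.left - off_l
            ep.right = ep.right - off_r
            ep.baseline_offset = (off_l, off_r)
        ep.state = "baselined"
    return epochs


def reject_artifacts(epochs: list[Epoch], cfg: PipelineConfig) -> list[Epoch]:
    """Exclude epochs whose normalised signal leaves the 60–140 % band.

    The thresholds refer to the normalised, pre-baseline signal (mean
    100); the stored baseline offsets are added back for the check.
    """
    _require_state(epochs, "baselined", "reject_artifacts")
    for ep in epochs:
        if not ep.included:
            continue
        off_l, off_r = ep.baseline_offset
        for x, off in ((ep.left, off_l), (ep.right, off_r)):
            pre = x + off
            if np.any(pre < cfg.artifact_low_pct) or np.any(pre > cfg.artifact_high_pct):
                ep.exclude("artifact_out_of_range")
                break
    return epochs


def preprocess_recording(rec: RawRecording, cfg: PipelineConfig) -> list[Epoch]:
    """Run the full preprocessing chain on a native-rate recording."""
    ds = downsample(rec, cfg.downsample_factor)
    epochs = segment_epochs(ds, cfg)
    if not epochs:
        return epochs
    despike(epochs, cfg)
    normalise(epochs)
    integrate_heart_cycles(epochs, cfg)
    baseline_correct(epochs, cfg)
    reject_artifacts(epochs, cfg)
    return epochs


def qc_frame(epochs: list[Epoch]) -> pd.DataFrame:
    """Per-trial quality-control table (trial, task, included, reason)."""
    return pd.DataFrame(
        {
            "trial": [ep.trial_index for ep in epochs],
            "task": [ep.task for ep in epochs],
            "included": [ep.included for ep in epochs],
            "exclusion_reason": [ep.exclusion_reason for ep in epochs],
        }
    )
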