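"""Signal, configuration and results I/O for the fTCD laterality pipeline.

All timing and threshold conventions live in :class:`PipelineConfig` so
that every stage of the pipeline reads them from one place.  Timing values
are expressed in seconds and converted to sample indices by rounding
half-up at the working sampling rate; windows are half-open ``[start,
end)`` unless noted otherwise.

The signal interchange format is a headered tab-separated file::

    # sample_rate_hz: 100
    # tasks: 1=list,2=sentence,3=word
    left<TAB>right<TAB>marker

with one row per sample.  ``left``/``right`` are cerebral blood flow
velocities (cm/s) from the two middle-cerebral-artery probes; ``marker``
is 0 except at the single sample marking each trial's stimulus onset,
where it carries the task code.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TASK_CODES",
    "TASK_NAMES",
    "TASKS",
    "FormatError",
    "ParseError",
    "ValidationError",
    "ProcessingError",
    "RawRecording",
    "PipelineConfig",
    "ResultsRow",
    "sec_to_index",
    "read_recording",
    "write_recording",
    "load_config",
    "write_results",
    "read_results",
]

#: marker code -> task name
TASK_CODES = {1: "list", 2: "sentence", 3: "word"}
#: task name -> marker code
TASK_NAMES = {name: code for code, name in TASK_CODES.items()}
#: canonical task order used in tables
TASKS = ("list", "sentence", "word")

#: minimum separation between trial markers (seconds)
MIN_MARKER_SEPARATION_S = 20.0


class FormatError(ValueError):
    """A file does not conform to the declared format."""


class ParseError(FormatError):
    """A data line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(ValueError):
    """Input values violate an invariant of the pipeline."""


class ProcessingError(RuntimeError):
    """A processing stage cannot proceed on otherwise valid input."""


def sec_to_index(t_s: float, rate: float) -> int:
    """Convert an epoch time in seconds to a sample index (round half-up)."""
    return int(math.floor(t_s * rate + 0.5))


@dataclass
class RawRecording:
    """Dual-channel CBFV recording with a trial-marker channel.

    Parameters
    ----------
    sample_rate : int
        Samples per second (native recordings are 100 Hz).
    left, right : ndarray
        CBFV in cm/s for the left / right middle cerebral artery.
    marker : ndarray of int
        0 everywhere except at stimulus-onset samples, where it holds the
        task code (1=list, 2=sentence, 3=word).
    """

    sample_rate: int
    left: np.ndarray
    right: np.ndarray
    marker: np.ndarray

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.marker = np.asarray(self.marker, dtype=int)
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValidationError(f"sample_rate must be a positive integer, got {self.sample_rate!r}")
        self.sample_rate = int(self.sample_rate)
        n = len(self.left)
        if n < 1 or len(self.right) != n or len(self.marker) != n:
            raise ValidationError(
                "left, right and marker must have identical length >= 1 "
                f"(got {len(self.left)}, {len(self.right)}, {len(self.marker)})"
            )
        if not (np.isfinite(self.left).all() and np.isfinite(self.right).all()):
            raise ValidationError("velocity channels contain non-finite values")
        codes = np.unique(self.marker)
        bad = [c for c in codes if c != 0 and c not in TASK_CODES]
        if bad:
            raise ValidationError(f"unknown marker code(s): {bad}")
        idx = self.marker_indices
        if len(idx) > 1:
            min_gap = MIN_MARKER_SEPARATION_S * self.sample_rate
            if np.diff(idx).min() < min_gap:
                raise ValidationError(
                    f"markers closer than {MIN_MARKER_SEPARATION_S} s at {self.sample_rate} Hz"
                )

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def marker_indices(self) -> np.ndarray:
        """Sample indices of the trial markers, in temporal order."""
        return np.flatnonzero(self.marker)

    def triggers(self) -> list[tuple[int, str]]:
        """``(sample_index, task_name)`` for each trial marker."""
        return [(int(i), TASK_CODES[int(self.marker[i])]) for i in self.marker_indices]


@dataclass
class PipelineConfig:
    """Timing windows and thresholds for the analysis pipeline.

    Defaults encode the study conventions: 100→25 Hz down-sampling, 30-s
    epochs starting 5 s before the trigger, a [0, 5) s resting baseline,
    a [7, 17) s period of interest (covert-generation phase), a 2-s
    LI window centred on the peak, 60/140 % artifact bounds on the
    normalised signal, and 0.0001/0.9999 spike quantiles.
    """

    downsample_factor: int = 4
    epoch_start_s: float = 5.0
    epoch_length_s: float = 30.0
    baseline_window_s: tuple[float, float] = (0.0, 5.0)
    poi_s: tuple[float, float] = (7.0, 17.0)
    peak_window_halfwidth_s: float = 1.0
    artifact_low_pct: float = 60.0
    artifact_high_pct: float = 140.0
    spike_quantile_low: float = 0.0001
    spike_quantile_high: float = 0.9999
    min_loss_run_s: float = 0.25
    predetermined_loa: tuple[float, float] = (-2.5, 2.5)
    ci_level: float = 0.95
    min_cycle_separation_s: float = 0.33
    bootstrap_n: int = 1999
    rng_seed: int = 0

    def __post_init__(self):
        self.baseline_window_s = tuple(float(v) for v in self.baseline_window_s)
        self.poi_s = tuple(float(v) for v in self.poi_s)
        self.predetermined_loa = tuple(float(v) for v in self.predetermined_loa)
        if self.downsample_factor < 1:
            raise ValidationError("downsample_factor must be >= 1")
        if self.epoch_length_s <= 0 or self.epoch_start_s < 0:
            raise ValidationError("epoch timing must be positive")
        for name in ("baseline_window_s", "poi_s", "predetermined_loa"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name}: require low < high, got ({lo}, {hi})")
        for name in ("baseline_window_s", "poi_s"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi > self.epoch_length_s:
                raise ValidationError(
                    f"{name} must lie within [0, {self.epoch_length_s}], got ({lo}, {hi})"
                )
        if not self.baseline_window_s[1] <= self.poi_s[0]:
            raise ValidationError("baseline window must precede the period of interest")
        for name in ("spike_quantile_low", "spike_quantile_high"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {q}")
        if not self.spike_quantile_low < self.spike_quantile_high:
            raise ValidationError("spike_quantile_low must be < spike_quantile_high")
        if not self.artifact_low_pct < self.artifact_high_pct:
            raise ValidationError("artifact_low_pct must be < artifact_high_pct")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must be in (0, 1)")
        if self.peak_window_halfwidth_s <= 0:
            raise ValidationError("peak_window_halfwidth_s must be positive")
        if self.min_cycle_separation_s <= 0:
            raise ValidationError("min_cycle_separation_s must be positive")
        if self.min_loss_run_s <= 0:
            raise ValidationError("min_loss_run_s must be positive")
        if self.bootstrap_n < 1:
            raise ValidationError("bootstrap_n must be >= 1")


CATEGORIES = ("left", "bilateral", "right")
METHODS = ("peak", "mean")

RESULTS_COLUMNS = [
    "participant_id",
    "task",
    "method",
    "n_trials_included",
    "li",
    "latency_s",
    "ci_low",
    "ci_high",
    "category",
    "split_half_odd",
    "split_half_even",
]


@dataclass
class ResultsRow:
    """One participant × task × method line of the results table."""

    participant_id: str
    task: str
    method: str
    n_trials_included: int
    li: float
    latency_s: float
    ci_low: float
    ci_high: float
    category: str
    split_half_odd: float = math.nan
    split_half_even: float = math.nan

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        tol = 1e-9 * max(1.0, abs(self.li))
        if not (self.ci_low <= self.li + tol and self.li <= self.ci_high + tol):
            raise ValidationError("require ci_low <= li <= ci_high")
        expected = "left" if self.ci_low > 0 else ("right" if self.ci_high < 0 else "bilateral")
        if self.category != expected:
            raise ValidationError(
                f"category {self.category!r} inconsistent with CI ({self.ci_low}, {self.ci_high})"
            )


# ---------------------------------------------------------------------------
# signal TSV


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording to the headered TSV interchange format.

    Velocities are written with 17 significant digits so that a read
    round-trips the float64 values bit-for-bit.
    """
    path = Path(path)
    tasks = ",".join(f"{c}={n}" for c, n in sorted(TASK_CODES.items()))
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {rec.sample_rate}\n")
        fh.write(f"# tasks: {tasks}\n")
        for l, r, m in zip(rec.left, rec.right, rec.marker):
            fh.write(f"{l:.17g}\t{r:.17g}\t{m:d}\n")


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording from the headered TSV interchange format.

    Raises
    ------
    FormatError
        Missing or garbled ``# sample_rate_hz`` header.
    ParseError
        A non-numeric or malformed data line (reported with line number).
    ValidationError
        Unknown marker codes or violated recording invariants.
    """
    path = Path(path)
    sample_rate = None
    left: list[float] = []
    right: list[float] = []
    marker: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("sample_rate_hz"):
                    try:
                        sample_rate = int(body.split(":", 1)[1].strip())
                    except (IndexError, ValueError) as exc:
                        raise FormatError(f"garbled sample_rate_hz header: {line!r}") from exc
                continue
            if sample_rate is None:
                raise FormatError("missing '# sample_rate_hz:' header before data")
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"expected 3 tab-separated columns, got {len(parts)}", lineno)
            try:
                left.append(float(parts[0]))
                right.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"non-numeric velocity value: {exc}", lineno) from None
            try:
                marker.append(int(parts[2]))
            except ValueError:
                raise ParseError(f"non-integer marker value {parts[2]!r}", lineno) from None
    if sample_rate is None:
        raise FormatError("missing '# sample_rate_hz:' header")
    if not left:
        raise FormatError("file contains no data rows")
    return RawRecording(sample_rate, np.array(left), np.array(right), np.array(marker, dtype=int))


# ---------------------------------------------------------------------------
# configuration JSON


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from JSON, applying defaults.

    Unknown keys are rejected so that typos in a configuration file fail
    loudly rather than silently falling back to a default.
    """
    with open(path) as fh:
        data = json.load(fh)
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    if not isinstance(data, dict):
        raise FormatError("configuration must be a JSON object")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown configuration key(s): {sorted(unknown)}")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# results CSV


def write_results(rows: Sequence[ResultsRow], path: str | Path) -> None:
    """Write validated results rows as CSV with a fixed column order.

    Floats are written at 6 significant digits; re-reading reproduces
    values to that precision.
    """
    records = [dataclasses.asdict(row) for row in rows]
    frame = pd.DataFrame.from_records(records, columns=RESULTS_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back into a DataFrame."""
    frame = pd.read_csv(path)
    missing = set(RESULTS_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"results file missing column(s): {sorted(missing)}")
    return frame
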