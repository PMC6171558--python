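"""End-to-end helpers tying preprocessing, laterality and comparison together.

These functions are the library-level workflow behind the command-line
interface: one participant's raw recording in, tidy result tables out.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math

import pandas as pd

from . import __version__
from .io_formats import PipelineConfig, RawRecording, ResultsRow
from .laterality import analyse_epochs
from .preprocess import preprocess_recording, qc_frame

__all__ = [
    "process_participant",
    "results_rows",
    "trial_li_frame",
    "wave_frame",
    "config_hash",
    "manifest",
]


def process_participant(rec: RawRecording, cfg: PipelineConfig) -> dict:
    """Preprocess one recording and analyse every task present.

    Returns ``{"epochs": [...], "analyses": {task: {...}}, "qc": frame}``.
    """
    epochs = preprocess_recording(rec, cfg)
    analyses = analyse_epochs(epochs, cfg)
    return {"epochs": epochs, "analyses": analyses, "qc": qc_frame(epochs)}


def results_rows(participant_id: str, analyses: dict) -> list[ResultsRow]:
    """Flatten per-task analyses into validated results rows.

    Split-half LIs (odd/even trials, peak procedure) are attached to the
    peak-method rows only.
    """
    rows = []
    for task in sorted(analyses):
        entry = analyses[task]
        odd, even = entry["split_half"]
        for method in ("peak", "mean"):
            res = entry[method]
            rows.append(
                ResultsRow(
                    participant_id=participant_id,
                    task=task,
                    method=method,
                    n_trials_included=res.n_trials,
                    li=res.li,
                    latency_s=res.latency_s,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    category=res.category,
                    split_half_odd=odd if method == "peak" else math.nan,
                    split_half_even=even if method == "peak" else math.nan,
                )
            )
    return rows


def trial_li_frame(participant_id: str, analyses: dict) -> pd.DataFrame:
    """Long per-trial LI table (participant, task, method, trial, li)."""
    records = []
    for task in sorted(analyses):
        for method in ("peak", "mean"):
            for j, li in enumerate(analyses[task][method].trial_lis):
                records.append(
                    {
                        "participant_id": participant_id,
                        "task": task,
                        "method": method,
                        "trial": j,
                        "li": float(li),
                    }
                )
    return pd.DataFrame.from_records(records)


def wave_frame(participant_id: str, analyses: dict) -> pd.DataFrame:
    """Long difference-wave table (participant, task, time_s, value)."""
    records = []
    for task in sorted(analyses):
        dw = analyses[task]["wave"]
        records.append(
            pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "task": task,
                    "time_s": dw.time_s,
                    "value": dw.values,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def config_hash(cfg) -> str:
    """Stable hash of a configuration dataclass for the run manifest."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def manifest(stage: str, cfg, inputs: list[str], outputs: list[str], counts: dict, seed=None) -> dict:
    """Reproducibility record written next to each stage's outputs."""
    return {
        "stage": stage,
        "package_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(p) for p in outputs),
        "counts": counts,
    }
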