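"""The patch-clamp diary: JSONL event log of attempts, and report generation."""

from __future__ import annotations

import csv
import json
import logging

import numpy as np

from .controller import PatchAttemptRecord

logger = logging.getLogger("autopatch.diary")


def diary_append(record: PatchAttemptRecord, path) -> None:
    """Append one attempt record as a JSON line."""
    with open(path, "a") as fh:
        fh.write(json.dumps(record.to_dict()) + "\n")


def read_diary(path):
    """Read attempt records back; corrupt lines are skipped with a warning.

    Returns ``(records, n_corrupt)``.
    """
    records, n_corrupt = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(PatchAttemptRecord.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                n_corrupt += 1
                logger.warning("skipping corrupt diary line %d: %s", lineno, exc)
    return records, n_corrupt


def _phase_durations(record: PatchAttemptRecord) -> dict:
    durations: dict = {}
    log = record.phase_log
    for row0, row1 in zip(log, log[1:]):
        t0, phase = row0[0], row0[1]
        t1 = row1[0]
        durations[phase] = durations.get(phase, 0.0) + (t1 - t0)
    return durations


def generate_report(diary_path, out_json_path, out_csv_path=None) -> dict:
    """Aggregate a diary into per-outcome counts and per-phase durations."""
    records, n_corrupt = read_diary(diary_path)
    outcomes: dict = {}
    rs_values = []
    phase_totals: dict = {}
    for rec in records:
        outcomes[rec.outcome.value] = outcomes.get(rec.outcome.value, 0) + 1
        if rec.Rs_Mohm is not None:
            rs_values.append(rec.Rs_Mohm)
        for phase, dur in _phase_durations(rec).items():
            phase_totals.setdefault(phase, []).append(dur)
    report = {
        "n_attempts": len(records),
        "n_corrupt_lines": n_corrupt,
        "outcomes": dict(sorted(outcomes.items())),
        "Rs_Mohm": {
            "n": len(rs_values),
            "mean": float(np.mean(rs_values)) if rs_values else None,
            "std": float(np.std(rs_values)) if rs_values else None,
        },
        "phase_duration_s_mean": {
            ph: float(np.mean(ds)) for ph, ds in sorted(phase_totals.items())
        },
    }
    with open(out_json_path, "w") as fh:
        json.dump(report, fh, indent=1)
    if out_csv_path is not None:
        with open(out_csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["outcome", "count"])
            for outcome, count in sorted(outcomes.items()):
                writer.writerow([outcome, count])
    return report
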