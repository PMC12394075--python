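"""Trace quality control: photobleach truncation and trace-count bookkeeping.

Photobleaching of either dye collapses one or both intensity channels; usable
dynamics end at that point.  Traces are truncated at the first *persistent*
violation of the intensity thresholds (single noisy frames are tolerated),
and the surviving trace count per condition feeds the missed-trace
correction factor c = n/n' used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import FretTrace

__all__ = ["QcThresholds", "QcResult", "trim_photobleach", "apply_qc",
           "count_ratio"]

#: traces shorter than this after trimming are excluded from kinetic analysis
MIN_KINETIC_FRAMES = 50


@dataclass(frozen=True)
class QcThresholds:
    """Intensity floors marking a photobleached frame (arbitrary units)."""

    acceptor_min: float = 5.0
    donor_min: float = 5.0
    total_min: float = 10.0


@dataclass
class QcResult:
    trace: FretTrace | None
    kept_frames: int
    rejected: bool
    reason: str = ""


def _first_persistent_violation(trace: FretTrace, thr: QcThresholds,
                                persistence: int) -> int | None:
    below = ((trace.acceptor < thr.acceptor_min)
             | (trace.donor < thr.donor_min)
             | (trace.donor + trace.acceptor < thr.total_min))
    if persistence <= 1:
        idx = np.flatnonzero(below)
        return int(idx[0]) if idx.size else None
    run = np.ones(persistence, dtype=int)
    hits = np.convolve(below.astype(int), run, mode="valid") == persistence
    idx = np.flatnonzero(hits)
    return int(idx[0]) if idx.size else None


def trim_photobleach(trace: FretTrace, thr: QcThresholds = QcThresholds(),
                     persistence: int = 3) -> QcResult:
    """Truncate a trace before its first persistent sub-threshold run.

    A frame violates QC when acceptor < acceptor_min OR donor < donor_min OR
    donor+acceptor < total_min; the trace is cut at the first frame starting a
    run of ``persistence`` consecutive violations.  A trace that is below
    threshold from frame 0 is rejected outright.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    cut = _first_persistent_violation(trace, thr, persistence)
    if cut is None:
        return QcResult(trace, len(trace), False)
    if cut == 0:
        return QcResult(None, 0, True, "rejected: below thresholds from start")
    trimmed = FretTrace(trace.frame_period, trace.donor[:cut],
                        trace.acceptor[:cut], meta=dict(trace.meta))
    return QcResult(trimmed, cut, False, "trimmed at photobleach")


def apply_qc(traces, thr: QcThresholds = QcThresholds(), persistence: int = 3,
             min_frames: int = MIN_KINETIC_FRAMES):
    """QC a trace set; return kept traces and a per-trace manifest table."""
    kept, rows = [], []
    for i, trace in enumerate(traces):
        res = trim_photobleach(trace, thr, persistence)
        reason = res.reason
        ok = not res.rejected and res.kept_frames >= min_frames
        if not res.rejected and res.kept_frames < min_frames:
            reason = f"rejected: shorter than {min_frames} frames after trim"
        if ok:
            kept.append(res.trace)
        rows.append({"trace_id": trace.meta.get("trace_id", str(i)),
                     "condition": trace.meta.get("condition", ""),
                     "kept_frames": res.kept_frames,
                     "accepted": ok,
                     "rejected_reason": "" if ok else (reason or "rejected")})
    return kept, pd.DataFrame(rows)


def count_ratio(n_condition: int, n_reference: int) -> float:
    """Missed-trace correction factor c = n/n'.

    ``n_condition`` is the number of traces passing selection in the condition
    of interest and ``n_reference`` the count under the saturating-ligand
    reference, assumed free of excluded traces.  Values above 1 are kept but
    warned about (they indicate the reference assumption is violated).
    """
    if n_reference <= 0:
        raise ValueError("reference trace count must be positive")
    c = n_condition / n_reference
    if c > 1.0:
        warnings.warn(f"count ratio c={c:.3f} exceeds 1; reference condition "
                      "may itself be missing traces", stacklevel=2)
    return c
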