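"""Multi-annotator gold-standard fusion and reaction-lag compensation.

Time-continuous affect ratings from several annotators disagree in offset,
scale and timing.  The fusion used here weights each annotator by how well
they agree with the others (mean pairwise Pearson correlation, floored at
zero), removes each annotator's own mean before averaging, and restores
the weighted grand mean so that unanimous annotators are reproduced
exactly.  A systematic annotator reaction lag — the delay between the
expressed emotion and the recorded rating — is estimated by maximising the
CCC between the back-shifted gold standard and a reference prediction,
segment by segment, and the mean lag is applied to the whole trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import ccc_value
from .traces import Trace

__all__ = ["AnnotationSet", "GoldStandard", "annotator_weights",
           "fuse_annotations", "estimate_reaction_lag", "apply_lag"]


@dataclass
class AnnotationSet:
    """K >= 2 annotator traces of one affect dimension on a common grid."""

    dimension: str  # "arousal" or "valence"
    traces: list[Trace]
    annotator_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.dimension not in ("arousal", "valence"):
            raise ValueError("dimension must be 'arousal' or 'valence'")
        if len(self.traces) < 2:
            raise ValueError("need at least two annotators")
        ref = self.traces[0]
        for tr in self.traces[1:]:
            if not ref.same_grid(tr):
                raise ValueError("annotator traces must share one grid")
        if self.annotator_ids is None:
            self.annotator_ids = [f"annotator_{k + 1}"
                                  for k in range(len(self.traces))]
        if len(self.annotator_ids) != len(self.traces):
            raise ValueError("one id per annotator trace")

    def __len__(self) -> int:
        return len(self.traces)

    def to_csv(self, path) -> None:
        data = {"time": self.traces[0].times}
        for aid, tr in zip(self.annotator_ids, self.traces):
            vals = tr.values.copy()
            vals[~tr.valid_mask] = np.nan
            data[aid] = vals
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dimension: str) -> "AnnotationSet":
        from .traces import _infer_period
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValueError("annotation CSV needs a 'time' column")
        t = df["time"].to_numpy(dtype=float)
        period = _infer_period(t)
        ids = [c for c in df.columns if c != "time"]
        traces = [Trace(period, df[c].to_numpy(dtype=float),
                        start_time=float(t[0])) for c in ids]
        return cls(dimension=dimension, traces=traces, annotator_ids=ids)


@dataclass
class GoldStandard:
    dimension: str
    trace: Trace
    weights: np.ndarray
    lag: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.lag < 0:
            raise ValueError("lag must be non-negative")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return np.nan
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0  # constant annotator carries no agreement information
    return float(np.corrcoef(x, y)[0, 1])


def annotator_weights(ann: AnnotationSet) -> np.ndarray:
    """Per-annotator weights: mean pairwise Pearson r, floored at 0, normalised.

    Raises
    ------
    ValueError
        If every annotator's floored weight is zero (irreconcilable set).
    """
    k = len(ann)
    joint = np.logical_and.reduce([tr.valid_mask for tr in ann.traces])
    vals = [tr.values[joint] for tr in ann.traces]
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = _pearson(vals[i], vals[j])
            corr[i, j] = corr[j, i] = 0.0 if np.isnan(r) else r
    raw = corr.sum(axis=1) / (k - 1)
    floored = np.maximum(raw, 0.0)
    total = floored.sum()
    if total <= 0.0:
        raise ValueError(
            "annotators are irreconcilable: no positive average agreement")
    return floored / total


def fuse_annotations(ann: AnnotationSet,
                     grand_mean: str = "restore") -> GoldStandard:
    """Fuse annotator traces into a single gold-standard trace.

    Each trace is centred on its own mean, the centred traces are combined
    with the normalised agreement weights, and (with ``grand_mean=
    'restore'``, the default) the weighted grand mean ``sum_k w_k mu_k``
    is added back, making unanimous annotators a fixed point.  With
    ``grand_mean='drop'`` the fused trace stays zero-mean.
    """
    if grand_mean not in ("restore", "drop"):
        raise ValueError("grand_mean must be 'restore' or 'drop'")
    w = annotator_weights(ann)
    ref = ann.traces[0]
    n = len(ref)

    mus = np.array([tr.values[tr.valid_mask].mean() for tr in ann.traces])
    num = np.zeros(n)
    den = np.zeros(n)
    for wk, mu, tr in zip(w, mus, ann.traces):
        m = tr.valid_mask
        num[m] += wk * (tr.values[m] - mu)
        den[m] += wk
    valid = den > 0
    fused = np.zeros(n)
    fused[valid] = num[valid] / den[valid]
    if grand_mean == "restore":
        fused[valid] += float(np.dot(w, mus))
    trace = Trace(ref.frame_period, fused, valid_mask=valid,
                  start_time=ref.start_time)
    return GoldStandard(dimension=ann.dimension, trace=trace, weights=w)


def apply_lag(trace: Trace, lag: float) -> Trace:
    """Shift a trace earlier by ``lag`` seconds (grid-quantised).

    ``out[t] = trace[t + lag]``; the trailing samples that fall off the end
    are marked invalid.  Compensates the annotator reaction delay.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    shift = int(round(lag / trace.frame_period))
    n = len(trace)
    if shift >= n:
        raise ValueError("lag exceeds the trace duration")
    if shift == 0:
        return trace.copy()
    values = np.empty(n)
    mask = np.zeros(n, dtype=bool)
    values[: n - shift] = trace.values[shift:]
    mask[: n - shift] = trace.valid_mask[shift:]
    values[n - shift:] = 0.0
    return Trace(trace.frame_period, values, valid_mask=mask,
                 start_time=trace.start_time)


def estimate_reaction_lag(gold: Trace, reference: Trace, max_lag: float,
                          segments: list[tuple[int, int]]) -> float:
    """Average annotator reaction lag over signal segments.

    For each ``(start, stop)`` frame range the lag in ``[0, max_lag]``
    (stepped by one frame) that maximises the CCC between the gold trace
    shifted *earlier* by that lag and the reference prediction is located;
    the returned value is the arithmetic mean over segments, so one lag
    serves the whole output range.  Segments shorter than ``2 * max_lag``
    are skipped; if all are skipped the lag is 0 and a warning is issued.
    """
    if not gold.same_grid(reference):
        raise ValueError("gold and reference must share one grid")
    dt = gold.frame_period
    max_shift = int(round(max_lag / dt))
    if max_lag >= gold.duration / 4:
        raise ValueError("max_lag must be below a quarter of the duration")

    per_segment = []
    for start, stop in segments:
        if stop - start < 2 * max_shift or stop - start < 2:
            continue
        best_lag, best_ccc = 0.0, -np.inf
        for shift in range(0, max_shift + 1):
            hi = min(stop, len(gold) - shift)
            if hi - start < 2:
                break
            g = gold.values[start + shift: hi + shift]
            gm = gold.valid_mask[start + shift: hi + shift]
            r = reference.values[start: hi]
            rm = reference.valid_mask[start: hi]
            joint = gm & rm
            if joint.sum() < 2:
                continue
            c = ccc_value(g[joint], r[joint])
            if not np.isnan(c) and c > best_ccc:
                best_ccc, best_lag = c, shift * dt
        if np.isfinite(best_ccc):
            per_segment.append(best_lag)
    if not per_segment:
        warnings.warn("no segment long enough for lag estimation; using 0 s",
                      stacklevel=2)
        return 0.0
    return float(np.mean(per_segment))
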