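"""Concordance Correlation Coefficient (CCC) and windowed agreement.

Lin's concordance coefficient between two series ``y1`` and ``y2`` is

    CCC = 2 * rho * s1 * s2 / (s1**2 + s2**2 + (m1 - m2)**2)

with means ``m1, m2``, standard deviations ``s1, s2`` and Pearson
correlation ``rho``.  Unlike plain correlation it penalises mean and scale
bias, so a shifted or rescaled copy of a signal scores below 1.  All
moments here use the population convention (divide by n).

Degenerate inputs are resolved so that a flat trace never spuriously
agrees with a moving one: two constant traces with equal means score 1,
any other constant case scores 0, and fewer than two jointly valid
samples yields NaN (the undefined sentinel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import Trace

__all__ = ["ConcordanceResult", "concordance_correlation", "ccc_value",
           "windowed_pairwise_concordance"]


@dataclass(frozen=True)
class ConcordanceResult:
    """CCC value (NaN when undefined) and the joint-sample count behind it."""

    ccc: float
    n_overlap: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.ccc)


def ccc_value(x, y) -> float:
    """CCC of two plain arrays of equal length (no masking).

    Returns NaN for fewer than 2 samples; applies the constant-trace
    conventions described in the module docstring.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sequences must share length")
    n = x.size
    if n < 2:
        return float("nan")
    mx = x.mean()
    my = y.mean()
    vx = x.var()
    vy = y.var()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        # both constant with equal means
        return 1.0
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = np.dot(x - mx, y - my) / n
    return float(2.0 * cov / denom)


def _joint_valid(a: Trace, b: Trace) -> np.ndarray:
    if abs(a.frame_period - b.frame_period) > 1e-9:
        raise ValueError("traces must share the frame period")
    if abs(a.start_time - b.start_time) > 1e-9 or len(a) != len(b):
        raise ValueError("traces must be aligned on a common grid")
    return a.valid_mask & b.valid_mask


def concordance_correlation(a: Trace, b: Trace) -> ConcordanceResult:
    """CCC between two aligned traces over their jointly valid samples."""
    joint = _joint_valid(a, b)
    n = int(joint.sum())
    if n < 2:
        return ConcordanceResult(float("nan"), n)
    return ConcordanceResult(ccc_value(a.values[joint], b.values[joint]), n)


def windowed_pairwise_concordance(ensemble: list[Trace], t_end: float,
                                  width: float) -> list[float]:
    """Average pairwise CCC of each ensemble member over a trailing window.

    The window is the right-aligned half-open interval ``(t_end - width,
    t_end]`` on the shared trace grid.  For every member the mean of its
    pairwise CCC with each other member is returned; pairs whose CCC is
    undefined are skipped in the mean, and a member whose pairings are all
    undefined receives NaN.

    Raises
    ------
    ValueError
        If fewer than two traces are supplied.
    """
    m = len(ensemble)
    if m < 2:
        raise ValueError("need at least two predictions to measure consensus")
    ref = ensemble[0]
    for tr in ensemble[1:]:
        if not ref.same_grid(tr):
            raise ValueError("ensemble traces must share one grid")
    t = ref.times
    in_win = (t > t_end - width + 1e-9) & (t <= t_end + 1e-9)
    idx = np.flatnonzero(in_win)

    sums = np.zeros(m)
    counts = np.zeros(m, dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            ai, aj = ensemble[i], ensemble[j]
            joint = ai.valid_mask[idx] & aj.valid_mask[idx]
            if joint.sum() < 2:
                continue
            c = ccc_value(ai.values[idx][joint], aj.values[idx][joint])
            if np.isnan(c):
                continue
            sums[i] += c
            sums[j] += c
            counts[i] += 1
            counts[j] += 1

    out = np.full(m, np.nan)
    has = counts > 0
    out[has] = sums[has] / counts[has]
    return out.tolist()
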