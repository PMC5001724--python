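"""Dynamic, adaptive consensus over an ensemble of per-speaker predictors.

At every time instant the cooperative rule

1. windows the ensemble predictions over a set of trailing widths
   (1 s … 8 s by default);
2. computes each member's average pairwise concordance (CCC) with the
   others inside each window;
3. splits the members at the adaptive threshold that maximises the mean
   concordance of the retained group minus the mean of the rest;
4. picks the window width whose retained group has the highest average
   CCC (ties resolved toward the smallest width);
5. fits one least-squares line to the pooled samples of the retained
   predictions over the most recent fit interval and extrapolates it one
   frame ahead.

If the best retained average CCC is negative, no prediction is produced
and the machine label at that instant is missing.  A machine-labeled
sequence is only trusted when the fraction of non-missing samples reaches
the sufficiency fraction.

The public scalar operations (:func:`split_by_threshold`,
:func:`optimal_window`, :func:`extrapolate`) define the semantics one
time step at a time; :func:`cooperative_predict` runs the identical chain
vectorised over the whole sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .metrics import ccc_value, windowed_pairwise_concordance
from .traces import FeatureMatrix, Trace

__all__ = ["ConsensusConfig", "ConsensusDiagnostics", "split_by_threshold",
           "optimal_window", "extrapolate", "consensus_predict",
           "cooperative_predict", "sufficiency_check", "NO_WINDOW"]

#: sentinel returned by :func:`optimal_window` when every width fails
NO_WINDOW = None


@dataclass
class ConsensusConfig:
    """Parameters of the cooperative aggregation rule.

    window_widths
        Trailing window widths in seconds, sorted ascending (default the
        1 s … 8 s grid with a 1 s step).
    fit_interval
        Length of the linear-fit interval used for the one-frame-ahead
        extrapolation; must not exceed the smallest window width.
    min_ensemble
        Minimum number of predictors required to form a consensus.
    sufficiency_fraction
        Minimum fraction of non-missing machine-label samples for the
        sequence to count as reliably labeled.
    redex_threshold
        Whole-sequence CCC above which a candidate model is considered
        redundant with a pool member (strict inequality excludes).
    min_retained
        Minimum size of the retained (concordant) group.
    """

    window_widths: tuple = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    fit_interval: float = 1.0
    min_ensemble: int = 2
    sufficiency_fraction: float = 0.5
    redex_threshold: float = 0.99
    min_retained: int = 1

    def __post_init__(self) -> None:
        widths = tuple(float(w) for w in self.window_widths)
        if not widths or any(w <= 0 for w in widths):
            raise ValueError("window widths must be positive")
        if list(widths) != sorted(widths):
            raise ValueError("window widths must be sorted ascending")
        self.window_widths = widths
        if self.fit_interval > min(widths) + 1e-12:
            raise ValueError("fit_interval must not exceed the smallest width")
        if not 0 < self.sufficiency_fraction <= 1:
            raise ValueError("sufficiency_fraction must lie in (0, 1]")


@dataclass
class ConsensusDiagnostics:
    """Per-time-step record of the consensus chain.

    Arrays are aligned with the output trace; entries are NaN / all-False
    where no prediction was produced.
    """

    times: np.ndarray
    width: np.ndarray
    threshold: np.ndarray
    retained: np.ndarray  # (n_members, n_steps) bool
    avg_ccc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "width": self.width,
                           "threshold": self.threshold,
                           "avg_ccc": self.avg_ccc})
        for m in range(self.retained.shape[0]):
            df[f"retained_{m}"] = self.retained[m]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scalar reference operations
# ---------------------------------------------------------------------------

def split_by_threshold(avg_cccs) -> tuple[float, np.ndarray, float]:
    """Adaptive threshold split of member-average concordances.

    Candidate thresholds are the midpoints between consecutive sorted
    distinct values.  The selected split maximises ``mean(above) -
    mean(below)`` with both sides non-empty; returned are the threshold,
    the above-threshold index set and the retained-side mean (the average
    CCC of the concordant responses).  If all defined entries are equal,
    everything is retained with objective 0 and a NaN threshold.  NaN
    entries (undefined concordance) are never retained.
    """
    a = np.asarray(avg_cccs, dtype=float)
    defined = np.flatnonzero(~np.isnan(a))
    if defined.size < 2:
        raise ValueError("need at least two defined average concordances")
    vals = a[defined]
    order = np.argsort(vals, kind="stable")
    s = vals[order]
    m = s.size
    best_obj, best_k = -np.inf, None
    prefix = np.cumsum(s)
    for k in range(1, m):
        if not s[k] > s[k - 1]:
            continue  # equal values cannot be separated by a threshold
        obj = (prefix[-1] - prefix[k - 1]) / (m - k) - prefix[k - 1] / k
        if obj > best_obj:
            best_obj, best_k = obj, k
    if best_k is None:  # all values equal
        return float("nan"), defined.copy(), 0.0
    thr = 0.5 * (s[best_k - 1] + s[best_k])
    retained = defined[vals > thr]
    return float(thr), retained, float(best_obj)


def retained_mean(avg_cccs, retained: np.ndarray) -> float:
    a = np.asarray(avg_cccs, dtype=float)
    return float(np.mean(a[retained]))


def optimal_window(ensemble: list[Trace], t_end: float,
                   config: ConsensusConfig):
    """Step-4 width selection at one time instant.

    Returns ``(width, retained index set, retained average CCC)`` for the
    width whose concordant group scores highest, or :data:`NO_WINDOW` when
    no width yields a defined split.  A width is admissible only when it
    fits entirely inside the observed past.
    """
    if len(ensemble) < config.min_ensemble:
        raise ValueError("ensemble smaller than the configured minimum")
    start = ensemble[0].start_time
    dt = ensemble[0].frame_period
    best = None
    for width in config.window_widths:
        # admissible only when the window holds its full complement of samples
        if t_end - width < start - dt - 1e-9:
            continue
        avgs = windowed_pairwise_concordance(ensemble, t_end, width)
        try:
            _, retained, _ = split_by_threshold(avgs)
        except ValueError:
            continue
        if retained.size < config.min_retained:
            continue
        score = retained_mean(avgs, retained)
        if best is None or score > best[2] + 1e-15:
            best = (width, retained, score)
    return NO_WINDOW if best is None else best


def extrapolate(retained: list[Trace], t_n: float, fit_interval: float) -> float:
    """OLS line through the pooled retained samples, evaluated one frame on.

    All retained traces contribute their samples in ``(t_n - fit_interval,
    t_n]`` to a single least-squares line, which is evaluated at
    ``t_n + frame_period``.  With fewer than two pooled samples (or a
    degenerate time spread) the mean of the pooled values is returned.
    """
    if not retained:
        raise ValueError("retained set must be non-empty")
    dt = retained[0].frame_period
    xs, ys = [], []
    for tr in retained:
        t = tr.times
        sel = (t > t_n - fit_interval + 1e-9) & (t <= t_n + 1e-9) & tr.valid_mask
        xs.append(t[sel])
        ys.append(tr.values[sel])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size == 0:
        raise ValueError("no valid samples inside the fit interval")
    if x.size < 2 or np.ptp(x) == 0.0:
        return float(y.mean())
    slope, icept = np.polyfit(x, y, 1)
    return float(slope * (t_n + dt) + icept)


def sufficiency_check(machine_label: Trace, config: ConsensusConfig) -> bool:
    """True when enough machine-label samples are valid to trust the label."""
    return machine_label.valid_fraction >= config.sufficiency_fraction


# ---------------------------------------------------------------------------
# vectorised whole-sequence chain
# ---------------------------------------------------------------------------

def _pairwise_windowed_ccc(V: np.ndarray, w: int) -> np.ndarray:
    """CCC over the trailing w-frame window for every member pair and end index.

    ``V`` is (M, T) with fully valid members.  Returns (P, T).
    """
    M, T = V.shape
    c1 = np.concatenate([np.zeros((M, 1)), np.cumsum(V, axis=1)], axis=1)
    c2 = np.concatenate([np.zeros((M, 1)), np.cumsum(V * V, axis=1)], axis=1)
    S1 = c1[:, w:] - c1[:, :-w]          # (M, T-w+1) sums
    S2 = c2[:, w:] - c2[:, :-w]
    mean = S1 / w
    var = S2 / w - mean ** 2
    np.clip(var, 0.0, None, out=var)

    pairs = list(combinations(range(M), 2))
    P = len(pairs)
    out = np.full((P, T), np.nan)
    for p, (i, j) in enumerate(pairs):
        prod = V[i] * V[j]
        cx = np.concatenate([[0.0], np.cumsum(prod)])
        Sxy = cx[w:] - cx[:-w]
        cov = Sxy / w - mean[i] * mean[j]
        dmu2 = (mean[i] - mean[j]) ** 2
        denom = var[i] + var[j] + dmu2
        ccc = np.zeros(denom.size)
        ok = denom > 0
        ccc[ok] = 2.0 * cov[ok] / denom[ok]
        # both windows constant with equal means -> perfect agreement
        ccc[~ok] = 1.0
        # one window constant (but not the equal-mean double-constant case)
        single_const = ((var[i] == 0) ^ (var[j] == 0)) | \
                       (((var[i] == 0) & (var[j] == 0)) & (dmu2 > 0))
        ccc[single_const] = 0.0
        out[p, w - 1:] = ccc
    return out


def _member_averages(pair_ccc: np.ndarray, M: int) -> np.ndarray:
    """Mean pairwise CCC per member, NaN-pair-skipping; (M, T)."""
    T = pair_ccc.shape[1]
    sums = np.zeros((M, T))
    counts = np.zeros((M, T))
    for p, (i, j) in enumerate(combinations(range(M), 2)):
        row = pair_ccc[p]
        ok = ~np.isnan(row)
        val = np.where(ok, row, 0.0)
        sums[i] += val
        sums[j] += val
        counts[i] += ok
        counts[j] += ok
    out = np.full((M, T), np.nan)
    has = counts > 0
    out[has] = sums[has] / counts[has]
    return out


def _split_columns(A: np.ndarray):
    """Vectorised adaptive-threshold split, one column per time step.

    Returns (retained_mask (M,T), retained_mean (T,), threshold (T,)).
    Columns containing NaN are left unretained.
    """
    M, T = A.shape
    col_ok = ~np.isnan(A).any(axis=0)
    S = np.sort(A, axis=0)
    P = np.cumsum(S, axis=0)
    total = P[-1]
    best_obj = np.full(T, -np.inf)
    best_k = np.zeros(T, dtype=int)  # 0 = no admissible split
    for k in range(1, M):
        admissible = col_ok & (S[k] > S[k - 1])
        obj = np.where(admissible,
                       (total - P[k - 1]) / (M - k) - P[k - 1] / k, -np.inf)
        better = obj > best_obj
        best_obj[better] = obj[better]
        best_k[better] = k
    has_split = best_k > 0
    thr = np.full(T, np.nan)
    rmean = np.full(T, np.nan)
    retained = np.zeros((M, T), dtype=bool)

    idx = np.flatnonzero(has_split)
    if idx.size:
        kk = best_k[idx]
        lo = S[kk - 1, idx]
        hi = S[kk, idx]
        thr[idx] = 0.5 * (lo + hi)
        rmean[idx] = (total[idx] - P[kk - 1, idx]) / (M - kk)
        retained[:, idx] = A[:, idx] > thr[idx]
    # all-equal columns: retain everyone, objective 0
    flat = col_ok & ~has_split
    if flat.any():
        retained[:, flat] = True
        rmean[flat] = A[0, flat]
    return retained, rmean, thr


def consensus_predict(ensemble: list[Trace], config: ConsensusConfig | None = None
                      ) -> tuple[Trace, ConsensusDiagnostics]:
    """Run the five-step cooperative rule over a whole sequence.

    All ensemble traces must be fully valid and share one grid (model
    predictions always are).  Equivalent to applying the scalar chain
    (:func:`optimal_window` then :func:`extrapolate`) at every frame.
    """
    config = config or ConsensusConfig()
    M = len(ensemble)
    if M < config.min_ensemble:
        raise ValueError("ensemble smaller than the configured minimum")
    ref = ensemble[0]
    for tr in ensemble[1:]:
        if not ref.same_grid(tr):
            raise ValueError("ensemble traces must share one grid")
        if not tr.valid_mask.all():
            raise ValueError("consensus expects fully valid predictions")
    if not ref.valid_mask.all():
        raise ValueError("consensus expects fully valid predictions")

    V = np.vstack([tr.values for tr in ensemble])
    T = len(ref)
    dt = ref.frame_period
    t = ref.times

    widths = list(config.window_widths)
    n_w = len(widths)
    rmean_w = np.full((n_w, T), np.nan)
    thr_w = np.full((n_w, T), np.nan)
    ret_w = np.zeros((n_w, M, T), dtype=bool)
    for wi, width in enumerate(widths):
        w = int(round(width / dt))
        if w < 2 or w > T:
            continue
        pair_ccc = _pairwise_windowed_ccc(V, w)
        A = _member_averages(pair_ccc, M)
        retained, rmean, thr = _split_columns(A)
        if config.min_retained > 1:
            # widths whose concordant group is too small yield no consensus
            too_small = retained.sum(axis=0) < config.min_retained
            rmean[too_small] = np.nan
            retained[:, too_small] = False
        ret_w[wi] = retained
        rmean_w[wi] = rmean
        thr_w[wi] = thr

    # step 4: width with maximal retained average; ties -> smallest width
    score = np.where(np.isnan(rmean_w), -np.inf, rmean_w)
    best_wi = np.argmax(score, axis=0)  # first (= smallest) width on ties
    cols = np.arange(T)
    best_rmean = rmean_w[best_wi, cols]
    any_defined = np.isfinite(score).any(axis=0)
    # negative optimal concordance -> missing output
    produce = any_defined & (best_rmean >= 0)

    chosen_width = np.where(any_defined,
                            np.asarray(widths)[best_wi], np.nan)
    chosen_thr = thr_w[best_wi, cols]
    chosen_ret = ret_w[best_wi, :, cols].T  # (M, T)
    chosen_ret[:, ~produce] = False

    # step 5: pooled linear fit over the trailing fit interval
    fw = max(1, int(round(config.fit_interval / dt)))
    c_y = np.concatenate([np.zeros((M, 1)), np.cumsum(V, axis=1)], axis=1)
    c_ty = np.concatenate([np.zeros((M, 1)), np.cumsum(V * t, axis=1)], axis=1)
    Sy = c_y[:, fw:] - c_y[:, :-fw]        # (M, T-fw+1), ends at index i
    Sty = c_ty[:, fw:] - c_ty[:, :-fw]
    # times relative to the window end t_i
    rel = -dt * np.arange(fw - 1, -1, -1)
    Tx = rel.sum()
    Txx = float(np.dot(rel, rel))
    denom_geom = fw * Txx - Tx * Tx        # fw^2 * var(rel times)

    values = np.zeros(T)
    valid = np.zeros(T, dtype=bool)
    diag_t = t
    out_idx = np.flatnonzero(produce)
    # prediction lands one frame after the window end
    out_idx = out_idx[(out_idx >= fw - 1) & (out_idx + 1 < T)]
    if out_idx.size:
        R = chosen_ret[:, out_idx]             # (M, n)
        nR = R.sum(axis=0)
        si = out_idx - (fw - 1)
        sy = (R * Sy[:, si]).sum(axis=0)
        sty = (R * Sty[:, si]).sum(axis=0)
        # shift absolute times to window-end-relative ones
        sty_rel = sty - t[out_idx] * sy
        mean_y = sy / (nR * fw)
        if denom_geom > 0:
            slope = (fw * sty_rel - Tx * sy) / (nR * denom_geom)
        else:
            slope = np.zeros(out_idx.size)
        pred = mean_y + slope * (dt - Tx / fw)
        values[out_idx + 1] = pred
        valid[out_idx + 1] = True

    label = Trace(dt, values, valid_mask=valid, start_time=ref.start_time)
    diags = ConsensusDiagnostics(times=diag_t, width=chosen_width,
                                 threshold=chosen_thr, retained=chosen_ret,
                                 avg_ccc=np.where(any_defined, best_rmean,
                                                  np.nan))
    return label, diags


def cooperative_predict(pool_models, X: FeatureMatrix,
                        config: ConsensusConfig | None = None
                        ) -> tuple[Trace, ConsensusDiagnostics]:
    """Predict a machine label for one sequence from an SSRM ensemble."""
    config = config or ConsensusConfig()
    if len(pool_models) < config.min_ensemble:
        raise ValueError("fewer models than the configured minimum ensemble")
    preds = [m.predict(X) for m in pool_models]
    return consensus_predict(preds, config)
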