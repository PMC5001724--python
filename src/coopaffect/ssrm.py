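"""Single Speaker Regression Models (SSRMs).

One SSRM maps a speaker's frame-level acoustic descriptors to one affect
dimension (arousal or valence).  Training follows a fixed pipeline:

1. fuse the annotator traces into a gold standard (skipped when training
   from machine labels);
2. split the gold standard into positive/negative sign segments — the
   quadrant decomposition of the circumplex affect plane;
3. per sign-segment set, greedy correlation-based feature selection (CFS),
   selections concatenated and de-duplicated;
4. estimate the annotators' reaction lag against a preliminary ridge
   prediction and shift the gold standard back by the mean lag;
5. z-score the selected descriptors and fit a latent-projection linear
   regression (partial least squares), the number of latent components
   chosen by blocked cross-validation maximising the CCC.

The fitted model is a plain affine map ``y = X_std @ w + b`` and therefore
fully deterministic at prediction time.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Ridge

from .gold_standard import (AnnotationSet, GoldStandard, apply_lag,
                            estimate_reaction_lag, fuse_annotations)
from .metrics import ccc_value
from .traces import FeatureMatrix, Trace

__all__ = ["SSRMConfig", "SSRM", "QuadrantSegments", "segment_by_sign",
           "select_features", "train_ssrm", "train_ssrm_from_gold",
           "SingleSpeakerModel", "SingleSpeakerResults"]


@dataclass
class SSRMConfig:
    """Tunable knobs of the SSRM training pipeline.

    max_features
        Cap on the CFS forward search per sign-segment set.
    max_lag
        Upper bound of the reaction-lag grid search, seconds.  Clamped to
        just under a quarter of the sequence duration on short inputs.
    ridge_alpha
        Penalty of the preliminary all-feature ridge prediction used as
        the lag-estimation reference.
    min_segment_frames
        Below this frame count a sign-segment set falls back to the full
        valid range for feature selection.
    """

    max_features: int = 40
    max_lag: float = 4.0
    ridge_alpha: float = 1.0
    cv_folds: int = 5
    max_components: int = 10
    min_segment_frames: int = 10
    grand_mean: str = "restore"


@dataclass
class QuadrantSegments:
    """Maximal runs of valid frames with gold >= 0 (positive) and < 0."""

    positive: list[tuple[int, int]]
    negative: list[tuple[int, int]]

    @property
    def all_segments(self) -> list[tuple[int, int]]:
        return sorted(self.positive + self.negative)

    def frames(self, side: str) -> np.ndarray:
        segs = self.positive if side == "positive" else self.negative
        if not segs:
            return np.array([], dtype=int)
        return np.concatenate([np.arange(s, e) for s, e in segs])


def segment_by_sign(gold: Trace) -> QuadrantSegments:
    """Partition valid frames into sign segments (zeros count as positive)."""
    if not gold.valid_mask.any():
        raise ValueError("gold standard has no valid frame")
    # label: 1 positive, -1 negative, 0 invalid (breaks runs)
    label = np.where(gold.valid_mask, np.where(gold.values >= 0, 1, -1), 0)
    pos, neg = [], []
    start = 0
    for i in range(1, len(label) + 1):
        if i == len(label) or label[i] != label[start]:
            if label[start] == 1:
                pos.append((start, i))
            elif label[start] == -1:
                neg.append((start, i))
            start = i
    return QuadrantSegments(positive=pos, negative=neg)


# ---------------------------------------------------------------------------
# correlation-based feature selection (CFS)
# ---------------------------------------------------------------------------

def _cfs_search(X: np.ndarray, y: np.ndarray, max_features: int,
                patience: int = 5) -> list[int]:
    """Greedy forward search maximising the CFS merit.

    merit(S) = k * mean|r_fy| / sqrt(k + k(k-1) * mean|r_ff|)

    Zero-variance features are skipped.  In the spirit of best-first CFS,
    the chain keeps growing through up to ``patience`` consecutive
    non-improving additions and the best-merit prefix is returned; the
    search also stops at ``max_features``.
    """
    n, p = X.shape
    sd = X.std(axis=0)
    sy = y.std()
    if sy == 0.0:
        raise ValueError("gold standard is constant on the selection frames")
    usable = sd > 0
    if not usable.any():
        raise ValueError("no feature has a defined correlation with the gold")

    Xc = (X - X.mean(axis=0)) / np.where(usable, sd, 1.0)
    yc = (y - y.mean()) / sy
    r_fy = np.abs(Xc.T @ yc) / n
    r_fy[~usable] = -np.inf
    absR = np.abs((Xc.T @ Xc) / n)

    chain: list[int] = []
    in_set = np.zeros(p, dtype=bool)
    sum_fy = 0.0       # sum of |r_fy| over S
    pair_total = 0.0   # sum of |r_ff| over all pairs inside S
    cross = np.zeros(p)  # sum of |r| between each candidate and the set S
    best_merit = -np.inf
    best_len = 0
    stall = 0
    while len(chain) < max_features:
        k = len(chain) + 1
        cand_fy = sum_fy + r_fy
        if k == 1:
            merits = cand_fy  # sqrt(1 + 0) = 1
        else:
            rbar_ff = (pair_total + cross) / (k * (k - 1) / 2.0)
            merits = cand_fy / np.sqrt(k + k * (k - 1) * rbar_ff)
        merits = np.where(in_set | ~usable, -np.inf, merits)
        f = int(np.argmax(merits))
        if not np.isfinite(merits[f]):
            break
        chain.append(f)
        in_set[f] = True
        sum_fy += r_fy[f]
        pair_total += cross[f]
        cross = cross + absR[f]
        if merits[f] > best_merit:
            best_merit = float(merits[f])
            best_len = len(chain)
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    if best_len == 0:
        raise ValueError("feature selection found no informative feature")
    return chain[:best_len]


def select_features(X: FeatureMatrix, gold: Trace, segs: QuadrantSegments,
                    max_features: int = 40,
                    min_segment_frames: int = 10) -> list[int]:
    """Quadrant-wise CFS: select per sign-segment set, concatenate, dedupe.

    A side whose segment set holds fewer than ``min_segment_frames`` valid
    frames falls back to the full valid range.
    """
    full = np.flatnonzero(gold.valid_mask)
    if full.size < 2:
        raise ValueError("gold standard has too few valid frames")
    selected: list[int] = []
    for side in ("positive", "negative"):
        frames = segs.frames(side)
        frames = frames[gold.valid_mask[frames]] if frames.size else frames
        if frames.size < min_segment_frames:
            frames = full
        idx = _cfs_search(X.values[frames], gold.values[frames], max_features)
        for f in idx:
            if f not in selected:
                selected.append(f)
    return selected


# ---------------------------------------------------------------------------
# the fitted model record
# ---------------------------------------------------------------------------

@dataclass
class SSRM:
    """A trained per-speaker, per-dimension affine predictor."""

    dimension: str
    feature_names: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    weights: np.ndarray
    intercept: float
    lag: float
    n_components: int
    training_ccc: float
    source: str = "labeled"  # "labeled" or "machine"

    def predict(self, X: FeatureMatrix) -> Trace:
        """Frame-wise prediction; the output trace is fully valid."""
        cols = X.column_indices(self.feature_names)
        Z = (X.values[:, cols] - self.mu) / self.sigma
        y = Z @ self.weights + self.intercept
        return Trace(X.frame_period, y, valid_mask=np.ones(len(y), dtype=bool),
                     start_time=X.start_time)

    # -- serialisation ---------------------------------------------------
    def to_json(self) -> str:
        d = {"dimension": self.dimension,
             "feature_names": self.feature_names,
             "mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
             "weights": self.weights.tolist(), "intercept": self.intercept,
             "lag": self.lag, "n_components": self.n_components,
             "training_ccc": self.training_ccc, "source": self.source,
             "regression": "partial least squares",
             "schema_hash": hashlib.sha1(
                 ",".join(self.feature_names).encode()).hexdigest()}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "SSRM":
        d = json.loads(s)
        return cls(dimension=d["dimension"], feature_names=d["feature_names"],
                   mu=np.asarray(d["mu"]), sigma=np.asarray(d["sigma"]),
                   weights=np.asarray(d["weights"]), intercept=d["intercept"],
                   lag=d["lag"], n_components=d["n_components"],
                   training_ccc=d["training_ccc"], source=d["source"])


def predict(model: SSRM, X: FeatureMatrix) -> Trace:
    return model.predict(X)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _blocked_folds(n: int, k: int) -> list[np.ndarray]:
    return [f for f in np.array_split(np.arange(n), k) if f.size >= 2]

def _pls_weights(Z: np.ndarray, y: np.ndarray, L: int):
    pls = PLSRegression(n_components=L, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Z, y.reshape(-1, 1))
    w = np.asarray(pls.coef_).reshape(-1)
    b = float(y.mean() - Z.mean(axis=0) @ w)
    return w, b


def _fit_latent_regression(Z: np.ndarray, y: np.ndarray, config: SSRMConfig,
                           lag_frames: int):
    """PLS fit with the component count chosen by blocked CV on the CCC."""
    n, k = Z.shape
    l_max = max(1, min(config.max_components, k, n - 2))
    folds = config.cv_folds
    if lag_frames > 0:
        while folds > 2 and n // folds < 2 * lag_frames:
            folds -= 1
        if folds < config.cv_folds:
            warnings.warn("cross-validation folds shortened below twice the "
                          f"lag; reduced to {folds} folds", stacklevel=2)
    splits = _blocked_folds(n, folds)
    scores = np.full(l_max, -np.inf)
    if len(splits) >= 2 and n > l_max + 2:
        for li, L in enumerate(range(1, l_max + 1)):
            cccs = []
            for val in splits:
                train = np.setdiff1d(np.arange(n), val, assume_unique=True)
                if train.size <= L + 1:
                    continue
                w, b = _pls_weights(Z[train], y[train], L)
                c = ccc_value(Z[val] @ w + b, y[val])
                if not np.isnan(c):
                    cccs.append(c)
            if cccs:
                scores[li] = float(np.mean(cccs))
    best_l = int(np.argmax(scores)) + 1 if np.isfinite(scores).any() else l_max
    w, b = _pls_weights(Z, y, best_l)
    return w, b, best_l


def train_ssrm_from_gold(X: FeatureMatrix, gold: Trace, dimension: str,
                         config: SSRMConfig | None = None,
                         source: str = "machine",
                         estimate_lag: bool = True) -> SSRM:
    """Train an SSRM against an already-available gold/machine-label trace.

    This is the shared back end of :func:`train_ssrm` (fused annotations)
    and of machine-labeled model construction, where the consensus output
    plays the role of the gold standard and no fusion happens.
    """
    config = config or SSRMConfig()
    if X.n_frames != len(gold):
        raise ValueError("feature matrix and gold trace must share the grid")
    valid_vals = gold.values[gold.valid_mask]
    if valid_vals.size < 10:
        raise ValueError("gold standard has too few valid frames to train on")
    if valid_vals.std() <= 1e-12 * max(1.0, np.abs(valid_vals).max()):
        raise ValueError("gold standard is constant; nothing to regress")

    segs = segment_by_sign(gold)
    sel = select_features(X, gold, segs, max_features=config.max_features,
                          min_segment_frames=config.min_segment_frames)

    lag = 0.0
    if estimate_lag:
        max_lag = min(config.max_lag,
                      gold.duration / 4 - 2 * gold.frame_period)
        if max_lag > 0:
            ref = _ridge_reference(X, gold, config.ridge_alpha)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lag = estimate_reaction_lag(gold, ref, max_lag,
                                            segs.all_segments)
    shifted = apply_lag(gold, lag)

    fit_mask = shifted.valid_mask
    Xsel = X.values[:, sel]
    mu = Xsel[fit_mask].mean(axis=0)
    sigma = Xsel[fit_mask].std(axis=0)
    sigma[sigma == 0.0] = 1.0
    Z = (Xsel - mu) / sigma
    y = shifted.values

    lag_frames = int(round(lag / gold.frame_period))
    w, b, n_comp = _fit_latent_regression(Z[fit_mask], y[fit_mask], config,
                                          lag_frames)
    fitted = Z[fit_mask] @ w + b
    train_ccc = ccc_value(fitted, y[fit_mask])
    return SSRM(dimension=dimension,
                feature_names=[X.descriptor_names[i] for i in sel],
                mu=mu, sigma=sigma, weights=w, intercept=float(b), lag=lag,
                n_components=n_comp, training_ccc=float(train_ccc),
                source=source)


def _ridge_reference(X: FeatureMatrix, gold: Trace, alpha: float) -> Trace:
    """Preliminary all-feature ridge prediction used as the lag reference."""
    m = gold.valid_mask
    mu = X.values[m].mean(axis=0)
    sd = X.values[m].std(axis=0)
    sd[sd == 0.0] = 1.0
    Z = (X.values - mu) / sd
    model = Ridge(alpha=alpha)
    model.fit(Z[m], gold.values[m])
    return Trace(gold.frame_period, model.predict(Z),
                 valid_mask=np.ones(len(gold), dtype=bool),
                 start_time=gold.start_time)


def train_ssrm(X: FeatureMatrix, ann: AnnotationSet, dimension: str | None = None,
               config: SSRMConfig | None = None) -> SSRM:
    """Full labeled-sequence pipeline: fusion, quadrant CFS, lag, PLS fit."""
    config = config or SSRMConfig()
    dimension = dimension or ann.dimension
    gold = fuse_annotations(ann, grand_mean=config.grand_mean)
    model = train_ssrm_from_gold(X, gold.trace, dimension, config,
                                 source="labeled")
    return model


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------

class SingleSpeakerModel:
    """Per-speaker affect regression model, statsmodels style.

    Construct from a feature matrix plus either an :class:`AnnotationSet`
    (labeled speaker) or a gold/machine-label :class:`Trace`, then call
    :meth:`fit` to obtain a :class:`SingleSpeakerResults`.

    Examples
    --------
    >>> model = SingleSpeakerModel(features, annotations=ann)   # doctest: +SKIP
    >>> res = model.fit()                                       # doctest: +SKIP
    >>> print(res.summary())                                    # doctest: +SKIP
    """

    def __init__(self, features: FeatureMatrix,
                 annotations: AnnotationSet | None = None,
                 gold: Trace | None = None,
                 dimension: str | None = None,
                 config: SSRMConfig | None = None):
        if (annotations is None) == (gold is None):
            raise ValueError("provide exactly one of annotations or gold")
        if annotations is not None:
            dimension = dimension or annotations.dimension
        if dimension not in ("arousal", "valence"):
            raise ValueError("dimension must be 'arousal' or 'valence'")
        self.features = features
        self.annotations = annotations
        self.gold = gold
        self.dimension = dimension
        self.config = config or SSRMConfig()

    def fit(self) -> "SingleSpeakerResults":
        if self.annotations is not None:
            ssrm = train_ssrm(self.features, self.annotations,
                              self.dimension, self.config)
        else:
            ssrm = train_ssrm_from_gold(self.features, self.gold,
                                        self.dimension, self.config)
        return SingleSpeakerResults(self, ssrm)


class SingleSpeakerResults:
    """Fitted SSRM plus convenience accessors and a text summary."""

    def __init__(self, model: SingleSpeakerModel, ssrm: SSRM):
        self.model = model
        self.ssrm = ssrm

    @property
    def params(self):
        import pandas as pd
        s = pd.Series(self.ssrm.weights, index=self.ssrm.feature_names,
                      name="weight")
        s.loc["intercept"] = self.ssrm.intercept
        return s

    @property
    def training_ccc(self) -> float:
        return self.ssrm.training_ccc

    @property
    def lag(self) -> float:
        return self.ssrm.lag

    def predict(self, X: FeatureMatrix | None = None) -> Trace:
        return self.ssrm.predict(X if X is not None else self.model.features)

    def summary(self) -> str:
        s = self.ssrm
        lines = [
            "Single Speaker Regression Model",
            "=" * 46,
            f"dimension:          {s.dimension}",
            f"source labels:      {s.source}",
            f"selected features:  {len(s.feature_names)}",
            f"latent components:  {s.n_components}",
            f"reaction lag [s]:   {s.lag:.3f}",
            f"training CCC:       {s.training_ccc:.4f}",
            "-" * 46,
            "top weights (|w|):",
        ]
        order = np.argsort(-np.abs(s.weights))[:10]
        for i in order:
            lines.append(f"  {s.feature_names[i]:<28s} {s.weights[i]:+.4f}")
        lines.append(f"  {'intercept':<28s} {s.intercept:+.4f}")
        return "\n".join(lines)
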