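"""Seeded replications of the three evaluation protocols.

* Protocol 1 — semi-supervised pool growth versus a fixed-pool supervised
  baseline on the same ordered test speakers, paired t-test per dimension.
* Protocol 2 — robustness to the order in which test speakers arrive:
  the semi-supervised arm is repeated under random permutations and the
  dispersion of per-order median CCCs is reported.
* Protocol 3 — self-referencing: the same sequence is fed repeatedly with
  the redundancy-exclusion criterion enabled or disabled, tracking
  prediction quality and pool cardinality.

All scores are CCCs between machine labels and the synthetic ground-truth
latent trajectories; boxplot statistics are reported as median +/-
interquartile range and significance at an alpha level of 0.05.

The supervised baseline is the minimal-difference control: the identical
consensus rule applied to the initial labeled pool only, with no pool
growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusConfig, cooperative_predict
from .metrics import concordance_correlation
from .pool import DIMENSIONS, Pool, PoolConfig
from .synthetic import SpeakerData, SyntheticDataset, clone_speaker
from .traces import Trace

__all__ = ["ExperimentResult", "paired_t", "build_pool",
           "run_supervised_baseline", "run_test1", "run_test2", "run_test3",
           "plot_ccc_boxplot"]

ALPHA = 0.05


@dataclass
class ExperimentResult:
    """Per-speaker, per-dimension CCC table plus protocol-level extras."""

    ccc: pd.DataFrame  # columns: speaker, dimension, condition, ccc
    tests: dict = field(default_factory=dict)       # dim -> (t, df, p)
    cardinality: dict = field(default_factory=dict)  # condition -> list[int]
    per_order: pd.DataFrame | None = None
    dispersion: dict = field(default_factory=dict)

    def median_ccc(self, condition: str, dimension: str) -> float:
        sel = self.ccc[(self.ccc.condition == condition)
                       & (self.ccc.dimension == dimension)]
        return float(sel.ccc.median())

    def iqr_ccc(self, condition: str, dimension: str) -> float:
        sel = self.ccc[(self.ccc.condition == condition)
                       & (self.ccc.dimension == dimension)]
        q75, q25 = np.percentile(sel.ccc.dropna(), [75, 25])
        return float(q75 - q25)

    def summary(self) -> str:
        lines = ["Experiment result (alpha = 0.05)", "=" * 44]
        for cond in self.ccc.condition.unique():
            for dim in DIMENSIONS:
                sel = self.ccc[(self.ccc.condition == cond)
                               & (self.ccc.dimension == dim)]
                if sel.empty:
                    continue
                lines.append(
                    f"{cond:>14s} {dim:<8s} median CCC "
                    f"{sel.ccc.median():+.3f} +/- {self.iqr_ccc(cond, dim):.3f}"
                    f"  (n={len(sel)})")
        for dim, (t, df, p) in self.tests.items():
            verdict = "significant" if p < ALPHA else "not significant"
            lines.append(f"paired t ({dim}): t = {t:.3f}, df = {df}, "
                         f"p = {p:.4g} ({verdict})")
        for cond, card in self.cardinality.items():
            lines.append(f"pool cardinality [{cond}]: {card}")
        return "\n".join(lines)


def paired_t(a, b) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    Zero-variance nonzero differences yield a signed infinite t with
    p = 0 (the degenerate-variance sentinel); identical inputs give t = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    n = d.size
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        m = d.mean()
        t = 0.0 if m == 0.0 else float(np.sign(m)) * float("inf")
        p = 1.0 if m == 0.0 else 0.0
        return t, df, p
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def _truth_ccc(label: Trace, truth: Trace) -> float:
    res = concordance_correlation(label, truth)
    return res.ccc


def build_pool(dataset: SyntheticDataset,
               config: PoolConfig | None = None) -> Pool:
    """Ingest the labeled speakers of a dataset into a fresh pool."""
    pool = Pool(config)
    for sp in dataset.labeled:
        pool.ingest_labeled(sp.speaker_id, sp.features, sp.annotations)
    return pool


def run_supervised_baseline(pool: Pool, test_speakers: list[SpeakerData],
                            config: PoolConfig | None = None
                            ) -> ExperimentResult:
    """Fixed-pool consensus predictions for every test speaker."""
    config = config or pool.config
    rows = []
    for sp in test_speakers:
        for dim in DIMENSIONS:
            label, _ = cooperative_predict(pool.active_models(dim),
                                           sp.features, config.consensus)
            rows.append({"speaker": sp.speaker_id, "dimension": dim,
                         "condition": "supervised",
                         "ccc": _truth_ccc(label, sp.latents[dim])})
    return ExperimentResult(ccc=pd.DataFrame(
        rows, columns=["speaker", "dimension", "condition", "ccc"]))


def _run_semi_arm(dataset: SyntheticDataset, order: list[int],
                  config: PoolConfig) -> tuple[pd.DataFrame, list[int]]:
    """Sequentially machine-label the test speakers in the given order."""
    pool = build_pool(dataset, config)
    rows = []
    cardinality = []
    speakers = [dataset.test[i] for i in order]
    for pos, sp in enumerate(speakers):
        nxt = speakers[pos + 1] if pos + 1 < len(speakers) else dataset.probe
        rec = pool.process_unlabeled(sp.speaker_id, sp.features,
                                     probe=nxt.features)
        for dim in DIMENSIONS:
            rows.append({"speaker": sp.speaker_id, "dimension": dim,
                         "condition": "semi-supervised",
                         "ccc": _truth_ccc(rec.machine_labels[dim],
                                           sp.latents[dim])})
        cardinality.append(pool.cardinality())
    return pd.DataFrame(rows), cardinality


def run_test1(dataset: SyntheticDataset,
              config: PoolConfig | None = None) -> ExperimentResult:
    """Semi-supervised versus supervised on identical data, paired t-test."""
    config = config or PoolConfig()
    semi_ccc, cardinality = _run_semi_arm(
        dataset, list(range(len(dataset.test))), config)
    sup = run_supervised_baseline(build_pool(dataset, config), dataset.test,
                                  config)
    ccc = pd.concat([semi_ccc, sup.ccc], ignore_index=True)
    tests = {}
    for dim in DIMENSIONS:
        a = [semi_ccc[(semi_ccc.speaker == s.speaker_id)
                      & (semi_ccc.dimension == dim)].ccc.iloc[0]
             for s in dataset.test]
        b = [sup.ccc[(sup.ccc.speaker == s.speaker_id)
                     & (sup.ccc.dimension == dim)].ccc.iloc[0]
             for s in dataset.test]
        a, b = np.asarray(a), np.asarray(b)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 2:
            tests[dim] = paired_t(a[ok], b[ok])
    return ExperimentResult(ccc=ccc, tests=tests,
                            cardinality={"semi-supervised": cardinality})


def run_test2(dataset: SyntheticDataset, n_orders: int = 10,
              config: PoolConfig | None = None,
              seed: int = 0) -> ExperimentResult:
    """Order-robustness: the semi arm under random speaker permutations.

    The same permutation serves both affect dimensions.  Reported are the
    per-order median CCCs for both arms (the supervised control does not
    depend on order) and their dispersion as the interquartile range
    across orders.
    """
    if n_orders < 2:
        raise ValueError("need at least two orders")
    config = config or PoolConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    n = len(dataset.test)

    sup = run_supervised_baseline(build_pool(dataset, config), dataset.test,
                                  config)
    sup_median = {d: sup.ccc[(sup.ccc.dimension == d)].ccc.median()
                  for d in DIMENSIONS}

    rows = []
    all_ccc = [sup.ccc]
    for it in range(n_orders):
        order = rng.permutation(n).tolist()
        semi_ccc, _ = _run_semi_arm(dataset, order, config)
        semi_ccc = semi_ccc.assign(order=it)
        all_ccc.append(semi_ccc)
        for dim in DIMENSIONS:
            rows.append({"order": it, "dimension": dim,
                         "condition": "semi-supervised",
                         "median_ccc": semi_ccc[
                             semi_ccc.dimension == dim].ccc.median()})
            rows.append({"order": it, "dimension": dim,
                         "condition": "supervised",
                         "median_ccc": sup_median[dim]})
    per_order = pd.DataFrame(rows)
    dispersion = {}
    for cond in ("semi-supervised", "supervised"):
        for dim in DIMENSIONS:
            v = per_order[(per_order.condition == cond)
                          & (per_order.dimension == dim)].median_ccc
            q75, q25 = np.percentile(v, [75, 25])
            dispersion[(cond, dim)] = float(q75 - q25)
    return ExperimentResult(ccc=pd.concat(all_ccc, ignore_index=True),
                            per_order=per_order, dispersion=dispersion)


def run_test3(dataset: SyntheticDataset, n_feeds: int = 10,
              redex_enabled: bool = True,
              config: PoolConfig | None = None,
              target: SpeakerData | None = None) -> ExperimentResult:
    """Self-referencing: feed exact clones of one sequence repeatedly.

    The re-fed sequence is, by default, a clone of the first *pool*
    speaker — the redundant-speaker situation the redundancy criterion
    exists for.  Tracks the machine-label CCC against the sequence's
    ground truth and the active-pool cardinality after every feed.
    """
    if n_feeds < 2:
        raise ValueError("need at least two feeds")
    config = config or PoolConfig()
    import dataclasses
    config = dataclasses.replace(config, redex_enabled=redex_enabled)
    pool = build_pool(dataset, config)
    target = target if target is not None else dataset.labeled[0]
    condition = "redex" if redex_enabled else "no-redex"

    rows = []
    cardinality = []
    for feed in range(n_feeds):
        clone = clone_speaker(target, seed=feed, epsilon=0.0,
                              speaker_id=f"{target.speaker_id}_feed{feed}")
        rec = pool.process_unlabeled(clone.speaker_id, clone.features,
                                     probe=dataset.probe.features)
        for dim in DIMENSIONS:
            rows.append({"speaker": clone.speaker_id, "feed": feed,
                         "dimension": dim, "condition": condition,
                         "ccc": _truth_ccc(rec.machine_labels[dim],
                                           target.latents[dim])})
        cardinality.append(pool.cardinality())
    return ExperimentResult(ccc=pd.DataFrame(rows),
                            cardinality={condition: cardinality})


def plot_ccc_boxplot(result: ExperimentResult, path) -> None:
    """Condition-wise CCC boxplots per dimension, written as SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = list(dict.fromkeys(result.ccc.condition))
    fig, axes = plt.subplots(1, len(DIMENSIONS), figsize=(8, 3.2),
                             sharey=True)
    for ax, dim in zip(np.atleast_1d(axes), DIMENSIONS):
        data = [result.ccc[(result.ccc.condition == c)
                           & (result.ccc.dimension == dim)].ccc.dropna()
                for c in conditions]
        ax.boxplot(data, tick_labels=conditions)
        ax.set_title(dim)
        ax.set_ylabel("CCC")
        ax.axhline(0.0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
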