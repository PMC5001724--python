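"""Speaker pool lifecycle and the redundancy-exclusion (RED-EX) criterion.

The semi-supervised system keeps an ensemble of per-speaker models.  Each
speech sequence moves through a small state machine:

* ``LABELED``    — human annotations available; models trained and active.
* ``UNLABELED``  — awaiting machine labeling by the cooperative ensemble.
* ``WFI``        — machine-labeled models trained, inclusion pending.
* ``INCLUDED``   — machine-labeled models accepted into the active pool.
* ``EXCLUDED``   — rejected, either for insufficient machine labels or for
  redundancy with the existing pool.

The only legal transitions are ``UNLABELED -> {EXCLUDED, WFI}`` and
``WFI -> {INCLUDED, EXCLUDED}``; ``LABELED`` is terminal.

RED-EX compares the candidate machine-labeled model against every active
model on a probe sequence: if the maximum whole-sequence CCC between the
candidate's probe prediction and any single active model's exceeds the
redundancy threshold (0.99 by default, strict inequality) in all affect
dimensions, the candidate adds nothing and is excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .consensus import (ConsensusConfig, cooperative_predict,
                        sufficiency_check)
from .gold_standard import AnnotationSet
from .metrics import concordance_correlation
from .ssrm import SSRM, SSRMConfig, train_ssrm, train_ssrm_from_gold
from .traces import FeatureMatrix, Trace

__all__ = ["SpeakerState", "SpeakerRecord", "Pool", "PoolConfig",
           "redex_decision"]

DIMENSIONS = ("arousal", "valence")


class SpeakerState(enum.Enum):
    LABELED = "LABELED"
    UNLABELED = "UNLABELED"
    WFI = "WFI"
    INCLUDED = "INCLUDED"
    EXCLUDED = "EXCLUDED"


_ALLOWED = {
    (SpeakerState.UNLABELED, SpeakerState.WFI),
    (SpeakerState.UNLABELED, SpeakerState.EXCLUDED),
    (SpeakerState.WFI, SpeakerState.INCLUDED),
    (SpeakerState.WFI, SpeakerState.EXCLUDED),
}


@dataclass
class SpeakerRecord:
    speaker_id: str
    state: SpeakerState
    features: FeatureMatrix
    annotations: dict[str, AnnotationSet] | None = None
    models: dict[str, SSRM] | None = None
    machine_labels: dict[str, Trace] | None = None
    history: list[tuple[str, str, str]] = field(default_factory=list)

    def _transition(self, to: SpeakerState, cause: str, log: list) -> None:
        if (self.state, to) not in _ALLOWED:
            raise RuntimeError(
                f"illegal transition {self.state.value} -> {to.value}")
        self.history.append((self.state.value, to.value, cause))
        log.append((self.speaker_id, self.state.value, to.value, cause))
        self.state = to


@dataclass
class PoolConfig:
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    ssrm: SSRMConfig = field(default_factory=SSRMConfig)
    redex_enabled: bool = True
    #: 'any' = exclude when redundant in at least one dimension (default:
    #: the per-dimension models are independent, so redundancy in either
    #: already means the speaker adds nothing there); 'all' = exclude only
    #: when redundant in every dimension
    redex_combine: str = "any"


def redex_decision(candidate_models: dict[str, SSRM], pool: "Pool",
                   probe: FeatureMatrix,
                   config: PoolConfig | None = None) -> SpeakerState:
    """Apply RED-EX: INCLUDED unless the candidate duplicates a pool model.

    For each dimension both the candidate and every active model predict
    the probe sequence; the maximum whole-sequence CCC between the
    candidate's prediction and any single active prediction is taken as
    the candidate's redundancy in that dimension.  Redundancies strictly
    above the threshold in all (``redex_combine='all'``) or any
    (``'any'``) dimensions exclude the candidate.
    """
    config = config or pool.config
    thr = config.consensus.redex_threshold
    redundant = []
    for dim in DIMENSIONS:
        cand = candidate_models[dim].predict(probe)
        max_ccc = -np.inf
        for model in pool.active_models(dim):
            res = concordance_correlation(cand, model.predict(probe))
            if res.defined and res.ccc > max_ccc:
                max_ccc = res.ccc
        redundant.append(max_ccc > thr)
    combine = all if config.redex_combine == "all" else any
    return SpeakerState.EXCLUDED if combine(redundant) else SpeakerState.INCLUDED


class Pool:
    """Collection of speaker records plus the active model ensemble."""

    def __init__(self, config: PoolConfig | None = None):
        self.config = config or PoolConfig()
        self.records: list[SpeakerRecord] = []
        self.transitions: list[tuple[str, str, str, str]] = []

    # -- bookkeeping -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def _check_unique(self, speaker_id: str) -> None:
        if any(r.speaker_id == speaker_id for r in self.records):
            raise ValueError(f"duplicate speaker id: {speaker_id}")

    def record(self, speaker_id: str) -> SpeakerRecord:
        for r in self.records:
            if r.speaker_id == speaker_id:
                return r
        raise KeyError(speaker_id)

    def active_models(self, dimension: str) -> list[SSRM]:
        """Models of LABELED and INCLUDED records, in ingestion order."""
        out = []
        for r in self.records:
            if r.state in (SpeakerState.LABELED, SpeakerState.INCLUDED) \
                    and r.models:
                out.append(r.models[dimension])
        return out

    def cardinality(self, dimension: str = "arousal") -> int:
        return len(self.active_models(dimension))

    # -- ingestion -------------------------------------------------------
    def ingest_labeled(self, speaker_id: str, features: FeatureMatrix,
                       annotations: dict[str, AnnotationSet]) -> SpeakerRecord:
        """Train SSRMs for a human-annotated sequence; state LABELED."""
        self._check_unique(speaker_id)
        missing = [d for d in DIMENSIONS if d not in annotations]
        if missing:
            raise ValueError(f"annotations missing for: {missing}")
        try:
            models = {d: train_ssrm(features, annotations[d], d,
                                    self.config.ssrm) for d in DIMENSIONS}
        except ValueError as exc:
            raise ValueError(
                f"speaker {speaker_id} rejected: training failed ({exc})"
            ) from exc
        rec = SpeakerRecord(speaker_id=speaker_id,
                            state=SpeakerState.LABELED, features=features,
                            annotations=annotations, models=models)
        self.records.append(rec)
        self.transitions.append((speaker_id, "-", "LABELED", "ingested"))
        return rec

    def process_unlabeled(self, speaker_id: str, features: FeatureMatrix,
                          probe: FeatureMatrix | None = None) -> SpeakerRecord:
        """Machine-label a new sequence and resolve its pool membership.

        Runs the cooperative ensemble per dimension; a sequence whose
        machine labels fail the sufficiency check in either dimension is
        EXCLUDED.  Otherwise machine-labeled models are trained (state
        WFI) and RED-EX decides INCLUDED/EXCLUDED against the probe
        sequence; without a probe the record stays parked in WFI.
        """
        self._check_unique(speaker_id)
        cfg = self.config
        if self.cardinality() < cfg.consensus.min_ensemble:
            raise RuntimeError("pool has too few active models to predict")

        rec = SpeakerRecord(speaker_id=speaker_id,
                            state=SpeakerState.UNLABELED, features=features)
        self.records.append(rec)
        self.transitions.append((speaker_id, "-", "UNLABELED", "received"))

        labels: dict[str, Trace] = {}
        for dim in DIMENSIONS:
            label, _ = cooperative_predict(self.active_models(dim), features,
                                           cfg.consensus)
            labels[dim] = label
        rec.machine_labels = labels

        if not all(sufficiency_check(labels[d], cfg.consensus)
                   for d in DIMENSIONS):
            rec._transition(SpeakerState.EXCLUDED,
                            "insufficient machine labels", self.transitions)
            return rec

        try:
            rec.models = {d: train_ssrm_from_gold(features, labels[d], d,
                                                  cfg.ssrm, source="machine")
                          for d in DIMENSIONS}
        except ValueError as exc:
            rec._transition(SpeakerState.EXCLUDED,
                            f"machine-label training failed: {exc}",
                            self.transitions)
            return rec
        rec._transition(SpeakerState.WFI, "machine-labeled models trained",
                        self.transitions)

        if not cfg.redex_enabled:
            rec._transition(SpeakerState.INCLUDED, "RED-EX disabled",
                            self.transitions)
            return rec
        if probe is None:
            return rec  # decision deferred until a probe arrives
        return self.resolve_wfi(speaker_id, probe)

    def resolve_wfi(self, speaker_id: str,
                    probe: FeatureMatrix) -> SpeakerRecord:
        """Apply RED-EX to a parked WFI record once a probe is available."""
        rec = self.record(speaker_id)
        if rec.state is not SpeakerState.WFI:
            raise RuntimeError(f"{speaker_id} is not waiting for inclusion")
        decision = redex_decision(rec.models, self, probe, self.config)
        cause = ("redundant with pool (RED-EX)"
                 if decision is SpeakerState.EXCLUDED
                 else "novel model (RED-EX passed)")
        rec._transition(decision, cause, self.transitions)
        return rec

    # -- manifest --------------------------------------------------------
    def manifest(self) -> dict:
        return {"records": [
            {"speaker_id": r.speaker_id, "state": r.state.value,
             "n_frames": r.features.n_frames,
             "models": {d: {"n_features": len(m.feature_names),
                            "training_ccc": m.training_ccc,
                            "lag": m.lag, "source": m.source}
                        for d, m in (r.models or {}).items()}}
            for r in self.records],
            "transitions": [list(t) for t in self.transitions]}
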