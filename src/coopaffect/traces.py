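"""Core time-series containers.

A :class:`Trace` is a uniformly sampled real-valued signal with a validity
mask — it holds annotator ratings, fused gold standards, model predictions
and machine labels alike.  A :class:`FeatureMatrix` holds the frame-level
acoustic low-level descriptors (LLDs) for one speech sequence, and
:class:`FeatureSchema` describes the descriptor layout (the ComParE-style
65-LLD set and its first-order deltas, 130 channels in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Trace", "FeatureMatrix", "FeatureSchema", "default_schema"]

#: tolerance (seconds) when checking grid uniformity / alignment
GRID_TOL = 1e-9


@dataclass
class Trace:
    """Uniformly sampled time series with a missing-value mask.

    Parameters
    ----------
    frame_period : float
        Seconds per sample (uniform grid), strictly positive.
    values : ndarray of float
        Sample values.  Affect labels live nominally in [-1, 1];
        predictions are unrestricted.
    valid_mask : ndarray of bool, optional
        Marks samples that carry a value.  Defaults to all-valid.
    start_time : float
        Time of the first sample, seconds.
    """

    frame_period: float
    values: np.ndarray
    valid_mask: np.ndarray | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask length must match values")
        if not self.frame_period > 0:
            raise ValueError("frame_period must be positive")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("valid samples must be finite")

    # -- basic geometry -------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.frame_period * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.frame_period * self.values.size

    @property
    def valid_fraction(self) -> float:
        if self.values.size == 0:
            return 0.0
        return float(self.valid_mask.mean())

    def copy(self) -> "Trace":
        return replace(self, values=self.values.copy(),
                       valid_mask=self.valid_mask.copy())

    def same_grid(self, other: "Trace") -> bool:
        return (abs(self.frame_period - other.frame_period) <= GRID_TOL
                and abs(self.start_time - other.start_time) <= GRID_TOL
                and len(self) == len(other))

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        vals = self.values.astype(float).copy()
        vals[~self.valid_mask] = np.nan
        return pd.DataFrame({"time": self.times, "value": vals})

    def to_csv(self, path) -> None:
        """Write ``time,value`` CSV; missing samples become empty fields."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        """Read a ``time,value`` CSV written by :meth:`to_csv`.

        The frame period is inferred from the time column and checked
        uniform to 1e-9 s.
        """
        df = pd.read_csv(path)
        if not {"time", "value"} <= set(df.columns):
            raise ValueError("trace CSV needs 'time' and 'value' columns")
        t = df["time"].to_numpy(dtype=float)
        return cls(frame_period=_infer_period(t),
                   values=df["value"].to_numpy(dtype=float),
                   valid_mask=np.isfinite(df["value"].to_numpy(dtype=float)),
                   start_time=float(t[0]))


def _infer_period(t: np.ndarray) -> float:
    if t.size < 2:
        raise ValueError("need at least two samples to infer a frame period")
    steps = np.diff(t)
    period = float(np.median(steps))
    if np.any(np.abs(steps - period) > GRID_TOL):
        raise ValueError("time grid is not uniform")
    return period


# ---------------------------------------------------------------------------
# feature schema
# ---------------------------------------------------------------------------

_ENERGY = ["loudness", "RMSenergy", "zcr", "energyInBand250_650"]

_SPECTRAL = (
    [f"mfcc{i}" for i in range(1, 15)]
    + [f"audSpecRasta{i}" for i in range(1, 27)]
    + ["spectralRollOff25", "spectralRollOff50", "spectralRollOff75",
       "spectralRollOff90", "spectralFlux", "spectralCentroid",
       "spectralEntropy", "spectralVariance", "spectralSkewness",
       "spectralKurtosis", "spectralSlope", "spectralDecrease",
       "spectralHarmonicity", "spectralFlatness", "psySharpness"]
)

_VOICING = ["F0final", "voicingProb", "jitterLocal", "jitterDDP",
            "shimmerLocal", "logHNR"]


@dataclass(frozen=True)
class FeatureSchema:
    """Named descriptor groups with an optional first-derivative doubling.

    The default layout mirrors the ComParE low-level-descriptor set:
    4 energy-related, 55 spectral-related and 6 voicing-related channels
    (65 base LLDs), doubled to 130 by first-order deltas.
    """

    energy: tuple = tuple(_ENERGY)
    spectral: tuple = tuple(_SPECTRAL)
    voicing: tuple = tuple(_VOICING)
    deltas: bool = True

    @property
    def base_names(self) -> list[str]:
        return list(self.energy) + list(self.spectral) + list(self.voicing)

    @property
    def names(self) -> list[str]:
        base = self.base_names
        if self.deltas:
            return base + [f"de_{n}" for n in base]
        return base

    @property
    def n_base(self) -> int:
        return len(self.base_names)

    @property
    def n_total(self) -> int:
        return len(self.names)

    def to_manifest(self) -> dict:
        return {"energy": list(self.energy), "spectral": list(self.spectral),
                "voicing": list(self.voicing), "deltas": self.deltas}

    @classmethod
    def from_manifest(cls, d: dict) -> "FeatureSchema":
        return cls(energy=tuple(d["energy"]), spectral=tuple(d["spectral"]),
                   voicing=tuple(d["voicing"]), deltas=bool(d["deltas"]))


def default_schema() -> FeatureSchema:
    """The 65-LLD (+deltas = 130) descriptor schema used throughout."""
    return FeatureSchema()


@dataclass
class FeatureMatrix:
    """Frames × descriptors matrix of acoustic low-level descriptors."""

    frame_period: float
    descriptor_names: list[str]
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be frames x descriptors")
        if self.values.shape[1] != len(self.descriptor_names):
            raise ValueError("descriptor_names length must match columns")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must be finite after preprocessing")
        if not self.frame_period > 0:
            raise ValueError("frame_period must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.frame_period * np.arange(self.n_frames)

    def column_indices(self, names) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.descriptor_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"descriptors not in matrix: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValueError("feature CSV needs a 'time' column")
        t = df["time"].to_numpy(dtype=float)
        names = [c for c in df.columns if c != "time"]
        return cls(frame_period=_infer_period(t), descriptor_names=names,
                   values=df[names].to_numpy(dtype=float), start_time=float(t[0]))
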