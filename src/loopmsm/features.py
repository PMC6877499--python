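"""Periodic featurization of torsions and the metadynamics collective variable.

Torsion angles enter all linear analyses through their sine and cosine,
which removes the -180/180 wrap discontinuity.  The enhanced-sampling
collective variable is a weighted linear combination of sin and cos of
selected psi angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TorsionSeries

_ANGLE_INDEX = {"omega": 0, "phi": 1, "psi": 2}


@dataclass
class FeatureMatrix:
    """Frames x features matrix of sin/cos torsion features."""

    X: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.labels):
            raise ValueError("feature matrix / label mismatch")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class CollectiveVariableSpec:
    """Selected psi angle indices with per-angle (sin, cos) weights."""

    psi_indices: list[int]
    sin_weights: np.ndarray | None = None
    cos_weights: np.ndarray | None = None

    def __post_init__(self):
        if len(self.psi_indices) < 1:
            raise ValueError("need >= 1 selected psi angle")
        n = len(self.psi_indices)
        if self.sin_weights is None:
            self.sin_weights = np.ones(n)
        if self.cos_weights is None:
            self.cos_weights = np.ones(n)
        self.sin_weights = np.asarray(self.sin_weights, dtype=float)
        self.cos_weights = np.asarray(self.cos_weights, dtype=float)
        if self.sin_weights.shape != (n,) or self.cos_weights.shape != (n,):
            raise ValueError("weight length mismatch")
        if not (np.isfinite(self.sin_weights).all()
                and np.isfinite(self.cos_weights).all()):
            raise ValueError("weights must be finite")


def torsions_to_features(t: TorsionSeries,
                         include: set[str] = frozenset({"phi", "psi"})) -> FeatureMatrix:
    """Map a torsion series to sin/cos features.

    One (sin, cos) column pair per included, defined angle.  Angles that
    are undefined (NaN) in any frame — i.e. the structurally missing
    terminal torsions — are dropped from the feature set entirely, never
    per-frame.
    """
    if not include:
        raise ValueError("empty include set")
    bad = set(include) - set(_ANGLE_INDEX)
    if bad:
        raise ValueError(f"unknown angle types: {sorted(bad)}")
    if t.n_frames == 0:
        raise ValueError("empty torsion series")
    cols = []
    labels = []
    order = [a for a in ("omega", "phi", "psi") if a in include]
    rad = np.radians(t.angles)
    for name in order:
        k = _ANGLE_INDEX[name]
        for r in range(t.loop_length):
            col = rad[:, r, k]
            if np.isnan(col).any():
                continue
            cols.append(np.sin(col))
            labels.append(f"{name}_{r}_sin")
            cols.append(np.cos(col))
            labels.append(f"{name}_{r}_cos")
    if not cols:
        raise ValueError("no defined angles to featurize")
    return FeatureMatrix(np.column_stack(cols), labels)


def cv_value(t: TorsionSeries, cv: CollectiveVariableSpec) -> np.ndarray:
    """Per-frame collective variable: sum of weighted sin and cos of the
    selected psi angles."""
    L = t.loop_length
    for idx in cv.psi_indices:
        if not 0 <= idx < L:
            raise ValueError(f"psi index {idx} out of range for loop length {L}")
    psi = np.radians(t.angles[:, cv.psi_indices, 2])
    return (np.sin(psi) @ cv.sin_weights) + (np.cos(psi) @ cv.cos_weights)
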