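"""Time-lagged independent component analysis (tICA).

Given mean-free features x(t), tICA solves the generalized eigenproblem

    C_tau v = lambda C_0 v

with C_0 the instantaneous covariance and C_tau the symmetrized
time-lagged covariance pooled over trajectories (pairs never span
trajectory boundaries).  Eigenvectors are the slowest linear collective
modes; eigenvalues map to relaxation timescales t_i = -tau / ln|lambda_i|.
The symmetrized (reversible) estimator keeps the spectrum real.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .features import FeatureMatrix


@dataclass
class TICAModel:
    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    eigenvalues: np.ndarray          # sorted descending
    eigenvectors: np.ndarray         # columns, C0-orthonormal
    timescales: np.ndarray           # frames; inf where |lambda| clipped
    retained_dim: int
    kept_features: np.ndarray        # indices into the original feature set
    feature_labels: list[str] | None = None
    frame_stride_ns: float = 1.0

    @property
    def timescales_ns(self) -> np.ndarray:
        return self.timescales * self.frame_stride_ns


def _as_arrays(trajs) -> list[np.ndarray]:
    out = []
    for t in trajs:
        X = t.X if isinstance(t, FeatureMatrix) else np.asarray(t, dtype=float)
        if X.ndim != 2:
            raise ValueError("each trajectory must be a 2-D feature array")
        out.append(X)
    return out


def fit_tica(trajs, lag: int, dim: int | None = None,
             kinetic_variance: float = 0.95,
             frame_stride_ns: float = 1.0) -> TICAModel:
    """Fit tICA on a list of feature trajectories at integer frame lag.

    Parameters
    ----------
    trajs : list of FeatureMatrix or 2-D arrays
        Feature trajectories; time-lagged pairs are formed within each.
    lag : int
        Lag time in frames; must be shorter than every trajectory.
    dim : int, optional
        Retained dimension override.  Default: smallest d whose cumulative
        squared eigenvalues reach ``kinetic_variance`` of the total.
    """
    Xs = _as_arrays(trajs)
    if not Xs:
        raise ValueError("no trajectories")
    labels = trajs[0].labels if isinstance(trajs[0], FeatureMatrix) else None
    lag = int(lag)
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    if any(X.shape[0] <= lag for X in Xs):
        raise ValueError("lag must be shorter than every trajectory")
    n_feat = Xs[0].shape[1]
    if n_feat < 2:
        raise ValueError("need >= 2 features")
    if any(X.shape[1] != n_feat for X in Xs):
        raise ValueError("trajectories differ in feature count")

    # drop zero-variance features
    allX = np.vstack(Xs)
    var = allX.var(axis=0)
    kept = np.nonzero(var > 1e-12)[0]
    if kept.size < n_feat:
        warnings.warn(f"dropping {n_feat - kept.size} zero-variance feature(s)")
    if kept.size < 2:
        raise ValueError("fewer than 2 informative features")
    Xs = [X[:, kept] for X in Xs]

    # pooled mean over all frames entering pairs
    n_pairs = sum(X.shape[0] - lag for X in Xs)
    mean = sum(X[:-lag].sum(axis=0) + X[lag:].sum(axis=0) for X in Xs) / (2 * n_pairs)
    d = kept.size
    c0 = np.zeros((d, d))
    ct = np.zeros((d, d))
    for X in Xs:
        A = X[:-lag] - mean
        B = X[lag:] - mean
        c0 += A.T @ A + B.T @ B
        ct += A.T @ B
    c0 /= 2 * n_pairs
    ct = (ct + ct.T) / (2 * n_pairs)

    eps = 1e-10 * np.trace(c0) / d
    w, v = scipy.linalg.eigh(ct, c0 + eps * np.eye(d))
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]

    absw = np.abs(w)
    clipped = absw >= 1.0 - 1e-12
    if clipped.any():
        warnings.warn("eigenvalue(s) at or above 1 clipped for timescales")
    ts = np.where(clipped, np.inf,
                  -lag / np.log(np.clip(absw, 1e-300, 1.0 - 1e-12)))

    if dim is None:
        kv = np.cumsum(w ** 2) / np.sum(w ** 2)
        dim = int(np.searchsorted(kv, kinetic_variance) + 1)
    dim = min(int(dim), d)
    return TICAModel(lag=lag, mean=mean, c0=c0, ctau=ct, eigenvalues=w,
                     eigenvectors=v, timescales=ts, retained_dim=dim,
                     kept_features=kept, feature_labels=labels,
                     frame_stride_ns=frame_stride_ns)


def tica_transform(model: TICAModel, x, dim: int | None = None) -> np.ndarray:
    """Project feature vectors on the retained tICs.

    Accepts a single feature vector, a 2-D array, or a FeatureMatrix; the
    feature dimension must match the training data (before zero-variance
    dropping)."""
    X = x.X if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    n_orig = int(model.kept_features.max()) + 1 if model.kept_features.size else 0
    if X.shape[1] == model.mean.size:
        Xk = X
    elif X.shape[1] >= n_orig:
        Xk = X[:, model.kept_features]
    else:
        raise ValueError("feature dimension mismatch")
    d = model.retained_dim if dim is None else int(dim)
    Y = (Xk - model.mean) @ model.eigenvectors[:, :d]
    return Y[0] if single else Y


def noise_eigenvalue_bound(trajs, lag: int, n_permutations: int = 10,
                           seed: int = 0) -> float:
    """Permutation bound on spurious tICA eigenvalues.

    Shuffles the frame order within each trajectory (destroying all time
    correlation while keeping the marginal distribution), refits tICA, and
    records the largest |eigenvalue|.  Returns mean + 3 std over
    permutations — eigenvalues above this bound indicate genuine slow
    dynamics rather than sampling noise.
    """
    Xs = _as_arrays(trajs)
    rng = np.random.default_rng(seed)
    maxima = []
    for _ in range(n_permutations):
        perm = [X[rng.permutation(X.shape[0])] for X in Xs]
        m = fit_tica(perm, lag)
        maxima.append(np.abs(m.eigenvalues).max())
    maxima = np.array(maxima)
    return float(maxima.mean() + 3.0 * maxima.std(ddof=1))
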