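"""Markov-state model estimation and coarse-graining.

The pipeline discretises tICA-projected frames into k-means microstates,
counts lag-tau transitions (sliding window, never across trajectory
boundaries), restricts to the largest strongly connected set ("the network
states must be fully connected"), and estimates a reversible
maximum-likelihood transition matrix by the detailed-balance fixed-point
iteration

    x_ij <- (C_ij + C_ji) / (c_i / x_i + c_j / x_j)

with c_i the count row sums and x_i = sum_j x_ij; then T_ij = x_ij / x_i
and pi_i = x_i / sum x.  Validation uses implied timescales, the VAMP-2
score and the Chapman-Kolmogorov test; PCCA+ coarse-grains microstates to
metastable macrostates, from which mean first-passage times are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans


# ---------------------------------------------------------------------------
# Microstates
# ---------------------------------------------------------------------------

@dataclass
class MicrostateModel:
    centers: np.ndarray
    labels: list[np.ndarray]        # per trajectory
    inertia: float
    seed: int

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def cluster_microstates(trajs, k: int, seed: int = 0) -> MicrostateModel:
    """k-means microstates in tIC space (k-means++ init, fixed seed).

    ``trajs`` is a list of (n_frames, d) coordinate arrays.
    """
    Ys = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trajs]
    X = np.vstack(Ys)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of frames {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    flat = km.fit_predict(X)
    labels = []
    ofs = 0
    for Y in Ys:
        labels.append(flat[ofs:ofs + Y.shape[0]].astype(np.int64))
        ofs += Y.shape[0]
    return MicrostateModel(km.cluster_centers_, labels, float(km.inertia_), seed)


def assign_microstates(model: MicrostateModel, Y: np.ndarray) -> np.ndarray:
    """Nearest-center microstate assignment for new coordinates."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    d2 = ((Y[:, None, :] - model.centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


# ---------------------------------------------------------------------------
# Counts and connectivity
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    lag: int
    counts: np.ndarray
    mode: str = "sliding"

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


def count_transitions(label_seqs, lag: int, mode: str = "sliding",
                      n_states: int | None = None) -> CountMatrix:
    """Count lag-tau transition pairs; pairs never span trajectory
    boundaries.  Sliding mode uses every pair (t, t+lag); strided mode uses
    t = 0, lag, 2 lag, ..."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError(f"unknown counting mode {mode!r}")
    seqs = [np.asarray(s, dtype=np.int64) for s in label_seqs]
    if not seqs:
        raise ValueError("no label sequences")
    if all(len(s) <= lag for s in seqs):
        raise ValueError("lag >= every trajectory length")
    k = n_states if n_states is not None else max(int(s.max()) for s in seqs) + 1
    C = np.zeros((k, k), dtype=np.int64)
    for s in seqs:
        if len(s) <= lag:
            continue
        a = s[:-lag]
        b = s[lag:]
        if mode == "strided":
            a = s[:-lag:lag]
            b = s[lag::lag]
        np.add.at(C, (a, b), 1)
    return CountMatrix(lag=lag, counts=C, mode=mode)


def largest_connected_set(c: CountMatrix):
    """Largest strongly connected component of the count graph.

    Ties between equally sized components are broken by larger total
    counts, then lowest member state index.  Returns (active_states,
    retained_state_fraction, retained_count_fraction).
    """
    C = c.counts
    k = C.shape[0]
    graph = scipy.sparse.csr_matrix((C > 0).astype(np.int8))
    n_comp, assign = connected_components(graph, directed=True,
                                          connection="strong")
    best = None
    total = C.sum()
    for comp in range(n_comp):
        members = np.nonzero(assign == comp)[0]
        cnt = C[np.ix_(members, members)].sum()
        key = (len(members), cnt, -members.min())
        if best is None or key > best[0]:
            best = (key, members)
    members = best[1]
    frac_states = len(members) / k
    frac_counts = float(C[np.ix_(members, members)].sum() / total) if total else 0.0
    return members, frac_states, frac_counts


def restrict_counts(c: CountMatrix, active: np.ndarray) -> CountMatrix:
    return CountMatrix(lag=c.lag, counts=c.counts[np.ix_(active, active)],
                       mode=c.mode)


# ---------------------------------------------------------------------------
# Reversible maximum-likelihood estimation
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    lag: int
    active_set: np.ndarray
    T: np.ndarray
    pi: np.ndarray
    eigenvalues: np.ndarray          # real, sorted descending
    frame_stride_ns: float = 1.0
    n_iterations: int = 0
    converged: bool = True

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def lag_ns(self) -> float:
        return self.lag * self.frame_stride_ns


def _reversible_eigenvalues(T: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Real spectrum of a reversible T via the symmetric similarity
    transform diag(sqrt(pi)) T diag(1/sqrt(pi))."""
    s = np.sqrt(pi)
    S = T * s[:, None] / s[None, :]
    S = (S + S.T) / 2
    w = scipy.linalg.eigvalsh(S)
    return w[::-1]


def _reversible_eigenvectors(T: np.ndarray, pi: np.ndarray):
    """(eigenvalues desc, right eigenvectors as columns) of reversible T."""
    s = np.sqrt(pi)
    S = T * s[:, None] / s[None, :]
    S = (S + S.T) / 2
    w, u = scipy.linalg.eigh(S)
    w = w[::-1]
    u = u[:, ::-1]
    R = u / s[:, None]               # right eigenvectors of T
    return w, R


def estimate_reversible(c: CountMatrix, active_set: np.ndarray | None = None,
                        tol: float = 1e-10, max_iter: int = 1_000_000,
                        frame_stride_ns: float = 1.0) -> TransitionModel:
    """Reversible MLE transition matrix by fixed-point iteration.

    The count matrix must already be restricted to a strongly connected
    active set.  Iterates until the maximum change of the (normalised)
    symmetric weights x_ij drops below ``tol``.
    """
    C = np.asarray(c.counts, dtype=float)
    k = C.shape[0]
    if active_set is None:
        active_set = np.arange(k)
    graph = scipy.sparse.csr_matrix((C > 0).astype(np.int8))
    n_comp, _ = connected_components(graph, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("count matrix is not strongly connected; restrict first")
    Csym = C + C.T
    crow = C.sum(axis=1)
    X = Csym / Csym.sum()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x = X.sum(axis=1)
        denom = crow[:, None] / x[:, None] + crow[None, :] / x[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            Xn = np.where(Csym > 0, Csym / denom, 0.0)
        Xn /= Xn.sum()
        delta = np.abs(Xn - X).max()
        X = Xn
        if delta < tol:
            converged = True
            break
    x = X.sum(axis=1)
    T = X / x[:, None]
    pi = x / x.sum()
    w = _reversible_eigenvalues(T, pi)
    return TransitionModel(lag=c.lag, active_set=np.asarray(active_set),
                           T=T, pi=pi, eigenvalues=w,
                           frame_stride_ns=frame_stride_ns,
                           n_iterations=it, converged=converged)


def transition_log_likelihood(T: np.ndarray, C: np.ndarray) -> float:
    """log L = sum_ij C_ij log T_ij (terms with C_ij = 0 contribute 0)."""
    mask = C > 0
    return float(np.sum(C[mask] * np.log(T[mask])))


def estimate_msm(label_seqs, lag: int, frame_stride_ns: float = 1.0,
                 mode: str = "sliding"):
    """Counts -> largest connected set -> reversible MLE, in one call.

    Returns (model, active_set, retained_state_fraction,
    retained_count_fraction); the model's T lives on the active set and its
    ``active_set`` maps back to original microstate indices.
    """
    c = count_transitions(label_seqs, lag, mode=mode)
    active, fs, fc = largest_connected_set(c)
    model = estimate_reversible(restrict_counts(c, active), active_set=active,
                                frame_stride_ns=frame_stride_ns)
    return model, active, fs, fc


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def timescales_from_model(m: TransitionModel, n: int | None = None) -> np.ndarray:
    """Implied timescales -tau/ln|lambda_i| in frames for the non-unit
    eigenvalues, descending; +inf where |lambda| reaches 1."""
    w = m.eigenvalues[1:]
    if n is not None:
        w = w[:n]
    absw = np.abs(w)
    with np.errstate(divide="ignore"):
        ts = np.where(absw >= 1.0 - 1e-12, np.inf, -m.lag / np.log(absw))
    return ts


def implied_timescales(label_seqs, lags, n_timescales: int = 5,
                       frame_stride_ns: float = 1.0) -> pd.DataFrame:
    """Implied-timescale table over a list of lags (frames and physical
    time)."""
    rows = []
    for lag in lags:
        model, _, _, _ = estimate_msm(label_seqs, int(lag),
                                      frame_stride_ns=frame_stride_ns)
        ts = timescales_from_model(model, n_timescales)
        for i, t in enumerate(ts):
            rows.append({"lag_frames": int(lag), "index": i + 1,
                         "timescale_frames": t,
                         "timescale_ns": t * frame_stride_ns})
    return pd.DataFrame(rows)


def vamp2_score(m: TransitionModel, rank: int) -> float:
    """Sum of the squared top-``rank`` eigenvalues (including the unit
    eigenvalue) — the reversible VAMP-2 score."""
    if rank > m.n_states:
        raise ValueError("rank exceeds active-set size")
    return float(np.sum(m.eigenvalues[:rank] ** 2))


def _set_self_probability(T: np.ndarray, pi: np.ndarray, members: np.ndarray,
                          power: int) -> float:
    """pi-weighted probability of being in `members` after `power` steps,
    starting inside `members`."""
    Tk = np.linalg.matrix_power(T, power)
    w = pi[members] / pi[members].sum()
    return float(w @ Tk[np.ix_(members, members)].sum(axis=1))


def ck_test(label_seqs, m: TransitionModel, coarse_sets,
            k_values=(1, 2, 3, 4, 5),
            frame_stride_ns: float = 1.0) -> pd.DataFrame:
    """Chapman-Kolmogorov test on a partition of the active set.

    For each set S and factor k, compares the model prediction
    (propagating T^k) against the same quantity from a model re-estimated
    at lag k*tau.  ``coarse_sets`` contains original microstate indices.
    Returns a table with predicted, estimated and relative deviation;
    factors without sufficient data are skipped with a warning.
    """
    orig_to_active = {s: i for i, s in enumerate(m.active_set)}
    rows = []
    for k in k_values:
        lag_k = k * m.lag
        if all(len(s) <= lag_k for s in label_seqs):
            warnings.warn(f"insufficient data at lag {lag_k}; skipping k={k}")
            continue
        mk, active_k, _, _ = estimate_msm(label_seqs, lag_k,
                                          frame_stride_ns=frame_stride_ns)
        orig_to_k = {s: i for i, s in enumerate(active_k)}
        for si, S in enumerate(coarse_sets):
            S = np.asarray(S)
            mem = np.array([orig_to_active[s] for s in S if s in orig_to_active])
            mem_k = np.array([orig_to_k[s] for s in S if s in orig_to_k])
            if mem.size == 0 or mem_k.size == 0:
                continue
            pred = _set_self_probability(m.T, m.pi, mem, k)
            est = _set_self_probability(mk.T, mk.pi, mem_k, 1)
            rows.append({"set": si, "k": int(k), "lag_frames": int(lag_k),
                         "predicted": pred, "estimated": est,
                         "rel_deviation": abs(pred - est) / max(est, 1e-12)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCCA+ coarse-graining and MFPTs
# ---------------------------------------------------------------------------

@dataclass
class CoarseModel:
    n_macrostates: int
    memberships: np.ndarray          # (n_micro_active, m), rows sum to 1
    crisp: np.ndarray                # per active microstate macrostate index
    populations: np.ndarray          # pi summed over crisp members
    mfpt_frames: np.ndarray          # (m, m), diagonal 0
    mfpt_ns: np.ndarray
    micro_model: TransitionModel = field(repr=False)

    def macro_sets(self) -> list[np.ndarray]:
        """Original microstate indices per macrostate."""
        return [self.micro_model.active_set[self.crisp == i]
                for i in range(self.n_macrostates)]


def pcca_plus(m: TransitionModel, n_macrostates: int) -> CoarseModel:
    """PCCA+ metastable coarse-graining of a reversible transition matrix.

    Uses the inner-simplex vertex construction on the first ``n_macrostates``
    right eigenvectors: after normalising away the trivial constant
    eigenvector, the most extreme rows are taken as simplex vertices and the
    linear map sending them to the corners of the probability simplex yields
    fuzzy memberships, which are clipped to be non-negative and
    row-renormalised.
    """
    mm = int(n_macrostates)
    if not 2 <= mm <= m.n_states:
        raise ValueError("n_macrostates must be in [2, active-set size]")
    w, R = _reversible_eigenvectors(m.T, m.pi)
    if mm < m.n_states and abs(w[mm - 1] - w[mm]) < 1e-10:
        raise ValueError(
            f"degenerate eigenvalue at the cut (lambda_{mm} == lambda_{mm+1}); "
            "choose a different number of macrostates")
    Psi = R[:, :mm].copy()
    # normalise the trivial direction to the constant vector 1
    Psi[:, 0] = 1.0
    n = Psi.shape[0]

    if mm == n:
        memberships = np.eye(n)
    else:
        # inner-simplex vertex hunting on the non-trivial coordinates
        Y = Psi[:, 1:]
        vertices = [int(np.argmax((Y ** 2).sum(axis=1)))]
        # Gram-Schmidt residual distance from the affine span of chosen rows
        for _ in range(1, mm):
            V = Y[vertices]
            D = Y - V[0]
            B = V[1:] - V[0]
            if B.size:
                Q, _ = np.linalg.qr(B.T)
                D = D - (D @ Q) @ Q.T
            dist = (D ** 2).sum(axis=1)
            dist[vertices] = -1.0
            vertices.append(int(np.argmax(dist)))
        A = np.linalg.inv(Psi[vertices])
        memberships = Psi @ A
        memberships = np.clip(memberships, 0.0, None)
        memberships /= memberships.sum(axis=1, keepdims=True)

    crisp = memberships.argmax(axis=1)
    # require every macrostate non-empty in the crisp assignment
    for i in range(mm):
        if not (crisp == i).any():
            raise ValueError("empty macrostate in crisp assignment; "
                             "choose a different number of macrostates")
    pops = np.array([m.pi[crisp == i].sum() for i in range(mm)])
    order = np.argsort(-pops, kind="stable")
    remap = np.empty(mm, dtype=int)
    remap[order] = np.arange(mm)
    memberships = memberships[:, order]
    crisp = remap[crisp]
    pops = pops[order]

    mf = _macro_mfpt(m, crisp, mm)
    return CoarseModel(n_macrostates=mm, memberships=memberships, crisp=crisp,
                       populations=pops, mfpt_frames=mf,
                       mfpt_ns=mf * m.frame_stride_ns, micro_model=m)


def mfpt_to_set(m: TransitionModel, target: np.ndarray) -> np.ndarray:
    """Mean first-passage time (frames) from every microstate to a target
    set, solving (I - T_restricted) h = tau on non-target states."""
    n = m.n_states
    target = np.asarray(target)
    rest = np.setdiff1d(np.arange(n), target)
    h = np.zeros(n)
    if rest.size:
        A = np.eye(rest.size) - m.T[np.ix_(rest, rest)]
        b = np.full(rest.size, float(m.lag))
        h[rest] = np.linalg.solve(A, b)
    return h


def _macro_mfpt(m: TransitionModel, crisp: np.ndarray, mm: int) -> np.ndarray:
    """Pairwise macrostate MFPTs (frames): pi-weighted over source members
    of the first-passage time to the target member set."""
    out = np.zeros((mm, mm))
    for j in range(mm):
        tgt = np.nonzero(crisp == j)[0]
        h = mfpt_to_set(m, tgt)
        for i in range(mm):
            if i == j:
                continue
            src = np.nonzero(crisp == i)[0]
            w = m.pi[src] / m.pi[src].sum()
            out[i, j] = float(w @ h[src])
    return out


def mfpt(model: TransitionModel) -> np.ndarray:
    """Pairwise microstate MFPT matrix in frames (diagonal zero)."""
    n = model.n_states
    out = np.zeros((n, n))
    for j in range(n):
        h = mfpt_to_set(model, np.array([j]))
        out[:, j] = h
    np.fill_diagonal(out, 0.0)
    return out
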