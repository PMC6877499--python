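"""Synthetic torsion-trajectory ensembles with known metastable kinetics.

The generator emulates the statistical structure the downstream analysis
assumes for a CDR loop sampled by many short seeded simulations: a hidden
Markov chain over a few metastable conformational states (the "canonical"
states), independent per-angle von Mises emissions around each state's
median (omega, phi, psi) vector, optional cis states (omega near 0) and an
ensemble of many short trajectories started from configurable seeding
weights.  Because the hidden chain and its transition matrix are known
exactly, every downstream estimate (stationary distribution, implied
timescales, macrostate partition, MFPTs) can be checked against closed-form
ground truth.

Angles are handled in degrees externally, radians internally, wrapped to
[-180, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import TorsionSeries, wrap_degrees


@dataclass
class SyntheticSystemSpec:
    """Ground-truth definition of a synthetic metastable loop system.

    Attributes
    ----------
    n_states : int
        Number of hidden metastable states.
    loop_length : int
        Number of loop residues L.
    state_medians : ndarray, shape (n_states, L, 3)
        Per-state median (omega, phi, psi) in degrees.
    concentration : float or ndarray
        von Mises kappa (>= 0) for emissions; 0 means uniform angles.
        Scalar or broadcastable to (L, 3).
    true_T : ndarray, shape (n_states, n_states)
        Row-stochastic hidden transition matrix at unit frame lag.
    seeding_weights : ndarray, shape (n_states,)
        Probability vector for trajectory start states.
    frame_stride_ns : float
        Physical time per frame in nanoseconds.
    seed : int
        Master seed; per-trajectory streams are derived from it.
    """

    n_states: int
    loop_length: int
    state_medians: np.ndarray
    concentration: float | np.ndarray
    true_T: np.ndarray
    seeding_weights: np.ndarray
    frame_stride_ns: float = 0.1
    seed: int = 0
    stationary: np.ndarray = field(default=None, repr=False)
    no_transitions: bool = field(default=False, repr=False)


@dataclass
class LabeledEnsemble:
    """Trajectories plus their ground-truth hidden state labels."""

    trajectories: list[TorsionSeries]
    hidden_labels: list[np.ndarray]
    spec: SyntheticSystemSpec

    def __post_init__(self):
        if len(self.trajectories) != len(self.hidden_labels):
            raise ValueError("trajectory / label list length mismatch")
        for t, lab in zip(self.trajectories, self.hidden_labels):
            if t.n_frames != len(lab):
                raise ValueError("label array length != frame count")
            if lab.min() < 0 or lab.max() >= self.spec.n_states:
                raise ValueError("hidden label out of range")

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left Perron
    eigenvector, normalised)."""
    w, v = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def make_system_spec(n_states: int, loop_length: int, state_medians,
                     concentration, true_T, seeding_weights=None,
                     frame_stride_ns: float = 0.1,
                     seed: int = 0) -> SyntheticSystemSpec:
    """Validate parameters and assemble a :class:`SyntheticSystemSpec`.

    Raises ValueError naming the offending field for non-stochastic rows,
    negative concentration, or median/loop-length mismatches.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    T = np.asarray(true_T, dtype=float)
    if T.shape != (n_states, n_states):
        raise ValueError("true_T must be square of size n_states")
    if (T < 0).any():
        raise ValueError("true_T has negative entries")
    rowsum = T.sum(axis=1)
    bad = np.nonzero(np.abs(rowsum - 1.0) > 1e-12)[0]
    if bad.size:
        raise ValueError(f"row {bad[0]} not stochastic (sums to {rowsum[bad[0]]:g})")
    medians = wrap_degrees(np.asarray(state_medians, dtype=float))
    if medians.shape != (n_states, loop_length, 3):
        raise ValueError(
            f"state_medians shape {medians.shape} does not match "
            f"(n_states, loop_length, 3) = ({n_states}, {loop_length}, 3)")
    kappa = np.asarray(concentration, dtype=float)
    if (kappa < 0).any():
        raise ValueError("concentration (kappa) must be >= 0")
    if seeding_weights is None:
        w = np.full(n_states, 1.0 / n_states)
    else:
        w = np.asarray(seeding_weights, dtype=float)
        if w.shape != (n_states,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("seeding_weights must be a probability vector of length n_states")
    spec = SyntheticSystemSpec(
        n_states=n_states, loop_length=loop_length, state_medians=medians,
        concentration=kappa if kappa.ndim else float(kappa), true_T=T,
        seeding_weights=w, frame_stride_ns=float(frame_stride_ns),
        seed=int(seed))
    spec.stationary = stationary_distribution(T)
    spec.no_transitions = bool(np.allclose(T, np.eye(n_states)))
    return spec


def simulate_hidden_chain(spec: SyntheticSystemSpec, n_frames: int,
                          start_state: int,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate the hidden Markov chain for ``n_frames`` frames."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0 <= start_state < spec.n_states:
        raise ValueError(f"start_state {start_state} out of range")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cum = np.cumsum(spec.true_T, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_frames - 1)
    states = np.empty(n_frames, dtype=np.int64)
    states[0] = start_state
    s = start_state
    for t in range(1, n_frames):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        states[t] = s
    return states


def emit_torsions(labels: np.ndarray, spec: SyntheticSystemSpec,
                  rng: np.random.Generator | None = None) -> TorsionSeries:
    """Emit per-frame torsions around the state medians.

    Each angle is drawn independently from a von Mises distribution centred
    on the state median with the spec's concentration; kappa = 0 yields
    uniform angles.
    """
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= spec.n_states:
        raise ValueError("label out of range")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mu = np.radians(spec.state_medians[labels])          # (n, L, 3)
    kappa = np.broadcast_to(np.asarray(spec.concentration, dtype=float),
                            mu.shape)
    ang = wrap_degrees(np.degrees(rng.vonmises(mu, kappa)))
    # terminal torsions are undefined on a real loop; keep the convention
    ang[:, 0, 0] = np.nan   # omega of first residue
    ang[:, 0, 1] = np.nan   # phi of first residue
    ang[:, -1, 2] = np.nan  # psi of last residue
    return TorsionSeries(ang, frame_stride_ns=spec.frame_stride_ns)


def generate_ensemble(spec: SyntheticSystemSpec, n_traj: int,
                      traj_len: int) -> LabeledEnsemble:
    """Generate ``n_traj`` independent trajectories of ``traj_len`` frames.

    Start states are drawn from the seeding weights.  Each trajectory uses
    its own RNG stream derived from the master seed, so the ensemble is
    reproducible and order-independent.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    trajs: list[TorsionSeries] = []
    labels: list[np.ndarray] = []
    cum_w = np.cumsum(spec.seeding_weights)
    cum_w[-1] = 1.0
    for i in range(n_traj):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        start = int(np.searchsorted(cum_w, rng.random(), side="right"))
        lab = simulate_hidden_chain(spec, traj_len, start, rng=rng)
        trajs.append(emit_torsions(lab, spec, rng=rng))
        labels.append(lab)
    return LabeledEnsemble(trajs, labels, spec)


# ---------------------------------------------------------------------------
# Reference synthetic systems
# ---------------------------------------------------------------------------

def _base_median(L: int) -> np.ndarray:
    """Extended-like loop: omega 180 (trans), phi -140, psi 135."""
    m = np.empty((L, 3))
    m[:, 0] = -180.0   # 180 == -180 after wrapping
    m[:, 1] = -140.0
    m[:, 2] = 135.0
    return m


def default_spec(seed: int = 0, kappa: float = 8.0,
                 frame_stride_ns: float = 0.1) -> SyntheticSystemSpec:
    """Desk-scale 4-state system for a 9-residue loop.

    One state carries a cis peptide bond (omega near 0) at residue index 6,
    mimicking a cis7 canonical cluster; the other states differ in phi/psi
    of several central residues.  The transition matrix is metastable with
    a slowest relaxation time of roughly 100 frames.
    """
    L = 9
    m = np.stack([_base_median(L)] * 4)
    # state 1: central psi flip (helix-like turn)
    m[1, 3:6, 2] = -30.0
    m[1, 3:6, 1] = -60.0
    # state 2: cis omega at residue 6 plus local phi change
    m[2, 6, 0] = 0.0
    m[2, 5:8, 2] = 60.0
    # state 3: polyproline-like stretch
    m[3, 2:7, 1] = -75.0
    m[3, 2:7, 2] = 160.0 - 360.0 * 0.0  # 160 deg
    T = np.array([
        [0.985, 0.010, 0.004, 0.001],
        [0.008, 0.980, 0.010, 0.002],
        [0.004, 0.012, 0.980, 0.004],
        [0.002, 0.004, 0.008, 0.986],
    ])
    return make_system_spec(4, L, m, kappa, T,
                            frame_stride_ns=frame_stride_ns, seed=seed)


def two_state_spec(seed: int = 0, kappa: float = 8.0,
                   p_switch: float = 0.02,
                   frame_stride_ns: float = 0.1) -> SyntheticSystemSpec:
    """Two metastable states of a 5-residue loop (tICA discrimination test)."""
    L = 5
    m = np.stack([_base_median(L)] * 2)
    m[1, 1:4, 1] = -60.0
    m[1, 1:4, 2] = -45.0
    T = np.array([[1 - p_switch, p_switch], [p_switch, 1 - p_switch]])
    return make_system_spec(2, L, m, kappa, T,
                            frame_stride_ns=frame_stride_ns, seed=seed)


def three_state_spec(seed: int = 0, kappa: float = 8.0,
                     frame_stride_ns: float = 0.1) -> SyntheticSystemSpec:
    """Three metastable states of a 7-residue loop, one cis (canonical
    mapping and kinetics-report tests)."""
    L = 7
    m = np.stack([_base_median(L)] * 3)
    m[1, 2:5, 1] = -60.0
    m[1, 2:5, 2] = -40.0
    m[2, 4, 0] = 0.0          # cis at residue 4
    m[2, 3:6, 2] = 70.0
    T = np.array([
        [0.980, 0.015, 0.005],
        [0.010, 0.982, 0.008],
        [0.005, 0.010, 0.985],
    ])
    return make_system_spec(3, L, m, kappa, T,
                            frame_stride_ns=frame_stride_ns, seed=seed)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def ensemble_to_frames(ens: LabeledEnsemble) -> pd.DataFrame:
    """Long-format torsion table: traj_id, frame, residue_index, omega/phi/psi."""
    parts = []
    for i, t in enumerate(ens.trajectories):
        n, L, _ = t.angles.shape
        df = pd.DataFrame({
            "traj_id": np.repeat(i, n * L),
            "frame": np.repeat(np.arange(n), L),
            "residue_index": np.tile(np.arange(L), n),
            "omega_deg": t.angles[:, :, 0].ravel(),
            "phi_deg": t.angles[:, :, 1].ravel(),
            "psi_deg": t.angles[:, :, 2].ravel(),
        })
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def write_ensemble(ens: LabeledEnsemble, torsion_path, label_path=None,
                   spec_path=None) -> None:
    """Write torsions (TSV), ground-truth labels (TSV) and the spec
    (key-value text)."""
    ensemble_to_frames(ens).to_csv(torsion_path, sep="\t", index=False,
                                   float_format="%.6f")
    if label_path is not None:
        rows = []
        for i, lab in enumerate(ens.hidden_labels):
            rows.append(pd.DataFrame({
                "traj_id": np.repeat(i, len(lab)),
                "frame": np.arange(len(lab)),
                "state": lab,
            }))
        pd.concat(rows, ignore_index=True).to_csv(label_path, sep="\t", index=False)
    if spec_path is not None:
        write_spec(ens.spec, spec_path)


def write_spec(spec: SyntheticSystemSpec, path) -> None:
    """Serialise a spec as a flat key=value text file (arrays as flat
    comma-separated floats)."""
    def flat(a):
        return ",".join(f"{v:.10g}" for v in np.asarray(a, dtype=float).ravel())
    lines = [
        f"n_states={spec.n_states}",
        f"loop_length={spec.loop_length}",
        f"concentration={flat(spec.concentration)}",
        f"frame_stride_ns={spec.frame_stride_ns:.10g}",
        f"seed={spec.seed}",
        f"true_T={flat(spec.true_T)}",
        f"seeding_weights={flat(spec.seeding_weights)}",
        f"state_medians={flat(spec.state_medians)}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_spec(path) -> SyntheticSystemSpec:
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()
    n = int(kv["n_states"])
    L = int(kv["loop_length"])
    arr = lambda key: np.array([float(x) for x in kv[key].split(",")])
    kappa = arr("concentration")
    kappa = float(kappa[0]) if kappa.size == 1 else kappa.reshape(L, 3)
    return make_system_spec(
        n, L, arr("state_medians").reshape(n, L, 3), kappa,
        arr("true_T").reshape(n, n), arr("seeding_weights"),
        frame_stride_ns=float(kv["frame_stride_ns"]), seed=int(kv["seed"]))


def read_ensemble(torsion_path, label_path=None, spec=None,
                  frame_stride_ns: float = 0.1) -> LabeledEnsemble | list[TorsionSeries]:
    """Read a torsion TSV back into trajectories (and labels if given)."""
    df = pd.read_csv(torsion_path, sep="\t")
    trajs = []
    order = []
    for tid, g in df.groupby("traj_id", sort=True):
        L = int(g["residue_index"].max()) + 1
        n = int(g["frame"].max()) + 1
        g = g.sort_values(["frame", "residue_index"])
        ang = np.stack([
            g["omega_deg"].to_numpy().reshape(n, L),
            g["phi_deg"].to_numpy().reshape(n, L),
            g["psi_deg"].to_numpy().reshape(n, L),
        ], axis=2)
        stride = spec.frame_stride_ns if spec is not None else frame_stride_ns
        trajs.append(TorsionSeries(wrap_degrees(ang), frame_stride_ns=stride))
        order.append(tid)
    if label_path is None:
        return trajs
    lf = pd.read_csv(label_path, sep="\t")
    labels = [lf[lf["traj_id"] == tid].sort_values("frame")["state"].to_numpy()
              for tid in order]
    return LabeledEnsemble(trajs, labels, spec)
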