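"""Canonical-cluster medians, dihedral-distance assignment, kinetics report.

A canonical cluster is a discrete backbone conformation class of a CDR loop
of given length, named like ``L3-9-cis7-1`` (chain-loop, length, cis
peptide positions, index).  Its median torsion vector serves as an
assignment reference: frames and macrostates are mapped to the nearest
median under a bounded circular metric, and the macrostate kinetic model
then yields transition timescales *between canonical clusters* — including
the case where several medians share one kinetic minimum.

The metric is the squared-chord circular distance averaged over the
included angles,

    d(a, b) = mean_theta 2 (1 - cos(delta_theta)),

bounded in [0, 4]; phi/psi are included by default and omega can be added
to discriminate cis states.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TorsionSeries, wrap_degrees

_ANGLE_INDEX = {"omega": 0, "phi": 1, "psi": 2}
_NAME_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)-(\d+)-(?:cis([\d,]+)-)?(\d+)$")


@dataclass
class CanonicalMedian:
    """Named canonical-cluster median torsion vector."""

    name: str
    torsions: np.ndarray             # (L, 3) degrees
    source_id: str | None = None

    def __post_init__(self):
        self.torsions = wrap_degrees(np.asarray(self.torsions, dtype=float))
        loop, length, cis, idx = parse_median_name(self.name)
        if length != self.torsions.shape[0]:
            raise ValueError(
                f"median {self.name!r}: name says length {length}, "
                f"torsion vector has {self.torsions.shape[0]} residues")

    @property
    def loop_length(self) -> int:
        return self.torsions.shape[0]


def parse_median_name(name: str):
    """Parse ``<loop>-<length>-[cis<positions>-]<index>`` (e.g.
    L3-9-cis7-1) into (loop, length, cis_positions, index)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"unparseable canonical cluster name {name!r}")
    loop, length, cis, idx = m.groups()
    cis_positions = tuple(int(p) for p in cis.split(",")) if cis else ()
    return loop, int(length), cis_positions, int(idx)


def dihedral_distance(a, b, include=frozenset({"phi", "psi"})) -> float:
    """Mean squared-chord circular distance over the included angle types.

    Angles undefined (NaN) in either vector are skipped; result is 0 iff
    all included angles agree mod 360.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("torsion vector length mismatch")
    if not include:
        raise ValueError("empty include set")
    cols = [_ANGLE_INDEX[x] for x in include]
    da = np.radians(a[..., cols] - b[..., cols])
    vals = 2.0 * (1.0 - np.cos(da))
    mask = np.isfinite(vals)
    if not mask.any():
        raise ValueError("no defined angles in common")
    return float(vals[mask].mean())


def read_median_library(path) -> list[CanonicalMedian]:
    """Read a median library text file.

    Format, one record per line (``#`` comments allowed)::

        <name> <loop_length> <omega_1> <phi_1> <psi_1> ... <omega_L> <phi_L> <psi_L>
    """
    medians = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            name, L = parts[0], int(parts[1])
            vals = [float(x) for x in parts[2:]]
            if len(vals) != 3 * L:
                raise ValueError(f"line {ln}: expected {3 * L} angles, got {len(vals)}")
            medians.append(CanonicalMedian(name, np.array(vals).reshape(L, 3)))
    if not medians:
        raise ValueError("empty median library")
    return medians


def write_median_library(medians: list[CanonicalMedian], path) -> None:
    with open(path, "w") as fh:
        for m in medians:
            angles = " ".join(f"{v:.4f}" for v in m.torsions.ravel())
            fh.write(f"{m.name} {m.loop_length} {angles}\n")


def assign_frames(t: TorsionSeries, medians: list[CanonicalMedian],
                  radius: float | None = None,
                  include=frozenset({"phi", "psi"})) -> pd.DataFrame:
    """Nearest-median assignment of every frame.

    Frames farther than ``radius`` from all medians are labelled
    ``unassigned``; distance ties are broken by lexicographic name.
    Returns a frame-indexed table with columns (name, distance).
    """
    if not medians:
        raise ValueError("empty median list")
    med = sorted(medians, key=lambda m: m.name)
    for m in med:
        if m.loop_length != t.loop_length:
            raise ValueError(f"median {m.name!r} length {m.loop_length} != "
                             f"loop length {t.loop_length}")
    cols = [_ANGLE_INDEX[x] for x in include]
    frames = np.radians(t.angles[:, :, cols])         # (n, L, |cols|)
    dists = np.empty((t.n_frames, len(med)))
    for j, m in enumerate(med):
        ref = np.radians(m.torsions[:, cols])
        vals = 2.0 * (1.0 - np.cos(frames - ref))
        mask = np.isfinite(vals)
        dists[:, j] = np.where(mask, vals, 0.0).sum(axis=(1, 2)) / mask.sum(axis=(1, 2))
    best = dists.argmin(axis=1)                       # first index wins ties
    names = np.array([m.name for m in med], dtype=object)[best]
    dmin = dists[np.arange(t.n_frames), best]
    if radius is not None:
        names = np.where(dmin > radius, "unassigned", names)
    return pd.DataFrame({"name": names, "distance": dmin})


@dataclass
class CanonicalReport:
    """Macrostate populations, hosted canonical clusters, pair kinetics."""

    populations: np.ndarray                      # per macrostate
    hosted: dict[int, list[str]]                 # macrostate -> median names
    unobserved: list[str]
    representative_frames: dict[int, int]        # macrostate -> global frame idx
    pair_mfpt_ns: pd.DataFrame                   # from, to, mfpt_ns, same_minimum
    frame_stride_ns: float = 1.0

    def to_json(self) -> str:
        obj = {
            "populations": [float(p) for p in self.populations],
            "hosted": {str(k): sorted(v) for k, v in sorted(self.hosted.items())},
            "unobserved": sorted(self.unobserved),
            "representative_frames": {str(k): int(v) for k, v in
                                      sorted(self.representative_frames.items())},
            "pair_mfpt_ns": self.pair_mfpt_ns.to_dict(orient="records"),
            "frame_stride_ns": self.frame_stride_ns,
        }
        return json.dumps(obj, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CanonicalReport":
        obj = json.loads(text)
        return cls(
            populations=np.array(obj["populations"]),
            hosted={int(k): list(v) for k, v in obj["hosted"].items()},
            unobserved=list(obj["unobserved"]),
            representative_frames={int(k): int(v) for k, v in
                                   obj["representative_frames"].items()},
            pair_mfpt_ns=pd.DataFrame(obj["pair_mfpt_ns"]),
            frame_stride_ns=float(obj["frame_stride_ns"]),
        )


def map_medians_to_macrostates(medians: list[CanonicalMedian], trajs,
                               coarse, micro_labels, radius: float = 1.0,
                               include=frozenset({"phi", "psi"})):
    """Assign each median to the macrostate of its nearest frame.

    ``trajs`` is the list of TorsionSeries the MSM was built from;
    ``micro_labels`` the per-trajectory microstate label arrays (original
    indices); ``coarse`` the CoarseModel.  A median whose nearest frame is
    farther than ``radius`` is listed unobserved.  Returns (hosted,
    unobserved, nearest_frame) with global frame indexing.
    """
    if not medians:
        raise ValueError("empty median list")
    angles = np.concatenate([t.angles for t in trajs], axis=0)
    labels = np.concatenate([np.asarray(l) for l in micro_labels])
    if angles.shape[0] != labels.shape[0]:
        raise ValueError("frame/label count mismatch")
    micro = coarse.micro_model
    active_map = {s: i for i, s in enumerate(micro.active_set)}
    cols = [_ANGLE_INDEX[x] for x in include]
    frames = np.radians(angles[:, :, cols])
    hosted: dict[int, list[str]] = {}
    unobserved: list[str] = []
    nearest_frame: dict[str, int] = {}
    for m in sorted(medians, key=lambda x: x.name):
        ref = np.radians(m.torsions[:, cols])
        vals = 2.0 * (1.0 - np.cos(frames - ref))
        mask = np.isfinite(vals)
        dist = np.where(mask, vals, 0.0).sum(axis=(1, 2)) / mask.sum(axis=(1, 2))
        # only frames inside the active set can carry a macrostate
        in_active = np.isin(labels, micro.active_set)
        dist_a = np.where(in_active, dist, np.inf)
        j = int(np.argmin(dist_a))
        if not np.isfinite(dist_a[j]) or dist_a[j] > radius:
            unobserved.append(m.name)
            continue
        macro = int(coarse.crisp[active_map[int(labels[j])]])
        hosted.setdefault(macro, []).append(m.name)
        nearest_frame[m.name] = j
    return hosted, unobserved, nearest_frame


def kinetics_report(coarse, hosted: dict[int, list[str]],
                    unobserved: list[str],
                    representative_frames: dict[int, int] | None = None,
                    frame_stride_ns: float | None = None) -> CanonicalReport:
    """Final canonical-transition kinetics report.

    Canonical-pair MFPTs are the macrostate MFPTs of the host macrostates
    in physical time; pairs sharing a macrostate are flagged as belonging
    to the same kinetic minimum with MFPT 0.
    """
    stride = (coarse.micro_model.frame_stride_ns
              if frame_stride_ns is None else frame_stride_ns)
    mf_ns = coarse.mfpt_frames * stride
    host_of = {name: macro for macro, names in hosted.items() for name in names}
    rows = []
    names = sorted(host_of)
    for a in names:
        for b in names:
            if a == b:
                continue
            ma, mb = host_of[a], host_of[b]
            same = ma == mb
            rows.append({"from": a, "to": b,
                         "mfpt_ns": 0.0 if same else float(mf_ns[ma, mb]),
                         "same_minimum": bool(same)})
    pair_df = pd.DataFrame(rows, columns=["from", "to", "mfpt_ns", "same_minimum"])
    return CanonicalReport(
        populations=coarse.populations,
        hosted={k: sorted(v) for k, v in hosted.items()},
        unobserved=sorted(unobserved),
        representative_frames=representative_frames or {},
        pair_mfpt_ns=pair_df,
        frame_stride_ns=stride,
    )
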