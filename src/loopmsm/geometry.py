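"""Backbone geometry: PDB multi-model I/O, torsions, chain building, RMSD.

A loop conformation is represented by its backbone N/CA/C atoms only
(:class:`BackboneChain`); side chains carry no information used anywhere in
the analysis.  Torsions follow the IUPAC sign convention:

    omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i)
    phi(i)   = C(i-1)-N(i)-CA(i)-C(i)
    psi(i)   = N(i)-CA(i)-C(i)-N(i+1)

so omega and phi are undefined for the first residue and psi for the last;
undefined torsions are stored as NaN, never zero-filled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

# Ideal backbone internal coordinates used for torsion -> coordinate
# building (Engh/Huber-style averages, Angstrom and degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

_BACKBONE_ATOMS = ("N", "CA", "C")


def wrap_degrees(a):
    """Wrap angles to the canonical torsion interval [-180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class BackboneChain:
    """Ordered backbone N/CA/C coordinates of one loop conformation.

    ``coords`` has shape (n_residues, 3, 3): residue x atom (N, CA, C) x xyz,
    in Angstrom.
    """

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (3, 3):
            raise ValueError("coords must have shape (n_residues, 3, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def atoms(self) -> np.ndarray:
        """Flat (3*n_residues, 3) atom array in N, CA, C order per residue."""
        return self.coords.reshape(-1, 3)


@dataclass
class TorsionSeries:
    """Per-frame (omega, phi, psi) angles of a loop, in degrees.

    ``angles`` has shape (n_frames, loop_length, 3); undefined terminal
    torsions are NaN.  ``frame_stride_ns`` is the physical time per frame.
    """

    angles: np.ndarray
    frame_stride_ns: float = 1.0

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 3 or self.angles.shape[2] != 3:
            raise ValueError("angles must have shape (n_frames, loop_length, 3)")
        defined = self.angles[np.isfinite(self.angles)]
        if defined.size and (defined.min() < -180.0 or defined.max() >= 180.0):
            raise ValueError("angles must lie in [-180, 180)")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def loop_length(self) -> int:
        return self.angles.shape[1]


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate dihedral: three collinear defining atoms")
    b1u = b1 / np.linalg.norm(b1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1u))
    return float(wrap_degrees(np.degrees(np.arctan2(y, x))))


def compute_torsions(chains: list[BackboneChain],
                     frame_stride_ns: float = 1.0) -> TorsionSeries:
    """Compute per-frame (omega, phi, psi) for a list of conformations.

    All chains must have the same residue count.  Terminal omega/phi of the
    first residue and psi of the last are NaN.
    """
    if not chains:
        raise ValueError("no chains given")
    L = chains[0].n_residues
    if L < 2:
        raise ValueError("need >= 2 residues for any torsion")
    if any(c.n_residues != L for c in chains):
        raise ValueError("chains differ in residue count")
    out = np.full((len(chains), L, 3), np.nan)
    for f, ch in enumerate(chains):
        N, CA, C = ch.coords[:, 0], ch.coords[:, 1], ch.coords[:, 2]
        for i in range(L):
            if i > 0:
                out[f, i, 0] = dihedral(CA[i - 1], C[i - 1], N[i], CA[i])
                out[f, i, 1] = dihedral(C[i - 1], N[i], CA[i], C[i])
            if i < L - 1:
                out[f, i, 2] = dihedral(N[i], CA[i], C[i], N[i + 1])
    return TorsionSeries(out, frame_stride_ns=frame_stride_ns)


def _place_atom(a, b, c, bond: float, angle_deg: float,
                torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |c-d| = bond, angle(b,c,d) and
    dihedral(a,b,c,d) as given."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    # local displacement in the frame of the b->c bond
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone(torsions: np.ndarray, loop_length: int | None = None) -> BackboneChain:
    """Build backbone coordinates from per-residue (omega, phi, psi) degrees.

    Uses sequential natural-extension (NeRF) placement with fixed ideal bond
    lengths and angles (module constants).  ``torsions`` has shape (L, 3);
    the unused terminal entries (omega/phi of residue 0, psi of the last
    residue) may be NaN.
    """
    t = np.asarray(torsions, dtype=float)
    if t.ndim != 2 or t.shape[1] != 3:
        raise ValueError("torsions must have shape (loop_length, 3)")
    L = t.shape[0] if loop_length is None else int(loop_length)
    if L != t.shape[0]:
        raise ValueError("loop_length does not match torsion array")
    if L < 2:
        raise ValueError("loop_length must be >= 2")

    coords = np.zeros((L, 3, 3))
    # residue 0: N at origin, CA on x, C in the xy-plane
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, L):
        Np, CAp, Cp = coords[i - 1]
        Ni = _place_atom(Np, CAp, Cp, BOND_C_N, ANGLE_CA_C_N, t[i - 1, 2])
        CAi = _place_atom(CAp, Cp, Ni, BOND_N_CA, ANGLE_C_N_CA, t[i, 0])
        Ci = _place_atom(Cp, Ni, CAi, BOND_CA_C, ANGLE_N_CA_C, t[i, 1])
        coords[i] = (Ni, CAi, Ci)
    return BackboneChain(coords)


def kabsch_rmsd(a: BackboneChain | np.ndarray, b: BackboneChain | np.ndarray) -> float:
    """Minimum RMSD between two atom sets over proper rotations+translations.

    Reflections are forbidden (rotation determinant +1), preserving
    chirality.  Inputs are BackboneChains or plain (n, 3) arrays with equal
    atom counts.
    """
    pa = a.atoms if isinstance(a, BackboneChain) else np.asarray(a, dtype=float)
    pb = b.atoms if isinstance(b, BackboneChain) else np.asarray(b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("atom count mismatch")
    if pa.shape[0] < 3:
        raise ValueError("need >= 3 atoms")
    ca = pa - pa.mean(axis=0)
    cb = pb - pb.mean(axis=0)
    H = ca.T @ cb
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = cb - ca @ R.T
    return float(np.sqrt((diff ** 2).sum() / pa.shape[0]))


def read_models(pdb_source, chain_id: str | None = None,
                residue_range: tuple[int, int] | None = None) -> list[BackboneChain]:
    """Read all models of a PDB file/stream into BackboneChains.

    ``residue_range`` is a 0-based half-open index range on the residues of
    the parsed chain (loop selection); ``chain_id`` restricts to one chain.
    Missing backbone atoms in the selection raise an error naming the
    residue.
    """
    if isinstance(pdb_source, str) and "\n" not in pdb_source:
        pdb = PDBFile.read(pdb_source)
    elif isinstance(pdb_source, str):
        pdb = PDBFile.read(io.StringIO(pdb_source))
    else:
        pdb = PDBFile.read(pdb_source)
    stack = pdb.get_structure(model=None)
    if stack.array_length() == 0:
        raise ValueError("empty selection: no atoms in PDB input")
    chains: list[BackboneChain] = []
    for model in stack:
        sel = np.isin(model.atom_name, _BACKBONE_ATOMS)
        if chain_id is not None:
            sel &= model.chain_id == chain_id
        sub = model[sel]
        if sub.array_length() == 0:
            raise ValueError("empty selection")
        res_ids = []
        for rid in sub.res_id:
            if rid not in res_ids:
                res_ids.append(rid)
        if residue_range is not None:
            lo, hi = residue_range
            res_ids = res_ids[lo:hi]
            if not res_ids:
                raise ValueError("empty selection: residue range selects nothing")
        coords = np.empty((len(res_ids), 3, 3))
        for j, rid in enumerate(res_ids):
            res_mask = sub.res_id == rid
            for k, name in enumerate(_BACKBONE_ATOMS):
                m = res_mask & (sub.atom_name == name)
                if not m.any():
                    raise ValueError(f"residue {rid} missing {name}")
                coords[j, k] = sub.coord[m][0]
        chains.append(BackboneChain(coords))
    return chains


def write_models(chains: list[BackboneChain], residue_name: str = "ALA") -> str:
    """Write conformations as a multi-model PDB text block."""
    if not chains:
        raise ValueError("no chains to write")
    for ch in chains:
        if np.abs(ch.coords).max() >= 10000.0:
            raise ValueError("coordinate field overflow: |coord| >= 10000 A")
    n_res = chains[0].n_residues
    template = bst.AtomArray(3 * n_res)
    template.chain_id[:] = "A"
    template.res_name[:] = residue_name
    template.element[:] = [a[0] for _ in range(n_res) for a in _BACKBONE_ATOMS]
    template.atom_name[:] = list(_BACKBONE_ATOMS) * n_res
    template.res_id[:] = np.repeat(np.arange(1, n_res + 1), 3)
    stack = bst.stack([template] * len(chains))
    for i, ch in enumerate(chains):
        if ch.n_residues != n_res:
            raise ValueError("chains differ in residue count")
        stack.coord[i] = ch.atoms
    pdb = PDBFile()
    pdb.set_structure(stack)
    buf = io.StringIO()
    pdb.write(buf)
    text = buf.getvalue()
    if "MODEL" not in text:
        # keep explicit MODEL/ENDMDL records even for a single model
        body = [l for l in text.splitlines() if l.startswith(("ATOM", "HETATM"))]
        text = "MODEL        1\n" + "\n".join(body) + "\nENDMDL\nEND\n"
    return text
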