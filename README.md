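# loopmsm

Markov-state modelling of protein loop conformational ensembles, built for
antibody CDR loops and the question of how a loop moves *between* its
canonical structures.

Crystallography assigns a CDR loop of a given length to one of a small set
of canonical backbone conformations. In solution, however, a loop is an
ensemble: it interconverts between those conformations on microsecond and
slower timescales. `loopmsm` characterises that ensemble from per-frame
backbone torsions (ω, φ, ψ):

1. **Featurization** — each torsion θ enters as (sin θ, cos θ), removing
   the ±180° wrap.
2. **tICA** — the generalized eigenproblem `C_τ v = λ C₀ v` (instantaneous
   vs. symmetrized time-lagged covariance) extracts the slowest linear
   modes; implied timescales are `t_i = −τ/ln|λ_i|`.
3. **MSM** — k-means microstates in tIC space, sliding-window transition
   counts restricted to the largest strongly connected set, and a
   reversible maximum-likelihood transition matrix from the
   detailed-balance fixed point
   `x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j)`.
   Validation: implied timescales, VAMP-2 score, Chapman–Kolmogorov test.
4. **PCCA+** — spectral coarse-graining of microstates into metastable
   macrostates; populations from the stationary distribution π and
   mean first-passage times from the standard linear system.
5. **Canonical mapping** — canonical-cluster medians (named like
   `L3-9-cis7-1`) are assigned to macrostates by the bounded circular
   metric `d(a,b) = mean 2(1 − cos Δθ)`, yielding populations and
   MFPTs *between canonical clusters*, including the case where several
   medians share one kinetic minimum.

Around this core the package provides backbone geometry (multi-model PDB
I/O, torsion computation, NeRF torsion→coordinate building, Kabsch RMSD),
average-linkage conformational clustering with a distance cut-off, a
desk-scale well-tempered metadynamics sampler on analytic periodic
potentials, and a synthetic torsion-trajectory generator whose hidden
Markov chain and von Mises emissions are known exactly — the ground truth
every estimator is validated against.

## Worked example

Run the full pipeline on the built-in three-state synthetic system (a
7-residue loop with one cis-containing state):

```sh
loopmsm pipeline --set system=three_state --set n_traj=8 --set traj_len=600 \
    --set m_macro=3 --set k_micro=30 --set seed=5 --out run
loopmsm report run
```

which prints

```
macrostate populations: [0.402, 0.315, 0.283]
macrostate 0: L3-7-2
macrostate 1: L3-7-cis5-3
macrostate 2: L3-7-1
L3-7-1 -> L3-7-2: 6.2 ns
L3-7-1 -> L3-7-cis5-3: 17.7 ns
L3-7-2 -> L3-7-1: 10.7 ns
L3-7-2 -> L3-7-cis5-3: 16.0 ns
L3-7-cis5-3 -> L3-7-1: 15.4 ns
L3-7-cis5-3 -> L3-7-2: 9.3 ns
```

Each macrostate hosts one canonical median; the numbers are macrostate
populations (stationary probability mass) and pairwise mean first-passage
times in nanoseconds at the 0.1 ns frame stride. With the generator's
transition matrix known, these can be compared directly against the
analytic stationary distribution and MFPTs — that comparison is what the
test suite automates. The same pipeline accepts real data as a torsion TSV
or a multi-model PDB plus a user-supplied canonical-median library.

## Layout

- `src/loopmsm/synthetic.py` — ground-truth generator (hidden chain, von
  Mises emissions, ensemble I/O)
- `src/loopmsm/geometry.py` — PDB models, torsions, NeRF build, Kabsch RMSD
- `src/loopmsm/features.py` — sin/cos features, ψ-sum collective variable
- `src/loopmsm/metad.py` — well-tempered metadynamics, FES reconstruction
- `src/loopmsm/clustering.py` — average-linkage clustering with cut-off
- `src/loopmsm/tica.py` — tICA fit/transform, permutation noise bound
- `src/loopmsm/msm.py` — counts, connectivity, reversible MLE, CK test,
  PCCA+, MFPTs
- `src/loopmsm/canonical.py` — median library, dihedral metric, kinetics
  report
- `src/loopmsm/pipeline.py`, `cli.py` — orchestration and `loopmsm` CLI

See `docs/methods.md` for the models, parameter choices and limitations.
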