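"""End-to-end pipeline: generate -> featurize -> cluster -> tICA -> MSM ->
PCCA+ -> canonical kinetics report.

One reproducible run per output directory: every stage writes its outputs
and parameters, a manifest records the seed, config hash and package
version, and identical config + seed produces byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .canonical import (CanonicalMedian, kinetics_report,
                        map_medians_to_macrostates, read_median_library,
                        write_median_library)
from .clustering import average_linkage_cluster, pairwise_distance_matrix, \
    transition_series
from .features import torsions_to_features
from .msm import (cluster_microstates, estimate_msm, pcca_plus,
                  timescales_from_model, vamp2_score)
from .synthetic import (LabeledEnsemble, default_spec, generate_ensemble,
                        read_ensemble, read_spec, three_state_spec,
                        two_state_spec, write_ensemble)
from .tica import fit_tica, tica_transform

log = logging.getLogger("loopmsm")


class PipelineError(RuntimeError):
    """Stage failure; the message names the stage and offending parameter."""


_REFERENCE_SPECS = {
    "default4": default_spec,
    "two_state": two_state_spec,
    "three_state": three_state_spec,
}


@dataclass
class PipelineConfig:
    """Flat pipeline configuration (key=value file representable)."""

    input: str = "synthetic"          # synthetic | torsion TSV path
    system: str = "default4"          # reference system name or spec file path
    seed: int = 0
    n_traj: int = 20
    traj_len: int = 1000
    include_omega: bool = False       # add omega to MSM features
    cluster_epsilon: float = 1.0
    cluster_metric: str = "dihedral-distance"
    cluster_max_frames: int = 300
    tica_lag_ns: float = 1.0
    tica_dim: int = 0                 # 0 = kinetic-variance rule
    k_micro: int = 75
    msm_lag_ns: float = 1.0
    m_macro: int = 4
    median_library: str = ""          # empty = derive from synthetic spec
    assign_radius: float = 1.0
    write_torsions: bool = False

    @classmethod
    def from_file(cls, path, overrides=()) -> "PipelineConfig":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                kv[k.strip()] = v.strip()
        for ov in overrides:
            k, _, v = ov.partition("=")
            kv[k.strip()] = v.strip()
        return cls._from_dict(kv)

    @classmethod
    def _from_dict(cls, kv: dict) -> "PipelineConfig":
        cfg = cls()
        casts = {f.name: f.type for f in fields(cls)}
        for k, v in kv.items():
            if k not in casts:
                raise PipelineError(f"config: unknown key {k!r}")
            cur = getattr(cfg, k)
            if isinstance(cur, bool):
                setattr(cfg, k, v.lower() in ("1", "true", "yes"))
            elif isinstance(cur, int):
                setattr(cfg, k, int(v))
            elif isinstance(cur, float):
                setattr(cfg, k, float(v))
            else:
                setattr(cfg, k, v)
        return cfg

    def config_hash(self) -> str:
        text = "\n".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_input(cfg: PipelineConfig):
    if cfg.input == "synthetic":
        if cfg.system in _REFERENCE_SPECS:
            spec = _REFERENCE_SPECS[cfg.system](seed=cfg.seed)
        else:
            spec = read_spec(cfg.system)
        ens = generate_ensemble(spec, cfg.n_traj, cfg.traj_len)
        return ens.trajectories, spec, ens
    trajs = read_ensemble(cfg.input)
    return trajs, None, None


def _derive_medians(spec) -> list[CanonicalMedian]:
    """Name each synthetic state median in canonical-cluster notation;
    cis positions are the 1-based residues whose omega median is closer to
    0 than to 180."""
    medians = []
    for i in range(spec.n_states):
        m = spec.state_medians[i]
        cis = [r + 1 for r in range(spec.loop_length) if abs(m[r, 0]) < 90.0]
        cis_part = f"cis{','.join(map(str, cis))}-" if cis else ""
        name = f"L3-{spec.loop_length}-{cis_part}{i + 1}"
        medians.append(CanonicalMedian(name, m))
    return medians


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all stages into ``outdir``; returns a result dictionary with the
    fitted models and the canonical report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: epsilon=%g tica_lag=%g ns k=%d msm_lag=%g ns "
             "m=%d seed=%d", cfg.cluster_epsilon, cfg.tica_lag_ns,
             cfg.k_micro, cfg.msm_lag_ns, cfg.m_macro, cfg.seed)
    manifest = {"version": __version__, "seed": cfg.seed,
                "config": asdict(cfg), "config_hash": cfg.config_hash(),
                "stages": []}

    # -- generate / load ----------------------------------------------------
    try:
        trajs, spec, ens = _load_input(cfg)
    except Exception as e:
        raise PipelineError(f"generate: {e}") from e
    stride = trajs[0].frame_stride_ns
    if cfg.write_torsions and ens is not None:
        write_ensemble(ens, out / "torsions.tsv", out / "hidden_labels.tsv",
                       out / "system_spec.txt")
    manifest["stages"].append("generate")

    # -- features ------------------------------------------------------------
    include = {"phi", "psi"} | ({"omega"} if cfg.include_omega else set())
    try:
        feats = [torsions_to_features(t, include=include) for t in trajs]
    except Exception as e:
        raise PipelineError(f"features: {e}") from e
    manifest["stages"].append("features")

    # -- conformational clustering (visualisation of transition frequency) --
    try:
        all_angles = np.concatenate([t.angles for t in trajs], axis=0)
        n_total = all_angles.shape[0]
        sub_stride = max(1, n_total // cfg.cluster_max_frames)
        sub = all_angles[::sub_stride]
        D = pairwise_distance_matrix(sub, metric=cfg.cluster_metric)
        cres = average_linkage_cluster(D, cfg.cluster_epsilon)
        # per-trajectory label series on the subsample
        lens = [t.n_frames for t in trajs]
        bounds = np.cumsum([0] + lens)
        sub_idx = np.arange(n_total)[::sub_stride]
        traj_of = np.searchsorted(bounds, sub_idx, side="right") - 1
        series = [cres.labels[traj_of == i] for i in range(len(trajs))
                  if (traj_of == i).any()]
        n_trans, _ = transition_series(series)
        pd.DataFrame({"frame_subsampled": sub_idx, "cluster": cres.labels}) \
            .to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineError(f"cluster.epsilon: {e}") from e
    manifest["stages"].append("cluster")
    manifest["n_conformational_clusters"] = int(cres.n_clusters)
    manifest["n_cluster_transitions"] = int(n_trans)

    # -- tICA ----------------------------------------------------------------
    tica_lag = max(1, int(round(cfg.tica_lag_ns / stride)))
    try:
        tmodel = fit_tica(feats, tica_lag,
                          dim=cfg.tica_dim or None, frame_stride_ns=stride)
    except Exception as e:
        raise PipelineError(f"tica.lag: {e}") from e
    Ys = [tica_transform(tmodel, f) for f in feats]
    manifest["stages"].append("tica")
    manifest["tica_dim"] = int(tmodel.retained_dim)

    # -- MSM -----------------------------------------------------------------
    msm_lag = max(1, int(round(cfg.msm_lag_ns / stride)))
    if all(len(y) <= msm_lag for y in Ys):
        raise PipelineError(f"msm.lag: lag of {msm_lag} frames is not shorter "
                            "than any trajectory")
    try:
        micro = cluster_microstates(Ys, cfg.k_micro, seed=cfg.seed)
        model, active, fs, fc = estimate_msm(micro.labels, msm_lag,
                                             frame_stride_ns=stride)
    except Exception as e:
        raise PipelineError(f"msm.lag: {e}") from e
    manifest["stages"].append("msm")
    manifest["active_state_fraction"] = float(fs)
    manifest["active_count_fraction"] = float(fc)
    manifest["vamp2_rank_m"] = float(vamp2_score(model, min(cfg.m_macro,
                                                            model.n_states)))
    ts = timescales_from_model(model, 5)
    manifest["implied_timescales_ns"] = [
        None if not np.isfinite(t) else float(t * stride) for t in ts]

    # -- PCCA+ ---------------------------------------------------------------
    try:
        coarse = pcca_plus(model, cfg.m_macro)
    except Exception as e:
        raise PipelineError(f"pcca.m_macro: {e}") from e
    manifest["stages"].append("pcca")
    manifest["macro_populations"] = [float(p) for p in coarse.populations]

    # -- canonical mapping and report ---------------------------------------
    try:
        if cfg.median_library:
            medians = read_median_library(cfg.median_library)
        elif spec is not None:
            medians = _derive_medians(spec)
            write_median_library(medians, out / "median_library.txt")
        else:
            raise ValueError("no median library given and input is not synthetic")
        include_assign = {"phi", "psi"} | ({"omega"} if cfg.include_omega else set())
        hosted, unobserved, nearest = map_medians_to_macrostates(
            medians, trajs, coarse, micro.labels, radius=cfg.assign_radius,
            include=include_assign)
        reps = {}
        for macro, names in hosted.items():
            reps[macro] = min(nearest[n] for n in names)
        report = kinetics_report(coarse, hosted, unobserved,
                                 representative_frames=reps,
                                 frame_stride_ns=stride)
    except Exception as e:
        raise PipelineError(f"canonical.median_library: {e}") from e
    (out / "canonical_report.json").write_text(report.to_json() + "\n")
    report.pair_mfpt_ns.to_csv(out / "pair_mfpt.tsv", sep="\t", index=False)
    manifest["stages"].append("report")

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"config": cfg, "trajectories": trajs, "spec": spec,
            "ensemble": ens, "features": feats, "cluster": cres,
            "tica": tmodel, "micro": micro, "msm": model, "coarse": coarse,
            "report": report, "manifest": manifest}
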