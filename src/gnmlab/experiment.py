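"""End-to-end experiment driver: synth -> fit -> rewire -> analyze.

A single YAML/JSON config declares the synthetic target, the models to
fit, the rewiring null, and the distance-resolved analyses. Each stage
writes its outputs and a JSON manifest into its own subdirectory; a
master seed deterministically derives every stage seed, so identical
configs produce byte-identical result CSVs. A stage is skipped on re-run
when its manifest, config snapshot and input digests all match
(staleness by digest).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .analyses import (distance_threshold_degree, formed_edge_fdr,
                       sliding_window_precision)
from .embedding import make_embedding
from .io import (file_digest, load_config, read_coords, read_network,
                 read_similarity, write_coords, write_edgelist,
                 write_features, write_manifest, write_network,
                 write_similarity)
from .measures import distance_binned_recovery
from .model import GenerativeNetworkModel
from .optimize import Budget
from .rewiring import RewiringConfig, rewiring_curves, rewiring_ensemble
from .synth import feature_similarity, plant_target, smooth_random_features

log = logging.getLogger("gnmlab")

__all__ = ["run_experiment", "validate_config"]

_STAGE_IDS = {"synth": 1, "fit": 2, "rewire": 3, "analyze": 4}

_MODEL_KINDS = {"spatial", "matching", "random_similarity"}


class ConfigError(ValueError):
    pass


def _require(cfg: dict, key: str, path: str):
    if key not in cfg:
        raise ConfigError(f"missing config key: {path}.{key}")
    return cfg[key]


def validate_config(cfg: dict) -> dict:
    """Check the experiment config schema; returns the config."""
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    _require(cfg, "seed", "<root>")
    _require(cfg, "stages", "<root>")
    stages = cfg["stages"]
    if "synth" not in stages:
        raise ConfigError("missing config key: stages.synth")
    sy = stages["synth"]
    for k in ("n", "m"):
        _require(sy, k, "stages.synth")
    if sy["m"] > sy["n"] * (sy["n"] - 1) // 2:
        raise ConfigError("stages.synth.m exceeds the number of node pairs")
    if "fit" in stages:
        models = _require(stages["fit"], "models", "stages.fit")
        for mk in models:
            if mk not in _MODEL_KINDS:
                raise ConfigError(
                    f"stages.fit.models: unknown model {mk!r} "
                    f"(expected one of {sorted(_MODEL_KINDS)})")
    return cfg


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _budget_of(spec) -> Budget:
    if isinstance(spec, str):
        from .model import _BUDGETS
        return _BUDGETS[spec]
    if isinstance(spec, dict):
        return Budget(init=spec.get("init", 2000),
                      rounds=spec.get("rounds", 4),
                      per_round=spec.get("per_round", 2000),
                      beta_schedule=tuple(spec.get(
                          "betas", (0.5, 1.0, 1.5, 2.0))))
    return spec


def _stage_fresh(stage_dir: Path, config: dict, inputs: dict) -> bool:
    """True when the stage's manifest matches its config and inputs."""
    mf = stage_dir / "manifest.json"
    if not mf.exists():
        return False
    with open(mf) as fh:
        manifest = json.load(fh)
    if manifest.get("config") != json.loads(json.dumps(config, default=str)):
        return False
    if manifest.get("input_digests") != inputs:
        return False
    for name in manifest.get("output_digests", {}):
        if not (stage_dir / name).exists():
            return False
    return True


def run_experiment(config, out_dir=None) -> Path:
    """Execute the declared stage graph; returns the output directory."""
    cfg = validate_config(load_config(config))
    out = Path(out_dir or cfg.get("out", "gnmlab_run"))
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    stages = cfg["stages"]
    t0 = time.time()

    # ---- synth -----------------------------------------------------------
    sy = stages["synth"]
    synth_dir = out / "synth"
    if not _stage_fresh(synth_dir, sy, {}):
        synth_dir.mkdir(exist_ok=True)
        seed = _stage_seed(master, "synth")
        emb = make_embedding(int(sy["n"]), sy.get("geometry", "shell"),
                             float(sy.get("scale", 100.0)), seed=seed)
        planted = plant_target(emb, int(sy["m"]),
                               decay=float(sy.get("decay", 0.0)),
                               hub_spec=sy.get("hubs"), seed=seed + 1)
        feats = smooth_random_features(emb,
                                       n_features=int(sy.get("n_features", 20)),
                                       n_smooth=int(sy.get("n_smooth", 5)),
                                       seed=seed + 2)
        sim = feature_similarity(
            feats, orientation=sy.get("feature_orientation", "similarity"))
        files = [
            write_coords(emb, synth_dir / "coords.tsv"),
            write_network(planted.network, synth_dir / "target_dense.tsv"),
            write_edgelist(planted.network, synth_dir / "target_edges.tsv"),
            write_features(feats, synth_dir / "features.tsv"),
            write_similarity(sim, synth_dir / "similarity.tsv"),
        ]
        write_manifest(synth_dir, command="synth", config=sy,
                       master_seed=master, child_seeds={"synth": seed},
                       outputs=files)
        log.info("synth stage done in %.1fs", time.time() - t0)
    emb = read_coords(synth_dir / "coords.tsv")
    target = read_network(synth_dir / "target_dense.tsv", emb.n)
    synth_digests = {p.name: file_digest(p) for p in sorted(
        synth_dir.glob("*.tsv"))}

    # ---- fit -------------------------------------------------------------
    if "fit" in stages:
        fit_cfg = stages["fit"]
        fit_dir = out / "fit"
        if not _stage_fresh(fit_dir, fit_cfg, synth_digests):
            fit_dir.mkdir(exist_ok=True)
            seed = _stage_seed(master, "fit")
            budget = _budget_of(fit_cfg.get("budget", "tiny"))
            n_final = int(fit_cfg.get("n_final", 5))
            summary_rows = []
            files = []
            for k, kind in enumerate(fit_cfg["models"]):
                feature = None
                if kind == "matching":
                    feature = "matching"
                elif kind == "random_similarity":
                    feature = read_similarity(synth_dir / "similarity.tsv").F
                model = GenerativeNetworkModel(target, emb,
                                               feature_source=feature,
                                               label=kind)
                res = model.fit(budget=budget, seed=seed + k,
                                n_final=n_final)
                ev_path = fit_dir / f"evaluations_{kind}.csv"
                res.evaluations.to_csv(ev_path, index=False,
                                       float_format="%.10g")
                files.append(ev_path)
                row = {"model": kind, "best_maxKS": res.best_score}
                row.update({f"best_{k_}": v
                            for k_, v in res.params.items()})
                diag = res.diagnostics()
                row["ensemble_mean_maxKS"] = diag["maxKS"].mean()
                row["ensemble_mean_R"] = diag["R"].mean()
                row["ensemble_mean_rho_degree"] = diag["rho_degree"].mean()
                summary_rows.append(row)
                best_net = res.networks[0] if res.networks else None
                if best_net is not None:
                    p = fit_dir / f"network_{kind}.tsv"
                    write_edgelist(best_net, p)
                    files.append(p)
            sm_path = fit_dir / "fit_summary.csv"
            pd.DataFrame(summary_rows).to_csv(sm_path, index=False,
                                              float_format="%.10g")
            files.append(sm_path)
            write_manifest(fit_dir, command="fit", config=fit_cfg,
                           master_seed=master, child_seeds={"fit": seed},
                           inputs=synth_digests, outputs=files)
            log.info("fit stage done in %.1fs", time.time() - t0)

    # ---- rewire ----------------------------------------------------------
    if "rewire" in stages:
        rw_cfg = stages["rewire"]
        rw_dir = out / "rewire"
        if not _stage_fresh(rw_dir, rw_cfg, synth_digests):
            rw_dir.mkdir(exist_ok=True)
            seed = _stage_seed(master, "rewire")
            config_ = RewiringConfig(
                ordering=rw_cfg.get("ordering", "random"),
                target_rule=rw_cfg.get("target", "similar"),
                n_runs=int(rw_cfg.get("runs", 30)))
            trajs = rewiring_ensemble(target, emb, config_, seed=seed)
            files = []
            per = pd.concat([t.frame().assign(run=i)
                             for i, t in enumerate(trajs)])
            p1 = rw_dir / "trajectories.csv"
            per.to_csv(p1, index=False, float_format="%.10g")
            files.append(p1)
            curve = rewiring_curves(trajs, "maxKS")
            p2 = rw_dir / "mean_curve.csv"
            curve.to_csv(p2, index=False, float_format="%.10g")
            files.append(p2)
            write_manifest(rw_dir, command="rewire", config=rw_cfg,
                           master_seed=master, child_seeds={"rewire": seed},
                           inputs=synth_digests, outputs=files)
            log.info("rewire stage done in %.1fs", time.time() - t0)

    # ---- analyze ---------------------------------------------------------
    if "analyze" in stages:
        an_cfg = stages["analyze"]
        an_dir = out / "analyze"
        fit_dir = out / "fit"
        inputs = dict(synth_digests)
        model_nets = {}
        for p in sorted(fit_dir.glob("network_*.tsv")):
            inputs[p.name] = file_digest(p)
            model_nets[p.stem.replace("network_", "")] = \
                read_network(p, emb.n)
        if not _stage_fresh(an_dir, an_cfg, inputs):
            an_dir.mkdir(exist_ok=True)
            seed = _stage_seed(master, "analyze")
            files = []
            edges = an_cfg.get("bin_edges", [0, 30, 90, float("inf")])
            edges = [float(e) for e in edges]
            rows = []
            for kind, net in model_nets.items():
                for r in distance_binned_recovery(net, target, emb, edges):
                    r["model"] = kind
                    rows.append(r)
                for r in formed_edge_fdr(net, target, emb, edges):
                    r["model"] = kind
                    r["measure"] = "fdr"
                    rows.append(r)
            if rows:
                p = an_dir / "binned_recovery.csv"
                pd.DataFrame(rows).to_csv(p, index=False,
                                          float_format="%.10g")
                files.append(p)
            thr = an_cfg.get("thresholds")
            if thr is None:
                dmax = float(emb.d_condensed.max())
                thr = list(np.linspace(5, dmax, 20))
            prof_rows = []
            for mode in ("below", "above"):
                prof = distance_threshold_degree(target, emb, thr, mode)
                prof_rows.append(prof.frame())
            p = an_dir / "threshold_degree.csv"
            pd.concat(prof_rows).to_csv(p, index=False, float_format="%.10g")
            files.append(p)
            # window precision needs a traced growth of one fitted model
            if model_nets and (fit_dir / "fit_summary.csv").exists():
                sm = pd.read_csv(fit_dir / "fit_summary.csv")
                kind = sm.loc[sm["best_maxKS"].idxmin(), "model"]
                feature = None
                if kind == "matching":
                    feature = "matching"
                elif kind == "random_similarity":
                    feature = read_similarity(
                        synth_dir / "similarity.tsv").F
                from .engine import GNMParams, ModelSpec, grow_network
                row = sm[sm["model"] == kind].iloc[0]
                gamma = row.get("best_gamma", 0.0)
                alpha = row.get("best_alpha", None)
                params = GNMParams(
                    eta=float(row.get("best_eta", 0.0)),
                    gamma=0.0 if pd.isna(gamma) else float(gamma),
                    alpha=None if alpha is None or pd.isna(alpha)
                    else float(alpha))
                spec = ModelSpec(params=params, feature_source=feature)
                _, tr = grow_network(emb, spec, target.m, seed=seed,
                                     trace=True, method="stepwise")
                wc = sliding_window_precision(tr.mean_P, target, emb,
                                              seed=seed)
                p = an_dir / "window_precision.csv"
                wc.frame().to_csv(p, index=False, float_format="%.10g")
                files.append(p)
            write_manifest(an_dir, command="analyze", config=an_cfg,
                           master_seed=master, child_seeds={"analyze": seed},
                           inputs=inputs, outputs=files)
            log.info("analyze stage done in %.1fs", time.time() - t0)
    return out
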