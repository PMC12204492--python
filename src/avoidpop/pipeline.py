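"""End-to-end pipeline: stage orchestration, configuration, seeding.

``run_pipeline`` executes the requested stages in dependency order
(simulate/load -> preprocess -> modulation / geometry / decoding /
clustering / GLM; connectivity is independent), writes result tables as CSV
and a few summary figures to the output directory, and logs every stage
together with the derived seed it ran under. One global seed governs the
run; per-stage seeds are derived by hashing the stage name so stages are
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, connectivity, decoding, geometry, glm, modulation
from .core import SessionBundle, TrialTensor, ValidationError
from .io import read_session_bundle, write_session_bundle
from .preprocess import build_trial_tensor, zscore_session
from .synth import SimConfig, generate_cohort, generate_input_counts

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "modulate",
    "geometry",
    "decode",
    "cluster",
    "glm",
    "connectivity",
)

#: stages needing z-scored tensors from preprocess
_NEEDS_PREPROCESS = {"modulate", "geometry", "decode", "cluster", "glm"}


class ConfigError(ValueError):
    pass


class DependencyError(ValueError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (zlib.crc32(stage.encode()) ^ int(global_seed)) % (2**31)


@dataclass
class PipelineConfig:
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    out_dir: str = "results"
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    inputs: list[str] = field(default_factory=list)  # existing bundle dirs
    n_boot: int = 20
    n_perm: int = 200
    n_shuffle: int = 100
    spatial_shuffles: int = 1000
    decode_neurons: int | None = None
    figures: bool = True
    connectivity_profiles: dict | None = None
    n_subjects_per_subtype: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f)


def _expand_stages(stages: list[str]) -> list[str]:
    if stages in (["all"], ("all",)):
        stages = list(STAGES)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stage names: {bad}")
    return [s for s in STAGES if s in stages]


def pool_tensors(
    tensors: list[TrialTensor], rng: np.random.Generator
) -> TrialTensor:
    """Pool neurons across sessions into one pseudo-population tensor.

    Trials are capped at the minimum available across sessions (random
    subsample per session), mirroring the assembly of pseudo-simultaneous
    trials across animals.
    """
    n_tr = min(t.n_trials for t in tensors)
    data = []
    for t in tensors:
        idx = rng.choice(t.n_trials, size=n_tr, replace=False)
        data.append(t.data[:, np.sort(idx), :])
    first = tensors[0]
    return TrialTensor(
        data=np.concatenate(data, axis=0),
        align_event=first.align_event,
        window_s=first.window_s,
        outcome=np.array([first.outcome[0]] * n_tr)
        if np.unique(first.outcome).size == 1
        else first.outcome[:n_tr],
        frame_rate_hz=first.frame_rate_hz,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of result tables."""
    stages = _expand_stages(list(config.stages))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    needs_data = [s for s in stages if s == "preprocess"]
    if needs_data and "simulate" not in stages and not config.inputs:
        raise DependencyError("preprocess requires 'simulate' or input bundles")
    for s in stages:
        if s in _NEEDS_PREPROCESS and "preprocess" not in stages:
            raise DependencyError(f"stage {s!r} requires 'preprocess'")

    sessions: list[SessionBundle] = []
    truths = []
    if "simulate" in stages:
        seed = stage_seed(config.seed, "simulate")
        log.info("stage simulate: seed=%d sim=%s", seed, config.sim)
        sim_cfg = SimConfig(**{**config.sim, "seed": seed})
        cohort = generate_cohort(sim_cfg)
        sim_dir = out / "sim"
        rows = []
        for k, (bundle, truth) in enumerate(cohort):
            sessions.append(bundle)
            truths.append(truth)
            write_session_bundle(bundle, sim_dir / f"session_{k}")
            for nid, name in zip(
                truth.amplitudes.index, truth.motif_names
            ):
                rows.append(dict(session=k, neuron_id=nid, motif=name))
        pd.DataFrame(rows).to_csv(sim_dir / "ground_truth.csv", index=False)
        results["simulate"] = cohort
    elif config.inputs:
        sessions = [read_session_bundle(p) for p in config.inputs]

    prep = []
    if "preprocess" in stages:
        log.info("stage preprocess: %d sessions", len(sessions))
        pre_dir = out / "preprocess"
        pre_dir.mkdir(exist_ok=True)
        for k, s in enumerate(sessions):
            z = zscore_session(s)
            tensors = {"cs": build_trial_tensor(s, z, "cs_onset", (-2.0, 3.0))}
            try:
                tensors["avrun"] = build_trial_tensor(
                    s, z, "avrun_onset", (-3.0, 3.0)
                )
            except ValidationError:
                pass
            try:
                tensors["shock"] = build_trial_tensor(
                    s, z, "shock_onset", (-2.0, 3.0)
                )
            except ValidationError:
                pass
            prep.append(dict(session=s, z=z, tensors=tensors))
            pd.DataFrame(
                z,
                index=[n.neuron_id for n in s.neurons],
            ).to_csv(pre_dir / f"zscored_traces_session_{k}.csv")
            pd.DataFrame(
                dict(
                    trial_index=tensors["cs"].trial_index,
                    outcome=tensors["cs"].outcome,
                )
            ).to_csv(pre_dir / f"trials_session_{k}.csv", index=False)
        results["preprocess"] = prep

    if "modulate" in stages:
        seed = stage_seed(config.seed, "modulate")
        log.info("stage modulate: seed=%d n_perm=%d", seed, config.n_perm)
        rows = []
        for k, p in enumerate(prep):
            ids = [n.neuron_id for n in p["session"].neurons]
            jobs = [("cs", "cs"), ("avrun", "avrun"),
                    ("pre_avrun", "avrun"), ("shock", "shock")]
            for variable, tkey in jobs:
                if tkey not in p["tensors"]:
                    continue
                res = modulation.circular_null_classify(
                    p["z"], p["tensors"][tkey], variable,
                    neuron_ids=ids, n_perm=config.n_perm,
                    seed=seed + k,
                )
                rows.extend(
                    dict(session=k, neuron_id=r.neuron_id, variable=r.variable,
                         auroc=r.auroc, null_lo=r.null_pcts[0],
                         null_hi=r.null_pcts[1], mod_class=r.mod_class)
                    for r in res
                )
        table = pd.DataFrame(rows)
        table.to_csv(out / "modulation.csv", index=False)
        frac = (
            table.groupby(["variable", "mod_class"]).size()
            / table.groupby("variable").size()
        )
        frac.rename("fraction").to_csv(out / "modulation_fractions.csv")
        results["modulate"] = table

    pooled = {}
    if any(s in stages for s in ("geometry", "decode", "cluster")):
        rng = np.random.default_rng(stage_seed(config.seed, "pool"))
        # avrun tensors are success-only and shock tensors failure-only, so
        # pooled outcome labels stay homogeneous
        for key in ("avrun", "shock"):
            per = [p["tensors"][key] for p in prep if key in p["tensors"]]
            if per:
                pooled[key] = pool_tensors(per, rng)
        for outc in ("success", "failure"):
            pooled[f"cs_{outc}"] = _pool_outcome(prep, "cs", outc, rng)

    if "geometry" in stages:
        seed = stage_seed(config.seed, "geometry")
        log.info("stage geometry: seed=%d n_boot=%d", seed, config.n_boot)
        ts, tf = pooled["cs_success"], pooled["cs_failure"]
        emb = geometry.trial_averaged_pca(ts, tf)
        cd = geometry.coding_direction(ts, tf)
        div = geometry.trajectory_divergence(
            ts, tf, n_boot=config.n_boot, seed=seed
        )
        pd.DataFrame(
            dict(pc=np.arange(1, emb.explained_variance_ratio.size + 1),
                 explained_variance_ratio=emb.explained_variance_ratio)
        ).to_csv(out / "pca_variance.csv", index=False)
        pd.DataFrame(
            dict(time_s=div.times, mean_z=div.mean_z,
                 significant=div.significant)
        ).to_csv(out / "divergence.csv", index=False)
        pd.DataFrame(dict(neuron=np.arange(cd.cd.size), cd=cd.cd)).to_csv(
            out / "coding_direction.csv", index=False
        )
        results["geometry"] = dict(embedding=emb, cd=cd, divergence=div)
        if config.figures:
            _trajectory_figure(emb, ts, tf, out / "trajectories.png")

    if "decode" in stages:
        seed = stage_seed(config.seed, "decode")
        log.info("stage decode: seed=%d n_boot=%d n_shuffle=%d",
                 seed, config.n_boot, config.n_shuffle)
        ts, tf = pooled["cs_success"], pooled["cs_failure"]
        emb = geometry.trial_averaged_pca(ts, tf)
        res = decoding.decode_window(
            ts, tf, emb, n_neurons=config.decode_neurons,
            n_boot=config.n_boot, seed=seed,
        )
        null, p = decoding.shuffle_null(
            ts, tf, observed=float(np.mean(res.accuracies)),
            n_neurons=config.decode_neurons,
            n_shuffle=config.n_shuffle, seed=seed + 1,
        )
        res.null_accuracies, res.p_value = null, p
        pd.DataFrame(dict(bootstrap=np.arange(res.accuracies.size),
                          accuracy=res.accuracies)).to_csv(
            out / "decoding_accuracy.csv", index=False
        )
        pd.DataFrame(
            [dict(mean_accuracy=float(np.mean(res.accuracies)),
                  null_p50=float(np.median(null)),
                  null_p95=float(np.percentile(null, 95)), p_value=p)]
        ).to_csv(out / "decoding_summary.csv", index=False)
        results["decode"] = res

    if "cluster" in stages:
        seed = stage_seed(config.seed, "cluster")
        log.info("stage cluster: seed=%d", seed)
        epochs = {
            "cs_success": pooled["cs_success"],
            "cs_failure": pooled["cs_failure"],
            "shock": pooled["shock"],
            "avrun": pooled["avrun"],
        }
        feats = clustering.epoch_feature_matrix(epochs)
        model = clustering.functional_clusters(feats, seed=seed)
        coords = np.array(
            [
                [n.ap_mm, n.ml_mm, n.dv_mm]
                for p in prep
                for n in p["session"].neurons
            ]
        )
        spatial_rows, tests = [], []
        for axis in ("AP", "ML", "DV"):
            for c in np.unique(model.assignments):
                t = clustering.spatial_concentration_test(
                    (model.assignments == c).astype(float), coords, axis,
                    n_shuffle=config.spatial_shuffles,
                    seed=stage_seed(config.seed, f"spatial_{axis}_{c}"),
                )
                tests.append(t)
                spatial_rows.append(dict(axis=axis, cluster=int(c)))
        clustering.correct_spatial_family(tests)
        for row, t in zip(spatial_rows, tests):
            row.update(statistic=t.statistic, p=t.p_value,
                       p_holm=t.corrected_p)
        pd.DataFrame(
            dict(neuron=np.arange(model.assignments.size),
                 cluster=model.assignments)
        ).to_csv(out / "cluster_assignments.csv", index=False)
        pd.DataFrame(dict(k=model.k_range, inertia=model.elbow_curve)).to_csv(
            out / "elbow.csv", index=False
        )
        pd.DataFrame(spatial_rows).to_csv(out / "spatial_tests.csv", index=False)
        results["cluster"] = model
        if config.figures:
            _heatmap_figure(model, epochs, out / "cluster_heatmap.png")

    if "glm" in stages:
        seed = stage_seed(config.seed, "glm")
        log.info("stage glm: seed=%d", seed)
        rows = []
        fits = {}
        for k, p in enumerate(prep):
            s = p["session"]
            design = glm.build_design_matrix(
                s.events, s.frame_rate_hz, s.n_frames
            )
            for i, nrec in enumerate(s.neurons):
                fit = glm.loo_cv(design, p["z"][i])
                for pred in design.columns[:-1]:
                    glm.predictor_contribution(fit, pred)
                fits[f"s{k}:{nrec.neuron_id}"] = fit
                row = dict(session=k, neuron_id=nrec.neuron_id,
                           r2_full=fit.r2_full, r2_cv=fit.r2_cv,
                           mse_cv=fit.mse_cv)
                row.update({f"beta_{c}": v for c, v in fit.betas.items()})
                row.update(
                    {f"drop_{c}": fit.contributions[c][0]
                     for c in fit.contributions}
                )
                rows.append(row)
        table = pd.DataFrame(rows)
        table.to_csv(out / "glm_fits.csv", index=False)
        idx = glm.derived_indices(fits)
        idx.to_csv(out / "glm_indices.csv")
        results["glm"] = dict(fits=fits, table=table, indices=idx)

    if "connectivity" in stages:
        seed = stage_seed(config.seed, "connectivity")
        log.info("stage connectivity: seed=%d", seed)
        profiles = config.connectivity_profiles or _default_profiles()
        icm = generate_input_counts(
            config.n_subjects_per_subtype,
            {k: np.asarray(v, float) for k, v in profiles.items()},
            seed=seed,
        )
        props = connectivity.proportions(icm)
        anova = connectivity.region_anova(props, icm.subtype)
        pca = connectivity.connectivity_pca_similarity(
            props, icm.subtype, n_perm=config.n_perm, seed=seed + 1
        )
        dec = connectivity.subtype_decoder(
            props, icm.subtype, n_boot=config.n_perm,
            n_perm=config.n_perm, seed=seed + 2,
        )
        anova.to_csv(out / "region_anova.csv")
        pca.similarity.to_csv(out / "similarity.csv")
        pd.DataFrame(
            [dict(loocv_accuracy=dec.loocv_accuracy,
                  permutation_p=dec.permutation_p,
                  significant=dec.significant)]
        ).to_csv(out / "subtype_decoder.csv", index=False)
        results["connectivity"] = dict(anova=anova, pca=pca, decoder=dec)

    return results


def _pool_outcome(prep, key, outcome, rng):
    per = [
        p["tensors"][key].select(outcome)
        for p in prep
        if key in p["tensors"] and (p["tensors"][key].outcome == outcome).any()
    ]
    return pool_tensors(per, rng)


def _default_profiles() -> dict:
    """Three illustrative subtype input profiles over the default regions."""
    base = np.array([8, 3, 6, 4, 10, 6, 5, 9, 4, 3, 2, 3, 4, 5], float)
    a = base.copy()
    b = base.copy()
    b[4] *= 2.5  # SuM-enriched
    c = base.copy()
    c[0] *= 2.0  # CA1-enriched
    return {"Glp1r": a, "Foxp2": b, "Calcr": c}


def _trajectory_figure(emb, ts, tf, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .geometry import project_single_trials

    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    for tensor, color, label in ((ts, "tab:blue", "success"),
                                 (tf, "tab:red", "failure")):
        proj = project_single_trials(emb, tensor, n_pcs=3).mean(axis=0)
        ax.plot(proj[:, 0], proj[:, 1], proj[:, 2], color=color, label=label)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _heatmap_figure(model, epochs, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .clustering import cluster_profiles

    prof = cluster_profiles(model, epochs)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(prof["normalized"][prof["heatmap_order"]], aspect="auto",
              cmap="viridis", interpolation="nearest")
    ax.set_xlabel("concatenated epoch time")
    ax.set_ylabel("neuron (cluster-ordered)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
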