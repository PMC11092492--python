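"""End-to-end experiment orchestration, group statistics and remediation.

The full experiment chains the stages: stimulus generation, the
excitability sweep, cohort matching (synthetic or from a CSV), the
behavioral / representational / manifold analyses at the reference
iteration, and the remediation probe (how much extra training matched
high-gain models need to reach the typical-group median accuracy).
Every stage writes plain CSV artifacts plus a manifest with the
configuration and seeds so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .behavior import behavior_summary
from .cohort_matching import (Cohort, MatchResult, generate_synthetic_cohort,
                              match_cohort, permutation_control,
                              select_reference_iteration)
from .manifolds import extract_result_manifolds, manifold_geometry_mft
from .network import ArchConfig, GainNetwork, forward_collect, gain_grid
from .representation import block_nrs, mean_response_matrix, similarity_matrix
from .stimuli import GlyphSource, build_dataset
from .training import (NOT_REACHED, SweepResult, TrainConfig, sweep_gains)


@dataclass
class GroupStats:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    p: float
    cohens_d: float  # (a - b) / pooled SD
    r: float | None = None
    r_p: float | None = None


def group_compare(values_a, values_b, paired_covariate=None) -> GroupStats:
    """Welch t-test plus Cohen's d (pooled SD); optional Pearson r."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        raise ValueError("Cohen's d undefined: zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else np.inf * np.sign(a.mean() - b.mean())
    r = r_p = None
    if paired_covariate is not None:
        both = np.concatenate([a, b])
        r, r_p = stats.pearsonr(np.asarray(paired_covariate, dtype=float), both)
        r, r_p = float(r), float(r_p)
    return GroupStats(float(a.mean()), float(b.mean()), float(a.std(ddof=1)),
                      float(b.std(ddof=1)), float(t), float(p), float(d), r, r_p)


def extra_training_to_reference(curves: dict, reference_iteration: int,
                                td_reference_accuracy: float) -> dict:
    """Per-model additional iterations to reach the TD median accuracy.

    For each curve (keyed by model id), find the evaluated iteration at
    or beyond the reference whose accuracy is closest to the target
    (ties towards the earlier iteration); returns additional iterations
    (0 if already closest at the reference), or NOT_REACHED when the
    curve never reaches within half the final accuracy gap.
    """
    out = {}
    for key, curve in curves.items():
        sel = curve.iterations >= reference_iteration
        its = curve.iterations[sel]
        accs = curve.accuracy[sel]
        if len(its) == 0:
            out[key] = NOT_REACHED
            continue
        gaps = np.abs(accs - td_reference_accuracy)
        best = int(np.argmin(gaps))  # argmin takes the first (earliest) minimum
        out[key] = int(its[best] - reference_iteration)
    return out


@dataclass
class ExperimentConfig:
    out_dir: str
    backend: str = "synthetic"
    pool_size: int = 12
    variants_per_problem: int = 20
    seed: int = 0
    gains: np.ndarray = None
    arch: ArchConfig = None
    train: TrainConfig = None
    n_td: int = 24
    n_mld: int = 21
    cohort_csv: str | None = None
    cohort_noise_sd: float = 0.02
    n_permutations: int = 1000
    analysis_layers: tuple = ("V1", "V2", "V3", "IPS")

    def __post_init__(self):
        if self.gains is None:
            self.gains = gain_grid()
        if self.arch is None:
            self.arch = ArchConfig()
        if self.train is None:
            self.train = TrainConfig(seed=self.seed)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute every stage; returns a summary dict (also written to disk)."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    stage = "generate"
    try:
        manifest = {
            "version": __version__, "seed": cfg.seed, "backend": cfg.backend,
            "pool_size": cfg.pool_size, "variants": cfg.variants_per_problem,
            "gains": list(map(float, cfg.gains)), "arch": cfg.arch.to_json(),
            "train": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                      for k, v in cfg.train.__dict__.items()},
            "cohort": {"n_td": cfg.n_td, "n_mld": cfg.n_mld,
                       "noise_sd": cfg.cohort_noise_sd, "csv": cfg.cohort_csv},
        }
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

        source = GlyphSource.synthetic("train", cfg.pool_size, cfg.seed)
        dataset = build_dataset(cfg.variants_per_problem, source, source, cfg.seed)

        stage = "sweep"
        train_cfg = TrainConfig(**{**cfg.train.__dict__,
                                   "checkpoint_dir": os.path.join(cfg.out_dir, "sweep")})
        sweep = sweep_gains(dataset, cfg.gains, cfg.arch, train_cfg)
        pd.DataFrame([
            {"gain": float(g), "iteration": int(it), "accuracy": float(acc)}
            for g, c in zip(sweep.gains, sweep.curves)
            for it, acc in zip(c.iterations, c.accuracy)
        ]).to_csv(os.path.join(cfg.out_dir, "sweep_summary.csv"), index=False)

        stage = "match"
        if cfg.cohort_csv:
            cohort = Cohort.from_csv(cfg.cohort_csv)
        else:
            mid = sweep.iterations[len(sweep.iterations) // 2]
            cohort = generate_synthetic_cohort(
                cfg.n_td, cfg.n_mld, sweep, mid, cfg.cohort_noise_sd, cfg.seed)
        cohort.to_csv(os.path.join(cfg.out_dir, "cohort.csv"))
        match = match_cohort(sweep, cohort)
        ref_iter = select_reference_iteration(match)
        perm = permutation_control(match, cfg.n_permutations, cfg.seed, ref_iter)
        _write_match(cfg.out_dir, match, ref_iter, perm)

        stage = "analyze"
        analysis = _analyze(cfg, sweep, match, ref_iter, dataset)

        stage = "remediate"
        remediation = _remediate(sweep, match, ref_iter)
        pd.DataFrame(remediation["per_model"]).to_csv(
            os.path.join(cfg.out_dir, "remediation.csv"), index=False)

        summary = {
            "reference_iteration": ref_iter,
            "fitted_mean_distance": perm.fitted_mean,
            "null_mean_distance": perm.null_mean,
            "group_gain": match.group_mean_gain(ref_iter),
            "analysis": analysis,
            "remediation": remediation["summary"],
        }
        with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        return summary
    except Exception as exc:
        raise RuntimeError(f"experiment failed during stage '{stage}': {exc}") from exc


def _write_match(out_dir, match: MatchResult, ref_iter, perm):
    rows = []
    for i, it in enumerate(match.iterations):
        for j, subj in enumerate(match.cohort.subjects):
            rows.append({"iteration": int(it), "subject_id": subj.id,
                         "best_gain": float(match.best_gain[i, j]),
                         "distance": float(match.distance[i, j])})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "match.csv"), index=False)
    with open(os.path.join(out_dir, "reference_iteration.txt"), "w") as fh:
        fh.write(f"{ref_iter}\n")
    pd.DataFrame({"permutation_mean_distance": perm.per_permutation}).to_csv(
        os.path.join(out_dir, "permutation.csv"), index=False)


def _load_checkpoint(sweep: SweepResult, gain, iteration) -> GainNetwork:
    i = int(np.argmin(np.abs(sweep.gains - gain)))
    path = sweep.curves[i].checkpoints.get(int(iteration))
    if path is None:
        raise KeyError(f"no checkpoint at iteration {iteration} for gain {gain}")
    return GainNetwork.load(path)


def _collect_layer_stats(net, dataset, layers, mft_samples=100, seed=0):
    acts_all = {}
    test = dataset.test
    chunk = 200
    for lo in range(0, len(test), chunk):
        idx = np.arange(lo, min(lo + chunk, len(test)))
        _, acts = forward_collect(net, test.batch(idx))
        for layer in layers:
            acts_all.setdefault(layer, []).append(acts[layer])
    out = {}
    for layer in layers:
        a = np.concatenate(acts_all[layer])
        mr = mean_response_matrix(a, test.problem_index, dataset.problems, layer)
        ms = extract_result_manifolds(mr)
        geom = manifold_geometry_mft(ms, n_samples=mft_samples, seed=seed)
        out[layer] = {"nrs": block_nrs(similarity_matrix(mr)),
                      "capacity": geom.capacity, "dimension": geom.dimension,
                      "radius": geom.radius,
                      "center_correlation": geom.center_correlation}
    return out


def _analyze(cfg, sweep, match, ref_iter, dataset):
    """Behavior + representation + manifold geometry per gain at reference."""
    out = {}
    for i, g in enumerate(sweep.gains):
        curve = sweep.curves[i]
        k = int(np.nonzero(curve.iterations == ref_iter)[0][0])
        entry = {}
        if curve.responses:
            resp = curve.responses[k]
            expected = dataset.test.result[curve.eval_indices]
            entry.update(behavior_summary(resp, expected))
        try:
            net = _load_checkpoint(sweep, g, ref_iter)
            entry["layers"] = _collect_layer_stats(net, dataset, cfg.analysis_layers,
                                                   seed=cfg.seed)
        except KeyError:
            pass
        out[float(g)] = entry
    return out


def _remediate(sweep, match, ref_iter):
    """Additional-iterations analysis for the matched MLD models."""
    i_ref = int(np.nonzero(match.iterations == ref_iter)[0][0])
    groups = match.cohort.groups
    td_gains = match.best_gain[i_ref, groups == "TD"]
    mld_gains = match.best_gain[i_ref, groups == "MLD"]
    acc = sweep.accuracy_table()
    k_ref = int(np.nonzero(sweep.iterations == ref_iter)[0][0])

    def acc_at(gain):
        return acc[int(np.argmin(np.abs(sweep.gains - gain))), k_ref]

    td_median = float(np.median([acc_at(g) for g in td_gains]))
    curves = {f"MLD_{j}": sweep.curves[int(np.argmin(np.abs(sweep.gains - g)))]
              for j, g in enumerate(mld_gains)}
    extra = extra_training_to_reference(curves, ref_iter, td_median)
    per_model = [{"model": k, "matched_gain": float(g), "extra_iterations": v,
                  "percent_extra": 100.0 * v / max(ref_iter, 1) if v != NOT_REACHED else np.nan}
                 for (k, v), g in zip(extra.items(), mld_gains)]
    vals = [v for v in extra.values() if v != NOT_REACHED]
    return {"per_model": per_model,
            "summary": {"td_median_accuracy": td_median,
                        "mean_extra_iterations": float(np.mean(vals)) if vals else np.nan,
                        "mean_percent_extra": float(np.mean(vals)) / max(ref_iter, 1) * 100
                        if vals else np.nan}}
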