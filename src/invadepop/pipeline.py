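"""Stage runner chaining the pipeline with config, logging and seed control.

A run config is a mapping with ``stages`` (ordered subset of
simulate / sfs / stats / fit / abc / fdist / report), a master ``seed``, an
``outdir``, and one optional parameter block per stage.  One master seed
deterministically derives per-stage seeds, so a rerun with the same config
reproduces every numerical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io_formats
from .abc import (Prior, abc_rejection, build_reference_table,
                  pairwise_summary_from_matrix, pls_reduce, regression_adjust)
from .fdist import (classify_outliers, locus_pvalues, observed_locus_stats,
                    simulate_fdist_null)
from .fit import fit_model, rank_models
from .presets import DEEP_CLUSTER, SHALLOW_CLUSTER, get_preset
from .sfs import compute_joint_sfs
from .stats import amova, nucleotide_diversity, pairwise_fst, pca_coordinates
from .synth import FixtureSpec, make_fixture

logger = logging.getLogger(__name__)

STAGES = ["simulate", "sfs", "stats", "fit", "abc", "fdist", "report"]

DEFAULT_GROUPING = {p: "brachygnathus" for p in DEEP_CLUSTER}
DEFAULT_GROUPING.update({p: "taihuensis" for p in SHALLOW_CLUSTER})
DEFAULT_GROUPING["SH"] = "nasus"


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_config(config: dict) -> dict:
    cfg = dict(config)
    stages = cfg.get("stages")
    if not stages:
        raise ConfigError("config field 'stages' must be a non-empty list")
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"config field 'stages' names unknown stage {s!r}")
    if "outdir" not in cfg:
        raise ConfigError("config field 'outdir' is required")
    cfg.setdefault("seed", 1)
    if not isinstance(cfg["seed"], int):
        raise ConfigError("config field 'seed' must be an integer")
    for key in cfg:
        if key not in {"stages", "outdir", "seed", "log_level", *STAGES}:
            raise ConfigError(f"unknown config field {key!r}")
    return cfg


def stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=(int(master), zlib.crc32(stage.encode())))
    return int(ss.generate_state(1)[0] % (2**31 - 2)) + 1


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(outdir: Path, cfg: dict):
    vcf = Path(cfg.get("vcf", outdir / "fixture.vcf"))
    popmap = Path(cfg.get("popmap", outdir / "popmap.tsv"))
    if not vcf.exists() or not popmap.exists():
        raise FileNotFoundError(
            f"missing upstream output ({vcf} / {popmap}); run the simulate "
            "stage first or point 'vcf'/'popmap' at existing files")
    gm = io_formats.read_vcf(vcf)
    pm = io_formats.read_popmap(popmap)
    pm.validate_against(gm)
    return gm, pm


def _stage_simulate(outdir: Path, cfg: dict, seed: int) -> list:
    spec = FixtureSpec(
        preset=cfg.get("preset", "model3"),
        scale=float(cfg.get("scale", 0.05)),
        params=cfg.get("params", {}),
        spike_fraction=float(cfg.get("spike_fraction", 0.0)),
        spike_migration_scale=float(cfg.get("spike_migration_scale", 1.0)),
        seed=int(cfg.get("seed", seed)),
    )
    paths = make_fixture(spec, outdir)
    return list(paths.values())


def _stage_sfs(outdir: Path, cfg: dict, seed: int) -> list:
    gm, pm = _load_inputs(outdir, cfg)
    pops = cfg.get("pops", [p for p in pm.labels if pm.individuals(p)])
    written = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            for folded in (True, False):
                sfs = compute_joint_sfs(gm, pm, [pops[i], pops[j]], folded=folded)
                kind = "folded" if folded else "unfolded"
                path = outdir / f"sfs_{pops[i]}_{pops[j]}_{kind}.sfs"
                io_formats.write_sfs(sfs, path)
                written.append(path)
    return written


def _stage_stats(outdir: Path, cfg: dict, seed: int) -> list:
    gm, pm = _load_inputs(outdir, cfg)
    n_perm_fst = int(cfg.get("fst_permutations", 200))
    n_perm_amova = int(cfg.get("amova_permutations", 200))
    grouping = cfg.get("grouping", {p: DEFAULT_GROUPING.get(p, p) for p in pm.labels})
    written = []

    pi = nucleotide_diversity(gm, pm)
    pi_path = outdir / "pi.tsv"
    pd.Series(pi, name="pi_per_variant").rename_axis("population").to_csv(pi_path, sep="\t")
    written.append(pi_path)

    fm = pairwise_fst(gm, pm, n_perm=n_perm_fst, seed=seed)
    fst_path = outdir / "fst.tsv"
    pd.DataFrame(fm.theta, index=fm.pop_names, columns=fm.pop_names).to_csv(fst_path, sep="\t")
    fstp_path = outdir / "fst_pvalues.tsv"
    pd.DataFrame(fm.p_values, index=fm.pop_names, columns=fm.pop_names).to_csv(fstp_path, sep="\t")
    written += [fst_path, fstp_path]

    res = amova(gm, pm, grouping, n_perm=n_perm_amova, seed=seed)
    rows = []
    for level in ("among_groups", "among_pops_within_groups", "within_pops"):
        rows.append({
            "source": level,
            "sum_of_squares": res.sum_of_squares[level],
            "df": res.df[level],
            "variance_component": res.components[level],
            "percentage": res.percentages[level],
            "p_value": res.p_values.get(level, float("nan")),
        })
    amova_path = outdir / "amova.tsv"
    pd.DataFrame(rows).to_csv(amova_path, sep="\t", index=False)
    written.append(amova_path)

    scores, explained = pca_coordinates(gm)
    n_keep = min(10, scores.shape[1])
    pca = pd.DataFrame(scores[:, :n_keep],
                       columns=[f"pc{k + 1}" for k in range(n_keep)])
    pca.insert(0, "individual", gm.individual_ids)
    pca.insert(1, "population", [pm.assignments[i] for i in gm.individual_ids])
    pca_path = outdir / "pca_scores.tsv"
    pca.to_csv(pca_path, sep="\t", index=False)
    evr_path = outdir / "pca_explained.tsv"
    pd.Series(explained[:n_keep], name="explained_fraction").to_csv(evr_path, sep="\t")
    written += [pca_path, evr_path]
    return written


def _stage_fit(outdir: Path, cfg: dict, seed: int) -> list:
    gm, pm = _load_inputs(outdir, cfg)
    pops = cfg.get("pops", ["DT", "CH", "SH"])
    folded = bool(cfg.get("folded", True))
    obs = compute_joint_sfs(gm, pm, pops, folded=folded)
    samples = {p: 2 * len(pm.individuals(p)) for p in pops}
    models = cfg.get("models", ["model1", "model2", "model3"])
    n_runs = int(cfg.get("runs", 2))
    n_sims = int(cfg.get("sims", 1000))
    cycles = (int(cfg.get("cycles_min", 3)), int(cfg.get("cycles_max", 5)))
    free_cfg = cfg.get("free_params", {})
    fits = []
    for name in models:
        preset = get_preset(name)
        free = free_cfg.get(name) or _default_free_params(name)
        fits.append(fit_model(obs, preset, free, samples=samples,
                              cycles=cycles, n_runs=n_runs, n_sims=n_sims,
                              seed=stage_seed(seed, name)))
    ranked = rank_models(fits)
    rows = [{
        "model": f.model_id,
        "sfs_type": "folded" if folded else "unfolded",
        "snps": "unlinked",
        "MaxEstLhood": f.lnl,
        "n_parameters": f.d,
        "AIC": f.aic,
        "rank": f.rank,
        "best_params": json.dumps(f.params, sort_keys=True),
    } for f in ranked]
    path = outdir / "model_comparison.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return [path]


def _default_free_params(name: str) -> dict:
    free = {"T1": (2000.0, 200000.0)}
    if name in ("model2", "model3", "model4"):
        free["T2"] = (500.0, 100000.0)
    if name in ("model3", "model4"):
        free["T3"] = (100.0, 20000.0)
    return free


def _stage_abc(outdir: Path, cfg: dict, seed: int) -> list:
    gm, pm = _load_inputs(outdir, cfg)
    pops = cfg.get("pops", ["CH", "TH", "SH"])
    preset = get_preset(cfg.get("model", "model3"))
    samples = {p: 2 * len(pm.individuals(p)) for p in pops}
    n_regions = len(set(gm.region_id))
    priors_cfg = cfg.get("priors", {"T3": [200.0, 20000.0, True]})
    priors = {k: Prior(*v) for k, v in priors_cfg.items()}
    n_sims = int(cfg.get("nsims", 300))
    n_accept = int(cfg.get("naccept", max(20, n_sims // 20)))
    n_pls = int(cfg.get("npls", 4))
    method = cfg.get("method", "loclinear")

    table = build_reference_table(preset, priors, n_sims=n_sims, samples=samples,
                                  seed=seed, n_regions=n_regions)
    observed = pairwise_summary_from_matrix(gm, pm, pops)
    reduced, reduced_obs, _ = pls_reduce(table, observed, n_components=n_pls)
    post = abc_rejection(reduced, reduced_obs, table.params, n_accept=n_accept)
    if method in ("loclinear", "neuralnet"):
        post = regression_adjust(post, reduced, reduced_obs, method=method, seed=seed)
    post = post.summarise()

    table_path = outdir / "abc_reference_table.tsv"
    ref = table.params.copy()
    ref.to_csv(table_path, sep="\t", index=False)
    draws_path = outdir / "abc_posterior_draws.tsv"
    draws = post.draws.copy()
    draws["weight"] = post.weights
    draws.to_csv(draws_path, sep="\t", index=False)
    summary_path = outdir / "abc_summary.json"
    with open(summary_path, "w") as fh:
        json.dump({
            "model": preset.name,
            "method": post.method,
            "n_sims": n_sims,
            "n_accept": n_accept,
            "n_pls": n_pls,
            "priors": {k: [v.low, v.high, v.log] for k, v in priors.items()},
            "point_estimates": post.point_estimates,
            "hpd95": post.hpd,
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [table_path, draws_path, summary_path]


def _stage_fdist(outdir: Path, cfg: dict, seed: int) -> list:
    gm, pm = _load_inputs(outdir, cfg)
    pops = cfg.get("pops", ["DT", "SH"])
    n_sims = int(cfg.get("nsims", 3000))
    n_demes = int(cfg.get("ndemes", 100))
    upper_q = float(cfg.get("upper_q", 0.95))
    lower_q = float(cfg.get("lower_q", 0.05))
    per_locus = bool(cfg.get("per_locus", True))
    observed = observed_locus_stats(gm, pm, pops, per_locus=per_locus)
    mean_fst = float(np.clip(np.mean([f for _, _, f in observed]), 0.005, 0.95))
    sample_sizes = [2 * len(pm.individuals(p)) for p in pops]
    snps_per_locus = (gm.n_sites / max(len(set(gm.region_id)), 1)
                      if per_locus else 1.0)
    he, fst, mig = simulate_fdist_null(
        n_demes=n_demes, demes_sampled=len(pops), sample_sizes=sample_sizes,
        target_mean_fst=mean_fst, n_sims=n_sims, seed=seed,
        tune_sims=int(cfg.get("tune_sims", 2000)),
        tol=float(cfg.get("tol", 0.002)),
        snps_per_locus=snps_per_locus)
    records = locus_pvalues(observed, he, fst,
                            randomized=bool(cfg.get("randomized", True)),
                            seed=seed)
    records, counts = classify_outliers(records, upper_q=upper_q, lower_q=lower_q)
    out_path = outdir / "outliers.tsv"
    pd.DataFrame([{
        "locus_id": r.locus_id, "He": r.he, "Fst": r.fst,
        "p_value": r.p_value, "p_lower": r.p_lower,
        "classification": r.classification,
    } for r in records]).to_csv(out_path, sep="\t", index=False)
    env_path = outdir / "fdist_null_envelope.tsv"
    order = np.argsort(he)
    qs = []
    w = max(50, len(he) // 40)
    for lo in range(0, len(he) - w + 1, w):
        blk = slice(lo, lo + w)
        qs.append({
            "He_mid": float(np.median(he[order][blk])),
            f"Fst_q{int(lower_q * 100)}": float(np.quantile(fst[order][blk], lower_q)),
            "Fst_median": float(np.median(fst[order][blk])),
            f"Fst_q{int(upper_q * 100)}": float(np.quantile(fst[order][blk], upper_q)),
        })
    pd.DataFrame(qs).to_csv(env_path, sep="\t", index=False)
    meta_path = outdir / "fdist_meta.json"
    with open(meta_path, "w") as fh:
        json.dump({"pops": pops, "target_mean_fst": mean_fst,
                   "scaled_migration": mig, "n_sims": n_sims,
                   "n_demes": n_demes, "counts": counts}, fh, indent=2)
        fh.write("\n")
    return [out_path, env_path, meta_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "sfs": _stage_sfs,
    "stats": _stage_stats,
    "fit": _stage_fit,
    "abc": _stage_abc,
    "fdist": _stage_fdist,
}


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    Any stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages stay on disk.
    """
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    manifest = {
        "version": __version__,
        "seed": master,
        "config": {k: v for k, v in cfg.items() if k != "outdir"},
        "stages": [],
    }
    for stage in cfg["stages"]:
        t0 = time.time()
        seed = stage_seed(master, stage)
        logger.info("[%s] starting (seed %d)", stage, seed)
        try:
            if stage == "report":
                outputs = [report(outdir)]
            else:
                outputs = _STAGE_FUNCS[stage](outdir, cfg.get(stage, {}) or {}, seed)
        except Exception as e:
            raise StageError(stage, e) from e
        manifest["stages"].append({
            "stage": stage,
            "seed": seed,
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": [{"path": str(p), "sha256": _sha256(Path(p))}
                        for p in outputs],
        })
        logger.info("[%s] done in %.1fs", stage, time.time() - t0)
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def report(run_dir) -> str:
    """Render the summary tables from existing stage outputs (pass-through
    only; nothing is recomputed)."""
    run_dir = Path(run_dir)
    lines = ["# pipeline report", ""]

    fit_path = run_dir / "model_comparison.tsv"
    if fit_path.exists():
        df = pd.read_csv(fit_path, sep="\t")
        lines.append("## model comparison (ascending AIC rank)")
        cols = ["model", "sfs_type", "snps", "MaxEstLhood", "n_parameters", "AIC", "rank"]
        lines.append(df.sort_values("rank")[cols].to_string(index=False))
        lines.append("")

    amova_path = run_dir / "amova.tsv"
    if amova_path.exists():
        df = pd.read_csv(amova_path, sep="\t")
        lines.append("## AMOVA")
        lines.append(df.to_string(index=False))
        lines.append("")

    fst_path = run_dir / "fst.tsv"
    if fst_path.exists():
        lines.append("## pairwise Fst")
        lines.append(pd.read_csv(fst_path, sep="\t", index_col=0).round(4).to_string())
        lines.append("")

    out_path = run_dir / "outliers.tsv"
    if out_path.exists():
        df = pd.read_csv(out_path, sep="\t")
        counts = df["classification"].value_counts() if len(df) else pd.Series(dtype=int)
        lines.append("## outlier scan")
        for cls in ("disruptive", "balancing", "neutral"):
            lines.append(f"{cls}: {int(counts.get(cls, 0))}")
        lines.append("")

    abc_path = run_dir / "abc_summary.json"
    if abc_path.exists():
        with open(abc_path) as fh:
            summary = json.load(fh)
        lines.append("## ABC estimates")
        for name, pe in summary.get("point_estimates", {}).items():
            hpd = summary["hpd95"][name]
            lines.append(
                f"{name}: median {pe['median']:.6g}, mode {pe['mode']:.6g}, "
                f"95% HPD [{hpd[0]:.6g}, {hpd[1]:.6g}]")
        lines.append("")

    text = "\n".join(lines)
    out = run_dir / "report.txt"
    out.write_text(text)
    return str(out)
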