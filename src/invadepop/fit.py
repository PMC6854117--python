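"""Composite-likelihood demographic fitting on joint SFS data.

The composite likelihood treats unmasked SFS cells as a multinomial
conditioned on polymorphism.  Expected cell probabilities are Monte-Carlo
estimates from simulated genealogies, weighting each branch by its length
(lower variance than tallying realised mutations).  Optimisation runs
seed-stable ECM-style cycles: each cycle re-estimates the expected SFS and
performs one coordinate-wise log-scale line update per free parameter, with
the per-cycle simulation count ramping up to anneal Monte-Carlo noise.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import msprime
import numpy as np

from .coalescent import DemographicModel
from .presets import ModelPreset
from .sfs import JointSFS

logger = logging.getLogger(__name__)


def aic(lnl: float, d: int) -> float:
    """Akaike information criterion, AIC = 2d - 2 ln(L)."""
    if d < 0:
        raise ValueError("d must be non-negative")
    return 2.0 * d - 2.0 * lnl


def bayes_factor_2ln(ml_a: float, ml_b: float) -> float:
    """Bayes-factor scale 2 ln(BF) = 2 x (ln ML_A - ln ML_B)."""
    return 2.0 * (ml_a - ml_b)


@dataclass
class ModelFitResult:
    model_id: str
    params: dict
    lnl: float
    d: int
    aic: float = None
    rank: int = None
    trajectories: list = field(default_factory=list)

    def __post_init__(self):
        if self.aic is None:
            self.aic = aic(self.lnl, self.d)


def rank_models(fits) -> list:
    """Rank by ascending AIC; ties broken by smaller d, then model_id."""
    order = sorted(fits, key=lambda f: (f.aic, f.d, f.model_id))
    out = []
    for r, f in enumerate(order, start=1):
        out.append(ModelFitResult(model_id=f.model_id, params=f.params, lnl=f.lnl,
                                  d=f.d, aic=f.aic, rank=r,
                                  trajectories=f.trajectories))
    return out


def composite_log_likelihood(obs: JointSFS, expected_probs, n_sim_trees: int = None) -> float:
    """ln L = sum over unmasked cells of m_e * ln(max(p_e, p_floor)), with
    p renormalised over unmasked cells and p_floor = 1 / (10 * n_sim_trees)."""
    probs = expected_probs.counts if isinstance(expected_probs, JointSFS) else np.asarray(expected_probs, dtype=float)
    if probs.shape != obs.counts.shape:
        raise ValueError(f"shape mismatch: obs {obs.counts.shape} vs expected {probs.shape}")
    if (probs < 0).any():
        raise ValueError("expected probabilities must be non-negative")
    if n_sim_trees is None:
        n_sim_trees = getattr(expected_probs, "n_sims", None)
    p_floor = 1.0 / (10.0 * n_sim_trees) if n_sim_trees else 1e-12
    mask = obs.mask()
    m = obs.counts[~mask]
    p = probs[~mask]
    total = p.sum()
    if total <= 0:
        raise ValueError("expected probabilities sum to zero over unmasked cells")
    p = p / total
    floored = (p < p_floor) & (m > 0)
    if floored.any():
        logger.warning("composite_log_likelihood: %d observed cells floored at %g",
                       int(floored.sum()), p_floor)
    return float((m * np.log(np.maximum(p, p_floor))).sum())


def _branch_sfs_tally(ts, pop_slices, arr):
    """Add branch lengths into SFS cells keyed by per-population descendant
    counts, for every tree of *ts*."""
    k = len(pop_slices)
    n_samples = ts.num_samples
    for tree in ts.trees():
        span = tree.interval.span / ts.sequence_length
        counts = np.zeros((ts.num_nodes, k), dtype=np.int32)
        time = ts.tables.nodes.time
        parent = tree.parent_array
        for order, (lo, hi) in enumerate(pop_slices):
            counts[lo:hi, order] = 1
        for u in tree.nodes(order="postorder"):
            p = parent[u]
            if p == -1:
                continue
            counts[p] += counts[u]
            tot = counts[u].sum()
            if tot == 0 or tot == n_samples:
                continue
            arr[tuple(counts[u])] += (time[p] - time[u]) * span


def expected_sfs(model: DemographicModel, samples: dict, n_sims: int, seed: int,
                 folded: bool = True) -> JointSFS:
    """Monte-Carlo expected per-cell polymorphic-site probabilities.

    Simulates *n_sims* region genealogies and accumulates branch lengths by
    the per-population descendant-count cell of each branch; normalised over
    unmasked cells.  Deterministic for a fixed seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    samples = {p: int(n) for p, n in samples.items() if n > 0}
    model.check_coalescible(samples.keys())
    pops = list(samples)
    dims = tuple(samples[p] + 1 for p in pops)
    arr = np.zeros(dims)
    sample_sets = [msprime.SampleSet(samples[p], population=p, ploidy=1) for p in pops]
    slices, lo = [], 0
    for p in pops:
        slices.append((lo, lo + samples[p]))
        lo += samples[p]
    reps = msprime.sim_ancestry(
        samples=sample_sets, demography=model.msprime_demography(), ploidy=1,
        sequence_length=model.region_length, num_replicates=n_sims,
        random_seed=int(seed) % (2**31 - 2) + 1,
    )
    for ts in reps:
        _branch_sfs_tally(ts, slices, arr)
    sfs = JointSFS(arr, folded=False, pop_names=tuple(pops))
    if folded:
        sfs = sfs.fold()
    mask = sfs.mask()
    sfs.counts[mask] = 0.0
    # mean branch length (generations x span fraction) per cell per region:
    # multiplied by mu * region_length it is the expected SNP count per cell
    sfs.mean_branch_intensity = sfs.counts / n_sims
    total = sfs.counts.sum()
    if total > 0:
        sfs.counts = sfs.counts / total
    sfs.n_sims = n_sims
    return sfs


def poisson_field_log_likelihood(obs: JointSFS, expected: JointSFS,
                                 mu: float, region_length: float,
                                 n_regions: int) -> float:
    """Poisson-random-field likelihood over unmasked cells:
    sum m_e ln(lambda_e) - lambda_e, with per-cell SNP intensity
    lambda_e = mu * region_length * n_regions * mean branch intensity.

    Unlike :func:`composite_log_likelihood` this is not conditioned on
    polymorphism, so overall population scale stays identifiable from
    SNP-only data.
    """
    intensity = getattr(expected, "mean_branch_intensity", None)
    if intensity is None:
        raise ValueError("expected SFS lacks branch intensities; use expected_sfs()")
    if intensity.shape != obs.counts.shape:
        raise ValueError("shape mismatch between observed and expected SFS")
    lam = mu * region_length * n_regions * intensity
    mask = obs.mask()
    m = obs.counts[~mask]
    lamu = lam[~mask]
    floor = max(lam.max() / (10.0 * getattr(expected, "n_sims", 1000)), 1e-300)
    lamu = np.maximum(lamu, floor)
    return float((m * np.log(lamu) - lamu).sum())


def _eval_seed(*parts) -> int:
    """Stable (process-independent) seed derivation from mixed int/str parts."""
    acc = []
    for p in parts:
        if isinstance(p, (int, np.integer)):
            acc.append(int(p) % (2**32))
        else:
            acc.append(zlib.crc32(str(p).encode()))
    ss = np.random.SeedSequence(entropy=tuple(acc))
    return int(ss.generate_state(1)[0])


def fit_model(
    obs: JointSFS,
    preset: ModelPreset,
    free_params: dict,
    samples: dict,
    fixed_params: dict = None,
    cycles: tuple = (10, 40),
    n_runs: int = 100,
    n_sims: int = 10000,
    seed: int = 1,
    objective: str = "conditioned",
    obs_regions: int = None,
) -> ModelFitResult:
    """Maximise the composite likelihood over *free_params* (name -> (lo, hi)
    bounds) of a model preset.

    Per independent run: parameters start at a log-uniform draw inside
    bounds, then up to ``cycles[1]`` ECM-style cycles each re-estimate the
    expected SFS (simulation count annealed from n_sims/10 up to n_sims,
    common random numbers within a cycle) and line-update every free
    parameter on a shrinking log-scale bracket.  Early exit after
    ``cycles[0]`` cycles once improvement stalls.  The best of ``n_runs``
    runs is returned; d = number of free parameters.

    ``objective`` selects the likelihood: ``"conditioned"`` (multinomial over
    polymorphic cells, the default) or ``"poisson"`` (Poisson random field
    with ``obs_regions`` regions, keeping absolute scale identifiable).
    """
    if not free_params:
        raise ValueError("free_params must name at least one parameter")
    for name, (lo, hi) in free_params.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo <= hi):
            raise ValueError(f"bounds for {name!r} must be finite and positive")
    cycles_min, cycles_max = cycles
    fixed_params = dict(fixed_params or {})
    free_names = list(free_params)

    if objective not in ("conditioned", "poisson"):
        raise ValueError("objective must be 'conditioned' or 'poisson'")

    def build(params):
        return preset.build({**fixed_params, **params})

    def lnl_at(params, n_sims_c, eval_seed):
        model = build(params)
        probs = expected_sfs(model, samples, n_sims=n_sims_c,
                             seed=eval_seed, folded=obs.folded)
        if objective == "poisson":
            n_reg = obs_regions if obs_regions is not None else model.n_regions
            return poisson_field_log_likelihood(obs, probs, model.mu,
                                                model.region_length, n_reg)
        return composite_log_likelihood(obs, probs)

    best = None
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), run)))
        params = {
            name: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            for name, (lo, hi) in free_params.items()
        }
        trajectory = []
        last_lnl, stall = -np.inf, 0
        for cycle in range(cycles_max):
            frac = cycle / max(cycles_max - 1, 1)
            n_sims_c = max(1, int(round(n_sims * (0.1 + 0.9 * frac))))
            factor = max(1.05, 2.0 * (0.75**cycle))
            cyc_seed = _eval_seed(seed, run, cycle)
            cur = lnl_at(params, n_sims_c, cyc_seed)
            for name in free_names:
                lo, hi = free_params[name]
                cands = [max(lo, params[name] / factor), min(hi, params[name] * factor)]
                lnls = [lnl_at({**params, name: c}, n_sims_c, cyc_seed) for c in cands]
                j = int(np.argmax(lnls))
                if lnls[j] > cur:
                    params[name] = cands[j]
                    cur = lnls[j]
            trajectory.append((cycle, cur, dict(params)))
            if cycle + 1 >= cycles_min:
                if cur - last_lnl < 1e-3 * max(1.0, abs(cur)):
                    stall += 1
                    if stall >= 2:
                        break
                else:
                    stall = 0
            last_lnl = cur
        final_lnl = lnl_at(params, n_sims, _eval_seed(seed, run, "final"))
        if not np.isfinite(final_lnl):
            continue
        if best is None or final_lnl > best[0]:
            best = (final_lnl, dict(params), trajectory)
    if best is None:
        raise RuntimeError("optimizer produced no finite likelihood in any run")
    lnl, params, trajectory = best
    return ModelFitResult(model_id=preset.name, params=params, lnl=lnl,
                          d=len(free_names), trajectories=trajectory)
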