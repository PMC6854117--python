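"""Approximate Bayesian computation with PLS-reduced pairwise-SFS summaries.

Workflow: draw parameters from priors, simulate datasets with the observed
configuration, summarise each as the concatenated pairwise folded SFS,
reduce summaries to a few supervised components (partial least squares fit
of summaries onto parameters), accept the draws nearest the observed data in
the standardised reduced space, then optionally apply a local-linear
(Epanechnikov-weighted) regression adjustment at the observed point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cross_decomposition import PLSRegression

from .coalescent import DemographicModel
from .io_formats import GenotypeMatrix, PopulationMap
from .sfs import JointSFS, compute_joint_sfs

__all__ = [
    "Prior", "ReferenceTable", "ABCPosterior",
    "build_reference_table", "pairwise_summary_from_matrix",
    "simulate_observed_summary", "pls_reduce", "abc_rejection",
    "regression_adjust", "hpd_interval",
]


@dataclass
class Prior:
    """A proper bounded prior, uniform on the natural or log scale."""

    low: float
    high: float
    log: bool = True

    def __post_init__(self):
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ValueError("prior bounds must be finite with low < high")
        if self.log and self.low <= 0:
            raise ValueError("log-scale prior needs positive bounds")

    def sample(self, rng) -> float:
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))


@dataclass
class ReferenceTable:
    params: pd.DataFrame
    summaries: np.ndarray
    seed: int
    model_id: str
    pop_names: tuple = ()

    def __post_init__(self):
        if len(self.params) != len(self.summaries):
            raise ValueError("one summary row per parameter row required")
        if not np.isfinite(self.summaries).all():
            raise ValueError("non-finite summary entries")


@dataclass
class ABCPosterior:
    draws: pd.DataFrame
    weights: np.ndarray
    distances: np.ndarray
    method: str
    point_estimates: dict = field(default_factory=dict)
    hpd: dict = field(default_factory=dict)

    def summarise(self, mass: float = 0.95) -> "ABCPosterior":
        pe, hpd = {}, {}
        for name in self.draws.columns:
            x = self.draws[name].to_numpy()
            w = self.weights
            order = np.argsort(x)
            cw = np.cumsum(w[order]) / w.sum()
            med = float(x[order][np.searchsorted(cw, 0.5)])
            pe[name] = {"median": med, "mode": _weighted_mode(x, w)}
            hpd[name] = hpd_interval(x, weights=w, mass=mass)
        self.point_estimates = pe
        self.hpd = hpd
        return self


def _weighted_mode(x, w) -> float:
    if np.ptp(x) == 0:
        return float(x[0])
    try:
        kde = gaussian_kde(x, weights=w)
        grid = np.linspace(x.min(), x.max(), 512)
        return float(grid[np.argmax(kde(grid))])
    except np.linalg.LinAlgError:
        return float(np.median(x))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _fold_pair(arr: np.ndarray) -> np.ndarray:
    """Fold a 2-D spectrum on total derived count (cf. sfs fold rule)."""
    n1, n2 = arr.shape[0] - 1, arr.shape[1] - 1
    out = np.zeros_like(arr)
    for v1 in range(n1 + 1):
        for v2 in range(n2 + 1):
            c = arr[v1, v2]
            if c == 0:
                continue
            tv, tn = v1 + v2, n1 + n2
            comp = (n1 - v1, n2 - v2)
            if 2 * tv > tn or (2 * tv == tn and comp < (v1, v2)):
                out[comp] += c
            else:
                out[v1, v2] += c
    return out


def _tally_pairwise(derived_by_pop: np.ndarray, sizes: list, folded: bool, arrays: list):
    """Add per-site derived counts (sites x pops) into pairwise 2-D spectra."""
    k = len(sizes)
    for idx, (i, j) in enumerate(itertools.combinations(range(k), 2)):
        np.add.at(arrays[idx], (derived_by_pop[:, i], derived_by_pop[:, j]), 1.0)


def _pair_arrays(sizes) -> list:
    return [np.zeros((sizes[i] + 1, sizes[j] + 1))
            for i, j in itertools.combinations(range(len(sizes)), 2)]


def _flatten_pairs(arrays, folded) -> np.ndarray:
    out = []
    for arr in arrays:
        a = _fold_pair(arr) if folded else arr
        out.append(a.ravel(order="C"))
    return np.concatenate(out)


def simulate_observed_summary(model: DemographicModel, samples: dict, seed: int,
                              folded: bool = True, n_regions: int = None) -> np.ndarray:
    """Summary vector (concatenated pairwise SFS, pair order (i, j) with
    i < j in population order, cells row-major) of one simulated dataset."""
    pops = list(samples)
    sizes = [int(samples[p]) for p in pops]
    arrays = _pair_arrays(sizes)
    sample_sets = [msprime.SampleSet(samples[p], population=p, ploidy=1) for p in pops]
    slices, lo = [], 0
    for n in sizes:
        slices.append((lo, lo + n))
        lo += n
    n_regions = model.n_regions if n_regions is None else int(n_regions)
    reps = msprime.sim_ancestry(
        samples=sample_sets, demography=model.msprime_demography(), ploidy=1,
        sequence_length=model.region_length, num_replicates=n_regions,
        random_seed=int(seed) % (2**31 - 2) + 1,
    )
    base = int(seed) % (2**31 - 2)
    for r, ts in enumerate(reps):
        mts = msprime.sim_mutations(ts, rate=model.mu, discrete_genome=False,
                                    model=msprime.BinaryMutationModel(),
                                    random_seed=(base + 7919 * r) % (2**31 - 2) + 1)
        if mts.num_sites == 0:
            continue
        g = mts.genotype_matrix()  # sites x samples
        derived = np.column_stack([g[:, a:b].sum(axis=1) for a, b in slices])
        _tally_pairwise(derived, sizes, folded, arrays)
    return _flatten_pairs(arrays, folded)


def pairwise_summary_from_matrix(gm: GenotypeMatrix, pm: PopulationMap, pops,
                                 folded: bool = True) -> np.ndarray:
    """Observed-data summary in the same layout as the reference table."""
    parts = []
    for i, j in itertools.combinations(range(len(pops)), 2):
        sfs = compute_joint_sfs(gm, pm, [pops[i], pops[j]], folded=folded)
        parts.append(sfs.counts.ravel(order="C"))
    return np.concatenate(parts)


def build_reference_table(preset, priors: dict, n_sims: int, samples: dict,
                          seed: int, fixed_params: dict = None,
                          folded: bool = True, n_regions: int = None) -> ReferenceTable:
    """Simulate *n_sims* parameter draws and their pairwise-SFS summaries.

    *preset* is a :class:`~invadepop.presets.ModelPreset` (or any object with
    a ``build(params) -> DemographicModel`` method and a ``name``).  Priors
    map parameter name -> :class:`Prior`.
    """
    priors = {k: (v if isinstance(v, Prior) else Prior(*v)) for k, v in priors.items()}
    fixed_params = dict(fixed_params or {})
    rows, summaries = [], []
    for i in range(n_sims):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), i)))
        draw = {name: pr.sample(rng) for name, pr in priors.items()}
        model = preset.build({**fixed_params, **draw})
        sim_seed = int(rng.integers(1, 2**31 - 2))
        summaries.append(simulate_observed_summary(model, samples, seed=sim_seed,
                                                   folded=folded, n_regions=n_regions))
        rows.append(draw)
    return ReferenceTable(
        params=pd.DataFrame(rows),
        summaries=np.asarray(summaries),
        seed=int(seed),
        model_id=getattr(preset, "name", "custom"),
        pop_names=tuple(samples),
    )


# ---------------------------------------------------------------------------
# PLS reduction, rejection, adjustment
# ---------------------------------------------------------------------------

def pls_reduce(table: ReferenceTable, observed_summary: np.ndarray,
               n_components: int = 10):
    """Supervised reduction: PLS of summaries onto parameters; both the table
    and the observed summary are projected.  Components are centred over the
    table rows.  Returns ``(reduced_table, reduced_observed, pls_model)``."""
    n_components = int(n_components)
    max_comp = min(table.summaries.shape[1], len(table.params) - 1)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    keep = table.summaries.std(axis=0) > 0
    S = table.summaries[:, keep]
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(S, table.params.to_numpy())
    reduced = pls.transform(S)
    reduced_obs = pls.transform(np.asarray(observed_summary)[keep].reshape(1, -1))[0]
    return reduced, reduced_obs, pls


def abc_rejection(reduced: np.ndarray, reduced_obs: np.ndarray,
                  params: pd.DataFrame, n_accept: int = 5000) -> ABCPosterior:
    """Accept the *n_accept* rows nearest the observed point (Euclidean
    distance after per-component standardisation by the table SD); ties at
    the cutoff broken by row order."""
    if n_accept > len(params):
        raise ValueError("n_accept exceeds the table size")
    sd = reduced.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (reduced - reduced_obs) / sd
    dist = np.sqrt((z**2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:n_accept]
    post = ABCPosterior(
        draws=params.iloc[order].reset_index(drop=True),
        weights=np.ones(len(order)),
        distances=dist[order],
        method="rejection",
    )
    post._accepted_rows = order
    return post


def regression_adjust(posterior: ABCPosterior, reduced: np.ndarray,
                      reduced_obs: np.ndarray, method: str = "loclinear",
                      seed: int = 1) -> ABCPosterior:
    """Regression-adjust the rejection posterior at the observed point.

    ``loclinear``: Epanechnikov-weighted linear regression of each parameter
    on the reduced summaries among accepted rows; residual correction
    applied at the observed point.  ``neuralnet``: single-hidden-layer
    regression with seeded initialisation (optional alternative).
    """
    rows = getattr(posterior, "_accepted_rows", None)
    if rows is None:
        raise ValueError("posterior must come from abc_rejection")
    S = reduced[rows] - reduced_obs
    d = posterior.distances
    dmax = d.max() if d.max() > 0 else 1.0
    w = 1.0 - (d / dmax) ** 2
    w = np.where(w > 0, w, 1e-12)
    theta = posterior.draws.to_numpy(dtype=float)
    if method == "loclinear":
        X = np.column_stack([np.ones(len(S)), S])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ theta, rcond=None)
        adjusted = theta - S @ beta[1:]
    elif method == "neuralnet":
        from sklearn.neural_network import MLPRegressor

        net = MLPRegressor(hidden_layer_sizes=(8,), max_iter=2000,
                           random_state=int(seed))
        net.fit(S, theta if theta.shape[1] > 1 else theta.ravel())
        pred = np.atleast_2d(net.predict(S))
        pred = pred.T if pred.shape[0] == 1 and theta.shape[0] > 1 else pred
        pred_obs = np.atleast_1d(net.predict(np.zeros((1, S.shape[1]))))
        adjusted = theta - (pred.reshape(theta.shape) - pred_obs.reshape(1, -1))
    else:
        raise ValueError("method must be 'loclinear' or 'neuralnet'")
    out = ABCPosterior(
        draws=pd.DataFrame(adjusted, columns=posterior.draws.columns),
        weights=w,
        distances=posterior.distances,
        method=method,
    )
    out._accepted_rows = rows
    return out


def hpd_interval(draws, weights=None, mass: float = 0.95) -> tuple:
    """Shortest contiguous interval holding >= *mass* of the weighted draws
    (sorted sliding window)."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("no draws")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.concatenate([[0.0], np.cumsum(ws)])
    total = cw[-1]
    n = len(xs)
    best = (np.inf, xs[0], xs[-1])
    j = 0
    for i in range(n):
        if j < i:
            j = i
        while j < n and (cw[j + 1] - cw[i]) < mass * total - 1e-12:
            j += 1
        if j >= n:
            break
        width = xs[j] - xs[i]
        if width < best[0]:
            best = (width, xs[i], xs[j])
    return (float(best[1]), float(best[2]))
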