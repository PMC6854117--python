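"""Descriptive population-genetic statistics.

Nucleotide diversity, multi-locus Weir & Cockerham (1984) theta with
permutation significance, three-level AMOVA on allele-mismatch distances, and
PCA coordinates of genotype dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "nucleotide_diversity",
    "pairwise_fst",
    "wc_theta",
    "wc_site_components",
    "amova",
    "amova_percentages",
    "AmovaResult",
    "FstMatrix",
    "pca_coordinates",
]


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------

def wc_site_components(alt, called, het):
    """Per-site Weir-Cockerham variance components a, b, c.

    Parameters are (n_sites, r) arrays: *alt* = alt-allele copy count,
    *called* = called haploid copies (2 x individuals), *het* = heterozygote
    individual count, per population.  Sites where any population has < 2
    called copies yield (0, 0, 0).
    """
    alt = np.asarray(alt, dtype=float)
    called = np.asarray(called, dtype=float)
    het = np.asarray(het, dtype=float)
    r = alt.shape[1]
    valid = (called >= 2).all(axis=1)
    n = np.where(called > 0, called / 2.0, np.nan)  # individuals
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / called
        h = het / n
        nbar = n.mean(axis=1)
        nc = (r * nbar - (n**2).sum(axis=1) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=1) / (r * nbar)
        s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=1) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = ~valid | ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    a[bad] = b[bad] = c[bad] = 0.0
    return a, b, c


def _pop_counts(geno, groups):
    """alt / called / het count arrays (n_sites, r) for column groups."""
    alt = np.empty((geno.shape[0], len(groups)))
    called = np.empty_like(alt)
    het = np.empty_like(alt)
    for k, cols in enumerate(groups):
        g = geno[:, cols]
        ok = g != MISSING
        alt[:, k] = np.where(ok, g, 0).sum(axis=1)
        called[:, k] = 2 * ok.sum(axis=1)
        het[:, k] = (g == 1).sum(axis=1)
    return alt, called, het


def wc_theta(geno, groups) -> float:
    """Multi-locus Weir-Cockerham theta = sum(a) / sum(a + b + c) for the
    given column groups of the dosage matrix."""
    a, b, c = wc_site_components(*_pop_counts(geno, groups))
    denom = (a + b + c).sum()
    return float(a.sum() / denom) if denom != 0 else float("nan")


@dataclass
class FstMatrix:
    pop_names: list
    theta: np.ndarray
    p_values: np.ndarray


def pairwise_fst(gm: GenotypeMatrix, pm: PopulationMap, n_perm: int = 1000,
                 seed: int = 1) -> FstMatrix:
    """Pairwise multi-locus Weir-Cockerham theta with label-permutation
    p-values, p = (#{theta_perm >= theta_obs} + 1) / (n_perm + 1)."""
    pm.validate_against(gm)
    pops = [p for p in pm.labels if pm.individuals(p)]
    cols = {p: np.array([gm.individual_ids.index(i) for i in pm.individuals(p)]) for p in pops}
    for p in pops:
        if len(cols[p]) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
    k = len(pops)
    theta = np.zeros((k, k))
    pvals = np.ones((k, k))
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            ci, cj = cols[pops[i]], cols[pops[j]]
            both = np.concatenate([ci, cj])
            geno = gm.genotypes[:, both]
            ni = len(ci)
            obs = wc_theta(geno, [np.arange(ni), np.arange(ni, len(both))])
            theta[i, j] = theta[j, i] = obs
            if n_perm > 0:
                count = 0
                for _ in range(n_perm):
                    perm = rng.permutation(len(both))
                    t = wc_theta(geno, [perm[:ni], perm[ni:]])
                    if not np.isnan(t) and t >= obs:
                        count += 1
                p = (count + 1) / (n_perm + 1)
                pvals[i, j] = pvals[j, i] = p
    np.fill_diagonal(pvals, 1.0)
    return FstMatrix(pop_names=pops, theta=theta, p_values=pvals)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(gm: GenotypeMatrix, pm: PopulationMap,
                         total_length: float = None,
                         region_lengths: dict = None) -> dict:
    """Per-population Pi: sum over sites of 2*p*q*n/(n-1), divided by the
    sequence length (``total_length``, or the summed ``region_lengths`` of
    regions present); per-variant average when no length is supplied."""
    pm.validate_against(gm)
    if total_length is None and region_lengths is not None:
        total_length = float(sum(region_lengths[r] for r in dict.fromkeys(gm.region_id)))
    out = {}
    for p in pm.labels:
        inds = pm.individuals(p)
        if not inds:
            continue
        c = np.array([gm.individual_ids.index(i) for i in inds])
        g = gm.genotypes[:, c]
        ok = g != MISSING
        n = 2.0 * ok.sum(axis=1)
        alt = np.where(ok, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_site = 2.0 * alt * (n - alt) / (n * (n - 1))
        per_site = np.where(n >= 2, per_site, 0.0)
        total = per_site.sum()
        denom = total_length if total_length else max(gm.n_sites, 1)
        out[p] = float(total / denom)
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    sum_of_squares: dict
    df: dict
    components: dict         # sigma_a, sigma_b, sigma_c as computed
    percentages: dict        # clamped-at-zero display percentages
    p_values: dict

    def total_component(self) -> float:
        return sum(self.components.values())


def amova_percentages(sigma_a: float, sigma_b: float, sigma_c: float) -> tuple:
    """Percentages of total variance; negative components clamped to zero for
    display only."""
    comp = np.array([max(sigma_a, 0.0), max(sigma_b, 0.0), max(sigma_c, 0.0)])
    total = comp.sum()
    if total == 0:
        return (0.0, 0.0, 0.0)
    pct = 100.0 * comp / total
    return tuple(float(x) for x in pct)


def _allele_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Gene-copy rows (2 per individual): 0/1 alleles, missing mean-imputed."""
    g = gm.genotypes.astype(float).T  # individuals x sites
    miss = g == MISSING
    with np.errstate(invalid="ignore"):
        site_mean = np.where(miss, np.nan, g).sum(axis=0) / (~miss).sum(axis=0)
    site_mean = np.nan_to_num(site_mean, nan=0.0)
    n_ind, n_sites = g.shape
    copies = np.empty((2 * n_ind, n_sites))
    # called dosage d -> copies (max(d-1,0), min(d,1)); imputed mean m -> (m/2, m/2)
    first = np.clip(g - 1.0, 0.0, 1.0)
    second = np.clip(g, 0.0, 1.0)
    imputed = site_mean[None, :] / 2.0
    copies[0::2] = np.where(miss, imputed, first)
    copies[1::2] = np.where(miss, imputed, second)
    return copies


def _ssd(x_sq_norms, x, index_sets):
    """Sum over sets S of (1/|S|) * sum_{i<j in S} ||x_i - x_j||^2."""
    total = 0.0
    for s in index_sets:
        ns = len(s)
        if ns < 2:
            continue
        sub_sq = x_sq_norms[s].sum()
        centroid = x[s].sum(axis=0)
        total += (ns * sub_sq - centroid @ centroid) / ns
    return total


def _amova_components(x, pops_of_copy, groups_of_pop):
    """Variance components from nested sums of squares over gene copies."""
    pops = list(dict.fromkeys(pops_of_copy))
    groups = list(dict.fromkeys(groups_of_pop[p] for p in pops))
    copy_idx = np.arange(len(pops_of_copy))
    by_pop = {p: copy_idx[[q == p for q in pops_of_copy]] for p in pops}
    by_group = {
        g: np.concatenate([by_pop[p] for p in pops if groups_of_pop[p] == g])
        for g in groups
    }
    N = len(pops_of_copy)
    P, G = len(pops), len(groups)
    sq = (x * x).sum(axis=1)
    ssd_total = _ssd(sq, x, [copy_idx])
    ssd_wp = _ssd(sq, x, list(by_pop.values()))
    ssd_wg = _ssd(sq, x, list(by_group.values()))
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ssd_wp / df_wp if df_wp else 0.0
    ms_ap = ssd_ap / df_ap if df_ap else 0.0
    ms_ag = ssd_ag / df_ag if df_ag else 0.0

    n_p = {p: len(by_pop[p]) for p in pops}
    N_g = {g: len(by_group[g]) for g in groups}
    sum_np2_over_Ng = sum(
        sum(n_p[p] ** 2 for p in pops if groups_of_pop[p] == g) / N_g[g] for g in groups
    )
    n1 = (N - sum_np2_over_Ng) / df_ap if df_ap else 1.0
    n2 = (sum_np2_over_Ng - sum(n_p[p] ** 2 for p in pops) / N) / df_ag if df_ag else 1.0
    n3 = (N - sum(N_g[g] ** 2 for g in groups) / N) / df_ag if df_ag else 1.0

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if n1 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if n3 else 0.0
    ss = {"among_groups": ssd_ag, "among_pops_within_groups": ssd_ap,
          "within_pops": ssd_wp, "total": ssd_total}
    df = {"among_groups": df_ag, "among_pops_within_groups": df_ap, "within_pops": df_wp}
    return sigma_a, sigma_b, sigma_c, ss, df


def amova(gm: GenotypeMatrix, pm: PopulationMap, grouping: dict,
          n_perm: int = 10000, seed: int = 1) -> AmovaResult:
    """Three-level AMOVA: among groups / among populations within groups /
    within populations, on allele-mismatch distances between gene copies.

    *grouping* maps population label -> group label.  Permutation p-values:
    sigma_a permutes populations among groups, sigma_b permutes individuals
    among populations within groups, sigma_c permutes individuals among all
    populations.
    """
    pm.validate_against(gm)
    pops = [p for p in pm.labels if pm.individuals(p)]
    for p in pops:
        if p not in grouping:
            raise ValueError(f"population {p!r} missing from grouping")
    x = _allele_matrix(gm)
    ind_pop = [pm.assignments[i] for i in gm.individual_ids]
    pops_of_copy = [p for p in ind_pop for _ in (0, 1)]
    sigma_a, sigma_b, sigma_c, ss, df = _amova_components(x, pops_of_copy, grouping)
    pct = amova_percentages(sigma_a, sigma_b, sigma_c)

    rng = np.random.default_rng(seed)
    p_values = {}
    if n_perm > 0:
        n_ind = len(ind_pop)
        count_a = count_b = count_c = 0
        group_of = dict(grouping)
        pop_list = list(pops)
        for _ in range(n_perm):
            # (a) populations among groups
            perm_groups = rng.permutation([group_of[p] for p in pop_list])
            ga = dict(zip(pop_list, perm_groups))
            sa, _, _, _, _ = _amova_components(x, pops_of_copy, ga)
            if sa >= sigma_a:
                count_a += 1
            # (b) individuals among populations within groups
            labels = np.array(ind_pop, dtype=object)
            for g in set(group_of.values()):
                members = np.flatnonzero([group_of[p] == g for p in labels])
                labels[members] = labels[members][rng.permutation(len(members))]
            copies_b = [p for p in labels for _ in (0, 1)]
            _, sb, _, _, _ = _amova_components(x, copies_b, group_of)
            if sb >= sigma_b:
                count_b += 1
            # (c) individuals among all populations
            labels_c = np.array(ind_pop, dtype=object)[rng.permutation(n_ind)]
            copies_c = [p for p in labels_c for _ in (0, 1)]
            _, _, sc, _, _ = _amova_components(x, copies_c, group_of)
            if sc >= sigma_c:
                count_c += 1
        p_values = {
            "among_groups": (count_a + 1) / (n_perm + 1),
            "among_pops_within_groups": (count_b + 1) / (n_perm + 1),
            "within_pops": (count_c + 1) / (n_perm + 1),
        }
    return AmovaResult(
        sum_of_squares=ss,
        df=df,
        components={"among_groups": sigma_a, "among_pops_within_groups": sigma_b,
                    "within_pops": sigma_c},
        percentages={"among_groups": pct[0], "among_pops_within_groups": pct[1],
                     "within_pops": pct[2]},
        p_values=p_values,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_coordinates(gm: GenotypeMatrix, n_components: int = None, scale: bool = False):
    """PC scores and explained-variance fractions of mean-imputed, centred
    genotype dosages.

    Sign convention: each component is flipped so its largest-magnitude score
    is positive.  Returns ``(scores, explained_fraction)``.
    """
    if gm.n_individuals < 2 or gm.n_sites < 1:
        raise ValueError("PCA needs at least 2 individuals and 1 variant")
    g = gm.genotypes.astype(float).T  # individuals x sites
    miss = g == MISSING
    with np.errstate(invalid="ignore"):
        col_mean = np.where(miss, np.nan, g).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    g = np.where(miss, col_mean[None, :], g)
    g = g - g.mean(axis=0)
    if scale:
        sd = g.std(axis=0, ddof=1)
        g = g / np.where(sd > 0, sd, 1.0)
    u, s, _vt = np.linalg.svd(g, full_matrices=False)
    scores = u * s
    for k in range(scores.shape[1]):
        if scores[np.argmax(np.abs(scores[:, k])), k] < 0:
            scores[:, k] = -scores[:, k]
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    if n_components is not None:
        scores = scores[:, :n_components]
        explained = explained[:n_components]
    return scores, explained
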