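"""Joint site-frequency spectra: construction, folding, polarisation,
projection and marginalisation.

Conventions
-----------
* ``dims = (n1+1, ..., nk+1)`` for haploid sample sizes ``n_i``.
* Monomorphic corners (all-zero cell; and the all-n cell when unfolded) are
  masked out of likelihood sums.
* Folding is on *total* derived count: cell ``v`` pairs with ``n - v``; at the
  exact midpoint the lexicographically smaller index vector holds the mass.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io_formats import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class JointSFS:
    counts: np.ndarray
    folded: bool = False
    pop_names: tuple = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("SFS counts must be non-negative")

    @property
    def dims(self) -> tuple:
        return self.counts.shape

    @property
    def sample_sizes(self) -> tuple:
        return tuple(d - 1 for d in self.counts.shape)

    def mask(self) -> np.ndarray:
        """Boolean array marking masked (monomorphic-corner) cells."""
        m = np.zeros(self.counts.shape, dtype=bool)
        zero = (0,) * self.counts.ndim
        m[zero] = True
        m[tuple(d - 1 for d in self.counts.shape)] = True
        return m

    def unmasked_sum(self) -> float:
        return float(self.counts[~self.mask()].sum())

    def fold(self) -> "JointSFS":
        """Fold on total derived count (idempotent)."""
        if self.folded:
            return JointSFS(self.counts.copy(), folded=True, pop_names=self.pop_names)
        n = self.sample_sizes
        out = np.zeros_like(self.counts)
        for v in itertools.product(*[range(d) for d in self.counts.shape]):
            c = self.counts[v]
            if c == 0:
                continue
            out[_fold_index(v, n)] += c
        return JointSFS(out, folded=True, pop_names=self.pop_names)

    def marginal(self, i: int, j: int) -> "JointSFS":
        """2-D margin over populations *i* and *j* (axes summed out)."""
        if self.counts.ndim < 2:
            raise ValueError("need at least 2 populations to marginalise")
        axes = tuple(a for a in range(self.counts.ndim) if a not in (i, j))
        arr = self.counts.sum(axis=axes) if axes else self.counts.copy()
        if i > j:
            arr = arr.T
        names = (self.pop_names[i], self.pop_names[j]) if self.pop_names else ()
        return JointSFS(arr, folded=self.folded, pop_names=names)


def _fold_index(v: tuple, n: tuple) -> tuple:
    comp = tuple(ni - vi for ni, vi in zip(n, v))
    tv, tn = sum(v), sum(n)
    if 2 * tv > tn:
        return comp
    if 2 * tv == tn:
        return min(v, comp)
    return v


def _projection_weights(n_from: int, k_from: int, n_to: int) -> np.ndarray:
    """Hypergeometric weights over derived counts 0..n_to when subsampling
    n_to copies from n_from copies of which k_from are derived."""
    j = np.arange(n_to + 1)
    return hypergeom.pmf(j, n_from, k_from, n_to)


def compute_joint_sfs(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pops,
    folded: bool = True,
    project_to=None,
) -> JointSFS:
    """Tally the k-dimensional joint SFS over the requested populations.

    Each site contributes one unit of mass at the cell of its per-population
    alt (derived) allele counts.  With ``project_to`` (haploid sizes per
    population), sites with missing data are hypergeometrically projected
    down; without it, sites incomplete in any requested population are
    skipped.
    """
    pops = list(pops)
    for p in pops:
        if p not in pm.labels:
            raise ValueError(f"population {p!r} not present in population map")
    col_idx = []
    for p in pops:
        inds = pm.individuals(p)
        cols = [gm.individual_ids.index(i) for i in inds if i in gm.individual_ids]
        if not cols:
            raise ValueError(f"population {p!r} has no individuals in the matrix")
        col_idx.append(np.array(cols))
    full_sizes = [2 * len(c) for c in col_idx]
    if project_to is not None:
        target = list(project_to)
        if len(target) != len(pops):
            raise ValueError("project_to must give one haploid size per population")
        for t, f in zip(target, full_sizes):
            if not 1 <= t <= f:
                raise ValueError("projection sizes must be in [1, full haploid size]")
    else:
        target = full_sizes

    dims = tuple(t + 1 for t in target)
    counts = np.zeros(dims)
    geno = gm.genotypes
    n_skipped = 0
    for s in range(gm.n_sites):
        derived, called = [], []
        for cols in col_idx:
            g = geno[s, cols]
            ok = g != MISSING
            derived.append(int(g[ok].sum()))
            called.append(int(2 * ok.sum()))
        if project_to is None:
            if any(c != f for c, f in zip(called, full_sizes)):
                n_skipped += 1
                continue
            counts[tuple(derived)] += 1.0
        else:
            if any(c < t for c, t in zip(called, target)):
                n_skipped += 1
                continue
            weights = [
                _projection_weights(c, d, t)
                for c, d, t in zip(called, derived, target)
            ]
            mass = weights[0]
            for w in weights[1:]:
                mass = np.multiply.outer(mass, w)
            counts += mass
    if n_skipped:
        logger.info("compute_joint_sfs: %d sites skipped (insufficient calls)", n_skipped)
    sfs = JointSFS(counts, folded=False, pop_names=tuple(pops))
    return sfs.fold() if folded else sfs


def polarize_with_outgroup(gm: GenotypeMatrix, outgroup_alleles) -> GenotypeMatrix:
    """Re-code alleles so 1 = the allele differing from the outgroup base.

    ``outgroup_alleles`` maps locus_id -> base (or is a per-site sequence).
    Sites without a known outgroup base, or where the base matches neither
    allele, are dropped with a logged count.
    """
    if not isinstance(outgroup_alleles, dict):
        if len(outgroup_alleles) != gm.n_sites:
            raise ValueError("per-site outgroup sequence length mismatch")
        outgroup_alleles = dict(zip(gm.locus_id, outgroup_alleles))
    keep, flip = [], []
    n_unknown = n_mismatch = 0
    for i in range(gm.n_sites):
        base = outgroup_alleles.get(gm.locus_id[i])
        if base is None or base == "N":
            n_unknown += 1
            continue
        if base == gm.ref_allele[i]:
            keep.append(i)
            flip.append(False)
        elif base == gm.alt_allele[i]:
            keep.append(i)
            flip.append(True)
        else:
            n_mismatch += 1
    if n_unknown or n_mismatch:
        logger.info(
            "polarize_with_outgroup: dropped %d sites with unknown and %d with "
            "mismatching outgroup base", n_unknown, n_mismatch,
        )
    out = gm.take_sites(keep)
    for row, do_flip in enumerate(flip):
        if do_flip:
            g = out.genotypes[row]
            valid = g != MISSING
            out.genotypes[row, valid] = 2 - g[valid]
            out.ref_allele[row], out.alt_allele[row] = out.alt_allele[row], out.ref_allele[row]
    return out


def marginal_pairwise_sfs(sfs: JointSFS, i: int, j: int) -> JointSFS:
    return sfs.marginal(i, j)
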