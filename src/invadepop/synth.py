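"""Seeded synthetic fixtures emulating the shape of the study data.

A fixture is a VCF + population map + truth JSON triple simulated from one
of the invasion presets, with the study's nine populations and per-population
sample sizes, optionally carrying spiked loci whose between-cluster migration
is rescaled as a divergent/balancing-selection proxy.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .coalescent import DemographicModel, simulate_dataset
from .io_formats import GenotypeMatrix, PopulationMap
from .presets import DEEP_CLUSTER, STUDY_SAMPLE_SIZES, get_preset

logger = logging.getLogger(__name__)


@dataclass
class FixtureSpec:
    preset: str = "model3"
    scale: float = 0.1
    sample_sizes: dict = field(default_factory=lambda: dict(STUDY_SAMPLE_SIZES))
    params: dict = field(default_factory=dict)
    spike_fraction: float = 0.0
    spike_migration_scale: float = 1.0
    seed: int = 1

    def __post_init__(self):
        if not 0 < self.scale <= 1:
            raise ValueError("scale must lie in (0, 1]")
        if any(n < 2 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be >= 2 diploids")
        if not 0 <= self.spike_fraction <= 1:
            raise ValueError("spike_fraction must lie in [0, 1]")


def _haploid_samples(spec: FixtureSpec) -> dict:
    return {p: 2 * n for p, n in spec.sample_sizes.items()}


def _build_model(spec: FixtureSpec) -> DemographicModel:
    return get_preset(spec.preset).build(spec.params or None)


def _between_cluster_scaled(model: DemographicModel, factor: float) -> DemographicModel:
    """Copy of *model* with migration between the deep cluster and the rest
    divided by *factor* (values > 1 reduce gene flow: divergent proxy)."""
    mig = model.migration.copy()
    names = model.pop_names
    crossing = False
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            if (a in DEEP_CLUSTER) != (b in DEEP_CLUSTER) and mig[i, j] > 0:
                mig[i, j] = mig[i, j] / factor
                crossing = True
    if not crossing and factor != 1.0:
        raise ValueError(
            "model has no between-cluster migration to rescale; use a "
            "migration-bearing preset (e.g. model4) for spiked fixtures"
        )
    return dataclasses.replace(model, migration=mig)


def spike_outlier_loci(gm: GenotypeMatrix, model: DemographicModel, samples: dict,
                       fraction: float, migration_scale: float, seed: int,
                       n_regions: int = None):
    """Resimulate a random *fraction* of regions with between-cluster
    migration divided by *migration_scale* (multiplied when < 1, the
    balancing proxy); returns ``(new_matrix, spiked_region_ids)``.

    Per-region child seeds are reused, so ``migration_scale == 1`` returns a
    matrix identical to the input.
    """
    n_regions = model.n_regions if n_regions is None else int(n_regions)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), zlib.crc32(b"spike"))))
    n_spiked = int(round(fraction * n_regions))
    if n_spiked == 0:
        return gm, []
    width = max(4, len(str(n_regions)))
    all_ids = [f"r{r:0{width}d}" for r in range(n_regions)]
    spiked_idx = sorted(rng.choice(n_regions, size=n_spiked, replace=False).tolist())
    spiked_ids = [all_ids[r] for r in spiked_idx]
    scaled = _between_cluster_scaled(model, migration_scale)
    new = simulate_dataset(scaled, samples, diploid=True, seed=seed,
                           n_regions=n_regions, region_indices=spiked_idx)
    spiked_set = set(spiked_ids)
    keep_old = [i for i in range(gm.n_sites) if gm.region_id[i] not in spiked_set]
    old = gm.take_sites(keep_old)
    merged = GenotypeMatrix(
        locus_id=old.locus_id + new.locus_id,
        region_id=old.region_id + new.region_id,
        position=np.concatenate([old.position, new.position]),
        ref_allele=old.ref_allele + new.ref_allele,
        alt_allele=old.alt_allele + new.alt_allele,
        qual=np.concatenate([old.qual, new.qual]),
        genotypes=np.vstack([old.genotypes, new.genotypes]),
        individual_ids=list(gm.individual_ids),
    )
    order = sorted(range(merged.n_sites),
                   key=lambda i: (merged.region_id[i], int(merged.position[i])))
    return merged.take_sites(order), spiked_ids


def simulate_fixture(spec: FixtureSpec):
    """Simulate a fixture in memory: ``(GenotypeMatrix, PopulationMap, truth)``."""
    model = _build_model(spec)
    n_regions = max(1, int(round(spec.scale * model.n_regions)))
    samples = _haploid_samples(spec)
    gm = simulate_dataset(model, samples, diploid=True, seed=spec.seed,
                          n_regions=n_regions)
    spiked_ids = []
    if spec.spike_fraction > 0:
        gm, spiked_ids = spike_outlier_loci(
            gm, model, samples, spec.spike_fraction, spec.spike_migration_scale,
            seed=spec.seed, n_regions=n_regions)
    pm = PopulationMap(assignments={i: i.split("_")[0] for i in gm.individual_ids},
                       labels=list(spec.sample_sizes))
    truth = {
        "preset": spec.preset,
        "scale": spec.scale,
        "n_regions": n_regions,
        "region_length": model.region_length,
        "mu": model.mu,
        "seed": spec.seed,
        "sample_sizes": dict(spec.sample_sizes),
        "params": get_preset(spec.preset).params(spec.params or None),
        "spiked_region_ids": spiked_ids,
        "spike_migration_scale": spec.spike_migration_scale,
        "n_sites": gm.n_sites,
        "n_variable_regions": len(set(gm.region_id)),
    }
    return gm, pm, truth


def make_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write VCF + popmap + truth JSON for *spec* into *outdir*; returns the
    paths.  Byte-identical for identical specs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, pm, truth = simulate_fixture(spec)
    paths = {
        "vcf": outdir / "fixture.vcf",
        "popmap": outdir / "popmap.tsv",
        "truth": outdir / "truth.json",
    }
    io_formats.write_vcf(gm, paths["vcf"])
    io_formats.write_popmap(pm, paths["popmap"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("make_fixture: %d sites over %d variable regions -> %s",
                gm.n_sites, truth["n_variable_regions"], outdir)
    return {k: str(v) for k, v in paths.items()}
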