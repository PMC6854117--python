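"""Structured-coalescent simulation over user-specified demographic models.

The engine behind expected SFS estimation, ABC reference tables and the
synthetic fixtures.  Genealogies are drawn with msprime; mutations follow an
infinite-sites model (binary alleles, continuous positions discretised to
distinct 1-based integer sites within each region).

Conventions
-----------
* Time is backward in generations before present.
* Population sizes are in haploid gene copies (the CLI accepts diploid N and
  doubles it).
* ``migration[i][j]`` is the backward per-generation probability that a
  lineage currently in population ``i`` traces back to population ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import yaml

from .io_formats import GenotypeMatrix


class ModelValidityError(ValueError):
    pass


@dataclass
class Fusion:
    """Backward in time, lineages in *source* move into *sink*."""

    time: float
    source: str
    sink: str
    kind: str = "fusion"


@dataclass
class SizeChange:
    time: float
    pop: str
    new_size: float
    kind: str = "size_change"


@dataclass
class MigrationChange:
    time: float
    matrix: object = None
    kind: str = "migration_change"


@dataclass
class DemographicModel:
    pop_names: list
    sizes: dict
    events: list = field(default_factory=list)
    migration: np.ndarray = None
    mu: float = 2.5e-8
    n_regions: int = 2869
    region_length: int = 214
    generation_time: float = 3.0

    def __post_init__(self):
        k = len(self.pop_names)
        if self.migration is None:
            self.migration = np.zeros((k, k))
        self.migration = np.asarray(self.migration, dtype=float)
        self._demography = None
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        k = len(self.pop_names)
        if len(set(self.pop_names)) != k:
            raise ModelValidityError("duplicate population names")
        for p in self.pop_names:
            if self.sizes.get(p, 0) <= 0:
                raise ModelValidityError(f"population {p!r} needs a positive size")
        if self.migration.shape != (k, k):
            raise ModelValidityError("migration matrix shape mismatch")
        off = self.migration[~np.eye(k, dtype=bool)]
        if (off < 0).any():
            raise ModelValidityError("negative migration rate")
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ModelValidityError("event times must be non-decreasing")
        for e in self.events:
            if isinstance(e, Fusion):
                for p in (e.source, e.sink):
                    if p not in self.pop_names:
                        raise ModelValidityError(f"fusion references unknown population {p!r}")
            elif isinstance(e, SizeChange):
                if e.pop not in self.pop_names:
                    raise ModelValidityError(f"size change references unknown population {e.pop!r}")
                if e.new_size <= 0:
                    raise ModelValidityError("size change to non-positive size")

    def check_coalescible(self, sampled_pops) -> None:
        """Error unless lineages from the sampled populations can all meet.

        Populations must be connected through fusions or through nonzero
        migration in some epoch; otherwise no common ancestor exists.
        """
        idx = {p: i for i, p in enumerate(self.pop_names)}
        parent = list(range(len(self.pop_names)))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            parent[find(a)] = find(b)

        mats = [self.migration] + [
            np.asarray(e.matrix, dtype=float) for e in self.events if isinstance(e, MigrationChange)
        ]
        for m in mats:
            for i in range(len(self.pop_names)):
                for j in range(len(self.pop_names)):
                    if i != j and (m[i, j] > 0 or m[j, i] > 0):
                        union(i, j)
        for e in self.events:
            if isinstance(e, Fusion):
                union(idx[e.source], idx[e.sink])
        roots = {find(idx[p]) for p in sampled_pops}
        if len(roots) > 1:
            raise ModelValidityError(
                "sampled populations cannot coalesce: no terminal fusion or "
                "migration connects them"
            )

    # -- msprime bridge -----------------------------------------------------

    def msprime_demography(self) -> msprime.Demography:
        if self._demography is not None:
            return self._demography
        dem = msprime.Demography()
        for p in self.pop_names:
            dem.add_population(name=p, initial_size=self.sizes[p])
        k = len(self.pop_names)
        for i in range(k):
            for j in range(k):
                if i != j and self.migration[i, j] > 0:
                    dem.set_migration_rate(source=self.pop_names[i], dest=self.pop_names[j],
                                           rate=self.migration[i, j])
        dead = set()
        for e in self.events:
            if isinstance(e, Fusion):
                dem.add_mass_migration(time=e.time, source=e.source, dest=e.sink, proportion=1.0)
                dead.add(e.source)
                for p in self.pop_names:
                    if p != e.source:
                        dem.add_migration_rate_change(time=e.time, rate=0.0,
                                                      source=e.source, dest=p)
                        dem.add_migration_rate_change(time=e.time, rate=0.0,
                                                      source=p, dest=e.source)
            elif isinstance(e, SizeChange):
                dem.add_population_parameters_change(time=e.time, initial_size=e.new_size,
                                                     population=e.pop)
            elif isinstance(e, MigrationChange):
                mat = np.asarray(e.matrix, dtype=float)
                for i in range(k):
                    for j in range(k):
                        if i != j and self.pop_names[i] not in dead and self.pop_names[j] not in dead:
                            dem.add_migration_rate_change(time=e.time, rate=mat[i, j],
                                                          source=self.pop_names[i],
                                                          dest=self.pop_names[j])
            else:
                raise ModelValidityError(f"unknown event {e!r}")
        dem.sort_events()
        self._demography = dem
        return dem


@dataclass
class HaplotypeSet:
    """Binary haplotypes for one simulated region (infinite sites)."""

    region_id: str
    positions: np.ndarray
    haplotypes: np.ndarray  # (n_haplotypes, n_sites) in {0, 1}
    sample_pops: list       # population label per haplotype row
    sample_sizes: dict

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


def region_seeds(master_seed: int, region_index: int) -> tuple:
    """Deterministic per-region child seeds: changing the region count never
    reshuffles earlier regions."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(region_index)))
    a, b = ss.generate_state(2)
    return int(a % (2**31 - 1)) + 1, int(b % (2**31 - 1)) + 1


def _integer_positions(float_positions, region_length: int) -> np.ndarray:
    """Map continuous infinite-sites positions to strictly increasing 1-based
    integers, preserving site order."""
    n = len(float_positions)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if n > region_length:
        raise ModelValidityError(
            f"{n} mutations exceed region length {region_length}; "
            "infinite-sites guard tripped"
        )
    q = np.clip(np.floor(np.asarray(float_positions)).astype(np.int64) + 1, 1, region_length)
    for i in range(1, n):  # forward pass: strictly increasing
        if q[i] <= q[i - 1]:
            q[i] = q[i - 1] + 1
    if q[-1] > region_length:  # backward pass: pull into range (feasible, n <= L)
        q[-1] = region_length
        for i in range(n - 2, -1, -1):
            if q[i] >= q[i + 1]:
                q[i] = q[i + 1] - 1
    return q


def simulate_region(model: DemographicModel, samples: dict, seed: int,
                    region_id: str = "r0", _region_index: int = 0) -> HaplotypeSet:
    """Simulate one region of the model: structured-coalescent genealogy plus
    Poisson infinite-sites mutations at rate mu * region_length.

    *samples* maps population name -> haploid sample count.  Deterministic
    for a fixed seed.
    """
    samples = {p: int(n) for p, n in samples.items() if n > 0}
    if not samples:
        raise ValueError("need positive samples for at least one population")
    model.check_coalescible(samples.keys())
    s_anc, s_mut = region_seeds(seed, _region_index)
    sample_sets = [msprime.SampleSet(n, population=p, ploidy=1) for p, n in samples.items()]
    ts = msprime.sim_ancestry(
        samples=sample_sets, demography=model.msprime_demography(), ploidy=1,
        sequence_length=model.region_length, random_seed=s_anc,
    )
    mts = msprime.sim_mutations(
        ts, rate=model.mu, random_seed=s_mut, discrete_genome=False,
        model=msprime.BinaryMutationModel(),
    )
    geno = mts.genotype_matrix().T if mts.num_sites else np.zeros((ts.num_samples, 0), dtype=np.int8)
    float_pos = [mts.site(i).position for i in range(mts.num_sites)]
    positions = _integer_positions(float_pos, model.region_length)
    pop_of_node = []
    for p in samples:
        pop_of_node.extend([p] * samples[p])
    return HaplotypeSet(
        region_id=region_id,
        positions=positions,
        haplotypes=geno.astype(np.int8),
        sample_pops=pop_of_node,
        sample_sizes=dict(samples),
    )


def simulate_dataset(model: DemographicModel, samples: dict, diploid: bool = True,
                     seed: int = 1, n_regions: int = None,
                     region_indices=None) -> GenotypeMatrix:
    """Simulate ``n_regions`` regions (default: the model's) and assemble one
    GenotypeMatrix, pairing consecutive haplotypes into diploids.

    ``region_indices`` restricts simulation to a subset of region indices
    while keeping their per-region child seeds (region r is identical whether
    or not the other regions are simulated).
    """
    samples = {p: int(n) for p, n in samples.items() if n > 0}
    if diploid and any(n % 2 for n in samples.values()):
        raise ValueError("diploid output requires an even haploid count per population")
    n_regions = model.n_regions if n_regions is None else int(n_regions)
    individual_ids = []
    for p, n in samples.items():
        n_ind = n // 2 if diploid else n
        individual_ids.extend(f"{p}_{k}" for k in range(n_ind))

    locus_id, region_id, position, ref_a, alt_a, rows = [], [], [], [], [], []
    width = max(4, len(str(n_regions)))
    indices = range(n_regions) if region_indices is None else region_indices
    for r in indices:
        rid = f"r{r:0{width}d}"
        hs = simulate_region(model, samples, seed=seed, region_id=rid, _region_index=r)
        if hs.n_sites == 0:
            continue
        hap = hs.haplotypes
        if diploid:
            dos = hap[0::2] + hap[1::2]
        else:
            dos = hap
        for c in range(hs.n_sites):
            locus_id.append(f"{rid}_{hs.positions[c]}")
            region_id.append(rid)
            position.append(int(hs.positions[c]))
            ref_a.append("A")
            alt_a.append("T")
            rows.append(dos[:, c])
    geno = (np.array(rows, dtype=np.int8) if rows
            else np.zeros((0, len(individual_ids)), dtype=np.int8))
    return GenotypeMatrix(
        locus_id=locus_id,
        region_id=region_id,
        position=np.array(position, dtype=np.int64),
        ref_allele=ref_a,
        alt_allele=alt_a,
        qual=np.full(len(rows), -np.inf),
        genotypes=geno,
        individual_ids=individual_ids,
    )


def island_model(n_demes: int, deme_size: float, migration_rate: float,
                 mu: float = 2.5e-8, region_length: int = 214,
                 n_regions: int = 1000) -> DemographicModel:
    """Symmetric island model: per-pair backward migration rate
    ``migration_rate / (n_demes - 1)`` so each lineage emigrates at total rate
    ``migration_rate``."""
    names = [f"d{i}" for i in range(n_demes)]
    m = np.full((n_demes, n_demes), migration_rate / (n_demes - 1))
    np.fill_diagonal(m, 0.0)
    return DemographicModel(
        pop_names=names, sizes={p: deme_size for p in names}, migration=m,
        mu=mu, region_length=region_length, n_regions=n_regions,
    )


# -- config round trip ------------------------------------------------------

def model_from_config(source) -> DemographicModel:
    """Build a model from a YAML path or an already-parsed mapping.

    Schema: blocks ``populations`` (list of ``{name, size}``), ``events``
    (list with ``kind`` in fusion/size_change/migration_change), ``migration``
    (k x k matrix), ``mutation`` (``mu``, ``n_regions``, ``region_length``)
    and ``generation_time``.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    pops = cfg.get("populations") or []
    if not pops:
        raise ModelValidityError("config needs a non-empty 'populations' block")
    names = [p["name"] for p in pops]
    sizes = {p["name"]: float(p["size"]) for p in pops}
    events = []
    for e in cfg.get("events", []):
        kind = e.get("kind")
        if kind == "fusion":
            events.append(Fusion(time=float(e["time"]), source=e["source"], sink=e["sink"]))
        elif kind == "size_change":
            events.append(SizeChange(time=float(e["time"]), pop=e["pop"], new_size=float(e["size"])))
        elif kind == "migration_change":
            events.append(MigrationChange(time=float(e["time"]), matrix=np.asarray(e["matrix"], dtype=float)))
        else:
            raise ModelValidityError(f"unknown event kind {kind!r}")
    mut = cfg.get("mutation", {})
    return DemographicModel(
        pop_names=names,
        sizes=sizes,
        events=sorted(events, key=lambda ev: ev.time),
        migration=np.asarray(cfg["migration"], dtype=float) if "migration" in cfg else None,
        mu=float(mut.get("mu", 2.5e-8)),
        n_regions=int(mut.get("n_regions", 2869)),
        region_length=int(mut.get("region_length", 214)),
        generation_time=float(cfg.get("generation_time", 3.0)),
    )


def model_to_config(model: DemographicModel) -> dict:
    events = []
    for e in model.events:
        if isinstance(e, Fusion):
            events.append({"kind": "fusion", "time": e.time, "source": e.source, "sink": e.sink})
        elif isinstance(e, SizeChange):
            events.append({"kind": "size_change", "time": e.time, "pop": e.pop, "size": e.new_size})
        elif isinstance(e, MigrationChange):
            events.append({"kind": "migration_change", "time": e.time,
                           "matrix": np.asarray(e.matrix).tolist()})
    return {
        "populations": [{"name": p, "size": model.sizes[p]} for p in model.pop_names],
        "events": events,
        "migration": model.migration.tolist(),
        "mutation": {"mu": model.mu, "n_regions": model.n_regions,
                     "region_length": model.region_length},
        "generation_time": model.generation_time,
    }
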