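"""Readers, writers and variant filters for the formats the pipeline touches.

Genotypes are held as alt-allele dosages (0, 1, 2) with ``-1`` for missing;
half-calls are treated as missing.  Coordinates are 1-based as in VCF and are
never re-based internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1


class FormatError(ValueError):
    """Raised for malformed input records; readers reject rather than coerce."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes, sites x individuals.

    Attributes
    ----------
    locus_id : list of str
        Per-site identifier (VCF ID when present, else ``chrom_pos``).
    region_id : list of str
        Capture-locus grouping (the VCF CHROM field).
    position : ndarray of int
        1-based site position within its region.
    ref_allele, alt_allele : list of str
        Single-base alleles.
    qual : ndarray of float
        VCF QUAL; ``-inf`` when absent (used only for tie-breaking).
    genotypes : ndarray of int8, shape (n_sites, n_individuals)
        Alt-allele dosage in {0, 1, 2}, ``-1`` = missing.
    individual_ids : list of str
    """

    locus_id: list
    region_id: list
    position: np.ndarray
    ref_allele: list
    alt_allele: list
    qual: np.ndarray
    genotypes: np.ndarray
    individual_ids: list

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.int64)
        self.qual = np.asarray(self.qual, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise FormatError("duplicate individual ids")
        ok = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not ok.all():
            raise FormatError("invalid genotype codes present")
        if self.genotypes.shape != (self.n_sites, len(self.individual_ids)):
            raise FormatError("genotype array shape does not match metadata")

    @property
    def n_sites(self) -> int:
        return len(self.locus_id)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of individuals with a missing call."""
        if self.n_individuals == 0:
            return np.zeros(self.n_sites)
        return (self.genotypes == MISSING).mean(axis=1)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            locus_id=[self.locus_id[i] for i in idx],
            region_id=[self.region_id[i] for i in idx],
            position=self.position[idx],
            ref_allele=[self.ref_allele[i] for i in idx],
            alt_allele=[self.alt_allele[i] for i in idx],
            qual=self.qual[idx],
            genotypes=self.genotypes[idx],
            individual_ids=list(self.individual_ids),
        )


@dataclass
class PopulationMap:
    """individual_id -> population label assignments."""

    assignments: dict
    labels: list = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            seen = []
            for v in self.assignments.values():
                if v not in seen:
                    seen.append(v)
            self.labels = seen
        for ind, pop in self.assignments.items():
            if pop not in self.labels:
                raise FormatError(f"individual {ind!r} assigned to undeclared population {pop!r}")

    def individuals(self, pop: str) -> list:
        return [i for i, p in self.assignments.items() if p == pop]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        """Every matrix individual labelled; every mapped individual present."""
        ids = set(gm.individual_ids)
        for ind in gm.individual_ids:
            if ind not in self.assignments:
                raise FormatError(f"individual {ind!r} has no population assignment")
        for ind in self.assignments:
            if ind not in ids:
                raise FormatError(f"popmap individual {ind!r} absent from genotype matrix")


_GT_CODE = {
    (0, 0): 0,
    (0, 1): 1,
    (1, 0): 1,
    (1, 1): 2,
}


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNP records (indels, symbolic alleles) are
    skipped with a logged count.  Half-calls are treated as missing.
    """
    header_ids = None
    locus_id, region_id, position = [], [], []
    ref_a, alt_a, quals, rows = [], [], [], []
    n_skipped = 0
    saw_format_gt = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise FormatError(f"{path}:{lineno}: VCF has no sample columns")
                header_ids = cols[9:]
                continue
            if header_ids is None:
                raise FormatError(f"{path}:{lineno}: data line before #CHROM header")
            cols = line.split("\t")
            if len(cols) != 9 + len(header_ids):
                raise FormatError(f"{path}:{lineno}: expected {9 + len(header_ids)} columns, got {len(cols)}")
            chrom, pos, vid, ref, alt, qual, _flt, _info, fmt = cols[:9]
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise FormatError(f"{path}:{lineno}: record lacks GT field")
            saw_format_gt = True
            alts = alt.split(",")
            if len(alts) != 1 or len(ref) != 1 or len(alts[0]) != 1 or alts[0] in (".", "*"):
                n_skipped += 1
                continue
            gt_idx = fmt_keys.index("GT")
            row = np.empty(len(header_ids), dtype=np.int8)
            for j, sample in enumerate(cols[9:]):
                gt = sample.split(":")[gt_idx]
                alleles = gt.replace("|", "/").split("/")
                if len(alleles) != 2 or "." in alleles:
                    row[j] = MISSING
                    continue
                try:
                    key = (int(alleles[0]), int(alleles[1]))
                except ValueError as e:
                    raise FormatError(f"{path}:{lineno}: bad GT {gt!r}") from e
                if key not in _GT_CODE:
                    raise FormatError(f"{path}:{lineno}: non-biallelic GT {gt!r}")
                row[j] = _GT_CODE[key]
            locus_id.append(vid if vid != "." else f"{chrom}_{pos}")
            region_id.append(chrom)
            position.append(int(pos))
            ref_a.append(ref)
            alt_a.append(alts[0])
            quals.append(float(qual) if qual not in (".", "") else -math.inf)
            rows.append(row)
    if header_ids is None:
        raise FormatError(f"{path}: no #CHROM header found")
    if not saw_format_gt and rows:
        raise FormatError(f"{path}: no GT field in any record")
    if not rows:
        raise FormatError(f"{path}: zero biallelic SNP records")
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    return GenotypeMatrix(
        locus_id=locus_id,
        region_id=region_id,
        position=np.array(position),
        ref_allele=ref_a,
        alt_allele=alt_a,
        qual=np.array(quals),
        genotypes=np.array(rows, dtype=np.int8),
        individual_ids=header_ids,
    )


_DOSAGE_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 representation of *gm*."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for region in dict.fromkeys(gm.region_id):
            fh.write(f"##contig=<ID={region}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.individual_ids) + "\n")
        for i in range(gm.n_sites):
            qual = "." if not np.isfinite(gm.qual[i]) else f"{gm.qual[i]:g}"
            gts = "\t".join(_DOSAGE_GT[int(g)] for g in gm.genotypes[i])
            fh.write(
                f"{gm.region_id[i]}\t{gm.position[i]}\t{gm.locus_id[i]}\t"
                f"{gm.ref_allele[i]}\t{gm.alt_allele[i]}\t{qual}\t.\t.\tGT\t{gts}\n"
            )


def filter_by_missingness(gm: GenotypeMatrix, max_missing: float) -> GenotypeMatrix:
    """Retain exactly the sites whose missing fraction is <= *max_missing*."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    keep = np.flatnonzero(gm.missing_fraction() <= max_missing)
    return gm.take_sites(keep)


def one_snp_per_locus(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep one site per region: least missing, then highest QUAL, then
    smallest position, then first in file."""
    miss = gm.missing_fraction()
    best = {}
    for i in range(gm.n_sites):
        key = gm.region_id[i]
        cand = (miss[i], -gm.qual[i], gm.position[i], i)
        if key not in best or cand < best[key]:
            best[key] = cand
    keep = sorted(v[3] for v in best.values())
    return gm.take_sites(keep)


def read_popmap(path) -> PopulationMap:
    """Read a 2-column TSV ``individual<TAB>population`` file."""
    assignments = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected 'individual<TAB>population', got {line!r}")
            ind, pop = parts
            if ind in assignments:
                raise FormatError(f"{path}:{lineno}: duplicate individual {ind!r}")
            assignments[ind] = pop
    return PopulationMap(assignments=assignments)


def write_popmap(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for ind, pop in pm.assignments.items():
            fh.write(f"{ind}\t{pop}\n")


def write_sfs(sfs, path) -> None:
    """Write a JointSFS in the text dialect: header line
    ``#dims n1+1 n2+1 ... folded|unfolded`` then row-major counts."""
    dims = " ".join(str(d) for d in sfs.counts.shape)
    kind = "folded" if sfs.folded else "unfolded"
    flat = sfs.counts.ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"#dims {dims} {kind}\n")
        fh.write(" ".join(f"{v:g}" for v in flat) + "\n")


def read_sfs(path):
    """Read the SFS text dialect written by :func:`write_sfs`."""
    from .sfs import JointSFS

    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#dims "):
            raise FormatError(f"{path}:1: missing '#dims' header")
        parts = header.split()
        kind = parts[-1]
        if kind not in ("folded", "unfolded"):
            raise FormatError(f"{path}:1: fold flag must be 'folded' or 'unfolded', got {kind!r}")
        try:
            dims = tuple(int(x) for x in parts[1:-1])
        except ValueError as e:
            raise FormatError(f"{path}:1: non-integer dimension in header") from e
        data = fh.read().split()
    n_expected = int(np.prod(dims))
    if len(data) != n_expected:
        raise FormatError(f"{path}: expected {n_expected} counts, got {len(data)}")
    counts = np.array([float(x) for x in data]).reshape(dims, order="C")
    return JointSFS(counts=counts, folded=(kind == "folded"))
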