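"""Synthetic population / assembly simulator with ground truth.

The population model is a founder mosaic: F founder haplotypes per
chromosome, each accession a mosaic of founder blocks with
Poisson-distributed crossover counts (a stand-in for a selfing
population sharing long haplotype blocks). Genotype calls are mostly
homozygous for the local founder allele, with configurable residual
heterozygosity, missingness and genotype error.

The reference is fragmented into contigs of known order and orientation
(the TruthMap), from which mate-pair link tables and long-read PAF
alignments with known spans can be generated. Recovery metrics compare
detected segment relations against the truth: a valid relation is
"adjacent" when its segments are neighbors on the true genome and
"remote" when they lie on different chromosomes or more than 1 Mbp
apart.

Also provides the closed-form k-mer genome-size estimator and an LD
r-squared decay table computed from genotype dosages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ldscaffold.fingerprint import Segment
from ldscaffold.popvar_io import AccessionPanel, Genotype, GenotypeMatrix, SiteRecord
from ldscaffold.relations import Relation
from ldscaffold.scaffold import revcomp

__all__ = [
    "SimConfig",
    "TruthMap",
    "SimResult",
    "RecoveryMetrics",
    "GenomeSizeEstimate",
    "simulate_population",
    "fragment_reference",
    "write_outputs",
    "write_vcf",
    "simulate_mate_links",
    "simulate_long_reads",
    "evaluate_recovery",
    "estimate_genome_size",
    "coverage_depth",
    "ld_r2_decay",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population and assembly."""

    seed: int
    n_chromosomes: int = 2
    chromosome_length: int = 2_000_000
    n_founders: int = 8
    n_accessions: int = 50
    variant_density: float = 3.5  # sites per kbp
    recombination_rate: float = 3.0  # expected crossovers / chromosome / lineage
    relatedness: float = 1.0  # probability a mosaic block copies a shared founder
    clade_weight_power: float = 1.0  # site frequency spectrum skew toward small clades
    het_fraction: float = 0.03
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.001
    contig_length_mean: int = 500_000
    contig_length_sd: int = 120_000
    contig_length_min: int = 120_000
    flip_probability: float = 0.5
    overlap_bp: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        for name in ("het_fraction", "missing_rate", "genotype_error_rate", "flip_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.contig_length_min < 1:
            raise ValueError("contig_length_min must be >= 1")


@dataclass
class TruthMap:
    """Known placement of every contig on the simulated genome."""

    placements: dict[str, tuple[str, int, int, str]]  # contig -> (chrom, start, end, orient)
    adjacencies: list[tuple[str, str, int]]  # (left contig, right contig, gap)
    chrom_lengths: dict[str, int]

    def contig_length(self, contig: str) -> int:
        _, s, e, _ = self.placements[contig]
        return e - s

    def segment_interval(self, seg: Segment) -> tuple[str, int, int]:
        """Genome interval of a contig segment, orientation-aware."""
        if seg.contig not in self.placements:
            raise ValueError(f"segment contig {seg.contig!r} missing from truth")
        chrom, start, end, orient = self.placements[seg.contig]
        clen = end - start
        if orient == "+":
            return chrom, start + seg.start, start + seg.end
        return chrom, start + (clen - seg.end), start + (clen - seg.start)

    @property
    def assembly_bp(self) -> int:
        return sum(e - s for _, s, e, _ in self.placements.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#record\tfields\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"chrom\t{chrom}\t{length}\n")
            for contig, (chrom, s, e, o) in self.placements.items():
                fh.write(f"placement\t{contig}\t{chrom}\t{s}\t{e}\t{o}\n")
            for u, v, gap in self.adjacencies:
                fh.write(f"adjacency\t{u}\t{v}\t{gap}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthMap":
        placements: dict[str, tuple[str, int, int, str]] = {}
        adjacencies: list[tuple[str, str, int]] = []
        chrom_lengths: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if f[0] == "chrom":
                    chrom_lengths[f[1]] = int(f[2])
                elif f[0] == "placement":
                    placements[f[1]] = (f[2], int(f[3]), int(f[4]), f[5])
                elif f[0] == "adjacency":
                    adjacencies.append((f[1], f[2], int(f[3])))
        return cls(placements, adjacencies, chrom_lengths)


@dataclass
class SimResult:
    """Everything a simulation produced, plus the ground truth."""

    cfg: SimConfig
    panel: AccessionPanel
    chrom_seqs: dict[str, str]
    chrom_matrix: GenotypeMatrix  # sites in chromosome coordinates
    founder_alleles: dict[str, np.ndarray]  # chrom -> (F, n_sites) 0/1
    contig_seqs: dict[str, str]
    matrix: GenotypeMatrix  # sites in contig coordinates
    truth: TruthMap


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _founder_clades(rng: np.random.Generator, n_founders: int) -> list[np.ndarray]:
    """Clades of a random founder genealogy (random sequential merges).

    Mutations are placed on tree edges, so every variant site's
    alt-carrying founder set is one of these clades — this is what makes
    variation patterns recur within a region instead of being unique per
    site. The root clade (all founders) is excluded except in the
    degenerate single-founder case.
    """
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n_founders)]
    clades: list[frozenset[int]] = list(clusters)
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        if len(merged) < n_founders:
            clades.append(merged)
    return [np.fromiter(sorted(c), dtype=np.int64) for c in clades]


def simulate_population(cfg: SimConfig) -> SimResult:
    """Simulate founders, accession mosaics, genotypes and contigs.

    Deterministic for a given config (one seeded generator drives every
    random choice in a fixed order).
    """
    rng = np.random.default_rng(cfg.seed)
    panel = AccessionPanel(tuple(f"acc{i + 1:03d}" for i in range(cfg.n_accessions)))

    chrom_seqs: dict[str, str] = {}
    chrom_sites: dict[str, list[SiteRecord]] = {}
    founder_alleles: dict[str, np.ndarray] = {}
    chrom_lengths: dict[str, int] = {}
    site_data: dict[str, tuple[np.ndarray, np.ndarray, list[str], list[str]]] = {}

    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        length = cfg.chromosome_length
        chrom_lengths[chrom] = length
        seq = _random_sequence(rng, length)
        chrom_seqs[chrom] = seq

        n_sites = int(rng.binomial(length, min(cfg.variant_density / 1000.0, 1.0)))
        pos0 = np.sort(rng.choice(length, size=n_sites, replace=False)) if n_sites else np.empty(0, dtype=int)
        clades = _founder_clades(rng, cfg.n_founders)
        # rare-allele-heavy site frequency spectrum: smaller clades are
        # proportionally more likely to carry a mutation
        weights = np.array([1.0 / len(c) ** cfg.clade_weight_power for c in clades])
        weights /= weights.sum()
        clade_of_site = rng.choice(len(clades), size=n_sites, p=weights)
        founders = np.zeros((cfg.n_founders, n_sites), dtype=np.int8)
        for i in range(n_sites):
            founders[clades[clade_of_site[i]], i] = 1
        founder_alleles[chrom] = founders

        # accession mosaics: founder index per site
        calls = np.empty((n_sites, cfg.n_accessions), dtype=np.int8)
        for a in range(cfg.n_accessions):
            n_cross = int(rng.poisson(cfg.recombination_rate))
            breaks = np.sort(rng.integers(0, length, size=n_cross))
            block_founders = rng.integers(0, cfg.n_founders, size=n_cross + 1)
            # blocks of unrelated (private) ancestry carry no shared
            # variation: model them as reference-like (their private
            # mutations would be singletons, removed by filtering)
            private = rng.random(n_cross + 1) >= cfg.relatedness
            block_of_site = np.searchsorted(breaks, pos0, side="right") if n_sites else np.empty(0, dtype=int)
            alleles = founders[block_founders[block_of_site], np.arange(n_sites)] if n_sites else np.empty(0, dtype=np.int8)
            alleles = np.where(private[block_of_site], 0, alleles) if n_sites else alleles
            col = (2 * alleles).astype(np.int8)
            if n_sites:
                u = rng.random(n_sites)
                col[u < cfg.het_fraction] = int(Genotype.HET)
                err = rng.random(n_sites) < cfg.genotype_error_rate
                col[err] = rng.integers(0, 3, size=int(err.sum()), dtype=np.int8)
                col[rng.random(n_sites) < cfg.missing_rate] = int(Genotype.MISSING)
            calls[:, a] = col

        refs: list[str] = []
        alts: list[str] = []
        others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
        alt_pick = rng.integers(0, 3, size=n_sites)
        for i, p in enumerate(pos0):
            ref = seq[int(p)]
            refs.append(ref)
            alts.append(others[ref][int(alt_pick[i])])

        site_data[chrom] = (pos0, calls, refs, alts)
        chrom_sites[chrom] = [
            SiteRecord(
                contig=chrom,
                pos=int(p) + 1,
                ref_allele=refs[i],
                alt_alleles=(alts[i],),
                calls=calls[i].copy(),
            )
            for i, p in enumerate(pos0)
        ]

    chrom_matrix = GenotypeMatrix(panel=panel, sites=chrom_sites, contig_lengths=dict(chrom_lengths))
    truth, contig_seqs = fragment_reference(cfg, chrom_seqs, rng)

    # project chromosome sites onto contigs (orientation-aware)
    contig_sites: dict[str, list[SiteRecord]] = {}
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    per_chrom_placements: dict[str, list[tuple[str, int, int, str]]] = {}
    for contig, (chrom, s, e, o) in truth.placements.items():
        per_chrom_placements.setdefault(chrom, []).append((contig, s, e, o))
    for chrom, placed in per_chrom_placements.items():
        pos0, calls, refs, alts = site_data[chrom]
        for contig, s, e, o in placed:
            lo = int(np.searchsorted(pos0, s, side="left"))
            hi = int(np.searchsorted(pos0, e, side="left"))
            recs = []
            clen = e - s
            for i in range(lo, hi):
                p = int(pos0[i])
                if o == "+":
                    local = p - s
                    ref, alt = refs[i], alts[i]
                else:
                    local = (clen - 1) - (p - s)
                    ref, alt = complement[refs[i]], complement[alts[i]]
                recs.append(
                    SiteRecord(
                        contig=contig,
                        pos=local + 1,
                        ref_allele=ref,
                        alt_alleles=(alt,),
                        calls=calls[i].copy(),
                    )
                )
            recs.sort(key=lambda r: r.pos)
            if recs:
                contig_sites[contig] = recs

    contig_lengths = {c: truth.contig_length(c) for c in truth.placements}
    matrix = GenotypeMatrix(panel=panel, sites=contig_sites, contig_lengths=contig_lengths)
    return SimResult(
        cfg=cfg,
        panel=panel,
        chrom_seqs=chrom_seqs,
        chrom_matrix=chrom_matrix,
        founder_alleles=founder_alleles,
        contig_seqs=contig_seqs,
        matrix=matrix,
        truth=truth,
    )


def fragment_reference(
    cfg: SimConfig,
    chrom_seqs: Mapping[str, str],
    rng: np.random.Generator,
) -> tuple[TruthMap, dict[str, str]]:
    """Cut chromosomes into contigs with known order and orientation.

    Contig lengths follow a clipped normal distribution; names are
    shuffled so lexicographic order carries no positional signal.
    Neighboring contigs optionally share ``overlap_bp`` of sequence (the
    true gap is then negative).
    """
    boundaries: list[tuple[str, int, int]] = []  # (chrom, start, end)
    for chrom, seq in chrom_seqs.items():
        length = len(seq)
        pos = 0
        while pos < length:
            size = int(rng.normal(cfg.contig_length_mean, cfg.contig_length_sd))
            size = max(size, cfg.contig_length_min)
            end = min(pos + size, length)
            if length - end < cfg.contig_length_min:
                end = length
            boundaries.append((chrom, pos, end))
            pos = end

    names = [f"ctg{i + 1:04d}" for i in range(len(boundaries))]
    order = rng.permutation(len(boundaries))
    assigned = [names[int(i)] for i in order]

    placements: dict[str, tuple[str, int, int, str]] = {}
    contig_seqs: dict[str, str] = {}
    adjacencies: list[tuple[str, str, int]] = []
    prev: tuple[str, str] | None = None  # (chrom, contig)
    for (chrom, s, e), contig in zip(boundaries, assigned):
        s_eff = s
        gap = 0
        if prev is not None and prev[0] == chrom and cfg.overlap_bp > 0 and s >= cfg.overlap_bp:
            s_eff = s - cfg.overlap_bp
            gap = -cfg.overlap_bp
        orient = "-" if rng.random() < cfg.flip_probability else "+"
        piece = chrom_seqs[chrom][s_eff:e]
        contig_seqs[contig] = revcomp(piece) if orient == "-" else piece
        placements[contig] = (chrom, s_eff, e, orient)
        if prev is not None and prev[0] == chrom:
            adjacencies.append((prev[1], contig, gap))
        prev = (chrom, contig)
    return TruthMap(placements, adjacencies, dict((c, len(s)) for c, s in chrom_seqs.items())), contig_seqs


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", 3: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the genotype matrix as an uncompressed VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in matrix.contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.panel.names) + "\n")
        for site in matrix.iter_sites():
            gts = "\t".join(_GT_STR[int(c)] for c in site.calls)
            alt = ",".join(site.alt_alleles) if site.alt_alleles else "."
            fh.write(
                f"{site.contig}\t{site.pos}\t.\t{site.ref_allele}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def _junction_geometry(truth: TruthMap, u: str, v: str) -> tuple[str, str, int, int]:
    """True orientations of (u, v) at their junction plus contig lengths."""
    _, su, eu, ou = truth.placements[u]
    _, sv, ev, ov = truth.placements[v]
    return ou, ov, eu - su, ev - sv


def simulate_mate_links(
    sim: SimResult,
    span: int,
    span_sd: int,
    pairs_per_junction: int,
    rng: np.random.Generator,
    library: str = "mp",
) -> list[str]:
    """Mate-pair link rows spanning every true junction.

    Rows follow the link-TSV convention of :mod:`ldscaffold.scaffold`
    (0-based positions; the strand encodes which contig end faces the
    junction).
    """
    rows: list[str] = []
    for j, (u, v, gap) in enumerate(sim.truth.adjacencies):
        ou, ov, lu, lv = _junction_geometry(sim.truth, u, v)
        for k in range(pairs_per_junction):
            s = int(round(rng.normal(span, span_sd)))
            s = max(s, gap + 2)
            d_total = s - gap
            d_a = int(rng.integers(1, d_total))
            d_b = d_total - d_a
            d_a = min(d_a, lu)
            d_b = min(d_b, lv)
            if ou == "+":
                pos_a, strand_a = lu - d_a, "+"
            else:
                pos_a, strand_a = d_a - 1, "-"
            if ov == "+":
                pos_b, strand_b = d_b - 1, "-"
            else:
                pos_b, strand_b = lv - d_b, "+"
            rows.append(
                f"{library}_j{j}_p{k}\t{u}\t{pos_a}\t{strand_a}\t{v}\t{pos_b}\t{strand_b}\t{library}"
            )
    return rows


def simulate_long_reads(
    sim: SimResult,
    read_length: int,
    reads_per_junction: int,
    rng: np.random.Generator,
) -> list[str]:
    """PAF lines of long reads spanning every true junction (split into
    one alignment per contig, sharing the read name)."""
    rows: list[str] = []
    for j, (u, v, gap) in enumerate(sim.truth.adjacencies):
        ou, ov, lu, lv = _junction_geometry(sim.truth, u, v)
        gap = max(gap, 0)
        for k in range(reads_per_junction):
            span_left = read_length - gap - 1
            if span_left < 2:
                continue
            x = int(rng.integers(1, min(span_left, lu)))
            y = min(read_length - gap - x, lv)
            qname = f"lr_j{j}_r{k}"
            if ou == "+":
                a = (qname, read_length, 0, x, "+", u, lu, lu - x, lu)
            else:
                a = (qname, read_length, 0, x, "-", u, lu, 0, x)
            if ov == "+":
                b = (qname, read_length, x + gap, x + gap + y, "+", v, lv, 0, y)
            else:
                b = (qname, read_length, x + gap, x + gap + y, "-", v, lv, lv - y, lv)
            for rec in (a, b):
                qn, ql, qs, qe, st, tn, tl, ts, te = rec
                rows.append(
                    f"{qn}\t{ql}\t{qs}\t{qe}\t{st}\t{tn}\t{tl}\t{ts}\t{te}\t{qe - qs}\t{qe - qs}\t60"
                )
    return rows


def write_outputs(
    sim: SimResult,
    outdir: str | Path,
    mate_span: int = 5000,
    mate_span_sd: int = 300,
    pairs_per_junction: int = 20,
    read_length: int = 8000,
    reads_per_junction: int = 3,
) -> dict[str, Path]:
    """Write genome/contigs FASTA, population VCF, link TSV, PAF, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.cfg.seed + 1)

    paths = {
        "genome": outdir / "genome.fa",
        "contigs": outdir / "contigs.fa",
        "vcf": outdir / "pop.vcf",
        "links": outdir / f"links_mp{mate_span}.tsv",
        "paf": outdir / "reads.paf",
        "truth": outdir / "truth.tsv",
    }
    _write_fasta(sim.chrom_seqs, paths["genome"])
    _write_fasta(sim.contig_seqs, paths["contigs"])
    write_vcf(sim.matrix, paths["vcf"])
    with open(paths["links"], "w") as fh:
        fh.write("#read\tcontigA\tposA\tstrandA\tcontigB\tposB\tstrandB\tlibrary\n")
        fh.write("\n".join(simulate_mate_links(sim, mate_span, mate_span_sd, pairs_per_junction, rng)) + "\n")
    with open(paths["paf"], "w") as fh:
        fh.write("\n".join(simulate_long_reads(sim, read_length, reads_per_junction, rng)) + "\n")
    sim.truth.to_tsv(paths["truth"])
    return paths


def _write_fasta(seqs: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, s in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


@dataclass
class RecoveryMetrics:
    adjacent_per_mbp: float
    remote_per_mbp: float
    precision: float
    recall: float
    n_adjacent: int = 0
    n_remote: int = 0
    n_other: int = 0
    n_junctions: int = 0
    n_recovered: int = 0


def evaluate_recovery(
    relations: Sequence[Relation],
    truth: TruthMap,
    segment_size: int = 100_000,
    remote_distance: int = 1_000_000,
) -> RecoveryMetrics:
    """Classify valid relations against the truth and compute rates.

    A relation is adjacent when its segments' true intervals are on the
    same chromosome within one segment size of each other; remote when
    on different chromosomes or more than ``remote_distance`` apart.
    Rates are per Mbp of assembly. A true contig junction counts as
    recovered when some valid adjacent relation links the two contigs.
    """
    mbp = truth.assembly_bp / 1e6
    n_adj = n_rem = n_other = 0
    recovered: set[tuple[str, str]] = set()
    junctions = {tuple(sorted((u, v))) for u, v, _ in truth.adjacencies}
    for rel in relations:
        if not rel.valid:
            continue
        ca, a0, a1 = truth.segment_interval(rel.segment_a)
        cb, b0, b1 = truth.segment_interval(rel.segment_b)
        if ca != cb:
            n_rem += 1
            continue
        dist = max(b0 - a1, a0 - b1, 0)
        if dist <= segment_size:
            n_adj += 1
            key = tuple(sorted((rel.segment_a.contig, rel.segment_b.contig)))
            if key in junctions:
                recovered.add(key)
        elif dist > remote_distance:
            n_rem += 1
        else:
            n_other += 1
    precision = n_adj / (n_adj + n_rem) if (n_adj + n_rem) else 0.0
    recall = len(recovered) / len(junctions) if junctions else 1.0
    return RecoveryMetrics(
        adjacent_per_mbp=n_adj / mbp if mbp else 0.0,
        remote_per_mbp=n_rem / mbp if mbp else 0.0,
        precision=precision,
        recall=recall,
        n_adjacent=n_adj,
        n_remote=n_rem,
        n_other=n_other,
        n_junctions=len(junctions),
        n_recovered=len(recovered),
    )


@dataclass(frozen=True)
class GenomeSizeEstimate:
    kmer_cov_peak: float
    read_length: float
    kmer_size: int
    total_bases: float
    seq_depth: float
    genome_size: float


def estimate_genome_size(
    kmer_cov_peak: float, read_length: float, kmer_size: int, total_bases: float
) -> GenomeSizeEstimate:
    """Closed-form k-mer genome size estimate.

    seq_depth = peak * read_length / (read_length - kmer_size + 1);
    genome_size = total_bases / seq_depth. Exact formula values are
    returned (no intermediate rounding).
    """
    if kmer_size < 1 or read_length <= kmer_size:
        raise ValueError("need read_length > kmer_size >= 1")
    if kmer_cov_peak <= 0 or total_bases <= 0:
        raise ValueError("peak and total_bases must be positive")
    seq_depth = kmer_cov_peak * read_length / (read_length - kmer_size + 1)
    return GenomeSizeEstimate(
        kmer_cov_peak=kmer_cov_peak,
        read_length=read_length,
        kmer_size=kmer_size,
        total_bases=total_bases,
        seq_depth=seq_depth,
        genome_size=total_bases / seq_depth,
    )


def coverage_depth(total_bases: float, genome_size: float) -> float:
    """Plain fold coverage: total sequenced bases over genome size."""
    if total_bases <= 0 or genome_size <= 0:
        raise ValueError("total_bases and genome_size must be positive")
    return total_bases / genome_size


def ld_r2_decay(
    matrix: GenotypeMatrix,
    thin_bp: int = 1000,
    max_dist: int = 100_000,
    bin_bp: int = 10_000,
):
    """Mean r-squared between dosage vectors, binned by distance.

    Sites are thinned to at least ``thin_bp`` spacing; r-squared is the
    squared Pearson correlation of allele dosages (0/1/2, missing
    excluded pairwise) for all within-contig pairs up to ``max_dist``.
    Monomorphic pairs are skipped. Returns a pandas DataFrame with
    columns bin_start, bin_end, mean_r2, n_pairs.
    """
    import pandas as pd

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for contig, recs in matrix.sites.items():
        kept: list[SiteRecord] = []
        last = -(10**18)
        for r in recs:
            if r.pos - last >= thin_bp:
                kept.append(r)
                last = r.pos
        pos = np.array([r.pos for r in kept])
        dose = np.array(
            [np.where(r.calls == Genotype.MISSING, np.nan, r.calls.astype(float)) for r in kept]
        )
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                d = int(pos[j] - pos[i])
                if d > max_dist:
                    break
                x, y = dose[i], dose[j]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 3:
                    continue
                xs, ys = x[ok], y[ok]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                b = d // bin_bp
                sums[b] = sums.get(b, 0.0) + float(r * r)
                counts[b] = counts.get(b, 0) + 1
    rows = [
        {
            "bin_start": b * bin_bp,
            "bin_end": (b + 1) * bin_bp,
            "mean_r2": sums[b] / counts[b],
            "n_pairs": counts[b],
        }
        for b in sorted(sums)
    ]
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])
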