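"""Segmentation, variation-pattern similarity, and fingerprint building.

A contig is cut into fixed-size segments (default 100 kbp; contigs
shorter than one segment form a single segment). Within a segment, the
per-position genotype vectors ("variation patterns") are clustered by a
greedy single pass: each site joins the first existing cluster whose
consensus it is similar to, otherwise it starts a new cluster. Clusters
supported by fewer than ``min_occurrence`` sites are dropped; the
surviving consensus patterns with their occurrence counts form the
segment's fingerprint.

Similarity between two patterns (the first being the cluster's "starting
pattern"):

* no accession may carry opposing homozygous calls;
* at most ``floor(het_tol * n)`` accessions may differ (differences are
  then necessarily via het or missing calls);
* if the starting pattern carries the alternative allele in fewer than
  ``rare_fraction * n`` accessions, no mismatch of any kind is allowed at
  those accessions (mirror rule for rare reference genotypes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ldscaffold.popvar_io import (
    Genotype,
    GenotypeMatrix,
    SiteRecord,
    calls_from_string,
    calls_to_string,
)

__all__ = [
    "Segment",
    "VariationPattern",
    "Fingerprint",
    "SimilarityConfig",
    "segment_assembly",
    "patterns_similar",
    "build_fingerprint",
    "fingerprints_for_matrix",
    "write_fingerprints_tsv",
    "read_fingerprints_tsv",
]


@dataclass(frozen=True, order=True)
class Segment:
    """Half-open 0-based slice of a contig; segments tile the contig."""

    contig: str
    start: int
    end: int
    index: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


@dataclass
class VariationPattern:
    """A cluster of similar site patterns, compressed to one consensus.

    ``occurrence`` counts member sites; ``tallies`` is an (n_accessions,
    4) count of observed genotype states across members.
    """

    consensus: np.ndarray
    occurrence: int
    members: list[int] = field(default_factory=list)
    tallies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.members and self.occurrence != len(self.members):
            raise ValueError("occurrence must equal the number of member positions")
        if self.occurrence < 1:
            raise ValueError("occurrence must be >= 1")


@dataclass
class Fingerprint:
    """Retained variation patterns of one segment."""

    segment: Segment
    patterns: list[VariationPattern]

    @property
    def total_occurrence(self) -> int:
        return sum(p.occurrence for p in self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)


@dataclass(frozen=True)
class SimilarityConfig:
    """Parameters for pattern similarity and fingerprint building."""

    het_tol: float = 0.10
    rare_fraction: float = 0.20
    min_occurrence: int = 3
    segment_size: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 < self.het_tol <= 1.0:
            raise ValueError("het_tol must be in (0, 1]")
        if not 0.0 < self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must be in (0, 1]")
        if self.min_occurrence < 1:
            raise ValueError("min_occurrence must be >= 1")
        if self.segment_size < 1:
            raise ValueError("segment_size must be >= 1")

    def max_mismatches(self, n_accessions: int) -> int:
        """Mismatch budget: floor of the tolerance times the panel size."""
        return math.floor(self.het_tol * n_accessions)


def segment_assembly(
    contig_lengths: Mapping[str, int], segment_size: int = 100_000
) -> list[Segment]:
    """Tile every contig with ``segment_size`` segments.

    A contig shorter than ``segment_size`` is one segment; otherwise
    full-size tiles are laid down and the remainder (< segment_size)
    becomes a final, shorter segment. Output is ordered by contig name,
    then start.
    """
    segments: list[Segment] = []
    for contig in sorted(contig_lengths):
        length = contig_lengths[contig]
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length {length}")
        if length < segment_size:
            segments.append(Segment(contig, 0, length, 0))
            continue
        starts = range(0, length, segment_size)
        for i, s in enumerate(starts):
            e = min(s + segment_size, length)
            if e > s:
                segments.append(Segment(contig, s, e, i))
    return segments


def _as_vector(p: VariationPattern | np.ndarray | Sequence[int]) -> np.ndarray:
    if isinstance(p, VariationPattern):
        return p.consensus
    return np.asarray(p, dtype=np.int8)


def _similar_rows(C: np.ndarray, b: np.ndarray, cfg: SimilarityConfig) -> np.ndarray:
    """Compare pattern ``b`` against every row of ``C`` (rows are the
    starting patterns). Returns a boolean vector over rows."""
    n = C.shape[1]
    max_diff = cfg.max_mismatches(n)
    rare_thr = cfg.rare_fraction * n

    diffs = C != b
    opposing = ((C == Genotype.REF_HOM) & (b == Genotype.ALT_HOM)) | (
        (C == Genotype.ALT_HOM) & (b == Genotype.REF_HOM)
    )
    ok = ~opposing.any(axis=1)
    ok &= diffs.sum(axis=1) <= max_diff

    alt_mask = (C == Genotype.HET) | (C == Genotype.ALT_HOM)
    ref_mask = (C == Genotype.HET) | (C == Genotype.REF_HOM)
    alt_rare = alt_mask.sum(axis=1) < rare_thr
    ref_rare = ref_mask.sum(axis=1) < rare_thr
    ok &= ~(alt_rare & (diffs & alt_mask).any(axis=1))
    ok &= ~(ref_rare & (diffs & ref_mask).any(axis=1))
    return ok


def patterns_similar(
    a: VariationPattern | np.ndarray | Sequence[int],
    b: VariationPattern | np.ndarray | Sequence[int],
    cfg: SimilarityConfig | None = None,
    n_accessions: int | None = None,
) -> bool:
    """Whether pattern ``b`` is similar to starting pattern ``a``.

    Note the rare-genotype rule makes this relation asymmetric in
    general: the rarity test and the protected accessions are taken from
    ``a``.
    """
    if cfg is None:
        cfg = SimilarityConfig()
    va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ValueError(f"pattern length mismatch: {va.shape} vs {vb.shape}")
    if n_accessions is not None and n_accessions != va.size:
        raise ValueError("n_accessions does not match vector length")
    return bool(_similar_rows(va[None, :], vb, cfg)[0])


def _update_consensus(consensus: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Refine a cluster consensus with a new member.

    Missing entries take any called state of the member; het entries take
    a homozygous call of the member. Homozygous entries never change
    (opposing homozygotes were excluded by the similarity test).
    """
    out = consensus.copy()
    missing = (out == Genotype.MISSING) & (member != Genotype.MISSING)
    out[missing] = member[missing]
    het = (out == Genotype.HET) & ((member == Genotype.REF_HOM) | (member == Genotype.ALT_HOM))
    out[het] = member[het]
    return out


def build_fingerprint(
    sites: Sequence[SiteRecord],
    segment: Segment,
    cfg: SimilarityConfig | None = None,
) -> Fingerprint:
    """Greedy single-pass clustering of a segment's site patterns.

    Sites are taken in genomic order; each is compared against existing
    cluster consensuses in creation order and absorbed by the first
    similar one (updating that consensus), else it seeds a new cluster.
    Clusters with fewer than ``min_occurrence`` members are dropped.
    """
    if cfg is None:
        cfg = SimilarityConfig()
    if not sites:
        return Fingerprint(segment=segment, patterns=[])
    n = sites[0].calls.size

    cap = 64
    C = np.empty((cap, n), dtype=np.int8)
    k = 0
    occurrences: list[int] = []
    members: list[list[int]] = []
    tallies: list[np.ndarray] = []
    acc_idx = np.arange(n)

    for site in sites:
        b = site.calls
        placed = False
        if k:
            hits = _similar_rows(C[:k], b, cfg)
            j = int(np.argmax(hits)) if hits.any() else -1
            if j >= 0:
                C[j] = _update_consensus(C[j], b)
                occurrences[j] += 1
                members[j].append(site.pos)
                tallies[j][acc_idx, b] += 1
                placed = True
        if not placed:
            if k == cap:
                cap *= 2
                C = np.vstack([C, np.empty((cap - k, n), dtype=np.int8)])
            C[k] = b
            occurrences.append(1)
            members.append([site.pos])
            t = np.zeros((n, 4), dtype=np.int32)
            t[acc_idx, b] += 1
            tallies.append(t)
            k += 1

    patterns = [
        VariationPattern(consensus=C[j].copy(), occurrence=occurrences[j], members=members[j], tallies=tallies[j])
        for j in range(k)
        if occurrences[j] >= cfg.min_occurrence
    ]
    return Fingerprint(segment=segment, patterns=patterns)


def fingerprints_for_matrix(
    matrix: GenotypeMatrix, cfg: SimilarityConfig | None = None
) -> list[Fingerprint]:
    """Segment every contig and build one fingerprint per segment.

    Segments without any (filtered) sites yield empty fingerprints,
    which are kept so segment indexing stays aligned with the assembly.
    """
    if cfg is None:
        cfg = SimilarityConfig()
    segments = segment_assembly(matrix.contig_lengths, cfg.segment_size)
    out: list[Fingerprint] = []
    for seg in segments:
        recs = matrix.sites.get(seg.contig, [])
        seg_sites = [r for r in recs if seg.contains_pos(r.pos)]
        out.append(build_fingerprint(seg_sites, seg, cfg))
    return out


def write_fingerprints_tsv(fps: Sequence[Fingerprint], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tseg_index\tpattern\toccurrence\tconsensus\n")
        for fp in fps:
            s = fp.segment
            if not fp.patterns:
                fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.index}\t-\t0\t-\n")
                continue
            for i, p in enumerate(fp.patterns):
                fh.write(
                    f"{s.contig}\t{s.start}\t{s.end}\t{s.index}\t{i}\t{p.occurrence}\t"
                    f"{calls_to_string(p.consensus)}\n"
                )


def read_fingerprints_tsv(path: str | Path) -> list[Fingerprint]:
    by_seg: dict[Segment, list[VariationPattern]] = {}
    order: list[Segment] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            contig, start, end, idx, pat, occ, cons = line.rstrip("\n").split("\t")
            seg = Segment(contig, int(start), int(end), int(idx))
            if seg not in by_seg:
                by_seg[seg] = []
                order.append(seg)
            if pat == "-":
                continue
            by_seg[seg].append(
                VariationPattern(consensus=calls_from_string(cons), occurrence=int(occ))
            )
    return [Fingerprint(segment=s, patterns=by_seg[s]) for s in order]
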