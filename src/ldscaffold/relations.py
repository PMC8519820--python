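"""All-vs-all fingerprint comparison and relation scoring.

Before comparison, patterns recurring across many segments are pruned:
mutually similar patterns are grouped by single linkage across all
fingerprints and any group touching more than ``max_pattern_fingerprints``
fingerprints (default 50, i.e. > 50 Mbp at 100-kbp segments) is removed
everywhere — such widespread haplotypes (including "yin-yang" pairs)
would otherwise create spurious long-range connections.

The directed similarity score of fingerprint A against B rescales each
matched B pattern's occurrence to its A counterpart (the per-pattern
"evening-out" coefficient o_A / o_B), giving

    score = I / (T_A + U_B)

with I the summed A-occurrences of the matched patterns, T_A the total
occurrence of A, and U_B the summed occurrences of B's unmatched
patterns. On a single shared pattern this reduces to the plain
occurrence-normalized Jaccard form. A relation's score is the larger of
the two directed scores and is valid at >= ``validity_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ldscaffold.fingerprint import (
    Fingerprint,
    Segment,
    SimilarityConfig,
    VariationPattern,
    _similar_rows,
)
from ldscaffold.popvar_io import Genotype

__all__ = [
    "RelationConfig",
    "SharedPatternMatch",
    "Relation",
    "PatternPrevalence",
    "prune_widespread",
    "match_patterns",
    "directed_score",
    "relation_score",
    "all_vs_all",
    "write_relations_tsv",
    "read_relations_tsv",
]


@dataclass(frozen=True)
class RelationConfig:
    validity_threshold: float = 0.1
    max_pattern_fingerprints: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.validity_threshold <= 1.0:
            raise ValueError("validity_threshold must be in (0, 1]")
        if self.max_pattern_fingerprints < 1:
            raise ValueError("max_pattern_fingerprints must be >= 1")


@dataclass(frozen=True)
class SharedPatternMatch:
    """A matched pattern pair: index and occurrence on each side."""

    index_a: int
    index_b: int
    occurrence_a: int
    occurrence_b: int


@dataclass
class Relation:
    """A scored link between two segments."""

    segment_a: Segment
    segment_b: Segment
    matches: list[SharedPatternMatch]
    score: float
    valid: bool
    score_ab: float = 0.0
    score_ba: float = 0.0

    @property
    def intra_contig(self) -> bool:
        return self.segment_a.contig == self.segment_b.contig

    @property
    def n_shared(self) -> int:
        return len(self.matches)


#: pattern key (fingerprint index, pattern index) -> number of distinct
#: fingerprints reached by the pattern's similarity group
PatternPrevalence = dict


def _similar_from(a: np.ndarray, B: np.ndarray, cfg: SimilarityConfig) -> np.ndarray:
    """Compare starting pattern ``a`` against every row of ``B``."""
    n = a.size
    max_diff = cfg.max_mismatches(n)
    rare_thr = cfg.rare_fraction * n

    diffs = a != B
    opposing = ((a == Genotype.REF_HOM) & (B == Genotype.ALT_HOM)) | (
        (a == Genotype.ALT_HOM) & (B == Genotype.REF_HOM)
    )
    ok = ~opposing.any(axis=1)
    ok &= diffs.sum(axis=1) <= max_diff

    alt_mask = (a == Genotype.HET) | (a == Genotype.ALT_HOM)
    ref_mask = (a == Genotype.HET) | (a == Genotype.REF_HOM)
    if alt_mask.sum() < rare_thr:
        ok &= ~(diffs & alt_mask).any(axis=1)
    if ref_mask.sum() < rare_thr:
        ok &= ~(diffs & ref_mask).any(axis=1)
    return ok


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def prune_widespread(
    fps: Sequence[Fingerprint],
    sim_cfg: SimilarityConfig | None = None,
    cfg: RelationConfig | None = None,
) -> tuple[list[Fingerprint], PatternPrevalence]:
    """Remove patterns that recur across too many fingerprints.

    For every pattern the prevalence is the number of distinct
    fingerprints (including its own) holding a similar pattern; patterns
    with prevalence strictly above ``max_pattern_fingerprints`` are
    dropped from their fingerprints. Counting is per pattern rather than
    by transitive similarity groups: gradual pattern drift along a
    chromosome would otherwise chain local haplotypes into one
    genome-wide group and prune legitimate local evidence.
    """
    if sim_cfg is None:
        sim_cfg = SimilarityConfig()
    if cfg is None:
        cfg = RelationConfig()

    keys: list[tuple[int, int]] = []
    rows: list[np.ndarray] = []
    fp_idx: list[int] = []
    for fi, fp in enumerate(fps):
        for pi, p in enumerate(fp.patterns):
            keys.append((fi, pi))
            rows.append(p.consensus)
            fp_idx.append(fi)
    prevalence: PatternPrevalence = {}
    if not rows:
        return [Fingerprint(fp.segment, list(fp.patterns)) for fp in fps], prevalence

    C = np.vstack(rows)
    fp_arr = np.asarray(fp_idx)
    n_fps = len(fps)
    drop: set[tuple[int, int]] = set()
    for i, key in enumerate(keys):
        hits = _similar_from(C[i], C, cfg=sim_cfg)
        touched = np.zeros(n_fps, dtype=bool)
        touched[fp_arr[hits]] = True
        count = int(touched.sum())
        prevalence[key] = count
        if count > cfg.max_pattern_fingerprints:
            drop.add(key)

    pruned = [
        Fingerprint(fp.segment, [p for pi, p in enumerate(fp.patterns) if (fi, pi) not in drop])
        for fi, fp in enumerate(fps)
    ]
    return pruned, prevalence


def _occurrence_order(fp: Fingerprint) -> list[int]:
    return sorted(range(len(fp.patterns)), key=lambda i: (-fp.patterns[i].occurrence, i))


class _FpView:
    """Cached matrix view of a fingerprint for fast pair comparison."""

    __slots__ = ("fp", "C", "occ", "order", "alt_mask", "ref_mask", "alt_rare", "ref_rare")

    def __init__(self, fp: Fingerprint, cfg: SimilarityConfig) -> None:
        self.fp = fp
        self.C = np.vstack([p.consensus for p in fp.patterns])
        self.occ = np.array([p.occurrence for p in fp.patterns])
        self.order = _occurrence_order(fp)
        n = self.C.shape[1]
        rare_thr = cfg.rare_fraction * n
        self.alt_mask = (self.C == Genotype.HET) | (self.C == Genotype.ALT_HOM)
        self.ref_mask = (self.C == Genotype.HET) | (self.C == Genotype.REF_HOM)
        self.alt_rare = self.alt_mask.sum(axis=1) < rare_thr
        self.ref_rare = self.ref_mask.sum(axis=1) < rare_thr


def _similarity_matrices(
    va: _FpView, vb: _FpView, cfg: SimilarityConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(sim_ab, sim_ba) boolean matrices over pattern pairs.

    ``sim_ab[i, j]`` is True when B's pattern j is similar to A's
    starting pattern i; ``sim_ba`` is the reverse direction (the rare
    rule makes the two differ in general).
    """
    A, B = va.C, vb.C
    n = A.shape[1]
    max_diff = cfg.max_mismatches(n)
    D = A[:, None, :] != B[None, :, :]
    opposing = ((A[:, None, :] == Genotype.REF_HOM) & (B[None, :, :] == Genotype.ALT_HOM)) | (
        (A[:, None, :] == Genotype.ALT_HOM) & (B[None, :, :] == Genotype.REF_HOM)
    )
    base = ~opposing.any(axis=2) & (D.sum(axis=2) <= max_diff)

    sim_ab = base & ~(
        va.alt_rare[:, None] & (D & va.alt_mask[:, None, :]).any(axis=2)
    ) & ~(va.ref_rare[:, None] & (D & va.ref_mask[:, None, :]).any(axis=2))
    sim_ba = base & ~(
        vb.alt_rare[None, :] & (D & vb.alt_mask[None, :, :]).any(axis=2)
    ) & ~(vb.ref_rare[None, :] & (D & vb.ref_mask[None, :, :]).any(axis=2))
    return sim_ab, sim_ba.T


def _greedy_match(
    sim: np.ndarray, va: _FpView, vb: _FpView
) -> list[SharedPatternMatch]:
    """Greedy one-to-one matching on a similarity matrix (rows = A)."""
    taken = set()
    matches: list[SharedPatternMatch] = []
    for ia in va.order:
        row = sim[ia]
        for ib in vb.order:
            if ib not in taken and row[ib]:
                taken.add(ib)
                matches.append(
                    SharedPatternMatch(ia, ib, int(va.occ[ia]), int(vb.occ[ib]))
                )
                break
    return matches


def match_patterns(
    fa: Fingerprint, fb: Fingerprint, cfg: SimilarityConfig | None = None
) -> list[SharedPatternMatch]:
    """Greedy one-to-one matching of A's patterns to B's.

    A's patterns are visited in occurrence-descending order (ties by
    index); each takes the first similar unmatched B pattern, also in
    occurrence-descending order. The A pattern acts as the starting
    pattern of the similarity test.
    """
    if cfg is None:
        cfg = SimilarityConfig()
    if not fa.patterns or not fb.patterns:
        return []
    va, vb = _FpView(fa, cfg), _FpView(fb, cfg)
    sim_ab, _ = _similarity_matrices(va, vb, cfg)
    return _greedy_match(sim_ab, va, vb)


def directed_score(
    fa: Fingerprint, fb: Fingerprint, matches: Sequence[SharedPatternMatch]
) -> float:
    """Occurrence-normalized Jaccard score of A against B.

    Matched B occurrences are rescaled to their A counterparts, so the
    union term is T_A plus only B's unmatched occurrences.
    """
    total_a = fa.total_occurrence
    if total_a == 0 or not fb.patterns:
        return 0.0
    intersection = sum(m.occurrence_a for m in matches)
    matched_b = {m.index_b for m in matches}
    unmatched_b = sum(p.occurrence for i, p in enumerate(fb.patterns) if i not in matched_b)
    denom = total_a + unmatched_b
    if denom == 0:
        return 0.0
    return intersection / denom


def relation_score(
    fa: Fingerprint,
    fb: Fingerprint,
    sim_cfg: SimilarityConfig | None = None,
    cfg: RelationConfig | None = None,
) -> Relation | None:
    """Score a segment pair; ``None`` when no pattern is shared.

    The relation score is the larger of the two directed scores (a
    haplotype fully contained in one fingerprint suffices); matches are
    reported from the winning direction, expressed in A/B terms.
    """
    if sim_cfg is None:
        sim_cfg = SimilarityConfig()
    if cfg is None:
        cfg = RelationConfig()
    if not fa.patterns or not fb.patterns:
        return None
    va, vb = _FpView(fa, sim_cfg), _FpView(fb, sim_cfg)
    return _relation_from_views(va, vb, sim_cfg, cfg)


def _relation_from_views(
    va: _FpView, vb: _FpView, sim_cfg: SimilarityConfig, cfg: RelationConfig
) -> Relation | None:
    fa, fb = va.fp, vb.fp
    sim_ab, sim_ba = _similarity_matrices(va, vb, sim_cfg)
    if not sim_ab.any() and not sim_ba.any():
        return None
    m_ab = _greedy_match(sim_ab, va, vb)
    m_ba = _greedy_match(sim_ba, vb, va)
    if not m_ab and not m_ba:
        return None
    s_ab = directed_score(fa, fb, m_ab)
    s_ba = directed_score(fb, fa, m_ba)
    if s_ab >= s_ba:
        matches = m_ab
    else:
        matches = [
            SharedPatternMatch(m.index_b, m.index_a, m.occurrence_b, m.occurrence_a)
            for m in m_ba
        ]
    score = max(s_ab, s_ba)
    return Relation(
        segment_a=fa.segment,
        segment_b=fb.segment,
        matches=matches,
        score=score,
        valid=score >= cfg.validity_threshold,
        score_ab=s_ab,
        score_ba=s_ba,
    )


def all_vs_all(
    fps: Sequence[Fingerprint],
    sim_cfg: SimilarityConfig | None = None,
    cfg: RelationConfig | None = None,
) -> list[Relation]:
    """All unordered segment pairs sharing at least one pattern.

    Intra-contig pairs are included (flagged via ``Relation.intra_contig``).
    Output order is deterministic: by the sorted pair of segment ids.
    """
    if sim_cfg is None:
        sim_cfg = SimilarityConfig()
    if cfg is None:
        cfg = RelationConfig()
    indexed = sorted(
        (fp for fp in fps if fp.patterns), key=lambda fp: (fp.segment.contig, fp.segment.start)
    )
    views = [_FpView(fp, sim_cfg) for fp in indexed]
    out: list[Relation] = []
    for i in range(len(views)):
        for j in range(i + 1, len(views)):
            rel = _relation_from_views(views[i], views[j], sim_cfg, cfg)
            if rel is not None:
                out.append(rel)
    return out


_REL_COLUMNS = (
    "contigA\tstartA\tendA\tidxA\tcontigB\tstartB\tendB\tidxB\t"
    "n_shared\tscore\tscore_ab\tscore_ba\tvalid\tintra_contig"
)


def write_relations_tsv(relations: Sequence[Relation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + _REL_COLUMNS + "\n")
        for r in relations:
            a, b = r.segment_a, r.segment_b
            fh.write(
                f"{a.contig}\t{a.start}\t{a.end}\t{a.index}\t"
                f"{b.contig}\t{b.start}\t{b.end}\t{b.index}\t"
                f"{r.n_shared}\t{r.score:.6f}\t{r.score_ab:.6f}\t{r.score_ba:.6f}\t"
                f"{int(r.valid)}\t{int(r.intra_contig)}\n"
            )


def read_relations_tsv(path: str | Path) -> list[Relation]:
    """Read relations back; per-pattern match details are not preserved,
    only the shared-pattern count and scores."""
    out: list[Relation] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            a = Segment(f[0], int(f[1]), int(f[2]), int(f[3]))
            b = Segment(f[4], int(f[5]), int(f[6]), int(f[7]))
            n_shared = int(f[8])
            rel = Relation(
                segment_a=a,
                segment_b=b,
                matches=[SharedPatternMatch(-1, -1, 0, 0)] * n_shared,
                score=float(f[9]),
                valid=bool(int(f[12])),
                score_ab=float(f[10]),
                score_ba=float(f[11]),
            )
            out.append(rel)
    return out
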