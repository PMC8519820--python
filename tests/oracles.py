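"""Independent brute-force reference implementations used as oracles.

These deliberately re-derive behavior with the simplest possible code
(scalar loops, naive enumeration) and must stay independent of the
vectorized production paths they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

REF, HET, ALT, MISS = 0, 1, 2, 3


def similar_oracle(a, b, het_tol=0.10, rare_fraction=0.20) -> bool:
    """Scalar re-statement of the pattern similarity rules."""
    a = list(a)
    b = list(b)
    n = len(a)
    assert len(b) == n
    for x, y in zip(a, b):
        if (x == REF and y == ALT) or (x == ALT and y == REF):
            return False
    ndiff = sum(x != y for x, y in zip(a, b))
    if ndiff > math.floor(het_tol * n):
        return False
    alt_idx = [i for i in range(n) if a[i] in (HET, ALT)]
    ref_idx = [i for i in range(n) if a[i] in (HET, REF)]
    if len(alt_idx) < rare_fraction * n and any(a[i] != b[i] for i in alt_idx):
        return False
    if len(ref_idx) < rare_fraction * n and any(a[i] != b[i] for i in ref_idx):
        return False
    return True


def update_oracle(consensus, member):
    out = list(consensus)
    for i, (c, m) in enumerate(zip(consensus, member)):
        if c == MISS and m != MISS:
            out[i] = m
        elif c == HET and m in (REF, ALT):
            out[i] = m
    return out


def cluster_oracle(site_vectors, het_tol=0.10, rare_fraction=0.20, min_occurrence=3):
    """Naive greedy clustering: first similar cluster in creation order."""
    clusters: list[dict] = []
    for vec in site_vectors:
        vec = list(vec)
        for cl in clusters:
            if similar_oracle(cl["consensus"], vec, het_tol, rare_fraction):
                cl["consensus"] = update_oracle(cl["consensus"], vec)
                cl["members"].append(vec)
                break
        else:
            clusters.append({"consensus": vec, "members": [vec]})
    return [cl for cl in clusters if len(cl["members"]) >= min_occurrence]


def greedy_match_oracle(pats_a, pats_b, het_tol=0.10, rare_fraction=0.20):
    """Naive greedy one-to-one matching; patterns are (consensus, occ)."""
    order_a = sorted(range(len(pats_a)), key=lambda i: (-pats_a[i][1], i))
    order_b = sorted(range(len(pats_b)), key=lambda i: (-pats_b[i][1], i))
    taken: set[int] = set()
    matches = []
    for ia in order_a:
        for ib in order_b:
            if ib in taken:
                continue
            if similar_oracle(pats_a[ia][0], pats_b[ib][0], het_tol, rare_fraction):
                taken.add(ib)
                matches.append((ia, ib))
                break
    return matches


def directed_score_oracle(pats_a, pats_b, matches):
    total_a = sum(o for _, o in pats_a)
    if total_a == 0 or not pats_b:
        return 0.0
    inter = sum(pats_a[ia][1] for ia, _ in matches)
    matched_b = {ib for _, ib in matches}
    u_b = sum(o for j, (_, o) in enumerate(pats_b) if j not in matched_b)
    return inter / (total_a + u_b) if (total_a + u_b) else 0.0


def max_cardinality_matching_oracle(pats_a, pats_b, het_tol=0.10, rare_fraction=0.20):
    """Exhaustive maximum-cardinality one-to-one matching size."""
    edges = [
        (i, j)
        for i in range(len(pats_a))
        for j in range(len(pats_b))
        if similar_oracle(pats_a[i][0], pats_b[j][0], het_tol, rare_fraction)
    ]
    best = 0
    for k in range(min(len(pats_a), len(pats_b)), 0, -1):
        for combo in combinations(edges, k):
            if len({i for i, _ in combo}) == k and len({j for _, j in combo}) == k:
                return k
    return best


def site_filter_oracle(site, n, cfg) -> bool:
    """Direct per-rule re-check of a site against the filter config."""
    calls = list(site.calls)
    if cfg.biallelic_snp_only:
        alleles = [site.ref_allele, *site.alt_alleles]
        if any(len(x) != 1 or x not in "ACGT" for x in alleles):
            return False
        if len(site.alt_alleles) != 1:
            return False
    called = sum(c != MISS for c in calls)
    if called / n < cfg.min_called_fraction:
        return False
    if cfg.max_missing_fraction is not None and (n - called) / n > cfg.max_missing_fraction:
        return False
    if site.total_depth is not None and site.total_depth > cfg.max_total_depth:
        return False
    if site.depths is not None:
        covered = sum(d >= cfg.min_depth_per_called_accession for d in site.depths)
        if covered / n < cfg.min_called_fraction:
            return False
    ref_c = sum(c in (REF, HET) for c in calls)
    alt_c = sum(c in (ALT, HET) for c in calls)
    if ref_c < cfg.min_ref_genotypes or alt_c < cfg.min_alt_genotypes:
        return False
    if called == 0:
        return False
    alt_freq = (2 * sum(c == ALT for c in calls) + sum(c == HET for c in calls)) / (2 * called)
    return min(alt_freq, 1 - alt_freq) >= cfg.maf_min


def components_oracle(edges, nodes=()):
    """Union-find connected components, written independently."""
    parent: dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for n in nodes:
        find(n)
    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict = {}
    for x in parent:
        comps.setdefault(find(x), set()).add(x)
    return sorted((frozenset(c) for c in comps.values()), key=lambda s: min(s))


def segment_count_oracle(length, size):
    if length < size:
        return 1
    return math.ceil(length / size)


def recovery_oracle(rel_rows, truth, segment_size=100_000, remote=1_000_000):
    """Recount recovery metrics from (contigA, startA, endA, contigB,
    startB, endB, valid) tuples and a TruthMap, scalar style."""
    def interval(contig, s, e):
        chrom, cs, ce, orient = truth.placements[contig]
        clen = ce - cs
        if orient == "+":
            return chrom, cs + s, cs + e
        return chrom, cs + (clen - e), cs + (clen - s)

    junctions = {tuple(sorted((u, v))) for u, v, _ in truth.adjacencies}
    n_adj = n_rem = 0
    hit = set()
    for ca, sa, ea, cb, sb, eb, valid in rel_rows:
        if not valid:
            continue
        cha, a0, a1 = interval(ca, sa, ea)
        chb, b0, b1 = interval(cb, sb, eb)
        if cha != chb:
            n_rem += 1
            continue
        dist = max(b0 - a1, a0 - b1, 0)
        if dist <= segment_size:
            n_adj += 1
            key = tuple(sorted((ca, cb)))
            if key in junctions:
                hit.add(key)
        elif dist > remote:
            n_rem += 1
    mbp = sum(e - s for _, s, e, _ in truth.placements.values()) / 1e6
    return {
        "adjacent_per_mbp": n_adj / mbp,
        "remote_per_mbp": n_rem / mbp,
        "precision": n_adj / (n_adj + n_rem) if (n_adj + n_rem) else 0.0,
        "recall": len(hit) / len(junctions) if junctions else 1.0,
    }


def overlap_dp_oracle(tail_a: str, head_b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Best suffix(A)/prefix(B) alignment score by plain DP.

    Free leading gap in A (overlap may start inside A) and free trailing
    gap in B; affine penalties are not modeled, so compare against an
    aligner configured with linear gap costs.
    """
    n, m = len(tail_a), len(head_b)
    prev = [0.0] * (m + 1)
    for j in range(1, m + 1):
        prev[j] = prev[j - 1] + gap
    for i in range(1, n + 1):
        cur = [0.0] * (m + 1)  # free gap before A's suffix
        for j in range(1, m + 1):
            s = match if tail_a[i - 1] == head_b[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    # A fully consumed; B's trailing overhang is free
    return max(prev)
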