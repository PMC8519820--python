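"""Physical-evidence integration and scaffold emission.

Haplotype-derived linear contig orders are confirmed junction by
junction with mate-pair links, end-proximal long-read alignments and
contig-end overlaps; only adjacencies with at least one kind of physical
evidence are joined. Orientation is decided by majority vote over
supporting read pairs / reads (exact ties reject the join). Gap sizes
come from the library span minus the summed read-to-contig-end
distances, aggregated by the median; estimated gaps below the minimum
trigger an overlap search before falling back to the minimum gap.

Link geometry conventions
-------------------------
Mate-pair rows are ``read_id contigA posA strandA contigB posB strandB
library`` with 0-based positions. Pairs are interpreted as
forward/reverse across the junction: a read on the first contig aligned
``+`` points at that contig's tail (so the contig enters the scaffold
forward), ``-`` at its head; the mirror logic applies to the second
contig. End distances are measured from the read position to the contig
end facing the junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MatePairLink",
    "LongReadLink",
    "OverlapCandidate",
    "Join",
    "ScaffoldSequence",
    "ScaffoldPlan",
    "read_mate_links",
    "estimate_gap",
    "longread_links",
    "find_overlap",
    "decide_joins",
    "emit_scaffolds",
    "read_agp",
    "detect_coverage_drop",
    "n50",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


@dataclass
class MatePairLink:
    """Aggregated mate-pair support for one contig pair from one library.

    ``pairs`` holds per-read-pair tuples ``(orient_a, orient_b, d_a,
    d_b)`` where orientations are expressed for the (contig_a, contig_b)
    order and d is the distance from the read to the junction-facing
    contig end.
    """

    contig_a: str
    contig_b: str
    library: str
    span: int
    pairs: list[tuple[str, str, int, int]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def orientation_votes(self) -> dict[tuple[str, str], int]:
        votes: dict[tuple[str, str], int] = {}
        for oa, ob, _, _ in self.pairs:
            votes[(oa, ob)] = votes.get((oa, ob), 0) + 1
        return votes


@dataclass
class LongReadLink:
    """Long-read support for one contig pair from end-proximal alignments."""

    contig_a: str
    contig_b: str
    read_ids: list[str] = field(default_factory=list)
    votes: dict[tuple[str, str], int] = field(default_factory=dict)
    gap_estimates: list[int] = field(default_factory=list)
    end_fraction: float = 0.10

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


@dataclass
class OverlapCandidate:
    """An end-to-end overlap between an oriented contig tail and head."""

    contig_a: str
    contig_b: str
    length: int
    identity: float
    trim_b: int  # bases to cut from B's (oriented) head when merging


@dataclass
class Join:
    """One decided junction between consecutive contigs of a scaffold."""

    contig_a: str
    contig_b: str
    kind: str  # "gap" | "overlap"
    gap: int = 0
    overlap: OverlapCandidate | None = None
    evidence: str = ""
    n_support: int = 0


@dataclass
class ScaffoldSequence:
    name: str
    members: list[tuple[str, str]]  # (contig, orientation)
    joins: list[Join] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.joins) != max(len(self.members) - 1, 0):
            raise ValueError("a scaffold needs exactly members - 1 joins")


@dataclass
class ScaffoldPlan:
    group: str
    sequences: list[ScaffoldSequence]
    rejected: list[str] = field(default_factory=list)


def read_mate_links(
    path: str | Path, library: str, span: int
) -> dict[tuple[str, str], MatePairLink]:
    """Read one library's link TSV into per-contig-pair links.

    Rows linking a contig to itself are ignored. Pair keys are
    normalized to sorted contig-name order (orientations and distances
    are remapped accordingly).
    """
    links: dict[tuple[str, str], MatePairLink] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            _, ca, pos_a, sa, cb, pos_b, sb = f[0], f[1], int(f[2]), f[3], f[4], int(f[5]), f[6]
            lib = f[7] if len(f) > 7 else library
            if lib != library or ca == cb:
                continue
            # orientations in (ca, cb) order; distances need contig
            # lengths, so keep raw position + strand and resolve later
            links.setdefault(
                tuple(sorted((ca, cb))),
                MatePairLink(*sorted((ca, cb)), library=library, span=span),
            )
            link = links[tuple(sorted((ca, cb)))]
            link.pairs.append(_raw_pair(ca, pos_a, sa, cb, pos_b, sb, link))
    return links


def _raw_pair(ca, pos_a, sa, cb, pos_b, sb, link) -> tuple[str, str, int, int]:
    """Normalize one raw pair into the link's canonical contig order.

    Distances are stored as raw positions at this point; they are turned
    into end distances in :func:`resolve_link_distances` once contig
    lengths are known.
    """
    oa = "+" if sa == "+" else "-"
    ob = "+" if sb == "-" else "-"
    if ca == link.contig_a:
        return (oa, ob, pos_a, pos_b)
    # file listed the pair as (cb_first); swap order => flip both
    return (_flip(ob), _flip(oa), pos_b, pos_a)


def resolve_link_distances(
    links: Mapping[tuple[str, str], MatePairLink],
    contig_lengths: Mapping[str, int],
) -> None:
    """Convert raw positions to junction-end distances, in place."""
    for (ca, cb), link in links.items():
        la, lb = contig_lengths[ca], contig_lengths[cb]
        resolved = []
        for oa, ob, pa, pb in link.pairs:
            d_a = la - pa if oa == "+" else pa + 1
            d_b = pb + 1 if ob == "+" else lb - pb
            resolved.append((oa, ob, d_a, d_b))
        link.pairs = resolved


def estimate_gap(link: MatePairLink, orientation: tuple[str, str] | None = None) -> int | None:
    """Median gap over supporting pairs: ``span - (d_a + d_b)``.

    Restricted to pairs voting for ``orientation`` when given. Negative
    values signal a probable overlap. ``None`` when no usable pair.
    """
    pairs = link.pairs
    if orientation is not None:
        pairs = [p for p in pairs if (p[0], p[1]) == orientation]
    if not pairs:
        return None
    gaps = [link.span - (d_a + d_b) for _, _, d_a, d_b in pairs]
    return int(np.median(gaps))


def longread_links(
    paf: str | Path,
    end_fraction: float = 0.10,
) -> dict[tuple[str, str], LongReadLink]:
    """Contig links from long reads aligning end-proximal on two contigs.

    Alignments of one read (split alignments share the read name) are
    ordered along the read; consecutive alignments to different contigs
    whose target intervals lie within ``end_fraction`` of the facing
    contig end yield a link with an orientation vote and a gap estimate.
    Malformed PAF lines are skipped with a warning.
    """
    import sys

    by_read: dict[str, list[tuple]] = {}
    with open(paf) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                qname, qstart, qend = f[0], int(f[2]), int(f[3])
                strand, tname = f[4], f[5]
                tlen, tstart, tend = int(f[6]), int(f[7]), int(f[8])
            except (IndexError, ValueError):
                print(f"warning: skipping malformed PAF line {ln}", file=sys.stderr)
                continue
            by_read.setdefault(qname, []).append((qstart, qend, strand, tname, tlen, tstart, tend))

    links: dict[tuple[str, str], LongReadLink] = {}
    for qname, alns in by_read.items():
        alns.sort()
        for first, second in zip(alns, alns[1:]):
            q1s, q1e, s1, t1, l1, t1s, t1e = first
            q2s, q2e, s2, t2, l2, t2s, t2e = second
            if t1 == t2:
                continue
            # the read exits contig 1 at its tail when aligned forward
            o1 = "+" if s1 == "+" else "-"
            o2 = "+" if s2 == "+" else "-"
            exit_ok = _end_proximal(t1s, t1e, l1, end_fraction, "tail" if o1 == "+" else "head")
            entry_ok = _end_proximal(t2s, t2e, l2, end_fraction, "head" if o2 == "+" else "tail")
            if not (exit_ok and entry_ok):
                continue
            over1 = l1 - t1e if o1 == "+" else t1s
            over2 = t2s if o2 == "+" else l2 - t2e
            gap = (q2s - q1e) - over1 - over2
            ca, cb = t1, t2
            if ca > cb:
                ca, cb, o1, o2 = cb, ca, _flip(o2), _flip(o1)
            link = links.setdefault(
                (ca, cb), LongReadLink(ca, cb, end_fraction=end_fraction)
            )
            link.read_ids.append(qname)
            link.votes[(o1, o2)] = link.votes.get((o1, o2), 0) + 1
            link.gap_estimates.append(gap)
    return links


def _end_proximal(tstart: int, tend: int, tlen: int, frac: float, which: str) -> bool:
    if which == "head":
        return tstart <= frac * tlen
    return tend >= (1.0 - frac) * tlen


def find_overlap(
    tail_a: str,
    head_b: str,
    min_len: int = 100,
    min_identity: float = 0.95,
    contig_a: str = "A",
    contig_b: str = "B",
) -> OverlapCandidate | None:
    """Best suffix(A)/prefix(B) overlap of two oriented contig ends.

    Uses a free-end-gap global alignment (overhangs of A's start and B's
    end are unpenalized); reported only when the aligned region reaches
    ``min_len`` and ``min_identity``.
    """
    if not tail_a or not head_b:
        return None
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    # free overhangs: A's unaligned prefix and B's unaligned suffix
    aligner.open_left_deletion_score = 0.0
    aligner.extend_left_deletion_score = 0.0
    aligner.open_right_insertion_score = 0.0
    aligner.extend_right_insertion_score = 0.0

    aln = aligner.align(tail_a.upper(), head_b.upper())[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    matches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        ta = tail_a[ts:te].upper()
        qa = head_b[qs:qe].upper()
        matches += sum(x == y for x, y in zip(ta, qa))
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    length = max(t_span, q_span)
    if length < min_len:
        return None
    identity = matches / length
    if identity < min_identity:
        return None
    return OverlapCandidate(
        contig_a=contig_a,
        contig_b=contig_b,
        length=length,
        identity=identity,
        trim_b=int(q_blocks[-1][1]),
    )


OverlapFinder = Callable[[str, str, str, str], OverlapCandidate | None]


def decide_joins(
    order: Sequence[str],
    mate_links: Mapping[tuple[str, str], Sequence[MatePairLink]] | None = None,
    lr_links: Mapping[tuple[str, str], LongReadLink] | None = None,
    overlap_finder: OverlapFinder | None = None,
    group: str = "group",
    min_gap: int = 10,
) -> ScaffoldPlan:
    """Confirm a linear contig order with physical evidence.

    Each adjacent pair is joined only when mate-pair, long-read or
    overlap evidence exists; orientation is the majority over all
    orientation votes (exact ties reject the join and are logged).
    Mate-pair / long-read gap estimates take precedence over overlaps,
    except that a sub-minimum estimated gap triggers an overlap search.
    Unconfirmed adjacencies split the scaffold; the pieces keep the
    group's name.
    """
    mate_links = mate_links or {}
    lr_links = lr_links or {}
    rejected: list[str] = []
    sequences: list[ScaffoldSequence] = []
    cur_members: list[tuple[str, str]] = []
    cur_joins: list[Join] = []

    def flush() -> None:
        nonlocal cur_members, cur_joins
        if cur_members:
            name = f"{group}_{len(sequences) + 1}"
            sequences.append(ScaffoldSequence(name, cur_members, cur_joins))
        cur_members, cur_joins = [], []

    prev_orient: str | None = None
    for u, v in zip(order, order[1:]):
        key = (u, v) if u < v else (v, u)
        flipped = key != (u, v)

        votes: dict[tuple[str, str], int] = {}
        links_here = list(mate_links.get(key, []))
        for link in links_here:
            for vote, count in link.orientation_votes().items():
                votes[vote] = votes.get(vote, 0) + count
        lr = lr_links.get(key)
        if lr is not None:
            for vote, count in lr.votes.items():
                votes[vote] = votes.get(vote, 0) + count
        if flipped:
            votes = {(_flip(ob), _flip(oa)): c for (oa, ob), c in votes.items()}

        have_reads = bool(votes)
        if not have_reads and overlap_finder is None:
            rejected.append(f"{u}--{v}: no physical evidence")
            if not cur_members:
                cur_members = [(u, prev_orient or "+")]
            flush()
            prev_orient = None
            continue

        if have_reads:
            best = max(votes.values())
            winners = [o for o, c in votes.items() if c == best]
            if len(winners) > 1:
                rejected.append(f"{u}--{v}: orientation tie {votes}")
                if not cur_members:
                    cur_members = [(u, prev_orient or "+")]
                flush()
                prev_orient = None
                continue
            orient_u, orient_v = winners[0]
            n_support = sum(votes.values())
        else:
            orient_u, orient_v = prev_orient or "+", "+"
            n_support = 0

        if cur_members and cur_members[-1][0] == u and cur_members[-1][1] != orient_u:
            rejected.append(
                f"{u}--{v}: orientation {orient_u} conflicts with assigned {cur_members[-1][1]}"
            )
            flush()
            prev_orient = None
            continue

        gap_estimates: list[int] = []
        for link in links_here:
            vote = (orient_u, orient_v) if not flipped else (_flip(orient_v), _flip(orient_u))
            g = estimate_gap(link, vote)
            if g is not None:
                gap_estimates.append(g)
        if lr is not None and lr.gap_estimates:
            gap_estimates.append(int(np.median(lr.gap_estimates)))

        evidence_bits = []
        if links_here:
            evidence_bits.append("mate-pair")
        if lr is not None:
            evidence_bits.append("long-read")

        join: Join | None = None
        gap = int(np.median(gap_estimates)) if gap_estimates else None
        if gap is not None and gap >= min_gap:
            join = Join(u, v, "gap", gap=gap, evidence="+".join(evidence_bits), n_support=n_support)
        else:
            ov = None
            if overlap_finder is not None:
                ov = overlap_finder(u, orient_u, v, orient_v)
            if ov is not None:
                bits = evidence_bits + ["overlap"]
                join = Join(u, v, "overlap", overlap=ov, evidence="+".join(bits), n_support=n_support)
            elif gap is not None:
                join = Join(
                    u, v, "gap", gap=max(gap, min_gap),
                    evidence="+".join(evidence_bits), n_support=n_support,
                )
            elif have_reads:
                join = Join(u, v, "gap", gap=min_gap, evidence="+".join(evidence_bits), n_support=n_support)

        if join is None:
            rejected.append(f"{u}--{v}: no physical evidence")
            if not cur_members:
                cur_members = [(u, prev_orient or "+")]
            flush()
            prev_orient = None
            continue

        if not cur_members:
            cur_members = [(u, orient_u)]
        cur_members.append((v, orient_v))
        cur_joins.append(join)
        prev_orient = orient_v

    if not cur_members and order:
        last = order[-1]
        if not sequences or sequences[-1].members[-1][0] != last:
            cur_members = [(last, prev_orient or "+")]
    flush()
    return ScaffoldPlan(group=group, sequences=sequences, rejected=rejected)


def emit_scaffolds(
    contigs: Mapping[str, str] | str | Path,
    plans: Sequence[ScaffoldPlan],
    min_gap: int = 10,
    overlap_gap: int = 10,
    out_fasta: str | Path | None = None,
    out_agp: str | Path | None = None,
) -> dict[str, str]:
    """Render scaffold plans to sequences, FASTA and AGP v2.1.

    Gap joins insert ``max(estimated gap, min_gap)`` Ns; overlap joins
    trim the downstream contig's oriented head and insert exactly
    ``overlap_gap`` Ns. A trim longer than the contig aborts that join
    (raises, since the plan is invalid for the given sequences).
    """
    if not isinstance(contigs, Mapping):
        from Bio import SeqIO

        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(contigs), "fasta")}

    out: dict[str, str] = {}
    agp_rows: list[str] = []
    for plan in plans:
        for seq in plan.sequences:
            parts: list[str] = []
            rows: list[tuple] = []
            pos = 0
            part_no = 0
            for i, (contig, orient) in enumerate(seq.members):
                s = contigs[contig]
                if orient == "-":
                    s = revcomp(s)
                comp_beg, comp_end = 1, len(contigs[contig])
                if i > 0:
                    join = seq.joins[i - 1]
                    if join.kind == "overlap":
                        trim = join.overlap.trim_b
                        if trim >= len(s):
                            raise ValueError(
                                f"overlap trim {trim} >= contig {contig} length {len(s)}"
                            )
                        s = s[trim:]
                        if orient == "+":
                            comp_beg = trim + 1
                        else:
                            comp_end = len(contigs[contig]) - trim
                        ns = overlap_gap
                    else:
                        ns = max(join.gap, min_gap)
                    part_no += 1
                    rows.append(
                        (pos + 1, pos + ns, part_no, "N", ns, "scaffold", "yes", "paired-ends")
                    )
                    parts.append("N" * ns)
                    pos += ns
                part_no += 1
                rows.append((pos + 1, pos + len(s), part_no, "W", contig, comp_beg, comp_end, orient))
                parts.append(s)
                pos += len(s)
            out[seq.name] = "".join(parts)
            for r in rows:
                agp_rows.append(seq.name + "\t" + "\t".join(str(x) for x in r))

    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for name, s in out.items():
                fh.write(f">{name}\n")
                for i in range(0, len(s), 80):
                    fh.write(s[i : i + 80] + "\n")
    if out_agp is not None:
        with open(out_agp, "w") as fh:
            fh.write("##agp-version\t2.1\n")
            fh.write("\n".join(agp_rows) + ("\n" if agp_rows else ""))
    return out


def read_agp(path: str | Path) -> list[dict]:
    """Parse an AGP v2.1 file into row dicts (W and N components)."""
    rows: list[dict] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            row = {
                "object": f[0],
                "object_beg": int(f[1]),
                "object_end": int(f[2]),
                "part_number": int(f[3]),
                "component_type": f[4],
            }
            if f[4] == "W":
                row.update(
                    component_id=f[5],
                    component_beg=int(f[6]),
                    component_end=int(f[7]),
                    orientation=f[8],
                )
            else:
                row.update(gap_length=int(f[5]), gap_type=f[6], linkage=f[7], evidence=f[8])
            rows.append(row)
    return rows


def detect_coverage_drop(
    coverage: Sequence[float] | np.ndarray,
    window: int = 1000,
    drop_ratio: float = 0.25,
    bin_size: int = 1,
) -> list[tuple[int, int]]:
    """Windows whose mean coverage falls below ``drop_ratio`` x median.

    ``coverage`` is per-base (``bin_size=1``) or binned; returned
    intervals are in bp, adjacent low windows merged. Used to localize
    putative misassemblies inside contigs carrying conflicting marker
    assignments.
    """
    cov = np.asarray(coverage, dtype=float)
    if cov.size == 0:
        return []
    median = float(np.median(cov))
    win_bins = max(window // bin_size, 1)
    candidates: list[tuple[int, int]] = []
    for start in range(0, cov.size, win_bins):
        chunk = cov[start : start + win_bins]
        if float(chunk.mean()) < drop_ratio * median:
            s_bp = start * bin_size
            e_bp = min((start + win_bins) * bin_size, cov.size * bin_size)
            if candidates and candidates[-1][1] == s_bp:
                candidates[-1] = (candidates[-1][0], e_bp)
            else:
                candidates.append((s_bp, e_bp))
    return candidates


def n50(lengths: Iterable[int]) -> int:
    """N50 of a set of sequence lengths (0 for an empty set)."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        return 0
    half = sum(ls) / 2
    acc = 0
    for l in ls:
        acc += l
        if acc >= half:
            return l
    return ls[-1]
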