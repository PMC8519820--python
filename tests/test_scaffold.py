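import numpy as np
import pytest

from ldscaffold.scaffold import (
    Join,
    MatePairLink,
    OverlapCandidate,
    ScaffoldPlan,
    ScaffoldSequence,
    decide_joins,
    detect_coverage_drop,
    emit_scaffolds,
    estimate_gap,
    find_overlap,
    longread_links,
    n50,
    read_agp,
    read_mate_links,
    resolve_link_distances,
    revcomp,
)

from oracles import overlap_dp_oracle


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestEstimateGap:
    def test_direct_arithmetic(self):
        link = MatePairLink("a", "b", "mp", span=5000, pairs=[("+", "+", 1000, 1500)])
        assert estimate_gap(link) == 2500

    def test_negative_gap_signals_overlap(self):
        link = MatePairLink("a", "b", "mp", span=5000, pairs=[("+", "+", 3000, 2500)])
        assert estimate_gap(link) == -500

    def test_no_pairs_undefined(self):
        link = MatePairLink("a", "b", "mp", span=5000, pairs=[])
        assert estimate_gap(link) is None

    def test_orientation_restriction(self):
        link = MatePairLink(
            "a", "b", "mp", span=5000,
            pairs=[("+", "+", 1000, 1500), ("-", "+", 10, 10)],
        )
        assert estimate_gap(link, ("+", "+")) == 2500

    def test_median_recovers_truth_under_noise(self, rng):
        span, sd, true_gap = 5000, 300, 800
        pairs = []
        for _ in range(100):
            s = rng.normal(span, sd)
            d_total = s - true_gap
            d_a = rng.uniform(1, d_total - 1)
            pairs.append(("+", "+", int(d_a), int(d_total - d_a)))
        link = MatePairLink("a", "b", "mp", span=span, pairs=pairs)
        assert abs(estimate_gap(link) - true_gap) <= 2 * sd


class TestMateLinkReading:
    def test_roundtrip_distances(self, tmp_path):
        # junction at a's tail (+) and b's head (+): d_a=1200, d_b=800
        p = tmp_path / "links.tsv"
        p.write_text("r1\tA\t8800\t+\tB\t799\t-\tmp\n")
        links = read_mate_links(p, library="mp", span=5000)
        resolve_link_distances(links, {"A": 10000, "B": 9000})
        link = links[("A", "B")]
        assert link.pairs == [("+", "+", 1200, 800)]
        assert estimate_gap(link) == 5000 - 2000

    def test_swapped_pair_order_normalized(self, tmp_path):
        p = tmp_path / "links.tsv"
        # same physical pair but B listed first
        p.write_text("r1\tB\t799\t-\tA\t8800\t+\tmp\n")
        links = read_mate_links(p, library="mp", span=5000)
        resolve_link_distances(links, {"A": 10000, "B": 9000})
        assert links[("A", "B")].pairs == [("+", "+", 1200, 800)]

    def test_self_links_ignored(self, tmp_path):
        p = tmp_path / "links.tsv"
        p.write_text("r1\tA\t10\t+\tA\t500\t-\tmp\n")
        assert read_mate_links(p, library="mp", span=5000) == {}


class TestLongReadLinks:
    def paf_line(self, qname, qs, qe, strand, tname, tlen, ts, te, qlen=10000):
        return f"{qname}\t{qlen}\t{qs}\t{qe}\t{strand}\t{tname}\t{tlen}\t{ts}\t{te}\t{qe-qs}\t{qe-qs}\t60"

    def test_end_proximal_boundary(self, tmp_path):
        p = tmp_path / "a.paf"
        # alignment ending at 95k of a 100k contig is end-proximal;
        # 85k is not
        p.write_text(
            "\n".join([
                self.paf_line("r1", 0, 5000, "+", "A", 100_000, 90_000, 95_000),
                self.paf_line("r1", 5000, 10000, "+", "B", 50_000, 0, 5_000),
                self.paf_line("r2", 0, 5000, "+", "A", 100_000, 80_000, 85_000),
                self.paf_line("r2", 5000, 10000, "+", "B", 50_000, 0, 5_000),
            ]) + "\n"
        )
        links = longread_links(p)
        assert ("A", "B") in links
        assert links[("A", "B")].read_ids == ["r1"]
        assert links[("A", "B")].votes == {("+", "+"): 1}

    def test_malformed_line_skipped(self, tmp_path, capsys):
        p = tmp_path / "a.paf"
        p.write_text("garbage line\n" + self.paf_line("r1", 0, 5, "+", "A", 100, 95, 100) + "\n")
        assert longread_links(p) == {}

    def test_simulated_junctions_recovered(self, small_sim, tmp_path, rng):
        from ldscaffold.simpop import simulate_long_reads

        rows = simulate_long_reads(small_sim, read_length=8000, reads_per_junction=2, rng=rng)
        p = tmp_path / "lr.paf"
        p.write_text("\n".join(rows) + "\n")
        links = longread_links(p)
        expected = {tuple(sorted((u, v))) for u, v, _ in small_sim.truth.adjacencies}
        assert set(links) == expected
        # orientations match the truth placements
        for (ca, cb), link in links.items():
            ((oa, ob),) = [max(link.votes, key=link.votes.get)]
            toa = small_sim.truth.placements[ca][3]
            tob = small_sim.truth.placements[cb][3]
            fwd = {(u, v) for u, v, _ in small_sim.truth.adjacencies}
            if (ca, cb) in fwd:
                assert (oa, ob) == (toa, tob)
            else:
                flip = {"+": "-", "-": "+"}
                assert (oa, ob) == (flip[tob], flip[toa])
            # gap estimates center on zero (contigs abut)
            assert abs(int(np.median(link.gap_estimates))) <= 2


class TestFindOverlap:
    def test_exact_500bp_overlap(self, rng):
        shared = random_seq(rng, 500)
        tail = random_seq(rng, 1500) + shared
        head = shared + random_seq(rng, 1500)
        ov = find_overlap(tail, head)
        assert ov is not None
        assert ov.length == 500 and ov.identity == 1.0 and ov.trim_b == 500

    def test_unrelated_ends_none(self, rng):
        assert find_overlap(random_seq(rng, 1000), random_seq(rng, 1000)) is None

    def test_mutated_overlap_vs_dp_oracle(self, rng):
        shared = random_seq(rng, 1000)
        mutated = list(shared)
        idx = rng.choice(1000, size=10, replace=False)
        for i in idx:
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        tail = random_seq(rng, 1000) + shared
        head = "".join(mutated) + random_seq(rng, 1000)
        ov = find_overlap(tail, head)
        assert ov is not None
        assert ov.identity == pytest.approx(0.99, abs=0.003)
        assert abs(ov.length - 1000) <= 5
        # score parity with a plain DP oracle under linear gap costs
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -2.0
        aligner.extend_gap_score = -2.0
        aligner.open_left_deletion_score = 0.0
        aligner.extend_left_deletion_score = 0.0
        aligner.open_right_insertion_score = 0.0
        aligner.extend_right_insertion_score = 0.0
        got = aligner.score(tail[-1200:], head[:1200])
        assert got == pytest.approx(overlap_dp_oracle(tail[-1200:], head[:1200]))

    def test_below_min_identity_rejected(self, rng):
        shared = random_seq(rng, 300)
        mutated = "".join(
            c if rng.random() > 0.2 else {"A": "C", "C": "G", "G": "T", "T": "A"}[c] for c in shared
        )
        assert find_overlap(random_seq(rng, 500) + shared, mutated + random_seq(rng, 500)) is None


class TestDecideJoins:
    def _link(self, u, v, orient, d=(500, 500), n=5, span=5000):
        pairs = [(*orient, *d)] * n
        return {tuple(sorted((u, v))): [MatePairLink(*sorted((u, v)), library="mp", span=span, pairs=pairs)]}

    def test_simple_chain_with_reversal(self):
        # b must be reversed relative to a
        links = self._link("a", "b", ("+", "-"))
        plan = decide_joins(["a", "b"], links)
        assert len(plan.sequences) == 1
        assert plan.sequences[0].members == [("a", "+"), ("b", "-")]
        assert plan.sequences[0].joins[0].gap == 4000

    def test_no_evidence_no_joins(self):
        plan = decide_joins(["a", "b", "c"], {})
        assert all(len(s.joins) == 0 for s in plan.sequences)
        assert {c for s in plan.sequences for c, _ in s.members} == {"a", "b", "c"}
        assert len(plan.rejected) == 2

    def test_orientation_tie_rejected(self):
        key = ("a", "b")
        link = MatePairLink("a", "b", "mp", span=5000,
                            pairs=[("+", "+", 100, 100), ("-", "-", 100, 100)])
        plan = decide_joins(["a", "b"], {key: [link]})
        assert all(len(s.joins) == 0 for s in plan.sequences)
        assert any("tie" in r for r in plan.rejected)

    def test_negative_gap_triggers_overlap(self, rng):
        shared = random_seq(rng, 400)
        seqs = {"a": random_seq(rng, 2000) + shared, "b": shared + random_seq(rng, 2000)}

        def finder(u, ou, v, ov):
            return find_overlap(seqs[u][-1000:], seqs[v][:1000], contig_a=u, contig_b=v)

        links = self._link("a", "b", ("+", "+"), d=(2600, 2600))
        plan = decide_joins(["a", "b"], links, overlap_finder=finder)
        join = plan.sequences[0].joins[0]
        assert join.kind == "overlap"
        assert join.overlap.length == 400

    def test_simulated_scaffold_matches_truth(self, small_sim, tmp_path, rng):
        from ldscaffold.simpop import simulate_mate_links

        rows = simulate_mate_links(small_sim, span=5000, span_sd=250, pairs_per_junction=15, rng=rng)
        p = tmp_path / "links.tsv"
        p.write_text("\n".join(rows) + "\n")
        lengths = {c: small_sim.truth.contig_length(c) for c in small_sim.truth.placements}
        links = read_mate_links(p, library="mp", span=5000)
        resolve_link_distances(links, lengths)
        mate = {k: [v] for k, v in links.items()}

        per_chrom = {}
        for u, v, _ in small_sim.truth.adjacencies:
            chrom = small_sim.truth.placements[u][0]
            per_chrom.setdefault(chrom, [u]).append(v)
        fwd = {(u, v) for u, v, _ in small_sim.truth.adjacencies}
        for chrom, order in per_chrom.items():
            plan = decide_joins(order, mate, {}, group=chrom)
            assert len(plan.sequences) == 1
            seq = plan.sequences[0]
            assert len(seq.joins) == len(order) - 1
            for (u, ou), (v, ov) in zip(seq.members, seq.members[1:]):
                tou = small_sim.truth.placements[u][3]
                tov = small_sim.truth.placements[v][3]
                assert (u, v) in fwd
                assert (ou == tou) == (ov == tov)  # consistent frame
                assert ou == tou  # first contig anchors the true frame


class TestEmitScaffolds:
    def test_overlap_merge_length_arithmetic(self, rng):
        shared = random_seq(rng, 500)
        a = random_seq(rng, 9500) + shared
        b = shared + random_seq(rng, 9500)
        ov = OverlapCandidate("a", "b", length=500, identity=1.0, trim_b=500)
        plan = ScaffoldPlan(
            "g", [ScaffoldSequence("g_1", [("a", "+"), ("b", "+")],
                                  [Join("a", "b", "overlap", overlap=ov)])]
        )
        out = emit_scaffolds({"a": a, "b": b}, [plan])
        assert len(out["g_1"]) == 10_000 + 10_000 - 500 + 10

    def test_gap_join_length(self, rng):
        a, b = random_seq(rng, 3000), random_seq(rng, 4000)
        plan = ScaffoldPlan(
            "g", [ScaffoldSequence("g_1", [("a", "+"), ("b", "+")],
                                  [Join("a", "b", "gap", gap=2500)])]
        )
        out = emit_scaffolds({"a": a, "b": b}, [plan])
        assert len(out["g_1"]) == 3000 + 2500 + 4000

    def test_agp_fasta_roundtrip_revcomp_aware(self, tmp_path, rng):
        contigs = {f"c{i}": random_seq(rng, rng.integers(2000, 5000)) for i in range(4)}
        plan = ScaffoldPlan(
            "g",
            [
                ScaffoldSequence(
                    "g_1",
                    [("c0", "+"), ("c1", "-"), ("c2", "+")],
                    [Join("c0", "c1", "gap", gap=100), Join("c1", "c2", "gap", gap=50)],
                ),
                ScaffoldSequence("g_2", [("c3", "-")], []),
            ],
        )
        fa, agp = tmp_path / "s.fa", tmp_path / "s.agp"
        out = emit_scaffolds(contigs, [plan], out_fasta=fa, out_agp=agp)
        rows = read_agp(agp)
        for row in rows:
            if row["component_type"] != "W":
                continue
            piece = out[row["object"]][row["object_beg"] - 1 : row["object_end"]]
            if row["orientation"] == "-":
                piece = revcomp(piece)
            original = contigs[row["component_id"]][row["component_beg"] - 1 : row["component_end"]]
            assert piece == original
        # every contig is fully represented
        covered = {r["component_id"]: r["component_end"] - r["component_beg"] + 1
                   for r in rows if r["component_type"] == "W"}
        assert covered == {c: len(s) for c, s in contigs.items()}
        # FASTA on disk matches returned sequences
        from Bio import SeqIO

        on_disk = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fa), "fasta")}
        assert on_disk == out

    def test_trim_longer_than_contig_aborts(self, rng):
        ov = OverlapCandidate("a", "b", length=50, identity=1.0, trim_b=600)
        plan = ScaffoldPlan(
            "g", [ScaffoldSequence("g_1", [("a", "+"), ("b", "+")],
                                  [Join("a", "b", "overlap", overlap=ov)])]
        )
        with pytest.raises(ValueError, match="trim"):
            emit_scaffolds({"a": random_seq(rng, 1000), "b": random_seq(rng, 500)}, [plan])

    def test_non_n_output_conserved(self, rng):
        a, b = random_seq(rng, 3000), random_seq(rng, 4000)
        plan = ScaffoldPlan(
            "g", [ScaffoldSequence("g_1", [("a", "+"), ("b", "-")],
                                  [Join("a", "b", "gap", gap=777)])]
        )
        out = emit_scaffolds({"a": a, "b": b}, [plan])
        s = out["g_1"]
        assert len(s) - s.count("N") == 7000


class TestCoverageDrop:
    def test_flat_coverage_no_candidates(self):
        assert detect_coverage_drop(np.full(10_000, 60.0)) == []

    def test_low_region_detected(self):
        cov = np.full(10_000, 60.0)
        cov[4000:6000] = 5.0
        got = detect_coverage_drop(cov, window=1000, drop_ratio=0.25)
        assert len(got) == 1
        s, e = got[0]
        assert s <= 4000 and e >= 6000

    def test_zero_ratio_never_triggers(self):
        cov = np.full(10_000, 60.0)
        cov[4000:6000] = 0.0
        assert detect_coverage_drop(cov, drop_ratio=0.0) == []

    def test_empty_track(self):
        assert detect_coverage_drop([]) == []


class TestN50:
    def test_known_value(self):
        assert n50([2, 2, 2, 3, 3, 4, 8, 8]) == 8

    def test_empty(self):
        assert n50([]) == 0

    def test_single(self):
        assert n50([7]) == 7
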