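# ldscaffold

Haplotype-guided genome-assembly scaffolding from population resequencing
data.

Resequencing a few dozen individuals against a draft assembly yields, at
every variant position, a "variation pattern" — the succession of
genotype calls (hom-ref / het / hom-alt / missing) across the panel.
Shared haplotypes make these patterns continue across contig boundaries.
`ldscaffold` exploits this: it summarizes patterns into per-segment
*fingerprints*, scores fingerprint sharing between all segments with an
occurrence-normalized Jaccard score, lifts valid relations to a contig
graph, resolves unambiguous groups into linear contig orders, and
scaffolds them wherever physical evidence (mate-pair links, end-proximal
long-read alignments, contig-end overlaps) confirms the adjacency. A
fully seeded population/assembly simulator with ground truth makes the
whole pipeline testable offline.

## Pipeline CLI

```sh
# 1. sites: read a population VCF, apply the noise filters
ldscaffold filter --vcf pop.vcf.gz --maf 0.05 --min-called-frac 0.5 \
    --max-depth 300 --out sites.tsv

# 2. fingerprints: 100-kbp segments, patterns retained at >= 3 positions
ldscaffold fingerprint --sites sites.tsv --segment-size 100000 \
    --min-occ 3 --het-tol 0.10 --out fp.tsv

# 3. relations: prune widespread patterns (> 50 fingerprints),
#    all-vs-all comparison, validity at score >= 0.1
ldscaffold relate --fingerprints fp.tsv --min-score 0.1 \
    --max-prevalence 50 --out relations.tsv

# 4. groups: contig graph, connected components, linearization,
#    genetic-marker consistency, DOT export
ldscaffold group --relations relations.tsv --markers markers.tsv --out groups/

# 5. scaffolds: physical-evidence joins, FASTA + AGP v2.1
ldscaffold scaffold --fasta asm.fa --groups groups/groups.tsv \
    --links links_mp5000.tsv --span 5000 --paf reads.paf --out refout/
```

Utilities:

```sh
ldscaffold simulate --seed 42 --out sim/        # synthetic benchmark data
ldscaffold evaluate --relations relations.tsv --truth sim/truth.tsv
ldscaffold genome-size --peak 81.4 --read-length 89 --kmer 17 \
    --total-bases 121826911748                  # closed-form k-mer estimate
ldscaffold ld-decay --sites sites.tsv --out ld.tsv
```

## Key parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| segment size | 100 kbp | contigs shorter than this form a single segment |
| min occurrence | 3 | positions needed to retain a pattern in a fingerprint |
| het tolerance | 10% | het/missing mismatches allowed between similar patterns (5 of 50); homozygous conflicts are never allowed |
| rare fraction | 20% | below this many alt (or ref) carriers, no mismatch is allowed at those carriers |
| max prevalence | 50 | patterns recurring in more fingerprints are pruned |
| validity | 0.1 | minimum relation score |
| filters | — | biallelic SNPs; >= 50% called; >= 2 ref and >= 2 alt genotypes; total depth <= 300; MAF >= 0.05 |

## Layout

- `src/ldscaffold/popvar_io.py` — VCF ingestion, genotype codes, site filters
- `src/ldscaffold/fingerprint.py` — segmentation, pattern similarity, clustering
- `src/ldscaffold/relations.py` — pruning, matching, relation scoring
- `src/ldscaffold/grouping.py` — contig graph, groups, linearization, markers, DOT
- `src/ldscaffold/scaffold.py` — gap estimation, overlaps, joins, FASTA/AGP
- `src/ldscaffold/simpop.py` — simulator, recovery metrics, genome-size & LD utilities
- `src/ldscaffold/pipeline.py` — orchestration and the fixed-seed benchmark config
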