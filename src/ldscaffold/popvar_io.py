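"""Population-VCF ingestion and site-level noise filtering.

Genotype calls are reduced to four per-accession codes (hom-ref, het,
hom-alt, missing) kept in a fixed accession order. Filtering retains
"informative" biallelic SNP sites: enough called accessions, both alleles
seen in at least two accessions each, bounded total read depth, and a
minor-allele-frequency floor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Genotype",
    "AccessionPanel",
    "SiteRecord",
    "GenotypeMatrix",
    "SiteFilterConfig",
    "FilterReport",
    "FILTER_RULE_ORDER",
    "read_vcf",
    "filter_sites",
    "minor_allele_frequency",
    "write_sites_tsv",
    "read_sites_tsv",
]

_BASES = frozenset("ACGT")


class Genotype(enum.IntEnum):
    """Per-accession genotype code."""

    REF_HOM = 0
    HET = 1
    ALT_HOM = 2
    MISSING = 3


#: characters used when (de)serializing call vectors
_CODE_CHARS = {Genotype.REF_HOM: "0", Genotype.HET: "1", Genotype.ALT_HOM: "2", Genotype.MISSING: "."}
_CHAR_CODES = {v: int(k) for k, v in _CODE_CHARS.items()}


@dataclass(frozen=True)
class AccessionPanel:
    """Ordered, frozen list of accession identifiers.

    The order is fixed for a whole run: every call vector in every
    :class:`SiteRecord` indexes accessions in this order.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("accession panel must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("accession names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class SiteRecord:
    """One variant position with per-accession genotype codes.

    ``pos`` follows the VCF convention (1-based). ``calls`` is an int8
    vector of :class:`Genotype` values over the panel. ``depths`` and
    ``total_depth`` are optional; depth-based filters are skipped when
    they are absent.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    calls: np.ndarray
    depths: np.ndarray | None = None
    total_depth: int | None = None

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and self.ref_allele in _BASES and all(
            len(a) == 1 and a in _BASES for a in self.alt_alleles
        )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    def call_counts(self) -> np.ndarray:
        """Counts of [REF_HOM, HET, ALT_HOM, MISSING] over the panel."""
        return np.bincount(self.calls, minlength=4)


@dataclass
class GenotypeMatrix:
    """Per-contig ordered site records over a fixed accession panel."""

    panel: AccessionPanel
    sites: dict[str, list[SiteRecord]]
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for contig, recs in self.sites.items():
            if contig not in self.contig_lengths:
                raise ValueError(f"contig {contig!r} has sites but no length")
            positions = [r.pos for r in recs]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(f"sites on {contig!r} are not strictly increasing")

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())

    def iter_sites(self) -> Iterable[SiteRecord]:
        for contig in self.sites:
            yield from self.sites[contig]


@dataclass(frozen=True)
class SiteFilterConfig:
    """Thresholds for the site-level noise filter.

    All "at least"/"at most" bounds are inclusive. ``max_missing_fraction``
    is an optional stricter override of the missingness rule (the pipeline
    default keeps sites with >= 50% called accessions; stricter runs may
    additionally require e.g. < 10% missing genotypes).
    """

    min_called_fraction: float = 0.5
    min_ref_genotypes: int = 2
    min_alt_genotypes: int = 2
    maf_min: float = 0.05
    max_total_depth: int = 300
    min_depth_per_called_accession: int = 1
    biallelic_snp_only: bool = True
    max_missing_fraction: float | None = None

    def __post_init__(self) -> None:
        for name in ("min_called_fraction", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.max_missing_fraction is not None and not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        for name in ("min_ref_genotypes", "min_alt_genotypes", "max_total_depth", "min_depth_per_called_accession"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: fixed first-failing-rule attribution order (cheap checks first)
FILTER_RULE_ORDER = (
    "not_snp",
    "not_biallelic",
    "missingness",
    "depth",
    "genotype_counts",
    "maf",
)


@dataclass
class FilterReport:
    """Removal counts partitioned by the first failing rule."""

    n_input: int = 0
    n_output: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in FILTER_RULE_ORDER})
    depth_rules_applied: bool = True

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def to_text(self) -> str:
        lines = [f"sites_in\t{self.n_input}", f"sites_out\t{self.n_output}"]
        for rule in FILTER_RULE_ORDER:
            lines.append(f"removed_{rule}\t{self.removed[rule]}")
        lines.append(f"depth_rules_applied\t{'yes' if self.depth_rules_applied else 'no'}")
        return "\n".join(lines) + "\n"


def _map_genotype(alleles: Sequence[int]) -> int:
    """Map a pair of VCF allele indices (-1 = missing) to a Genotype."""
    a, b = alleles[0], alleles[1]
    if a < 0 or b < 0:
        return int(Genotype.MISSING)
    if a == 0 and b == 0:
        return int(Genotype.REF_HOM)
    if a == 0 or b == 0:
        return int(Genotype.HET)
    return int(Genotype.ALT_HOM)


def read_vcf(
    path: str | Path,
    panel_subset: Sequence[str] | None = None,
    fai: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Genotypes are mapped 0/0 -> REF_HOM, 0/1 or 1/0 -> HET, 1/1 ->
    ALT_HOM, ./. -> MISSING; any non-zero/non-zero pair of a multiallelic
    record maps to ALT_HOM (such records are dropped later by the
    biallelic filter). Contig lengths come from ``##contig`` header lines
    or, failing that, a companion FASTA ``.fai`` index.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    panel_subset
        Optional accession names to keep, in this order.
    fai
        Optional FASTA index supplying contig lengths.
    """
    from cyvcf2 import VCF

    path = str(path)
    probe = VCF(path)
    if "##FORMAT=<ID=GT" not in probe.raw_header:
        probe.close()
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    all_samples = list(probe.samples)
    probe.close()

    if panel_subset is not None:
        missing = [s for s in panel_subset if s not in all_samples]
        if missing:
            raise ValueError(f"requested accession(s) absent from VCF: {', '.join(missing)}")
        vcf = VCF(path, samples=list(panel_subset))
        # cyvcf2 returns samples in file order; re-order columns afterwards
        file_order = list(vcf.samples)
        panel = AccessionPanel(tuple(panel_subset))
        col_of = np.array([file_order.index(s) for s in panel_subset])
    else:
        vcf = VCF(path)
        panel = AccessionPanel(tuple(all_samples))
        col_of = None

    contig_lengths: dict[str, int] = {}
    if vcf.seqlens:
        contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    if fai is not None:
        with open(fai) as fh:
            for line in fh:
                parts = line.split("\t")
                contig_lengths[parts[0]] = int(parts[1])

    sites: dict[str, list[SiteRecord]] = {}
    for var in vcf:
        calls = np.fromiter(
            (_map_genotype(g) for g in var.genotypes), dtype=np.int8, count=len(var.genotypes)
        )
        depths = None
        try:
            dp = var.format("DP")
        except KeyError:  # DP not declared in the header
            dp = None
        if dp is not None:
            depths = dp[:, 0].astype(np.int64)
            depths[depths < 0] = 0
        if col_of is not None:
            calls = calls[col_of]
            if depths is not None:
                depths = depths[col_of]
        total = var.INFO.get("DP")
        if total is None and depths is not None:
            total = int(depths.sum())
        rec = SiteRecord(
            contig=var.CHROM,
            pos=var.POS,
            ref_allele=var.REF,
            alt_alleles=tuple(var.ALT),
            calls=calls,
            depths=depths,
            total_depth=None if total is None else int(total),
        )
        sites.setdefault(var.CHROM, []).append(rec)
    vcf.close()

    for contig in sites:
        if contig not in contig_lengths:
            raise ValueError(
                f"no length available for contig {contig!r}; add ##contig headers or pass a .fai"
            )
    return GenotypeMatrix(panel=panel, sites=sites, contig_lengths=contig_lengths)


def minor_allele_frequency(site: SiteRecord) -> float | None:
    """MAF of a biallelic site from genotype codes.

    Alt allele count is ``2 * ALT_HOM + HET`` over ``2 * called``.
    Returns ``None`` when no accession is called (the site is then
    treated as filtered).
    """
    counts = site.call_counts()
    called = int(counts[Genotype.REF_HOM] + counts[Genotype.HET] + counts[Genotype.ALT_HOM])
    if called == 0:
        return None
    alt_freq = (2 * int(counts[Genotype.ALT_HOM]) + int(counts[Genotype.HET])) / (2 * called)
    return min(alt_freq, 1.0 - alt_freq)


def _first_failing_rule(site: SiteRecord, cfg: SiteFilterConfig, n: int) -> str | None:
    if cfg.biallelic_snp_only and not site.is_snp:
        return "not_snp"
    if cfg.biallelic_snp_only and not site.is_biallelic:
        return "not_biallelic"
    counts = site.call_counts()
    n_missing = int(counts[Genotype.MISSING])
    called_frac = (n - n_missing) / n
    if called_frac < cfg.min_called_fraction:
        return "missingness"
    if cfg.max_missing_fraction is not None and n_missing / n > cfg.max_missing_fraction:
        return "missingness"
    if site.total_depth is not None and site.total_depth > cfg.max_total_depth:
        return "depth"
    if site.depths is not None:
        covered = int((site.depths >= cfg.min_depth_per_called_accession).sum())
        if covered / n < cfg.min_called_fraction:
            return "depth"
    ref_carrying = int(counts[Genotype.REF_HOM] + counts[Genotype.HET])
    alt_carrying = int(counts[Genotype.ALT_HOM] + counts[Genotype.HET])
    if ref_carrying < cfg.min_ref_genotypes or alt_carrying < cfg.min_alt_genotypes:
        return "genotype_counts"
    maf = minor_allele_frequency(site)
    if maf is None or maf < cfg.maf_min:
        return "maf"
    return None


def filter_sites(
    matrix: GenotypeMatrix, cfg: SiteFilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply all site-level noise filters; never reorders sites.

    Removals are attributed to the first failing rule in
    :data:`FILTER_RULE_ORDER`. Depth rules only apply to sites that carry
    depth information; the report notes whether any site did.
    """
    if cfg is None:
        cfg = SiteFilterConfig()
    n = len(matrix.panel)
    report = FilterReport(n_input=matrix.n_sites)
    any_depth = False
    kept: dict[str, list[SiteRecord]] = {}
    for contig, recs in matrix.sites.items():
        out: list[SiteRecord] = []
        for site in recs:
            if site.total_depth is not None or site.depths is not None:
                any_depth = True
            rule = _first_failing_rule(site, cfg, n)
            if rule is None:
                out.append(site)
            else:
                report.removed[rule] += 1
        if out:
            kept[contig] = out
    report.depth_rules_applied = any_depth
    report.n_output = sum(len(v) for v in kept.values())
    filtered = GenotypeMatrix(panel=matrix.panel, sites=kept, contig_lengths=dict(matrix.contig_lengths))
    return filtered, report


def calls_to_string(calls: np.ndarray) -> str:
    return "".join(_CODE_CHARS[Genotype(int(c))] for c in calls)


def calls_from_string(s: str) -> np.ndarray:
    return np.fromiter((_CHAR_CODES[c] for c in s), dtype=np.int8, count=len(s))


def write_sites_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Serialize a genotype matrix to the filtered-sites TSV format.

    Header carries the accession order and contig lengths so the matrix
    round-trips without the original VCF.
    """
    with open(path, "w") as fh:
        fh.write("##accessions=" + ",".join(matrix.panel.names) + "\n")
        for contig, length in matrix.contig_lengths.items():
            fh.write(f"##contig={contig}:{length}\n")
        fh.write("#contig\tpos\tref\talt\tcalls\n")
        for site in matrix.iter_sites():
            alt = ",".join(site.alt_alleles)
            fh.write(
                f"{site.contig}\t{site.pos}\t{site.ref_allele}\t{alt}\t{calls_to_string(site.calls)}\n"
            )


def read_sites_tsv(path: str | Path) -> GenotypeMatrix:
    """Read back a TSV written by :func:`write_sites_tsv`."""
    panel: AccessionPanel | None = None
    contig_lengths: dict[str, int] = {}
    sites: dict[str, list[SiteRecord]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##accessions="):
                panel = AccessionPanel(tuple(line.split("=", 1)[1].split(",")))
                continue
            if line.startswith("##contig="):
                name, length = line.split("=", 1)[1].rsplit(":", 1)
                contig_lengths[name] = int(length)
                continue
            if line.startswith("#") or not line:
                continue
            contig, pos, ref, alt, calls = line.split("\t")
            sites.setdefault(contig, []).append(
                SiteRecord(
                    contig=contig,
                    pos=int(pos),
                    ref_allele=ref,
                    alt_alleles=tuple(alt.split(",")) if alt else (),
                    calls=calls_from_string(calls),
                )
            )
    if panel is None:
        raise ValueError(f"{path}: missing ##accessions header")
    return GenotypeMatrix(panel=panel, sites=sites, contig_lengths=contig_lengths)
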