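"""Genomic feature overlap enrichment for differential regions.

Differential regions (split by direction of change) are intersected with a
catalogue of feature interval sets — CpG islands, gene bodies, exons,
introns, strand-aware 3 kb promoters, 1 bp TSSs and the non-genic
complement — and summarized as 2x2 contingency tables. Enrichment is
reported as the log2 conditional-maximum-likelihood odds ratio with an
exact conditional 95% CI and a two-sided Fisher exact p value; a Woolf
normal-approximation CI is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .intervals import (GeneModel, GenomicInterval, any_overlap, build_tree,
                        complement, merge_intervals)

FEATURE_ORDER = ["CGI", "gene_body", "non_genic", "intron", "exon", "promoter", "TSS"]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of regions overlapping (OL) / not overlapping a feature, by direction."""

    up_ol: int
    up_nol: int
    down_ol: int
    down_nol: int

    def as_array(self) -> np.ndarray:
        return np.array([[self.up_ol, self.up_nol], [self.down_ol, self.down_nol]])


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    table: ContingencyTable
    log2_or: float
    ci_low: float
    ci_high: float
    p: float


class FeatureCatalog:
    """Named feature interval sets derived from gene models and CGIs.

    Features may overlap one another (an exon is also gene body). The
    promoter is the strand-aware 3 kb upstream of the TSS; the TSS is a
    1 bp interval; introns are gene body minus exons; non-genic is the
    complement of gene bodies union promoters (switchable to gene bodies
    only).
    """

    def __init__(self, genes: list[GeneModel], cgis: list[GenomicInterval],
                 chrom_lengths: dict[str, int], promoter_upstream: int = 3000,
                 nongenic_excludes_promoters: bool = True):
        self.genes = list(genes)
        self.chrom_lengths = dict(chrom_lengths)
        bodies = [g.body for g in genes]
        promoters = [g.promoter(promoter_upstream, chrom_lengths.get(g.chrom))
                     for g in genes]
        exons = [GenomicInterval(g.chrom, s, e) for g in genes for s, e in g.exons]
        introns = [iv for g in genes for iv in g.introns()]
        tss = [g.tss_interval() for g in genes]
        genic = bodies + promoters if nongenic_excludes_promoters else bodies
        self.features: dict[str, list[GenomicInterval]] = {
            "CGI": list(cgis),
            "gene_body": bodies,
            "non_genic": complement(genic, chrom_lengths),
            "intron": introns,
            "exon": exons,
            "promoter": promoters,
            "TSS": tss,
        }
        self._trees = {name: build_tree(ivs) for name, ivs in self.features.items()}
        # per-gene feature instances, for gene-set construction
        self.per_gene: dict[str, dict[str, list[GenomicInterval]]] = {
            g.name: {
                "gene_body": [g.body],
                "TSS": [g.tss_interval()],
                "promoter": [g.promoter(promoter_upstream, chrom_lengths.get(g.chrom))],
                "exon": [GenomicInterval(g.chrom, s, e) for s, e in g.exons],
                "intron": g.introns(),
            }
            for g in genes
        }

    def genome_fraction(self, feature: str) -> float:
        merged = merge_intervals(self.features[feature])
        return sum(iv.length for iv in merged) / sum(self.chrom_lengths.values())

    def overlaps(self, iv: GenomicInterval, feature: str) -> bool:
        return any_overlap(iv, self._trees[feature])


def classify_overlap(regions: list[GenomicInterval],
                     feature_intervals: list[GenomicInterval],
                     ) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition regions into (overlapping, non-overlapping) a feature set.

    Overlap means an intersection of at least 1 bp; book-ended intervals do
    not overlap under half-open coordinates.
    """
    trees = build_tree(feature_intervals)
    ol = [r for r in regions if any_overlap(r, trees)]
    nol = [r for r in regions if not any_overlap(r, trees)]
    return ol, nol


def build_contingency(hyper_regions: list[GenomicInterval],
                      hypo_regions: list[GenomicInterval],
                      feature_intervals: list[GenomicInterval]) -> ContingencyTable:
    """2x2 table of hyper/hypo regions overlapping / not overlapping a feature."""
    if not hyper_regions or not hypo_regions:
        raise ValueError("both hyper and hypo region sets must be nonempty")
    up_ol, up_nol = classify_overlap(hyper_regions, feature_intervals)
    dn_ol, dn_nol = classify_overlap(hypo_regions, feature_intervals)
    return ContingencyTable(len(up_ol), len(up_nol), len(dn_ol), len(dn_nol))


def fisher_exact_two_sided(table: ContingencyTable | np.ndarray) -> float:
    """Two-sided Fisher exact p (hypergeometric, conditioned on margins).

    Returns 1 by convention when any margin is zero.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table)
    if (arr < 0).any():
        raise ValueError("contingency counts must be nonnegative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def log2_odds_ratio_ci(table: ContingencyTable | np.ndarray, alpha: float = 0.05,
                       method: str = "conditional") -> tuple[float, float, float]:
    """Log2 odds ratio with a 95% (or 1-alpha) confidence interval.

    method "conditional": point estimate is the conditional maximum-
    likelihood odds ratio with the exact conditional interval (matches
    asymmetric published CIs). method "woolf": sample odds ratio with the
    normal-approximation interval. When a cell is zero the point estimate
    uses the Haldane-Anscombe 0.5 correction on all cells.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table)
    a, b = arr[0]
    c, d = arr[1]
    if (a == 0 and b == 0) or (c == 0 and d == 0) or \
       (a == 0 and c == 0) or (b == 0 and d == 0):
        raise ValueError("a zero margin leaves the odds ratio undefined")
    zero_cell = (arr == 0).any()
    if method == "woolf":
        aa, bb, cc, dd = (arr + 0.5).ravel() if zero_cell else arr.ravel().astype(float)
        log2_or = float(np.log2(aa * dd / (bb * cc)))
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd) / np.log(2)
        z = stats.norm.ppf(1 - alpha / 2)
        return log2_or, log2_or - z * se, log2_or + z * se
    if method != "conditional":
        raise ValueError(f"unknown CI method {method!r}")
    res = _odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(1 - alpha)
    if zero_cell:
        aa, bb, cc, dd = (arr + 0.5).ravel()
        point = float(np.log2(aa * dd / (bb * cc)))
    else:
        point = float(np.log2(res.statistic))
    with np.errstate(divide="ignore"):
        lo = float(np.log2(ci.low)) if ci.low > 0 else -np.inf
        hi = float(np.log2(ci.high)) if np.isfinite(ci.high) else np.inf
    return point, lo, hi


def enrichment_from_table(feature: str, table: ContingencyTable,
                          method: str = "conditional") -> EnrichmentResult:
    log2_or, lo, hi = log2_odds_ratio_ci(table, method=method)
    return EnrichmentResult(feature, table, log2_or, lo, hi,
                            fisher_exact_two_sided(table))


def feature_enrichment_table(hyper_regions: list[GenomicInterval],
                             hypo_regions: list[GenomicInterval],
                             catalog: FeatureCatalog,
                             method: str = "conditional") -> list[EnrichmentResult]:
    """Hyper-vs-hypo enrichment across every catalogue feature."""
    out = []
    for feature in FEATURE_ORDER:
        table = build_contingency(hyper_regions, hypo_regions,
                                  catalog.features[feature])
        out.append(enrichment_from_table(feature, table, method=method))
    return out


def background_frequency_enrichment(diff_regions: list[GenomicInterval],
                                    nondiff_regions: list[GenomicInterval],
                                    feature_intervals: list[GenomicInterval],
                                    feature: str = "",
                                    method: str = "conditional") -> EnrichmentResult:
    """Enrichment of one direction of change against a non-differential background.

    The background is the set of tested regions that showed no evidence of
    change (-log10 p below 0.25 in the reference workflow). Overlap
    frequency of the differential direction is compared to the background
    frequency as a 2x2 table.
    """
    if not nondiff_regions:
        raise ValueError("empty non-differential background")
    if not diff_regions:
        raise ValueError("no regions in this direction of change")
    d_ol, d_nol = classify_overlap(diff_regions, feature_intervals)
    b_ol, b_nol = classify_overlap(nondiff_regions, feature_intervals)
    table = ContingencyTable(len(d_ol), len(d_nol), len(b_ol), len(b_nol))
    return enrichment_from_table(feature, table, method=method)
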