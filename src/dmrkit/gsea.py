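"""Preranked gene-set enrichment analysis (GSEA).

Genes are ranked by -log10(p) x sign(log fold change) from the expression
differential test, so upregulated genes carry positive scores. Gene sets
are built from feature-overlapping differentially methylated regions
(feature x direction) or from TF ChIP intervals intersected with
promoters. The enrichment score is the standard weighted Kolmogorov-
Smirnov running-sum statistic; significance comes from gene-set
permutation: size-matched random draws from the ranked universe, with
sign-matched normalization (NES), nominal p and pooled-null FDR q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import FeatureCatalog
from .intervals import GenomicInterval, build_tree, any_overlap

MAX_NEGLOG10_P = 320.0
GENE_SET_FEATURES = ["gene_body", "TSS", "promoter", "exon", "intron"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


# ------------------------------------------------------------------ ranking

def rank_scores(differential: pd.DataFrame, max_score: float = MAX_NEGLOG10_P) -> pd.Series:
    """Rank scores -log10(p) x sign(logFC), ordered descending.

    Ties break deterministically by gene id (ascending). A p of zero is
    capped at ``max_score`` with a warning; a zero logFC gives score 0.
    """
    p = differential["p"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    if (p == 0).any():
        warnings.warn(f"p = 0 capped at -log10 p = {max_score}", stacklevel=2)
    neglog = np.where(p > 0, -np.log10(np.maximum(p, 10.0 ** -max_score)), max_score)
    neglog = np.minimum(neglog, max_score)
    scores = pd.Series(neglog * np.sign(differential["logFC"].to_numpy()),
                       index=differential.index, name="rank_score")
    order = sorted(scores.index, key=lambda g: (-scores[g], str(g)))
    return scores.loc[order]


# ------------------------------------------------------------------ gene sets

def build_methylation_gene_sets(dmr_table: pd.DataFrame, catalog: FeatureCatalog,
                                p_cut: float = 0.01) -> list[GeneSet]:
    """Gene sets from feature-overlapping differentially methylated regions.

    ``dmr_table`` needs columns chrom, start, end, logFC, p. Regions with
    p < ``p_cut`` are split by direction of change; a gene joins the set
    (feature, direction) when that feature instance of the gene shares
    >= 1 bp with a qualifying region. Up to 10 sets (5 features x 2
    directions); empty sets are dropped with a warning.
    """
    qual = dmr_table[dmr_table["p"] < p_cut]
    trees = {}
    for direction, sub in (("increased", qual[qual["logFC"] > 0]),
                           ("decreased", qual[qual["logFC"] < 0])):
        trees[direction] = build_tree(
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in sub.itertuples(index=False))
    members: dict[tuple[str, str], set[str]] = {
        (f, d): set() for f in GENE_SET_FEATURES for d in ("increased", "decreased")}
    for gene, feats in catalog.per_gene.items():
        for feature in GENE_SET_FEATURES:
            for direction in ("increased", "decreased"):
                if any(any_overlap(iv, trees[direction]) for iv in feats[feature]):
                    members[(feature, direction)].add(gene)
    sets = []
    for (feature, direction), genes in members.items():
        name = f"{feature}_{direction}_methylation"
        if not genes:
            warnings.warn(f"gene set {name!r} is empty; dropped", stacklevel=2)
            continue
        sets.append(GeneSet(name, frozenset(genes), provenance=f"{feature}|{direction}"))
    return sets


def build_promoter_tf_gene_sets(chip_intervals_by_tf: dict[str, list[GenomicInterval]],
                                catalog: FeatureCatalog,
                                ortholog_map: dict[str, str] | None = None,
                                min_size: int = 15, max_size: int = 500) -> list[GeneSet]:
    """One gene set per TF/cell-line track: genes whose promoter overlaps a peak.

    ``ortholog_map`` translates annotation gene ids into ranked-list ids
    (e.g. across species); unmapped genes are dropped with a logged count.
    Sets outside [min_size, max_size] are excluded.
    """
    sets = []
    dropped_unmapped = 0
    for tf, peaks in chip_intervals_by_tf.items():
        trees = build_tree(peaks)
        hit = set()
        for gene, feats in catalog.per_gene.items():
            if any(any_overlap(iv, trees) for iv in feats["promoter"]):
                if ortholog_map is not None:
                    if gene in ortholog_map:
                        hit.add(ortholog_map[gene])
                    else:
                        dropped_unmapped += 1
                else:
                    hit.add(gene)
        if min_size <= len(hit) <= max_size:
            sets.append(GeneSet(tf, frozenset(hit), provenance=f"TF|{tf}"))
    if dropped_unmapped:
        warnings.warn(f"{dropped_unmapped} gene hits without ortholog mapping dropped",
                      stacklevel=2)
    return sets


# ------------------------------------------------------------------ ES

def enrichment_score(ranked: pd.Series, gene_set: "GeneSet | set[str]",
                     weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the running-sum profile.

    Hits increment the running sum by |score|^weight normalized to the
    set's total; misses decrement by 1/(N - Nh). ES is the signed maximum
    deviation from zero. The set must intersect the universe and not cover
    it entirely.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else set(gene_set)
    is_hit = ranked.index.isin(members)
    n, nh = len(ranked), int(is_hit.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if nh == n:
        raise ValueError("gene set covers the entire universe; ES undefined")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores zero: fall back to unweighted hits
        hit_w = is_hit.astype(float)
        denom = hit_w.sum()
    running = np.cumsum(hit_w / denom - (~is_hit) / (n - nh))
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _es_only(scores: np.ndarray, is_hit: np.ndarray, weight: float) -> float:
    n = scores.size
    nh = int(is_hit.sum())
    w = np.abs(scores) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = is_hit.astype(float)
        denom = float(nh)
    running = np.cumsum(hit_w / denom - (~is_hit) / (n - nh))
    return float(running[np.argmax(np.abs(running))])


# ------------------------------------------------------------------ model API

class PrerankedGSEA:
    """Preranked GSEA with gene-set permutation.

    Parameters
    ----------
    ranked : Series
        Gene id -> rank score, ordered descending (see :func:`rank_scores`).
    gene_sets : list of GeneSet
        Sets are restricted to the ranked universe before testing.
    weight : float
        Exponent on |score| for hit increments (1 = classic weighted ES).
    """

    def __init__(self, ranked: pd.Series, gene_sets: list[GeneSet],
                 weight: float = 1.0):
        if ranked.index.duplicated().any():
            raise ValueError("duplicate gene ids in ranked list")
        if not np.isfinite(ranked.to_numpy(dtype=float)).all():
            raise ValueError("rank scores must be finite")
        self.ranked = ranked
        self.gene_sets = list(gene_sets)
        self.weight = weight

    def fit(self, n_perm: int = 1000, seed: int = 0) -> "GseaResults":
        """Run the permutation test; deterministic for a fixed seed."""
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        scores = self.ranked.to_numpy(dtype=float)
        n = scores.size
        universe = self.ranked.index
        rows = []
        null_nes_pool: list[np.ndarray] = []
        obs_nes = []
        for gs in self.gene_sets:
            is_hit = universe.isin(gs.members)
            nh = int(is_hit.sum())
            if nh == 0 or nh == n:
                warnings.warn(f"set {gs.name!r} skipped (size {nh} in universe)",
                              stacklevel=2)
                continue
            es, _ = enrichment_score(self.ranked, gs, self.weight)
            null = np.empty(n_perm)
            for k in range(n_perm):
                idx = rng.choice(n, size=nh, replace=False)
                hit = np.zeros(n, dtype=bool)
                hit[idx] = True
                null[k] = _es_only(scores, hit, self.weight)
            pos, neg = null[null >= 0], null[null < 0]
            if es >= 0:
                mean_same = pos.mean() if pos.size else np.nan
                nominal_p = ((pos >= es).sum() + 1) / (pos.size + 1) if pos.size else 1.0
            else:
                mean_same = -neg.mean() if neg.size else np.nan
                nominal_p = ((neg <= es).sum() + 1) / (neg.size + 1) if neg.size else 1.0
            nes = es / mean_same if np.isfinite(mean_same) and mean_same > 0 else np.nan
            null_nes = np.concatenate([
                pos / pos.mean() if pos.size else pos,
                -(neg / neg.mean()) if neg.size else neg,
            ])
            null_nes_pool.append(null_nes)
            obs_nes.append(nes)
            rows.append({"set": gs.name, "size": nh, "es": es, "nes": nes,
                         "nominal_p": float(nominal_p)})
        table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
            columns=["size", "es", "nes", "nominal_p"])
        if rows:
            pooled = np.concatenate(null_nes_pool)
            obs = np.asarray(obs_nes, dtype=float)
            q = np.ones(len(obs))
            for i, nes in enumerate(obs):
                if not np.isfinite(nes):
                    continue
                if nes >= 0:
                    frac_null = (pooled >= nes).mean() if pooled.size else 1.0
                    frac_obs = (obs[np.isfinite(obs)] >= nes).mean()
                else:
                    frac_null = (pooled <= nes).mean() if pooled.size else 1.0
                    frac_obs = (obs[np.isfinite(obs)] <= nes).mean()
                q[i] = min(1.0, frac_null / max(frac_obs, 1e-12))
            table["fdr_q"] = q
        return GseaResults(self, table)


class GseaResults:
    """GSEA results: per-set ES, NES, nominal p and FDR q."""

    def __init__(self, model: PrerankedGSEA, table: pd.DataFrame):
        self.model = model
        self.table = table

    def significant(self, fdr_cutoff: float = 0.25) -> pd.DataFrame:
        return self.table[self.table["fdr_q"] < fdr_cutoff]

    def summary(self) -> str:
        t = self.table.sort_values("fdr_q")
        return ("Preranked GSEA (gene-set permutation)\n"
                f"  sets tested: {len(t)}   FDR q < 0.25: "
                f"{(t['fdr_q'] < 0.25).sum()}\n\n"
                + t.to_string(float_format=lambda x: f"{x:.3g}"))


def gsea_preranked(ranked: pd.Series, gene_sets: list[GeneSet],
                   n_perm: int = 1000, seed: int = 0,
                   weight: float = 1.0) -> pd.DataFrame:
    """Functional wrapper around :class:`PrerankedGSEA`."""
    return PrerankedGSEA(ranked, gene_sets, weight=weight).fit(n_perm, seed).table
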