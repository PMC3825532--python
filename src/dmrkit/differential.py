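"""Differential tag abundance for count matrices.

The statistical core is a re-implementation of the classic two-group
negative-binomial workflow for sequencing count data: trimmed-mean (TMM)
library normalization, common dispersion by maximizing the conditional NB
likelihood pooled over rows, tagwise dispersions shrunk toward the common
value by weighted likelihood (prior weight ``prior_df``), and an exact
two-sided test on the conditional distribution of the case-group sum given
the row total at equalized library sizes. P values are adjusted with the
Benjamini-Hochberg step-up procedure.

Library equalization scales each sample's counts to the median effective
library size (library size x TMM factor) and rounds; this makes the test
exactly invariant to rescaling any one sample's counts.

The model-object interface mirrors the statsmodels idiom::

    model = DifferentialAbundanceModel(counts, groups, case="PILO", control="CTRL")
    res = model.fit()
    res.table          # id, logFC, p, fdr
    res.summary()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval
from .regions import DEFAULT_SHIFT, shift_positions

DEFAULT_PRIOR_DF = 10.0
DEFAULT_PRIOR_COUNT = 0.125


# ------------------------------------------------------------------ counting

def count_tags_per_region(regions: list[GenomicInterval], tags: pd.DataFrame,
                          shift: int = DEFAULT_SHIFT,
                          chrom_lengths: dict[str, int] | None = None,
                          samples: list[str] | None = None) -> pd.DataFrame:
    """Count tags per region per sample.

    A tag is assigned to a region when its shifted position lies in
    [start, end). Regions must be disjoint (run them through
    :func:`~dmrkit.intervals.merge_intervals` first); overlap is an error
    because assignment would be ambiguous.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(regions):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs[:-1], ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping regions on {chrom}: ambiguous assignment")
    samples = samples or sorted(tags["sample"].unique())
    ids = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions]
    out = pd.DataFrame(0, index=ids, columns=samples)
    shifted = shift_positions(tags, shift, chrom_lengths)
    for (chrom, sample), grp in shifted.groupby(["chrom", "sample"]):
        ivs = by_chrom.get(chrom)
        if not ivs:
            continue
        pos = np.sort(grp["pos"].to_numpy())
        for s, e, i in ivs:
            n = np.searchsorted(pos, e, "left") - np.searchsorted(pos, s, "left")
            if n:
                out.iloc[i, out.columns.get_loc(sample)] += int(n)
    return out


def centile_filter(matrix: pd.DataFrame, centile: float) -> pd.DataFrame:
    """Drop rows whose count sum falls below the given empirical centile.

    The threshold is the linear-interpolation percentile of the row sums;
    rows strictly below it are removed, ties at the threshold retained.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty count matrix")
    if not 0 <= centile <= 100:
        raise ValueError("centile must be in [0, 100]")
    sums = matrix.sum(axis=1).to_numpy()
    threshold = np.percentile(sums, centile)
    return matrix.loc[sums >= threshold]


# ------------------------------------------------------------------ TMM

def tmm_factors(matrix: pd.DataFrame, logratio_trim: float = 0.30,
                abs_trim: float = 0.05,
                lib_size: pd.Series | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the column whose upper quartile of relative
    counts is closest to the mean upper quartile. Per sample, the factor is
    2^(precision-weighted doubly-trimmed mean of per-row log2 ratios versus
    the reference); factors are rescaled to multiply to 1. The effective
    library size of sample j is ``lib_size[j] * factor[j]``.
    """
    counts = matrix.to_numpy(dtype=float)
    lib = (lib_size.reindex(matrix.columns).to_numpy(dtype=float)
           if lib_size is not None else counts.sum(axis=0))
    if (lib == 0).any():
        bad = matrix.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    uq = np.array([np.percentile(counts[counts[:, j] > 0, j] / lib[j], 75)
                   if (counts[:, j] > 0).any() else 0.0
                   for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    yr, nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        yj, nj = counts[:, j], lib[j]
        keep = (yj > 0) & (yr > 0)
        if keep.sum() == 0:
            continue
        m = np.log2((yj[keep] / nj) / (yr[keep] / nr))
        a = 0.5 * np.log2((yj[keep] / nj) * (yr[keep] / nr))
        v = (nj - yj[keep]) / (nj * yj[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        n = m.size
        lo_l = int(np.floor(n * logratio_trim)) + 1
        hi_l = n + 1 - lo_l
        lo_s = int(np.floor(n * abs_trim)) + 1
        hi_s = n + 1 - lo_s
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        sel = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
        if sel.any() and np.isfinite(v[sel]).all() and (v[sel] > 0).all():
            f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
        else:
            f = np.median(m) if n else 0.0
        factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns, name="tmm_factor")


# ------------------------------------------------------------------ dispersion

@dataclass(frozen=True)
class DispersionEstimate:
    common: float
    tagwise: np.ndarray  # aligned with matrix rows
    prior_df: float


def _pseudo_counts(matrix: pd.DataFrame, norm_factors: pd.Series,
                   lib_size: pd.Series | None = None) -> pd.DataFrame:
    """Counts rescaled to the median effective library size and rounded."""
    lib = lib_size.reindex(matrix.columns) if lib_size is not None \
        else matrix.sum(axis=0)
    lib_eff = lib * norm_factors.reindex(matrix.columns)
    common = float(np.median(lib_eff))
    scaled = matrix.to_numpy(dtype=float) * (common / lib_eff.to_numpy())
    return pd.DataFrame(np.rint(scaled).astype(np.int64),
                        index=matrix.index, columns=matrix.columns)


def _group_arrays(matrix: pd.DataFrame, groups: pd.Series) -> list[np.ndarray]:
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        missing = matrix.columns[groups.isna()][0]
        raise ValueError(f"sample {missing!r} has no group label")
    return [matrix.loc[:, groups == g].to_numpy(dtype=float)
            for g in groups.unique()]


def _cond_loglik_rows(group_arrays: list[np.ndarray], phi: float) -> np.ndarray:
    """Per-row conditional NB log-likelihood at equal library sizes.

    For a group with counts y_1..y_n summing to z the likelihood of the
    counts conditional on z is free of the mean and depends on phi only:
    sum_i lgamma(y_i + r) - n lgamma(r) + lgamma(n r) - lgamma(z + n r),
    with r = 1/phi. Single-sample groups contribute nothing.
    """
    r = 1.0 / max(phi, 1e-12)
    total = np.zeros(group_arrays[0].shape[0])
    for y in group_arrays:
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        total += (gammaln(y + r).sum(axis=1) - n * gammaln(r)
                  + gammaln(n * r) - gammaln(z + n * r))
    return total


def estimate_dispersions(matrix: pd.DataFrame, groups: pd.Series,
                         norm_factors: pd.Series | None = None,
                         prior_df: float = DEFAULT_PRIOR_DF,
                         lib_size: pd.Series | None = None) -> DispersionEstimate:
    """Common and shrunken tagwise NB dispersions.

    The common dispersion maximizes the conditional likelihood pooled over
    rows (counts equalized to a common library size first); each tagwise
    dispersion maximizes the row's conditional likelihood plus ``prior_df``
    times the per-row average likelihood, shrinking single-row estimates
    toward the common value. Requires at least one group with >= 2 samples.
    """
    groups = groups.reindex(matrix.columns)
    if not any((groups == g).sum() >= 2 for g in groups.unique()):
        raise ValueError(
            "no residual degrees of freedom: every group has a single sample; "
            "supply a fixed dispersion instead")
    if norm_factors is None:
        norm_factors = tmm_factors(matrix, lib_size=lib_size)
    pseudo = _pseudo_counts(matrix, norm_factors, lib_size)
    arrays = _group_arrays(pseudo, groups)

    def neg_total(log10_phi: float) -> float:
        return -float(_cond_loglik_rows(arrays, 10.0 ** log10_phi).sum())

    res = optimize.minimize_scalar(neg_total, bounds=(-8.0, 2.0), method="bounded")
    common = float(10.0 ** res.x)

    # weighted-likelihood tagwise maximization on a grid around the common value
    centre = max(common, 1e-6)
    grid = centre * 2.0 ** np.linspace(-10, 10, 81)
    ll = np.stack([_cond_loglik_rows(arrays, p) for p in grid], axis=1)
    weighted = ll + prior_df * ll.mean(axis=0)[None, :]
    tagwise = grid[np.argmax(weighted, axis=1)]
    return DispersionEstimate(common=common, tagwise=tagwise, prior_df=prior_df)


# ------------------------------------------------------------------ exact test

def _exact_nb_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for the split of the row total between two groups.

    Conditional on t = sum_a + sum_b, with per-sample mean t/(n_a+n_b), the
    group sums are NB (Poisson at phi = 0); the p value sums the conditional
    probabilities of all splits no more probable than the observed one
    (double-tail convention). At phi = 0 this is an exact binomial split.
    """
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    mu = t / (n_a + n_b)
    ks = np.arange(t + 1)
    if phi > 1e-12:
        ra, rb = n_a / phi, n_b / phi
        pa = ra / (ra + n_a * mu)
        pb = rb / (rb + n_b * mu)
        la = (gammaln(ks + ra) - gammaln(ra) - gammaln(ks + 1)
              + ra * np.log(pa) + ks * np.log1p(-pa))
        lb = (gammaln(ks + rb) - gammaln(rb) - gammaln(ks + 1)
              + rb * np.log(pb) + ks * np.log1p(-pb))
    else:
        la = ks * np.log(n_a * mu) - gammaln(ks + 1)
        lb = ks * np.log(n_b * mu) - gammaln(ks + 1)
    joint = la + lb[::-1]
    joint -= logsumexp(joint)
    prob = np.exp(joint)
    return float(prob[prob <= prob[sum_a] * (1 + 1e-10)].sum())


def nb_exact_test(matrix: pd.DataFrame, groups: pd.Series,
                  dispersions: DispersionEstimate | float,
                  norm_factors: pd.Series | None = None,
                  case: str | None = None, control: str | None = None,
                  prior_count: float = DEFAULT_PRIOR_COUNT,
                  lib_size: pd.Series | None = None) -> pd.DataFrame:
    """Exact two-group NB test on a count matrix.

    Returns a DataFrame indexed by row id with columns ``logFC`` (log2 fold
    change, case minus control), ``p`` and ``fdr`` (Benjamini-Hochberg).
    ``prior_count`` is added per sample to each group mean before the log
    ratio so zero counts stay finite. Exactly two groups are required; run
    each case group against the control separately otherwise.
    """
    groups = groups.reindex(matrix.columns)
    uniq = list(pd.unique(groups))
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 groups required, got {uniq}; run pairwise")
    if case is None or control is None:
        control, case = uniq[0], uniq[1]
    if norm_factors is None:
        norm_factors = tmm_factors(matrix, lib_size=lib_size)
    pseudo = _pseudo_counts(matrix, norm_factors, lib_size)
    ya = pseudo.loc[:, groups == case].to_numpy()
    yb = pseudo.loc[:, groups == control].to_numpy()
    n_a, n_b = ya.shape[1], yb.shape[1]
    sum_a, sum_b = ya.sum(axis=1), yb.sum(axis=1)
    if isinstance(dispersions, DispersionEstimate):
        phis = np.asarray(dispersions.tagwise, dtype=float)
        if phis.shape[0] != matrix.shape[0]:
            raise ValueError("dispersion vector length does not match matrix rows")
    else:
        phis = np.full(matrix.shape[0], float(dispersions))
    pvals = np.array([
        _exact_nb_pvalue(int(a), int(b), n_a, n_b, float(phi))
        for a, b, phi in zip(sum_a, sum_b, phis)
    ])
    pvals = np.minimum(pvals, 1.0)
    logfc = (np.log2(sum_a + prior_count * n_a) - np.log2(n_a)
             - np.log2(sum_b + prior_count * n_b) + np.log2(n_b))
    return pd.DataFrame(
        {"logFC": logfc, "p": pvals, "fdr": bh_adjust(pvals)}, index=matrix.index)


def bh_adjust(pvalues: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------------ clustering

@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    zscores: pd.DataFrame

    def column_split(self) -> dict[str, int]:
        """Membership of the column dendrogram's top split (1 or 2)."""
        labels = hierarchy.fcluster(self.col_linkage, t=2, criterion="maxclust")
        return dict(zip(self.zscores.columns, labels.tolist()))


def zscore_cluster(matrix: pd.DataFrame, method: str = "complete") -> ClusterResult:
    """Row-standardize and hierarchically cluster rows and columns.

    Each row is centred and scaled to unit variance; rows and columns are
    clustered on Euclidean distance with complete linkage (the default of
    the common heat-mapping tools). Constant rows are dropped with a
    warning. Columns are ordered lexicographically before clustering so the
    result is invariant to input column order.
    """
    matrix = matrix.loc[:, sorted(matrix.columns)]
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant row(s)", stacklevel=2)
    if keep.sum() < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 non-constant rows and >= 2 columns to cluster")
    values = values[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    zdf = pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)
    row_link = hierarchy.linkage(pdist(z), method=method)
    col_link = hierarchy.linkage(pdist(z.T), method=method)
    row_order = [zdf.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [zdf.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterResult(row_link, col_link, row_order, col_order, zdf)


# ------------------------------------------------------------------ model API

class DifferentialAbundanceModel:
    """Two-group NB differential-abundance model for a count matrix.

    Parameters
    ----------
    counts : DataFrame
        Rows are regions or genes, columns sample labels.
    groups : Series or mapping
        Sample label -> group label; exactly two groups.
    case, control : str
        Which group is the case (logFC sign: case minus control).
    centile : float, optional
        If given, rows with count sums below this centile are removed
        before fitting (50 for capture tags, 30 for expression in the
        reference workflow).
    prior_df : float
        Shrinkage weight for tagwise dispersions.
    lib_size : Series, optional
        Per-sample library sizes (e.g. genome-wide tag totals); defaults
        to the column sums of the analyzed matrix.
    """

    def __init__(self, counts: pd.DataFrame, groups: "pd.Series | dict",
                 case: str | None = None, control: str | None = None, *,
                 centile: float | None = None,
                 prior_df: float = DEFAULT_PRIOR_DF,
                 prior_count: float = DEFAULT_PRIOR_COUNT,
                 lib_size: pd.Series | None = None):
        self.counts = counts
        self.groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
        self.case = case
        self.control = control
        self.centile = centile
        self.prior_df = prior_df
        self.prior_count = prior_count
        self.lib_size = lib_size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_row: str = "group",
                       **kwargs) -> "DifferentialAbundanceModel":
        """Build from a DataFrame whose row ``group_row`` holds group labels."""
        groups = df.loc[group_row]
        counts = df.drop(index=group_row).astype(int)
        return cls(counts, groups, **kwargs)

    def fit(self) -> "DifferentialAbundanceResults":
        counts = self.counts
        if self.centile is not None:
            counts = centile_filter(counts, self.centile)
        factors = tmm_factors(counts, lib_size=self.lib_size)
        disp = estimate_dispersions(counts, self.groups, factors,
                                    prior_df=self.prior_df, lib_size=self.lib_size)
        table = nb_exact_test(counts, self.groups, disp, factors,
                              case=self.case, control=self.control,
                              prior_count=self.prior_count, lib_size=self.lib_size)
        return DifferentialAbundanceResults(self, counts, factors, disp, table)


class DifferentialAbundanceResults:
    """Fitted differential-abundance results.

    Attributes
    ----------
    table : DataFrame
        Per-row ``logFC``, ``p``, ``fdr``.
    norm_factors : Series
        TMM factors per sample.
    dispersion : DispersionEstimate
    """

    def __init__(self, model, counts, norm_factors, dispersion, table):
        self.model = model
        self.counts = counts
        self.norm_factors = norm_factors
        self.dispersion = dispersion
        self.table = table

    def significant(self, p_cutoff: float = 0.01) -> pd.DataFrame:
        return self.table[self.table["p"] < p_cutoff]

    def cluster(self, p_cutoff: float = 0.01) -> ClusterResult:
        """Z-score clustering of normalized counts for significant rows."""
        sig = self.significant(p_cutoff).index
        lib = (self.model.lib_size.reindex(self.counts.columns)
               if self.model.lib_size is not None else self.counts.sum(axis=0))
        lib_eff = lib * self.norm_factors
        normalized = self.counts.loc[sig] / lib_eff * float(np.median(lib_eff))
        return zscore_cluster(normalized)

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p")
        lines = [
            "Differential abundance (NB exact test, TMM-normalized)",
            f"  rows tested:      {len(t)}",
            f"  common dispersion: {self.dispersion.common:.4f}",
            f"  p < 0.01:         {(t['p'] < 0.01).sum()}",
            f"  FDR < 0.05:       {(t['fdr'] < 0.05).sum()}",
            "",
            t.head(top).to_string(float_format=lambda x: f"{x:.3g}"),
        ]
        return "\n".join(lines)
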