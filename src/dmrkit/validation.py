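"""Statistics for bisulfite-clone and qPCR validation experiments.

Clone matrices are binary (clones x CpG sites, 1 = methylated). Group
differences in methylation are tested with the Mann-Whitney U test on
per-clone methylation proportions (exact for small samples) and per-CpG
with Fisher's exact test. Relative expression from qPCR plates uses the
comparative ddCt method with two reference assays combined as the
arithmetic mean of their Ct values (the geometric mean of expression).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

MIN_CLONES = 6
REFERENCE_ASSAYS = ("Actb", "Gapdh")


def _check_binary(matrix: pd.DataFrame) -> None:
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("clone matrix entries must be 0 or 1")


def clone_methylation_summary(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-clone methylation proportions and per-CpG methylation frequencies.

    Fewer than six clones fails the QC gate: the summary is still returned
    but a warning is raised.
    """
    _check_binary(matrix)
    if matrix.shape[0] < MIN_CLONES:
        warnings.warn(
            f"only {matrix.shape[0]} clones (< {MIN_CLONES}): QC gate failed",
            stacklevel=2)
    return matrix.mean(axis=1), matrix.mean(axis=0)


def mannwhitney_group_test(values_a, values_b,
                           exact_limit: int = 20) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p; exact when combined n is small.

    Exact enumeration is used when n_a + n_b <= ``exact_limit`` and there
    are no ties; otherwise the normal approximation with tie correction.
    Returns (U of the first sample, p). All values tied gives p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    combined = np.concatenate([a, b])
    if np.unique(combined).size == 1:
        return float(a.size * b.size / 2), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= exact_limit and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def percpg_fisher(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                  adjust: bool = False) -> pd.Series:
    """Per-CpG two-sided Fisher exact p for group x methylated independence.

    Both matrices must cover the same CpG sites (columns). With
    ``adjust=True`` the p values are Benjamini-Hochberg corrected across
    sites.
    """
    _check_binary(matrix_a)
    _check_binary(matrix_b)
    if list(matrix_a.columns) != list(matrix_b.columns):
        raise ValueError("CpG sites differ between the two groups")
    pvals = []
    for site in matrix_a.columns:
        ma, mb = int(matrix_a[site].sum()), int(matrix_b[site].sum())
        table = [[ma, len(matrix_a) - ma], [mb, len(matrix_b) - mb]]
        pvals.append(float(stats.fisher_exact(table)[1]))
    out = pd.Series(pvals, index=matrix_a.columns, name="fisher_p")
    if adjust:
        out = pd.Series(bh_adjust(out.to_numpy()), index=out.index, name="fisher_fdr")
    return out


def ddct_relative_expression(qpcr: pd.DataFrame, case_group: list[str],
                             control_group: list[str],
                             references: tuple[str, str] = REFERENCE_ASSAYS,
                             ) -> tuple[pd.Series, dict[str, float]]:
    """Comparative ddCt relative quantification against a control group.

    ``qpcr`` is long format with columns sample, assay, replicate, ct; the
    target assay is named "target". Per sample, dCt = mean target Ct minus
    the arithmetic mean Ct of the two reference assays; ddCt subtracts the
    control-group mean dCt; relative quantity RQ = 2^(-ddCt). Adding a
    constant to every Ct leaves RQ unchanged.

    Returns (per-sample RQ over case+control, group summary dict).
    """
    for ref in references:
        if not (qpcr["assay"] == ref).any():
            raise ValueError(f"reference assay {ref!r} missing from plate")
    if not (qpcr["assay"] == "target").any():
        raise ValueError("target assay missing from plate")
    dct = {}
    for sample, grp in qpcr.groupby("sample"):
        t = grp.loc[grp["assay"] == "target", "ct"]
        refs = grp.loc[grp["assay"].isin(references), "ct"]
        if t.empty or refs.empty:
            raise ValueError(f"sample {sample!r}: missing target or reference Cts")
        ref_mean = np.mean([grp.loc[grp["assay"] == r, "ct"].mean() for r in references])
        dct[sample] = float(t.mean() - ref_mean)
    missing = [s for s in list(case_group) + list(control_group) if s not in dct]
    if missing:
        raise ValueError(f"samples absent from plate: {missing}")
    ctrl_mean = float(np.mean([dct[s] for s in control_group]))
    rq = pd.Series({s: 2.0 ** -(dct[s] - ctrl_mean)
                    for s in list(case_group) + list(control_group)}, name="rq")
    summary = {
        "case_mean_rq": float(rq[list(case_group)].mean()),
        "control_mean_rq": float(rq[list(control_group)].mean()),
        "fold_change": float(rq[list(case_group)].mean() / rq[list(control_group)].mean()),
    }
    return rq, summary


def group_mean_tests(values_by_group: dict[str, "np.ndarray | list[float]"],
                     design: str = "ttest") -> pd.DataFrame:
    """Two-group t test or one-way ANOVA with Bonferroni pairwise post hoc.

    design "ttest": unpaired two-tailed t test (exactly two groups).
    design "anova": one-way ANOVA over all groups followed by pairwise t
    tests with Bonferroni correction (p multiplied by the number of pairs,
    capped at 1).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
    names = list(groups)
    if design == "ttest":
        if len(names) != 2:
            raise ValueError("t test design requires exactly two groups")
        t, p = stats.ttest_ind(groups[names[0]], groups[names[1]])
        return pd.DataFrame([{"comparison": f"{names[0]} vs {names[1]}",
                              "statistic": float(t), "p": float(p)}])
    if design != "anova":
        raise ValueError(f"unknown design {design!r}")
    f, p = stats.f_oneway(*groups.values())
    rows = [{"comparison": "ANOVA", "statistic": float(f), "p": float(p)}]
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    for a, b in pairs:
        t, pp = stats.ttest_ind(groups[a], groups[b])
        rows.append({"comparison": f"{a} vs {b} (Bonferroni)",
                     "statistic": float(t), "p": min(1.0, float(pp) * len(pairs))})
    return pd.DataFrame(rows)


def lollipop_text(matrix: pd.DataFrame) -> str:
    """Lollipop-style text rendering of a clone matrix (o = unmethylated)."""
    _check_binary(matrix)
    lines = [f"{idx:>10s}  " + "".join("●" if v else "○" for v in row)
             for idx, row in zip(matrix.index.astype(str), matrix.to_numpy())]
    return "\n".join(lines)
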