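"""Candidate region discovery by Poisson window enrichment.

A deliberately simplified single-scale peak caller in the MACS 1.4 family:
tag 5' positions are shifted a fixed 75 bp toward the fragment centre, a
window of twice the shift slides along the genome, and a window is called
in a treatment/control pair when the upper-tail Poisson p value of the
treatment count — against the larger of the genome-wide and local-10 kb
control rate, scaled for window width and library-size ratio — falls below
the cutoff (default 1e-5). No fragment-model building, no summit
refinement, a single local-lambda scale instead of MACS's 1k/5k/10k
ensemble. All ordered sample pairs are compared so both gains and losses
surface, and the pair-level regions are merged bedtools-style.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, merge_intervals

DEFAULT_SHIFT = 75
DEFAULT_P_CUTOFF = 1e-5
LOCAL_LAMBDA_WINDOW = 10_000


@dataclass(frozen=True)
class EnrichedRegion:
    interval: GenomicInterval
    source_pair: tuple[str, str]  # (treatment, control)
    peak_p: float


def deduplicate_tags(tags: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one tag per (sample, chrom, pos5, strand).

    Order-independent: the result is sorted on the key columns.
    """
    out = tags.drop_duplicates(subset=["sample", "chrom", "pos5", "strand"])
    return (out.sort_values(["sample", "chrom", "pos5", "strand"])
               .reset_index(drop=True))


def shift_positions(tags: pd.DataFrame, shift: int = DEFAULT_SHIFT,
                    chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Shift each tag's 5' position ``shift`` bp in the 3' direction.

    Plus-strand tags move to pos5 + shift, minus-strand to pos5 - shift,
    clamped to chromosome bounds. Returns a copy with a ``pos`` column.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    out = tags.copy()
    sign = np.where(out["strand"].to_numpy() == "+", 1, -1)
    pos = out["pos5"].to_numpy() + sign * shift
    pos = np.maximum(pos, 0)
    if chrom_lengths:
        limits = out["chrom"].map(lambda c: chrom_lengths[c] - 1).to_numpy()
        pos = np.minimum(pos, limits)
    out["pos"] = pos
    return out


def shift_and_pile(tags: pd.DataFrame, shift: int = DEFAULT_SHIFT,
                   chrom_lengths: dict[str, int] | None = None) -> dict[str, pd.Series]:
    """Per-chromosome pileup of shifted positions (position -> tag count)."""
    shifted = shift_positions(tags, shift, chrom_lengths)
    return {
        chrom: grp.groupby("pos").size().sort_index()
        for chrom, grp in shifted.groupby("chrom")
    }


def _window_counts(positions: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    """Counts of sorted ``positions`` falling in [start, start+width) per window."""
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, starts + width, side="left")
    return hi - lo


def call_enriched_windows(treatment_tags: pd.DataFrame, control_tags: pd.DataFrame,
                          chrom_lengths: dict[str, int],
                          shift: int = DEFAULT_SHIFT,
                          p_cutoff: float = DEFAULT_P_CUTOFF,
                          step: int | None = None,
                          source_pair: tuple[str, str] = ("treatment", "control"),
                          ) -> list[EnrichedRegion]:
    """Call treatment-enriched windows against a control sample.

    Windows of width 2 x shift are evaluated every ``step`` bp (default
    shift/2). The Poisson rate is lambda = max(genome-wide control rate,
    control rate in a centred 10 kb window) * window width * library-size
    ratio. Overlapping significant windows are fused, keeping the minimum p.
    """
    if len(control_tags) == 0:
        raise ValueError("empty control sample: no background rate estimable")
    width = 2 * shift if shift > 0 else 100
    step = step or max(1, shift // 2)
    genome_size = sum(chrom_lengths.values())
    lib_ratio = len(treatment_tags) / len(control_tags)
    bg_rate = len(control_tags) / genome_size  # control tags per bp

    t_shift = shift_positions(treatment_tags, shift, chrom_lengths)
    c_shift = shift_positions(control_tags, shift, chrom_lengths)
    t_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in t_shift.groupby("chrom")}
    c_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in c_shift.groupby("chrom")}

    hits: list[tuple[GenomicInterval, float]] = []
    for chrom, length in chrom_lengths.items():
        tpos = t_by_chrom.get(chrom)
        if tpos is None or len(tpos) == 0:
            continue
        cpos = c_by_chrom.get(chrom, np.array([], dtype=np.int64))
        starts = np.arange(0, max(1, length - width + 1), step)
        tcounts = _window_counts(tpos, starts, width)
        cand = tcounts > 0
        if not cand.any():
            continue
        starts, tcounts = starts[cand], tcounts[cand]
        # local lambda from a centred 10 kb control window
        centre = starts + width // 2
        loc_lo = np.maximum(centre - LOCAL_LAMBDA_WINDOW // 2, 0)
        loc_hi = np.minimum(centre + LOCAL_LAMBDA_WINDOW // 2, length)
        local = (np.searchsorted(cpos, loc_hi, side="left")
                 - np.searchsorted(cpos, loc_lo, side="left"))
        local_rate = local / np.maximum(loc_hi - loc_lo, 1)
        lam = np.maximum(bg_rate, local_rate) * width * lib_ratio
        pvals = stats.poisson.sf(tcounts - 1, lam)
        for s, p in zip(starts[pvals < p_cutoff], pvals[pvals < p_cutoff]):
            hits.append((GenomicInterval(chrom, int(s), int(min(s + width, length))), float(p)))

    # fuse overlapping significant windows, keeping the minimum p
    regions: list[EnrichedRegion] = []
    hits.sort(key=lambda h: (h[0].chrom, h[0].start))
    i = 0
    while i < len(hits):
        iv, p = hits[i]
        chrom, s, e = iv.chrom, iv.start, iv.end
        j = i + 1
        while j < len(hits) and hits[j][0].chrom == chrom and hits[j][0].start < e:
            e = max(e, hits[j][0].end)
            p = min(p, hits[j][1])
            j += 1
        regions.append(EnrichedRegion(GenomicInterval(chrom, s, e), source_pair, p))
        i = j
    return regions


def pairwise_candidate_regions(tags: pd.DataFrame, chrom_lengths: dict[str, int],
                               shift: int = DEFAULT_SHIFT,
                               p_cutoff: float = DEFAULT_P_CUTOFF,
                               step: int | None = None) -> list[EnrichedRegion]:
    """Accumulate enriched regions over every ordered pair of samples."""
    samples = sorted(tags["sample"].unique())
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for pairwise comparison")
    by_sample = {s: g for s, g in tags.groupby("sample")}
    regions: list[EnrichedRegion] = []
    for treat, ctrl in permutations(samples, 2):
        regions.extend(call_enriched_windows(
            by_sample[treat], by_sample[ctrl], chrom_lengths,
            shift=shift, p_cutoff=p_cutoff, step=step, source_pair=(treat, ctrl)))
    return regions


def candidate_region_catalog(regions: list[EnrichedRegion]) -> list[GenomicInterval]:
    """Merge pair-level regions into a disjoint candidate-region catalogue."""
    return merge_intervals(r.interval for r in regions)
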