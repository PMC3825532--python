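"""Synthetic data generator.

Emulates the statistical structure of a methyl-capture sequencing study:
a toy genome with genes and CpG islands, group-structured capture-tag
densities (hyper-/hypomethylation planted preferentially on CGIs and gene
bodies, sparing one designated chromosome), negative-binomial expression
counts inversely coupled to gene-body methylation, clone-level bisulfite
calls, and qPCR Ct plates.

The capture density model is piecewise-constant: a strictly positive
baseline (tags/bp) multiplied inside each effect interval by its
fold-change for the affected group. Fragment-size distributions, sequence
content and conversion chemistry are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval


class SizingError(ValueError):
    """The requested features cannot be placed on the requested genome."""


@dataclass(frozen=True)
class ToyGenome:
    chromosomes: tuple[tuple[str, int], ...]
    genes: tuple[GeneModel, ...]
    cgis: tuple[GenomicInterval, ...]
    spared_chrom: str | None = None

    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def validate(self) -> None:
        lengths = self.chrom_lengths()
        for g in self.genes:
            if g.chrom not in lengths or not (0 <= g.start < g.end <= lengths[g.chrom]):
                raise ValueError(f"gene {g.name} outside chromosome bounds")
        for iv in self.cgis:
            if iv.chrom not in lengths or not (0 <= iv.start < iv.end <= lengths[iv.chrom]):
                raise ValueError(f"CGI {iv} outside chromosome bounds")
        if self.spared_chrom is not None and self.spared_chrom not in lengths:
            raise ValueError(f"spared chromosome {self.spared_chrom!r} unknown")


@dataclass(frozen=True)
class MethylEffect:
    interval: GenomicInterval
    group: str
    fold_change: float  # >1 hypermethylation, <1 hypomethylation in `group`

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")


@dataclass
class MethylationLandscape:
    """Per-group relative capture density over the genome."""

    baseline_density: float  # tags/bp relative weight, > 0
    effects: list[MethylEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline_density <= 0:
            raise ValueError("baseline density must be strictly positive")

    def validate(self, genome: ToyGenome) -> None:
        lengths = genome.chrom_lengths()
        for eff in self.effects:
            iv = eff.interval
            if iv.chrom not in lengths or not (0 <= iv.start < iv.end <= lengths[iv.chrom]):
                raise ValueError(f"effect interval {iv} outside chromosome bounds")
            if genome.spared_chrom is not None and iv.chrom == genome.spared_chrom:
                raise ValueError(
                    f"effect interval on spared chromosome {genome.spared_chrom!r}")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_samples: dict[str, int] = field(default_factory=lambda: {"CTRL": 5, "PILO": 4})
    depth: float = 100_000.0       # expected tags per sample
    duplicate_rate: float = 0.0
    nb_dispersion: float = 0.1     # expression counts
    coupling: float = 1.0          # |log2FC| applied to effect-carrying genes
    expression_depth: float = 1_000_000.0

    def __post_init__(self) -> None:
        if not (0 <= self.duplicate_rate < 1):
            raise ValueError("duplicate_rate must be in [0, 1)")
        if self.nb_dispersion < 0 or self.depth < 0 or self.expression_depth < 0:
            raise ValueError("rates and depths must be nonnegative")
        if any(n < 0 for n in self.n_samples.values()):
            raise ValueError("sample counts must be nonnegative")

    def sample_labels(self) -> dict[str, str]:
        """Sample label -> group label, deterministic order."""
        return {f"{g}_{i+1}": g for g in self.n_samples for i in range(self.n_samples[g])}


# ------------------------------------------------------------------ genome

def generate_toy_genome(n_chroms: int, chrom_length: int, n_genes: int,
                        n_cgis: int, seed: int,
                        spare_last_chrom: bool = False) -> ToyGenome:
    """Generate a toy genome with strand-aware genes and CpG islands.

    Genes are non-overlapping, each with 1-8 ordered exons; CGIs (200-2000 bp)
    are placed uniformly so they fall both inside and outside gene bodies.
    Deterministic for a fixed seed. Raises :class:`SizingError` when the
    requested features cannot be placed.
    """
    rng = np.random.default_rng(seed)
    chroms = tuple((f"chr{i+1}", int(chrom_length)) for i in range(n_chroms))
    gene_lengths = rng.integers(2_000, 10_001, size=n_genes)
    if gene_lengths.sum() > n_chroms * chrom_length * 0.8:
        raise SizingError(
            f"cannot place {n_genes} genes on {n_chroms} x {chrom_length} bp")
    # sequential placement with random gaps, chromosomes filled round-robin
    genes: list[GeneModel] = []
    cursors = {name: 0 for name, _ in chroms}
    order = rng.permutation(n_genes)
    for idx, gi in enumerate(order):
        glen = int(gene_lengths[gi])
        placed = False
        for name, clen in sorted(chroms, key=lambda c: cursors[c[0]]):
            gap = int(rng.integers(200, max(201, (clen - cursors[name]) // max(1, n_genes // n_chroms))))
            start = cursors[name] + gap
            if start + glen <= clen:
                n_ex = int(rng.integers(1, 9))
                bounds = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2,
                                            replace=False)) if n_ex > 1 else np.array([], int)
                edges = np.concatenate([[0], bounds, [glen]])
                exons = tuple(
                    (start + int(edges[2 * k]), start + int(edges[2 * k + 1]))
                    for k in range(n_ex)
                )
                exons = tuple((s, e) for s, e in exons if e > s)
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(f"gene{len(genes)+1:04d}", name, start,
                                       start + glen, strand, exons))
                cursors[name] = start + glen
                placed = True
                break
        if not placed:
            raise SizingError(
                f"cannot place gene of {glen} bp: genome too small or too full")
    cgis = []
    for i in range(n_cgis):
        clen = int(rng.integers(200, 2001))
        name, length = chroms[int(rng.integers(n_chroms))]
        if length <= clen:
            raise SizingError("chromosome too short for a CGI")
        start = int(rng.integers(0, length - clen))
        cgis.append(GenomicInterval(name, start, start + clen))
    genome = ToyGenome(chroms, tuple(genes), tuple(cgis),
                       spared_chrom=chroms[-1][0] if spare_last_chrom else None)
    genome.validate()
    return genome


def plant_effects(genome: ToyGenome, groups: list[str], n_effects: int,
                  fold_change: float, seed: int, feature_weight: float = 0.7,
                  hyper_fraction: float = 0.6,
                  baseline_density: float = 1.0) -> MethylationLandscape:
    """Place differential-methylation effect intervals on the genome.

    With probability ``feature_weight`` an effect is dropped onto a CGI or a
    gene body (mirroring the observed targeting of methylation changes);
    otherwise anywhere outside the spared chromosome. A ``hyper_fraction``
    of effects get fold-change ``fold_change`` (hypermethylation in the
    affected group), the rest ``1/fold_change``.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.chrom_lengths()
    allowed = [c for c in lengths if c != genome.spared_chrom]
    if not allowed:
        raise ValueError("no chromosome available for effects")
    features = [g.body for g in genome.genes] + list(genome.cgis)
    features = [iv for iv in features if iv.chrom != genome.spared_chrom]
    effects = []
    for i in range(n_effects):
        width = int(rng.integers(500, 3001))
        if features and rng.random() < feature_weight:
            anchor = features[int(rng.integers(len(features)))]
            center = int(rng.integers(anchor.start, anchor.end))
            chrom = anchor.chrom
        else:
            chrom = allowed[int(rng.integers(len(allowed)))]
            center = int(rng.integers(0, lengths[chrom]))
        start = max(0, center - width // 2)
        end = min(lengths[chrom], start + width)
        fold = fold_change if rng.random() < hyper_fraction else 1.0 / fold_change
        group = groups[int(rng.integers(len(groups)))]
        effects.append(MethylEffect(GenomicInterval(chrom, start, end), group, fold))
    landscape = MethylationLandscape(baseline_density, effects)
    landscape.validate(genome)
    return landscape


def plant_individual_effects(genome: ToyGenome, samples: list[str],
                             n_per_sample: int, fold_change: float,
                             seed: int, feature_weight: float = 0.7,
                             ) -> list[MethylEffect]:
    """Per-sample (inter-individual) methylation effects.

    Real methyl-capture cohorts show abundant individual variability: most
    candidate regions from all-pairwise peak calling differ between
    individuals, not between groups. These effects attach to a single
    sample label (hyper or hypo with equal probability) and make the
    simulated candidate catalogue predominantly group-null, as observed.
    Append them to a landscape's effects before simulating tags.
    """
    effects = []
    for i, sample in enumerate(samples):
        lab = plant_effects(genome, [sample], n_per_sample, fold_change,
                            seed=seed + 7919 * (i + 1),
                            feature_weight=feature_weight, hyper_fraction=0.5)
        effects.extend(lab.effects)
    return effects


# ------------------------------------------------------------------ tags

def _density_segments(genome: ToyGenome, landscape: MethylationLandscape,
                      labels: set[str]) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-constant density for one sample: segments of chrom/start/len/weight.

    ``labels`` holds the sample's group label and its own sample label, so
    both group-level and individual (per-sample) effects apply.
    """
    chroms, starts, lens, weights = [], [], [], []
    for chrom, length in genome.chromosomes:
        cuts = {0, length}
        effs = [e for e in landscape.effects
                if e.group in labels and e.interval.chrom == chrom]
        for e in effs:
            cuts.add(e.interval.start)
            cuts.add(e.interval.end)
        edges = sorted(cuts)
        for s, e in zip(edges[:-1], edges[1:]):
            w = landscape.baseline_density
            for eff in effs:
                if eff.interval.start <= s and e <= eff.interval.end:
                    w *= eff.fold_change
            chroms.append(chrom)
            starts.append(s)
            lens.append(e - s)
            weights.append(w)
    return chroms, np.asarray(starts), np.asarray(lens), np.asarray(weights, float)


def simulate_capture_tags(genome: ToyGenome, landscape: MethylationLandscape,
                          config: SimulationConfig) -> pd.DataFrame:
    """Simulate methyl-capture tag alignments for every sample.

    Per sample, the tag total is Poisson(depth); 5' positions are drawn from
    the group's piecewise-constant density, strands uniformly; a
    ``duplicate_rate`` fraction of tags are exact resamples of other tags of
    the same sample (same chrom, position and strand). Returns a DataFrame
    with columns chrom, pos5, strand, sample.
    """
    landscape.validate(genome)
    rng = np.random.default_rng(config.seed)
    frames = []
    for sample, group in config.sample_labels().items():
        chroms, starts, lens, weights = _density_segments(
            genome, landscape, {group, sample})
        probs = weights * lens
        probs = probs / probs.sum()
        n = rng.poisson(config.depth)
        n_dup = rng.binomial(n, config.duplicate_rate) if n else 0
        n_fresh = n - n_dup
        seg = rng.choice(len(probs), size=n_fresh, p=probs)
        offset = (rng.random(n_fresh) * lens[seg]).astype(np.int64)
        pos = starts[seg] + offset
        strand = np.where(rng.random(n_fresh) < 0.5, "+", "-")
        chrom = np.asarray(chroms, dtype=object)[seg]
        if n_dup and n_fresh:
            src = rng.integers(0, n_fresh, size=n_dup)
            chrom = np.concatenate([chrom, chrom[src]])
            pos = np.concatenate([pos, pos[src]])
            strand = np.concatenate([strand, strand[src]])
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos5": pos, "strand": strand, "sample": sample}))
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------------ expression

def simulate_expression_counts(genome: ToyGenome, landscape: MethylationLandscape,
                               config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes x samples NB count matrix coupled to methylation.

    A gene whose body overlaps a hypermethylation effect (fold > 1) for group
    g has its mean multiplied by 2^(-coupling) in that group's samples
    (repression); a hypomethylation effect gives 2^(+coupling). Counts are
    NB with the configured dispersion (Poisson when dispersion == 0).

    Returns (counts DataFrame, sample -> group Series).
    """
    rng = np.random.default_rng(config.seed)
    labels = config.sample_labels()
    genes = genome.genes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    base = base / base.sum() * config.expression_depth  # per-sample library size
    # per-gene, per-group log2 shift from overlapping effects
    shift = {g: np.zeros(len(genes)) for g in config.n_samples}
    for eff in landscape.effects:
        if eff.group not in shift:  # individual effects do not shift groups
            continue
        for i, gene in enumerate(genes):
            if gene.body.overlaps(eff.interval):
                direction = -1.0 if eff.fold_change > 1 else 1.0
                shift[eff.group][i] += direction * config.coupling
    counts = {}
    for sample, group in labels.items():
        mu = base * (2.0 ** shift[group])
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape=r, scale=mu / r)
            counts[sample] = rng.poisson(lam)
        else:
            counts[sample] = rng.poisson(mu)
    df = pd.DataFrame(counts, index=[g.name for g in genes])
    return df, pd.Series(labels, name="group")


# ------------------------------------------------------------------ bisulfite

def simulate_bisulfite_clones(true_methylation: "np.ndarray | list[float]",
                              n_clones: int, seed: int) -> pd.DataFrame:
    """Simulate a clones x CpG binary matrix of bisulfite calls.

    Each clone calls each CpG methylated independently with that CpG's true
    proportion. Rows are clone ids, columns CpG indices.
    """
    props = np.asarray(true_methylation, dtype=float)
    if props.ndim != 1 or ((props < 0) | (props > 1)).any():
        raise ValueError("methylation proportions must lie in [0, 1]")
    if n_clones < 1:
        raise ValueError("need at least one clone")
    rng = np.random.default_rng(seed)
    calls = (rng.random((n_clones, props.size)) < props).astype(int)
    return pd.DataFrame(calls,
                        index=[f"clone{i+1}" for i in range(n_clones)],
                        columns=[f"CpG{j+1}" for j in range(props.size)])


# ------------------------------------------------------------------ qPCR

def simulate_qpcr_plate(true_rel_expression: dict[str, float], ct_noise_sd: float,
                        n_replicates: int, seed: int,
                        reference_ct: float = 20.0,
                        references: tuple[str, str] = ("Actb", "Gapdh")) -> pd.DataFrame:
    """Simulate a qPCR plate for one target and two reference assays.

    ``true_rel_expression`` maps sample -> relative expression of the target.
    Target Ct = reference Ct - log2(relative expression) + noise. Requires
    at least triplicate measurements. Returns a long-format DataFrame with
    columns sample, assay, replicate, ct.
    """
    if n_replicates < 3:
        raise ValueError("qPCR requires at least triplicates")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, rel in true_rel_expression.items():
        if rel <= 0:
            raise ValueError("relative expression must be positive")
        for rep in range(1, n_replicates + 1):
            for ref in references:
                rows.append((sample, ref, rep,
                             reference_ct + rng.normal(0, ct_noise_sd)))
            rows.append((sample, "target", rep,
                         reference_ct - np.log2(rel) + rng.normal(0, ct_noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "assay", "replicate", "ct"])
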