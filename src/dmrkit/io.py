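"""Reading and writing the plain-text formats the pipeline touches.

Internally everything is 0-based half-open; BED files are consumed and
produced natively in that convention. The gene table is a tab-separated
dialect with one gene per line and comma-separated exon blocks.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .intervals import GeneModel, GenomicInterval


class ParseError(ValueError):
    """A malformed line in an input file, reported with its location."""


# ---------------------------------------------------------------- intervals

def read_intervals(path: str | Path, dialect: str = "BED") -> list[GenomicInterval]:
    """Read intervals from a BED-like file.

    dialect "BED": columns chrom, start, end (extra columns ignored).
    dialect "gene-table": the gene dialect of :func:`read_genes`; only the
    gene-body span is returned.
    """
    path = Path(path)
    if dialect == "gene-table":
        return [g.body for g in read_genes(path)]
    if dialect != "BED":
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start > end:
                raise ParseError(f"{path}:{lineno}: start {start} > end {end}")
            out.append(GenomicInterval(fields[0], start, end))
    if not out:
        warnings.warn(f"{path}: no intervals found", stacklevel=2)
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path,
                    names: Sequence[str] | None = None,
                    scores: Sequence[float] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                fields.append(str(names[i]))
            if scores is not None:
                fields.append(format(scores[i], ".6g"))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------- tags (BED6)

def read_tags(path: str | Path) -> pd.DataFrame:
    """Read tag alignments from 6-column BED (name column = sample label).

    Returns a DataFrame with columns chrom, pos5, strand, sample; the 5'
    coordinate is the BED start for + tags and end-1 for - tags.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if f[5] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {f[5]!r}")
            pos5 = start if f[5] == "+" else end - 1
            rows.append((f[0], pos5, f[5], f[3]))
    return pd.DataFrame(rows, columns=["chrom", "pos5", "strand", "sample"])


def write_tags(tags: pd.DataFrame, path: str | Path, tag_length: int = 36) -> None:
    """Write tags as 6-column BED; the 36 bp read length is metadata only."""
    with open(path, "w") as fh:
        for t in tags.itertuples(index=False):
            if t.strand == "+":
                start, end = t.pos5, t.pos5 + tag_length
            else:
                start, end = max(0, t.pos5 + 1 - tag_length), t.pos5 + 1
            fh.write(f"{t.chrom}\t{start}\t{end}\t{t.sample}\t0\t{t.strand}\n")


# ---------------------------------------------------------------- gene table

def read_genes(path: str | Path) -> list[GeneModel]:
    """Read the tab-separated gene table.

    Columns: name, chrom, start, end, strand, exons where exons is a
    comma-separated list of start-end blocks, e.g. ``100-200,300-400``.
    """
    path = Path(path)
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields")
            try:
                exons = tuple(
                    tuple(int(x) for x in block.split("-"))
                    for block in f[5].split(",")
                )
                genes.append(GeneModel(f[0], f[1], int(f[2]), int(f[3]), f[4], exons))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# name\tchrom\tstart\tend\tstrand\texons\n")
        for g in genes:
            blocks = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.name}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{blocks}\n")


# ---------------------------------------------------------------- count matrix

def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV: first column row ids, header row of sample labels.

    Counts must be nonnegative integers and row ids unique.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate row id {dup!r}")
    values = df.to_numpy()
    if not ((values == values.astype(int)) & (values >= 0)).all():
        raise ParseError(f"{path}: counts must be nonnegative integers")
    return df.astype(int)


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


# ---------------------------------------------------------------- gene sets

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected name, description, >=1 member")
            sets[f[0]] = set(f[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------- config

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: expected a key-value mapping")
    return cfg
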