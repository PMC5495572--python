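"""Coverage accumulation and median-of-coverage gene expression.

Unique read placements are turned into per-base depth tracks; a gene's
expression is the median depth over every base of its annotated
interval(s).  The median is robust to the coverage spikes and edge dips
that read stacking produces, which is why it is used instead of a mean
or a raw read count.  No length normalization is applied: the median of
per-base depth is already a per-base quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnnotationError, ConsistencyError
from .mapper import Placement
from .refindex import ReferenceSet


@dataclass
class Annotation:
    """Gene intervals, 0-based half-open: (sequence_id, start, end, gene_id).

    A gene may own several intervals (multi-exon stand-in); its expression
    is the median over the concatenated bases of all of them.
    """

    intervals: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise AnnotationError("annotation has no intervals")
        for seq_id, start, end, gene in self.intervals:
            if not gene:
                raise AnnotationError("empty gene_id in annotation")
            if not (0 <= start < end):
                raise AnnotationError(
                    f"gene {gene!r}: invalid interval [{start}, {end})"
                )

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, _, gene in self.intervals:
            seen.setdefault(gene)
        return list(seen)

    def by_gene(self) -> dict[str, list[tuple[str, int, int]]]:
        out: dict[str, list[tuple[str, int, int]]] = {}
        for seq_id, start, end, gene in self.intervals:
            out.setdefault(gene, []).append((seq_id, start, end))
        return out

    def validate_bounds(self, refs: ReferenceSet) -> None:
        lengths = refs.lengths
        for seq_id, start, end, gene in self.intervals:
            if seq_id not in lengths:
                raise AnnotationError(f"gene {gene!r}: unknown sequence {seq_id!r}")
            if end > lengths[seq_id]:
                raise AnnotationError(
                    f"gene {gene!r}: interval end {end} exceeds {seq_id} length "
                    f"{lengths[seq_id]}"
                )


def read_bed(path) -> Annotation:
    """Parse a 4+-column BED file (chrom, start, end, name)."""
    intervals = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            fields = ln.split("\t")
            if len(fields) < 4:
                raise AnnotationError(f"BED line has fewer than 4 columns: {ln!r}")
            intervals.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return Annotation(intervals)


def write_bed(annotation: Annotation, path) -> None:
    with open(path, "w") as fh:
        for seq_id, start, end, gene in annotation.intervals:
            fh.write(f"{seq_id}\t{start}\t{end}\t{gene}\n")


CoverageTrack = dict[str, np.ndarray]


def accumulate_coverage(placements, refs: ReferenceSet) -> CoverageTrack:
    """Per-base depth from unique placements.

    Each unique placement adds 1 over its full trimmed span
    [start, start + span); multi/unmapped/discordant reads contribute
    nothing.  The depth sum therefore equals span × (number of unique
    placements).
    """
    cov: CoverageTrack = {
        name: np.zeros(length, dtype=np.int64) for name, length in refs.lengths.items()
    }
    for p in placements:
        if p.status != "unique":
            continue
        if p.sequence_id not in cov:
            raise ConsistencyError(
                f"placement {p.read_id!r} references unknown sequence {p.sequence_id!r}"
            )
        track = cov[p.sequence_id]
        if p.start < 0 or p.start + p.span > len(track):
            raise ConsistencyError(
                f"placement {p.read_id!r} at {p.sequence_id}:{p.start} "
                f"span {p.span} exceeds sequence bounds"
            )
        track[p.start : p.start + p.span] += 1
    return cov


def gene_expression(coverage: CoverageTrack, annotation: Annotation) -> pd.Series:
    """Median depth across each gene's bases (even count: mean of the two
    central order statistics)."""
    values = {}
    for gene, ivs in annotation.by_gene().items():
        depths = []
        for seq_id, start, end in ivs:
            if seq_id not in coverage:
                raise AnnotationError(f"gene {gene!r}: unknown sequence {seq_id!r}")
            track = coverage[seq_id]
            if end > len(track):
                raise AnnotationError(
                    f"gene {gene!r}: interval exceeds {seq_id} bounds"
                )
            depths.append(track[start:end])
        pooled = np.concatenate(depths)
        if pooled.size == 0:
            raise AnnotationError(f"gene {gene!r} has a zero-length footprint")
        values[gene] = float(np.median(pooled))
    return pd.Series(values, name="expression").loc[annotation.gene_ids]


def build_matrix(samples: list[tuple[str, pd.Series]], annotation: Annotation) -> pd.DataFrame:
    """Assemble per-sample expression vectors into a genes × samples matrix.

    Rows follow annotation order, columns input order; duplicate sample ids
    or a sample missing a gene raise :class:`ConsistencyError`.
    """
    if not samples:
        raise ConsistencyError("no samples supplied")
    ids = [sid for sid, _ in samples]
    if len(set(ids)) != len(ids):
        raise ConsistencyError("duplicate sample_id in matrix assembly")
    genes = annotation.gene_ids
    cols = {}
    for sid, vec in samples:
        missing = set(genes) - set(vec.index)
        if missing:
            raise ConsistencyError(
                f"sample {sid!r} missing genes: {sorted(missing)[:5]}"
            )
        cols[sid] = vec.loc[genes].astype(float)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


def write_bedgraph(coverage: CoverageTrack, path) -> None:
    """Run-length encoded bedGraph of a coverage track."""
    with open(path, "w") as fh:
        for seq_id in coverage:
            depths = coverage[seq_id]
            if depths.size == 0:
                continue
            change = np.flatnonzero(np.diff(depths)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [depths.size]))
            for s, e in zip(starts, ends):
                d = int(depths[s])
                if d != 0:
                    fh.write(f"{seq_id}\t{s}\t{e}\t{d}\n")


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
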