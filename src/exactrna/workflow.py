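"""End-to-end glue: reads → placements → expression → differential table.

Thin convenience layer over the individual stages; every step is also
usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mapper import MappingStats, Placement, place_read
from .normfc import DETable, NoiseEstimate, de_table, detect_outliers, estimate_noise, quantile_normalize
from .quant import Annotation, accumulate_coverage, build_matrix, gene_expression
from .refindex import ReferenceSet, SuffixIndex, build_index


def map_reads(index: SuffixIndex, reads, min_part: int = 20):
    """Map an in-memory read iterable; returns (placements, stats)."""
    from .errors import GeometryError

    stats = MappingStats()
    placements: list[Placement] = []
    for read in reads:
        stats.total += 1
        try:
            pl = place_read(index, read, min_part=min_part)
        except GeometryError:
            stats.geometry_skipped += 1
            continue
        placements.append(pl)
        setattr(stats, pl.status, getattr(stats, pl.status) + 1)
    return placements, stats


def quantify_samples(
    refs: ReferenceSet, annotation: Annotation, samples: dict[str, list]
) -> tuple[pd.DataFrame, dict[str, MappingStats]]:
    """Map and quantify every sample into a genes × samples matrix."""
    index = build_index(refs)
    vectors = []
    all_stats = {}
    for sid, reads in samples.items():
        placements, stats = map_reads(index, reads)
        cov = accumulate_coverage(placements, refs)
        vectors.append((sid, gene_expression(cov, annotation)))
        all_stats[sid] = stats
    return build_matrix(vectors, annotation), all_stats


@dataclass
class DEResult:
    matrix_normalized: pd.DataFrame
    noise: NoiseEstimate
    de: DETable
    outliers: "pd.Series | None" = None


def differential_expression(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    noise: float | None = None,
    exclude_outliers: bool = True,
    orientation: str = "case-over-ctrl",
) -> DEResult:
    """Quantile-normalize, estimate noise from the density peak (unless a
    fixed noise level is supplied), flag outlier samples, and compute the
    regularized log2 fold-change table."""
    report = detect_outliers(matrix) if exclude_outliers else None
    kept = matrix
    use_groups = dict(groups)
    if report is not None and report.excluded:
        kept = matrix.drop(columns=report.excluded)
        use_groups = {s: g for s, g in groups.items() if s not in report.excluded}
    normalized = quantile_normalize(kept)
    ne = estimate_noise(normalized) if noise is None else NoiseEstimate(value=float(noise))
    de = de_table(normalized, use_groups, ne, orientation=orientation)
    return DEResult(
        matrix_normalized=normalized,
        noise=ne,
        de=de,
        outliers=report.similarity if report is not None else None,
    )
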