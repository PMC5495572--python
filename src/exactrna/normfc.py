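"""Normalization, noise estimation and regularized differential expression.

The differential-expression statistic is a noise-regularized log2 fold
change: the pooled density of (log-transformed) expression values has a
pronounced peak at the low-expression floor, and the expression value at
that peak — "the noise" — is added to both group means before the ratio
is formed,

    lgFC(g) = log2( (mean_case(g) + noise) / (mean_ctrl(g) + noise) ).

The additive noise term shrinks ratios of weakly expressed genes toward
zero, so genes at the noise floor cannot dominate the fold-change
ranking, while well-expressed genes are nearly unaffected.  No p-values
are computed; ranking is by |lgFC|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import GroupingError

DEFAULT_CLIP = 1.5  # heat-map display range on the log2 scale
DEFAULT_OUTLIER_THRESHOLD = 0.8


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common distribution given by
    the across-sample mean of order statistics.

    After the call each column holds the same multiset of values; ties
    within a column receive the mean of their tied target quantiles, so the
    transform is deterministic and rank-preserving.  Idempotent.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 1:
        raise ValueError("quantile normalization needs >= 2 samples and >= 1 gene")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN")
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = target
        # average target quantiles over ties
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class NoiseEstimate:
    """Expression level at the density peak of the pooled values."""

    value: float
    bandwidth: float | None = None
    grid_size: int = 512
    scale: str = "log2(1+x)"
    degenerate: bool = False

    def __float__(self) -> float:
        return self.value


def estimate_noise(
    matrix: pd.DataFrame | np.ndarray,
    bw_method: str | float = "silverman",
    grid_size: int = 512,
) -> NoiseEstimate:
    """Noise level = the mode of the pooled expression density.

    Values are pooled across the whole matrix, transformed by log2(1+x),
    smoothed with a Gaussian kernel (Silverman bandwidth by default) on a
    uniform ``grid_size``-point grid, and the argmax is transformed back.
    With a cohort of genes sitting at a shared low-expression floor the
    mode lands on that floor, which is the quantity used to regularize
    fold changes.
    """
    values = np.asarray(matrix, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values to estimate noise")
    if np.isnan(values).any() or (values < 0).any():
        raise ValueError("expression values must be finite and non-negative")
    y = np.log2(1.0 + values)
    if np.allclose(y, y[0]):
        return NoiseEstimate(value=float(values[0]), degenerate=True, grid_size=grid_size)
    kde = gaussian_kde(y, bw_method=bw_method)
    pad = kde.factor * y.std(ddof=1)
    grid = np.linspace(y.min() - pad, y.max() + pad, grid_size)
    density = kde(grid)
    y_star = grid[int(np.argmax(density))]
    return NoiseEstimate(
        value=float(max(2.0**y_star - 1.0, 0.0)),
        bandwidth=float(kde.factor),
        grid_size=grid_size,
    )


def regularized_fc(
    mean_ctrl: float,
    mean_case: float,
    noise: float,
    log_base: float = 2.0,
    orientation: str = "case-over-ctrl",
) -> float:
    """Noise-regularized log fold change of one gene.

    ``case-over-ctrl`` (default) reports up-regulation in the case group as
    positive; ``printed`` uses the control-over-case orientation, the sign
    convention being the only difference.
    """
    if noise <= 0:
        raise ValueError(f"noise must be > 0, got {noise}")
    if mean_ctrl < 0 or mean_case < 0:
        raise ValueError("group means must be non-negative")
    if orientation == "case-over-ctrl":
        ratio = (mean_case + noise) / (mean_ctrl + noise)
    elif orientation == "printed":
        ratio = (mean_ctrl + noise) / (mean_case + noise)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return float(np.log(ratio) / np.log(log_base))


@dataclass
class DETable:
    """Per-gene regularized log fold changes, sorted by |lgFC| descending."""

    table: pd.DataFrame  # columns: mean_ctrl, mean_case, lgFC; index: gene_id
    noise: NoiseEstimate
    orientation: str = "case-over-ctrl"


def de_table(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    noise: NoiseEstimate | float,
    orientation: str = "case-over-ctrl",
    log_base: float = 2.0,
) -> DETable:
    """Group means on the normalized matrix, then regularized log FC.

    ``groups`` maps sample_id → 'ctrl' | 'case'; samples absent from the
    mapping (e.g. flagged outliers) are ignored.  The result is sorted by
    |lgFC| descending with ties broken by gene_id.
    """
    ctrl = [s for s in matrix.columns if groups.get(s) == "ctrl"]
    case = [s for s in matrix.columns if groups.get(s) == "case"]
    if not ctrl or not case:
        raise GroupingError(
            f"both groups must be non-empty (ctrl={len(ctrl)}, case={len(case)})"
        )
    noise_value = float(noise)
    mean_ctrl = matrix[ctrl].mean(axis=1)
    mean_case = matrix[case].mean(axis=1)
    lgfc = [
        regularized_fc(c, t, noise_value, log_base=log_base, orientation=orientation)
        for c, t in zip(mean_ctrl, mean_case)
    ]
    tab = pd.DataFrame(
        {"mean_ctrl": mean_ctrl, "mean_case": mean_case, "lgFC": lgfc},
        index=matrix.index,
    )
    idx_name = tab.index.name or "gene_id"
    tab.index.name = idx_name
    tab["_abs"] = tab["lgFC"].abs()
    tab = (
        tab.reset_index()
        .sort_values(by=["_abs", idx_name], ascending=[False, True], kind="stable")
        .set_index(idx_name)
        .drop(columns="_abs")
    )
    ne = noise if isinstance(noise, NoiseEstimate) else NoiseEstimate(value=noise_value)
    return DETable(table=tab, noise=ne, orientation=orientation)


@dataclass
class OutlierReport:
    """Mean inter-sample similarity and exclusion flags."""

    similarity: pd.Series  # sample_id -> mean Pearson r to the other samples
    excluded: list[str] = field(default_factory=list)
    threshold: float = DEFAULT_OUTLIER_THRESHOLD
    note: str | None = None

    def retained(self, sample_ids) -> list[str]:
        return [s for s in sample_ids if s not in self.excluded]


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    # constant columns: correlation undefined; treat exact duplicates as 1
    if a.std() == 0 or b.std() == 0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def detect_outliers(
    matrix: pd.DataFrame, threshold: float = DEFAULT_OUTLIER_THRESHOLD
) -> OutlierReport:
    """Flag replicate columns that fail to correlate with the others.

    Pairwise Pearson correlation on log2(1+x) columns.  A sample is
    flagged when its mean correlation to the other retained samples falls
    below ``threshold``; exclusion is greedy and iterative (worst sample
    first, similarities recomputed among the remainder) so that a single
    rogue column does not drag genuine replicates below the cutoff.  At
    least two samples are always retained.  The reported similarity is
    each sample's mean correlation at the moment of its decision.
    """
    samples = list(matrix.columns)
    if len(samples) < 3:
        return OutlierReport(
            similarity=pd.Series(np.nan, index=samples),
            excluded=[],
            threshold=threshold,
            note="fewer than 3 samples: outlier detection not applicable",
        )
    X = np.log2(1.0 + matrix.to_numpy(dtype=float))
    n = len(samples)
    corr = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            corr[i, j] = corr[j, i] = _safe_pearson(X[:, i], X[:, j])
    remaining = list(range(n))
    excluded_idx: list[int] = []
    sim_at_decision: dict[int, float] = {}
    while len(remaining) > 2:
        sub = corr[np.ix_(remaining, remaining)]
        mean_sim = (sub.sum(axis=1) - 1.0) / (len(remaining) - 1)
        worst = int(np.argmin(mean_sim))
        if mean_sim[worst] >= threshold:
            break
        idx = remaining[worst]
        sim_at_decision[idx] = float(mean_sim[worst])
        excluded_idx.append(idx)
        remaining.remove(idx)
    sub = corr[np.ix_(remaining, remaining)]
    final = (sub.sum(axis=1) - 1.0) / (len(remaining) - 1)
    for pos, idx in enumerate(remaining):
        sim_at_decision[idx] = float(final[pos])
    sim = pd.Series([sim_at_decision[i] for i in range(n)], index=samples)
    return OutlierReport(
        similarity=sim,
        excluded=[samples[i] for i in sorted(excluded_idx)],
        threshold=threshold,
    )


def standardize_for_heatmap(
    de: DETable, panel: list[str], clip: float = DEFAULT_CLIP
) -> tuple[pd.DataFrame, list[str]]:
    """Clip panel lgFC values to [-clip, +clip] for heat-map display.

    Rows follow panel order.  Genes absent from the table are returned in
    the second element rather than silently dropped.
    """
    if not panel:
        raise ValueError("empty gene panel")
    present = [g for g in panel if g in de.table.index]
    missing = [g for g in panel if g not in de.table.index]
    clipped = de.table.loc[present, ["lgFC"]].clip(lower=-clip, upper=clip)
    clipped.columns = ["lgFC_clipped"]
    return clipped, missing


def plot_heatmap(panel_matrix: pd.DataFrame, path, clip: float = DEFAULT_CLIP) -> None:
    """Optional blue-white-red panel figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * panel_matrix.shape[1], 0.4 * len(panel_matrix) + 1.0)
    )
    im = ax.imshow(
        panel_matrix.to_numpy(), cmap="bwr", vmin=-clip, vmax=clip, aspect="auto"
    )
    ax.set_yticks(range(len(panel_matrix)), panel_matrix.index)
    ax.set_xticks(range(panel_matrix.shape[1]), panel_matrix.columns, rotation=45)
    fig.colorbar(im, ax=ax, label="log2 FC (clipped)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
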