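"""Relative qPCR quantification against a reference gene.

Replicate Ct values (threshold cycles) are averaged per (sample, gene) on
the Ct scale, converted to relative expression against a reference gene
measured in the same sample,

    rel_expr = 2^-Ct(target) / 2^-Ct(reference) = 2^(Ct_ref - Ct_target),

and condition fold change is the ratio of condition means of those
per-sample relative expressions.  Perfect amplification efficiency is
assumed: one cycle = one doubling.  Sample-wide efficiency shifts cancel
through the reference gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, GroupingError

CONDITIONS = ("ctrl", "case")


@dataclass
class CtTable:
    """Ct replicates per (sample, gene) with a designated reference gene.

    ``data`` is long-form with columns sample_id, condition, pair_id
    (nullable), gene_id, and one or more replicate columns ct_1..ct_n
    (NaN where a sample has fewer replicates).
    """

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "gene_id"}
        missing = required - set(self.data.columns)
        if missing:
            raise ConsistencyError(f"CtTable missing columns: {sorted(missing)}")
        self.ct_columns = [c for c in self.data.columns if c.startswith("ct_")]
        if not self.ct_columns:
            raise ConsistencyError("CtTable has no ct_* replicate columns")
        cts = self.data[self.ct_columns].to_numpy(dtype=float)
        if np.nanmin(cts) <= 0 or not np.isfinite(cts[~np.isnan(cts)]).all():
            raise ConsistencyError("Ct values must be positive and finite")
        if self.data[self.ct_columns].isna().all(axis=1).any():
            raise ConsistencyError("every (sample, gene) row needs >= 1 replicate")
        bad = set(self.data["condition"]) - set(CONDITIONS)
        if bad:
            raise ConsistencyError(f"unknown conditions {sorted(bad)}")
        for sid, sub in self.data.groupby("sample_id"):
            if self.reference_gene not in set(sub["gene_id"]):
                raise ConsistencyError(
                    f"reference gene {self.reference_gene!r} not measured in "
                    f"sample {sid!r}"
                )

    def mean_ct(self, sample_id: str, gene_id: str) -> float:
        """Replicates averaged arithmetically on the Ct scale."""
        rows = self.data[
            (self.data["sample_id"] == sample_id) & (self.data["gene_id"] == gene_id)
        ]
        if rows.empty:
            raise ConsistencyError(
                f"gene {gene_id!r} not measured in sample {sample_id!r}"
            )
        return float(np.nanmean(rows[self.ct_columns].to_numpy(dtype=float)))


def read_ct_tsv(path, reference_gene: str) -> CtTable:
    df = pd.read_csv(path, sep="\t")
    return CtTable(data=df, reference_gene=reference_gene)


def write_ct_tsv(table: CtTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^-Ct(target) / 2^-Ct(reference); one cycle difference = two-fold."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_reference - ct_target)


def sample_relative_expression(table: CtTable, gene_id: str) -> pd.DataFrame:
    """Per-sample relative expression of one gene against the reference.

    Returns a frame with columns sample_id, condition, pair_id, rel_expr.
    """
    rows = []
    meta = table.data[["sample_id", "condition"]].drop_duplicates("sample_id")
    pair_col = "pair_id" if "pair_id" in table.data.columns else None
    for _, m in meta.iterrows():
        sid = m["sample_id"]
        sub = table.data[
            (table.data["sample_id"] == sid) & (table.data["gene_id"] == gene_id)
        ]
        if sub.empty:
            continue
        rel = relative_expression(
            table.mean_ct(sid, gene_id), table.mean_ct(sid, table.reference_gene)
        )
        pair = sub.iloc[0][pair_col] if pair_col else None
        rows.append(
            {"sample_id": sid, "condition": m["condition"], "pair_id": pair, "rel_expr": rel}
        )
    if not rows:
        raise GroupingError(f"gene {gene_id!r} not measured in any sample")
    return pd.DataFrame(rows)


def fold_change(
    table: CtTable, gene_id: str, paired: bool = False
) -> tuple[float, pd.DataFrame]:
    """Condition fold change of one gene (case over ctrl).

    Unpaired: ratio of condition means of per-sample relative expressions.
    Paired: per-pair case/ctrl ratios averaged (requires pair_id on every
    sample and both conditions within each pair).
    """
    per_sample = sample_relative_expression(table, gene_id)
    have = set(per_sample["condition"])
    if not {"ctrl", "case"} <= have:
        raise GroupingError(
            f"gene {gene_id!r} absent from condition(s) "
            f"{sorted({'ctrl', 'case'} - have)}"
        )
    if paired:
        if per_sample["pair_id"].isna().any():
            raise GroupingError("paired mode requires pair_id on every sample")
        ratios = []
        for pid, sub in per_sample.groupby("pair_id"):
            ctrl = sub[sub["condition"] == "ctrl"]["rel_expr"]
            case = sub[sub["condition"] == "case"]["rel_expr"]
            if ctrl.empty or case.empty:
                raise GroupingError(f"pair {pid!r} missing one condition")
            ratios.append(case.mean() / ctrl.mean())
        fc = float(np.mean(ratios))
    else:
        ctrl = per_sample[per_sample["condition"] == "ctrl"]["rel_expr"]
        case = per_sample[per_sample["condition"] == "case"]["rel_expr"]
        fc = float(case.mean() / ctrl.mean())
    return fc, per_sample
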