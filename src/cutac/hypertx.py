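"""Tumor-vs-normal RNAPII difference scoring per interval.

Hypertranscription of an interval is the excess of normalized tumor signal
over the matched normal (T - N, in normalized count units, after depth
equalization upstream). Rankings are by T - N descending; log10((T+N)/2 + eps)
is carried for the standard MA-style scatter.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import SignalMatrix
from .peaks import PeakSet, overlap_with_intervals

DEFAULT_EPSILON = 1e-3


def _rank_by_diff(df: pd.DataFrame) -> np.ndarray:
    """Dense 1..n ranks by diff descending; ties broken by (chrom, start)."""
    order = np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy(),
                        -df["diff"].to_numpy()))
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(1, len(df) + 1)
    return ranks


def pair_diff(matrix: SignalMatrix, tumor_id: str, normal_id: str,
              epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Per-interval T, N, diff = T - N, mean_log and rank for one pair."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    for sid in (tumor_id, normal_id):
        if sid not in matrix.values.index:
            raise KeyError(f"sample {sid!r} not in matrix")
    t = matrix.sample_vector(tumor_id)
    n = matrix.sample_vector(normal_id)
    df = matrix.intervals.reset_index(drop=True).copy()
    df["T"] = t
    df["N"] = n
    df["diff"] = t - n
    df["mean_log"] = np.log10((t + n) / 2.0 + epsilon)
    df["rank"] = _rank_by_diff(df)
    df.attrs["tumor_id"] = tumor_id
    df.attrs["normal_id"] = normal_id
    return df


def max_diffs(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise maximum of T - N across pairs, with the argmax pair."""
    if not tables:
        raise ValueError("need at least one pair table")
    ref_ids = tables[0]["id"].to_numpy()
    diffs = []
    for tab in tables:
        if not np.array_equal(tab["id"].to_numpy(), ref_ids):
            raise ValueError("pair tables cover different interval universes")
        diffs.append(tab["diff"].to_numpy())
    stack = np.vstack(diffs)
    winner = stack.argmax(axis=0)
    pair_ids = [t.attrs.get("tumor_id", f"pair{i + 1}")
                for i, t in enumerate(tables)]
    out = tables[0][["chrom", "start", "end", "id", "category"]].copy()
    out["diff"] = stack.max(axis=0)
    out["argmax_pair"] = [pair_ids[w] for w in winner]
    out["rank"] = _rank_by_diff(out)
    return out


def category_profiles(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-category views with ranks recomputed within each category."""
    views = {}
    for cat, grp in table.groupby("category", sort=True):
        view = grp.reset_index(drop=True).copy()
        view["rank"] = _rank_by_diff(view)
        views[cat] = view
    return views


def _nearest_gene(table: pd.DataFrame,
                  gene_spans: pd.DataFrame) -> tuple[list, np.ndarray]:
    """Nearest gene by span-midpoint distance to the interval midpoint."""
    names: list[Optional[str]] = []
    dists = np.full(len(table), np.nan)
    by_chrom = {}
    for chrom, grp in gene_spans.groupby("chrom"):
        mids = ((grp["start"] + grp["end"]) / 2).to_numpy()
        order = np.argsort(mids)
        by_chrom[chrom] = (mids[order], grp["id"].to_numpy()[order])
    for i, rec in enumerate(table.itertuples(index=False)):
        if rec.chrom not in by_chrom:
            names.append(None)
            continue
        mids, ids = by_chrom[rec.chrom]
        mid = (rec.start + rec.end) / 2
        j = np.clip(np.searchsorted(mids, mid), 0, mids.size - 1)
        j = min((jj for jj in (j - 1, j) if jj >= 0),
                key=lambda jj: abs(mids[jj] - mid))
        names.append(str(ids[j]))
        dists[i] = abs(mids[j] - mid)
    return names, dists


def top_k_report(table: pd.DataFrame, k: int,
                 gene_spans: Optional[pd.DataFrame] = None,
                 peaksets: Sequence[PeakSet] = ()) -> pd.DataFrame:
    """Top-k intervals by T - N with gene and peak-overlap annotations."""
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    top = (table.sort_values("rank").head(k).reset_index(drop=True))
    if gene_spans is not None and len(gene_spans):
        names, dists = _nearest_gene(top, gene_spans)
        top["nearest_gene"] = names
        top["nearest_gene_dist"] = dists
    if peaksets:
        flags = overlap_with_intervals(peaksets,
                                       top[["chrom", "start", "end", "id"]])
        top["n_peaksets"] = flags["n_peaksets"].to_numpy()
    return top
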