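"""Recurrence-free survival separation and whole-arm aneuploidy inference.

Biomarker groupings split patients into a "malignant" top-k group by a
biomarker value (histone-gene signal, ribosomal-gene signal, chrM fraction,
or arm status) and compare recurrence-free survival by Kaplan-Meier curves
and the log-rank test, scanning all top-k thresholds. Whole-arm dosage is
called per patient from the relative mean signal of an arm's intervals
against the median of per-arm means; the fraction of an arm's cCREs with
exactly zero signal ("null occupancy") rises with arm loss and falls with
gain, so its per-arm Spearman correlation with the histone signature, with
a patient-resampling bootstrap SD, reproduces the sign logic linking
histone-gene hypertranscription to whole-arm losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy.stats import spearmanr

from .coverage import SignalMatrix
from .genome import GenomeModel

MIN_INTERVALS_PER_ARM = 10


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]   # group -> (time, survival)
    p_value: float
    statistic: float


def _as_records(records: pd.DataFrame) -> pd.DataFrame:
    need = {"recurrence_months", "event"}
    if not need <= set(records.columns):
        raise ValueError(f"records must have columns {need}")
    return records


def km_logrank(records: pd.DataFrame, groups: pd.Series) -> KMResult:
    """Product-limit curves per group and the two-sided log-rank p."""
    records = _as_records(records)
    names = pd.unique(groups)
    if len(names) != 2:
        raise ValueError("need exactly two groups")
    curves = {}
    masks = {}
    for name in names:
        mask = (groups == name).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {name!r} is empty")
        sub = records[mask]
        if sub["event"].sum() == 0:
            warnings.warn(f"group {name!r} has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["recurrence_months"], sub["event"], label=str(name))
        curves[str(name)] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(name): "survival"})
        masks[str(name)] = mask
    a, b = [records[masks[str(n)]] for n in names]
    res = logrank_test(a["recurrence_months"], b["recurrence_months"],
                       event_observed_A=a["event"],
                       event_observed_B=b["event"])
    return KMResult(curves=curves, p_value=float(res.p_value),
                    statistic=float(res.test_statistic))


def top_k_groups(values: pd.Series, k: int,
                 direction: str = "high") -> pd.Series:
    """Label the top-k patients by value as 'malignant', rest 'benign'.

    ``direction='high'`` means high values are putatively malignant. Ties at
    the k-th value are broken deterministically by patient id.
    """
    v = values.sort_index()
    asc = direction == "low"
    order = v.reset_index()
    order.columns = ["patient", "value"]
    order = order.sort_values(["value", "patient"],
                              ascending=[asc, True]).reset_index(drop=True)
    malignant = set(order["patient"].iloc[:k])
    return pd.Series(["malignant" if p in malignant else "benign"
                      for p in values.index], index=values.index)


def threshold_scan(records: pd.DataFrame, values: pd.Series,
                   direction: str = "high",
                   k_range: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Log-rank p for every top-k malignant/benign split."""
    records = _as_records(records)
    n = len(values)
    if k_range is None:
        k_range = range(2, n - 1)
    rows = []
    for k in k_range:
        if not 1 <= k <= n - 1:
            raise ValueError(f"k={k} outside [1, n-1]")
        groups = top_k_groups(values, k, direction)
        res = km_logrank(records, groups)
        rows.append({"k": k, "p": res.p_value,
                     "direction_ok": _direction_ok(records, groups)})
    return pd.DataFrame(rows)


def _direction_ok(records: pd.DataFrame,
                  groups: pd.Series) -> Optional[bool]:
    """True if the malignant group's survival is worse (lower RMST)."""
    horizon = float(records["recurrence_months"].max())
    rmst = {}
    for name in ("malignant", "benign"):
        sub = records[(groups == name).to_numpy()]
        kmf = KaplanMeierFitter().fit(sub["recurrence_months"], sub["event"])
        rmst[name] = float(restricted_mean_survival_time(kmf, t=horizon))
    if np.isclose(rmst["malignant"], rmst["benign"]):
        return None
    return rmst["malignant"] < rmst["benign"]


def direction_check(records: pd.DataFrame, values: pd.Series,
                    scan: pd.DataFrame,
                    direction: str = "high") -> pd.DataFrame:
    """Annotate a threshold scan with curve-order validity per k."""
    out = scan.copy()
    flags = []
    for k in out["k"]:
        groups = top_k_groups(values, int(k), direction)
        flags.append(_direction_ok(records, groups))
    out["direction_ok"] = flags
    return out


# -- arm dosage -----------------------------------------------------------


def _interval_arms(intervals: pd.DataFrame,
                   genome: GenomeModel) -> np.ndarray:
    mids = ((intervals["start"] + intervals["end"]) // 2).to_numpy()
    chroms = intervals["chrom"].to_numpy()
    arms = np.empty(len(intervals), dtype=object)
    arms[:] = None
    for a in genome.analyzed_arms():
        sel = (chroms == a.chrom) & (mids >= a.start) & (mids < a.end)
        arms[sel] = a.name
    return arms


def arm_dosage(matrix: SignalMatrix, genome: GenomeModel,
               gain_delta: float = 0.25, loss_delta: float = 0.25,
               null_fractions: bool = True) -> pd.DataFrame:
    """Per sample x arm relative dosage, gain/loss call and null fraction.

    dosage(arm) = mean(signal of intervals on arm) / median over arms of
    those means, per sample; gain if dosage >= 1 + gain_delta, loss if
    <= 1 - loss_delta. Arms with fewer than 10 intervals get NA calls.
    ``null_fractions`` additionally reports the fraction of the arm's
    intervals with exactly zero signal (meaningful for cCRE matrices).
    """
    if not (0 < gain_delta < 1 and 0 < loss_delta < 1):
        raise ValueError("deltas must lie in (0, 1)")
    arms = _interval_arms(matrix.intervals, genome)
    rows = []
    arm_names = [a.name for a in genome.analyzed_arms()]
    for sid in matrix.values.index:
        v = matrix.sample_vector(sid)
        means = {}
        for name in arm_names:
            sel = arms == name
            if sel.sum() >= 1:
                means[name] = float(v[sel].mean())
        ref = float(np.median([m for m in means.values()]))
        for name in arm_names:
            sel = arms == name
            n_iv = int(sel.sum())
            if name not in means or ref == 0:
                continue
            dosage = means[name] / ref if ref > 0 else np.nan
            if n_iv < MIN_INTERVALS_PER_ARM:
                call = None
            elif dosage >= 1 + gain_delta:
                call = "gain"
            elif dosage <= 1 - loss_delta:
                call = "loss"
            else:
                call = "neutral"
            row = {"sample": sid, "arm": name, "n_intervals": n_iv,
                   "dosage": dosage, "call": call}
            if null_fractions:
                row["null_fraction"] = float((v[sel] == 0).mean())
            rows.append(row)
    return pd.DataFrame(rows)


def rnaseq_arm_matrix(rnaseq: pd.DataFrame,
                      genome: GenomeModel) -> SignalMatrix:
    """Wrap a genes x samples count table as a gene-span SignalMatrix so the
    same dosage operation applies to RNA-seq (counts per gene, per-sample
    scale removed by the median-of-arm-means reference)."""
    spans = genome.gene_spans_frame()
    spans = spans[spans["id"].isin(rnaseq.index)].reset_index(drop=True)
    spans["category"] = "gene"
    values = rnaseq.loc[spans["id"]].T
    values.columns = spans["id"]
    return SignalMatrix(values=values.astype(float), intervals=spans,
                        interval_kind="gene_span")


def histone_vs_aneuploidy(scores: pd.Series,
                          dosage_table: pd.DataFrame) -> dict:
    """Spearman of the histone signature vs counts of arm gains and losses."""
    if len(scores) < 5:
        raise ValueError("need >= 5 patients")
    counts = (dosage_table.groupby("sample")["call"]
              .agg(gains=lambda s: (s == "gain").sum(),
                   losses=lambda s: (s == "loss").sum()))
    counts = counts.reindex(scores.index)
    out = {}
    for what in ("gains", "losses"):
        x = counts[what].to_numpy(float)
        if np.unique(x[~np.isnan(x)]).size <= 1:
            out[f"r_{what}"], out[f"p_{what}"] = float("nan"), float("nan")
        else:
            r, p = spearmanr(scores.to_numpy(float), x)
            out[f"r_{what}"], out[f"p_{what}"] = float(r), float(p)
    out["counts"] = counts
    return out


def per_arm_null_correlation(scores: pd.Series, dosage_table: pd.DataFrame,
                             n_bootstrap: int = 1000,
                             seed: int = 0) -> pd.DataFrame:
    """Per-arm Spearman(histone score, null cCRE fraction) across patients.

    SD is a patient-resampling bootstrap (default 1000 replicates); p comes
    from the asymptotic rank test; stars at 0.05/0.01/0.001. The summary
    count of positive-rho arms is in ``attrs['n_positive']``.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    rng = np.random.default_rng(seed)
    rows = []
    for arm, grp in dosage_table.groupby("arm", sort=True):
        nf = grp.set_index("sample")["null_fraction"].reindex(scores.index)
        x = scores.to_numpy(float)
        y = nf.to_numpy(float)
        ok = ~np.isnan(y)
        x, y = x[ok], y[ok]
        if np.unique(y).size <= 1 or x.size < 5:
            rows.append({"arm": arm, "rho": np.nan, "sd": np.nan,
                         "p": np.nan, "stars": ""})
            continue
        rho, p = spearmanr(x, y)
        boots = np.empty(n_bootstrap)
        n = x.size
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size <= 1 or np.unique(x[idx]).size <= 1:
                boots[b] = np.nan
                continue
            boots[b] = spearmanr(x[idx], y[idx])[0]
        sd = float(np.nanstd(boots))
        stars = ("***" if p < 0.001 else "**" if p < 0.01
                 else "*" if p < 0.05 else "")
        rows.append({"arm": arm, "rho": float(rho), "sd": sd,
                     "p": float(p), "stars": stars})
    out = pd.DataFrame(rows)
    out.attrs["n_positive"] = int((out["rho"] > 0).sum())
    return out


def biomarker_report(groupings: dict[str, tuple[pd.Series, str]],
                     records: pd.DataFrame,
                     k_range: Sequence[int]) -> pd.DataFrame:
    """Side-by-side log-rank p per biomarker per top-k threshold.

    ``groupings`` maps biomarker name -> (per-patient values, direction).
    The scan is exploratory: p-values are reported uncorrected across k.
    """
    frames = []
    for name, (values, direction) in groupings.items():
        scan = threshold_scan(records, values, direction, k_range)
        scan.insert(0, "biomarker", name)
        frames.append(scan)
    return pd.concat(frames, ignore_index=True)
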