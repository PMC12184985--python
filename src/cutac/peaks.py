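"""Sparse-enrichment peak calling with the matched normal as control.

Signal blocks are maximal runs of strictly positive normalized depth. The
enrichment threshold is chosen on block *totals* (area under the block): over
candidate thresholds t (the unique block totals of target and control
pooled), compute the fraction of target blocks and of control blocks with
total >= t and pick the t maximizing that difference. ``relaxed`` mode takes
the smallest t attaining the maximum, ``stringent`` (default) the largest.

If the maximum achievable separation does not exceed ``min_separation``
(as a fraction of blocks), the target is declared not enriched over the
control and the threshold is set to the largest observed total, so at most
one block passes — this is the behavior expected of a control-dominated or
null comparison, where the raw argmax would otherwise sit on sampling noise.

Blocks should be built from depth-equalized, normalized tracks so the two
samples are compared on an equal footing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, FragmentSet, coverage, equalize_depth
from .genome import GenomeModel

logger = logging.getLogger("cutac")

DEFAULT_MIN_SEPARATION = 0.005


@dataclass
class SignalBlock:
    chrom: str
    start: int
    end: int
    total_signal: float
    max_signal: float


@dataclass
class PeakSet:
    peaks: list[SignalBlock]
    threshold: float
    mode: str
    merged: bool = False
    merge_gap: int = 0

    def __len__(self) -> int:
        return len(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.chrom, p.start, p.end, p.total_signal, p.max_signal)
             for p in self.peaks],
            columns=["chrom", "start", "end", "total_signal", "max_signal"])

    def write_meta(self, path) -> None:
        """Auxiliary JSON with the selected threshold and calling mode."""
        import json

        with open(path, "w") as fh:
            json.dump({"threshold": self.threshold, "mode": self.mode,
                       "merged": self.merged, "merge_gap": self.merge_gap,
                       "n_peaks": len(self.peaks)}, fh, indent=1)

    def write_bed(self, path) -> None:
        """BED6: name = peak rank by total signal, score = total (4 dp)."""
        order = np.argsort([-p.total_signal for p in self.peaks])
        rank = np.empty(len(self.peaks), dtype=int)
        rank[order] = np.arange(1, len(self.peaks) + 1)
        with open(path, "w") as fh:
            for p, r in zip(self.peaks, rank):
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{r}\t"
                         f"{p.total_signal:.4f}\t.\n")


def signal_blocks(track: CoverageTrack) -> list[SignalBlock]:
    """Maximal runs of strictly positive depth, with totals and maxima."""
    blocks: list[SignalBlock] = []
    for chrom in sorted(track.values):
        v = track.values[chrom]
        pos = v > 0
        if not pos.any():
            continue
        # run boundaries: starts where pos flips 0->1, ends where 1->0
        flips = np.diff(np.concatenate([[0], pos.view(np.int8), [0]]))
        run_starts = np.flatnonzero(flips == 1)
        run_ends = np.flatnonzero(flips == -1)
        csum = np.concatenate([[0.0], np.cumsum(v)])
        totals = csum[run_ends] - csum[run_starts]
        maxima = np.maximum.reduceat(v, run_starts)
        for s, e, t, m in zip(run_starts, run_ends, totals, maxima):
            blocks.append(SignalBlock(chrom, int(s), int(e), float(t),
                                      float(m)))
    return blocks


def _cdf_mismatch(t_sorted: np.ndarray, c_scaled_sorted: np.ndarray) -> float:
    """Integrated |F_target - F_control| over log block total."""
    grid = np.unique(np.concatenate([t_sorted, c_scaled_sorted]))
    ft = np.searchsorted(t_sorted, grid, side="right") / t_sorted.size
    fc = (np.searchsorted(c_scaled_sorted, grid, side="right")
          / c_scaled_sorted.size)
    lg = np.log(grid)
    return float(np.trapezoid(np.abs(ft - fc), lg))


def _control_scale(t_tot: np.ndarray, c_tot: np.ndarray) -> float:
    """Scale aligning the control block-total distribution to the target's.

    Chosen to minimize the integrated CDF distance between the target
    totals and the scaled control totals (coarse log-grid search around the
    quantile ratios, then two refinement passes). Superimposing the
    distributions this way removes global scale offsets — e.g. from
    per-track normalization when one sample concentrates extra mass in a
    few loci — while an enriched minority of blocks, being a small fraction
    of either distribution, cannot drag the alignment.
    """
    t_sorted = np.sort(t_tot)
    c_sorted = np.sort(c_tot)
    qs = np.array([0.25, 0.5, 0.75])
    seeds = np.log(np.quantile(t_sorted, qs) / np.quantile(c_sorted, qs))
    lo, hi = seeds.min() - 0.3, seeds.max() + 0.3

    def cost(log_s: float) -> float:
        return _cdf_mismatch(t_sorted, c_sorted * np.exp(log_s))

    best, step = lo, (hi - lo) / 40
    grid = np.linspace(lo, hi, 41)
    best = grid[int(np.argmin([cost(x) for x in grid]))]
    for _ in range(2):
        fine = np.linspace(best - step, best + step, 21)
        best = fine[int(np.argmin([cost(x) for x in fine]))]
        step /= 10.0
    # depth-equalized pairs are scale-matched by construction and their
    # single-fragment block totals sit on a shared quantized grid; a sub-2%
    # "optimal" offset only misaligns that grid, so snap it to identity
    if abs(best) < 0.02:
        return 1.0
    return float(np.exp(best))


def select_threshold(target_blocks: Sequence[SignalBlock],
                     control_blocks: Sequence[SignalBlock],
                     mode: str = "stringent",
                     min_separation: float = DEFAULT_MIN_SEPARATION,
                     normalize_control: bool = True,
                     control_tolerance: float = 0.01) -> float:
    """Block-total threshold maximizing target-vs-control survival gap.

    With ``normalize_control`` (default, the published method's "norm"
    behavior) control totals are first rescaled to superimpose the two
    block-total distributions (see :func:`_control_scale`), so a global
    scale offset between the samples — e.g. from per-track normalization
    when one sample concentrates extra signal in a few loci — cannot
    masquerade as genome-wide enrichment. Control blocks within
    ``control_tolerance`` (relative) below a candidate still count as
    passing it, so residual alignment error cannot turn a shared block into
    apparent enrichment.
    """
    if mode not in ("stringent", "relaxed"):
        raise ValueError("mode must be 'stringent' or 'relaxed'")
    if not target_blocks or not control_blocks:
        raise ValueError("both block lists must be non-empty")
    t_tot = np.sort([b.total_signal for b in target_blocks])
    c_tot = np.sort([b.total_signal for b in control_blocks])
    if normalize_control:
        c_tot = c_tot * _control_scale(t_tot, c_tot)
    cand = np.unique(np.concatenate([t_tot, c_tot]))
    if cand.size == 1:
        warnings.warn("all block totals equal; threshold degenerate")
        return float(cand[0])
    # survival fractions: fraction of blocks with total >= t
    f_t = 1.0 - np.searchsorted(t_tot, cand, side="left") / t_tot.size
    f_c = 1.0 - np.searchsorted(
        c_tot, cand * (1.0 - control_tolerance), side="left") / c_tot.size
    d = f_t - f_c
    d_max = float(d.max())
    if d_max <= min_separation:
        logger.info("no separation above control (max gap %.4f); "
                    "returning max total", d_max)
        return float(cand[-1])
    argmax = np.flatnonzero(d >= d_max - 1e-9)  # float-safe tie set
    pick = argmax[-1] if mode == "stringent" else argmax[0]
    return float(cand[pick])


def _merge_blocks(blocks: list[SignalBlock], gap: int) -> list[SignalBlock]:
    merged: list[SignalBlock] = []
    for b in sorted(blocks, key=lambda x: (x.chrom, x.start)):
        if (merged and merged[-1].chrom == b.chrom
                and b.start - merged[-1].end < gap):
            last = merged[-1]
            merged[-1] = SignalBlock(last.chrom, last.start, b.end,
                                     last.total_signal + b.total_signal,
                                     max(last.max_signal, b.max_signal))
        else:
            merged.append(b)
    return merged


def call_peaks(tumor_track: CoverageTrack, normal_track: CoverageTrack,
               mode: str = "stringent", merge_gap: Optional[int] = None,
               min_separation: float = DEFAULT_MIN_SEPARATION,
               normalize_control: bool = True) -> PeakSet:
    """Call tumor peaks using the matched normal as background control.

    Mitochondrial blocks are excluded: chrM is a single saturated block in
    any sample and carries no positional enrichment information.
    """
    t_blocks = [b for b in signal_blocks(tumor_track)
                if b.chrom != tumor_track.mito_name]
    n_blocks = [b for b in signal_blocks(normal_track)
                if b.chrom != normal_track.mito_name]
    if not t_blocks:
        warnings.warn("tumor track has no signal; empty peak set")
        return PeakSet([], threshold=float("inf"), mode=mode)
    if not n_blocks:
        # no control signal at all: everything is enrichment
        thr = min(b.total_signal for b in t_blocks)
    else:
        thr = select_threshold(t_blocks, n_blocks, mode, min_separation,
                               normalize_control)
    kept = [b for b in t_blocks if b.total_signal >= thr]
    merged = False
    if merge_gap:
        kept = _merge_blocks(kept, merge_gap)
        merged = True
    return PeakSet(peaks=kept, threshold=thr, mode=mode, merged=merged,
                   merge_gap=merge_gap or 0)


def paired_peaks(tumor: FragmentSet, normal: FragmentSet, genome: GenomeModel,
                 seed: int = 0, mode: str = "stringent",
                 merge_gap: Optional[int] = None,
                 min_separation: float = DEFAULT_MIN_SEPARATION) -> PeakSet:
    """Equalize depths, build normalized tracks and call tumor peaks."""
    t_eq, n_eq = equalize_depth(tumor, normal, seed)
    return call_peaks(coverage(t_eq, genome), coverage(n_eq, genome),
                      mode=mode, merge_gap=merge_gap,
                      min_separation=min_separation)


def swap_control_counts(pairs: Sequence[tuple[FragmentSet, FragmentSet]],
                        genome: GenomeModel, seed: int = 0,
                        mode: str = "stringent") -> pd.DataFrame:
    """Peak counts per pair in both orientations, with medians appended.

    Row per pair: peaks calling tumor with normal as control (t_vs_n) and
    the swapped orientation (n_vs_t); a final "median" row summarizes.
    """
    rows = []
    for i, (t, n) in enumerate(pairs):
        t_eq, n_eq = equalize_depth(t, n, seed + i)
        t_cov, n_cov = coverage(t_eq, genome), coverage(n_eq, genome)
        rows.append({"pair_id": t.pair_id or f"pair{i + 1}",
                     "t_vs_n": len(call_peaks(t_cov, n_cov, mode=mode)),
                     "n_vs_t": len(call_peaks(n_cov, t_cov, mode=mode))})
    df = pd.DataFrame(rows)
    med = {"pair_id": "median",
           "t_vs_n": float(df["t_vs_n"].median()),
           "n_vs_t": float(df["n_vs_t"].median())}
    return pd.concat([df, pd.DataFrame([med])], ignore_index=True)


def overlap_with_intervals(peaksets: Sequence[PeakSet],
                           intervals: pd.DataFrame) -> pd.DataFrame:
    """Any-overlap (>= 1 bp, half-open) flags per interval per peak set.

    Returns the interval frame with one boolean column per peak set and a
    ``n_peaksets`` multiplicity column (how many sets hit each interval).
    """
    out = intervals.reset_index(drop=True).copy()
    hits_total = np.zeros(len(out), dtype=int)
    for k, ps in enumerate(peaksets):
        hit = np.zeros(len(out), dtype=bool)
        by_chrom: dict[str, list[SignalBlock]] = {}
        for p in ps.peaks:
            by_chrom.setdefault(p.chrom, []).append(p)
        for chrom, plist in by_chrom.items():
            starts = np.array([p.start for p in plist])
            ends = np.array([p.end for p in plist])
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            sel = out["chrom"] == chrom
            for i in np.flatnonzero(sel.to_numpy()):
                s, e = out.at[i, "start"], out.at[i, "end"]
                j = np.searchsorted(starts, e, side="left")
                if j > 0 and (ends[:j] > s).any():
                    hit[i] = True
        out[f"set{k + 1}"] = hit
        hits_total += hit.astype(int)
    out["n_peaksets"] = hits_total
    return out
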