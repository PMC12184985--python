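"""Fragment files to genome-scaled coverage and interval signal matrices.

Normalization convention: per-base depth is the number of fragments spanning
the base; each track is rescaled so the mean depth over all *non-mitochondrial*
bases is exactly 1 (the mitochondrion carries the same scale factor but is
excluded from the denominator, so variable mtDNA content cannot distort
nuclear signal). chrX would be included and chrY excluded from the denominator
if present; the miniature genomes used here carry neither.

Two equivalent aggregation engines are provided: a per-base array path
(used for peak calling and dense bin tilings) and a fragment-overlap path
(used for sparse interval sets such as cCREs and gene spans). Both compute
value(interval) = mean normalized depth over the interval's bases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .genome import GenomeModel, ValidationError

logger = logging.getLogger("cutac")

BIN_KINDS = {"bin500": 500, "bin1000": 1000}
INTERVAL_KINDS = ("ccre", "bin500", "bin1000", "gene_span")


@dataclass(eq=False)
class FragmentSet:
    """One sample's mapped fragments (BED3-like) plus metadata."""

    sample_id: str
    frags: pd.DataFrame  # columns chrom, start, end; sorted by (chrom, start)
    role: str = "tumor"  # tumor | normal
    pair_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frags = (self.frags.sort_values(["chrom", "start", "end"])
                      .reset_index(drop=True))

    @property
    def total_count(self) -> int:
        return len(self.frags)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for chrom, grp in self.frags.groupby("chrom", sort=True):
            out[chrom] = (grp["start"].to_numpy(np.int64),
                          grp["end"].to_numpy(np.int64))
        return out


@dataclass(eq=False)
class CoverageTrack:
    """Per-chromosome arrays of normalized per-base depth."""

    values: dict[str, np.ndarray]
    scale_factor: float
    mito_name: str

    def nonmito_mean(self) -> float:
        tot = sum(float(v.sum()) for c, v in self.values.items()
                  if c != self.mito_name)
        n = sum(v.size for c, v in self.values.items() if c != self.mito_name)
        return tot / n


@dataclass(eq=False)
class SignalMatrix:
    """samples x intervals matrix of mean normalized depth.

    ``values``: DataFrame, index = sample ids, columns = interval ids.
    ``intervals``: DataFrame with columns chrom, start, end, id, category,
    aligned with the value columns.
    """

    values: pd.DataFrame
    intervals: pd.DataFrame
    interval_kind: str

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.values.loc[sample_id].to_numpy(float)

    def to_tsv(self, path) -> None:
        out = self.intervals.copy()
        for sid in self.values.index:
            out[sid] = self.values.loc[sid].to_numpy()
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")


# -- fragment I/O ---------------------------------------------------------


def read_fragments(path, genome: GenomeModel, sample_id: Optional[str] = None,
                   **meta) -> FragmentSet:
    """Read and validate a BED3(+) fragment file; output is sorted."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    return validate_fragments(df, genome,
                              sample_id=sample_id or str(path), **meta)


def validate_fragments(df: pd.DataFrame, genome: GenomeModel, sample_id: str,
                       **meta) -> FragmentSet:
    unknown = set(df["chrom"]) - set(genome.chrom_sizes)
    if unknown:
        raise ValidationError(f"unknown chromosome(s) in fragments: "
                              f"{sorted(unknown)}")
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} fragment(s) with start >= end, first: "
            f"{df[bad].iloc[0].tolist()}")
    if (df["start"] < 0).any():
        raise ValidationError("negative fragment start")
    sizes = df["chrom"].map(genome.chrom_sizes)
    if (df["end"] > sizes).any():
        raise ValidationError("fragment end beyond chromosome length")
    role = meta.pop("role", "tumor")
    pair_id = meta.pop("pair_id", "")
    return FragmentSet(sample_id=sample_id, frags=df, role=role,
                       pair_id=pair_id, meta=meta)


def pool_fragments(fragsets: Iterable[FragmentSet], sample_id: str,
                   **meta) -> FragmentSet:
    """Concatenate replicate fragment sets (e.g. slides from one block)."""
    fragsets = list(fragsets)
    df = pd.concat([fs.frags for fs in fragsets], ignore_index=True)
    role = meta.pop("role", fragsets[0].role)
    pair_id = meta.pop("pair_id", fragsets[0].pair_id)
    return FragmentSet(sample_id=sample_id, frags=df, role=role,
                       pair_id=pair_id, meta=meta)


def equalize_depth(a: FragmentSet, b: FragmentSet,
                   seed: int) -> tuple[FragmentSet, FragmentSet]:
    """Down-sample the larger set (without replacement) to the smaller's count.

    Deterministic given ``seed``; equal counts are returned unchanged.
    """
    if a.total_count == b.total_count:
        return a, b
    rng = np.random.default_rng(seed)
    big, small = (a, b) if a.total_count > b.total_count else (b, a)
    keep = np.sort(rng.choice(big.total_count, size=small.total_count,
                              replace=False))
    sub = FragmentSet(sample_id=big.sample_id,
                      frags=big.frags.iloc[keep].reset_index(drop=True),
                      role=big.role, pair_id=big.pair_id, meta=dict(big.meta))
    return (sub, small) if big is a else (small, sub)


# -- coverage -------------------------------------------------------------


def _raw_depth(starts: np.ndarray, ends: np.ndarray, length: int) -> np.ndarray:
    """Per-base fragment depth via start/end event accumulation."""
    delta = np.zeros(length + 1, dtype=np.float64)
    np.add.at(delta, starts, 1.0)
    np.add.at(delta, ends, -1.0)
    return np.cumsum(delta[:-1])


def coverage(fragset: FragmentSet, genome: GenomeModel) -> CoverageTrack:
    """Genome-scaled per-base coverage.

    raw(b) = number of fragments overlapping base b; the track is multiplied
    by scale = (non-mito genome length) / (sum of raw over non-mito bases).
    """
    per_chrom = fragset.by_chrom()
    values: dict[str, np.ndarray] = {}
    raw_nonmito = 0.0
    for chrom, size in genome.chrom_sizes.items():
        if chrom in per_chrom:
            starts, ends = per_chrom[chrom]
            arr = _raw_depth(starts, ends, size)
        else:
            arr = np.zeros(size, dtype=np.float64)
        values[chrom] = arr
        if chrom != genome.mito_name:
            raw_nonmito += float(np.sum(ends - starts)) if chrom in per_chrom else 0.0
    if raw_nonmito == 0:
        raise ValidationError("no non-mitochondrial fragments; cannot scale")
    scale = genome.nuclear_length() / raw_nonmito
    for chrom in values:
        values[chrom] *= scale
    return CoverageTrack(values=values, scale_factor=scale,
                         mito_name=genome.mito_name)


def aggregate(track: CoverageTrack, intervals: pd.DataFrame) -> np.ndarray:
    """Mean normalized depth per interval (columns chrom, start, end)."""
    out = np.zeros(len(intervals), dtype=np.float64)
    for i, rec in enumerate(intervals.itertuples(index=False)):
        if rec.end <= rec.start:
            warnings.warn(f"zero-width interval at {rec.chrom}:{rec.start}")
            continue
        seg = track.values[rec.chrom][rec.start:rec.end]
        out[i] = float(seg.mean())
    return out


def _fragment_scale(fragset: FragmentSet, genome: GenomeModel) -> float:
    """Normalization scale factor computed without building arrays."""
    frags = fragset.frags
    nonmito = frags["chrom"] != genome.mito_name
    raw = float((frags.loc[nonmito, "end"] - frags.loc[nonmito, "start"]).sum())
    if raw == 0:
        raise ValidationError("no non-mitochondrial fragments; cannot scale")
    return genome.nuclear_length() / raw


def _interval_means_direct(fragset: FragmentSet, genome: GenomeModel,
                           intervals: pd.DataFrame) -> np.ndarray:
    """Fragment-overlap aggregation: identical to aggregate(coverage(...))."""
    scale = _fragment_scale(fragset, genome)
    per_chrom = fragset.by_chrom()
    out = np.zeros(len(intervals), dtype=np.float64)
    for chrom, grp in intervals.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if chrom not in per_chrom:
            continue
        starts, ends = per_chrom[chrom]
        maxlen = int((ends - starts).max()) if starts.size else 0
        s_arr = grp["start"].to_numpy(np.int64)
        e_arr = grp["end"].to_numpy(np.int64)
        for j, (s, e) in enumerate(zip(s_arr, e_arr)):
            if e <= s:
                warnings.warn(f"zero-width interval at {chrom}:{s}")
                continue
            lo = np.searchsorted(starts, s - maxlen, side="left")
            hi = np.searchsorted(starts, e, side="left")
            if hi <= lo:
                continue
            ov = (np.minimum(ends[lo:hi], e)
                  - np.maximum(starts[lo:hi], s)).clip(min=0)
            out[idx[j]] = float(ov.sum()) * scale / (e - s)
    return out


def _bin_means(fragset: FragmentSet, genome: GenomeModel,
               bin_size: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean normalized depth in fixed bins tiling each nuclear chromosome.

    Half-open bins from 0; the final partial bin is kept.
    """
    scale = _fragment_scale(fragset, genome)
    per_chrom = fragset.by_chrom()
    frames, vals = [], []
    for chrom in genome.nuclear_chroms:
        size = genome.chrom_sizes[chrom]
        edges = np.arange(0, size + bin_size, bin_size)
        edges[-1] = min(edges[-1], size)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        widths = np.diff(edges)
        if chrom in per_chrom:
            starts, ends = per_chrom[chrom]
            arr = _raw_depth(starts, ends, size)
            csum = np.concatenate([[0.0], np.cumsum(arr)])
            sums = csum[edges[1:]] - csum[edges[:-1]]
        else:
            sums = np.zeros(len(widths))
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": edges[:-1], "end": edges[1:],
            "id": [f"{chrom}:{s}-{e}" for s, e in zip(edges[:-1], edges[1:])],
            "category": f"bin{bin_size}"}))
        vals.append(sums * scale / widths)
    return pd.concat(frames, ignore_index=True), np.concatenate(vals)


def build_signal_matrix(samples: list[FragmentSet], genome: GenomeModel,
                        interval_kind: str,
                        bin_size: Optional[int] = None) -> SignalMatrix:
    """Aggregate every sample over cCREs, fixed bins or gene spans."""
    if interval_kind not in INTERVAL_KINDS:
        raise ValueError(f"interval_kind must be one of {INTERVAL_KINDS}")
    if interval_kind in BIN_KINDS:
        size = bin_size or BIN_KINDS[interval_kind]
        intervals = None
        rows = []
        for fs in samples:
            intervals, v = _bin_means(fs, genome, size)
            rows.append(v)
        values = pd.DataFrame(rows, index=[fs.sample_id for fs in samples],
                              columns=intervals["id"])
        return SignalMatrix(values=values, intervals=intervals,
                            interval_kind=interval_kind)

    if interval_kind == "ccre":
        intervals = genome.ccres.reset_index(drop=True)
    else:  # gene_span
        try:
            spans = genome.gene_spans_frame()
        except ValidationError as err:
            raise ValidationError(
                "gene spans absent; run genome.build_gene_spans(model) "
                "before building a gene_span matrix") from err
        member_of = {}
        for set_name, members in genome.gene_sets.items():
            for gid in members:
                member_of[gid] = set_name
        spans["category"] = spans["id"].map(member_of).fillna("gene")
        intervals = spans
    rows = [_interval_means_direct(fs, genome, intervals) for fs in samples]
    values = pd.DataFrame(rows, index=[fs.sample_id for fs in samples],
                          columns=intervals["id"])
    return SignalMatrix(values=values, intervals=intervals,
                        interval_kind=interval_kind)


def mito_fraction(fragset: FragmentSet, genome: GenomeModel) -> float:
    """Fraction of fragments whose midpoint lies on the mitochondrion."""
    if fragset.total_count == 0:
        raise ValidationError("empty fragment set")
    mids_on_mito = fragset.frags["chrom"] == genome.mito_name
    return float(mids_on_mito.mean())


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length-compressed 4-column bedGraph, 6-decimal values."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [v.size]])
            for s, e in zip(starts, ends):
                if v[s] != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.6f}\n")
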