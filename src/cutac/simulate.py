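"""Synthetic paired tumor/normal CUTAC cohorts over a miniature genome.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any external download:

* a miniature ~27 Mb nuclear genome (3 autosomes with p/q arms) plus a
  mitochondrial chromosome, carrying 2,500 cCREs in the five ENCODE-style
  element categories, a clustered locus of 64 short replication-dependent
  histone genes, 25 ribosomal-protein genes, ~200 further genes and
  scattered LINE elements;
* per-sample fragment sets drawn from a piecewise-constant intensity:
  background + category-weighted cCRE enrichment + gene-body emission.
  Tumors multiply cCRE intensity by (1 + hyper_factor), histone-gene
  emission scales with a latent proliferation rate rho, whole arms scale
  with per-arm copy ratios, and focal amplicons multiply local intensity by
  a copy ratio shaped by promoter-centered triangular summit weights;
* mitochondrial fragments injected to hit a per-sample target fraction
  (tumors lower than normals, mirroring reduced tumor mtDNA content);
* recurrence-free survival times with hazard h0*exp(beta*rho), censored at
  a fixed horizon, and WHO-like grades assigned by rho tertiles;
* matched RNA-seq counts sharing each tumor's latent expression program
  and arm copy state with the CUTAC fragments, so cross-modality
  integration has a recoverable truth pairing.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import (Arm, GeneAnnotation, GenomeModel, HISTONE_SET,
                     RIBOSOMAL_SET, build_gene_spans)
from .coverage import FragmentSet

# intensity model constants (rates per bp, in arbitrary units relative to
# background = 1); cCRE category weights are *excess* over background
BACKGROUND_RATE = 1.0
CCRE_WEIGHTS = {"PLS": 120.0, "pELS": 80.0, "dELS": 50.0,
                "CA-CTCF": 40.0, "CA-H3K4me3": 60.0}
GENE_BODY_RATE = 10.0          # multiplied by a per-gene lognormal activity
HISTONE_RATE = 60.0           # multiplied by the sample's proliferation rho
RIBOSOMAL_RATE = 20.0
RHO_NORMAL = 0.1              # baseline proliferation of normal tissue
TYPE_PROGRAM_SD = 0.4         # per-tumor-type lognormal cCRE signature (ln)
GENE_PROGRAM_SD = 0.35        # per-tumor lognormal gene program (ln), shared
                              # between CUTAC gene emission and RNA-seq
RNASEQ_LIBRARY = 300_000


@dataclass
class Amplicon:
    """Focal amplification: intensity is multiplied by
    copy_ratio * (1 + summit_gain * tri(x)) inside [start, end), where tri is
    a triangular kernel of the given half-width centered on each promoter."""

    chrom: str
    start: int
    end: int
    copy_ratio: float
    promoters: tuple = ()
    summit_halfwidth: int = 50_000
    summit_gain: float = 1.0

    def factor(self, pos: np.ndarray) -> np.ndarray:
        tri = np.zeros_like(np.asarray(pos, dtype=float))
        for p in self.promoters:
            tri = np.maximum(tri, np.clip(1.0 - np.abs(pos - p)
                                          / self.summit_halfwidth, 0.0, 1.0))
        return self.copy_ratio * (1.0 + self.summit_gain * tri)


@dataclass
class SimulationConfig:
    genome: GenomeModel
    n_pairs: int = 10
    depth_per_sample: int = 100_000
    hyper_factor: Union[float, Sequence[float]] = 0.5
    proliferation: Optional[Sequence[float]] = None  # default: bimodal draw
    amplicons: Sequence[Amplicon] = ()               # applied to every tumor
    arm_cn: Union[None, str, dict, Sequence[dict]] = "proliferation_linked"
    mito_fraction: Union[float, dict] = field(
        default_factory=lambda: {"tumor": 0.05, "normal": 0.15})
    frag_len_mean: float = 120.0
    frag_len_sd: float = 35.0
    ccre_program_sd: float = TYPE_PROGRAM_SD   # per-type cCRE signature (ln)
    gene_program_sd: float = GENE_PROGRAM_SD   # per-tumor gene program (ln)
    recurrence_beta: float = 3.0
    baseline_hazard: float = 0.002   # events per month at rho = 0
    censor_time: float = 120.0       # months of follow-up
    seed: int = 0

    def mito_target(self, role: str) -> float:
        if isinstance(self.mito_fraction, dict):
            return float(self.mito_fraction[role])
        return float(self.mito_fraction)

    def validate(self) -> None:
        for role in ("tumor", "normal"):
            f = self.mito_target(role)
            if not 0.0 <= f <= 1.0:
                raise ValueError("mito_fraction must lie in [0, 1]")
            if f >= 1.0 and self.depth_per_sample > 0:
                raise ValueError("mito_fraction = 1 leaves no nuclear depth")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for amp in self.amplicons:
            if amp.copy_ratio <= 0:
                raise ValueError("amplicon copy ratios must be > 0")


@dataclass
class Cohort:
    samples: list[FragmentSet]
    metadata: pd.DataFrame
    rnaseq: pd.DataFrame          # genes x RNA-seq samples
    truth: dict
    genome: GenomeModel

    def sample(self, sample_id: str) -> FragmentSet:
        for fs in self.samples:
            if fs.sample_id == sample_id:
                return fs
        raise KeyError(sample_id)

    def pairs(self) -> list[tuple[FragmentSet, FragmentSet]]:
        out = []
        for pid, grp in self.metadata.groupby("pair_id", sort=True):
            t = grp[grp["role"] == "tumor"]["sample_id"].iloc[0]
            n = grp[grp["role"] == "normal"]["sample_id"].iloc[0]
            out.append((self.sample(t), self.sample(n)))
        return out


# -- miniature genome -----------------------------------------------------

_GENOME_BUILD_SEED = 20240613  # fixed: the genome is a constant, not a draw


def miniature_genome() -> GenomeModel:
    """Deterministic ~27 Mb three-autosome genome plus chrM.

    chr1 10 Mb (centromere 6 Mb), chr2 9 Mb (4 Mb), chr3 8 Mb (3 Mb),
    chrM 16,569 bp. The histone locus (64 genes of 500 bp every 2.5 kb)
    sits on chr1p at 1.0 Mb.
    """
    rng = np.random.default_rng(_GENOME_BUILD_SEED)
    sizes = {"chr1": 10_000_000, "chr2": 9_000_000, "chr3": 8_000_000,
             "chrM": 16_569}
    cens = {"chr1": 6_000_000, "chr2": 4_000_000, "chr3": 3_000_000}
    arms = []
    for c, cen in cens.items():
        arms.append(Arm(c, "p", 0, cen))
        arms.append(Arm(c, "q", cen, sizes[c]))
    nuclear = list(cens)

    genes: list[GeneAnnotation] = []
    occupied: list[tuple[str, int, int]] = []

    hist_ids = []
    for i in range(64):
        start = 1_000_000 + i * 2_500
        gid = f"HIST_{i + 1:02d}"
        genes.append(GeneAnnotation(gid, "chr1", "+", [start], [start + 500]))
        hist_ids.append(gid)
    occupied.append(("chr1", 1_000_000, 1_160_000))

    def place(width: int, min_gap: int = 5_000) -> tuple[str, int]:
        for _ in range(1000):
            chrom = nuclear[rng.integers(len(nuclear))]
            start = int(rng.integers(10_000, sizes[chrom] - width - 10_000))
            if all(c != chrom or start + width + min_gap <= s
                   or start >= e + min_gap for c, s, e in occupied):
                occupied.append((chrom, start, start + width))
                return chrom, start
        raise RuntimeError("could not place feature")

    ribo_ids = []
    for i in range(25):
        gid = f"RPL_{i + 1:02d}"
        chrom, start = place(1_500)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(gid, chrom, strand,
                                    [start], [start + 1_500]))
        ribo_ids.append(gid)

    for i in range(210):
        gid = f"GENE_{i + 1:03d}"
        width = int(rng.integers(2_000, 10_000))
        chrom, start = place(width)
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(1, 4))
        tx_starts = [start + int(rng.integers(0, max(1, width // 5)))
                     for _ in range(n_tx)]
        tx_ends = [start + width - int(rng.integers(0, max(1, width // 5)))
                   for _ in range(n_tx)]
        tx_starts[0], tx_ends[0] = start, start + width
        genes.append(GeneAnnotation(gid, chrom, strand, tx_starts, tx_ends))

    cats = list(CCRE_WEIGHTS)
    cat_p = np.array([0.15, 0.25, 0.35, 0.10, 0.15])
    rows = []
    for i in range(2_500):
        chrom = nuclear[int(rng.integers(len(nuclear)))]
        width = int(rng.integers(200, 400))
        start = int(rng.integers(0, sizes[chrom] - width))
        cat = cats[int(rng.choice(len(cats), p=cat_p))]
        rows.append((chrom, start, start + width, f"cCRE_{i + 1:05d}", cat))
    ccres = (pd.DataFrame(rows, columns=["chrom", "start", "end", "id",
                                         "category"])
             .sort_values(["chrom", "start"]).reset_index(drop=True))

    line_rows = []
    for _ in range(300):
        chrom = nuclear[int(rng.integers(len(nuclear)))]
        width = int(rng.integers(500, 6_000))
        start = int(rng.integers(0, sizes[chrom] - width))
        line_rows.append((chrom, start, start + width))
    lines = (pd.DataFrame(line_rows, columns=["chrom", "start", "end"])
             .sort_values(["chrom", "start"]).reset_index(drop=True))

    model = GenomeModel(chrom_sizes=sizes, mito_name="chrM", arms=arms,
                        ccres=ccres, genes=genes, lines=lines,
                        gene_sets={HISTONE_SET: hist_ids,
                                   RIBOSOMAL_SET: ribo_ids})
    return build_gene_spans(model)


# -- intensity pieces -----------------------------------------------------


@dataclass
class _Piece:
    chrom: str
    start: int
    end: int
    rate: float
    kind: str           # background | ccre | gene
    tag: str = ""       # ccre index / gene id

    @property
    def width(self) -> int:
        return self.end - self.start


def _base_pieces(genome: GenomeModel) -> list[_Piece]:
    """Baseline (normal-tissue) intensity decomposition; components add."""
    pieces = [ _Piece(a.chrom, a.start, a.end, BACKGROUND_RATE, "background",
                      a.name) for a in genome.arms ]
    for i, rec in enumerate(genome.ccres.itertuples(index=False)):
        pieces.append(_Piece(rec.chrom, rec.start, rec.end,
                             CCRE_WEIGHTS[rec.category], "ccre", rec.id))
    grng = np.random.default_rng(_GENOME_BUILD_SEED + 1)
    for g in genome.genes:
        lo, hi = g.extent
        if g.gene_id.startswith("HIST_"):
            rate = HISTONE_RATE  # multiplied by rho per sample
        elif g.gene_id.startswith("RPL_"):
            rate = RIBOSOMAL_RATE
        else:
            rate = GENE_BODY_RATE * float(grng.lognormal(0.0, 1.0))
        pieces.append(_Piece(g.chrom, lo, hi, rate, "gene", g.gene_id))
    return pieces


def _split_for_amplicons(pieces: list[_Piece],
                         amplicons: Sequence[Amplicon]) -> list[_Piece]:
    """Split background pieces on a 1-kb grid inside amplicons so the
    triangular summit weight is resolved; short pieces are left whole and
    take the factor at their midpoint."""
    if not amplicons:
        return pieces
    out = []
    for p in pieces:
        hit = [a for a in amplicons
               if a.chrom == p.chrom and a.start < p.end and a.end > p.start]
        if not hit or p.width <= 2_000:
            out.append(p)
            continue
        cuts = {p.start, p.end}
        for a in hit:
            lo, hi = max(a.start, p.start), min(a.end, p.end)
            cuts.update(range(lo, hi + 1, 1_000))
            cuts.update((lo, hi))
        edges = sorted(c for c in cuts if p.start <= c <= p.end)
        for s, e in zip(edges, edges[1:]):
            if e > s:
                out.append(_Piece(p.chrom, s, e, p.rate, p.kind, p.tag))
    return out


def _sample_weights(pieces: list[_Piece], genome: GenomeModel, *,
                    role: str, rho: float, hyper: float,
                    arm_cn: dict, amplicons: Sequence[Amplicon],
                    ccre_program: Optional[np.ndarray] = None,
                    ccre_index: Optional[dict] = None,
                    gene_program: Optional[dict] = None) -> np.ndarray:
    """Per-piece sampling weights (rate x width x sample modifiers)."""
    arm_lookup = {}
    for a in genome.arms:
        arm_lookup[a.name] = arm_cn.get(a.name, 1.0) if role == "tumor" else 1.0

    def arm_factor(chrom: str, mid: float) -> float:
        for a in genome.arms:
            if a.chrom == chrom and a.start <= mid < a.end:
                return arm_lookup[a.name]
        return 1.0

    w = np.empty(len(pieces))
    for i, p in enumerate(pieces):
        rate = p.rate
        if p.kind == "ccre" and role == "tumor":
            rate *= (1.0 + hyper)
            if ccre_program is not None:
                rate *= ccre_program[ccre_index[p.tag]]
        if p.kind == "gene":
            if p.tag.startswith("HIST_"):
                rate = p.rate * (rho if role == "tumor" else RHO_NORMAL)
            if role == "tumor" and gene_program is not None:
                rate *= gene_program.get(p.tag, 1.0)
        mid = (p.start + p.end) / 2.0
        f = arm_factor(p.chrom, mid)
        if role == "tumor":
            for a in amplicons:
                if a.chrom == p.chrom and a.start <= mid < a.end:
                    f *= float(a.factor(np.array([mid]))[0])
        w[i] = rate * p.width * f
    return w


def _draw_fragments(pieces: list[_Piece], weights: np.ndarray, n: int,
                    genome: GenomeModel, cfg_len: tuple[float, float],
                    mito_n: int, rng: np.random.Generator) -> pd.DataFrame:
    mean, sd = cfg_len
    counts = rng.multinomial(n, weights / weights.sum())
    idx = np.repeat(np.arange(len(pieces)), counts)
    starts_lo = np.array([p.start for p in pieces])[idx]
    widths = np.array([p.width for p in pieces])[idx]
    starts = starts_lo + (rng.random(idx.size) * widths).astype(np.int64)
    chroms = np.array([p.chrom for p in pieces], dtype=object)[idx]

    if mito_n > 0:
        msize = genome.chrom_sizes[genome.mito_name]
        mstarts = rng.integers(0, msize - 20, size=mito_n)
        starts = np.concatenate([starts, mstarts])
        chroms = np.concatenate([chroms,
                                 np.full(mito_n, genome.mito_name,
                                         dtype=object)])

    lens = np.maximum(20, rng.normal(mean, sd, size=starts.size)).astype(np.int64)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms])
    starts = np.minimum(starts, sizes - 20)
    ends = np.minimum(starts + lens, sizes)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


# -- cohort simulation ----------------------------------------------------


def _resolve_tumor_params(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_pairs
    if cfg.proliferation is None:
        # mostly-benign cohort with a small aggressive subgroup: about one
        # patient in six proliferates rapidly, the rest slowly
        n_high = max(1, round(n / 6))
        rho = np.concatenate([rng.uniform(0.85, 1.0, size=n_high),
                              rng.uniform(0.0, 0.2, size=n - n_high)])
        rng.shuffle(rho)
    else:
        rho = np.asarray(cfg.proliferation, dtype=float)
        if rho.size != n:
            raise ValueError("proliferation must have one rho per pair")
    if np.isscalar(cfg.hyper_factor):
        hyper = np.full(n, float(cfg.hyper_factor))
    else:
        hyper = np.asarray(cfg.hyper_factor, dtype=float)
    histone_chroms = {g.chrom for g in cfg.genome.genes
                      if g.gene_id in cfg.genome.gene_sets[HISTONE_SET]}
    histone_arms = {a.name for a in cfg.genome.arms
                    if a.chrom in histone_chroms
                    and any(a.start <= sum(g.extent) / 2 < a.end
                            for g in cfg.genome.genes
                            if g.gene_id in cfg.genome.gene_sets[HISTONE_SET]
                            and g.chrom == a.chrom)}
    # the histone-locus arm is kept diploid: packing all histone genes onto
    # one miniature arm would otherwise couple dosage directly into the
    # proliferation signature, an artifact of genome compression
    arm_names = [a.name for a in cfg.genome.analyzed_arms()
                 if a.name not in histone_arms]
    if cfg.arm_cn is None:
        arm_cn = [dict() for _ in range(n)]
    elif cfg.arm_cn == "proliferation_linked":
        # whole-arm losses are subclonal and graded: on loss-susceptible
        # arms the fraction of tumor cells carrying a one-copy loss grows
        # with proliferation, so measured dosage falls continuously from 1
        # toward 0.5. Susceptibility differs between arms (as it does in
        # real tumors); stable arms anchor the per-sample dosage reference.
        # Gains are rare and proliferation-independent.
        susceptibility = {name: (1.0 if i % 2 == 0 else 0.0)
                          for i, name in enumerate(arm_names)}
        arm_cn = []
        for r in rho:
            d = {}
            for name in arm_names:
                sus = susceptibility[name]
                f = sus * float(np.clip(
                    r - 0.25 + 0.10 * rng.standard_normal(), 0.0, 1.0))
                if f > 0.02:
                    d[name] = 1.0 - 0.5 * f
                elif rng.random() > 0.97:
                    d[name] = 1.5
            arm_cn.append(d)
    elif isinstance(cfg.arm_cn, dict):
        arm_cn = [dict(cfg.arm_cn) for _ in range(n)]
    else:
        arm_cn = [dict(d) for d in cfg.arm_cn]
    return rho, hyper, arm_cn


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full paired cohort with metadata and matched RNA-seq."""
    config.validate()
    genome = config.genome
    rng = np.random.default_rng(config.seed)
    rho, hyper, arm_cn = _resolve_tumor_params(config, rng)

    pieces = _split_for_amplicons(_base_pieces(genome), config.amplicons)
    ccre_index = {rec.id: i for i, rec in
                  enumerate(genome.ccres.itertuples(index=False))}
    tumor_types = ["meningioma", "breast"]
    type_programs = {t: np.exp(rng.normal(0.0, config.ccre_program_sd,
                                          size=len(ccre_index)))
                     for t in tumor_types}

    gene_ids = [g.gene_id for g in genome.genes]
    gene_programs = [
        {gid: float(v) for gid, v in
         zip(gene_ids, np.exp(rng.normal(0.0, config.gene_program_sd,
                                         size=len(gene_ids))))}
        for _ in range(config.n_pairs)]

    # recurrence: hazard h0 * exp(beta * rho), censored at censor_time
    haz = config.baseline_hazard * np.exp(config.recurrence_beta * rho)
    raw_times = rng.exponential(1.0 / haz)
    events = (raw_times <= config.censor_time).astype(int)
    times = np.minimum(raw_times, config.censor_time)

    grades = (pd.qcut(pd.Series(rho), 3, labels=False,
                      duplicates="drop") + 1).to_numpy() \
        if len(np.unique(rho)) >= 3 else np.ones(config.n_pairs, dtype=int)

    samples, meta_rows = [], []
    for i in range(config.n_pairs):
        pid = f"P{i + 1:02d}"
        ttype = tumor_types[i % len(tumor_types)]
        for role in ("tumor", "normal"):
            depth = config.depth_per_sample
            mito_n = int(round(depth * config.mito_target(role)))
            w = _sample_weights(
                pieces, genome, role=role, rho=float(rho[i]),
                hyper=float(hyper[i]), arm_cn=arm_cn[i],
                amplicons=config.amplicons,
                ccre_program=type_programs[ttype], ccre_index=ccre_index,
                gene_program=gene_programs[i])
            frags = _draw_fragments(
                pieces, w, depth - mito_n, genome,
                (config.frag_len_mean, config.frag_len_sd), mito_n, rng)
            sid = f"{pid}_{'T' if role == 'tumor' else 'N'}"
            samples.append(FragmentSet(sample_id=sid, frags=frags, role=role,
                                       pair_id=pid,
                                       meta={"type": ttype}))
            meta_rows.append({
                "sample_id": sid, "pair_id": pid, "role": role,
                "type": ttype, "who_grade": int(grades[i]),
                "recurrence_months": round(float(times[i]), 3),
                "event": int(events[i])})
    metadata = pd.DataFrame(meta_rows)

    rnaseq = _simulate_rnaseq(config, genome, rho, arm_cn, gene_programs, rng)

    truth = {
        "n_pairs": config.n_pairs,
        "depth_per_sample": config.depth_per_sample,
        "hyper_factor": [float(h) for h in hyper],
        "proliferation": [float(r) for r in rho],
        "arm_cn": arm_cn,
        "amplicons": [asdict(a) if not isinstance(a, dict) else a
                      for a in config.amplicons],
        "mito_fraction": (config.mito_fraction if
                          isinstance(config.mito_fraction, (int, float))
                          else dict(config.mito_fraction)),
        "frag_len_mean": config.frag_len_mean,
        "frag_len_sd": config.frag_len_sd,
        "recurrence_beta": config.recurrence_beta,
        "baseline_hazard": config.baseline_hazard,
        "censor_time": config.censor_time,
        "seed": config.seed,
    }
    return Cohort(samples=samples, metadata=metadata, rnaseq=rnaseq,
                  truth=truth, genome=genome)


def _simulate_rnaseq(config: SimulationConfig, genome: GenomeModel,
                     rho: np.ndarray, arm_cn: list[dict],
                     gene_programs: list[dict],
                     rng: np.random.Generator) -> pd.DataFrame:
    """Poisson counts per gene for each tumor, sharing the tumor's latent
    expression program and arm copy state with its CUTAC fragments."""
    grng = np.random.default_rng(_GENOME_BUILD_SEED + 1)
    base = {}
    for g in genome.genes:
        if g.gene_id.startswith("HIST_"):
            base[g.gene_id] = ("histone", HISTONE_RATE)
        elif g.gene_id.startswith("RPL_"):
            base[g.gene_id] = ("ribosomal", RIBOSOMAL_RATE)
        else:
            base[g.gene_id] = ("gene",
                               GENE_BODY_RATE * float(grng.lognormal(0.0, 1.0)))

    def arm_name_of(g: GeneAnnotation) -> Optional[str]:
        mid = sum(g.extent) / 2
        for a in genome.arms:
            if a.chrom == g.chrom and a.start <= mid < a.end:
                return a.name
        return None

    cols = {}
    gene_ids = [g.gene_id for g in genome.genes]
    for i in range(config.n_pairs):
        expr = np.empty(len(gene_ids))
        for j, g in enumerate(genome.genes):
            kind, rate = base[g.gene_id]
            if kind == "histone":
                rate = rate * float(rho[i])
            rate *= gene_programs[i].get(g.gene_id, 1.0)
            an = arm_name_of(g)
            if an is not None:
                rate *= arm_cn[i].get(an, 1.0)
            expr[j] = rate
        p = expr / expr.sum()
        cols[f"P{i + 1:02d}_R"] = rng.poisson(RNASEQ_LIBRARY * p)
    return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))


# -- spike-in benchmark pair ----------------------------------------------


def simulate_spiked_pair(genome: GenomeModel, depth: int, n_spikes: int,
                         fold: float, seed: int,
                         flank: int = 0) -> tuple[FragmentSet, FragmentSet,
                                                  pd.DataFrame]:
    """Matched-background spike-in pair for enrichment-detector benchmarks.

    The matched background is the cCRE occupancy landscape (the targeted
    assay's enriched-site blocks): the normal sample is a draw of ``depth``
    fragments over the genome's cCREs. The tumor *shares* that entire
    fragment pool and additionally carries fresh fragments inside the
    ``n_spikes`` windows (the widest promoter-class cCREs, plus ``flank``
    bp each side) drawn at (fold - 1) times the local baseline rate, so
    in-window intensity is ``fold`` times the matched background. Sharing
    the background isolates detector behavior from background sampling
    noise, which is what a spike-in benchmark is for.

    Returns (tumor, normal, spikes) where spikes is a BED-like frame of the
    injected windows.
    """
    rng = np.random.default_rng(seed)
    pieces = [p for p in _base_pieces(genome) if p.kind == "ccre"]
    weights = np.array([p.rate * p.width for p in pieces])

    pls = genome.ccres[genome.ccres["category"] == "PLS"].copy()
    pls["width"] = pls["end"] - pls["start"]
    chosen = (pls.sort_values("width", ascending=False).head(n_spikes)
              .sort_values(["chrom", "start"]))
    spikes = pd.DataFrame({
        "chrom": chosen["chrom"].to_numpy(),
        "start": chosen["start"].to_numpy() - flank,
        "end": chosen["end"].to_numpy() + flank,
        "id": [f"spike_{i + 1:02d}" for i in range(n_spikes)]})

    def in_spike(p: _Piece) -> bool:
        mid = (p.start + p.end) / 2
        sel = spikes[(spikes["chrom"] == p.chrom)
                     & (spikes["start"] < p.end) & (spikes["end"] > p.start)]
        return len(sel) > 0 and any(
            s <= mid < e for s, e in zip(sel["start"], sel["end"]))

    spike_mask = np.array([in_spike(p) for p in pieces])
    w_spike = weights[spike_mask].sum()

    normal_frags = _draw_fragments(pieces, weights, depth, genome,
                                   (120.0, 35.0), 0, rng)
    n_extra = int(rng.poisson((fold - 1.0) * w_spike / weights.sum() * depth))
    sp_pieces = [p for p, m in zip(pieces, spike_mask) if m]
    extra = _draw_fragments(sp_pieces, weights[spike_mask], n_extra,
                            genome, (120.0, 35.0), 0, rng)
    tumor_frags = pd.concat([normal_frags, extra], ignore_index=True)

    tumor = FragmentSet("spike_T", tumor_frags, role="tumor", pair_id="spike")
    normal = FragmentSet("spike_N", normal_frags, role="normal",
                         pair_id="spike")
    return tumor, normal, spikes


def benchmark_amplicon() -> Amplicon:
    """Packaged focal-amplification benchmark on the miniature genome.

    An 8-copy, 268-kb amplicon over a dense cCRE stretch of chr3, with its
    summit centered on the promoter cluster at 6.760 Mb — the point whose
    induced intensity-weighted apex coincides with itself under the default
    10-kb profile smoothing, so the designated promoter is the true summit
    location. Edges abut flanking cCREs, as detectable breakpoints must.
    """
    return Amplicon("chr3", 6_619_000, 6_887_000, copy_ratio=8.0,
                    promoters=(6_760_000,), summit_gain=3.0)


def simulate_amplified_pair(genome: GenomeModel, depth: int,
                            amplicon: Amplicon, seed: int
                            ) -> tuple[FragmentSet, FragmentSet]:
    """Matched-background pair carrying one focal amplification.

    Like :func:`simulate_spiked_pair`, the matched background is the cCRE
    occupancy landscape and the tumor shares the normal's entire fragment
    pool; inside the amplicon it additionally carries fresh fragments at
    (factor(x) - 1) times the local rate, where factor is the amplicon's
    copy ratio shaped by its promoter-centered triangular summit weight.
    """
    rng = np.random.default_rng(seed)
    pieces = [p for p in _base_pieces(genome) if p.kind == "ccre"]
    weights = np.array([p.rate * p.width for p in pieces])
    mids = np.array([(p.start + p.end) / 2.0 for p in pieces])
    inside = np.array([p.chrom == amplicon.chrom
                       and amplicon.start <= m < amplicon.end
                       for p, m in zip(pieces, mids)])
    normal_frags = _draw_fragments(pieces, weights, depth, genome,
                                   (120.0, 35.0), 0, rng)
    boost = np.zeros(len(pieces))
    boost[inside] = amplicon.factor(mids[inside]) - 1.0
    extra_w = weights * boost
    n_extra = int(rng.poisson(extra_w.sum() / weights.sum() * depth))
    amp_pieces = [p for p, m in zip(pieces, inside) if m]
    extra = _draw_fragments(amp_pieces, extra_w[inside], n_extra, genome,
                            (120.0, 35.0), 0, rng)
    tumor_frags = pd.concat([normal_frags, extra], ignore_index=True)
    tumor = FragmentSet("amp_T", tumor_frags, role="tumor", pair_id="amp")
    normal = FragmentSet("amp_N", normal_frags, role="normal", pair_id="amp")
    return tumor, normal


# -- persistence ----------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """One sorted BED3 per sample + metadata TSV + RNA-seq TSV + truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {"fragments": {}}
    for fs in cohort.samples:
        p = os.path.join(out_dir, f"{fs.sample_id}.fragments.bed")
        fs.frags.to_csv(p, sep="\t", header=False, index=False)
        paths["fragments"][fs.sample_id] = p
    paths["metadata"] = os.path.join(out_dir, "metadata.tsv")
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    paths["rnaseq"] = os.path.join(out_dir, "rnaseq.tsv")
    cohort.rnaseq.to_csv(paths["rnaseq"], sep="\t")
    paths["truth"] = os.path.join(out_dir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return paths


def load_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
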