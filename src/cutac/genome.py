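"""Reference structure for the analysis: chromosomes, arms, cCREs, genes, LINEs.

All coordinates are 0-based half-open (BED convention) throughout the
package; 1-based coordinates appear only in human-readable reports.

The central object is :class:`GenomeModel`, a validated registry of

* chromosome sizes (one chromosome designated mitochondrial),
* chromosome arms as half-open intervals tiling each nuclear chromosome,
  with acrocentric short arms optionally flagged ``excluded`` so that the
  canonical human configuration analyses 39 autosomal arms,
* candidate cis-regulatory elements (cCREs) with a category label,
* gene annotations with per-transcript start/end coordinates, from which
  custom gene spans are derived (:func:`build_gene_spans`),
* LINE elements, and
* named gene sets (at minimum ``histone`` and ``ribosomal_protein``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("cutac")

HISTONE_SET = "histone"
RIBOSOMAL_SET = "ribosomal_protein"
REQUIRED_GENE_SETS = (HISTONE_SET, RIBOSOMAL_SET)

#: Acrocentric autosomal short arms excluded from arm-level analyses in the
#: canonical human configuration (22 autosomes x 2 arms - 5 = 39 analyzed arms).
HUMAN_EXCLUDED_ARMS = (("chr13", "p"), ("chr14", "p"), ("chr15", "p"),
                       ("chr21", "p"), ("chr22", "p"))

# Approximate hg38 autosome lengths and centromere midpoints (Mb resolution).
_HG38_AUTOSOMES = {
    "chr1": (248_956_422, 123_400_000), "chr2": (242_193_529, 93_900_000),
    "chr3": (198_295_559, 90_900_000), "chr4": (190_214_555, 50_000_000),
    "chr5": (181_538_259, 48_800_000), "chr6": (170_805_979, 59_800_000),
    "chr7": (159_345_973, 60_100_000), "chr8": (145_138_636, 45_200_000),
    "chr9": (138_394_717, 43_000_000), "chr10": (133_797_422, 39_800_000),
    "chr11": (135_086_622, 53_400_000), "chr12": (133_275_309, 35_500_000),
    "chr13": (114_364_328, 17_700_000), "chr14": (107_043_718, 17_200_000),
    "chr15": (101_991_189, 19_000_000), "chr16": (90_338_345, 36_800_000),
    "chr17": (83_257_441, 25_100_000), "chr18": (80_373_285, 18_500_000),
    "chr19": (58_617_616, 26_200_000), "chr20": (64_444_167, 28_100_000),
    "chr21": (46_709_983, 12_000_000), "chr22": (50_818_468, 15_000_000),
}


class ConfigurationError(ValueError):
    """A required piece of the genome configuration is missing."""


class ValidationError(ValueError):
    """An input record violates the genome model's invariants."""


@dataclass
class GeneAnnotation:
    """One gene with its transcript start/end coordinates.

    ``span`` is the derived analysis interval (see :func:`build_gene_spans`);
    it is ``None`` until spans have been built. Strand is retained for
    reporting only — span geometry uses the unstranded union extent.
    """

    gene_id: str
    chrom: str
    strand: str
    transcript_starts: list[int]
    transcript_ends: list[int]
    span: Optional[tuple[int, int]] = None

    @property
    def extent(self) -> tuple[int, int]:
        """Union extent of all transcripts: [min start, max end)."""
        return (min(self.transcript_starts), max(self.transcript_ends))


@dataclass
class Arm:
    chrom: str
    label: str  # "p" or "q"
    start: int
    end: int
    excluded: bool = False

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.label}"


@dataclass
class GenomeModel:
    chrom_sizes: dict[str, int]
    mito_name: str
    arms: list[Arm]
    ccres: pd.DataFrame  # columns: chrom, start, end, id, category
    genes: list[GeneAnnotation]
    lines: pd.DataFrame  # columns: chrom, start, end
    gene_sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.mito_name not in self.chrom_sizes:
            raise ConfigurationError(
                f"mitochondrial chromosome {self.mito_name!r} not in chrom_sizes")
        for name in REQUIRED_GENE_SETS:
            if name not in self.gene_sets:
                raise ConfigurationError(f"required gene set {name!r} missing")
        known = set(g.gene_id for g in self.genes)
        for set_name, members in self.gene_sets.items():
            missing = [m for m in members if m not in known]
            if missing:
                raise ConfigurationError(
                    f"gene set {set_name!r} has unknown members: {missing[:5]}")
        # arms tile each armed chromosome and never touch the mitochondrion
        by_chrom: dict[str, list[Arm]] = {}
        for arm in self.arms:
            if arm.chrom == self.mito_name:
                raise ValidationError("mitochondrial chromosome cannot have arms")
            if arm.chrom not in self.chrom_sizes:
                raise ValidationError(f"arm on unknown chromosome {arm.chrom!r}")
            by_chrom.setdefault(arm.chrom, []).append(arm)
        for chrom, arms in by_chrom.items():
            arms = sorted(arms, key=lambda a: a.start)
            if arms[0].start != 0 or arms[-1].end != self.chrom_sizes[chrom]:
                raise ValidationError(f"arms do not tile {chrom}")
            for a, b in zip(arms, arms[1:]):
                if a.end != b.start:
                    raise ValidationError(
                        f"arms on {chrom} not contiguous at {a.end}/{b.start}")
        self._check_intervals(self.ccres, "cCRE")
        if (self.ccres["chrom"] == self.mito_name).any():
            raise ValidationError("mitochondrial chromosome cannot carry cCREs")
        self._check_intervals(self.lines, "LINE")
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValidationError(f"gene {g.gene_id}: unknown chrom {g.chrom!r}")
            if not g.transcript_starts or not g.transcript_ends:
                raise ValidationError(f"gene {g.gene_id}: no transcripts")
            lo, hi = g.extent
            if lo < 0 or hi > self.chrom_sizes[g.chrom]:
                raise ValidationError(f"gene {g.gene_id}: extent out of bounds")

    def _check_intervals(self, df: pd.DataFrame, what: str) -> None:
        for rec in df.itertuples(index=False):
            size = self.chrom_sizes.get(rec.chrom)
            if size is None:
                raise ValidationError(f"{what} on unknown chromosome: {rec}")
            if not (0 <= rec.start < rec.end <= size):
                raise ValidationError(f"{what} outside chromosome bounds: {rec}")

    # -- convenience ------------------------------------------------------

    @property
    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.chrom_sizes if c != self.mito_name]

    def nuclear_length(self) -> int:
        return sum(self.chrom_sizes[c] for c in self.nuclear_chroms)

    def analyzed_arms(self) -> list[Arm]:
        """Arms entering arm-level analyses (non-excluded, nuclear)."""
        return [a for a in self.arms if not a.excluded]

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_spans_frame(self) -> pd.DataFrame:
        """Gene spans as an interval table (requires build_gene_spans)."""
        rows = []
        for g in self.genes:
            if g.span is None:
                raise ValidationError(
                    "gene spans not built; call build_gene_spans first")
            rows.append((g.chrom, g.span[0], g.span[1], g.gene_id))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])


# -- operations -----------------------------------------------------------


def arm_of(model: GenomeModel, chrom: str, position: int) -> Optional[str]:
    """Arm label ("p"/"q") containing ``position``, or None on the mitochondrion.

    Arms are half-open, so the centromere base itself belongs to the q arm.
    """
    if chrom not in model.chrom_sizes:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not 0 <= position < model.chrom_sizes[chrom]:
        raise ValidationError(f"position {position} out of bounds on {chrom}")
    if chrom == model.mito_name:
        return None
    for arm in model.arms:
        if arm.chrom == chrom and arm.start <= position < arm.end:
            return arm.label
    return None


def build_gene_spans(model: GenomeModel) -> GenomeModel:
    """Assign each gene its analysis span, clipped at neighboring features.

    A gene's span starts from the union extent of its own transcripts (its
    isoforms merge), then is truncated so it does not cross any boundary
    (start or end) of another gene's transcript extent or of a LINE element.
    Offending boundaries left of the extent midpoint clip the span start,
    those right of the midpoint clip the span end, so truncation only ever
    shrinks the span and the result is deterministic and order-independent.

    Returns the same model with ``span`` set on every gene (idempotent).
    """
    bounds: dict[str, list[tuple[int, str]]] = {}
    for g in model.genes:
        lo, hi = g.extent
        bounds.setdefault(g.chrom, []).extend([(lo, g.gene_id), (hi, g.gene_id)])
    for rec in model.lines.itertuples(index=False):
        bounds.setdefault(rec.chrom, []).extend(
            [(rec.start, "__line__"), (rec.end, "__line__")])

    by_chrom = {c: (np.array([p for p, _ in v]), [o for _, o in v])
                for c, v in bounds.items()}

    for g in model.genes:
        lo, hi = g.extent
        mid = (lo + hi) / 2
        positions, owners = by_chrom[g.chrom]
        inside = [(p, o) for p, o in zip(positions, owners)
                  if lo < p < hi and o != g.gene_id]
        left = [p for p, _ in inside if p <= mid]
        right = [p for p, _ in inside if p > mid]
        start = max(left) if left else lo
        end = min(right) if right else hi
        if start >= end:
            logger.warning("gene %s: span degenerate after clipping (%d,%d)",
                           g.gene_id, start, end)
            end = start
        g.span = (start, end)
    return model


def human_arm_configuration() -> GenomeModel:
    """Canonical human autosomal arm configuration (hg38, Mb-resolution).

    22 autosomes split at the centromere into p/q arms, with the five
    acrocentric short arms (13p, 14p, 15p, 21p, 22p) flagged excluded, so
    ``analyzed_arms()`` returns the 39 autosomal arms used in arm-level
    analyses. Carries no cCREs/genes — it is an arm registry only.
    """
    excluded = set(HUMAN_EXCLUDED_ARMS)
    sizes = {c: s for c, (s, _) in _HG38_AUTOSOMES.items()}
    sizes["chrM"] = 16_569
    arms = []
    for chrom, (size, cen) in _HG38_AUTOSOMES.items():
        arms.append(Arm(chrom, "p", 0, cen, (chrom, "p") in excluded))
        arms.append(Arm(chrom, "q", cen, size, (chrom, "q") in excluded))
    empty = pd.DataFrame(columns=["chrom", "start", "end", "id", "category"])
    placeholder = GeneAnnotation("_placeholder", "chr1", "+", [0], [1])
    return GenomeModel(
        chrom_sizes=sizes, mito_name="chrM", arms=arms,
        ccres=empty, genes=[placeholder],
        lines=pd.DataFrame(columns=["chrom", "start", "end"]),
        gene_sets={HISTONE_SET: ["_placeholder"], RIBOSOMAL_SET: ["_placeholder"]},
    )


# -- file loading ---------------------------------------------------------


def load_genome_model(chrom_sizes_path, arms_path, ccre_bed_path, genes_path,
                      lines_bed_path, gene_sets_path) -> GenomeModel:
    """Build a validated GenomeModel from the on-disk text formats.

    chrom sizes: 2-column TSV (name, length); the mitochondrial chromosome is
    recognized by name ("chrM" or "MT"). Arms: BED-like TSV with arm label in
    column 4, optional "excluded" flag in column 5. cCREs: BED with id (col 4)
    and category (col 5). Genes: TSV (gene_id, chrom, strand, comma-separated
    transcript starts, comma-separated transcript ends). LINEs: BED3.
    Gene sets: 2-column TSV (set_name, gene_id).
    """
    sizes_df = pd.read_csv(chrom_sizes_path, sep="\t", header=None,
                           names=["chrom", "length"])
    chrom_sizes = dict(zip(sizes_df["chrom"], sizes_df["length"].astype(int)))
    mito = next((c for c in chrom_sizes if c in ("chrM", "MT", "chrMT")), None)
    if mito is None:
        raise ConfigurationError("no mitochondrial chromosome (chrM/MT) found")

    arms_df = pd.read_csv(arms_path, sep="\t", header=None).iloc[:, :5]
    arms_df.columns = ["chrom", "start", "end", "label", "flag"][: arms_df.shape[1]]
    arms = [Arm(r.chrom, r.label, int(r.start), int(r.end),
                str(getattr(r, "flag", "")).strip() == "excluded")
            for r in arms_df.itertuples(index=False)]

    ccres = pd.read_csv(ccre_bed_path, sep="\t", header=None,
                        names=["chrom", "start", "end", "id", "category"])

    genes = []
    genes_df = pd.read_csv(genes_path, sep="\t", header=None,
                           names=["gene_id", "chrom", "strand", "starts", "ends"])
    for r in genes_df.itertuples(index=False):
        genes.append(GeneAnnotation(
            r.gene_id, r.chrom, r.strand,
            [int(x) for x in str(r.starts).split(",")],
            [int(x) for x in str(r.ends).split(",")]))

    lines = pd.read_csv(lines_bed_path, sep="\t", header=None,
                        names=["chrom", "start", "end"])

    sets_df = pd.read_csv(gene_sets_path, sep="\t", header=None,
                          names=["set_name", "gene_id"])
    gene_sets = {name: list(grp["gene_id"])
                 for name, grp in sets_df.groupby("set_name", sort=True)}

    return GenomeModel(chrom_sizes=chrom_sizes, mito_name=mito, arms=arms,
                       ccres=ccres, genes=genes, lines=lines,
                       gene_sets=gene_sets)


def write_genome_model(model: GenomeModel, out_dir) -> dict[str, str]:
    """Write the model to the same text formats load_genome_model reads."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, f"{k}.tsv") for k in
             ("chrom_sizes", "arms", "ccres", "genes", "lines", "gene_sets")}
    pd.DataFrame(sorted(model.chrom_sizes.items())).to_csv(
        paths["chrom_sizes"], sep="\t", header=False, index=False)
    pd.DataFrame(
        [(a.chrom, a.start, a.end, a.label, "excluded" if a.excluded else ".")
         for a in model.arms]).to_csv(paths["arms"], sep="\t", header=False,
                                      index=False)
    model.ccres.to_csv(paths["ccres"], sep="\t", header=False, index=False)
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand,
          ",".join(map(str, g.transcript_starts)),
          ",".join(map(str, g.transcript_ends))) for g in model.genes]
    ).to_csv(paths["genes"], sep="\t", header=False, index=False)
    model.lines.to_csv(paths["lines"], sep="\t", header=False, index=False)
    pd.DataFrame(
        [(name, gid) for name in sorted(model.gene_sets)
         for gid in model.gene_sets[name]]
    ).to_csv(paths["gene_sets"], sep="\t", header=False, index=False)
    return paths
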