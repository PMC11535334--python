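"""Shared domain types for the complementation-screen pipeline.

Coordinates are 1-based and inclusive throughout (GFF3 convention); the
length of an interval is ``end - start + 1``.  A gene is carried in the
"sense" orientation when its coding strand matches the direction of
transcription from the vector's synthetic promoter, i.e. when
``gene.strand == insert.vector_orientation``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

_ACGT = frozenset("ACGT")
BARCODE_LENGTH = 20


class ValidationError(ValueError):
    """Raised when an on-disk record violates a domain invariant."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene on one source genome."""

    gene_id: str
    genome_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive, >= start
    strand: str  # '+' or '-'
    cds_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id}: require 1 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.cds_sequence is not None and len(self.cds_sequence) % 3 != 0:
            raise ValidationError(
                f"gene {self.gene_id}: CDS length {len(self.cds_sequence)} "
                "is not a multiple of 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FragmentInsert:
    """One barcoded genomic fragment cloned into the expression vector.

    ``vector_orientation`` is the strand of the genomic + strand relative
    to the synthetic promoter's direction of transcription.
    """

    barcode: str
    genome_id: str
    start: int
    end: int
    vector_orientation: str

    def __post_init__(self) -> None:
        if len(self.barcode) != BARCODE_LENGTH or not _ACGT.issuperset(self.barcode):
            raise ValidationError(
                f"barcode {self.barcode!r} is not a {BARCODE_LENGTH}-nt ACGT string"
            )
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"insert {self.barcode}: bad interval [{self.start}, {self.end}]"
            )
        if self.vector_orientation not in ("+", "-"):
            raise ValidationError(
                f"insert {self.barcode}: bad orientation {self.vector_orientation!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains_gene(self, gene: GeneAnnotation) -> bool:
        """Full containment on the same genome, strand-agnostic."""
        return (
            gene.genome_id == self.genome_id
            and self.start <= gene.start
            and gene.end <= self.end
        )

    def gene_is_sense(self, gene: GeneAnnotation) -> bool:
        return gene.strand == self.vector_orientation


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one BarSeq sample from the experiment sheet."""

    sample_id: str
    background: str  # mutant background, e.g. "dhisC"
    inducer: str  # e.g. "1x" or "5x" aTc
    role: str  # "t0" or "selected"
    t0_pair: Optional[str] = None  # sample_id of the paired t0 (selected only)
    library_label: str = "lib"

    def __post_init__(self) -> None:
        if self.role not in ("t0", "selected"):
            raise ValidationError(f"sample {self.sample_id}: bad role {self.role!r}")
        if self.role == "selected" and not self.t0_pair:
            raise ValidationError(
                f"selected sample {self.sample_id} has no paired t0 sample"
            )


@dataclass
class CountTable:
    """Dense reads-per-barcode-per-sample matrix with sample metadata.

    ``counts`` is indexed by barcode with one integer column per sample;
    a barcode absent from a sample has count 0, never NaN.
    """

    counts: pd.DataFrame
    samples: dict[str, SampleMeta]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("negative read count")
        missing = set(self.counts.columns) - set(self.samples)
        if missing:
            raise ValidationError(f"samples missing from sheet: {sorted(missing)}")

    @property
    def barcodes(self) -> pd.Index:
        return self.counts.index

    def selected_pairs(self) -> list[tuple[str, str]]:
        """(selected sample, paired t0 sample) tuples, in sheet order."""
        return [
            (m.sample_id, m.t0_pair)
            for m in self.samples.values()
            if m.role == "selected"
        ]


@dataclass(frozen=True)
class FitnessParams:
    """Pseudocount and significance thresholds for the fitness statistics."""

    pseudocount: float = 0.5  # reads added per barcode
    tau_f: float = 5.0  # log2-fitness threshold (strict >)
    tau_z: float = 4.0  # z threshold (strict >)

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.tau_f <= 0 or self.tau_z <= 0:
            raise ValidationError("thresholds must be positive")


@dataclass(frozen=True)
class BarcodeExtractionSpec:
    """Where the 20-nt barcode sits in a BarSeq read.

    Defaults follow the amplicon layout: the barcode is flanked by
    ``...CGTACG`` upstream and ``AGAGACCTCGTGGACATC`` downstream.
    ``min_quality`` is 0 when counting for fitness and 30 when estimating
    library diversity.
    """

    upstream_flank: str = "CGTACG"
    downstream_flank: str = "AGAGACCTCGTGGACATC"
    barcode_length: int = BARCODE_LENGTH
    min_quality: int = 0

    def __post_init__(self) -> None:
        if not self.upstream_flank or not self.downstream_flank:
            raise ValidationError("flanks must be non-empty")
        if self.barcode_length != BARCODE_LENGTH:
            raise ValidationError("barcode_length must be 20")


@dataclass
class LibraryStats:
    """Per-library QC summary: insert-size moments, genes-per-fragment and
    fragments-per-gene breakdowns, and full-containment gene coverage."""

    n_mapped_fragments: int
    insert_mean: float
    insert_sd: float
    genes_per_fragment: dict[str, float]  # keys "0","1","2","3+" -> fractions
    genes_per_fragment_mean: float
    fragments_per_gene: dict[str, float]
    fragments_per_gene_mean: float
    gene_coverage: float  # fraction of genes fully contained in >=1 fragment


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic screen generator.

    The defaults encode the study conditions the generator emulates:
    ~3 kb sheared fragments size-selected to a 1.5-5 kb gel window,
    random 20-nt barcodes, log-normal starting abundances with ~13%
    transformation dropout, all-or-nothing colony selection with sense
    fragments succeeding at 0.66 and antisense at 0.35, ~2^10 enrichment
    of winners, a small shared "faint colony" background mass, and a
    1e-3 per-base sequencing error rate.
    """

    seed: int = 0
    genome_length: int = 200_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (600, 1800)
    gc_fraction: float = 0.5
    n_fragments: int = 2000
    fragment_mean: float = 3000.0
    fragment_sd: float = 800.0
    fragment_window: tuple[int, int] = (1500, 5000)
    t0_lognormal_sigma: float = 1.0
    t0_dropout: float = 0.13
    depth_t0: int = 500_000
    depth_sel: int = 500_000
    complementing_genes: tuple[str, ...] = ()
    p_sense: float = 0.66
    p_antisense: float = 0.35
    enrichment_log2: float = 10.0
    background_mass: float = 1e-4
    read_error_rate: float = 0.001
    low_quality_fraction: float = 0.0  # fraction of bases given Q < 30
    genome_id: str = "simg1"
    background: str = "dmut"

    def __post_init__(self) -> None:
        for name in ("t0_dropout", "p_sense", "p_antisense", "background_mass",
                     "read_error_rate", "low_quality_fraction", "gc_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.fragment_window
        if not (0 < lo <= hi <= self.genome_length):
            raise ValidationError("fragment_window outside (0, genome_length]")
        if self.depth_t0 <= 0 or self.depth_sel <= 0:
            raise ValidationError("sequencing depths must be positive")


@dataclass
class GroundTruth:
    """Simulation bookkeeping for one barcode."""

    barcode: str
    carries_full_length: Optional[str] = None  # gene_id of a contained gene
    sense: bool = False  # orientation of that gene w.r.t. the promoter
    dropped_at_t0: bool = False
    selected_winner: bool = False


@dataclass
class Hit:
    """A barcode x background with at least one significant experiment."""

    barcode: str
    background: str
    significant_in: list[str] = field(default_factory=list)
    confirmation: str = "none"  # overlap_same_experiment | replicate_other_experiment | both | none
    mean_f: float = float("nan")  # mean f across the background's experiments

    @property
    def high_confidence(self) -> bool:
        return bool(self.significant_in) and self.confirmation != "none"


@dataclass
class Region:
    """Union interval of transitively overlapping high-confidence inserts
    within one mutant background and source genome."""

    background: str
    genome_id: str
    start: int
    end: int
    member_barcodes: list[str]
    best_barcode: str
    best_mean_f: float
    associated_genes: list[str]
    nearly_full_genes: list[str]
    orf_class: str  # one_orf | multi_orf | no_full_orf


@dataclass
class ExpectedHitStatus:
    """Computed recovery status of one a-priori expected complementing protein."""

    protein_id: str
    gene_id: str
    genome_id: str
    background: str
    in_library_full_length: bool = False
    detected_t0: bool = False
    any_sense_insert: bool = False
    recovered: str = "not_recovered"  # full_length | nearly_full_length | not_recovered
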