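"""Readers and writers for the pipeline's on-disk artifacts.

Formats: genome FASTA, gene annotation GFF3 (``gene``/``CDS`` features),
BarSeq reads FASTQ, and fixed-header TSV tables:

* mapping:   ``barcode  genome_id  start  end  vector_orientation``
* counts:    ``barcode  <sample_id> ...``
* sheet:     ``sample_id  background  inducer  role  t0_pair  library_label``
* expected:  ``protein_id  genome_id  background  gene_id``

Validation is strict by default; readers accepting ``permissive=True``
downgrade recoverable problems (duplicate barcodes) to warnings.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    CountTable,
    FragmentInsert,
    GeneAnnotation,
    SampleMeta,
    SimConfig,
    ValidationError,
)

PathLike = Union[str, Path]

MAPPING_COLUMNS = ["barcode", "genome_id", "start", "end", "vector_orientation"]
SHEET_COLUMNS = ["sample_id", "background", "inducer", "role", "t0_pair", "library_label"]
EXPECTED_COLUMNS = ["protein_id", "genome_id", "background", "gene_id"]


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path: PathLike) -> dict[str, str]:
    """Read genome FASTA into {genome_id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genomes: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in genomes.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 annotation

def read_annotation(path: PathLike, genome: Optional[dict[str, str]] = None) -> list[GeneAnnotation]:
    """Read protein-coding genes from a GFF3 file.

    One record per ``gene`` feature (``CDS`` features standing alone are
    also accepted); coordinates are copied 1-based inclusive.  When a
    ``genome`` dict is given, CDS sequences are extracted (reverse
    complemented for - strand genes).  Records are returned sorted by
    (genome_id, start, gene_id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    body = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not body:
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils wraps line info in the message
        raise ValidationError(f"malformed GFF3 {path}: {exc}") from exc

    genes: list[GeneAnnotation] = []
    feature_types = set(db.featuretypes())
    wanted = "gene" if "gene" in feature_types else "CDS"
    for feat in db.features_of_type(wanted):
        if feat.end < feat.start:
            raise ValidationError(
                f"{path}: feature {feat.id} has end < start ({feat.end} < {feat.start})"
            )
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        cds = None
        if genome is not None and feat.seqid in genome:
            cds = genome[feat.seqid][feat.start - 1 : feat.end]
            if feat.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            if len(cds) % 3 != 0:  # not a clean CDS; drop rather than fail
                cds = None
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                genome_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                cds_sequence=cds,
            )
        )
    genes.sort(key=lambda g: (g.genome_id, g.start, g.gene_id))
    return genes


def write_annotation(genes: Iterable[GeneAnnotation], path: PathLike) -> None:
    """Write genes as minimal GFF3 (gene + CDS feature per record)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.genome_id, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.genome_id}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.genome_id}\tsim\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID=cds-{g.gene_id};Parent={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# mapping table

def read_mapping_table(
    path: PathLike,
    permissive: bool = False,
    known_genomes: Optional[set[str]] = None,
) -> list[FragmentInsert]:
    """Read the barcode -> fragment mapping TSV.

    Duplicate barcodes raise in strict mode; with ``permissive=True`` the
    last row wins and a warning is issued.
    """
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "genome_id": str})
    missing = set(MAPPING_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"mapping table {path} missing columns {sorted(missing)}")
    dupes = df["barcode"][df["barcode"].duplicated()].unique().tolist()
    if dupes:
        if not permissive:
            raise ValidationError(f"duplicate barcodes in mapping table: {dupes}")
        warnings.warn(f"duplicate barcodes (last row wins): {dupes}")
        df = df.drop_duplicates("barcode", keep="last")
    inserts = [
        FragmentInsert(
            barcode=row.barcode,
            genome_id=row.genome_id,
            start=int(row.start),
            end=int(row.end),
            vector_orientation=row.vector_orientation,
        )
        for row in df.itertuples()
    ]
    if known_genomes is not None:
        unknown = {i.genome_id for i in inserts} - known_genomes
        if unknown:
            warnings.warn(f"mapping table references unknown genomes: {sorted(unknown)}")
    return inserts


def write_mapping_table(inserts: Iterable[FragmentInsert], path: PathLike) -> None:
    pd.DataFrame(
        [
            (i.barcode, i.genome_id, i.start, i.end, i.vector_orientation)
            for i in inserts
        ],
        columns=MAPPING_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts + experiment sheet

def read_sheet(path: PathLike) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sheet {path} missing columns {sorted(missing)}")
    samples = {}
    for row in df.itertuples():
        samples[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            background=row.background,
            inducer=row.inducer,
            role=row.role,
            t0_pair=row.t0_pair or None,
            library_label=row.library_label or "lib",
        )
    for m in samples.values():
        if m.role == "selected" and m.t0_pair not in samples:
            raise ValidationError(
                f"selected sample {m.sample_id} paired to unknown t0 {m.t0_pair!r}"
            )
    return samples


def write_sheet(samples: dict[str, SampleMeta], path: PathLike) -> None:
    pd.DataFrame(
        [
            (m.sample_id, m.background, m.inducer, m.role, m.t0_pair or "", m.library_label)
            for m in samples.values()
        ],
        columns=SHEET_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_count_table(counts_path: PathLike, sheet_path: PathLike) -> CountTable:
    """Read counts TSV + experiment sheet into a dense :class:`CountTable`.

    Every sample column must appear in the sheet; missing barcode cells
    become 0 reads (absent means not detected, not missing data).
    """
    samples = read_sheet(sheet_path)
    df = pd.read_csv(counts_path, sep="\t", dtype={"barcode": str})
    if "barcode" not in df.columns:
        raise ValidationError(f"counts table {counts_path} lacks a 'barcode' column")
    df = df.set_index("barcode")
    unknown = set(df.columns) - set(samples)
    if unknown:
        raise ValidationError(
            f"samples present in counts but absent from sheet: {sorted(unknown)}"
        )
    df = df.fillna(0).astype(int)
    if (df.values < 0).any():
        raise ValidationError("negative count in counts table")
    used = {sid: samples[sid] for sid in df.columns}
    # a selected sample's t0 pair must itself carry counts
    for m in used.values():
        if m.role == "selected" and m.t0_pair not in df.columns:
            raise ValidationError(
                f"selected sample {m.sample_id}: paired t0 {m.t0_pair} has no counts"
            )
    return CountTable(counts=df, samples=used)


def write_count_table(table: CountTable, counts_path: PathLike, sheet_path: Optional[PathLike] = None) -> None:
    table.counts.reset_index().rename(columns={"index": "barcode"}).to_csv(
        counts_path, sep="\t", index=False
    )
    if sheet_path is not None:
        write_sheet(table.samples, sheet_path)


# ---------------------------------------------------------------------------
# expected-hit table

def read_expected_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(EXPECTED_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"expected table {path} missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# config

def read_sim_config(path: PathLike) -> SimConfig:
    """Load a :class:`SimConfig` from a flat YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("gene_length_range", "fragment_window", "complementing_genes"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)
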