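"""Synthetic screen generator.

Emulates the data-generating process of a pooled auxotroph-complementation
screen with barcoded genomic fragments:

* a random genome with non-overlapping protein-coding genes;
* a sheared fragment library (truncated-normal lengths inside the gel
  window, uniform starts and orientations, unique random 20-nt barcodes);
* one t0 and one or more selected BarSeq samples.  Starting abundances
  are log-normal with an independent dropout fraction; selection is
  all-or-nothing per clone: a barcode whose fragment carries a full-length
  complementing gene wins with probability ``p_sense`` (sense w.r.t. the
  synthetic promoter) or ``p_antisense`` (antisense), winners are enriched
  by ``2**enrichment_log2``, and all non-winners share a small
  "faint colony" background mass; reads are multinomial at the configured
  depth;
* optionally, raw BarSeq FASTQ with per-base substitution errors.

Every operation draws from its own RNG stream seeded from
``(config.seed, fixed offset)`` so partial re-runs are reproducible.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    BARCODE_LENGTH,
    CountTable,
    FragmentInsert,
    GeneAnnotation,
    GroundTruth,
    SampleMeta,
    SimConfig,
    ValidationError,
)

# fixed stream offsets, one per operation
_STREAM_GENOME = 0
_STREAM_SHEAR = 1
_STREAM_EXPERIMENT = 2
_STREAM_READS = 3

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(config: SimConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), offset])


def simulate_genome(config: SimConfig) -> tuple[str, list[GeneAnnotation]]:
    """Random genome sequence plus non-overlapping gene annotation.

    Gene lengths are uniform on ``gene_length_range`` rounded down to a
    multiple of 3; genes are separated by random gaps and get random
    strands.  Raises if the requested genes cannot fit.
    """
    rng = _rng(config, _STREAM_GENOME)
    L, n = config.genome_length, config.n_genes
    lo, hi = config.gene_length_range
    lengths = (rng.integers(lo, hi + 1, size=n) // 3) * 3 if n else np.array([], dtype=int)
    total = int(lengths.sum())
    spare = L - total
    if spare < n + 1:
        raise ValidationError(
            f"cannot place {n} genes totalling {total} nt in {L} nt genome"
        )
    # distribute spare length over n+1 gaps (each >= 1 where possible)
    cuts = np.sort(rng.choice(spare, size=n, replace=False)) if n else np.array([], dtype=int)
    gaps = np.diff(np.concatenate([[0], cuts, [spare]]))
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq_arr = rng.choice(_BASES, size=L, p=p)
    seq = bytearray(seq_arr.tobytes())

    # proper ORFs: ATG start, sense codons biased to the genome GC, one
    # terminal stop, no internal stops
    sense_codons = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    codon_p = np.array(
        [np.prod([p["ACGT".index(ch)] for ch in codon]) for codon in sense_codons]
    )
    codon_p /= codon_p.sum()
    stops = ("TAA", "TAG", "TGA")
    comp = str.maketrans("ACGT", "TGCA")

    genes = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        start = pos + 1  # 1-based
        end = start + int(lengths[i]) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(lengths[i]) // 3
        body = rng.choice(len(sense_codons), size=n_codons - 2, p=codon_p)
        cds = "ATG" + "".join(sense_codons[j] for j in body) + stops[rng.integers(3)]
        planted = cds if strand == "+" else cds[::-1].translate(comp)
        seq[start - 1 : end] = planted.encode()
        genes.append(
            GeneAnnotation(
                gene_id=f"gene{i + 1:04d}",
                genome_id=config.genome_id,
                start=start,
                end=end,
                strand=strand,
                cds_sequence=cds,
            )
        )
        pos = end
    return seq.decode(), genes


def _random_barcodes(rng: np.random.Generator, n: int, max_retries: int = 20) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for _ in range(max_retries):
        need = n - len(out)
        if need == 0:
            return out
        draw = rng.integers(0, 4, size=(need, BARCODE_LENGTH))
        for row in draw:
            bc = "".join("ACGT"[b] for b in row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    raise ValidationError(f"could not draw {n} unique barcodes")


def shear_library(
    genome: str,
    annotation: list[GeneAnnotation],
    config: SimConfig,
) -> tuple[list[FragmentInsert], dict[str, GroundTruth]]:
    """Simulate shearing + gel size selection + barcoded cloning.

    Fragment lengths follow Normal(fragment_mean, fragment_sd) truncated
    to the gel window; starts are uniform; vector orientation is uniform
    +/-.  Ground truth records, per barcode, which complementing gene (if
    any) is fully carried and whether it is sense to the promoter; when
    no complementing gene is carried, the first fully contained gene is
    recorded instead.
    """
    rng = _rng(config, _STREAM_SHEAR)
    L = len(genome)
    lo, hi = config.fragment_window
    a = (lo - config.fragment_mean) / config.fragment_sd
    b = (hi - config.fragment_mean) / config.fragment_sd
    lengths = stats.truncnorm.rvs(
        a, b, loc=config.fragment_mean, scale=config.fragment_sd,
        size=config.n_fragments, random_state=rng,
    ).round().astype(int)
    lengths = np.clip(lengths, lo, min(hi, L))
    starts = rng.integers(1, L - lengths + 2)  # 1-based, end <= L
    orientations = np.where(rng.random(config.n_fragments) < 0.5, "+", "-")
    barcodes = _random_barcodes(rng, config.n_fragments)

    complementing = set(config.complementing_genes)
    genes_sorted = sorted(annotation, key=lambda g: g.start)
    inserts: list[FragmentInsert] = []
    truth: dict[str, GroundTruth] = {}
    for bc, s, ln, o in zip(barcodes, starts, lengths, orientations):
        ins = FragmentInsert(
            barcode=bc,
            genome_id=config.genome_id,
            start=int(s),
            end=int(s + ln - 1),
            vector_orientation=str(o),
        )
        inserts.append(ins)
        contained = [g for g in genes_sorted if ins.contains_gene(g)]
        carried = next((g for g in contained if g.gene_id in complementing), None)
        if carried is None and contained:
            carried = contained[0]
        truth[bc] = GroundTruth(
            barcode=bc,
            carries_full_length=carried.gene_id if carried else None,
            sense=bool(carried and ins.gene_is_sense(carried)),
        )
    return inserts, truth


def simulate_experiment(
    mapping: list[FragmentInsert],
    truth: dict[str, GroundTruth],
    config: SimConfig,
    n_selected: int = 1,
) -> CountTable:
    """Simulate one t0 sample plus ``n_selected`` selected samples.

    Winner indicators are drawn once per barcode (a clone either forms a
    colony lineage or it does not), so selected samples of one screen act
    as replicates at different inducer labels.
    """
    if not mapping:
        raise ValidationError("empty mapping")
    rng = _rng(config, _STREAM_EXPERIMENT)
    barcodes = [i.barcode for i in mapping]
    n = len(barcodes)

    abundance = rng.lognormal(mean=0.0, sigma=config.t0_lognormal_sigma, size=n)
    dropped = rng.random(n) < config.t0_dropout
    abundance[dropped] = 0.0
    if abundance.sum() == 0:
        raise ValidationError("no barcodes detectable at t0")
    t0_p = abundance / abundance.sum()
    t0_counts = rng.multinomial(config.depth_t0, t0_p)

    complementing = set(config.complementing_genes)
    winners = np.zeros(n, dtype=bool)
    for j, bc in enumerate(barcodes):
        gt = truth[bc]
        gt.dropped_at_t0 = bool(dropped[j])
        carries = gt.carries_full_length in complementing
        if carries and abundance[j] > 0:
            p_win = config.p_sense if gt.sense else config.p_antisense
            gt.selected_winner = bool(rng.random() < p_win)
            winners[j] = gt.selected_winner
        else:
            gt.selected_winner = False

    # post-selection mass: winners get t0 abundance * 2^enrichment, then
    # are normalised to (1 - background_mass); non-winners share the
    # background mass in proportion to their t0 abundance.  With no
    # winners everything is background growth, i.e. the t0 distribution.
    if winners.any():
        wmass = abundance * np.exp2(config.enrichment_log2) * winners
        wmass = wmass / wmass.sum() * (1.0 - config.background_mass)
        nw = abundance * ~winners
        nwmass = nw / nw.sum() * config.background_mass if nw.sum() > 0 else nw
        sel_p = wmass + nwmass
    else:
        sel_p = t0_p.copy()
    sel_p = sel_p / sel_p.sum()

    data = {"t0": t0_counts}
    samples = {
        "t0": SampleMeta(
            sample_id="t0", background=config.background, inducer="",
            role="t0", library_label="sim",
        )
    }
    inducers = ["1x", "5x"] + [f"{k}x" for k in range(3, n_selected + 1)]
    for k in range(n_selected):
        sid = f"sel{k + 1}"
        data[sid] = rng.multinomial(config.depth_sel, sel_p)
        samples[sid] = SampleMeta(
            sample_id=sid, background=config.background, inducer=inducers[k],
            role="selected", t0_pair="t0", library_label="sim",
        )
    counts = pd.DataFrame(data, index=pd.Index(barcodes, name="barcode"))
    return CountTable(counts=counts, samples=samples)


def emit_barseq_reads(
    table: CountTable,
    config: SimConfig,
    out_dir: Optional[Path] = None,
    upstream: str = "GTCGACCTGCAGCGTACG",
    downstream: str = "AGAGACCTCGTGGACATC",
) -> dict[str, Path] | dict[str, list[str]]:
    """Emit one FASTQ record per counted read: flank + barcode + flank.

    Per-base substitution errors occur at ``read_error_rate``; qualities
    are Q37 except a ``low_quality_fraction`` of bases set to Q20.  When
    ``out_dir`` is given, writes ``<sample>.fastq`` files and returns
    their paths; otherwise returns the FASTQ text lines per sample.
    """
    rng = _rng(config, _STREAM_READS)
    tmpl = upstream + "{bc}" + downstream
    read_len = len(upstream) + BARCODE_LENGTH + len(downstream)
    hi_q = chr(37 + 33)
    lo_q = chr(20 + 33)
    sub = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}

    out: dict = {}
    for sid in table.counts.columns:
        lines: list[str] = []
        col = table.counts[sid]
        ridx = 0
        for bc, cnt in col.items():
            seq0 = tmpl.format(bc=bc)
            for _ in range(int(cnt)):
                seq = seq0
                if config.read_error_rate > 0:
                    nerr = rng.binomial(read_len, config.read_error_rate)
                    if nerr:
                        chars = list(seq)
                        for pos in rng.choice(read_len, size=nerr, replace=False):
                            chars[pos] = sub[chars[pos]][rng.integers(3)]
                        seq = "".join(chars)
                qual = hi_q * read_len
                if config.low_quality_fraction > 0:
                    nlo = rng.binomial(read_len, config.low_quality_fraction)
                    if nlo:
                        qchars = list(qual)
                        for pos in rng.choice(read_len, size=nlo, replace=False):
                            qchars[pos] = lo_q
                        qual = "".join(qchars)
                ridx += 1
                lines.extend((f"@{sid}.{ridx} {bc}", seq, "+", qual))
        if out_dir is not None:
            path = Path(out_dir) / f"{sid}.fastq"
            path.write_text("\n".join(lines) + ("\n" if lines else ""))
            out[sid] = path
        else:
            out[sid] = lines
    return out


def simulate_screen(config: SimConfig, n_selected: int = 1):
    """Convenience wrapper: genome -> library -> experiment.

    Returns (genome sequence, annotation, mapping, ground truth, counts).
    """
    genome, annotation = simulate_genome(config)
    mapping, truth = shear_library(genome, annotation, config)
    counts = simulate_experiment(mapping, truth, config, n_selected=n_selected)
    return genome, annotation, mapping, truth, counts


def default_complementing_genes(annotation: Iterable[GeneAnnotation], k: int, seed: int) -> tuple[str, ...]:
    """Pick ``k`` genes (deterministically under ``seed``) to act as the
    complementing set for a screen."""
    ids = sorted(g.gene_id for g in annotation)
    rng = np.random.default_rng([seed, 99])
    return tuple(sorted(rng.choice(ids, size=min(k, len(ids)), replace=False)))
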