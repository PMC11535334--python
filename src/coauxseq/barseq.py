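"""BarSeq read processing: barcode extraction, counting, off-by-1
collapse, and library-diversity estimation.

Counting for fitness uses ``min_quality=0``; diversity estimation uses
``min_quality=30``, under which the per-barcode error probability is
bounded by 20 x 0.001 = 2% (union bound over the 20 positions at the
Q30 per-base error ceiling of 0.001).
"""
from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import BarcodeExtractionSpec, ValidationError

# rejection reasons, in tally order
REASONS = ("no_flank", "wrong_length", "ambiguous_base", "low_quality")


def extract_barcode(
    sequence: str,
    quality: str,
    spec: BarcodeExtractionSpec = BarcodeExtractionSpec(),
) -> tuple[str | None, str | None]:
    """Extract the barcode between exact flank matches.

    Returns ``(barcode, None)`` on success or ``(None, reason)`` where
    reason is one of :data:`REASONS`.  The barcode must be exactly
    ``spec.barcode_length`` nt (i.e. the downstream flank must follow
    immediately), contain no N, and every base must have Phred quality
    >= ``spec.min_quality``.
    """
    if len(sequence) != len(quality):
        raise ValidationError("sequence/quality length mismatch")
    up = sequence.find(spec.upstream_flank)
    if up < 0:
        return None, "no_flank"
    bc_start = up + len(spec.upstream_flank)
    down = sequence.find(spec.downstream_flank, bc_start)
    if down < 0:
        return None, "no_flank"
    if down - bc_start != spec.barcode_length:
        return None, "wrong_length"
    barcode = sequence[bc_start:down]
    if "N" in barcode:
        return None, "ambiguous_base"
    if spec.min_quality > 0:
        for q in quality[bc_start:down]:
            if ord(q) - 33 < spec.min_quality:
                return None, "low_quality"
    return barcode, None


def count_barcodes(
    fastq: Union[str, Path, TextIO, Iterable[str]],
    spec: BarcodeExtractionSpec = BarcodeExtractionSpec(),
) -> tuple[Counter[str], Counter[str]]:
    """Count accepted barcodes in a FASTQ stream.

    Returns ``(counts, rejection tally)``.  Conservation holds:
    ``sum(counts.values()) + sum(tally.values())`` equals the number of
    reads in the stream.
    """
    if isinstance(fastq, (str, Path)):
        with open(fastq) as fh:
            return count_barcodes(fh, spec)
    if not hasattr(fastq, "read") and isinstance(fastq, Iterable) and not hasattr(fastq, "readline"):
        # accept a list of FASTQ lines
        import io

        lines = list(fastq)
        fastq = io.StringIO("\n".join(lines) + "\n" if lines else "")
    counts: Counter[str] = Counter()
    tally: Counter[str] = Counter()
    for _title, seq, qual in FastqGeneralIterator(fastq):
        barcode, reason = extract_barcode(seq.upper(), qual, spec)
        if barcode is None:
            tally[reason] += 1
        else:
            counts[barcode] += 1
    return counts, tally


def _neighbors(barcode: str) -> Iterable[str]:
    for i, base in enumerate(barcode):
        for other in "ACGT":
            if other != base:
                yield barcode[:i] + other + barcode[i + 1 :]


def collapse_offby1(counts: dict[str, int]) -> dict[str, int]:
    """Eliminate barcodes that are off-by-1 errors of a more common one.

    A barcode is removed when some barcode at Hamming distance 1 has a
    *strictly* greater count (ties keep both); its reads are discarded,
    not reassigned.  Decisions use the input counts, so the operation is
    idempotent and order-independent, and the result never contains a
    distance-1 pair with unequal counts.
    """
    lengths = {len(b) for b in counts}
    if len(lengths) > 1:
        raise ValidationError(f"mixed barcode lengths: {sorted(lengths)}")
    kept = {}
    for bc, cnt in counts.items():
        if not any(counts.get(nb, 0) > cnt for nb in _neighbors(bc)):
            kept[bc] = cnt
    return kept


def estimate_diversity(counts: dict[str, int]) -> int:
    """Number of distinct barcodes after Q>=30 filtering and off-by-1
    collapse (the inputs are assumed to have been produced that way)."""
    return sum(1 for c in counts.values() if c > 0)
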