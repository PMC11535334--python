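"""Library QC: insert-size moments, genes-per-fragment and
fragments-per-gene breakdowns, and gene coverage.

"Covered" means the gene is fully contained in at least one mapped
fragment (the containment relevant to complementation), which makes
``gene_coverage == 1 - fragments_per_gene["0"]`` an identity.
Fragments must satisfy ``start <= end``; origin-spanning fragments of
circular genomes are not supported.
"""
from __future__ import annotations

import warnings
from bisect import bisect_right

import numpy as np

from .types import FragmentInsert, GeneAnnotation, LibraryStats, ValidationError

_BINS = ("0", "1", "2", "3+")


def genes_in_fragment(
    insert: FragmentInsert,
    annotation: list[GeneAnnotation],
) -> list[str]:
    """Gene ids fully contained in the insert (same genome, strand-agnostic)."""
    genomes = {g.genome_id for g in annotation}
    if insert.genome_id not in genomes:
        raise ValidationError(f"genome {insert.genome_id!r} not in annotation")
    return [g.gene_id for g in annotation if insert.contains_gene(g)]


def _containment_pairs(
    mapping: list[FragmentInsert], annotation: list[GeneAnnotation]
) -> list[tuple[str, str]]:
    """(barcode, gene_id) pairs for every full containment.

    Genes are bucketed per genome and sorted by start so each fragment
    only scans genes starting within its interval.
    """
    by_genome: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_genome.setdefault(g.genome_id, []).append(g)
    for genes in by_genome.values():
        genes.sort(key=lambda g: g.start)
    starts = {gid: [g.start for g in genes] for gid, genes in by_genome.items()}

    pairs = []
    for ins in mapping:
        genes = by_genome.get(ins.genome_id, [])
        if not genes:
            continue
        st = starts[ins.genome_id]
        lo = bisect_right(st, ins.start - 1)
        hi = bisect_right(st, ins.end)
        for g in genes[lo:hi]:
            if g.end <= ins.end:
                pairs.append((ins.barcode, g.gene_id))
    return pairs


def _bin_fractions(counts: np.ndarray) -> dict[str, float]:
    n = len(counts)
    if n == 0:
        return {b: 0.0 for b in _BINS}
    return {
        "0": float((counts == 0).sum() / n),
        "1": float((counts == 1).sum() / n),
        "2": float((counts == 2).sum() / n),
        "3+": float((counts >= 3).sum() / n),
    }


def library_stats(
    mapping: list[FragmentInsert],
    annotation: list[GeneAnnotation],
) -> LibraryStats:
    """Compute :class:`LibraryStats` for one mapped library.

    The two breakdown means satisfy the pair-count identity
    ``mean(genes_per_fragment) * n_fragments ==
    mean(fragments_per_gene) * n_genes`` (both count the full-containment
    (fragment, gene) pairs).
    """
    if not mapping:
        raise ValidationError("empty mapping")
    lengths = np.array([i.length for i in mapping], dtype=float)
    pairs = _containment_pairs(mapping, annotation)

    per_fragment = {i.barcode: 0 for i in mapping}
    per_gene = {g.gene_id: 0 for g in annotation}
    for bc, gid in pairs:
        per_fragment[bc] += 1
        per_gene[gid] += 1
    gpf = np.array(list(per_fragment.values()))
    fpg = np.array(list(per_gene.values()))

    if len(fpg) == 0:
        warnings.warn("no genes in annotation; gene_coverage reported as 0")
        coverage = 0.0
        fpg_mean = 0.0
    else:
        coverage = float((fpg > 0).sum() / len(fpg))
        fpg_mean = float(fpg.mean())

    return LibraryStats(
        n_mapped_fragments=len(mapping),
        insert_mean=float(lengths.mean()),
        insert_sd=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        genes_per_fragment=_bin_fractions(gpf),
        genes_per_fragment_mean=float(gpf.mean()),
        fragments_per_gene=_bin_fractions(fpg),
        fragments_per_gene_mean=fpg_mean,
        gene_coverage=coverage,
    )
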