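"""Hit calling: significance flags, high-confidence confirmation,
region merging, gene association, and the fitness-cutoff scan.

A fragment is *significant* in an experiment when f > tau_f and
z > tau_z (strict, defaults 5 and 4).  A significant fragment becomes a
*high-confidence* hit in a mutant background when either

1. an overlapping fragment (same source genome, >= 1 shared bp) was also
   significant in that same experiment, or
2. the fragment was significant in another experiment of the same
   background (regardless of induction level).

High-confidence inserts are then merged, per (background, genome), into
regions: connected components of the interval-overlap graph, reported as
the union span.  Each region is associated with the genes fully
contained in its highest-mean-fitness insert; genes that are >= 90%
contained including the start codon are reported separately as "nearly
full length" and do not enter the ORF classification.
"""
from __future__ import annotations

import warnings
from typing import Optional

import pandas as pd

from .types import (
    FitnessParams,
    FragmentInsert,
    GeneAnnotation,
    Hit,
    Region,
    ValidationError,
)

NEARLY_FULL_FRACTION = 0.9


def flag_significant(records: pd.DataFrame, params: FitnessParams = FitnessParams()) -> pd.Series:
    """Boolean per fitness record: f > tau_f and z > tau_z (strict)."""
    return (records["f"] > params.tau_f) & (records["z"] > params.tau_z)


def significant_instances(records: pd.DataFrame, params: FitnessParams = FitnessParams()) -> pd.DataFrame:
    """Distinct (barcode, background) pairs significant in >= 1 experiment
    — the pre-confirmation "instances" layer of the screen."""
    sig = records[flag_significant(records, params)]
    return sig[["barcode", "background"]].drop_duplicates().reset_index(drop=True)


def _overlaps(a: FragmentInsert, b: FragmentInsert) -> bool:
    return (
        a.genome_id == b.genome_id
        and a.start <= b.end
        and b.start <= a.end
    )


def confirm_hits(
    records: pd.DataFrame,
    mapping: list[FragmentInsert],
    params: FitnessParams = FitnessParams(),
) -> tuple[list[Hit], list[str]]:
    """Build confirmed :class:`Hit` objects from fitness records.

    Returns ``(hits, unmapped)`` where ``hits`` holds one entry per
    significant (barcode, background) with its confirmation status and
    background-mean fitness, and ``unmapped`` lists significant barcodes
    missing from the mapping table (excluded from hits).
    """
    by_barcode = {i.barcode: i for i in mapping}
    sig_mask = flag_significant(records, params)
    sig = records[sig_mask]

    unmapped = sorted(set(sig["barcode"]) - set(by_barcode))
    if unmapped:
        warnings.warn(f"{len(unmapped)} significant barcodes missing from mapping")
    sig = sig[sig["barcode"].isin(by_barcode)]

    mean_f = (
        records[records["barcode"].isin(by_barcode)]
        .groupby(["barcode", "background"])["f"]
        .mean()
    )

    # per experiment: the set of significant inserts, for overlap lookup
    sig_by_exp: dict[str, list[FragmentInsert]] = {}
    for exp_id, group in sig.groupby("experiment_id"):
        sig_by_exp[exp_id] = [by_barcode[bc] for bc in group["barcode"]]

    hits: list[Hit] = []
    for (bc, background), group in sig.groupby(["barcode", "background"], sort=True):
        exps = sorted(group["experiment_id"].unique())
        ins = by_barcode[bc]
        overlap = any(
            _overlaps(ins, other)
            for exp_id in exps
            for other in sig_by_exp[exp_id]
            if other.barcode != bc
        )
        replicate = len(exps) >= 2
        if overlap and replicate:
            confirmation = "both"
        elif overlap:
            confirmation = "overlap_same_experiment"
        elif replicate:
            confirmation = "replicate_other_experiment"
        else:
            confirmation = "none"
        hits.append(
            Hit(
                barcode=bc,
                background=background,
                significant_in=exps,
                confirmation=confirmation,
                mean_f=float(mean_f.loc[(bc, background)]),
            )
        )
    return hits, unmapped


def merge_regions(hits: list[Hit], mapping: list[FragmentInsert]) -> list[Region]:
    """Merge high-confidence hits into regions.

    Connected components of the overlap graph per (background, genome),
    computed by a sort-and-sweep (overlap is transitive along the sweep).
    Regions are returned sorted by (background, genome, start); gene
    association fields are left empty until :func:`associate_genes`.
    """
    by_barcode = {i.barcode: i for i in mapping}
    groups: dict[tuple[str, str], list[Hit]] = {}
    for h in hits:
        if not h.high_confidence:
            continue
        if h.barcode not in by_barcode:
            raise ValidationError(f"hit barcode {h.barcode} missing from mapping")
        ins = by_barcode[h.barcode]
        groups.setdefault((h.background, ins.genome_id), []).append(h)

    regions: list[Region] = []
    for (background, genome_id), members in sorted(groups.items()):
        members.sort(key=lambda h: (by_barcode[h.barcode].start, h.barcode))
        current: list[Hit] = []
        cur_start = cur_end = None
        for h in members:
            ins = by_barcode[h.barcode]
            if current and ins.start <= cur_end:  # >= 1 shared bp (1-based inclusive)
                current.append(h)
                cur_end = max(cur_end, ins.end)
            else:
                if current:
                    regions.append(
                        _make_region(background, genome_id, cur_start, cur_end, current, by_barcode)
                    )
                current = [h]
                cur_start, cur_end = ins.start, ins.end
        if current:
            regions.append(
                _make_region(background, genome_id, cur_start, cur_end, current, by_barcode)
            )
    return regions


def _make_region(background, genome_id, start, end, members, by_barcode) -> Region:
    # best insert: max mean_f; ties -> longer insert, then lexicographic barcode
    best = min(
        members,
        key=lambda h: (-h.mean_f, -by_barcode[h.barcode].length, h.barcode),
    )
    return Region(
        background=background,
        genome_id=genome_id,
        start=start,
        end=end,
        member_barcodes=[h.barcode for h in members],
        best_barcode=best.barcode,
        best_mean_f=best.mean_f,
        associated_genes=[],
        nearly_full_genes=[],
        orf_class="",
    )


def nearly_contains(insert: FragmentInsert, gene: GeneAnnotation, fraction: float = NEARLY_FULL_FRACTION) -> bool:
    """True when the insert covers >= ``fraction`` of the gene including
    its start codon (5' end on the coding strand), but not the whole gene."""
    if gene.genome_id != insert.genome_id:
        return False
    if insert.contains_gene(gene):
        return False
    overlap = min(insert.end, gene.end) - max(insert.start, gene.start) + 1
    if overlap < fraction * gene.length:
        return False
    start_codon_pos = gene.start if gene.strand == "+" else gene.end
    return insert.start <= start_codon_pos <= insert.end


def associate_genes(
    region: Region,
    annotation: list[GeneAnnotation],
    mapping: list[FragmentInsert],
) -> Region:
    """Fill a region's associated genes and ORF class from its best insert."""
    by_barcode = {i.barcode: i for i in mapping}
    ins = by_barcode[region.best_barcode]
    genes = [g for g in annotation if g.genome_id == ins.genome_id]
    region.associated_genes = sorted(
        g.gene_id for g in genes if ins.contains_gene(g)
    )
    region.nearly_full_genes = sorted(
        g.gene_id for g in genes if nearly_contains(ins, g)
    )
    n = len(region.associated_genes)
    region.orf_class = "no_full_orf" if n == 0 else ("one_orf" if n == 1 else "multi_orf")
    return region


def call_regions(
    records: pd.DataFrame,
    mapping: list[FragmentInsert],
    annotation: list[GeneAnnotation],
    params: FitnessParams = FitnessParams(),
) -> tuple[list[Hit], list[Region]]:
    """Full chain: significance -> confirmation -> regions -> genes."""
    hits, _ = confirm_hits(records, mapping, params)
    regions = merge_regions(hits, mapping)
    for r in regions:
        associate_genes(r, annotation, mapping)
    return hits, regions


def cutoff_scan(
    records: pd.DataFrame,
    mapping: list[FragmentInsert],
    annotation: list[GeneAnnotation],
    expected: Optional[pd.DataFrame],
    tau_f_grid: tuple[float, ...] = (5.0, 6.0, 7.0),
    params: FitnessParams = FitnessParams(),
) -> pd.DataFrame:
    """Re-run the pipeline at each fitness cutoff.

    Returns one row per cutoff with the number of expected proteins
    recovered (full or nearly full length on a high-confidence insert of
    the right background) and the number of regions not associated with
    any expected gene.  Raising the cutoff can only shrink both counts'
    underlying hit sets.
    """
    by_gene = {g.gene_id: g for g in annotation}
    rows = []
    for tau_f in tau_f_grid:
        p = FitnessParams(pseudocount=params.pseudocount, tau_f=tau_f, tau_z=params.tau_z)
        hits, regions = call_regions(records, mapping, annotation, p)
        by_barcode = {i.barcode: i for i in mapping}
        n_recovered = 0
        expected_genes_by_bg: dict[str, set[str]] = {}
        if expected is not None and len(expected):
            for row in expected.itertuples():
                expected_genes_by_bg.setdefault(row.background, set()).add(row.gene_id)
                gene = by_gene.get(row.gene_id)
                if gene is None:
                    continue
                hc_inserts = [
                    by_barcode[h.barcode]
                    for h in hits
                    if h.high_confidence and h.background == row.background
                ]
                if any(
                    i.contains_gene(gene) or nearly_contains(i, gene) for i in hc_inserts
                ):
                    n_recovered += 1
        n_unexpected = sum(
            1
            for r in regions
            if not (set(r.associated_genes) & expected_genes_by_bg.get(r.background, set()))
        )
        rows.append((tau_f, n_recovered, n_unexpected))
    return pd.DataFrame(rows, columns=["tau_f", "n_expected_recovered", "n_unexpected_regions"])
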