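#!/usr/bin/env python
"""Fitness statistics and hit calling on the simulated screen.

Computes per-barcode fitness f and z for each selected/t0 pair, flags
significant fragments (f > 5 and z > 4), confirms high-confidence hits
by overlap or replication, merges them into regions with associated
genes, and scans the fitness cutoff from 5 to 7.  Writes
results/fitness.tsv, hits.tsv, regions.tsv, cutoff_scan.tsv."""
from pathlib import Path

import pandas as pd

from coauxseq import io
from coauxseq.fitness import fitness_table
from coauxseq.hits import call_regions, cutoff_scan, significant_instances

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    screen = ROOT / "screen"
    counts = io.read_count_table(screen / "counts.tsv", screen / "sheet.tsv")
    mapping = io.read_mapping_table(screen / "mapping.tsv")
    annotation = io.read_annotation(screen / "annotation.gff3")
    expected = io.read_expected_table(screen / "expected.tsv")

    records = fitness_table(counts)
    records.to_csv(ROOT / "fitness.tsv", sep="\t", index=False)

    hits, regions = call_regions(records, mapping, annotation)
    hc = [h for h in hits if h.high_confidence]
    pd.DataFrame(
        [
            (h.barcode, h.background, ";".join(h.significant_in), h.confirmation,
             int(h.high_confidence), round(h.mean_f, 3))
            for h in hits
        ],
        columns=["barcode", "background", "significant_in", "confirmation",
                 "high_confidence", "mean_f"],
    ).to_csv(ROOT / "hits.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (r.background, r.genome_id, r.start, r.end, len(r.member_barcodes),
             r.best_barcode, round(r.best_mean_f, 3), ";".join(r.associated_genes),
             ";".join(r.nearly_full_genes), r.orf_class)
            for r in regions
        ],
        columns=["background", "genome_id", "start", "end", "n_members",
                 "best_barcode", "best_mean_f", "associated_genes",
                 "nearly_full_genes", "orf_class"],
    ).to_csv(ROOT / "regions.tsv", sep="\t", index=False)

    scan = cutoff_scan(records, mapping, annotation, expected, (5.0, 6.0, 7.0))
    scan.to_csv(ROOT / "cutoff_scan.tsv", sep="\t", index=False)

    n_inst = len(significant_instances(records))
    print(f"{n_inst} significant fragment x background instances")
    print(f"{len(hc)} high-confidence hits -> {len(regions)} regions")
    for cls in ("one_orf", "multi_orf", "no_full_orf"):
        print(f"  {cls}: {sum(r.orf_class == cls for r in regions)}")
    print("cutoff scan (tau_f, expected recovered, unexpected regions):")
    for row in scan.itertuples(index=False):
        print(f"  {row.tau_f:>3} {row.n_expected_recovered:>3} {row.n_unexpected_regions:>3}")


if __name__ == "__main__":
    main()
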