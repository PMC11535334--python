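#!/usr/bin/env python
"""Generate the synthetic complementation screen used by the downstream
analysis steps.

Produces, under results/screen/: the source genome (FASTA), its gene
annotation (GFF3), the barcode->fragment mapping table, BarSeq count
tables for one t0 and two selected samples (1x and 5x inducer), the
experiment sheet, the expected-hit table, and the simulation ground
truth.  The screen has 25,000 ~3 kb fragments over a 400 kb genome with
60 genes, six of which complement the mutant background.
"""
import dataclasses
import sys
from pathlib import Path

import pandas as pd

from coauxseq import SimConfig
from coauxseq import io
from coauxseq import simulate as sim

SEED = 20240901 % (2**31 - 1)
OUT = Path(__file__).resolve().parent.parent / "results" / "screen"


def main(seed: int = SEED) -> None:
    cfg = SimConfig(
        seed=seed, genome_length=400_000, n_genes=60, n_fragments=25_000,
        depth_t0=1_000_000, depth_sel=1_000_000,
    )
    _, annotation = sim.simulate_genome(cfg)
    comp = sim.default_complementing_genes(annotation, 6, seed)
    cfg = dataclasses.replace(cfg, complementing_genes=comp)
    genome, annotation, mapping, truth, counts = sim.simulate_screen(cfg, n_selected=2)

    OUT.mkdir(parents=True, exist_ok=True)
    io.write_genome({cfg.genome_id: genome}, OUT / "genome.fasta")
    io.write_annotation(annotation, OUT / "annotation.gff3")
    io.write_mapping_table(mapping, OUT / "mapping.tsv")
    io.write_count_table(counts, OUT / "counts.tsv", OUT / "sheet.tsv")
    pd.DataFrame(
        [
            (t.barcode, t.carries_full_length or "", int(t.sense),
             int(t.dropped_at_t0), int(t.selected_winner))
            for t in truth.values()
        ],
        columns=["barcode", "carries_full_length", "sense", "dropped_at_t0",
                 "selected_winner"],
    ).to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(f"prot_{g}", cfg.genome_id, cfg.background, g) for g in comp],
        columns=io.EXPECTED_COLUMNS,
    ).to_csv(OUT / "expected.tsv", sep="\t", index=False)

    n_winners = sum(t.selected_winner for t in truth.values())
    n_carriers = sum(
        1 for t in truth.values() if t.carries_full_length in set(comp)
    )
    print(f"wrote screen to {OUT}")
    print(f"  {len(mapping)} fragments, {len(annotation)} genes, "
          f"{len(comp)} complementing genes")
    print(f"  {n_carriers} carrier fragments, {n_winners} drawn winners")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else SEED)
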