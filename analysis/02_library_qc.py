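#!/usr/bin/env python
"""Library QC for the simulated screen: insert-size moments, the
genes-per-fragment and fragments-per-gene breakdowns, and full-length
gene coverage.  Writes results/library_qc.tsv."""
from pathlib import Path

import pandas as pd

from coauxseq import io
from coauxseq.qc import library_stats

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    mapping = io.read_mapping_table(ROOT / "screen" / "mapping.tsv")
    annotation = io.read_annotation(ROOT / "screen" / "annotation.gff3")
    s = library_stats(mapping, annotation)
    row = {
        "n_mapped_fragments": s.n_mapped_fragments,
        "insert_mean_kb": round(s.insert_mean / 1000, 3),
        "insert_sd_kb": round(s.insert_sd / 1000, 3),
        "genes_per_fragment_mean": round(s.genes_per_fragment_mean, 3),
        **{f"gpf_{k}": round(v, 4) for k, v in s.genes_per_fragment.items()},
        "fragments_per_gene_mean": round(s.fragments_per_gene_mean, 2),
        **{f"fpg_{k}": round(v, 4) for k, v in s.fragments_per_gene.items()},
        "gene_coverage": round(s.gene_coverage, 4),
    }
    pd.DataFrame([row]).to_csv(ROOT / "library_qc.tsv", sep="\t", index=False)
    print(f"{s.n_mapped_fragments} mapped fragments, "
          f"mean insert {s.insert_mean/1000:.2f} kb (sd {s.insert_sd/1000:.2f})")
    print(f"genes/fragment mean {s.genes_per_fragment_mean:.2f}; "
          f"gene coverage {s.gene_coverage:.1%}")


if __name__ == "__main__":
    main()
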