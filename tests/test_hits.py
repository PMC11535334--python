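"""Hit calling: significance, confirmation rules, region merging,
gene association, and the cutoff scan."""
import itertools
import random

import networkx as nx
import pandas as pd
import pytest

from coauxseq import FitnessParams, FragmentInsert, GeneAnnotation
from coauxseq.hits import (
    associate_genes,
    call_regions,
    confirm_hits,
    cutoff_scan,
    flag_significant,
    merge_regions,
    nearly_contains,
    significant_instances,
)
from coauxseq.types import Hit

_BCS = ["".join(c) * 7 for c in itertools.product("ACGT", repeat=3)]


def _bc(i: int) -> str:
    return _BCS[i][:20] if len(_BCS[i]) >= 20 else _BCS[i]


def _bc20(i: int) -> str:
    base = "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(10))
    return (base * 2)[:20]


_COLUMNS = ["barcode", "experiment_id", "background", "inducer", "n_t0", "n_sel", "f", "z"]


def _records(rows):
    """rows: (barcode, experiment_id, background, inducer, f, z)."""
    return pd.DataFrame(
        [
            {
                "barcode": bc, "experiment_id": e, "background": bg,
                "inducer": ind, "n_t0": 100, "n_sel": 1000, "f": f, "z": z,
            }
            for bc, e, bg, ind, f, z in rows
        ],
        columns=_COLUMNS,
    )


def _insert(i, start, end, genome="g1"):
    return FragmentInsert(_bc20(i), genome, start, end, "+")


class TestFlagSignificant:
    @pytest.mark.parametrize(
        "f,z,expected",
        [(5.1, 4.2, True), (5.0, 10.0, False), (6.0, 3.9, False), (5.01, 4.01, True)],
    )
    def test_strict_thresholds(self, f, z, expected):
        records = _records([(_bc20(0), "e1", "dX", "1x", f, z)])
        assert flag_significant(records, FitnessParams()).iloc[0] == expected


class TestConfirmHits:
    def test_overlap_in_same_experiment(self):
        mapping = [_insert(0, 100, 3000), _insert(1, 2500, 5500)]
        records = _records(
            [
                (_bc20(0), "e1", "dX", "1x", 8.0, 10.0),
                (_bc20(1), "e1", "dX", "1x", 7.0, 9.0),
            ]
        )
        hits, unmapped = confirm_hits(records, mapping)
        assert unmapped == []
        assert all(h.high_confidence for h in hits)
        assert {h.confirmation for h in hits} == {"overlap_same_experiment"}

    def test_replicate_across_inducer_levels(self):
        mapping = [_insert(0, 100, 3000)]
        records = _records(
            [
                (_bc20(0), "e1", "dX", "1x", 8.0, 10.0),
                (_bc20(0), "e2", "dX", "5x", 7.5, 9.0),
            ]
        )
        (hit,), _ = confirm_hits(records, mapping)
        assert hit.high_confidence
        assert hit.confirmation == "replicate_other_experiment"
        assert hit.significant_in == ["e1", "e2"]
        assert hit.mean_f == pytest.approx(7.75)

    def test_lone_significant_insert_not_confirmed(self):
        mapping = [_insert(0, 100, 3000), _insert(1, 50_000, 53_000)]
        records = _records(
            [
                (_bc20(0), "e1", "dX", "1x", 8.0, 10.0),
                (_bc20(1), "e1", "dX", "1x", 2.0, 1.0),
            ]
        )
        (hit,), _ = confirm_hits(records, mapping)
        assert hit.barcode == _bc20(0)
        assert not hit.high_confidence and hit.confirmation == "none"

    def test_different_backgrounds_do_not_confirm(self):
        mapping = [_insert(0, 100, 3000)]
        records = _records(
            [
                (_bc20(0), "e1", "dX", "1x", 8.0, 10.0),
                (_bc20(0), "e2", "dY", "1x", 8.0, 10.0),
            ]
        )
        hits, _ = confirm_hits(records, mapping)
        assert len(hits) == 2
        assert not any(h.high_confidence for h in hits)

    def test_unmapped_significant_barcode_reported(self):
        records = _records([(_bc20(5), "e1", "dX", "1x", 8.0, 10.0)])
        with pytest.warns(UserWarning):
            hits, unmapped = confirm_hits(records, [_insert(0, 1, 2000)])
        assert unmapped == [_bc20(5)]
        assert hits == []

    def test_instances_layer_counts_pre_confirmation(self):
        records = _records(
            [
                (_bc20(0), "e1", "dX", "1x", 8.0, 10.0),
                (_bc20(0), "e2", "dX", "5x", 8.0, 10.0),
                (_bc20(1), "e1", "dX", "1x", 1.0, 1.0),
            ]
        )
        assert len(significant_instances(records)) == 1


def _hc_hit(i, background="dX", mean_f=8.0):
    return Hit(
        barcode=_bc20(i), background=background,
        significant_in=["e1", "e2"], confirmation="replicate_other_experiment",
        mean_f=mean_f,
    )


class TestMergeRegions:
    def test_two_overlapping_inserts_one_region(self):
        mapping = [_insert(0, 1, 3000), _insert(1, 2500, 5500)]
        (region,) = merge_regions([_hc_hit(0), _hc_hit(1)], mapping)
        assert (region.start, region.end) == (1, 5500)
        assert sorted(region.member_barcodes) == sorted([_bc20(0), _bc20(1)])

    def test_transitive_chain_merges(self):
        """A overlaps B, B overlaps C, A does not overlap C."""
        mapping = [_insert(0, 1, 3000), _insert(1, 2800, 6000), _insert(2, 5500, 9000)]
        (region,) = merge_regions([_hc_hit(i) for i in range(3)], mapping)
        assert len(region.member_barcodes) == 3
        assert (region.start, region.end) == (1, 9000)

    def test_disjoint_inserts_separate_regions(self):
        mapping = [_insert(0, 1, 3000), _insert(1, 10_000, 13_000)]
        regions = merge_regions([_hc_hit(0), _hc_hit(1)], mapping)
        assert len(regions) == 2

    def test_adjacent_but_not_overlapping(self):
        # 1-based inclusive: [1,3000] and [3001,6000] share no bp
        mapping = [_insert(0, 1, 3000), _insert(1, 3001, 6000)]
        assert len(merge_regions([_hc_hit(0), _hc_hit(1)], mapping)) == 2
        # [1,3000] and [3000,6000] share exactly 1 bp
        mapping = [_insert(0, 1, 3000), _insert(1, 3000, 6000)]
        assert len(merge_regions([_hc_hit(0), _hc_hit(1)], mapping)) == 1

    def test_backgrounds_never_merge(self):
        mapping = [_insert(0, 1, 3000), _insert(1, 2000, 5000)]
        regions = merge_regions([_hc_hit(0, "dX"), _hc_hit(1, "dY")], mapping)
        assert len(regions) == 2

    def test_matches_connected_components_oracle(self):
        rng = random.Random(7)
        for _ in range(30):
            n = rng.randint(2, 60)
            mapping = []
            for i in range(n):
                s = rng.randint(1, 50_000)
                mapping.append(_insert(i, s, s + rng.randint(1500, 5000)))
            hits = [_hc_hit(i) for i in range(n)]
            regions = merge_regions(hits, mapping)
            got = {frozenset(r.member_barcodes) for r in regions}
            g = nx.Graph()
            g.add_nodes_from(i.barcode for i in mapping)
            for a, b in itertools.combinations(mapping, 2):
                if a.start <= b.end and b.start <= a.end:
                    g.add_edge(a.barcode, b.barcode)
            expected = {frozenset(c) for c in nx.connected_components(g)}
            assert got == expected

    def test_every_hit_in_exactly_one_region(self, screen):
        from coauxseq.fitness import fitness_table

        records = fitness_table(screen["counts"])
        hits, regions = call_regions(records, screen["mapping"], screen["annotation"])
        hc = [h for h in hits if h.high_confidence]
        member_counts = sum(len(r.member_barcodes) for r in regions)
        assert member_counts == len(hc)
        all_members = [bc for r in regions for bc in r.member_barcodes]
        assert len(all_members) == len(set(all_members))


class TestAssociateGenes:
    GENES = [
        GeneAnnotation("gA", "g1", 500, 1999, "+"),
        GeneAnnotation("gB", "g1", 2500, 3999, "-"),
        GeneAnnotation("gC", "g1", 9000, 10_499, "+"),
    ]

    def test_single_orf(self):
        mapping = [_insert(0, 100, 2200)]
        (region,) = merge_regions([_hc_hit(0)], mapping)
        associate_genes(region, self.GENES, mapping)
        assert region.associated_genes == ["gA"]
        assert region.orf_class == "one_orf"

    def test_no_full_orf(self):
        mapping = [_insert(0, 600, 2200)]  # clips gA's start
        (region,) = merge_regions([_hc_hit(0)], mapping)
        associate_genes(region, self.GENES, mapping)
        assert region.associated_genes == []
        assert region.orf_class == "no_full_orf"

    def test_multi_orf(self):
        mapping = [_insert(0, 100, 4200)]
        (region,) = merge_regions([_hc_hit(0)], mapping)
        associate_genes(region, self.GENES, mapping)
        assert region.associated_genes == ["gA", "gB"]
        assert region.orf_class == "multi_orf"

    def test_classification_follows_best_insert(self):
        """The weaker insert contains a gene, the stronger does not; the
        region is classified by the stronger insert."""
        mapping = [_insert(0, 100, 2200), _insert(1, 2000, 2400)]
        hits = [_hc_hit(0, mean_f=7.0), _hc_hit(1, mean_f=9.0)]
        (region,) = merge_regions(hits, mapping)
        associate_genes(region, self.GENES, mapping)
        assert region.best_barcode == _bc20(1)
        assert region.orf_class == "no_full_orf"

    def test_tie_breaks_longer_then_lexicographic(self):
        mapping = [_insert(0, 100, 2200), _insert(1, 100, 2300)]
        hits = [_hc_hit(0, mean_f=8.0), _hc_hit(1, mean_f=8.0)]
        (region,) = merge_regions(hits, mapping)
        assert region.best_barcode == _bc20(1)  # longer wins

    def test_nearly_full_gene_reported_separately(self):
        # gA is 1500 nt at [500,1999], + strand; insert covers [500,1900]
        # => 1401/1500 = 93.4% including the start codon
        mapping = [_insert(0, 450, 1900)]
        (region,) = merge_regions([_hc_hit(0)], mapping)
        associate_genes(region, self.GENES, mapping)
        assert region.associated_genes == []
        assert region.nearly_full_genes == ["gA"]
        assert region.orf_class == "no_full_orf"

    def test_nearly_contains_requires_start_codon(self):
        gene = GeneAnnotation("gA", "g1", 500, 1999, "+")
        covers_start = _insert(0, 450, 1900)
        misses_start = _insert(1, 600, 1999)  # 93% but lacks the 5' end
        assert nearly_contains(covers_start, gene)
        assert not nearly_contains(misses_start, gene)
        # on the minus strand the start codon sits at gene.end
        gene_minus = GeneAnnotation("gA", "g1", 500, 1999, "-")
        assert not nearly_contains(covers_start, gene_minus)
        assert nearly_contains(misses_start, gene_minus)


class TestThresholdMonotonicity:
    def test_raising_cutoffs_never_adds_calls(self, screen):
        from coauxseq.fitness import fitness_table

        records = fitness_table(screen["counts"])
        mapping, annotation = screen["mapping"], screen["annotation"]
        prev = None
        for tau_f in (4.0, 5.0, 6.0, 7.0):
            params = FitnessParams(tau_f=tau_f)
            n_sig = int(flag_significant(records, params).sum())
            hits, regions = call_regions(records, mapping, annotation, params)
            n_hc = sum(h.high_confidence for h in hits)
            current = (n_sig, n_hc, len(regions))
            if prev is not None:
                assert all(c <= p for c, p in zip(current, prev))
            prev = current


class TestCutoffScan:
    GENES = [GeneAnnotation("gA", "g1", 500, 1999, "+")]
    EXPECTED = pd.DataFrame(
        [{"protein_id": "pA", "genome_id": "g1", "background": "dX", "gene_id": "gA"}]
    )

    def test_strong_hits_stable_across_cutoffs(self):
        mapping = [_insert(0, 100, 2200), _insert(1, 150, 2300)]
        records = _records(
            [
                (_bc20(0), "e1", "dX", "1x", 10.0, 20.0),
                (_bc20(1), "e1", "dX", "1x", 10.5, 21.0),
            ]
        )
        scan = cutoff_scan(records, mapping, self.GENES, self.EXPECTED, (5.0, 6.0, 7.0))
        assert scan["n_expected_recovered"].tolist() == [1, 1, 1]
        assert scan["n_unexpected_regions"].tolist() == [0, 0, 0]

    def test_borderline_false_positives_drop_between_5_and_6(self):
        mapping = [
            _insert(0, 100, 2200), _insert(1, 150, 2300),   # true hits, f ~ 10
            _insert(2, 30_000, 33_000), _insert(3, 30_500, 33_500),  # f ~ 5.5
        ]
        records = _records(
            [
                (_bc20(0), "e1", "dX", "1x", 10.0, 20.0),
                (_bc20(1), "e1", "dX", "1x", 10.0, 20.0),
                (_bc20(2), "e1", "dX", "1x", 5.5, 8.0),
                (_bc20(3), "e1", "dX", "1x", 5.6, 8.0),
            ]
        )
        scan = cutoff_scan(records, mapping, self.GENES, self.EXPECTED, (5.0, 6.0))
        assert scan["n_unexpected_regions"].tolist() == [1, 0]
        assert scan["n_expected_recovered"].tolist() == [1, 1]

    def test_empty_records_all_zero(self):
        scan = cutoff_scan(
            _records([]), [_insert(0, 1, 2000)], self.GENES, self.EXPECTED, (5.0, 6.0)
        )
        assert (scan[["n_expected_recovered", "n_unexpected_regions"]] == 0).all().all()
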