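"""Expected-hit recovery analysis.

Given the a-priori table of proteins expected to complement each mutant
background, this module classifies each expected protein (carried
full-length in the library? detected at t0? any sense-oriented insert?
recovered by a high-confidence hit?), estimates orientation-stratified
success rates with exact binomial confidence intervals, measures
inducer-level concordance of significance calls, and computes sequence
covariates of success: GC content, codon adaptation index (CAI), and
the fraction of codons from the classic set of eight codons rare in
E. coli (ATA, CGG, CGA, CTA, AGA, AGG, GGA, CCC).
"""
from __future__ import annotations

import math
import warnings
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .fitness import background_mean_f  # noqa: F401  (re-exported convenience)
from .hits import Hit, flag_significant, nearly_contains
from .types import (
    CountTable,
    ExpectedHitStatus,
    FitnessParams,
    FragmentInsert,
    GeneAnnotation,
    ValidationError,
)

RARE_CODONS = frozenset({"ATA", "CGG", "CGA", "CTA", "AGA", "AGG", "GGA", "CCC"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SINGLE_CODON_FAMILIES = frozenset({"ATG", "TGG"})  # Met, Trp

# codon -> amino acid (standard table), for grouping synonymous families
_CODON_AA = {
    codon: aa
    for codon, aa in zip(
        ["".join((a, b, c)) for a in "TCAG" for b in "TCAG" for c in "TCAG"],
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    )
}


def load_ecoli_reference_usage() -> dict[str, float]:
    """Relative adaptiveness (w) of each codon in highly expressed
    E. coli genes, after Sharp & Li's reference usage table."""
    with resources.files("coauxseq.data").joinpath("ecoli_sharp_li_w.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["codon"], df["w"].astype(float)))


# ---------------------------------------------------------------------------
# sequence covariates

def gc_content(sequence: str) -> float:
    """(G + C) / length of an ACGT string."""
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValidationError(f"non-ACGT characters in sequence: {set(seq) - set('ACGT')}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _codons(cds: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} is not a multiple of 3")
    if set(cds) - set("ACGT"):
        raise ValidationError("non-ACGT characters in CDS")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def cai(cds: str, reference_usage: Optional[dict[str, float]] = None) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    ``w(codon) = usage(codon) / max usage among its synonyms``; stop
    codons and the single-codon families (ATG, TGG) are excluded from
    the mean, following the Sharp & Li / EMBOSS convention.  A terminal
    stop codon is ignored; internal stops are skipped with a warning.
    ``reference_usage`` may hold raw usage frequencies or pre-normalised
    w values (they are renormalised per family either way); the default
    is the shipped E. coli highly-expressed-gene table.
    """
    if reference_usage is None:
        reference_usage = load_ecoli_reference_usage()
    # normalise usage to relative adaptiveness within synonymous families
    family_max: dict[str, float] = {}
    for codon, usage in reference_usage.items():
        aa = _CODON_AA.get(codon)
        if aa and aa != "*":
            family_max[aa] = max(family_max.get(aa, 0.0), usage)

    codons = _codons(cds)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    log_sum = 0.0
    n = 0
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            warnings.warn(f"internal stop codon {codon} at codon {i + 1}; skipped")
            continue
        if codon in SINGLE_CODON_FAMILIES:
            continue
        aa = _CODON_AA[codon]
        w = reference_usage.get(codon, 0.0) / family_max[aa]
        if w == 0.0:
            w = 0.01  # floor for codons unobserved in the reference set
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise ValidationError("no codons usable for CAI")
    return math.exp(log_sum / n)


def rare_codon_fraction(cds: str) -> float:
    """Fraction of (non-stop) codons belonging to the rare-codon set."""
    codons = [c for c in _codons(cds) if c not in STOP_CODONS]
    if not codons:
        raise ValidationError("no non-stop codons")
    return sum(1 for c in codons if c in RARE_CODONS) / len(codons)


# ---------------------------------------------------------------------------
# expected-hit classification

def classify_expected(
    expected: pd.DataFrame,
    mapping: list[FragmentInsert],
    counts: CountTable,
    hits: list[Hit],
    annotation: list[GeneAnnotation],
) -> list[ExpectedHitStatus]:
    """Compute containment / t0-detection / orientation / recovery status
    for every expected protein.

    ``recovered`` is ``full_length`` when a high-confidence hit of the
    right background fully contains the gene, ``nearly_full_length``
    when such an insert covers >= 90% of the gene including the start
    codon, else ``not_recovered``.
    """
    by_gene = {g.gene_id: g for g in annotation}
    t0_ids = [m.sample_id for m in counts.samples.values() if m.role == "t0"]
    t0_reads = counts.counts[t0_ids].sum(axis=1) if t0_ids else None
    hc_by_bg: dict[str, list[str]] = {}
    for h in hits:
        if h.high_confidence:
            hc_by_bg.setdefault(h.background, []).append(h.barcode)
    by_barcode = {i.barcode: i for i in mapping}

    out: list[ExpectedHitStatus] = []
    for row in expected.itertuples():
        gene = by_gene.get(row.gene_id)
        if gene is None:
            raise ValidationError(f"expected gene {row.gene_id!r} absent from annotation")
        carriers = [i for i in mapping if i.contains_gene(gene)]
        status = ExpectedHitStatus(
            protein_id=row.protein_id,
            gene_id=row.gene_id,
            genome_id=row.genome_id,
            background=row.background,
            in_library_full_length=bool(carriers),
            detected_t0=bool(
                t0_reads is not None
                and any(t0_reads.get(i.barcode, 0) > 0 for i in carriers)
            ),
            any_sense_insert=any(i.gene_is_sense(gene) for i in carriers),
        )
        hc_inserts = [
            by_barcode[bc] for bc in hc_by_bg.get(row.background, []) if bc in by_barcode
        ]
        if any(i.contains_gene(gene) for i in hc_inserts):
            status.recovered = "full_length"
        elif any(nearly_contains(i, gene) for i in hc_inserts):
            status.recovered = "nearly_full_length"
        out.append(status)
    return out


def build_covariate_table(
    expected: pd.DataFrame,
    mapping: list[FragmentInsert],
    counts: CountTable,
    records: pd.DataFrame,
    annotation: list[GeneAnnotation],
    genome: Optional[dict[str, str]] = None,
    params: FitnessParams = FitnessParams(),
    rbs_strength: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Per (expected gene, carrying insert) covariate rows.

    One row per insert fully containing an expected gene and detected at
    t0, with the insert's orientation relative to the gene, success
    (significant in >= 1 experiment of the expected background), the
    insert's GC content (when the genome is supplied), and the gene's
    CAI and rare-codon fraction (when its CDS is available).
    ``rbs_strength`` is an optional external covariate keyed by gene_id.
    """
    by_gene = {g.gene_id: g for g in annotation}
    t0_ids = [m.sample_id for m in counts.samples.values() if m.role == "t0"]
    t0_reads = counts.counts[t0_ids].sum(axis=1)
    sig = records[flag_significant(records, params)]
    sig_pairs = set(zip(sig["barcode"], sig["background"]))

    cov_cache: dict[str, tuple[float, float]] = {}
    rows = []
    for row in expected.itertuples():
        gene = by_gene.get(row.gene_id)
        if gene is None:
            raise ValidationError(f"expected gene {row.gene_id!r} absent from annotation")
        cds = gene.cds_sequence
        if gene.gene_id not in cov_cache:
            cov_cache[gene.gene_id] = (
                cai(cds) if cds else np.nan,
                rare_codon_fraction(cds) if cds else np.nan,
            )
        gene_cai, gene_rare = cov_cache[gene.gene_id]
        for ins in mapping:
            if not ins.contains_gene(gene):
                continue
            if t0_reads.get(ins.barcode, 0) <= 0:
                continue
            frag_seq = (
                genome[ins.genome_id][ins.start - 1 : ins.end]
                if genome and ins.genome_id in genome
                else None
            )
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "barcode": ins.barcode,
                    "background": row.background,
                    "orientation": "sense" if ins.gene_is_sense(gene) else "antisense",
                    "success": (ins.barcode, row.background) in sig_pairs,
                    "gc_fraction": gc_content(frag_seq) if frag_seq else np.nan,
                    "cai": gene_cai,
                    "rare_codon_fraction": gene_rare,
                    "rbs_strength": (rbs_strength or {}).get(gene.gene_id, np.nan),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "barcode", "background", "orientation", "success",
            "gc_fraction", "cai", "rare_codon_fraction", "rbs_strength",
        ],
    )


# ---------------------------------------------------------------------------
# rates, concordance, tests

def clopper_pearson(successes: int, n: int, confidence: float = 0.90) -> tuple[float, float]:
    """Central exact binomial (Clopper-Pearson) confidence interval."""
    if n <= 0:
        raise ValidationError("n must be positive")
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def success_rate(
    table: pd.DataFrame,
    group: str = "orientation",
    confidence: float = 0.90,
) -> pd.DataFrame:
    """Success rate per group with exact binomial CI.

    Empty groups are omitted (with a warning when the grouping column
    has declared categories that do not appear).
    """
    if table.empty:
        warnings.warn("empty covariate table; no rates computed")
        return pd.DataFrame(columns=[group, "n", "successes", "rate", "ci_low", "ci_high"])
    rows = []
    for key, grp in table.groupby(group):
        n = len(grp)
        s = int(grp["success"].sum())
        lo, hi = clopper_pearson(s, n, confidence)
        rows.append((key, n, s, s / n, lo, hi))
    return pd.DataFrame(rows, columns=[group, "n", "successes", "rate", "ci_low", "ci_high"])


def inducer_concordance(
    records: pd.DataFrame,
    hits: list[Hit],
    low_inducer: str = "1x",
    high_inducer: str = "5x",
    params: FitnessParams = FitnessParams(),
) -> pd.DataFrame:
    """P(significant at high inducer | significant at low inducer).

    Computed per background over barcodes measured at both levels; the
    second row restricts the denominator to overlap-confirmed hits.
    Backgrounds lacking both levels are skipped with a warning.
    """
    sig = flag_significant(records, params)
    rec = records.assign(significant=sig)
    overlap_confirmed = {
        (h.barcode, h.background)
        for h in hits
        if h.confirmation in ("overlap_same_experiment", "both")
    }

    rows = []
    for restricted in (False, True):
        num = denom = 0
        for background, grp in rec.groupby("background"):
            inducers = set(grp["inducer"])
            if not {low_inducer, high_inducer} <= inducers:
                if not restricted:
                    warnings.warn(f"background {background}: missing an inducer level; skipped")
                continue
            lo = grp[grp["inducer"] == low_inducer].set_index("barcode")["significant"]
            hi = grp[grp["inducer"] == high_inducer].set_index("barcode")["significant"]
            common = lo.index.intersection(hi.index)
            for bc in common:
                if not lo.loc[bc]:
                    continue
                if restricted and (bc, background) not in overlap_confirmed:
                    continue
                denom += 1
                num += int(hi.loc[bc])
        rows.append(
            (
                "overlap_confirmed" if restricted else "all_significant",
                denom,
                num,
                num / denom if denom else float("nan"),
            )
        )
    return pd.DataFrame(rows, columns=["subset", "n_significant_low", "n_also_high", "concordance"])


def covariate_tests(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("gc_fraction", "cai", "rare_codon_fraction", "rbs_strength"),
    n_libraries_bonferroni: int = 1,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of each covariate between
    successful and unsuccessful rows; per-library RBS means get a t test
    with Bonferroni correction for the number of libraries."""
    rows = []
    succ = table[table["success"]]
    fail = table[~table["success"]]
    for cov in covariates:
        if cov not in table.columns:
            continue
        a = succ[cov].dropna()
        b = fail[cov].dropna()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"covariate {cov}: a group has n < 2; test skipped")
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            (cov, "wilcoxon_rank_sum", len(a), len(b),
             float(a.median()), float(b.median()), float(p))
        )
        if cov == "rbs_strength":
            t, pt = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                (cov, f"t_test_bonferroni_x{n_libraries_bonferroni}", len(a), len(b),
                 float(a.mean()), float(b.mean()),
                 float(min(1.0, pt * n_libraries_bonferroni)))
            )
    return pd.DataFrame(
        rows,
        columns=["covariate", "test", "n_success", "n_failure",
                 "center_success", "center_failure", "p_value"],
    )
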