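"""TSS classification rules, 5'-UTR statistics and census arithmetic."""

import numpy as np
import pytest

import primatx
from primatx.genome_model import GeneFeature, GenomeAnnotation, Replicon
from primatx.tss_annotation import (
    CATEGORIES,
    ClassificationConfig,
    census_from_counts,
    classify_all,
    classify_tss,
    compute_utr_statistics,
    summarize_tss_counts,
)
from primatx.tss_detection import TSSCall
from .conftest import random_sequence


def _call(pos, strand, replicon="chr", conds=("A",)):
    return TSSCall(replicon, pos, strand, set(conds), {})


def brute_force_categories(pos, strand, genes, config):
    """Oracle: evaluate every gene against every rule, plain loops."""
    fired = set()
    for g in genes:
        d = g.start - pos if strand == "+" else pos - g.end
        same = g.strand == strand
        if same and g.feature_class == "CDS" and 1 <= d <= config.gtss_window:
            fired.add("gTSS")
        if same and g.start <= pos <= g.end:
            fired.add("iTSS")
        if not same and g.start - config.atss_flank <= pos <= g.end + config.atss_flank:
            fired.add("aTSS")
        if (
            same
            and g.feature_class in ("tRNA", "rRNA", "sRNA", "other_ncRNA")
            and 1 <= d <= config.gtss_window
        ):
            fired.add("nTSS")
    if not fired:
        fired = {"nTSS"}
    winner = next(c for c in config.precedence if c in fired)
    return winner, fired


class TestClassificationExamples:
    def test_gtss_within_window(self, toy_annotation):
        # 150 nt upstream of cdsF (start 2001), same strand
        r = classify_tss(_call(1851, "+"), toy_annotation)
        assert r.category == "gTSS"
        assert r.associated_gene_id == "cdsF"
        assert r.utr_length == 150

    def test_gtss_window_boundary_inclusive(self, toy_annotation):
        r = classify_tss(_call(1801, "+"), toy_annotation)
        assert r.category == "gTSS" and r.utr_length == 200
        r2 = classify_tss(_call(1800, "+"), toy_annotation)
        assert r2.category != "gTSS"

    def test_itss_inside_gene(self, toy_annotation):
        # inside cdsR (4001..4500, -), far from any same-strand CDS start
        r = classify_tss(_call(4200, "-"), toy_annotation)
        assert r.category == "iTSS"
        assert r.associated_gene_id == "cdsR"

    def test_atss_in_downstream_flank(self, toy_annotation):
        # opposite strand, 30 nt past cdsR's 5' flank: position 4530 (+)
        r = classify_tss(_call(4530, "+"), toy_annotation)
        assert "aTSS" in r.all_categories

    def test_ntss_upstream_of_trna(self, toy_annotation):
        # 100 nt upstream of trnaF (tRNA at 6001), same strand
        r = classify_tss(_call(5901, "+"), toy_annotation)
        assert r.category == "nTSS"
        assert r.associated_gene_id == "trnaF"

    def test_precedence_gtss_over_itss(self, toy_annotation):
        # inside cdsF (2001..2900) and 200 nt upstream of cdsF2 (3100)
        r = classify_tss(_call(2900, "+"), toy_annotation)
        assert r.all_categories >= {"gTSS", "iTSS"}
        assert r.category == "gTSS"
        assert r.associated_gene_id == "cdsF2"

    def test_coverage_extension_long_utr(self, toy_annotation):
        from primatx.end_coverage import EndCountTrack, LibraryMeta

        pos = 1700  # 301 nt upstream of cdsF: outside the window
        plain = classify_tss(_call(pos, "+"), toy_annotation)
        assert plain.category != "gTSS"
        rnaseq = EndCountTrack(LibraryMeta("RNASEQ_pooled", "A", 1, "RNASEQ"))
        for p in range(pos, 2001):
            rnaseq.add("chr", "+", p, 8)
        config = ClassificationConfig(use_coverage_extension=True)
        r = classify_tss(_call(pos, "+"), toy_annotation, config, rnaseq)
        assert r.category == "gTSS" and r.utr_length == 301
        # a coverage gap breaks the extension
        gappy = EndCountTrack(LibraryMeta("RNASEQ_pooled", "A", 1, "RNASEQ"))
        for p in range(pos, 2001):
            if p != 1900:
                gappy.add("chr", "+", p, 8)
        r2 = classify_tss(_call(pos, "+"), toy_annotation, config, gappy)
        assert r2.category != "gTSS"


class TestOracleEquivalence:
    def test_thousand_random_fixtures(self):
        """classify_tss agrees with brute-force rule evaluation everywhere."""
        rng = np.random.default_rng(42)
        config = ClassificationConfig()
        classes = ["CDS", "CDS", "CDS", "tRNA", "sRNA"]
        for _ in range(1000):
            n_genes = int(rng.integers(1, 9))
            genes = []
            for i in range(n_genes):
                start = int(rng.integers(1, 4500))
                end = min(5000, start + int(rng.integers(50, 900)))
                genes.append(
                    GeneFeature(
                        f"g{i}",
                        "chr",
                        start,
                        end,
                        "+" if rng.random() < 0.5 else "-",
                        classes[rng.integers(len(classes))],
                    )
                )
            ann = GenomeAnnotation([Replicon("chr", 5000, "A" * 5000)], genes)
            pos = int(rng.integers(1, 5001))
            strand = "+" if rng.random() < 0.5 else "-"
            record = classify_tss(_call(pos, strand), ann, config)
            winner, fired = brute_force_categories(pos, strand, genes, config)
            assert record.category == winner, (pos, strand, genes)
            assert record.all_categories == fired

    def test_partition_sums(self, default_records):
        """Every record has one category; census cells sum to their totals."""
        for r in default_records:
            assert r.category in CATEGORIES
            assert r.category in r.all_categories
        census = summarize_tss_counts(default_records)
        for rep_table in census["per_replicon"].values():
            for cell in rep_table.values():
                assert cell["total"] == sum(
                    n for n, _ in cell["categories"].values()
                )


class TestUtrStatistics:
    def _record(self, utr):
        return primatx.TSSRecord(
            "chr", 1000, "+", {"A"}, {}, "gTSS", "g", utr, utr <= 10, {"gTSS"}
        )

    def test_single_value_median(self):
        stats = compute_utr_statistics([self._record(63)])
        assert stats["median_utr"] == 63

    def test_mixed_lengths(self):
        stats = compute_utr_statistics([self._record(u) for u in (0, 5, 63, 250)])
        assert stats["leaderless"] == 2
        assert stats["long_utr"] == 1
        assert stats["median_utr"] == 34

    def test_empty_warns(self):
        with pytest.warns(UserWarning, match="no gTSS"):
            stats = compute_utr_statistics([])
        assert stats["median_utr"] is None

    def test_planted_median_recovered(self, default_bundle, default_records):
        """Classification recovers the planted 5'-UTR median (+-2 nt)."""
        _, _, truth, _ = default_bundle
        planted = np.median(
            [t.utr_length for t in truth.tss if t.category == "gTSS"]
        )
        stats = compute_utr_statistics(default_records)
        assert abs(stats["median_utr"] - planted) <= 2

    def test_utr_sampler_median_at_nominal_value(self):
        """The planted-UTR sampler is centred on a 63-nt median."""
        rng = np.random.default_rng(0)
        draws = np.clip(np.round(rng.lognormal(np.log(63), 0.6, 200_000)), 1, 400)
        assert abs(np.median(draws) - 63) <= 1


class TestCensus:
    def test_chromosome_census_identities(self):
        cell = census_from_counts({"gTSS": 1282, "aTSS": 130, "iTSS": 595, "nTSS": 174})
        assert cell["total"] == 2181
        assert cell["categories"]["gTSS"] == (1282, 58.78)
        assert cell["categories"]["aTSS"] == (130, 5.96)
        assert cell["categories"]["iTSS"] == (595, 27.28)
        assert cell["categories"]["nTSS"] == (174, 7.98)

    def test_plasmid_census_identities(self):
        cell = census_from_counts({"gTSS": 33, "aTSS": 16, "iTSS": 35, "nTSS": 15})
        assert cell["total"] == 99
        assert cell["categories"]["iTSS"] == (35, 35.35)
        assert cell["categories"]["gTSS"] == (33, 33.33)

    def test_all_zero_blank_percentages(self):
        cell = census_from_counts({})
        assert cell["total"] == 0
        assert all(pct is None for _, pct in cell["categories"].values())
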