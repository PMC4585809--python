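import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glk.annotation_accounting import (
    GeneModel,
    gene_model_stats,
    merge_intervals,
    read_gene_models,
    repeat_fractions,
    rpkm,
    rpkm_table,
    support_ratios,
    write_gene_models,
)
from glk.sequence_io import GenomicInterval


def mask_union_bases(intervals, size=100_000):
    masks: dict[str, np.ndarray] = {}
    for iv in intervals:
        masks.setdefault(iv.seq_id, np.zeros(size, dtype=bool))[
            iv.start : iv.end
        ] = True
    return sum(int(m.sum()) for m in masks.values())


interval_strategy = st.lists(
    st.tuples(st.integers(0, 3), st.integers(0, 5000), st.integers(1, 300)),
    min_size=1,
    max_size=60,
).map(
    lambda triples: [
        GenomicInterval(f"s{sid}", start, start + ln, "rep")
        for sid, start, ln in triples
    ]
)


class TestMergeIntervals:
    def test_overlap_unions(self):
        merged, total = merge_intervals(
            [GenomicInterval("s", 0, 10), GenomicInterval("s", 5, 15)]
        )
        assert [(m.start, m.end) for m in merged] == [(0, 15)]
        assert total == 15

    def test_book_ended_unions(self):
        _, total = merge_intervals(
            [GenomicInterval("s", 0, 5), GenomicInterval("s", 5, 10)]
        )
        assert total == 10

    def test_disjoint_unchanged(self):
        merged, total = merge_intervals(
            [GenomicInterval("s", 0, 5), GenomicInterval("s", 10, 15)]
        )
        assert len(merged) == 2 and total == 10

    def test_categories_kept_separate_when_requested(self):
        ivs = [
            GenomicInterval("s", 0, 10, "LINE"),
            GenomicInterval("s", 5, 15, "SINE"),
        ]
        merged, total = merge_intervals(ivs, by_category=True)
        assert len(merged) == 2 and total == 20

    def test_random_total_matches_mask_oracle(self, rng):
        ivs = []
        for _ in range(10_000):
            sid = f"s{int(rng.integers(0, 5))}"
            start = int(rng.integers(0, 50_000))
            ivs.append(GenomicInterval(sid, start, start + int(rng.integers(1, 400))))
        _, total = merge_intervals(ivs)
        assert total == mask_union_bases(ivs)

    @given(interval_strategy)
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_order_invariant(self, ivs):
        merged, total = merge_intervals(ivs)
        again, total2 = merge_intervals(merged)
        assert total == total2 == mask_union_bases(ivs)
        _, total3 = merge_intervals(list(reversed(ivs)))
        assert total3 == total


class TestRepeatFractions:
    def test_printed_combined_fraction(self):
        """689,687,572 repeat bases on a 1,747,524,961 bp gap-free genome
        is 39.47 %; the LINE subset 213,508,152 bp is 12.2 %."""
        from glk.annotation_accounting import genome_percent

        assert genome_percent(689_687_572, 1_747_524_961, 2) == 39.47
        assert genome_percent(213_508_152, 1_747_524_961, 1) == 12.2

    def test_zero_repeats(self):
        ledger = repeat_fractions({"m": []}, 1000)
        assert ledger.combined_all_bases == 0
        assert ledger.combined_all_percent == 0.0

    def test_union_bounded_by_sum_of_methods(self, rng):
        per_method = {}
        for m in range(3):
            ivs = []
            for _ in range(50):
                start = int(rng.integers(0, 9000))
                ivs.append(
                    GenomicInterval("s", start, start + int(rng.integers(1, 500)),
                                    str(rng.choice(["LINE", "DNA"])))
                )
            per_method[f"m{m}"] = ivs
        ledger = repeat_fractions(per_method, 10_000)
        assert ledger.combined_all_bases <= ledger.per_method["bases"].sum()
        assert ledger.combined_all_bases == mask_union_bases(
            [iv for ivs in per_method.values() for iv in ivs]
        )
        # categories may overlap each other: their sum can exceed the union
        assert ledger.per_category["bases"].sum() >= ledger.combined_all_bases

    def test_tandem_excluded_from_te_union(self):
        per_method = {
            "repbase": [GenomicInterval("s", 0, 100, "LINE")],
            "trf": [GenomicInterval("s", 200, 300, "tandem")],
        }
        ledger = repeat_fractions(per_method, 1000, tandem_methods=("trf",))
        assert ledger.combined_te_bases == 100
        assert ledger.combined_all_bases == 200


class TestGeneModels:
    def test_hand_computed_stats(self):
        m = GeneModel("g", "s", 0, 250, [(0, 100), (150, 250)])
        stats = gene_model_stats([m])
        assert stats == {
            "total": 1,
            "single_exon_genes": 0,
            "mean_gene_length": 250.0,
            "mean_mrna_length": 200.0,
            "mean_exons_per_gene": 2.0,
            "mean_exon_length": 100.0,
            "mean_intron_length": 50.0,
        }

    def test_single_exon_only(self):
        models = [GeneModel(f"g{i}", "s", 0, 100, [(0, 100)]) for i in range(3)]
        stats = gene_model_stats(models)
        assert stats["single_exon_genes"] == stats["total"] == 3
        assert stats["mean_intron_length"] is None

    def test_overlapping_exons_rejected_with_id(self):
        with pytest.raises(ValueError, match="gBAD"):
            GeneModel("gBAD", "s", 0, 100, [(0, 50), (40, 100)])

    def test_random_models_match_flat_loop_oracle(self, rng):
        models = []
        for i in range(500):
            n_ex = int(rng.integers(1, 8))
            pos = int(rng.integers(0, 1000))
            start = pos
            exons = []
            for _ in range(n_ex):
                L = int(rng.integers(50, 300))
                exons.append((pos, pos + L))
                pos += L + int(rng.integers(30, 500))
            end = exons[-1][1]
            models.append(GeneModel(f"g{i}", "s", start, end, exons))
        stats = gene_model_stats(models)
        gl = [m.end - m.start for m in models]
        ml = [sum(e - s for s, e in m.exons) for m in models]
        ex = [e - s for m in models for s, e in m.exons]
        ints = [
            m.exons[i + 1][0] - m.exons[i][1]
            for m in models
            for i in range(len(m.exons) - 1)
        ]
        assert stats["mean_gene_length"] == pytest.approx(sum(gl) / len(gl))
        assert stats["mean_mrna_length"] == pytest.approx(sum(ml) / len(ml))
        assert stats["mean_exon_length"] == pytest.approx(sum(ex) / len(ex))
        assert stats["mean_intron_length"] == pytest.approx(sum(ints) / len(ints))
        assert stats["mean_exons_per_gene"] == pytest.approx(
            sum(len(m.exons) for m in models) / len(models)
        )

    def test_gff3_round_trip(self, tmp_path):
        models = [
            GeneModel("gA", "sc1", 0, 250, [(0, 100), (150, 250)]),
            GeneModel("gB", "sc2", 10, 110, [(10, 110)]),
        ]
        path = tmp_path / "genes.gff3"
        write_gene_models(models, path)
        back = read_gene_models(path)
        assert [(m.gene_id, m.start, m.end, m.exons) for m in back] == [
            (m.gene_id, m.start, m.end, m.exons) for m in models
        ]


class TestRPKM:
    def test_unit_definition(self):
        assert rpkm(1, 1000, 1_000_000) == 1.0
        assert rpkm(0, 500, 10**7) == 0.0

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 10)
        with pytest.raises(ValueError):
            rpkm(1, 10, 0)

    def test_table_matches_formula_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("ABCD"),
        )
        lengths = pd.Series(
            rng.integers(200, 5000, size=30).astype(float),
            index=counts.index,
        )
        totals = pd.Series(
            rng.integers(10**6, 10**7, size=4).astype(float), index=counts.columns
        )
        table = rpkm_table(counts, lengths, totals)
        for g in counts.index:
            for s in counts.columns:
                assert table.loc[g, s] == pytest.approx(
                    rpkm(counts.loc[g, s], lengths[g], totals[s])
                )

    def test_rpkm_zero_iff_count_zero(self, rng):
        counts = pd.DataFrame({"A": [0, 3]}, index=["g0", "g1"])
        lengths = pd.Series({"g0": 100.0, "g1": 100.0})
        table = rpkm_table(counts, lengths, pd.Series({"A": 1e6}))
        assert table.loc["g0", "A"] == 0.0 and table.loc["g1", "A"] > 0


class TestSupportRatios:
    def test_printed_combined_ratio(self):
        """18,833 supported of 19,406 annotated genes is 97.05 %."""
        from glk.sequencing_effort import percent_of

        assert percent_of(18_833, 19_406, 2) == 97.05

    def test_all_zero_table(self):
        rpkms = pd.DataFrame({"A": [0.0, 0.0], "B": [0.0, 0.0]})
        out = support_ratios(rpkms, total_annotated=10)
        assert (out.filter(like="n_rpkm") == 0).all().all()

    def test_combined_row_matches_any_sample_oracle(self, rng):
        rpkms = pd.DataFrame(
            rng.exponential(2.0, size=(200, 3)) * (rng.random((200, 3)) > 0.3),
            columns=["s1", "s2", "s3"],
        )
        out = support_ratios(rpkms, total_annotated=250)
        for t in (0, 1, 5):
            expected = sum(
                any(rpkms.iloc[i, j] > t for j in range(3)) for i in range(200)
            )
            assert out.loc["Combined", f"n_rpkm_gt_{t:g}"] == expected
            # combined >= every per-sample count
            for s in ("s1", "s2", "s3"):
                assert out.loc["Combined", f"n_rpkm_gt_{t:g}"] >= out.loc[
                    s, f"n_rpkm_gt_{t:g}"
                ]
        # counts weakly decrease as threshold increases
        for row in out.index:
            ns = [out.loc[row, f"n_rpkm_gt_{t:g}"] for t in (0, 1, 5)]
            assert ns == sorted(ns, reverse=True)

    def test_strict_inequality_at_threshold(self):
        rpkms = pd.DataFrame({"A": [1.0, 1.0001]})
        out = support_ratios(rpkms, total_annotated=2, thresholds=(1.0,))
        assert out.loc["A", "n_rpkm_gt_1"] == 1
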