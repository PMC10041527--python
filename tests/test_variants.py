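"""Variant records, filtering, effect prediction, cohort and eQTL analyses."""

import numpy as np
import pandas as pd
import pytest

from epistate.track_graph import MeasurementMatrix
from epistate.variants import (
    EffectRecord,
    EqtlRecord,
    Variant,
    filter_variants,
    gtex_score,
    gtex_test,
    predict_effects,
    read_variants_tsv,
    read_variants_vcf,
    summarize_cohort,
    write_effects_tsv,
)


class TestVariantValidation:
    def test_rejects_equal_alleles(self):
        with pytest.raises(ValueError):
            Variant("chr1", 100, "A", "A")

    def test_rejects_indels(self):
        with pytest.raises(ValueError):
            Variant("chr1", 100, "AT", "A")

    def test_rejects_malformed_alleles(self):
        with pytest.raises(ValueError):
            Variant("chr1", 100, "A", "X")


class TestFilterVariants:
    TSS = {"gene1": ("chr1", 100_000), "gene2": ("chr2", 500_000)}

    def test_boundary_distance(self):
        inside = Variant("chr1", 150_000, "A", "G")
        outside = Variant("chr1", 150_001, "A", "G")
        kept = filter_variants([inside, outside], self.TSS)
        assert kept == [inside]

    def test_duplicates_collapse(self):
        v = Variant("chr1", 99_000, "C", "T")
        assert filter_variants([v, Variant("chr1", 99_000, "C", "T")], self.TSS) == [v]

    def test_wrong_chromosome_excluded(self):
        v = Variant("chr3", 100_000, "A", "G")
        assert filter_variants([v], self.TSS) == []

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            filter_variants([], {})


class TestPredictEffects:
    def test_effect_shape_covers_all_tracks(self, variant_result):
        est = variant_result["estimator"]
        world = variant_result["world"]
        chrom, pos, _ = world.truth[0]
        seq = world.genome[chrom]
        p0 = pos + 4
        v = Variant(chrom, p0 + 1, seq[p0], "A" if seq[p0] != "A" else "C")
        rec = predict_effects(est, world.genome, v)
        assert rec.effects.shape == (est.n_cells_, est.n_features_)
        assert np.isfinite(rec.effects).all()

    def test_swapping_alleles_negates_effects_exactly(self, variant_result):
        est = variant_result["estimator"]
        world = variant_result["world"]
        chrom, pos, _ = world.truth[1]
        seq = world.genome[chrom]
        p0 = pos + 2
        ref = seq[p0]
        alt = "A" if ref != "A" else "C"
        fwd = predict_effects(est, world.genome, Variant(chrom, p0 + 1, ref, alt))
        # swapped orientation: pretend alt is the genome base (lenient mode)
        rev = predict_effects(
            est, world.genome, Variant(chrom, p0 + 1, alt, ref), strict=False
        )
        # prediction(ref)-prediction(alt) vs prediction(alt)-prediction(ref):
        # the windows are built from the genome, so the same two forward
        # passes appear with opposite signs
        np.testing.assert_array_equal(fwd.effects, -rev.effects)

    def test_identical_windows_give_exactly_zero_difference(self, variant_result):
        """Bitwise-identical forward passes: the ref==alt guard aside, two
        predictions of the same window cancel exactly."""
        est = variant_result["estimator"]
        world = variant_result["world"]
        chrom = next(iter(world.genome))
        from epistate.tracks import encode_sequence

        window = world.genome[chrom][1000:2000]
        x = encode_sequence(window)
        a = est.predict(x)
        b = est.predict(x)
        np.testing.assert_array_equal(a, b)

    def test_ref_mismatch_strict_raises(self, variant_result):
        est = variant_result["estimator"]
        world = variant_result["world"]
        chrom = next(iter(world.genome))
        seq = world.genome[chrom]
        p0 = 5000
        wrong = "A" if seq[p0] != "A" else "C"
        alt = "G" if wrong != "G" else "T"
        with pytest.raises(ValueError, match="does not match"):
            predict_effects(est, world.genome, Variant(chrom, p0 + 1, wrong, alt))

    def test_near_edge_rejected(self, variant_result):
        est = variant_result["estimator"]
        world = variant_result["world"]
        chrom = next(iter(world.genome))
        seq = world.genome[chrom]
        with pytest.raises(ValueError, match="chromosome end"):
            predict_effects(
                est, world.genome,
                Variant(chrom, 100, seq[99], "A" if seq[99] != "A" else "C"),
            )

    def test_motif_ablation_positive_effect_in_strongest_group(self, variant_result):
        """Ablating a motif's core base lowers the alternative prediction for
        cells of the group driven by that motif, giving ref-alt > 0."""
        est = variant_result["estimator"]
        world = variant_result["world"]
        W = world.config.feature_motif_weights
        F = world.config.group_factor_matrix
        wins = 0
        total = 0
        for chrom, pos, mi in world.truth[:15]:
            seq = world.genome[chrom]
            p0 = pos + 4
            ref = seq[p0]
            alt = "A" if ref != "A" else "C"
            rec = predict_effects(est, world.genome, Variant(chrom, p0 + 1, ref, alt))
            strongest_group = int(np.argmax(F[:, mi]))
            cells = [
                i for i, c in enumerate(world.cells)
                if world.cell_group_of[c] == strongest_group
            ]
            feat = int(np.argmax(W[:, mi]))
            total += 1
            if rec.effects[cells, feat].mean() > 0:
                wins += 1
        assert wins / total > 0.7


class TestEffectRecord:
    def test_max_abs_and_argmax(self):
        effects = np.array([[0.1, -0.5], [0.2, 0.3]])
        rec = EffectRecord(Variant("chr1", 1000, "A", "G"), effects)
        assert rec.max_abs_effect == pytest.approx(0.5)
        assert rec.argmax == (0, 1)


class TestSummarizeCohort:
    def _records(self, values):
        return [
            EffectRecord(Variant("chr1", 1000 + i, "A", "G"), v)
            for i, v in enumerate(values)
        ]

    def test_identical_cohorts_all_zero(self, rng):
        effects = [rng.normal(size=(3, 2)) for _ in range(4)]
        table = summarize_cohort(self._records(effects), self._records(effects))
        assert np.allclose(table["difference"], 0.0)

    def test_row_per_track(self, rng):
        table = summarize_cohort(
            self._records([rng.normal(size=(5, 4))]),
            self._records([rng.normal(size=(5, 4))]),
        )
        assert len(table) == 20

    def test_measured_flag_from_mask(self, rng):
        mask = MeasurementMatrix(
            ["c0", "c1"], ["f0"], np.array([[True], [False]])
        )
        table = summarize_cohort(
            self._records([rng.normal(size=(2, 1))]),
            self._records([rng.normal(size=(2, 1))]),
            mask=mask,
        )
        assert table.loc[0, "measured"] == True  # noqa: E712
        assert table.loc[1, "measured"] == False  # noqa: E712

    def test_empty_cohort_rejected(self, rng):
        with pytest.raises(ValueError):
            summarize_cohort([], self._records([rng.normal(size=(2, 1))]))

    def test_larger_affected_effects_give_positive_difference(self, rng):
        big = self._records([np.full((2, 2), 2.0) + rng.normal(0, 0.1, (2, 2))])
        small = self._records([rng.normal(0, 0.1, (2, 2))])
        table = summarize_cohort(big, small)
        assert (table["difference"] > 0).all()


def _effect(variant, matrix):
    return EffectRecord(variant, np.asarray(matrix, float))


class TestGtexScore:
    V1 = Variant("chr1", 1000, "A", "G", id="v1")
    V2 = Variant("chr1", 2000, "C", "T", id="v2")

    def test_single_cell_tissue_score(self):
        effects = [_effect(self.V1, [[0.5, -0.2]])]
        eqtl = [EqtlRecord(self.V1, "liver", +1, True)]
        scores = gtex_score(effects, {"liver": [0]}, eqtl)
        assert scores.loc[scores["feature"] == 0, "score"].iloc[0] == pytest.approx(0.5)
        assert scores.loc[scores["feature"] == 1, "score"].iloc[0] == pytest.approx(-0.2)

    def test_opposite_signs_across_tissues_excluded(self):
        effects = [_effect(self.V1, [[0.5]]), _effect(self.V2, [[0.1]])]
        eqtl = [
            EqtlRecord(self.V1, "liver", +1, True),
            EqtlRecord(self.V1, "lung", -1, True),
            EqtlRecord(self.V2, "liver", +1, False),
        ]
        scores = gtex_score(effects, {"liver": [0], "lung": [0]}, eqtl)
        assert set(scores["variant"]) == {"v2"}

    def test_sign_flip_flips_scores(self):
        effects = [_effect(self.V1, [[0.5, -0.2]])]
        plus = gtex_score(effects, {"liver": [0]},
                          [EqtlRecord(self.V1, "liver", +1, True)])
        minus = gtex_score(effects, {"liver": [0]},
                           [EqtlRecord(self.V1, "liver", -1, True)])
        np.testing.assert_allclose(plus["score"], -minus["score"])

    def test_feature_subset_restriction(self):
        effects = [_effect(self.V1, [[0.5, -0.2, 0.9]])]
        scores = gtex_score(effects, {"liver": [0]},
                            [EqtlRecord(self.V1, "liver", +1, True)], features=[2])
        assert list(scores["feature"]) == [2]

    def test_tissue_without_cells_rejected(self):
        effects = [_effect(self.V1, [[0.5]])]
        with pytest.raises(ValueError):
            gtex_score(effects, {"liver": []}, [EqtlRecord(self.V1, "liver", 1, True)])


class TestGtexTest:
    def _frame(self, sig, non, tissue="liver", feature=0):
        rows = [
            {"variant": f"s{i}", "tissue": tissue, "feature": feature,
             "score": v, "significant": True}
            for i, v in enumerate(sig)
        ] + [
            {"variant": f"n{i}", "tissue": tissue, "feature": feature,
             "score": v, "significant": False}
            for i, v in enumerate(non)
        ]
        return pd.DataFrame(rows)

    def test_bonferroni_threshold_value(self, rng):
        frame = self._frame(rng.normal(size=10), rng.normal(size=10))
        out = gtex_test(frame, n_tissues=22, family_alpha=0.05)
        assert out["threshold"].iloc[0] == pytest.approx(0.05 / 22)
        assert round(out["threshold"].iloc[0], 4) == 0.0023

    def test_identical_distributions_not_significant(self, rng):
        hits = 0
        for trial in range(30):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            out = gtex_test(self._frame(x, y))
            hits += int(out["significant"].iloc[0])
        assert hits == 0  # threshold 0.0023 makes null hits very rare

    def test_separated_groups_significant(self, rng):
        out = gtex_test(
            self._frame(rng.normal(1.0, 0.1, 30), rng.normal(0.0, 0.1, 30))
        )
        assert out["p"].iloc[0] < 1e-10
        assert bool(out["significant"].iloc[0])


class TestVariantIo:
    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "variants.tsv"
        pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "pos": [100, 200],
             "ref": ["A", "C"], "alt": ["G", "T"]}
        ).to_csv(path, sep="\t", index=False)
        variants = read_variants_tsv(path)
        assert variants[0] == Variant("chr1", 100, "A", "G")
        assert variants[1] == Variant("chr2", 200, "C", "T")

    def test_vcf_snvs_only(self, tmp_path):
        path = tmp_path / "variants.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=100000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t1000\trs1\tA\tG\t.\t.\t.\n"
            "chr1\t2000\trs2\tAT\tA\t.\t.\t.\n"  # indel skipped
            "chr1\t3000\trs3\tC\tT,G\t.\t.\t.\n"  # multiallelic SNVs kept
        )
        variants = read_variants_vcf(path)
        assert [(v.pos, v.ref, v.alt) for v in variants] == [
            (1000, "A", "G"), (3000, "C", "T"), (3000, "C", "G"),
        ]

    def test_effects_tsv_export(self, tmp_path, rng):
        recs = [EffectRecord(Variant("chr1", 1000, "A", "G"), rng.normal(size=(2, 2)))]
        long_path = tmp_path / "effects.tsv"
        summary_path = tmp_path / "summary.tsv"
        write_effects_tsv(recs, long_path, summary_path)
        long_df = pd.read_csv(long_path, sep="\t")
        assert len(long_df) == 4
        summary = pd.read_csv(summary_path, sep="\t")
        assert summary["max_abs_effect"].iloc[0] == pytest.approx(
            recs[0].max_abs_effect
        )
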