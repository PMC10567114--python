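"""Feature extraction: the nine per-sample cfDNA feature groups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfmosaic.bins import BinScheme, TargetRegions
from cfmosaic.features import (
    FEATURE_GROUPS,
    MultiFeatureSet,
    apply_normalization,
    assemble_feature_set,
    extract_cna,
    extract_em,
    extract_flen,
    extract_fragment_bin_features,
    extract_gwm,
    extract_tm,
    fit_normalization,
    methylation_ratio,
)


def _frags(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "length"])


class TestMethylationRatio:
    @pytest.mark.parametrize(
        "m,u,expected", [(80, 20, 0.8), (0, 50, 0.0), (50, 0, 1.0)]
    )
    def test_values(self, m, u, expected):
        assert methylation_ratio(m, u) == expected

    def test_zero_coverage_is_missing_not_zero(self):
        assert np.isnan(methylation_ratio(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            methylation_ratio(-1, 5)


class TestTargetAndGenomeMethylation:
    def _panel(self, n=450):
        return TargetRegions(pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 100,
            "end": np.arange(n) * 100 + 50,
            "region_id": [f"r{i:04d}" for i in range(n)],
            "baseline": 0.5,
        }))

    def test_uniform_counts_give_constant_half(self):
        panel = self._panel()
        table = pd.DataFrame({
            "sample_id": "s", "interval_id": panel.region_ids,
            "methylated": 50, "unmethylated": 50,
        })
        tm = extract_tm(table, panel)
        assert len(tm) == 450
        assert (tm == 0.5).all()

    def test_row_order_independence(self):
        panel = self._panel(20)
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "sample_id": "s", "interval_id": panel.region_ids,
            "methylated": rng.integers(0, 100, 20),
            "unmethylated": rng.integers(1, 100, 20),
        })
        shuffled = table.sample(frac=1.0, random_state=1)
        pd.testing.assert_series_equal(
            extract_tm(table, panel), extract_tm(shuffled, panel)
        )

    def test_missing_region_names_ids(self):
        panel = self._panel(5)
        table = pd.DataFrame({
            "sample_id": "s", "interval_id": panel.region_ids[:3],
            "methylated": 1, "unmethylated": 1,
        })
        with pytest.raises(KeyError, match="r0003"):
            extract_tm(table, panel)

    def test_all_methylated_gives_ones_and_mask_respected(self):
        scheme = BinScheme.tile({"chr1": 100_000}, 10_000,
                                exclude={"chr1:20000-30000"})
        table = pd.DataFrame({
            "sample_id": "s", "interval_id": scheme.bin_ids,
            "methylated": 30, "unmethylated": 0,
        })
        gwm = extract_gwm(table, scheme)
        assert (gwm == 1.0).all()
        assert "chr1:20000-30000" not in gwm.index
        assert len(gwm) == 9


class TestCopyNumber:
    def _scheme(self):
        return BinScheme.tile({"chr1": 2_000_000}, 20_000)

    def _frags_from_counts(self, scheme, counts):
        rows = []
        for start, c in zip(scheme.included_frame()["start"], counts):
            rows += [("s", "chr1", start, 167)] * int(c)
        return _frags(rows)

    def test_gc_trend_removed(self):
        """Counts exactly on a linear GC trend, flat truth -> ~zero log2."""
        scheme = self._scheme()
        rng = np.random.default_rng(1)
        gc = np.linspace(0.35, 0.65, 100)
        rng.shuffle(gc)
        counts = np.round(400 * (0.5 + gc))
        vals = extract_cna(self._frags_from_counts(scheme, counts), scheme, gc)
        assert np.abs(vals).max() < 0.05

    def test_doubled_bin_is_one_log2_unit(self):
        scheme = self._scheme()
        counts = np.full(100, 500)
        counts[40] *= 2
        vals = extract_cna(
            self._frags_from_counts(scheme, counts), scheme, np.full(100, 0.5)
        )
        assert vals.iloc[40] == pytest.approx(1.0, abs=0.1)

    def test_all_zero_counts_rejected(self):
        scheme = self._scheme()
        frags = _frags([("s", "chr9", 0, 167)])  # wrong chromosome
        with pytest.raises(ValueError):
            extract_cna(frags, scheme, np.full(100, 0.5))

    def test_designed_gain_segment_recovered(self, cohort_features, cohort_labels):
        """Liver-class gain bins exceed the rest (t-test, designed effect)."""
        cna = cohort_features.matrices["CNA"].loc[cohort_labels == "liver"]
        gain_cols = [
            c for c in cna.columns
            if c.startswith("chr2:") and int(c.split(":")[1].split("-")[0]) < 100_000
        ]
        other_cols = [c for c in cna.columns if c not in gain_cols
                      and not c.startswith("chr2:1") and not c.startswith("chr2:2")]
        inside = cna[gain_cols].mean(axis=1)
        outside = cna[other_cols].mean(axis=1)
        t, p = stats.ttest_rel(inside, outside)
        assert t > 0 and p < 0.01


class TestFragmentLength:
    def test_single_length_point_mass(self):
        flen = extract_flen(_frags([("s", "chr1", i, 167) for i in range(10)]))
        assert len(flen) == 151
        assert flen["len_167"] == 100.0
        assert flen.drop("len_167").sum() == 0.0

    def test_out_of_range_ignored(self):
        flen = extract_flen(_frags([
            ("s", "chr1", 0, 99), ("s", "chr1", 1, 251), ("s", "chr1", 2, 150),
        ]))
        assert flen.sum() == pytest.approx(100.0)
        assert flen["len_150"] == 100.0

    def test_no_in_range_fragments_rejected(self):
        with pytest.raises(ValueError):
            extract_flen(_frags([("s", "chr1", 0, 50)]))

    def test_sums_to_100(self, cohort_features):
        sums = cohort_features.matrices["FLEN"].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-6)


class TestFragmentBins:
    def test_hand_counts(self):
        scheme = BinScheme.tile({"chr1": 100_000}, 100_000)
        rows = [("s", "chr1", i, 120) for i in range(27)]
        rows += [("s", "chr1", i, 200) for i in range(100)]
        feats = extract_fragment_bin_features(_frags(rows), scheme)
        assert feats.loc["chr1:0-100000", "short"] == 27
        assert feats.loc["chr1:0-100000", "long"] == 100
        assert feats.loc["chr1:0-100000", "ratio"] == pytest.approx(0.27)

    def test_conservation_short_plus_long_is_total(self, cohort_features):
        s = cohort_features.matrices["SHORT"]
        l = cohort_features.matrices["LONG"]
        t = cohort_features.matrices["TOTAL"]
        assert (s.to_numpy() + l.to_numpy() == t.to_numpy()).all()

    def test_zero_long_is_missing(self):
        scheme = BinScheme.tile({"chr1": 100_000}, 100_000)
        feats = extract_fragment_bin_features(
            _frags([("s", "chr1", 0, 120)]), scheme
        )
        assert np.isnan(feats["ratio"].iloc[0])


class TestEndMotifs:
    def test_brute_force_recount_oracle(self, reference):
        """extract_em agrees exactly with direct string slicing."""
        rng = np.random.default_rng(2)
        n = 2_000
        chroms = rng.choice(reference.chrom_names, n)
        starts = rng.integers(0, 99_000, n)
        frags = _frags(list(zip(["s"] * n, chroms, starts, [167] * n)))
        em = extract_em(frags, reference)
        naive = {}
        for c, s in zip(chroms, starts):
            motif = reference.slice(c, s, s + 4)
            if set(motif) <= set("ACGT") and len(motif) == 4:
                naive[motif] = naive.get(motif, 0) + 1
        total = sum(naive.values())
        assert len(em) == 256
        assert em.sum() == pytest.approx(1.0, abs=1e-9)
        for motif, count in naive.items():
            assert em[motif] == pytest.approx(count / total, abs=1e-12)

    def test_point_mass(self, reference):
        table = reference.motif_index["ACGT"]
        frags = _frags([
            ("s", reference.chrom_names[ci], pos, 167) for ci, pos in table[:50]
        ])
        em = extract_em(frags, reference)
        assert em["ACGT"] == 1.0

    def test_missing_chromosome_rejected(self, reference):
        with pytest.raises(KeyError):
            extract_em(_frags([("s", "chrX", 0, 167)]), reference)

    def test_permutation_invariance(self, reference):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 90_000, 500)
        frags = _frags([("s", "chr1", s, 167) for s in starts])
        shuffled = frags.sample(frac=1.0, random_state=4)
        pd.testing.assert_series_equal(
            extract_em(frags, reference), extract_em(shuffled, reference)
        )


class TestNormalization:
    def test_training_columns_become_standard(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.normal(2, 3, size=(30, 4)))
        model = fit_normalization(mat)
        z = apply_normalization(model, mat)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_constant_column_flagged_and_zeroed(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        model = fit_normalization(mat)
        assert model.flagged == ["a"]
        z = apply_normalization(model, mat)
        assert (z["a"] == 0.0).all()

    def test_validation_at_training_mean_is_zero(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.normal(size=(20, 3)))
        model = fit_normalization(mat)
        probe = pd.DataFrame([model.mean])
        assert np.allclose(apply_normalization(model, probe).to_numpy(), 0.0)

    def test_statistics_come_from_training_rows_only(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.normal(size=(40, 3)))
        mask = np.zeros(40, dtype=bool)
        mask[:25] = True
        model = fit_normalization(mat, mask)
        pd.testing.assert_series_equal(model.mean, mat.iloc[:25].mean(axis=0))


class TestAssembly:
    def test_all_nine_groups_required(self, cohort_features):
        assert sorted(cohort_features.matrices) == sorted(FEATURE_GROUPS)
        partial = {g: cohort_features.matrices[g] for g in FEATURE_GROUPS if g != "EM"}
        with pytest.raises(ValueError, match="EM"):
            assemble_feature_set(partial)

    def test_cardinalities(self, cohort_features):
        assert cohort_features.matrices["EM"].shape[1] == 256
        assert cohort_features.matrices["FLEN"].shape[1] == 151
        assert cohort_features.matrices["TM"].shape[1] == 450

    def test_round_trip_preserves_values(self, tmp_path, cohort_features):
        cohort_features.to_dir(tmp_path / "fx")
        back = MultiFeatureSet.from_dir(tmp_path / "fx")
        for g in FEATURE_GROUPS:
            pd.testing.assert_frame_equal(
                back.matrices[g], cohort_features.matrices[g],
                check_names=False,
            )

    def test_normalize_zscores_count_groups_only(self, cohort_features):
        norm = cohort_features.normalize()
        assert sorted(norm.zscored) == ["LONG", "SHORT", "TOTAL"]
        for g in ("SHORT", "LONG", "TOTAL"):
            assert np.allclose(norm.matrices[g].mean(axis=0), 0, atol=1e-9)
        # RATIO stays on its natural scale
        assert norm.matrices["RATIO"].to_numpy().mean() > 0.2
        assert not norm.concatenated().isna().any().any()

    def test_ratio_bounds(self, cohort_features):
        tm = cohort_features.matrices["TM"].to_numpy()
        gwm = cohort_features.matrices["GWM"].to_numpy()
        assert ((tm >= 0) & (tm <= 1)).all()
        assert ((gwm >= 0) & (gwm <= 1)).all()
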