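"""Radiomic extraction arithmetic, imputation, and ICC reliability filtering."""

import numpy as np
import pandas as pd
import pytest

from habitomics import (
    ExtractionConfig,
    FeatureName,
    extract_features,
    feature_names,
    filter_by_icc,
    icc_two_way,
    integrated_habitat_features,
    knn_impute,
)
from habitomics.features import icc_two_way_table
from habitomics.imaging import RegionMask, Volume


class TestFeatureArithmetic:
    def test_total_and_class_counts(self):
        names = [FeatureName.parse(n) for n in feature_names("intra")]
        assert len(names) == 1015
        by_class = pd.Series([n.feature_class for n in names]).value_counts()
        assert by_class["shape"] == 14
        assert by_class["firstorder"] == 198
        assert by_class["glcm"] == 242
        assert by_class["glrlm"] == 176
        assert by_class["glszm"] == 176
        assert by_class["ngtdm"] == 55
        assert by_class["gldm"] == 154

    def test_shape_only_under_original_filter(self):
        names = [FeatureName.parse(n) for n in feature_names("intra")]
        assert all(
            n.image_filter == "original" for n in names if n.feature_class == "shape"
        )
        with pytest.raises(ValueError):
            FeatureName("intra", "wavelet-LLL", "shape", "Sphericity")

    def test_name_round_trip(self):
        for n in feature_names("ring_2mm")[:50]:
            assert str(FeatureName.parse(n)) == n


class TestExtraction:
    def test_sphere_sphericity_near_one(self, sphere_volume):
        vol, mask = sphere_volume
        vec = extract_features(vol, mask.with_role("intra"))
        assert abs(vec["intra|original|shape|Sphericity"] - 1.0) < 0.05
        analytic = 4.0 / 3.0 * np.pi * 8.0**3
        assert abs(vec["intra|original|shape|MeshVolume"] - analytic) / analytic < 0.05

    def test_deterministic(self, sphere_volume):
        vol, mask = sphere_volume
        a = extract_features(vol, mask.with_role("intra"))
        b = extract_features(vol, mask.with_role("intra"))
        pd.testing.assert_series_equal(a, b)

    def test_firstorder_on_constant_region(self):
        img = np.full((16, 16, 16), 3.0)
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[4:12, 4:12, 4:12] = True
        vec = extract_features(Volume(img), RegionMask(mask, role="intra"))
        assert vec["intra|original|firstorder|Mean"] == pytest.approx(3.0)
        assert vec["intra|original|firstorder|Variance"] == pytest.approx(0.0)
        assert vec["intra|original|firstorder|Entropy"] == pytest.approx(0.0, abs=1e-9)
        assert vec["intra|original|firstorder|Uniformity"] == pytest.approx(1.0)

    def test_small_mask_returns_missing_vector(self, sphere_volume):
        vol, _ = sphere_volume
        tiny = np.zeros(vol.shape, dtype=bool)
        tiny[16, 16, 16] = True
        vec = extract_features(vol, RegionMask(tiny, role="h2"))
        assert len(vec) == 1015
        assert vec.isna().all()


class TestIntegratedHabitat:
    def test_concatenation_length_and_round_trip(self, sphere_volume):
        vol, mask = sphere_volume
        vecs = {
            t: extract_features(vol, mask.with_role(t)) for t in ("h1", "h2", "h3")
        }
        integ = integrated_habitat_features(vecs["h1"], vecs["h2"], vecs["h3"])
        assert len(integ) == 3045
        parsed = [FeatureName.parse(n) for n in integ.index]
        assert all(p.region == "habitat_integrated" for p in parsed)
        suffixes = pd.Series([p.base_name.rsplit("_", 1)[1] for p in parsed])
        assert (suffixes.value_counts() == 1015).all()

    def test_missing_habitat_propagates(self, sphere_volume):
        vol, mask = sphere_volume
        full = extract_features(vol, mask.with_role("h1"))
        missing = pd.Series(np.nan, index=feature_names("h2"))
        integ = integrated_habitat_features(full, missing, full.rename(lambda s: s.replace("h1", "h3")))
        assert integ.isna().sum() == 1015


class TestKnnImpute:
    def test_identical_rows_fill_shared_value(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [2.0, 2.0, np.nan, 2.0]})
        out = knn_impute(table)
        assert out.loc[2, "b"] == pytest.approx(2.0)

    def test_complete_table_unchanged(self, rng):
        table = pd.DataFrame(rng.normal(size=(10, 4)))
        table.columns = [f"f{i}" for i in range(4)]
        pd.testing.assert_frame_equal(knn_impute(table), table)

    def test_observed_cells_untouched_and_rmse_below_sd(self, rng):
        n, p = 80, 6
        base = rng.normal(size=(n, 2))
        X = base @ rng.normal(size=(2, p)) + 0.3 * rng.normal(size=(n, p))
        table = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
        holes = pd.DataFrame(
            rng.random(table.shape) < 0.1, index=table.index, columns=table.columns
        )
        masked = table.mask(holes)
        out = knn_impute(masked)
        pd.testing.assert_frame_equal(out.where(~holes), masked.where(~holes))
        err = (out - table).where(holes).stack()
        rmse = np.sqrt((err**2).mean())
        assert rmse < table.stack().std()

    def test_fully_missing_column_errors(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="b"):
            knn_impute(table)


class TestIcc:
    def test_identical_readers_give_one(self, rng):
        x = rng.normal(size=20)
        assert icc_two_way(x, x) == pytest.approx(1.0)

    def test_matches_pingouin_on_worked_table(self):
        pg = pytest.importorskip("pingouin")
        r1 = np.array([9.0, 6.0, 8.0, 7.0, 10.0])
        r2 = np.array([2.0, 1.0, 4.0, 1.0, 5.0])
        ours = icc_two_way(r1, r2)
        n = len(r1)
        df = pd.DataFrame(
            {
                "subject": list(range(n)) * 2,
                "rater": ["a"] * n + ["b"] * n,
                "score": np.concatenate([r1, r2]),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert ours == pytest.approx(icc2, rel=1e-10)

    def test_independent_noise_gives_near_zero(self, rng):
        r1 = rng.normal(size=200)
        r2 = rng.normal(size=200)
        assert abs(icc_two_way(r1, r2)) < 0.15

    def test_affine_rescaling_both_readers_invariant(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.3, 30)
        assert icc_two_way(3 * x + 5, 3 * y + 5) == pytest.approx(
            icc_two_way(x, y), rel=1e-9
        )

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            icc_two_way(np.ones(5), np.ones(5))


class TestIccFilter:
    @staticmethod
    def _cols(region, k):
        return [f"{region}|original|firstorder|F{i}" for i in range(k)]

    def test_identical_tables_drop_nothing(self, rng):
        cols = self._cols("intra", 4)
        t = pd.DataFrame(rng.normal(size=(10, 4)), columns=cols)
        kept, report = filter_by_icc(t, t.copy())
        assert list(kept.columns) == cols
        assert report["kept"].all()

    def test_habitat_columns_always_retained(self, rng):
        cols = self._cols("h1", 3)
        t = pd.DataFrame(rng.normal(size=(12, 3)), columns=cols)
        kept, report = filter_by_icc(t, pd.DataFrame(index=t.index))
        assert list(kept.columns) == cols
        assert report["exempt"].all()

    def test_noise_columns_mostly_dropped(self, rng):
        n = 100
        good = rng.normal(size=(n, 10))
        cols_good = self._cols("intra", 10)
        cols_bad = [f"ring_2mm|original|firstorder|N{i}" for i in range(10)]
        t1 = pd.DataFrame(
            np.hstack([good, rng.normal(size=(n, 10))]),
            columns=cols_good + cols_bad,
        )
        t2 = pd.DataFrame(
            np.hstack([good + rng.normal(0, 0.05, (n, 10)), rng.normal(size=(n, 10))]),
            columns=cols_good + cols_bad,
        )
        kept, report = filter_by_icc(t1, t2)
        dropped_bad = [c for c in cols_bad if c not in kept.columns]
        assert len(dropped_bad) >= 9
        assert all(c in kept.columns for c in cols_good)

    def test_missing_reader2_region_errors(self, rng):
        t1 = pd.DataFrame(rng.normal(size=(8, 2)), columns=self._cols("intra", 2))
        with pytest.raises(ValueError, match="reader-2"):
            filter_by_icc(t1, pd.DataFrame(index=t1.index))
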