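import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from mycoassembly.distance_decay import (
    EARTH_RADIUS_KM,
    geo_matrix,
    haversine_km,
    mantel,
    mantel_correlogram,
    mantel_masked,
    mask_zero_geo,
    mrm,
)

coords = st.tuples(
    st.floats(-90, 90), st.floats(-180, 180)
)


def euclid_dm(points, ids=None):
    ids = ids or [str(i) for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km(12.3, -45.6, 12.3, -45.6) == 0.0

    def test_one_degree_on_equator(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(
            2 * math.pi * EARTH_RADIUS_KM / 360
        )

    def test_survey_sites_against_law_of_cosines(self):
        # two Californian collection sites, cross-checked with the
        # spherical law of cosines
        lat1, lon1 = 38.319755, -123.05514
        lat2, lon2 = 32.713756, -117.22547
        p1, l1, p2, l2 = map(math.radians, (lat1, lon1, lat2, lon2))
        ref = EARTH_RADIUS_KM * math.acos(
            math.sin(p1) * math.sin(p2)
            + math.cos(p1) * math.cos(p2) * math.cos(l2 - l1)
        )
        assert haversine_km(lat1, lon1, lat2, lon2) == pytest.approx(ref, rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(coords, coords, coords)
    def test_metric_axioms(self, a, b, c):
        dab = haversine_km(a[0], a[1], b[0], b[1])
        dba = haversine_km(b[0], b[1], a[0], a[1])
        dac = haversine_km(a[0], a[1], c[0], c[1])
        dcb = haversine_km(c[0], c[1], b[0], b[1])
        assert dab == pytest.approx(dba)
        assert dab >= 0
        assert dab <= dac + dcb + 1e-6


class TestGeoMatrix:
    def test_same_site_zero_two_sites_block(self, toy_metadata):
        gm = geo_matrix(toy_metadata)
        assert gm["s1", "s2"] == 0.0
        assert gm["s1", "s3"] == pytest.approx(
            haversine_km(38.319755, -123.05514, 32.713756, -117.22547)
        )

    def test_missing_coordinates_listed(self, toy_metadata):
        bad = toy_metadata.copy()
        bad.loc["s2", "latitude"] = np.nan
        with pytest.raises(ValueError, match="s2"):
            geo_matrix(bad)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        dm = euclid_dm(rng.normal(size=(6, 2)))
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_skbio(self, rng):
        a = euclid_dm(rng.normal(size=(10, 2)))
        b = euclid_dm(rng.normal(size=(10, 2)))
        mine = mantel(a, b, n_perm=999, seed=1)
        r_ref, p_ref, _ = skbio_mantel(a, b, permutations=999, alternative="greater")
        assert mine.statistic == pytest.approx(r_ref)
        assert abs(mine.p_value - p_ref) < 0.05

    def test_exhaustive_equals_enumeration_oracle(self, rng):
        a = squareform(pdist(rng.normal(size=(5, 2))))
        b = squareform(pdist(rng.normal(size=(5, 2))))
        da = DistanceMatrix(a, ids=list("abcde"))
        db = DistanceMatrix(b, ids=list("abcde"))
        res = mantel(da, db, exact=True)
        iu = np.triu_indices(5, 1)
        obs = stats.pearsonr(a[iu], b[iu]).statistic
        perm_stats = [
            stats.pearsonr(a[iu], b[np.ix_(p, p)][iu]).statistic
            for p in itertools.permutations(range(5))
        ]
        assert res.n_permutations == 120
        assert res.p_value == pytest.approx(
            np.mean(np.asarray(perm_stats) >= obs - 1e-9)
        )

    def test_scale_invariance_of_r(self, rng):
        a = euclid_dm(rng.normal(size=(7, 2)))
        b_pts = rng.normal(size=(7, 2))
        b1 = euclid_dm(b_pts)
        b2 = DistanceMatrix(b1.data * 3.7, ids=b1.ids)
        r1 = mantel(a, b1, n_perm=99, seed=2).statistic
        r2 = mantel(a, b2, n_perm=99, seed=2).statistic
        assert r1 == pytest.approx(r2)

    def test_mismatched_ids_rejected(self, rng):
        a = euclid_dm(rng.normal(size=(5, 2)), ids=list("abcde"))
        b = euclid_dm(rng.normal(size=(5, 2)), ids=list("vwxyz"))
        with pytest.raises(ValueError):
            mantel(a, b)


class TestCorrelogram:
    def test_classes_partition_all_pairs(self, rng):
        n = 12
        comm = euclid_dm(rng.normal(size=(n, 3)))
        geo = euclid_dm(rng.uniform(0, 1000, size=(n, 1)))
        res = mantel_correlogram(comm, geo, n_perm=99, seed=0)
        assert res.class_counts.sum() == n * (n - 1) // 2

    def test_hand_binned_breaks(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0]])
        comm = euclid_dm(np.random.default_rng(0).normal(size=(4, 2)))
        geo = euclid_dm(pts)
        res = mantel_correlogram(comm, geo, n_classes=3, n_perm=99, seed=0)
        assert np.allclose(res.breaks, np.linspace(1.0, 10.0, 4))

    def test_decay_signal_detected_in_first_class(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pos = rng.uniform(0, 2000, size=(25, 1))
            geo = euclid_dm(pos)
            sim = np.exp(-squareform(pdist(pos)) / 400.0)
            comm = DistanceMatrix(1 - sim, ids=geo.ids)
            res = mantel_correlogram(comm, geo, n_perm=199, seed=seed)
            first = np.flatnonzero(~np.isnan(res.mantel_r))[0]
            hits += res.mantel_r[first] > 0 and res.p_values[first] < 0.05
        assert hits >= 4

    def test_far_classes_untested(self, rng):
        geo = euclid_dm(rng.uniform(0, 5000, size=(15, 1)))
        comm = euclid_dm(rng.normal(size=(15, 2)))
        res = mantel_correlogram(comm, geo, n_perm=99, seed=1)
        untested = res.class_midpoints > np.max(geo.condensed_form()) / 2
        assert np.isnan(res.p_values[untested]).all()


class TestMRM:
    def test_exact_linear_relationship(self, rng):
        pred = euclid_dm(rng.normal(size=(8, 2)))
        resp = DistanceMatrix(2.5 * pred.data, ids=pred.ids)
        res = mrm(resp, [pred], n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.coefficients.iloc[1] == pytest.approx(2.5)

    def test_single_predictor_equals_direct_ols(self, rng):
        a = euclid_dm(rng.normal(size=(9, 2)))
        b = euclid_dm(rng.normal(size=(9, 2)))
        res = mrm(a, [b], n_perm=99, seed=1)
        iu = np.triu_indices(9, 1)
        slope, intercept, r, *_ = stats.linregress(b.data[iu], a.data[iu])
        assert res.coefficients.iloc[1] == pytest.approx(slope)
        assert res.coefficients.iloc[0] == pytest.approx(intercept)
        assert res.r_squared == pytest.approx(r**2)

    def test_collinear_predictors_rejected(self, rng):
        a = euclid_dm(rng.normal(size=(7, 2)))
        b = DistanceMatrix(a.data * 2.0, ids=a.ids)
        with pytest.raises(ValueError, match="condition"):
            mrm(euclid_dm(rng.normal(size=(7, 2))), [a, b], n_perm=99, seed=0)


class TestMaskedMantel:
    def _two_site_setup(self, rng, inflate=0.0):
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "site_code": ["A"] * 4 + ["B"] * 4,
                "latitude": [38.3] * 4 + [32.7] * 4,
                "longitude": [-123.0] * 4 + [-117.2] * 4,
            }
        ).set_index("sample_id", drop=False)
        geo = geo_matrix(meta)
        base = squareform(pdist(rng.normal(size=(8, 3))))
        if inflate:
            same = (np.arange(8)[:, None] // 4) == (np.arange(8)[None, :] // 4)
            base = base + inflate * (~same)
            np.fill_diagonal(base, 0)
        comm = DistanceMatrix(base, ids=list(meta.index))
        return comm, geo

    def test_single_site_degenerate(self, rng):
        meta = pd.DataFrame(
            {
                "sample_id": ["x", "y"],
                "latitude": [1.0, 1.0],
                "longitude": [2.0, 2.0],
            }
        ).set_index("sample_id", drop=False)
        geo = geo_matrix(meta)
        comm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["x", "y"])
        with pytest.raises(ValueError):
            mask_zero_geo(comm, geo)

    def test_two_site_pair_count(self, rng):
        comm, geo = self._two_site_setup(rng)
        _, n_kept = mask_zero_geo(comm, geo)
        assert n_kept == 4 * 4

    def test_masking_removes_same_site_inflation(self, rng):
        # same-site similarity inflation drives the unmasked correlation
        comm, geo = self._two_site_setup(rng, inflate=2.0)
        full = mantel(comm, geo, n_perm=199, seed=0)
        masked = mantel_masked(comm, geo, n_perm=199, seed=0)
        assert masked.statistic < full.statistic
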