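import numpy as np
import pandas as pd
import pytest

from mycoassembly.core_neutral import (
    AbundanceOccupancy,
    abundance_occupancy,
    classify_deviation,
    core_by_contribution,
    fit_sloan,
    rank_asvs,
    sloan_occupancy_curve,
    summarize_core,
)
from mycoassembly.data_io import CountTable


def make_ao(p, occ, n_samples=100, depth=1000, sem=None):
    frame = pd.DataFrame(
        {
            "mean_rel_abund": p,
            "sem_rel_abund": np.zeros(len(p)) if sem is None else sem,
            "occupancy": occ,
            "site_consistency": np.ones(len(p)),
        },
        index=pd.Index([f"a{i}" for i in range(len(p))], name="asv_id"),
    )
    return AbundanceOccupancy(frame, n_samples, 4, depth)


class TestAbundanceOccupancy:
    def test_hand_computation(self, toy_metadata):
        t = CountTable(
            pd.DataFrame(
                [[5, 5, 0], [3, 7, 0], [0, 2, 8]],
                index=["s1", "s2", "s3"],
                columns=["a", "b", "c"],
            )
        )
        ao = abundance_occupancy(t, toy_metadata)
        f = ao.frame
        assert f.loc["a", "occupancy"] == pytest.approx(2 / 3)
        assert f.loc["b", "occupancy"] == 1.0
        assert f.loc["a", "mean_rel_abund"] == pytest.approx((0.5 + 0.3 + 0) / 3)
        # site consistency: a detected at BB only; b at both sites
        assert f.loc["a", "site_consistency"] == pytest.approx(0.5)
        assert f.loc["b", "site_consistency"] == 1.0

    def test_absent_asv_excluded(self, toy_metadata):
        t = CountTable(
            pd.DataFrame(
                [[5, 0], [5, 0], [5, 0]],
                index=["s1", "s2", "s3"],
                columns=["a", "gone"],
            )
        )
        ao = abundance_occupancy(t, toy_metadata)
        assert ao.asv_ids == ["a"]

    def test_unequal_depths_rejected(self, toy_metadata):
        t = CountTable(
            pd.DataFrame(
                [[5, 5], [3, 3], [1, 1]],
                index=["s1", "s2", "s3"],
                columns=["a", "b"],
            )
        )
        with pytest.raises(ValueError, match="rarefy"):
            abundance_occupancy(t, toy_metadata)


class TestRankAsvs:
    def test_ubiquitous_beats_rare(self):
        ao = make_ao([0.01, 0.0001], [1.0, 0.05])
        ao.frame.loc["a1", "site_consistency"] = 0.25
        assert rank_asvs(ao) == ["a0", "a1"]

    def test_abundance_breaks_ties(self):
        ao = make_ao([0.001, 0.01], [0.5, 0.5])
        assert rank_asvs(ao) == ["a1", "a0"]

    def test_five_asv_hand_scored_order(self):
        occ = np.array([1.0, 0.8, 0.8, 0.4, 0.2])
        sc = np.array([1.0, 1.0, 0.5, 0.5, 0.25])
        p = np.array([0.01, 0.02, 0.02, 0.05, 0.3])
        ao = make_ao(p, occ)
        ao.frame["site_consistency"] = sc
        score = 0.5 * occ / occ.max() + 0.5 * sc / sc.max()
        expected = [f"a{i}" for i in np.argsort(-score, kind="stable")]
        assert rank_asvs(ao) == expected


class TestCoreByContribution:
    def test_single_driver_core(self, rng):
        # one ASV explains all turnover; the rest constant across samples
        n = 20
        driver = rng.integers(0, 200, n)
        driver[driver == 0] = 1
        counts = np.column_stack(
            [driver] + [np.full(n, 50)] * 5
        )
        t = CountTable(
            pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(n)],
                columns=[f"a{i}" for i in range(6)],
            )
        )
        ranking = [f"a{i}" for i in range(6)]
        res = core_by_contribution(t, ranking)
        assert res.core_set == ["a0"]

    def test_high_threshold_rank_one_only(self, rng):
        counts = rng.integers(1, 50, size=(10, 6))
        t = CountTable(
            pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(10)],
                columns=[f"a{i}" for i in range(6)],
            )
        )
        res = core_by_contribution(t, [f"a{i}" for i in range(6)], threshold=0.999)
        assert res.core_set == ["a0"]

    def test_contribution_curve_monotone_and_normalized(self, rng):
        counts = rng.integers(0, 30, size=(12, 15))
        counts[:, 0] += 1
        t = CountTable(
            pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(12)],
                columns=[f"a{i}" for i in range(15)],
            )
        )
        res = core_by_contribution(t, [f"a{i}" for i in range(15)])
        assert np.all(np.diff(res.contribution_curve) >= -1e-12)
        assert res.contribution_curve[-1] == pytest.approx(1.0)

    def test_prefix_invariant_to_tail_relabeling(self, rng):
        counts = rng.integers(0, 30, size=(8, 10))
        counts[:, 0] += 1
        ids = [f"a{i}" for i in range(10)]
        t = CountTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(8)], columns=ids)
        )
        r1 = core_by_contribution(t, ids)
        swapped = ids[:6] + ids[8:10] + ids[6:8]
        r2 = core_by_contribution(t, swapped)
        assert np.allclose(
            r1.contribution_curve[:6], r2.contribution_curve[:6]
        )

    def test_planted_drivers_recovered(self):
        from mycoassembly.synthetic_data import simulate_core_community

        precs, recs = [], []
        for seed in range(5):
            t, meta, drivers = simulate_core_community(seed=seed)
            t = t.drop_empty_asvs()
            ao = abundance_occupancy(t, meta)
            res = core_by_contribution(t, rank_asvs(ao))
            got, want = set(res.core_set), set(drivers)
            precs.append(len(got & want) / len(got))
            recs.append(len(got & want) / len(want))
        assert np.mean(precs) >= 0.9 and np.mean(recs) >= 0.9


class TestFitSloan:
    def test_perfect_model_data_r2_one(self, rng):
        p = np.sort(rng.lognormal(-10, 2, 200))
        p /= p.sum() * 5  # keep p small
        occ = sloan_occupancy_curve(p, 1000, 0.01)
        ao = make_ao(p, occ, n_samples=150, depth=1000)
        fit = fit_sloan(ao)
        assert fit.m == pytest.approx(0.01, rel=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_prediction_limits_and_monotonicity(self):
        p_grid = np.linspace(1e-6, 0.999, 400)
        pred = sloan_occupancy_curve(p_grid, 1000, 0.01)
        assert np.all(np.diff(pred) >= -1e-12)
        assert pred[-1] > 0.999
        # monotone in m for taxa at or above the detection limit 1/N;
        # below it, strong immigration pins abundance under the limit and
        # the predicted occupancy eventually declines with m
        ms = np.linspace(1e-4, 0.5, 100)
        for p_fix in (1e-3, 1e-2, 0.1):
            preds = [sloan_occupancy_curve(np.array([p_fix]), 1000, m)[0] for m in ms]
            assert np.all(np.diff(preds) >= -1e-9)
        sub = np.array(
            [sloan_occupancy_curve(np.array([1e-4]), 1000, m)[0] for m in ms]
        )
        assert (np.diff(sub) < 0).any()

    def test_r_squared_negative_for_anti_model_data(self, rng):
        p = np.sort(rng.lognormal(-10, 2, 100))
        p /= p.sum() * 5
        # invert the occupancy pattern: abundant taxa rare, rare ubiquitous
        occ = 1.0 - sloan_occupancy_curve(p, 1000, 0.01)
        ao = make_ao(p, occ)
        fit = fit_sloan(ao)
        assert fit.r_squared < 0

    def test_too_few_asvs_rejected(self):
        ao = make_ao([0.1] * 5, [0.5] * 5)
        with pytest.raises(ValueError, match="10"):
            fit_sloan(ao)

    def test_all_occupied_rejected(self):
        ao = make_ao(np.linspace(0.01, 0.1, 20), np.ones(20))
        with pytest.raises(ValueError):
            fit_sloan(ao)

    def test_bounds_bracket_prediction(self, rng):
        p = np.sort(rng.lognormal(-9, 2, 50))
        p /= p.sum() * 3
        occ = np.clip(sloan_occupancy_curve(p, 1000, 0.005) + rng.normal(0, 0.02, 50), 0, 1)
        ao = make_ao(p, occ)
        fit = fit_sloan(ao)
        assert (fit.frame["lower"] <= fit.frame["predicted"] + 1e-12).all()
        assert (fit.frame["predicted"] <= fit.frame["upper"] + 1e-12).all()


class TestClassifyDeviation:
    def test_on_prediction_is_neutral(self, rng):
        p = np.sort(rng.lognormal(-10, 2, 50))
        p /= p.sum() * 5
        occ = sloan_occupancy_curve(p, 1000, 0.01)
        ao = make_ao(p, occ)
        fit = fit_sloan(ao)
        labels = classify_deviation(ao, fit)
        assert (labels == "neutral").all()

    def test_planted_extremes_labelled(self, rng):
        p = np.sort(rng.lognormal(-10, 2, 60))
        p /= p.sum() * 5
        occ = sloan_occupancy_curve(p, 1000, 0.01)
        occ[10] = 1.0   # rare but ubiquitous -> above
        occ[-1] = 0.01  # abundant but single-site -> below
        ao = make_ao(p, occ)
        fit = fit_sloan(ao)
        labels = classify_deviation(ao, fit)
        assert labels.iloc[10] == "above"
        assert labels.iloc[-1] == "below"


class TestSummarizeCore:
    def _cores(self):
        from mycoassembly.core_neutral import CoreResult

        def core(ids, members):
            return CoreResult(ids, np.ones(len(ids)), np.ones(len(ids)),
                              members, 0.1)

        return {
            "leaf": core(["sv1", "sv2"], ["sv1", "sv2"]),
            "root": core(["sv3", "sv1"], ["sv3"]),
        }

    def test_joined_row_shape(self):
        labels = {
            "leaf": pd.Series({"sv1": "below", "sv2": "neutral"}),
            "root": pd.Series({"sv3": "above"}),
        }
        da = pd.DataFrame(
            {
                "asv_id": ["sv1", "sv1", "sv9"],
                "comparison": ["leaf_vs_sediment", "root_vs_sediment", "leaf_vs_root"],
                "log2fc": [2.0, 1.5, 1.0],
                "padj": [0.001, 0.002, 0.001],
            }
        )
        out = summarize_core(self._cores(), labels, da, alpha=0.05)
        assert list(out["asv_id"]) == ["sv1"]
        row = out.iloc[0]
        assert row["core_prediction"] == "Leaf"
        assert row["neutral_deviation"] == "Below"
        assert row["significant_comparisons"] == "leaf > sediment; root > sediment"

    def test_non_core_and_non_significant_excluded(self):
        labels = {"leaf": pd.Series({"sv1": "neutral", "sv2": "neutral"}),
                  "root": pd.Series({"sv3": "neutral"})}
        da = pd.DataFrame(
            {
                "asv_id": ["sv2", "sv9"],
                "comparison": ["leaf_vs_root", "leaf_vs_root"],
                "log2fc": [1.0, -1.0],
                "padj": [0.5, 0.001],
            }
        )
        out = summarize_core(self._cores(), labels, da, alpha=0.05)
        assert out.empty

    def test_multi_core_labels_in_core_order(self):
        cores = self._cores()
        cores["root"].core_set.append("sv1")
        labels = {
            "leaf": pd.Series({"sv1": "above"}),
            "root": pd.Series({"sv1": "neutral"}),
        }
        da = pd.DataFrame(
            {
                "asv_id": ["sv1"],
                "comparison": ["root_vs_sediment"],
                "log2fc": [-2.0],
                "padj": [0.01],
            }
        )
        out = summarize_core(cores, labels, da, alpha=0.05)
        row = out.iloc[0]
        assert row["core_prediction"] == "Leaf, Root"
        assert row["neutral_deviation"] == "Above, neutral"
        assert row["significant_comparisons"] == "sediment > root"
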