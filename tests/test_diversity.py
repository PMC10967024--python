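import numpy as np
import pandas as pd
import pytest

from potatonet import diversity
from potatonet.tables_io import CountTable, SampleFrame
from _oracles import expected_richness_exact


def _table(rows, sample_ids=None, taxon_ids=None, marker="16S"):
    rows = np.asarray(rows)
    sids = sample_ids or [f"s{i}" for i in range(rows.shape[0])]
    tids = taxon_ids or [f"t{j}" for j in range(rows.shape[1])]
    return CountTable(sids, tids, rows, marker)


class TestRarefy:
    def test_exact_depth_unchanged(self):
        t = _table([[3, 4, 3]])
        out = diversity.rarefy(t, 10, seed=0)
        np.testing.assert_array_equal(out.table.counts, t.counts)

    def test_below_depth_dropped_and_listed(self):
        t = _table([[2, 2, 1], [5, 5, 5]])
        out = diversity.rarefy(t, 10, seed=0)
        assert out.dropped == ["s0"]
        assert out.table.sample_ids == ["s1"]

    def test_deterministic(self):
        t = _table([[40, 30, 30], [20, 50, 30]])
        a = diversity.rarefy(t, 50, seed=42)
        b = diversity.rarefy(t, 50, seed=42)
        np.testing.assert_array_equal(a.table.counts, b.table.counts)

    def test_row_sums_exact(self):
        t = _table([[40, 30, 30], [20, 50, 30]])
        out = diversity.rarefy(t, 37, seed=1)
        np.testing.assert_array_equal(out.table.sample_totals(), [37, 37])

    def test_all_below_depth_raises(self):
        with pytest.raises(ValueError, match="below depth"):
            diversity.rarefy(_table([[1, 1]]), 10, seed=0)


class TestRarefactionCurve:
    def test_single_taxon_richness_one(self):
        t = _table([[50, 0]])
        out = diversity.rarefaction_curve(t, [5, 10, 20], n_draws=5, seed=0)
        assert (out["richness"] == 1.0).all()

    def test_depth_equals_total_gives_observed(self):
        t = _table([[5, 3, 2]])
        out = diversity.rarefaction_curve(t, [10], n_draws=3, seed=0)
        assert out.loc[0, "richness"] == 3.0

    def test_mean_matches_hypergeometric_expectation(self):
        """Monte-Carlo mean within 2 SE of the closed-form expectation."""
        counts = np.array([12, 6, 3, 1])
        t = _table([counts])
        n_draws = 400
        out = diversity.rarefaction_curve(t, [8], n_draws=n_draws, seed=3)
        exact = expected_richness_exact(counts, 8)
        assert abs(exact - diversity.expected_rarefied_richness(counts, 8)) < 1e-9
        # per-draw richness is in {1..4}; sd bounded by 1
        se = 1.0 / np.sqrt(n_draws)
        assert abs(out.loc[0, "richness"] - exact) < 2 * se

    def test_decreasing_depths_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            diversity.rarefaction_curve(_table([[5, 5]]), [10, 5], 2, 0)


class TestAlpha:
    def test_chao1_no_singletons(self):
        out = diversity.alpha(_table([[2, 2, 2]]))
        assert out["chao1"].iloc[0] == 3.0

    def test_shannon_uniform(self):
        out = diversity.alpha(_table([[5, 5, 5, 5]]))
        assert out["shannon"].iloc[0] == pytest.approx(np.log(4), abs=1e-12)

    def test_chao1_bias_corrected_hand_value(self):
        # counts [1,1,2]: S=3, F1=2, F2=1 -> 3 + 2*1/(2*2) = 3.5
        out = diversity.alpha(_table([[1, 1, 2]]))
        assert out["chao1"].iloc[0] == pytest.approx(3.5)

    def test_empty_sample_reported_missing(self):
        out = diversity.alpha(_table([[0, 0], [1, 1]]))
        assert np.isnan(out["shannon"].iloc[0])
        assert not np.isnan(out["shannon"].iloc[1])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = diversity.bray_curtis(_table([[3, 3], [3, 3]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = diversity.bray_curtis(_table([[5, 0], [0, 7]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        # relative abundances (1,0) vs (0.5,0.5) -> BC = 0.5
        d = diversity.bray_curtis(_table([[8, 0], [5, 5]]))
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_total_rescaling_invariance(self):
        a = _table([[10, 5, 5], [2, 8, 10]])
        b = _table([[20, 10, 10], [1, 4, 5]])
        pd.testing.assert_frame_equal(diversity.bray_curtis(a), diversity.bray_curtis(b))

    def test_zero_total_sample_rejected(self):
        with pytest.raises(Exception, match="zero-total"):
            diversity.bray_curtis(_table([[0, 0], [1, 1]]))


class TestPcoa:
    def test_equilateral_two_equal_eigenvalues(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = diversity.pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(x)), index=range(6), columns=range(6))
        res = diversity.pcoa(d)
        coords = res.coordinates.to_numpy()
        d2 = squareform(pdist(coords))
        np.testing.assert_allclose(d2, d.to_numpy(), atol=1e-8)

    def test_two_samples_single_axis_full_variance(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        res = diversity.pcoa(d)
        assert res.coordinates.shape[1] == 1
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_coordinates_centered(self):
        d = pd.DataFrame(
            [[0, 0.2, 0.7], [0.2, 0, 0.5], [0.7, 0.5, 0]],
            index=list("abc"), columns=list("abc"),
        )
        res = diversity.pcoa(d)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-12)

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 0.5], [0.2, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            diversity.pcoa(d)


def _frame_for(n, labels):
    return SampleFrame(
        pd.DataFrame(labels, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
    )


class TestPermanova:
    def _toy(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 50, size=(n, 8))
        t = CountTable([f"s{i}" for i in range(n)], [f"t{j}" for j in range(8)], counts)
        frame = _frame_for(
            n,
            {
                "location": ["L1", "L2"] * (n // 2),
                "treatment": ["control", "treated"] * (n // 2),
                "timepoint": ["T0"] * (n // 2) + ["T1"] * (n // 2),
            },
        )
        return diversity.bray_curtis(t), frame

    def test_r2_sums_to_100(self):
        d, frame = self._toy()
        res = diversity.permanova(d, frame, ["location", "treatment", "time"], n_perm=49, seed=0)
        assert res.table["R2_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_duplicating_samples_preserves_r2(self):
        d, frame = self._toy()
        res1 = diversity.permanova(d, frame, ["location", "treatment"], n_perm=9, seed=0)
        dup_ids = [f"{s}{tag}" for tag in ("", "x") for s in d.index]
        d2 = pd.DataFrame(np.tile(d.to_numpy(), (2, 2)), index=dup_ids, columns=dup_ids)
        f2 = SampleFrame(
            pd.concat([frame.data, frame.data.set_axis([f"{s}x" for s in frame.data.index])])
        )
        res2 = diversity.permanova(d2, f2, ["location", "treatment"], n_perm=9, seed=0)
        np.testing.assert_allclose(
            res1.table["R2_pct"], res2.table["R2_pct"], atol=1e-8
        )

    def test_reproducible_under_seed(self):
        d, frame = self._toy()
        a = diversity.permanova(d, frame, ["location"], n_perm=99, seed=5)
        b = diversity.permanova(d, frame, ["location"], n_perm=99, seed=5)
        assert a.table.equals(b.table)

    def test_single_level_term_rejected(self):
        d, frame = self._toy()
        frame.data["treatment"] = "control"
        with pytest.raises(ValueError, match="single level"):
            diversity.permanova(d, frame, ["treatment"], n_perm=9, seed=0)

    def test_interaction_term_accepted(self):
        d, frame = self._toy()
        res = diversity.permanova(
            d, frame, ["location", "treatment", "location:treatment"], n_perm=19, seed=0
        )
        assert "location:treatment" in res.table.index

    def test_strata_permutation_stays_within_location(self):
        d, frame = self._toy()
        res = diversity.permanova(
            d, frame, ["treatment"], n_perm=49, seed=1, strata="location"
        )
        assert 0 < res.table.loc["treatment", "p"] <= 1


class TestFitVectors:
    def _ordination(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 60, size=(10, 6))
        t = CountTable([f"s{i}" for i in range(10)], [f"t{j}" for j in range(6)], counts)
        return diversity.pcoa(diversity.bray_curtis(t))

    def test_axis1_variable_r2_one(self):
        ordn = self._ordination()
        frame = _frame_for(
            10,
            {
                "location": ["L1"] * 5 + ["L2"] * 5,
                "treatment": ["control", "treated"] * 5,
                "timepoint": ["T0"] * 10,
                "v": ordn.coordinates.iloc[:, 0].to_numpy(),
            },
        )
        out = diversity.fit_vectors(ordn, frame, ["v"], n_perm=49, seed=0)
        assert out.loc["v", "R2"] == pytest.approx(1.0)
        assert out.loc["v", "p"] <= 0.05

    def test_missing_value_complete_cases(self):
        ordn = self._ordination()
        v = ordn.coordinates.iloc[:, 0].to_numpy().copy()
        v[0] = np.nan
        frame = _frame_for(
            10,
            {
                "location": ["L1"] * 10,
                "treatment": ["control"] * 10,
                "timepoint": ["T0"] * 10,
                "v": v,
            },
        )
        out = diversity.fit_vectors(ordn, frame, ["v"], n_perm=9, seed=0)
        assert out.loc["v", "n"] == 9

    def test_constant_variable_rejected(self):
        ordn = self._ordination()
        frame = _frame_for(
            10,
            {
                "location": ["L1"] * 10,
                "treatment": ["control"] * 10,
                "timepoint": ["T0"] * 10,
                "v": [1.0] * 10,
            },
        )
        with pytest.raises(ValueError, match="constant"):
            diversity.fit_vectors(ordn, frame, ["v"], n_perm=9, seed=0)


class TestRdaLocationCentered:
    def test_location_only_variation_gives_zero(self):
        """Counts constant within location -> centering leaves nothing."""
        counts = np.vstack([np.full((4, 5), 10 * (i + 1)) for i in range(3)])
        n = counts.shape[0]
        t = CountTable([f"s{i}" for i in range(n)], [f"t{j}" for j in range(5)], counts)
        frame = _frame_for(
            n,
            {
                "location": sum([[f"L{i}"] * 4 for i in range(3)], []),
                "treatment": ["control", "treated"] * 6,
                "timepoint": ["T0", "T0", "T1", "T1"] * 3,
            },
        )
        res = diversity.rda_location_centered(t, frame, ["treatment", "time"], n_perm=9, seed=0)
        np.testing.assert_allclose(res["R2_pct"], 0.0, atol=1e-10)

    def test_reproducible(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 40, size=(16, 10))
        t = CountTable([f"s{i}" for i in range(16)], [f"t{j}" for j in range(10)], counts)
        frame = _frame_for(
            16,
            {
                "location": ["L1"] * 8 + ["L2"] * 8,
                "treatment": ["control", "treated"] * 8,
                "timepoint": ["T0"] * 8 + ["T1"] * 8,
            },
        )
        a = diversity.rda_location_centered(t, frame, ["treatment", "time"], n_perm=49, seed=3)
        b = diversity.rda_location_centered(t, frame, ["treatment", "time"], n_perm=49, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert ((a["p"] > 0) & (a["p"] <= 1)).all()
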