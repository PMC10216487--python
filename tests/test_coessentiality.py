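"""Correlation screen, BH control, and elbow-threshold detection."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fitscreen import coessentiality as co
from fitscreen import simkit
from fitscreen.errors import DegenerateCurveError, InputError, QueryLookupError
from fitscreen.simkit import SimConfig


class TestPearsonProfile:
    def test_identity_and_negation(self):
        x = np.array([0.3, -1.2, 0.7, 2.0])
        assert co.pearson_profile(x, x)[0] == pytest.approx(1.0)
        assert co.pearson_profile(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # direct evaluation of the Pearson formula: r = 6.5 / sqrt(5 * 8.75)
        r, p = co.pearson_profile([1, 2, 3, 4], [1, 2, 3, 5])
        assert r == pytest.approx(6.5 / np.sqrt(5 * 8.75), abs=1e-12)
        assert r == pytest.approx(0.9827, abs=5e-5)
        assert 0 < p < 1

    def test_missing_entries_removed_pairwise(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 9.0, 8.0, np.nan]
        r, _ = co.pearson_profile(x, y)
        assert r == pytest.approx(1.0)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(InputError, match="variance"):
            co.pearson_profile([1, 1, 1], [1, 2, 3])

    def test_p_matches_t_transform(self):
        x = np.array([0.1, 0.9, -0.4, 1.3, 0.2, -0.7])
        y = np.array([0.0, 1.1, -0.2, 0.9, 0.4, -0.9])
        from scipy import stats
        r, p = co.pearson_profile(x, y)
        assert p == pytest.approx(stats.pearsonr(x, y).pvalue, rel=1e-9)


class TestBHAdjust:
    def test_hand_applied_step_up(self):
        # m=4: q_i = min_j>=i p_j * 4 / j -> all collapse to 0.04
        np.testing.assert_allclose(
            co.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_identity(self):
        assert co.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(co.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            co.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_order_invariance_and_dominance(self, ps, rnd):
        q = co.bh_adjust(ps)
        order = list(range(len(ps)))
        rnd.shuffle(order)
        q_shuf = co.bh_adjust([ps[i] for i in order])
        np.testing.assert_allclose(q[order], q_shuf, atol=1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-12) and np.all(q <= 1 + 1e-12)


class TestInflectionThreshold:
    def test_brute_force_oracle(self):
        r = np.array([1.0, 0.4, 0.2, 0.1, 0.05, 0.0])
        # oracle: perpendicular distance of each scaled point to the chord
        x = np.linspace(0, 1, len(r))
        y = (r - r[-1]) / (r[0] - r[-1])
        d = np.abs(x + y - 1) / np.sqrt(2)
        best = np.flatnonzero(d >= d.max() - 1e-12)[0]
        assert co.inflection_threshold(r) == r[best] == 0.4

    def test_exactly_linear_three_points_degenerate(self):
        # (1.0, 0.5, 0.0) lies exactly on its own chord: no elbow exists
        with pytest.raises(DegenerateCurveError):
            co.inflection_threshold([1.0, 0.5, 0.0])

    def test_near_linear_with_slight_bend_picks_middle(self):
        assert co.inflection_threshold([1.0, 0.45, 0.0]) == pytest.approx(0.45)

    def test_tie_breaks_toward_larger_r(self):
        # indices 1 and 2 are equidistant from the chord; pick the larger r
        assert co.inflection_threshold([1.0, 0.4, 0.2, 0.1, 0.05, 0.0]) == 0.4

    def test_linear_curve_is_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            co.inflection_threshold(np.linspace(1, 0, 10))

    def test_rank_axis_rescaling_equivariance(self):
        """Appending an affine tail preserves scale equivariance of the elbow."""
        r = np.array([1.0, 0.9, 0.3, 0.1, 0.05, 0.02, 0.0])
        thr = co.inflection_threshold(r)
        assert co.inflection_threshold(2 * r - 0.5) == pytest.approx(2 * thr - 0.5)


def planted_screen(seed=0, rho=0.9, n_lines=500, n_genes=2000, module_size=10):
    module = tuple(range(0, module_size * 22, 22))  # all land on chromosome "1"
    cfg = SimConfig(n_genes=n_genes, n_lines=n_lines, group_sizes={"WT": n_lines},
                    planted_coessential=((module, rho),), seed=seed)
    return simkit.sim_fitness_screen(cfg)


class TestCoessentialScreen:
    def test_query_missing_raises(self):
        screen, _ = planted_screen(n_genes=50, n_lines=40, module_size=3)
        with pytest.raises(QueryLookupError):
            co.coessential_screen(screen, "NOPE")

    def test_planted_module_all_flagged(self):
        screen, truth = planted_screen(seed=7)
        query = sorted(truth.coessential_genes)[0]
        res = co.coessential_screen(screen, query)
        rows = res.rows.set_index("gene")
        others = sorted(truth.coessential_genes - {query})
        assert rows.loc[others, "passes"].all()
        # the query itself is never reported as passing
        assert not rows.loc[query, "passes"]

    def test_symmetry_of_reported_r(self):
        screen, truth = planted_screen(n_genes=100, n_lines=60, module_size=4)
        a, b = sorted(truth.coessential_genes)[:2]
        ra = co.coessential_screen(screen, a).rows.set_index("gene").loc[b, "r"]
        rb = co.coessential_screen(screen, b).rows.set_index("gene").loc[a, "r"]
        assert ra == pytest.approx(rb, abs=1e-12)

    def test_exclude_chrom_drops_planted_chromosome(self):
        screen, truth = planted_screen(seed=3)
        # module genes are multiples of 22 -> all on chromosome "1"; query from
        # another chromosome sees zero passes once chr1 is excluded
        query = simkit.gene_symbol(1)  # chromosome "2"
        res = co.coessential_screen(screen, query, exclude_chrom="1")
        assert not set(res.rows.loc[res.rows["passes"], "gene"]) & truth.coessential_genes
        assert "1" not in set(res.rows["chrom"])

    def test_exclusion_happens_before_bh(self):
        """Non-syntenic q-values are BH over the kept genes' p-values only."""
        screen, _ = planted_screen(seed=5)
        query = simkit.gene_symbol(1)  # chromosome "2"
        full = co.coessential_screen(screen, query).rows.set_index("gene")
        nosyn = co.coessential_screen(screen, query, exclude_chrom="1").rows.set_index("gene")
        assert "1" not in set(nosyn["chrom"])
        expected_q = co.bh_adjust(nosyn["p"].to_numpy())
        import numpy as np
        np.testing.assert_allclose(nosyn["q"].to_numpy(), expected_q, atol=1e-12)
        # and the p-values themselves are unchanged by the exclusion
        np.testing.assert_allclose(nosyn["p"], full.loc[nosyn.index, "p"], atol=1e-12)

    def test_null_screen_calibration(self):
        """Without planting, essentially no gene should pass the screen."""
        frac = []
        for seed in range(20):
            cfg = SimConfig(n_genes=400, n_lines=150, group_sizes={"WT": 150}, seed=seed)
            screen, _ = simkit.sim_fitness_screen(cfg)
            res = co.coessential_screen(screen, simkit.gene_symbol(0))
            frac.append(res.rows["passes"].mean())
        assert np.mean(frac) <= 0.05
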