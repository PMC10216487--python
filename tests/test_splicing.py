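"""Entropy scoring, differential-splicing calls, and UTR direction."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fitscreen import simkit, splicing
from fitscreen.errors import InputError
from fitscreen.splicing import (DiffCall, SplicingEvent, classify_high_entropy,
                                compare_entropy_distributions, diff_splice, entropy,
                                tally_events, utr_direction)


def make_event(psi_a, psi_b, etype="CE", strand="+", start=100, end=150, gene="g"):
    psis = {("A", i + 1): p for i, p in enumerate(psi_a)}
    psis.update({("B", i + 1): p for i, p in enumerate(psi_b)})
    return SplicingEvent(gene=gene, chrom="chr1", start=start, end=end,
                         strand=strand, etype=etype, psi_by_rep=psis)


class TestEntropy:
    @pytest.mark.parametrize(
        "usage, expected",
        [
            ((1.0, 0.0), 0.0),
            ((0.5, 0.5), 1.0),
            ((0.25,) * 4, 2.0),
            ((0.7, 0.2, 0.1), 1.1567796494470395),  # -sum p log2 p directly
        ],
    )
    def test_closed_forms(self, usage, expected):
        assert entropy(usage) == pytest.approx(expected, abs=1e-12)

    def test_bad_inputs(self):
        with pytest.raises(InputError):
            entropy([0.5, 0.6])
        with pytest.raises(InputError):
            entropy([1.2, -0.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=8), st.randoms())
    def test_permutation_invariant_and_bounded(self, weights, rnd):
        u = np.array(weights) / np.sum(weights)
        e = entropy(u)
        shuffled = list(u)
        rnd.shuffle(shuffled)
        assert entropy(shuffled) == pytest.approx(e, abs=1e-9)
        assert 0 <= e <= np.log2(len(u)) + 1e-9
        # maximal iff uniform
        assert entropy(np.full(len(u), 1 / len(u))) >= e - 1e-9


class TestHighEntropy:
    def test_uniform_three_isoforms_is_high(self):
        assert classify_high_entropy(entropy([1 / 3] * 3))  # log2 3 ~ 1.585 > 1.5

    @pytest.mark.parametrize("e, expected", [(1.0, False), (1.5, False), (1.50001, True)])
    def test_strict_threshold(self, e, expected):
        assert classify_high_entropy(e) is expected


class TestDiffSplice:
    def test_identical_replicates_not_significant(self):
        call = diff_splice(make_event([0.4, 0.4], [0.4, 0.4]), seed=0)
        assert call.dpsi == 0.0 and not call.significant

    def test_noise_free_shift_has_probability_one(self):
        call = diff_splice(make_event([0.2, 0.2, 0.2], [0.5, 0.5, 0.5]), seed=0)
        assert call.dpsi == pytest.approx(0.3)
        assert call.probability == 1.0
        assert call.significant

    def test_antisymmetric_under_condition_swap(self):
        ev = make_event([0.2, 0.25, 0.3], [0.5, 0.55, 0.6])
        fwd = diff_splice(ev, seed=1)
        rev = diff_splice(ev, seed=1, condition_a="B", condition_b="A")
        assert rev.dpsi == pytest.approx(-fwd.dpsi)
        assert rev.probability == pytest.approx(fwd.probability, abs=0.05)

    def test_requires_two_replicates(self):
        with pytest.raises(InputError):
            diff_splice(make_event([0.2], [0.5, 0.5]), seed=0)

    def test_probability_monotone_in_true_effect(self):
        """Bootstrap sign-stability grows with |ΔΨ| at fixed dispersion."""
        probs = []
        for dpsi in (0.0, 0.1, 0.3):
            events = [dict(gene=f"g{i}", chrom="chr1", start=i * 100, end=i * 100 + 50,
                           strand="+", type="CE", psi=0.3) for i in range(40)]
            truth = {f"g{i}:chr1:{i * 100}-{i * 100 + 50}": dpsi for i in range(40)}
            ta, tb = simkit.sim_psi_tables(events, 3, truth, dispersion=0.02, seed=8)
            evs = splicing.events_from_psi_tables(ta, tb)
            calls = [diff_splice(e, seed=3) for e in evs]
            probs.append(np.mean([c.probability for c in calls]))
        assert probs[0] <= probs[1] <= probs[2]


class TestUTRDirection:
    def span(self):
        return (1000, 2000)

    def test_non_utr_type_not_applicable(self):
        call = diff_splice(make_event([0.2, 0.2], [0.5, 0.5], etype="RI"), seed=0)
        assert utr_direction(call, self.span()).utr_direction == "not_applicable"

    def test_plus_strand_te_proximal_up_is_shortened(self):
        # earlier of two terminal nodes on + strand: nearer the coding region
        ev = make_event([0.2, 0.2], [0.5, 0.5], etype="TE", start=2100, end=2150)
        call = diff_splice(ev, seed=0)
        out = utr_direction(call, self.span(), sibling_nodes=[(2100, 2150), (2400, 2450)])
        assert out.utr_direction == "shortened"

    def test_sign_flip_lengthens(self):
        ev = make_event([0.5, 0.5], [0.2, 0.2], etype="TE", start=2100, end=2150)
        call = diff_splice(ev, seed=0)
        out = utr_direction(call, self.span(), sibling_nodes=[(2100, 2150), (2400, 2450)])
        assert out.utr_direction == "lengthened"

    def test_minus_strand_te_mirrors(self):
        # on the minus strand the largest coordinates are 5'-ward of the gene,
        # so the high-coordinate terminal node is the proximal (early) poly-A
        ev = make_event([0.2, 0.2], [0.5, 0.5], etype="TE", strand="-",
                        start=900, end=950)
        call = diff_splice(ev, seed=0)
        out = utr_direction(call, self.span(), sibling_nodes=[(900, 950), (500, 550)])
        assert out.utr_direction == "shortened"

    def test_ts_mirrors_te(self):
        # for tandem TSS the coding region lies 3'-ward: the later (downstream)
        # start site shortens the 5' UTR when its usage increases
        ev = make_event([0.2, 0.2], [0.5, 0.5], etype="TS", start=900, end=950)
        call = diff_splice(ev, seed=0)
        out = utr_direction(call, self.span(), sibling_nodes=[(900, 950), (500, 550)])
        assert out.utr_direction == "shortened"

    def test_single_node_span_fallback(self):
        # a lone TE node far inside the span (relative to its own length)
        # counts as proximal; one abutting the span end counts as distal
        near = diff_splice(make_event([0.2, 0.2], [0.5, 0.5], etype="TE",
                                      start=1980, end=2000), seed=0)
        far = diff_splice(make_event([0.2, 0.2], [0.5, 0.5], etype="TE",
                                     start=1500, end=1520), seed=0)
        assert utr_direction(near, self.span()).utr_direction == "lengthened"
        assert utr_direction(far, self.span()).utr_direction == "shortened"


class TestCompareEntropyDistributions:
    def test_identical_samples(self):
        d, p = compare_entropy_distributions([0.1, 0.5, 1.0], [0.1, 0.5, 1.0])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = compare_entropy_distributions([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert d == 1.0

    def test_null_calibration(self, rng):
        rejections = sum(
            compare_entropy_distributions(rng.normal(size=200), rng.normal(size=200))[1] < 0.05
            for _ in range(100)
        )
        assert rejections <= 10

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            compare_entropy_distributions([], [1.0])


class TestTally:
    def test_empty(self):
        assert len(tally_events([])) == 0

    def test_events_and_distinct_genes(self):
        calls = []
        for i, gene in enumerate(["g1", "g1", "g2"]):
            ev = make_event([0.2, 0.2], [0.6, 0.6], etype="TE", gene=gene,
                            start=2000 + i * 100, end=2050 + i * 100)
            call = diff_splice(ev, seed=0)
            calls.append(utr_direction(call, (0, 1800),
                                       sibling_nodes=[(2000, 2050), (2100, 2150), (2200, 2250)]))
        tally = tally_events(calls).set_index(["type", "direction"])
        assert tally.loc[("TE", "shortened"), "n_events"] == 1   # earliest node
        assert tally.loc[("TE", "lengthened"), "n_events"] == 2
        assert tally["n_genes"].sum() == 3  # g1 counted once per direction

    def test_insignificant_calls_excluded(self):
        call = diff_splice(make_event([0.4, 0.4], [0.45, 0.45]), seed=0)
        assert len(tally_events([call])) == 0

    def test_round_trip_with_simkit_truth(self):
        """Planted noise-free ΔΨ events tally exactly to the planted truth."""
        events = [dict(gene=f"g{i}", chrom="chr1", start=i * 1000, end=i * 1000 + 100,
                       strand="+", type="RI", psi=0.3) for i in range(10)]
        truth = {f"g{i}:chr1:{i * 1000}-{i * 1000 + 100}": 0.4 for i in range(5)}
        ta, tb = simkit.sim_psi_tables(events, 3, truth, dispersion=0.0, seed=2)
        evs = splicing.events_from_psi_tables(ta, tb)
        calls = [diff_splice(e, seed=0) for e in evs]
        tally = tally_events(calls).set_index(["type", "direction"])
        assert tally.loc[("RI", "not_applicable"), "n_events"] == 5
        assert tally.loc[("RI", "not_applicable"), "n_genes"] == 5
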