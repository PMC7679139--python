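"""Division classification, sister comparisons and endosome partition."""

import numpy as np
import pytest

from asymtrack import asymmetry
from asymtrack.asymmetry import DivisionCall, DivisionClass
from asymtrack.io_tracks import Fate, SisterPair, ValidationError
from asymtrack.stats import wilson_interval
from conftest import make_track


def make_pair(fates, depths_a, depths_b, pair_id="p1", bp=None, endo=None):
    kw_a, kw_b = {}, {}
    if bp is not None:
        kw_a["basal_process"], kw_b["basal_process"] = bp == "A", bp == "B"
    if endo is not None:
        kw_a["endosome_count"], kw_b["endosome_count"] = endo
    a = make_track(depths_a, track_id=f"{pair_id}a", pair_id=pair_id, fate=fates[0], **kw_a)
    b = make_track(depths_b, track_id=f"{pair_id}b", pair_id=pair_id, fate=fates[1], **kw_b)
    return SisterPair(pair_id=pair_id, daughter_a=a, daughter_b=b)


class TestClassification:
    @pytest.mark.parametrize(
        "fates,expected",
        [
            ((Fate.ATH5_POS, Fate.ATH5_NEG), DivisionClass.ASYMMETRIC),
            ((Fate.ATH5_POS, Fate.ATH5_POS), DivisionClass.SYMMETRIC_NEUROGENIC),
            ((Fate.ATH5_NEG, Fate.ATH5_NEG), DivisionClass.SYMMETRIC_PROLIFERATIVE),
            ((Fate.ATH5_NEG, Fate.UNKNOWN), DivisionClass.INDETERMINATE),
        ],
    )
    def test_mapping(self, fates, expected):
        call = asymmetry.classify_division(make_pair(fates, [1, 2], [1, 2]))
        assert call.call is expected

    def test_pos_count(self):
        call = asymmetry.classify_division(
            make_pair((Fate.ATH5_POS, Fate.ATH5_NEG), [1, 2], [1, 2])
        )
        assert call.ath5_pos_count == 1


class TestProportions:
    def calls(self, n_asym, n_sym):
        out = [
            DivisionCall(f"a{i}", DivisionClass.ASYMMETRIC, 1, embryo_id=f"E{i % 3}")
            for i in range(n_asym)
        ]
        out += [
            DivisionCall(f"s{i}", DivisionClass.SYMMETRIC_NEUROGENIC, 2, embryo_id="E0")
            for i in range(n_sym)
        ]
        return out

    def test_cohort_fractions(self):
        # a 38-division cohort split 35/3 gives 92.1% vs 7.9%
        table = asymmetry.division_proportions(self.calls(35, 3))
        by = table.set_index("call")
        assert by.loc["ASYMMETRIC", "fraction"] == pytest.approx(35 / 38)
        assert round(100 * by.loc["ASYMMETRIC", "fraction"], 1) == 92.1
        assert round(100 * by.loc["SYMMETRIC_NEUROGENIC", "fraction"], 1) == 7.9
        lo, hi = wilson_interval(35, 38)
        assert by.loc["ASYMMETRIC", "ci_low"] == pytest.approx(lo)
        assert by.loc["ASYMMETRIC", "ci_high"] == pytest.approx(hi)

    def test_single_call(self):
        table = asymmetry.division_proportions(self.calls(1, 0))
        assert table.set_index("call").loc["ASYMMETRIC", "fraction"] == 1.0

    def test_order_invariance(self, rng):
        calls = self.calls(10, 4)
        ref = asymmetry.division_proportions(calls)
        perm = [calls[i] for i in rng.permutation(len(calls))]
        assert asymmetry.division_proportions(perm).equals(ref)

    def test_all_indeterminate_raises(self):
        calls = [DivisionCall("x", DivisionClass.INDETERMINATE, 0)]
        with pytest.raises(ValidationError):
            asymmetry.division_proportions(calls)

    def test_fractions_sum_to_one(self):
        table = asymmetry.division_proportions(self.calls(7, 5))
        assert table["fraction"].sum() == pytest.approx(1.0)


class TestCompareSisters:
    def test_arithmetic(self):
        pair = make_pair((Fate.ATH5_POS, Fate.ATH5_NEG), [0, 30], [0, 18])
        c = asymmetry.compare_sisters(pair)
        assert c.abs_difference == 12.0 and c.more_basal_fate == "ATH5_POS"

    def test_tie(self):
        pair = make_pair((Fate.ATH5_POS, Fate.ATH5_NEG), [0, 20], [0, 20])
        assert asymmetry.compare_sisters(pair).more_basal_fate == "TIE"

    def test_basal_process_flag(self):
        pair = make_pair((Fate.ATH5_POS, Fate.ATH5_NEG), [0, 30], [0, 18], bp="B")
        assert asymmetry.compare_sisters(pair).basal_process_to_more_basal is False


class TestStratified:
    def test_hand_example(self):
        comps = [
            asymmetry.SisterComparison("p1", 10, 5, 5.0, "ATH5_POS", None),
            asymmetry.SisterComparison("p2", 12, 5, 7.0, "ATH5_POS", None),
            asymmetry.SisterComparison("p3", 5, 8, 3.0, "ATH5_NEG", None),
        ]
        table = asymmetry.stratified_difference(comps).set_index("more_basal_fate")
        assert table.loc["ATH5_POS", "mean_um"] == 6.0
        assert table.loc["ATH5_POS", "sd_um"] == pytest.approx(np.sqrt(2))
        assert np.isnan(table.loc["ATH5_NEG", "sd_um"])  # one-element stratum

    def test_matches_two_pass_oracle(self, rng):
        comps = [
            asymmetry.SisterComparison(
                f"p{i}", 0, 0, float(v), str(rng.choice(["ATH5_POS", "ATH5_NEG"])), None
            )
            for i, v in enumerate(rng.uniform(0, 20, 40))
        ]
        table = asymmetry.stratified_difference(comps).set_index("more_basal_fate")
        for stratum in ("ATH5_POS", "ATH5_NEG"):
            vals = [c.abs_difference for c in comps if c.more_basal_fate == stratum]
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert table.loc[stratum, "mean_um"] == pytest.approx(mean)
            assert table.loc[stratum, "sd_um"] == pytest.approx(sd)


class TestEndosomePartition:
    def test_all_to_one(self):
        p = make_pair((Fate.ATH5_POS, Fate.ATH5_NEG), [0, 1], [0, 1], endo=(3, 0))
        s = asymmetry.endosome_partition(p)
        assert (s.total, s.minority_fraction, s.all_to_one) == (3, 0.0, True)

    def test_even_split(self):
        p = make_pair((Fate.ATH5_POS, Fate.ATH5_NEG), [0, 1], [0, 1], endo=(2, 2))
        s = asymmetry.endosome_partition(p)
        assert (s.minority_fraction, s.all_to_one) == (0.5, False)

    def test_zero_total(self):
        p = make_pair((Fate.ATH5_POS, Fate.ATH5_NEG), [0, 1], [0, 1], endo=(0, 0))
        s = asymmetry.endosome_partition(p)
        assert np.isnan(s.minority_fraction) and not s.all_to_one

    def test_missing_counts_raise(self):
        p = make_pair((Fate.ATH5_POS, Fate.ATH5_NEG), [0, 1], [0, 1])
        with pytest.raises(ValidationError):
            asymmetry.endosome_partition(p)

    def test_all_to_one_rate_recovers_simulated_probability(self, rng):
        # all-to-one with probability q, otherwise a fair split of 4
        q, n = 0.7, 400
        hits = 0
        for i in range(n):
            if rng.random() < q:
                counts = (4, 0)
            else:
                k = int(rng.binomial(4, 0.5))
                counts = (k, 4 - k)
            p = make_pair((Fate.ATH5_POS, Fate.ATH5_NEG), [0, 1], [0, 1], endo=counts)
            hits += asymmetry.endosome_partition(p).all_to_one
        # observed all-to-one rate = q + (1-q) P(binomial split is 0 or 4)
        expected = q + (1 - q) * (2 * 0.5**4)
        lo, hi = wilson_interval(hits, n)
        assert lo <= expected <= hi


class TestConcordance:
    def test_fifteen_of_sixteen(self, rng):
        pairs = []
        for i in range(16):
            concordant = i < 15
            # basal process owner is daughter A; A is more basal iff concordant
            depths_a = [0, 30] if concordant else [0, 10]
            fate_a = Fate.ATH5_POS if i < 10 else Fate.ATH5_NEG
            fate_b = Fate.ATH5_NEG if fate_a is Fate.ATH5_POS else Fate.ATH5_POS
            pairs.append(make_pair((fate_a, fate_b), depths_a, [0, 20], pair_id=f"p{i}", bp="A"))
        table = asymmetry.basal_process_concordance(pairs).set_index("event")
        assert table.loc["process_inheritor_more_basal", "count"] == 15
        assert table.loc["process_inheritor_more_basal", "n"] == 16
        assert table.loc["process_inheritor_ath5_pos", "count"] == 10

    def test_no_eligible_pairs(self):
        pairs = [make_pair((Fate.ATH5_POS, Fate.ATH5_NEG), [0, 5], [0, 9])]
        table = asymmetry.basal_process_concordance(pairs).set_index("event")
        assert table.loc["process_inheritor_more_basal", "n"] == 0
        assert np.isnan(table.loc["process_inheritor_more_basal", "fraction"])

    def test_order_invariance(self, rng):
        pairs = [
            make_pair(
                (Fate.ATH5_POS, Fate.ATH5_NEG),
                [0, float(rng.uniform(5, 30))],
                [0, float(rng.uniform(5, 30))],
                pair_id=f"p{i}",
                bp=str(rng.choice(["A", "B"])),
            )
            for i in range(12)
        ]
        ref = asymmetry.basal_process_concordance(pairs)
        perm = [pairs[i] for i in rng.permutation(len(pairs))]
        assert asymmetry.basal_process_concordance(perm).equals(ref)
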