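"""Binned sampling, set-level discriminability, reversal search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from percat.boundary import DiscriminabilityRecord
from percat.design import (
    bin_and_sample,
    bin_label,
    reversal_search,
    set_discriminability,
)

from conftest import axis_mean, gaussian_descriptors


def _rec(image_id, rate, dval=0.0):
    return DiscriminabilityRecord(
        image_id=image_id, task="t", test_appearances=5,
        correct_rate=rate, mean_decision_value=dval,
    )


class TestBinLabel:
    @pytest.mark.parametrize(
        "rate,label",
        [(0.95, 1.0), (0.15, 0.2), (0.0, 0.2), (0.2, 0.2), (0.21, 0.4),
         (0.6, 0.6), (3 / 5, 0.6), (0.8, 0.8), (1.0, 1.0)],
    )
    def test_edges_and_float_fuzz(self, rate, label):
        assert bin_label(rate) == label

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_partition_property(self, rate):
        """Every rate lands in exactly one bin whose half-open interval
        (lower, upper] — closed at 0 — contains it."""
        label = bin_label(rate)
        assert label in (0.2, 0.4, 0.6, 0.8, 1.0)
        assert (label - 0.2 < rate <= label + 1e-9) or (rate == 0.0 and label == 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bin_label(1.2)


class TestBinAndSample:
    def _records(self, per_bin_pop=8, classes=("natural", "manmade")):
        records, class_of = [], {}
        for cls in classes:
            for b, label in enumerate((0.2, 0.4, 0.6, 0.8, 1.0)):
                for k in range(per_bin_pop):
                    i = f"{cls}_{label}_{k}"
                    records.append(_rec(i, label - 0.01 * (k % 3)))
                    class_of[i] = cls
        return records, class_of

    def test_samples_distinct_ids_across_all_bins(self):
        records, class_of = self._records()
        out = bin_and_sample(records, per_bin=5, seed=1, class_of=class_of)
        assert len(out) == 10  # 5 bins x 2 classes
        all_ids = [i for sb in out.values() for i in sb.ids]
        assert len(all_ids) == 50 == len(set(all_ids))

    def test_realized_mean_close_to_bin_label(self):
        records, class_of = self._records()
        out = bin_and_sample(records, per_bin=5, seed=2, class_of=class_of)
        for (cls, label), sb in out.items():
            assert sb.realized_mean == pytest.approx(label, abs=0.05)

    def test_exclusions_never_sampled(self):
        records, class_of = self._records()
        excluded = {f"natural_0.4_{k}" for k in range(3)}
        out = bin_and_sample(
            records, per_bin=5, seed=3, exclusion_list=excluded, class_of=class_of
        )
        sampled = set(out[("natural", 0.4)].ids)
        assert len(sampled) == 5 and not (sampled & excluded)

    def test_same_seed_reproducible(self):
        records, class_of = self._records()
        a = bin_and_sample(records, per_bin=5, seed=4, class_of=class_of)
        b = bin_and_sample(records, per_bin=5, seed=4, class_of=class_of)
        assert {k: v.ids for k, v in a.items()} == {k: v.ids for k, v in b.items()}

    def test_underpopulated_bin_names_bin_and_shortfall(self):
        records, class_of = self._records(per_bin_pop=4)
        with pytest.raises(ValueError, match=r"0\.2.*4 eligible.*short 2"):
            bin_and_sample(records, per_bin=6, seed=5, class_of=class_of)


class TestSetDiscriminability:
    def test_identical_distributions_zero(self):
        v = list(np.random.default_rng(0).standard_normal(50))
        assert set_discriminability(v, list(v)) == 0.0

    def test_unit_variance_unit_separation(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(4000) + 1.0
        d = rng.standard_normal(4000)
        assert set_discriminability(t, d) == pytest.approx(1.0, abs=0.06)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(2)
        t, d = rng.normal(2, 3, 17), rng.normal(-1, 2, 23)
        pooled = math.sqrt(
            ((len(t) - 1) * np.var(t, ddof=1) + (len(d) - 1) * np.var(d, ddof=1))
            / (len(t) + len(d) - 2)
        )
        assert set_discriminability(t, d) == abs(t.mean() - d.mean()) / pooled

    def test_degenerate_cases(self):
        assert set_discriminability([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert set_discriminability([1.0, 1.0], [2.0, 2.0]) == math.inf
        with pytest.raises(ValueError):
            set_discriminability([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            set_discriminability([np.nan, 1.0], [1.0, 2.0])


def reversal_fixture(seed=0, n=14, dim=24):
    """Natural pool split into two families: one confusable with the man-made
    cluster (hard superordinate / easy basic), one confusable with the basic
    target (easy superordinate / hard basic)."""
    margin = 6.0
    e_man, e_basic = axis_mean(dim, 0, margin), axis_mean(dim, 1, margin)
    means = {
        "man_0": e_man, "man_1": e_man + axis_mean(dim, 2, 2.0),
        "man_2": e_man + axis_mean(dim, 3, 2.0),
        "forestlike": e_basic,
        # near the man-made cluster:
        "nat_likeman_0": e_man + axis_mean(dim, 4, 1.0),
        "nat_likeman_1": e_man + axis_mean(dim, 5, 1.0),
        # near the basic target:
        "nat_likebasic_0": e_basic + axis_mean(dim, 6, 1.0),
        "nat_likebasic_1": e_basic + axis_mean(dim, 7, 1.0),
        "nat_neutral": np.zeros(dim),
    }
    desc, cats = gaussian_descriptors(means, n, seed=seed, dim=dim)
    natural = [c for c in means if c.startswith("nat_")]
    manmade = [c for c in means if c.startswith("man_")]
    return desc, cats, natural, manmade, "forestlike"


class TestReversalSearch:
    def test_opposite_advantage_conditions_found(self):
        desc, cats, nat, man, target = reversal_fixture()
        res = reversal_search(
            desc, cats, nat, man, target, k=3, n_splits=2, seed=1, c_grid=[1.0]
        )
        assert res.superordinate_advantage.advantage > 0
        assert res.basic_advantage.advantage < 0
        # the confusable families drive the extremes
        assert set(res.basic_advantage.natural_set) >= {"nat_likeman_0", "nat_likeman_1"}
        assert set(res.superordinate_advantage.natural_set) >= {
            "nat_likebasic_0", "nat_likebasic_1"
        }

    def test_enumerates_all_combinations(self):
        desc, cats, nat, man, target = reversal_fixture()
        res = reversal_search(
            desc, cats, nat, man, target, k=2, n_splits=1, seed=2, c_grid=[1.0]
        )
        assert len(res.table) == math.comb(len(nat), 2) * math.comb(len(man), 2)

    def test_invariant_to_pool_order(self):
        desc, cats, nat, man, target = reversal_fixture()
        a = reversal_search(desc, cats, nat, man, target, k=3, n_splits=1, seed=3, c_grid=[1.0])
        b = reversal_search(
            desc, cats, nat[::-1], man[::-1], target, k=3, n_splits=1, seed=3, c_grid=[1.0]
        )
        assert a.superordinate_advantage == b.superordinate_advantage
        assert a.basic_advantage == b.basic_advantage

    def test_k_equal_to_pool_size_degenerates(self):
        desc, cats, nat, man, target = reversal_fixture()
        res = reversal_search(
            desc, cats, nat[:3], man, target, k=3, n_splits=1, seed=4, c_grid=[1.0]
        )
        assert (res.table["natural_set"].map(tuple) == tuple(sorted(nat[:3]))).all()

    def test_small_pool_rejected(self):
        desc, cats, nat, man, target = reversal_fixture()
        with pytest.raises(ValueError):
            reversal_search(desc, cats, nat[:2], man, target, k=3)
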