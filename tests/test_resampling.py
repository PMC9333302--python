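from collections import Counter
from itertools import chain, combinations

import numpy as np
import pytest

from reproscore import (
    BiomarkerSet,
    DatasetError,
    DiscoveryConfig,
    LabeledDataset,
    discover,
    SyntheticSpec,
    bootstrap_pair,
    disjoint_half_partition,
    doubled_balanced_partition,
    estimate,
    generate,
    jaccard,
    rs_hat_half,
    rs_star_monte_carlo,
    subset_curve,
)


def _balanced_dataset(n_per_class, r=3, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(2 * n_per_class, r))
    return LabeledDataset(
        values, ["+"] * n_per_class + ["-"] * n_per_class, positive_label="+"
    )


def all_subsets(universe):
    return [
        frozenset(c)
        for c in chain.from_iterable(
            combinations(universe, k) for k in range(len(universe) + 1)
        )
    ]


class TestJaccard:
    def test_identical_nonempty_sets(self):
        assert jaccard(BiomarkerSet({"g1", "g2"}), BiomarkerSet({"g1", "g2"})) == 1.0

    def test_disjoint_sets(self):
        assert jaccard(BiomarkerSet({"g1"}), BiomarkerSet({"g2"})) == 0.0

    def test_partial_overlap(self):
        assert jaccard({"g1", "g2"}, {"g2", "g3"}) == pytest.approx(1 / 3)

    def test_both_empty_is_zero_by_convention(self):
        assert jaccard(BiomarkerSet(), BiomarkerSet()) == 0.0

    def test_exhaustive_contract_on_four_element_universe(self):
        subsets = all_subsets("abcd")
        for a in subsets:
            for b in subsets:
                j = jaccard(a, b)
                expected = len(a & b) / len(a | b) if (a | b) else 0.0
                assert j == expected
                assert j == jaccard(b, a)
                assert 0.0 <= j <= 1.0
                assert (j == 1.0) == (a == b and len(a) > 0)
                assert (j == 0.0) == (len(a & b) == 0)


class TestDoubledPartition:
    def test_multiset_union_equals_doubled_dataset(self):
        ds = _balanced_dataset(7)
        pair = doubled_balanced_partition(ds, np.random.default_rng(1))
        combined = Counter(pair.d1.subject_ids) + Counter(pair.d2.subject_ids)
        assert combined == Counter({s: 2 for s in ds.subject_ids})

    def test_halves_are_comparable(self):
        ds = _balanced_dataset(9)
        pair = doubled_balanced_partition(ds, np.random.default_rng(2))
        assert pair.d1.class_counts() == ds.class_counts()
        assert pair.d2.class_counts() == ds.class_counts()

    def test_single_subject_per_class_forces_full_overlap(self):
        ds = LabeledDataset([[1.0], [2.0]], ["+", "-"], positive_label="+")
        pair = doubled_balanced_partition(ds, np.random.default_rng(3))
        assert sorted(pair.d1.subject_ids) == sorted(ds.subject_ids)
        assert sorted(pair.d2.subject_ids) == sorted(ds.subject_ids)

    def test_duplicated_subjects_inflate_type_one_error(self):
        # a doubled half holds ~75% distinct subjects, so the nominal
        # t-test is anticonservative on it: the null rejection rate at
        # alpha = 0.05 roughly doubles.  This is what erodes the overbound
        # once discovery saturates (see the methods note).
        spec = SyntheticSpec(n_plus=100, n_minus=100, r=2000, n_true=0, seed=8)
        ds = generate(spec)
        cfg_raw = DiscoveryConfig(alpha=0.05, mcc="none")
        rates = []
        for rep in range(5):
            pair = doubled_balanced_partition(ds, np.random.default_rng(rep))
            found, _ = discover(pair.d1, cfg_raw)
            rates.append(len(found) / ds.r)
        assert 0.08 < np.mean(rates) < 0.14

    def test_expected_distinct_overlap_near_half(self):
        # P(a subject's two copies land in different halves) = n/(2n-1)
        ds = _balanced_dataset(50)
        fracs = []
        for rep in range(300):
            pair = doubled_balanced_partition(ds, np.random.default_rng(rep))
            both = set(pair.d1.subject_ids) & set(pair.d2.subject_ids)
            fracs.append(len(both) / ds.n)
        assert np.mean(fracs) == pytest.approx(50 / 99, abs=0.02)


class TestDisjointHalving:
    def test_halves_are_disjoint_and_floored(self):
        ds = LabeledDataset(
            np.arange(22.0).reshape(11, 2),
            ["+"] * 5 + ["-"] * 6,
            positive_label="+",
        )
        pair = disjoint_half_partition(ds, np.random.default_rng(0))
        assert not set(pair.d1.subject_ids) & set(pair.d2.subject_ids)
        assert pair.d1.class_counts().as_tuple() == (2, 3)
        assert pair.d2.class_counts().as_tuple() == (2, 3)

    def test_every_subject_eventually_sampled(self):
        ds = LabeledDataset(
            np.arange(18.0).reshape(9, 2),
            ["+"] * 5 + ["-"] * 4,
            positive_label="+",
        )
        seen = set()
        for rep in range(500):
            pair = disjoint_half_partition(ds, np.random.default_rng(rep))
            seen |= set(pair.d1.subject_ids) | set(pair.d2.subject_ids)
        assert seen == set(ds.subject_ids)

    def test_too_small_dataset_rejected(self):
        ds = _balanced_dataset(3)
        with pytest.raises(DatasetError):
            disjoint_half_partition(ds, np.random.default_rng(0))


class TestBootstrapPair:
    def test_class_counts_preserved(self):
        ds = LabeledDataset(
            np.arange(26.0).reshape(13, 2),
            ["+"] * 6 + ["-"] * 7,
            positive_label="+",
        )
        pair = bootstrap_pair(ds, np.random.default_rng(0))
        assert pair.d1.class_counts() == ds.class_counts()
        assert pair.d2.class_counts() == ds.class_counts()

    def test_distinct_coverage_matches_bootstrap_identity(self):
        # expected distinct fraction of an n-out-of-n resample:
        # 1 - (1 - 1/n)^n
        n = 40
        ds = _balanced_dataset(n)
        fracs = []
        for rep in range(300):
            pair = bootstrap_pair(ds, np.random.default_rng(rep))
            pos = [s for s in pair.d1.subject_ids if s in ds.subject_ids[:n]]
            fracs.append(len(set(pos)) / n)
        assert np.mean(fracs) == pytest.approx(1 - (1 - 1 / n) ** n, abs=0.02)


class TestEstimate:
    def test_stub_selecting_everything_gives_one(self, cfg):
        ds = _balanced_dataset(10)
        est = estimate(
            ds, cfg, "oRS", k=8, seed=1,
            selector=lambda d: BiomarkerSet(d.feature_ids),
        )
        assert est.per_iteration == (1.0,) * 8
        assert est.mean == 1.0
        assert est.sd == 0.0

    def test_stub_selecting_nothing_gives_zero(self, cfg):
        ds = _balanced_dataset(10)
        est = estimate(
            ds, cfg, "uRS", k=5, seed=1, selector=lambda d: BiomarkerSet()
        )
        assert est.mean == 0.0

    def test_bitwise_reproducible_under_seed(self, signal_dataset, cfg):
        for method in ("oRS", "uRS", "bRS"):
            a = estimate(signal_dataset, cfg, method, k=6, seed=123)
            b = estimate(signal_dataset, cfg, method, k=6, seed=123)
            assert a.per_iteration == b.per_iteration
            assert a.mean == b.mean

    def test_growing_k_extends_earlier_repetitions(self, signal_dataset, cfg):
        short = estimate(signal_dataset, cfg, "uRS", k=4, seed=9)
        long = estimate(signal_dataset, cfg, "uRS", k=8, seed=9)
        assert long.per_iteration[:4] == short.per_iteration

    def test_sd_is_sample_standard_deviation(self, signal_dataset, cfg):
        est = estimate(signal_dataset, cfg, "uRS", k=10, seed=2)
        assert est.sd == pytest.approx(
            np.std(est.per_iteration, ddof=1), abs=1e-15
        )

    def test_unknown_method_rejected(self, signal_dataset, cfg):
        with pytest.raises(ValueError):
            estimate(signal_dataset, cfg, "xRS", k=2, seed=0)

    def test_bootstrap_overlap_exceeds_doubling_under_null(self, cfg):
        # with no signal the doubling halves almost never agree on a
        # discovery while bootstrap duplication lets chance findings recur
        spec = SyntheticSpec(n_plus=50, n_minus=50, r=100, n_true=0, seed=21)
        ds = generate(spec)
        b = estimate(ds, cfg, "bRS", k=200, seed=4)
        o = estimate(ds, cfg, "oRS", k=200, seed=4)
        assert b.mean >= o.mean


class TestRsHat:
    def test_is_urs_under_a_different_tag(self, signal_dataset, cfg):
        hat = rs_hat_half(signal_dataset, cfg, k=6, seed=77)
        urs = estimate(signal_dataset, cfg, "uRS", k=6, seed=77)
        assert hat.method == "RS-hat"
        assert hat.per_iteration == urs.per_iteration

    def test_brackets_truth_for_half_sized_data_weak_signal(self, cfg):
        # the validation protocol: uRS on the full dataset estimates the
        # reproducibility of its half-sized subsets, which oRS/uRS computed
        # on a fixed half must bracket.  Checked in the weak-signal regime
        # (Jaccard well below saturation) where the bounds are reliable.
        u_half, hats, o_half = [], [], []
        for seed in range(1, 7):
            spec = SyntheticSpec(
                n_plus=100, n_minus=100, r=200, n_true=20, effect=0.5,
                seed=seed,
            )
            ds = generate(spec)
            hats.append(rs_hat_half(ds, cfg, k=50, seed=seed).mean)
            idx = np.concatenate(
                [
                    np.flatnonzero(ds.positive_mask)[:50],
                    np.flatnonzero(~ds.positive_mask)[:50],
                ]
            )
            half = ds.take(idx)
            u_half.append(estimate(half, cfg, "uRS", k=50, seed=seed).mean)
            o_half.append(estimate(half, cfg, "oRS", k=50, seed=seed).mean)
        assert np.mean(u_half) <= np.mean(hats) <= np.mean(o_half)


class TestSubsetCurve:
    def test_quota_and_disjointness(self, signal_dataset, cfg):
        pts = subset_curve(
            signal_dataset, cfg, sizes=[20, 50], k=3, seed=5,
            selector=lambda d: BiomarkerSet(),
        )
        assert [p.subset_size for p in pts] == [20, 50]
        assert all(p.k == 3 for p in pts)

    def test_infeasible_sizes_skipped_with_warning(self, signal_dataset, cfg):
        with pytest.warns(UserWarning, match="infeasible"):
            pts = subset_curve(
                signal_dataset, cfg, sizes=[2, 40], k=2, seed=5,
                selector=lambda d: BiomarkerSet(),
            )
        assert [p.subset_size for p in pts] == [40]

    def test_rises_with_subset_size_on_strong_signal(self, cfg):
        spec = SyntheticSpec(
            n_plus=100, n_minus=100, r=100, n_true=20, effect=1.0, seed=13
        )
        ds = generate(spec)
        pts = subset_curve(ds, cfg, sizes=[20, 50, 100], k=10, seed=13)
        means = [p.mean for p in pts]
        assert means[0] <= means[1] + 0.05
        assert means[1] <= means[2] + 0.05
        assert means[2] > means[0]


class TestRsStar:
    def test_saturating_effect_reaches_one(self, cfg):
        spec = SyntheticSpec(
            n_plus=60, n_minus=60, r=30, n_true=5, effect=5.0, seed=1
        )
        est = rs_star_monte_carlo(spec, cfg, k=30, seed=1)
        assert est.mean > 0.9

    def test_zero_effect_near_zero(self, cfg):
        spec = SyntheticSpec(n_plus=30, n_minus=30, r=40, n_true=0, seed=2)
        est = rs_star_monte_carlo(spec, cfg, k=100, seed=2)
        assert est.mean < 0.05

    def test_reproducible(self, cfg):
        spec = SyntheticSpec(
            n_plus=30, n_minus=30, r=40, n_true=5, effect=1.0, seed=3
        )
        a = rs_star_monte_carlo(spec, cfg, k=10, seed=3)
        b = rs_star_monte_carlo(spec, cfg, k=10, seed=3)
        assert a.per_iteration == b.per_iteration
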