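"""Cohort association statistics: FD-FC, group contrasts, FDR, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neomotion import (
    DegenerateDataError,
    InvalidConfigError,
    ValidationError,
    censor_distance_shift,
    distance_dependence,
    edgewise_fd_association,
    fd_fc_association,
    fdr_bh,
    group_contrast,
    make_confounded_table,
    partial_corr,
    pma_association,
    split_by_motion,
    strength_comparison,
    within_group_map,
)
from neomotion.association import fc_column, fd_column


def make_table(fd, fc, network="net", condition="none", pma=None):
    n = len(fd)
    data = {
        "scan_id": [f"s{i:03d}" for i in range(n)],
        fd_column(condition): fd,
        fc_column(network, condition): fc,
    }
    if pma is not None:
        data["pma_weeks"] = pma
    return pd.DataFrame(data)


class TestFdFcAssociation:
    def test_perfect_linearity(self):
        fd = np.linspace(0.01, 0.5, 10)
        res = fd_fc_association(make_table(fd, 2 * fd + 1), "net", "none")
        assert res.r == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self):
        fd = np.array([0.1, 0.2, 0.15, 0.4, 0.05])
        fc = np.array([0.5, 0.3, 0.6, 0.2, 0.7])
        res = fd_fc_association(make_table(fd, fc), "net", "none")
        num = ((fd - fd.mean()) * (fc - fc.mean())).sum()
        den = np.sqrt(((fd - fd.mean()) ** 2).sum() * ((fc - fc.mean()) ** 2).sum())
        assert res.r == pytest.approx(num / den, abs=1e-12)
        assert res.n == 5

    def test_permutation_null_is_uniform(self, rng):
        """Shuffling FD against FC makes p uniform: the rejection rate at .05
        over 1000 permutations stays within the binomial 99% band."""
        fd = rng.gamma(1.0, 0.13, size=40)
        fc = rng.normal(size=40)
        rejections = 0
        for _ in range(1000):
            perm = rng.permutation(fd)
            res = fd_fc_association(make_table(perm, fc), "net", "none")
            rejections += res.p < 0.05
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rejections / 1000 - 0.05) < 2.58 * se

    def test_constant_variable_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fd_fc_association(make_table(np.ones(5), np.arange(5.0)), "net", "none")

    def test_too_few_scans(self):
        with pytest.raises(ValidationError):
            fd_fc_association(make_table(np.arange(3.0), np.arange(3.0)), "net", "none")


class TestEdgewise:
    def test_edge_count_for_90_rois(self, rng):
        stack = rng.normal(size=(10, 4005))
        res = edgewise_fd_association(stack, rng.random(10))
        assert res.n_edges == 4005

    def test_null_fraction_near_alpha(self, rng):
        stack = rng.normal(size=(40, 500))
        fd = rng.gamma(1.0, 0.13, size=40)
        res = edgewise_fd_association(stack, fd, alpha=0.05)
        se = np.sqrt(0.05 * 0.95 / 500)
        assert abs(res.significant_fraction - 0.05) < 3 * se

    def test_matches_pearsonr_per_edge(self, rng):
        stack = rng.normal(size=(12, 8))
        fd = rng.random(12)
        res = edgewise_fd_association(stack, fd)
        for e in range(8):
            r, p = stats.pearsonr(fd, stack[:, e])
            assert res.r[e] == pytest.approx(r, abs=1e-12)
            assert res.p[e] == pytest.approx(p, abs=1e-12)


class TestSplitByMotion:
    def test_149_scans_quartile_gives_37(self):
        fd = np.random.default_rng(0).random(149)
        low, high = split_by_motion(make_table(fd, fd), "none", 0.25)
        assert len(low) == 37 and len(high) == 37
        assert not set(low) & set(high)

    def test_extremes_selected(self):
        fd = np.array([0.9, 0.1, 0.8, 0.2, 0.7, 0.3, 0.6, 0.4])
        low, high = split_by_motion(make_table(fd, fd), "none", 0.25)
        assert low == ["s001", "s003"]
        assert set(high) == {"s000", "s002"}

    def test_ties_broken_deterministically(self):
        fd = np.ones(8)
        low1, high1 = split_by_motion(make_table(fd, fd), "none", 0.25)
        low2, high2 = split_by_motion(make_table(fd, fd), "none", 0.25)
        assert low1 == low2 and high1 == high2
        assert not set(low1) & set(high1)

    def test_bad_fraction_rejected(self):
        fd = np.arange(10.0)
        with pytest.raises(InvalidConfigError):
            split_by_motion(make_table(fd, fd), "none", 0.75)


class TestGroupContrast:
    def test_identical_groups_nothing_significant(self, rng):
        maps = rng.normal(size=(5, 20))
        gc = group_contrast(maps, maps.copy())
        assert gc.n_sig_unc == 0 and gc.n_sig_fdr == 0

    def test_null_uncorrected_rate_near_alpha(self, rng):
        """Two groups from the same distribution: ~1% of units exceed the
        uncorrected .01 threshold (Monte-Carlo band over 3000 units)."""
        hits, total = 0, 0
        for _ in range(30):
            lo = rng.normal(size=(10, 100))
            hi = rng.normal(size=(10, 100))
            gc = group_contrast(lo, hi, alpha_unc=0.01)
            hits += gc.n_sig_unc
            total += gc.n_valid
        se = np.sqrt(0.01 * 0.99 / total)
        assert abs(hits / total - 0.01) < 3 * se

    def test_three_vs_three_matches_closed_form(self):
        lo = np.array([[0.1], [0.2], [0.3]])
        hi = np.array([[0.5], [0.6], [0.9]])
        gc = group_contrast(lo, hi)
        n1 = n2 = 3
        m1, m2 = hi.mean(), lo.mean()
        sp2 = (hi.var(ddof=1) * (n1 - 1) + lo.var(ddof=1) * (n2 - 1)) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), df=4)
        assert gc.t[0] == pytest.approx(t, abs=1e-12)
        assert gc.p[0] == pytest.approx(p, abs=1e-12)
        assert gc.delta_z[0] == pytest.approx(m1 - m2, abs=1e-12)

    def test_zero_variance_unit_excluded(self, rng):
        lo = np.column_stack([np.ones(4), rng.normal(size=4)])
        hi = np.column_stack([np.ones(4), rng.normal(size=4)])
        gc = group_contrast(lo, hi)
        assert gc.excluded[0] and not gc.excluded[1]
        assert gc.n_valid == 1


class TestWithinGroupMap:
    def test_all_zero_maps_empty_mask(self):
        out = within_group_map(np.zeros((5, 10)))
        assert not out["mask"].any()

    def test_strong_offset_detected(self, rng):
        maps = rng.normal(size=(10, 5)) * 0.1
        maps[:, 2] += 5.0
        out = within_group_map(maps)
        assert out["mask"][2]

    def test_fdr_calibration_on_null_units(self, rng):
        """With mixed null and strong-signal units the realized false
        discovery proportion stays at or below q in expectation."""
        fdp = []
        for _ in range(200):
            maps = rng.normal(size=(12, 50))
            maps[:, :10] += 3.0  # 10 real effects, 40 nulls
            out = within_group_map(maps, fdr_q=0.05)
            rejected = np.flatnonzero(out["mask"])
            if rejected.size:
                fdp.append((rejected >= 10).sum() / rejected.size)
            else:
                fdp.append(0.0)
        assert np.mean(fdp) <= 0.05


class TestStrengthComparison:
    def test_identical_sets_f_zero(self, rng):
        vals = rng.normal(size=30)
        out = strength_comparison({"a": vals, "b": vals.copy(), "c": vals.copy()})
        assert out["F"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=20), rng.normal(0.5, 1, size=25)
        out = strength_comparison({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b)
        assert out["F"] == pytest.approx(t**2, rel=1e-10)
        assert out["df"] == (1, 43)

    def test_matches_textbook_anova(self, rng):
        groups = {k: rng.normal(i * 0.3, 1, size=15) for i, k in enumerate("abc")}
        out = strength_comparison(groups)
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(15 * (g.mean() - grand) ** 2 for g in groups.values())
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        f = (ssb / 2) / (ssw / (45 - 3))
        assert out["F"] == pytest.approx(f, rel=1e-10)
        assert len(out["posthoc"]) == 3


class TestDistance:
    def test_hand_built_four_roi_case(self):
        z = np.array(
            [
                [np.nan, 0.8, 0.3, 0.2],
                [0.8, np.nan, 0.25, 0.15],
                [0.3, 0.25, np.nan, 0.6],
                [0.2, 0.15, 0.6, np.nan],
            ]
        )
        d = np.array(
            [
                [0.0, 10, 40, 50],
                [10, 0.0, 35, 45],
                [40, 35, 0.0, 12],
                [50, 45, 12, 0.0],
            ],
            dtype=float,
        )
        res = distance_dependence(z, d)
        iu = np.triu_indices(4, 1)
        r, p = stats.pearsonr(d[iu], z[iu])
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.n == 6

    def test_identical_matrices_shift_degenerate(self, rng):
        z = rng.normal(size=(5, 5))
        z = (z + z.T) / 2
        d = np.abs(rng.normal(size=(5, 5)))
        res = censor_distance_shift(z, z.copy(), d)
        assert res.degenerate
        assert np.isnan(res.r)


class TestPmaBootstrap:
    def test_determinism_under_fixed_seed(self):
        table = make_confounded_table(60, 0.03, 1.0, seed=5)
        a = pma_association(table, "synthetic", "none", n_boot=50, seed=9)
        b = pma_association(table, "synthetic", "none", n_boot=50, seed=9)
        np.testing.assert_array_equal(a.simple_z, b.simple_z)
        np.testing.assert_array_equal(a.partial_z, b.partial_z)
        assert a.n_boot == 50 and a.simple_z.size == 50

    def test_partial_equals_simple_without_confound(self):
        """With the FD effect at zero, partialling FD changes nothing:
        |mean partial - mean simple| <= 0.02 at n=200."""
        table = make_confounded_table(200, 0.03, 0.0, seed=3)
        res = pma_association(table, "synthetic", "none", n_boot=400, seed=11)
        assert abs(res.mean_partial - res.mean_simple) <= 0.02

    def test_partial_beats_simple_under_confound(self):
        """With a real FD effect on strength, removing FD variance brings the
        PMA association closer to the confound-free value."""
        wins = 0
        for seed in range(10):
            table = make_confounded_table(200, 0.03, 1.0, seed=seed)
            res = pma_association(
                table, "synthetic", "none", n_boot=200, seed=seed
            )
            wins += res.mean_partial > res.mean_simple
        assert wins >= 9

    def test_partial_corr_matches_closed_form(self, rng):
        x, y, z = rng.normal(size=(3, 100))
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        want = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert partial_corr(x, y, z) == pytest.approx(want, abs=1e-12)

    def test_small_subset_rejected(self):
        table = make_confounded_table(12, 0.03, 1.0, seed=0)
        with pytest.raises(ValidationError):
            pma_association(table, "synthetic", "none", subset_frac=0.25, n_boot=5)


class TestFdrBH:
    def bh_oracle(self, p, q):
        """Hand-coded Benjamini-Hochberg step-up."""
        m = len(p)
        order = np.argsort(p)
        thresh = q * (np.arange(1, m + 1)) / m
        below = np.flatnonzero(np.array(p)[order] <= thresh)
        mask = np.zeros(m, dtype=bool)
        if below.size:
            mask[order[: below[-1] + 1]] = True
        return mask

    def test_hand_example(self):
        mask, _ = fdr_bh(np.array([0.001, 0.5, 0.9]), q=0.05)
        assert mask.tolist() == [True, False, False]

    def test_all_ones_rejects_nothing(self):
        mask, _ = fdr_bh(np.ones(10), q=0.05)
        assert not mask.any()

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(3, 60)))
            mask, q = fdr_bh(p, q=0.05)
            np.testing.assert_array_equal(mask, self.bh_oracle(p, 0.05))
            assert np.all((q >= 0) & (q <= 1))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh(np.array([0.5, 1.2]))
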