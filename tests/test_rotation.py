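"""Best-match rotation, coherency ranking and circular statistics."""
from itertools import combinations

import numpy as np
import pytest

from reomap.errors import DomainError
from reomap.rate_maps import RateMap
from reomap.rotation import (ROTATION_ANGLES, BMRRecord, best_match_rotation,
                             bmr_proportions, bmr_records_for_cell,
                             center_out_differences, coherency_per_trial_pair,
                             double_angles, joint_bmr_distribution,
                             rotate_square)


def _square(grid, mask=None):
    grid = np.asarray(grid, float)
    assert grid.shape == (20, 20)
    mask = np.ones_like(grid, bool) if mask is None else mask
    return RateMap(rate=np.where(mask, grid, np.nan),
                   occupancy=np.where(mask, 1.0, 0.0), sampled_mask=mask,
                   bin_x_cm=1.0, bin_y_cm=1.5, sigma_cm=0.0)


def _random_square(rng):
    return _square(rng.uniform(0, 5, size=(20, 20)))


class TestBestMatchRotation:
    def test_map_vs_itself(self, rng):
        m = _random_square(rng)
        rec = best_match_rotation(m, m)
        assert rec.best_angle == 0
        assert rec.best_correlation == pytest.approx(1.0)

    def test_constructed_180_rotation(self, rng):
        m = _random_square(rng)
        r180 = _square(np.rot90(np.where(m.sampled_mask, m.rate, 0), 2))
        rec = best_match_rotation(m, r180)
        # rotating m by 180 reproduces r180 exactly
        assert rec.best_angle == 180
        assert rec.best_correlation == pytest.approx(1.0)

    def test_toy_maps_match_bruteforce_enumeration(self, rng):
        a, b = _random_square(rng), _random_square(rng)
        rec = best_match_rotation(a, b)
        ga = np.where(a.sampled_mask, a.rate, 0)
        gb = np.where(b.sampled_mask, b.rate, 0)
        for ang in ROTATION_ANGLES:
            expect = np.corrcoef(np.rot90(ga, ang // 90).ravel(), gb.ravel())[0, 1]
            assert rec.correlations[ang] == pytest.approx(expect, abs=1e-12)
        best = max(rec.correlations.values())
        assert rec.best_correlation == best

    def test_symmetry_of_pair_order(self, rng):
        a, b = _random_square(rng), _random_square(rng)
        fwd = best_match_rotation(a, b)
        rev = best_match_rotation(b, a)
        assert rev.best_angle == (360 - fwd.best_angle) % 360
        assert rev.best_correlation == pytest.approx(fwd.best_correlation)

    def test_tie_breaks_to_smaller_angle(self):
        # radially symmetric map: all four rotations correlate perfectly
        yy, xx = np.mgrid[0:20, 0:20]
        sym = _square(np.hypot(yy - 9.5, xx - 9.5))
        rec = best_match_rotation(sym, sym)
        assert all(rec.correlations[a] == pytest.approx(1.0)
                   for a in ROTATION_ANGLES)
        assert rec.best_angle == 0

    def test_insufficient_overlap_flagged_undefined(self, rng):
        mask = np.zeros((20, 20), bool)
        mask[:3, :3] = True  # 9 < 20 joint pixels at every rotation
        a = _square(rng.uniform(size=(20, 20)), mask.copy())
        b = _square(rng.uniform(size=(20, 20)), mask.copy())
        rec = best_match_rotation(a, b)
        assert not rec.defined

    def test_zero_variance_map_undefined(self, rng):
        rec = best_match_rotation(_square(np.ones((20, 20))), _random_square(rng))
        assert not rec.defined

    def test_non_square_rejected(self, rng, day1_tables):
        cid = day1_tables.cell_ids[0]
        with pytest.raises(DomainError):
            best_match_rotation(day1_tables.native_maps[cid][0],
                                day1_tables.native_maps[cid][1])


class TestBMRProportions:
    def test_twelve_trials_give_66_pairs(self, rng):
        maps = {t: _random_square(rng) for t in range(12)}
        recs = bmr_records_for_cell(maps, cell_id=0)
        assert len(recs) == 66
        per_cell, _ = bmr_proportions(recs)
        assert per_cell.iloc[0]["n_pairs"] == 66

    def test_all_zero_degree_pairs(self, rng):
        m = _random_square(rng)
        recs = bmr_records_for_cell({t: m for t in range(4)}, cell_id=1)
        per_cell, per_animal = bmr_proportions(recs)
        assert per_cell.iloc[0]["p0"] == 1.0
        assert per_animal.iloc[0][["p90", "p180", "p270"]].sum() == 0.0

    def test_shares_sum_to_one(self, rng):
        maps = {t: _random_square(rng) for t in range(6)}
        per_cell, _ = bmr_proportions(bmr_records_for_cell(maps, 0))
        assert per_cell[["p0", "p90", "p180", "p270"]].sum(axis=1).iloc[0] == \
            pytest.approx(1.0)

    def test_coherent_ensemble_mass_on_geometric_axis(self, clean_tables,
                                                      clean_bundle):
        # coherence 1: every BMR is the orientation difference, 0 or 180
        from reomap.session import session_bmr_records
        recs = session_bmr_records(clean_tables)
        gt = clean_bundle.ground_truth
        fi = set(gt.cells.query("cell_class == 'FI'")["cell_id"])
        per_cell, _ = bmr_proportions([r for r in recs if r.cell_id in fi])
        share_axis = per_cell["p0"] + per_cell["p180"]
        assert (share_axis > 0.95).all()


class TestCenterOut:
    def test_identical_angles_yield_zero_differences(self):
        d = center_out_differences({t: 40.0 for t in range(5)})
        assert np.all(d == 0.0)

    def test_alternating_bimodal_construction(self):
        angles = {t: 10.0 if t % 2 == 0 else 190.0 for t in range(6)}
        d = center_out_differences(angles)
        assert set(np.round(d)) <= {0.0, 180.0}

    def test_uniform_angles_yield_uniform_differences(self):
        rng = np.random.default_rng(12)
        angles = {t: rng.uniform(0, 360) for t in range(150)}
        d = center_out_differences(angles)
        from scipy.stats import kstest
        assert kstest(d / 360.0, "uniform").pvalue > 0.01

    def test_fewer_than_two_defined_angles(self):
        assert center_out_differences({0: None, 1: 30.0}).size == 0


class TestDoubleAngles:
    def test_axial_pair_becomes_unimodal(self):
        doubled, rbar = double_angles([10.0, 190.0])
        assert np.allclose(doubled, [20.0, 20.0])
        assert rbar == pytest.approx(1.0)

    def test_four_quarters_cancel(self):
        doubled, rbar = double_angles([0.0, 90.0, 180.0, 270.0])
        assert np.allclose(sorted(doubled), [0.0, 0.0, 180.0, 180.0])
        assert rbar == pytest.approx(0.0, abs=1e-12)

    def test_uniform_resultant_shrinks(self):
        rng = np.random.default_rng(1)
        _, r_small = double_angles(rng.uniform(0, 360, 20))
        _, r_large = double_angles(rng.uniform(0, 360, 20000))
        assert r_large < 0.05 < 1.0
        assert 0.0 <= r_small <= 1.0


def _rec(cell, pair, angle):
    return BMRRecord(cell_id=cell, trial_pair=pair, best_angle=angle,
                     best_correlation=0.9,
                     correlations={a: 0.0 for a in ROTATION_ANGLES})


class TestCoherency:
    def test_unanimous_agreement(self):
        recs = [_rec(c, (0, 1), 180) for c in range(7)]
        row = coherency_per_trial_pair(recs, (0, 1))
        assert row.ranked_shares == (1.0, 0.0, 0.0, 0.0)
        assert row.first_bmr == 180

    def test_ranking_matches_constructed_shares(self):
        angles = [0] * 10 + [90] * 6 + [180] * 3 + [270] * 1
        recs = [_rec(c, (2, 5), a) for c, a in enumerate(angles)]
        row = coherency_per_trial_pair(recs, (2, 5))
        assert row.ranked_shares == (0.5, 0.3, 0.15, 0.05)
        assert row.ranked_angles == (0, 90, 180, 270)
        assert sum(row.ranked_shares) == pytest.approx(1.0)
        assert np.all(np.diff(row.ranked_shares) <= 0)

    def test_uniform_random_shares_near_chance(self):
        rng = np.random.default_rng(9)
        shares = []
        for p in range(300):
            recs = [_rec(c, (0, 1), ROTATION_ANGLES[rng.integers(4)])
                    for c in range(40)]
            shares.append(coherency_per_trial_pair(recs, (0, 1)).shares[0])
        assert np.mean(shares) == pytest.approx(0.25, abs=0.02)

    def test_excluded_cells_and_empty_pair(self):
        recs = [_rec(c, (0, 1), 0) for c in range(4)]
        row = coherency_per_trial_pair(recs, (0, 1), included_cells={1, 2})
        assert row.n_cells_included == 2
        assert coherency_per_trial_pair(recs, (0, 1), included_cells=set()) is None


class TestJointBMR:
    def test_single_mass_cell(self):
        rows = [coherency_per_trial_pair(
            [_rec(c, (i, j), 180 if c < 8 else 0) for c in range(10)], (i, j))
            for i, j in combinations(range(4), 2)]
        joint, marginal = joint_bmr_distribution(rows)
        assert joint[2, 0] == pytest.approx(1.0)   # (180, 0) cell
        assert marginal[2] == pytest.approx(1.0)

    def test_uniform_first_second_never_coincide(self):
        rng = np.random.default_rng(4)
        rows = []
        for k in range(500):
            angles = [ROTATION_ANGLES[rng.integers(4)] for _ in range(9)]
            rows.append(coherency_per_trial_pair(
                [_rec(c, (0, k + 1), a) for c, a in enumerate(angles)],
                (0, k + 1)))
        joint, _ = joint_bmr_distribution(rows)
        assert np.all(np.diag(joint) == 0.0)
        assert joint.sum() == pytest.approx(1.0)
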