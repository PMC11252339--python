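"""Best-match rotation (BMR) statistics and ensemble coherency.

For every cell and ordered trial pair (i < j), the square-compressed map of
trial i is rotated by quarter turns (0, 90, 180, 270 deg) and Pearson
correlation to the trial-j map is computed over pixels sampled in both; the
angle maximizing the correlation is the BMR.  Ties break toward the smaller
angle; comparisons with fewer than ``MIN_OVERLAP_PIXELS`` jointly sampled
pixels, or a zero-variance map, are flagged undefined.

Ensemble coherency for a trial pair is the share of simultaneously recorded
cells agreeing on each rotation, ranked 1st (largest) through 4th; with
independent rotations every share is expected at chance = 25%.  Cells that
were inactive in either trial of the pair are excluded.

Center-out angle differences provide a compression-free validation of BMR;
angle doubling (theta -> 2*theta mod 360) maps the geometric {0, 180}
bimodality onto a unimodal distribution whose mean resultant length can be
tested for circular uniformity.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .rate_maps import RateMap, masked_pearson

ROTATION_ANGLES = (0, 90, 180, 270)
MIN_OVERLAP_PIXELS = 20
CHANCE_SHARE = 0.25


@dataclass
class BMRRecord:
    """Best-match rotation between one cell's maps on one trial pair."""

    cell_id: int
    trial_pair: tuple[int, int]
    best_angle: int | None
    best_correlation: float
    correlations: dict[int, float]

    @property
    def defined(self) -> bool:
        return self.best_angle is not None


def rotate_square(grid: np.ndarray, angle: int) -> np.ndarray:
    """Quarter-turn (counterclockwise) of a square grid; masks rotate with
    data by calling this on both."""
    if angle not in ROTATION_ANGLES:
        raise DomainError(f"angle must be one of {ROTATION_ANGLES}")
    return np.rot90(grid, angle // 90)


def best_match_rotation(a: RateMap, b: RateMap,
                        min_overlap: int = MIN_OVERLAP_PIXELS,
                        cell_id: int = -1,
                        trial_pair: tuple[int, int] = (-1, -1)) -> BMRRecord:
    """The rotation of map ``a`` maximizing pixel-to-pixel correlation to ``b``."""
    if not (a.is_square and b.is_square):
        raise DomainError("best-match rotation requires 20x20 square maps")
    corrs: dict[int, float] = {}
    for ang in ROTATION_ANGLES:
        ra = rotate_square(np.where(a.sampled_mask, a.rate, 0.0), ang)
        rm = rotate_square(a.sampled_mask, ang)
        r, _ = masked_pearson(ra, np.where(b.sampled_mask, b.rate, 0.0),
                              rm, b.sampled_mask, min_overlap=min_overlap)
        corrs[ang] = r
    valid = [(ang, r) for ang, r in corrs.items() if np.isfinite(r)]
    if not valid:
        return BMRRecord(cell_id, trial_pair, None, float("nan"), corrs)
    best_r = max(r for _, r in valid)
    best_angle = min(ang for ang, r in valid if r == best_r)  # tie -> smaller angle
    return BMRRecord(cell_id, trial_pair, best_angle, best_r, corrs)


def bmr_records_for_cell(square_maps: Mapping[int, RateMap], cell_id: int,
                         min_overlap: int = MIN_OVERLAP_PIXELS) -> list[BMRRecord]:
    """All pairwise BMRs over a cell's per-trial square maps
    (66 pairs for a 12-trial session)."""
    trial_ids = sorted(square_maps)
    return [
        best_match_rotation(square_maps[i], square_maps[j], min_overlap,
                            cell_id=cell_id, trial_pair=(i, j))
        for i, j in combinations(trial_ids, 2)
    ]


def bmr_proportions(records: Iterable[BMRRecord],
                    trial_subset: set[int] | None = None,
                    animal_of_cell: Mapping[int, int] | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Share of pairwise comparisons won by each rotation.

    Returns (per_cell, per_animal) tables; per-cell shares are over that
    cell's defined pairs and sum to 1; the animal level averages its cells
    with equal weight.  Cells with no valid pair are excluded.
    """
    by_cell: dict[int, list[BMRRecord]] = {}
    for rec in records:
        if trial_subset is not None and not set(rec.trial_pair) <= trial_subset:
            continue
        if rec.defined:
            by_cell.setdefault(rec.cell_id, []).append(rec)
    rows = []
    for cid, recs in sorted(by_cell.items()):
        angles = np.array([r.best_angle for r in recs])
        row = {"cell_id": cid, "n_pairs": len(recs)}
        for ang in ROTATION_ANGLES:
            row[f"p{ang}"] = float(np.mean(angles == ang))
        rows.append(row)
    per_cell = pd.DataFrame(rows)
    if per_cell.empty:
        return per_cell, pd.DataFrame()
    if animal_of_cell is not None:
        per_cell["animal"] = per_cell["cell_id"].map(animal_of_cell)
    else:
        per_cell["animal"] = 0
    cols = [f"p{ang}" for ang in ROTATION_ANGLES]
    per_animal = per_cell.groupby("animal")[cols].mean().reset_index()
    return per_cell, per_animal


def center_out_differences(angles_by_trial: Mapping[int, float | None]
                           ) -> np.ndarray:
    """Circular pairwise differences of a cell's per-trial center-out angles,
    wrapped to [0, 360).  Trials with undefined angle are dropped; fewer
    than two defined angles leave nothing to compare."""
    defined = [(t, a) for t, a in sorted(angles_by_trial.items()) if a is not None]
    if len(defined) < 2:
        return np.array([])
    diffs = [ (aj - ai) % 360.0 for (_, ai), (_, aj) in combinations(defined, 2)]
    return np.asarray(diffs)


def angle_histogram(angles_deg: np.ndarray, bin_width_deg: float = 20.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Polar histogram counts over [0, 360) with the given bin width."""
    edges = np.arange(0.0, 360.0 + bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(np.mod(angles_deg, 360.0), bins=edges)
    return counts, edges


def double_angles(angles_deg: Sequence[float]) -> tuple[np.ndarray, float]:
    """Angle doubling for axial data: (2*theta) mod 360, plus the mean
    resultant length r of the doubled angles (1 = perfectly axial,
    0 = uniform)."""
    arr = np.asarray(list(angles_deg), dtype=float)
    if arr.size == 0:
        raise DomainError("need at least one angle")
    doubled = np.mod(2.0 * arr, 360.0)
    z = np.exp(1j * np.deg2rad(doubled))
    return doubled, float(np.abs(z.mean()))


@dataclass
class CoherencyRow:
    """Per-trial-pair rotation agreement across simultaneously recorded cells."""

    trial_pair: tuple[int, int]
    shares: dict[int, float]           # angle -> share of included cells
    ranked_shares: tuple[float, float, float, float]
    ranked_angles: tuple[int, int, int, int]
    n_cells_included: int
    comparison: str = ""               # "within" or "across" context

    @property
    def first_bmr(self) -> int:
        return self.ranked_angles[0]

    @property
    def second_bmr(self) -> int:
        return self.ranked_angles[1]


def coherency_per_trial_pair(records: Iterable[BMRRecord],
                             pair: tuple[int, int],
                             included_cells: set[int] | None = None,
                             comparison: str = "") -> CoherencyRow | None:
    """Rank rotation agreement for one trial pair.

    ``included_cells`` should already exclude cells inactive in either trial
    of the pair; undefined BMR records are dropped too.  Returns None (pair
    dropped) when no cell remains.  Rank ties break toward the smaller angle
    so 1st/2nd BMR are deterministic.
    """
    angles = [r.best_angle for r in records
              if r.trial_pair == pair and r.defined
              and (included_cells is None or r.cell_id in included_cells)]
    if not angles:
        return None
    arr = np.array(angles)
    shares = {ang: float(np.mean(arr == ang)) for ang in ROTATION_ANGLES}
    order = sorted(ROTATION_ANGLES, key=lambda a: (-shares[a], a))
    return CoherencyRow(
        trial_pair=pair,
        shares=shares,
        ranked_shares=tuple(shares[a] for a in order),
        ranked_angles=tuple(order),
        n_cells_included=len(angles),
        comparison=comparison,
    )


def coherency_table(rows: Iterable[CoherencyRow]) -> pd.DataFrame:
    out = []
    for r in rows:
        if r is None:
            continue
        rec = {"trial_i": r.trial_pair[0], "trial_j": r.trial_pair[1],
               "comparison": r.comparison, "n_cells": r.n_cells_included,
               "first_bmr": r.first_bmr, "second_bmr": r.second_bmr}
        for k, (s, a) in enumerate(zip(r.ranked_shares, r.ranked_angles), 1):
            rec[f"share_rank{k}"] = s
            rec[f"angle_rank{k}"] = a
        out.append(rec)
    return pd.DataFrame(out)


def joint_bmr_distribution(rows: Sequence[CoherencyRow | None],
                           animal_of_pair: Mapping[tuple[int, int], int] | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """4x4 joint probability of (1st BMR angle, 2nd BMR angle) over trial
    pairs, averaged per animal and then across animals.

    Returns (joint, marginal_first); rows index the 1st BMR angle and
    columns the 2nd, in the order 0/90/180/270.
    """
    idx = {ang: k for k, ang in enumerate(ROTATION_ANGLES)}
    per_animal: dict[int, list[np.ndarray]] = {}
    for r in rows:
        if r is None:
            continue
        m = np.zeros((4, 4))
        m[idx[r.first_bmr], idx[r.second_bmr]] = 1.0
        animal = animal_of_pair.get(r.trial_pair, 0) if animal_of_pair else 0
        per_animal.setdefault(animal, []).append(m)
    if not per_animal:
        raise DomainError("no defined coherency rows")
    mats = [np.mean(ms, axis=0) for ms in per_animal.values()]
    joint = np.mean(mats, axis=0)
    return joint, joint.sum(axis=1)
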