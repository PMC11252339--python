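"""Rate remapping: absolute mean-rate difference matrices across trials.

For each cell, the 12 x 12 matrix |r_i - r_j| of per-trial mean firing
rates is split into within-context pairs (A-A and B-B pooled) and
across-context pairs (A-B); their means quantify how much the cell's rate
code distinguishes the two contexts.  Per-animal heatmaps are cellwise mean
matrices.  No normalization by pooled rate is applied — the statistic is
the absolute difference.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError


@dataclass
class RateDifferenceMatrix:
    """Symmetric |rate_i - rate_j| matrix for one cell, with context labels."""

    cell_id: int
    trial_ids: list[int]
    matrix: np.ndarray                 # NaN rows/cols for undefined trials
    contexts: list[str]
    defined: np.ndarray                # per-trial rate defined

    @property
    def within_mask(self) -> np.ndarray:
        ctx = np.asarray(self.contexts)
        same = ctx[:, None] == ctx[None, :]
        return self._offdiag(same)

    @property
    def across_mask(self) -> np.ndarray:
        ctx = np.asarray(self.contexts)
        return self._offdiag(ctx[:, None] != ctx[None, :])

    def _offdiag(self, m: np.ndarray) -> np.ndarray:
        out = m & self.defined[:, None] & self.defined[None, :]
        np.fill_diagonal(out, False)
        return out


def rate_difference_matrix(
    cell_rates: Mapping[int, float | None],
    contexts: Mapping[int, str],
    cell_id: int = -1,
) -> RateDifferenceMatrix:
    """Pairwise absolute mean-rate differences for one cell.

    Trials with undefined rates are masked out of their whole row and
    column; fewer than two defined trials is an error (the caller excludes
    the cell and logs it)."""
    trial_ids = sorted(contexts)
    rates = np.array([np.nan if cell_rates.get(t) is None else cell_rates[t]
                      for t in trial_ids], dtype=float)
    defined = np.isfinite(rates)
    if defined.sum() < 2:
        raise DomainError(f"cell {cell_id}: fewer than 2 trials with defined rates")
    mat = np.abs(rates[:, None] - rates[None, :])
    return RateDifferenceMatrix(
        cell_id=cell_id,
        trial_ids=trial_ids,
        matrix=mat,
        contexts=[contexts[t] for t in trial_ids],
        defined=defined,
    )


def within_across_summary(rdm: RateDifferenceMatrix) -> tuple[float, float]:
    """(mean within-context, mean across-context) absolute rate difference.

    Within pools the A-A and B-B pairs; an empty mask yields NaN for that
    component (flagged, not zero)."""
    w = rdm.within_mask
    a = rdm.across_mask
    mean_w = float(np.mean(rdm.matrix[w])) if w.any() else float("nan")
    mean_a = float(np.mean(rdm.matrix[a])) if a.any() else float("nan")
    return mean_w, mean_a


def summary_table(
    rates_by_cell: Mapping[int, Mapping[int, float | None]],
    contexts: Mapping[int, str],
) -> pd.DataFrame:
    """Per-cell within/across rate-difference summary; cells with fewer than
    two defined trials are excluded (with a row in the exclusion log)."""
    rows, excluded = [], []
    for cid in sorted(rates_by_cell):
        try:
            rdm = rate_difference_matrix(rates_by_cell[cid], contexts, cell_id=cid)
        except DomainError:
            excluded.append(cid)
            continue
        w, a = within_across_summary(rdm)
        rows.append({"cell_id": cid, "mean_within": w, "mean_across": a,
                     "gap": a - w})
    df = pd.DataFrame(rows)
    df.attrs["excluded_cells"] = excluded
    return df


def animal_mean_matrix(
    rates_by_cell: Mapping[int, Mapping[int, float | None]],
    contexts: Mapping[int, str],
) -> np.ndarray:
    """Cellwise mean rate-difference matrix (the per-animal heatmap)."""
    mats = []
    for cid in sorted(rates_by_cell):
        try:
            mats.append(rate_difference_matrix(rates_by_cell[cid], contexts,
                                               cell_id=cid).matrix)
        except DomainError:
            continue
    if not mats:
        raise DomainError("no cell with enough defined trials")
    return np.nanmean(np.stack(mats), axis=0)
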