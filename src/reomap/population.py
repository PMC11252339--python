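"""Population-vector similarity across contexts and location-based context
prediction.

For each map pixel, the values of all cells' average aligned maps form a
population vector per context; the cosine (normalized dot product) between
the context-A and context-B vectors at that pixel measures how similar the
two population representations are there.  With nonnegative rates the
cosine lies in [0, 1]; pixels where either vector is zero, or where either
context average is unsampled, are flagged undefined.

Context is decoded from firing location by leave-one-out: the context
averages are recomputed without the withheld trial, the withheld trial's
maps are compared to each candidate average by normalized dot product
(averaged over cells and valid pixels), and the higher-scoring context wins.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .context import AlignedMapSet, align_within_context
from .errors import DomainError, StructuralError
from .rate_maps import RateMap
from .rotation import rotate_square


@dataclass
class PopulationStack:
    """cells x pixels matrix of average aligned map values for one context."""

    cell_ids: list[int]
    values: np.ndarray                 # (n_cells, n_pixels) for valid pixels
    pixel_mask: np.ndarray             # 2D validity mask the columns refer to

    @classmethod
    def from_aligned(cls, aligned: Mapping[int, AlignedMapSet]) -> "PopulationStack":
        cell_ids = sorted(aligned)
        if not cell_ids:
            raise DomainError("no cells to stack")
        mask = np.ones_like(aligned[cell_ids[0]].mask, dtype=bool)
        for cid in cell_ids:
            mask &= aligned[cid].mask
        vals = np.stack([aligned[cid].average[mask] for cid in cell_ids])
        return cls(cell_ids=cell_ids, values=vals, pixel_mask=mask)


def normalized_dot_product(stack_a: PopulationStack, stack_b: PopulationStack
                           ) -> np.ndarray:
    """Per-pixel cosine similarity between the across-cell vectors of the
    two contexts; NaN where either vector is zero.  Pixels must be valid in
    both stacks (enforced by intersecting the masks)."""
    if stack_a.cell_ids != stack_b.cell_ids:
        raise StructuralError("population stacks must share cell ordering")
    common = stack_a.pixel_mask & stack_b.pixel_mask
    ia = common[stack_a.pixel_mask]
    ib = common[stack_b.pixel_mask]
    va = stack_a.values[:, ia]
    vb = stack_b.values[:, ib]
    na = np.linalg.norm(va, axis=0)
    nb = np.linalg.norm(vb, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (va * vb).sum(axis=0) / (na * nb)
    cos[(na == 0) | (nb == 0)] = np.nan
    return cos


def _mean_dot(map_grid: np.ndarray, map_mask: np.ndarray,
              avg: AlignedMapSet) -> float:
    """Mean per-pixel normalized dot product between one cell's trial map and
    a context average, over jointly valid pixels (scalar pixel values, so the
    'cosine' reduces to sign agreement of magnitudes normalized per pixel —
    computed as the cosine between the two full pixel vectors)."""
    m = map_mask & avg.mask
    if not m.any():
        return float("nan")
    u, v = map_grid[m], avg.average[m]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(np.dot(u, v) / (nu * nv))


def predict_context_by_location(
    trial_maps: Mapping[int, Mapping[int, RateMap]],
    contexts: Mapping[int, str],
    cell_subset: Sequence[int],
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, list[dict]]:
    """Leave-one-out context prediction from firing location.

    ``trial_maps[cell_id][trial_id]`` are square maps; ``contexts`` labels
    each trial 'A' or 'B'.  For each withheld trial the per-context average
    aligned maps are recomputed from the remaining trials, the withheld
    trial's map is aligned to each candidate average by its best of
    {0, 180} deg, and the context whose averages score the higher mean
    normalized dot product (over cells) wins.  Ties are broken by a seeded
    coin flip, recorded per trial.  Returns (accuracy over predicted trials,
    per-trial log)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    trial_ids = sorted(contexts)
    log, correct, predicted = [], 0, 0
    for withheld in trial_ids:
        scores = {"A": [], "B": []}
        for cid in cell_subset:
            cmaps = trial_maps.get(cid, {})
            wm = cmaps.get(withheld)
            if wm is None or wm.empty:
                continue
            wgrid = np.where(wm.sampled_mask, wm.rate, 0.0)
            for ctx in ("A", "B"):
                rest = {t: m for t, m in cmaps.items()
                        if t != withheld and contexts[t] == ctx and not m.empty}
                if len(rest) < 2:
                    continue
                avg = align_within_context(rest)
                best = np.nanmax([
                    _mean_dot(rotate_square(wgrid, rot),
                              rotate_square(wm.sampled_mask, rot), avg)
                    for rot in (0, 180)
                ])
                if np.isfinite(best):
                    scores[ctx].append(best)
        if not scores["A"] or not scores["B"]:
            log.append({"trial_id": withheld, "true": contexts[withheld],
                        "predicted": None, "margin": np.nan, "tie": False})
            continue
        sa, sb = float(np.mean(scores["A"])), float(np.mean(scores["B"]))
        tie = sa == sb
        if tie:
            pred = "A" if rng.random() < 0.5 else "B"
        else:
            pred = "A" if sa > sb else "B"
        predicted += 1
        correct += pred == contexts[withheld]
        log.append({"trial_id": withheld, "true": contexts[withheld],
                    "predicted": pred, "margin": sa - sb, "tie": tie})
    if predicted == 0:
        raise DomainError("no trial could be predicted")
    return correct / predicted, log
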