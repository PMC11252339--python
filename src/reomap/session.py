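"""Per-session derived tables: maps, angles, rates, cell classes.

This is the glue between the raw (or synthetic) session data and the
analysis modules: it computes, once per session, every per-trial per-cell
quantity the decoders and remapping statistics consume — native and
square-compressed rate maps, largest-field center-out angles, speed-filtered
mean rates, field presence — plus the per-cell context-similarity
classification.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import rate_maps as rm
from .context import (SIMILARITY_THRESHOLD, AlignedMapSet, align_within_context,
                      context_similarity)
from .rotation import BMRRecord, bmr_records_for_cell
from .synthetic import SessionBundle


@dataclass
class SessionTables:
    """All derived per-trial per-cell quantities for one session."""

    animal: int
    day: int
    contexts: dict[int, str]                       # trial -> 'A'/'B'
    dig1: dict[int, str]                           # trial -> first dig
    native_maps: dict[int, dict[int, rm.RateMap]]  # cell -> trial -> map
    square_maps: dict[int, dict[int, rm.RateMap]]
    angles: dict[int, dict[int, float | None]]     # center-out angle (native)
    mean_rates: dict[int, dict[int, float | None]]
    field_presence: dict[int, dict[int, bool]]     # square-map field detected
    spatial_info: dict[int, dict[int, float | None]] = field(default_factory=dict)

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.native_maps)

    @property
    def trial_ids(self) -> list[int]:
        return sorted(self.contexts)

    def inactive(self, cell_id: int, trial_id: int) -> bool:
        """Inactive = no detected field and zero speed-filtered activity."""
        no_field = not self.field_presence[cell_id].get(trial_id, False)
        r = self.mean_rates[cell_id].get(trial_id)
        return no_field and (r is None or r == 0.0)

    def included_cells_for_pair(self, pair: tuple[int, int]) -> set[int]:
        """Coherency inclusion: active in both trials of the pair."""
        i, j = pair
        return {c for c in self.cell_ids
                if not self.inactive(c, i) and not self.inactive(c, j)}

    def pair_comparison(self, pair: tuple[int, int]) -> str:
        return "within" if self.contexts[pair[0]] == self.contexts[pair[1]] \
            else "across"


def compute_session_tables(bundle: SessionBundle,
                           sigma_cm: float = rm.SMOOTH_SIGMA_CM,
                           with_spatial_info: bool = False) -> SessionTables:
    """Build every derived table for one session bundle."""
    contexts = {t.trial_id: t.context for t in bundle.trials}
    dig1 = {t.trial_id: t.dig(1) for t in bundle.trials}
    native, square, angles, rates, presence, sinfo = {}, {}, {}, {}, {}, {}
    for trial_id, trains in bundle.activity.items():
        traj = bundle.trajectories[trial_id]
        occ_n = rm.compute_occupancy(traj, square=False, sigma_cm=sigma_cm)
        occ_s = rm.compute_occupancy(traj, square=True, sigma_cm=sigma_cm)
        for cid, act in trains.items():
            nm = rm.compute_rate_map(traj, act, sigma_cm=sigma_cm, occupancy=occ_n)
            sq = rm.compress_to_square(nm, occupancy=occ_s)
            native.setdefault(cid, {})[trial_id] = nm
            square.setdefault(cid, {})[trial_id] = sq
            fields = rm.detect_place_fields(nm)
            angles.setdefault(cid, {})[trial_id] = (
                rm.center_out_angle(fields[0]) if fields else None)
            presence.setdefault(cid, {})[trial_id] = \
                len(rm.detect_place_fields(sq)) > 0
            rates.setdefault(cid, {})[trial_id] = rm.trial_rate_stats(act, traj)
            if with_spatial_info:
                sinfo.setdefault(cid, {})[trial_id] = rm.spatial_information(nm)
    return SessionTables(animal=bundle.animal, day=bundle.day,
                         contexts=contexts, dig1=dig1,
                         native_maps=native, square_maps=square,
                         angles=angles, mean_rates=rates,
                         field_presence=presence, spatial_info=sinfo)


def compute_heading_angles(bundle: SessionBundle,
                           sigma_cm: float = rm.SMOOTH_SIGMA_CM,
                           ) -> tuple[dict[int, dict[int, float | None]],
                                      dict[int, str]]:
    """Light path for the heading decoder: per-cell per-trial center-out
    angles (largest native-map field) and first-dig labels, skipping square
    maps and rate statistics."""
    angles: dict[int, dict[int, float | None]] = {}
    for trial_id, trains in bundle.activity.items():
        traj = bundle.trajectories[trial_id]
        occ = rm.compute_occupancy(traj, square=False, sigma_cm=sigma_cm)
        for cid, act in trains.items():
            nm = rm.compute_rate_map(traj, act, sigma_cm=sigma_cm, occupancy=occ)
            fields = rm.detect_place_fields(nm)
            angles.setdefault(cid, {})[trial_id] = (
                rm.center_out_angle(fields[0]) if fields else None)
    dig1 = {t.trial_id: t.dig(1) for t in bundle.trials}
    return angles, dig1


def _single_map_average(m: rm.RateMap) -> AlignedMapSet:
    grid = np.where(m.sampled_mask, m.rate, 0.0)
    return AlignedMapSet(rotations={}, average=grid,
                         mask=m.sampled_mask.copy(),
                         trial_count=m.sampled_mask.astype(int),
                         mean_pairwise_corr=float("nan"))


def context_average_map(tables: SessionTables, cell_id: int, context: str,
                        require_field: bool = True) -> AlignedMapSet | None:
    """Geometry-aligned average map of one cell in one context.

    Uses trials where the cell's square map is defined (and, by default, has
    a detected field).  One qualifying trial yields that map unaligned; none
    yields None."""
    cmaps = {
        t: m for t, m in tables.square_maps[cell_id].items()
        if tables.contexts[t] == context and not m.empty
        and (not require_field or tables.field_presence[cell_id].get(t, False))
    }
    if not cmaps:
        return None
    if len(cmaps) == 1:
        return _single_map_average(next(iter(cmaps.values())))
    return align_within_context(cmaps)


def classify_cells(tables: SessionTables,
                   threshold: float = SIMILARITY_THRESHOLD) -> pd.DataFrame:
    """Context similarity and FI/FS label per cell.

    A cell needs at least one trial with a place field in each context for
    the score to be defined; cells failing the rule get class 'undefined'.
    The frame also carries each cell's average within-context pairwise
    correlation (mean of the two contexts' alignment scores) and the trial
    counts behind the inclusion rules.
    """
    rows = []
    for cid in tables.cell_ids:
        n_fields = {"A": 0, "B": 0}
        for t, has in tables.field_presence[cid].items():
            if has:
                n_fields[tables.contexts[t]] += 1
        avg_a = context_average_map(tables, cid, "A")
        avg_b = context_average_map(tables, cid, "B")
        if min(n_fields.values()) < 1 or avg_a is None or avg_b is None:
            rows.append({"cell_id": cid, "similarity": np.nan,
                         "cell_class": "undefined", "within": np.nan,
                         "n_fields_a": n_fields["A"], "n_fields_b": n_fields["B"]})
            continue
        score = context_similarity(avg_a, avg_b, cell_id=cid, threshold=threshold)
        withins = [s.mean_pairwise_corr for s in (avg_a, avg_b)
                   if np.isfinite(s.mean_pairwise_corr)]
        rows.append({"cell_id": cid, "similarity": score.value,
                     "cell_class": score.cell_class,
                     "within": float(np.mean(withins)) if withins else np.nan,
                     "n_fields_a": n_fields["A"], "n_fields_b": n_fields["B"]})
    return pd.DataFrame(rows)


def session_bmr_records(tables: SessionTables) -> list[BMRRecord]:
    """All pairwise best-match rotations for every cell in the session."""
    recs: list[BMRRecord] = []
    for cid in tables.cell_ids:
        recs.extend(bmr_records_for_cell(tables.square_maps[cid], cid))
    return recs


def trial_pairs(tables: SessionTables) -> list[tuple[int, int]]:
    return list(combinations(tables.trial_ids, 2))
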