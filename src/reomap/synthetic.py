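"""Synthetic two-context reorientation sessions with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, at the level of post-extraction data (trajectories and per-cell
event trains — no video, no raw fluorescence):

* each animal runs 12 trials/day (alternating contexts A and B, 6 each) for
  3 days in a 20 x 30 cm chamber;
* on every trial the disoriented animal's hippocampal map adopts an ensemble
  orientation drawn uniformly from {0 deg, 180 deg} — the two orientations
  compatible with the rectangle's geometry;
* **feature-insensitive (FI)** cells keep the same field in both contexts
  and rotate with the ensemble; **feature-sensitive (FS)** cells remap
  across contexts: their context-B field sits near the 180 deg image of the
  context-A field but displaced by ``fs_remap_shift_cm``.  A pure 180 deg
  rotation alone would be absorbed by the geometric alignment downstream
  (it is exactly the chamber's symmetry), so the displacement is what makes
  the remapping detectable while the rotation is what flips the
  across-context best-match rotation axis;
* per cell and trial the applied rotation follows the ensemble orientation
  with probability ``coherence_by_day`` (increasing over days as the map
  stabilizes with learning), otherwise it flips;
* mean rates differ across contexts by a per-day multiplicative gain with a
  per-cell direction, growing over days (rate remapping with learning);
* the first dig is categorical over {C, G, N, F} with per-day weights; when
  it lands on the rewarded axis, the C-vs-G choice matches the ensemble
  orientation with probability ``p_dig_follows_orientation``.

Randomness is organized as named substreams derived from the master seed per
(animal, day, trial), so identical configurations are bit-identical and any
stage can be regenerated independently.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry as geom
from .behavior import DIG_LABELS, TrialRecord
from .errors import ConfigurationError, DomainError
from .rate_maps import ActivityTrain, Trajectory

_FIELD_MARGIN_CM = 4.0      # keep field centers off the walls
_MIN_FIELD_RADIUS_CM = 6.0  # and off the chamber center, so angles are stable


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the synthetic experiment.

    Defaults encode the study conditions: 14 animals, 3 days of 12
    alternating-context trials, a 20 x 30 cm chamber, an FS fraction of 20%,
    coherence and across-context rate gain increasing over days, and dig
    preferences shifting from the geometric axis toward the rewarded corner.
    """

    n_animals: int = 14
    n_days: int = 3
    trials_per_day: int = 12
    chamber_x_cm: float = geom.CHAMBER_X_CM
    chamber_y_cm: float = geom.CHAMBER_Y_CM
    trial_duration_s: float = 120.0
    frame_rate_hz: float = 10.0
    n_fi_cells: int = 40
    n_fs_cells: int = 10
    field_sigma_cm: float = 3.0
    peak_rate_hz: float = 5.0
    noise_rate_hz: float = 0.1
    coherence_by_day: tuple[float, ...] = (0.75, 0.85, 0.95)
    fs_context_offset_deg: float = 180.0
    fs_remap_shift_cm: float = 10.0
    rate_gain_by_day: tuple[float, ...] = (1.0, 1.25, 1.5)
    dig_probs_by_day: tuple[tuple[float, float, float, float], ...] = (
        (0.375, 0.375, 0.125, 0.125),
        (0.55, 0.25, 0.10, 0.10),
        (0.65, 0.20, 0.075, 0.075),
    )
    p_dig_follows_orientation: float = 0.8
    fs_identity_retention: float = 0.8
    speed_scale_cm_s: float = 6.0
    speed_tau_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_duration_s <= 0 or self.trial_duration_s > 180.0:
            raise ConfigurationError("trial_duration_s must be in (0, 180]")
        if self.frame_rate_hz <= 0:
            raise ConfigurationError("frame_rate_hz must be positive")
        if self.trials_per_day % 2 != 0:
            raise ConfigurationError("trials_per_day must be even (equal per context)")
        if abs(self.chamber_x_cm / self.chamber_y_cm - 2.0 / 3.0) > 1e-9:
            raise ConfigurationError("chamber aspect must be 2:3 for square compression")
        for name in ("p_dig_follows_orientation", "fs_identity_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for seq_name in ("coherence_by_day", "rate_gain_by_day", "dig_probs_by_day"):
            if len(getattr(self, seq_name)) != self.n_days:
                raise ConfigurationError(f"{seq_name} must have one entry per day")
        for p in self.coherence_by_day:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("coherence_by_day entries must be in [0, 1]")
        for row in self.dig_probs_by_day:
            if len(row) != 4 or any(p < 0 for p in row) or abs(sum(row) - 1.0) > 1e-9:
                raise ConfigurationError("dig_probs_by_day rows must be 4 nonnegative "
                                         "weights summing to 1")

    @property
    def n_cells(self) -> int:
        return self.n_fi_cells + self.n_fs_cells


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth tuning of one cell for one day."""

    cell_id: int
    cell_class: str                    # "FI" or "FS" on this day
    center_a: tuple[float, float]      # field center in context A (cm)
    center_b: tuple[float, float]      # field center in context B (cm)
    sigma_cm: float
    peak_rate_hz: float
    noise_rate_hz: float
    gain_sign: int                     # +1: context B scaled up; -1: down


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    cells: pd.DataFrame                          # cell_id, cell_class, centers, gain_sign
    orientation_by_trial: dict[int, float]       # trial_id -> ensemble orientation
    applied_rotation: dict[tuple[int, int], float]  # (trial_id, cell_id) -> rotation
    identity_map: dict[int, int]                 # day cell_id -> cross-day global id


@dataclass
class SessionBundle:
    """One animal-day of synthetic data."""

    animal: int
    day: int
    config: SimConfig
    trials: list[TrialRecord]
    trajectories: dict[int, Trajectory]
    activity: dict[int, dict[int, ActivityTrain]]
    ground_truth: GroundTruth


def _rng(config_seed: int, *key: int) -> np.random.Generator:
    """Named substream: one generator per (animal, day, trial, stream)."""
    return np.random.default_rng(np.random.SeedSequence(config_seed, spawn_key=tuple(key)))


def simulate_trajectory(config: SimConfig, trial_seed) -> Trajectory:
    """Bounded correlated random walk (Ornstein-Uhlenbeck velocity).

    Positions are folded reflectively into the chamber; speeds fluctuate
    around ``speed_scale_cm_s`` with relaxation time ``speed_tau_s`` and
    naturally include epochs below the 2 cm/s movement threshold, so the
    speed filter downstream is exercised.
    """
    if config.trial_duration_s <= 0 or config.frame_rate_hz <= 0:
        raise ConfigurationError("duration and frame rate must be positive")
    rng = trial_seed if isinstance(trial_seed, np.random.Generator) \
        else np.random.default_rng(trial_seed)
    n = int(round(config.trial_duration_s * config.frame_rate_hz))
    dt = 1.0 / config.frame_rate_hz
    t = np.arange(n) * dt
    s = config.speed_scale_cm_s / np.sqrt(2.0)  # per-axis stationary std
    if s == 0:
        x0 = rng.uniform(0, config.chamber_x_cm)
        y0 = rng.uniform(0, config.chamber_y_cm)
        return Trajectory(t=t, x=np.full(n, x0), y=np.full(n, y0))
    phi = np.exp(-dt / config.speed_tau_s)
    innov_sd = s * np.sqrt(1.0 - phi**2)
    # exact AR(1) simulation of the OU velocity: v_k = phi v_{k-1} + eps_k
    from scipy.signal import lfilter

    x = rng.normal(size=(n, 2)) * innov_sd
    x[0] = rng.normal(size=2) * s  # stationary initial velocity
    v = lfilter([1.0], [1.0, -phi], x, axis=0)
    pos0 = np.array([rng.uniform(0, config.chamber_x_cm),
                     rng.uniform(0, config.chamber_y_cm)])
    pos = pos0 + np.cumsum(v * dt, axis=0) - v[0] * dt
    x = geom.fold_into_interval(pos[:, 0], config.chamber_x_cm)
    y = geom.fold_into_interval(pos[:, 1], config.chamber_y_cm)
    return Trajectory(t=t, x=x, y=y)


def simulate_activity(
    traj: Trajectory,
    cell: CellSpec,
    trial_context: str,
    applied_orientation_deg: float,
    seed,
    rate_gain: float = 1.0,
) -> ActivityTrain:
    """Inhomogeneous-Poisson event train for one cell on one trial.

    Intensity at position p is baseline + peak * Gaussian(distance from p to
    the field center rotated by the applied orientation about the chamber
    center); context B uses the cell's context-B center and is scaled by
    ``rate_gain ** gain_sign``.  Events are emitted at sampled timestamps
    with unit weights.
    """
    if applied_orientation_deg not in (0.0, 180.0, 0, 180):
        raise DomainError("orientation must be 0 or 180 degrees")
    if trial_context not in ("A", "B"):
        raise DomainError("context must be 'A' or 'B'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = cell.center_a if trial_context == "A" else cell.center_b
    center = geom.rotate_about_center(np.asarray(center, float), applied_orientation_deg)
    d2 = (traj.x - center[0]) ** 2 + (traj.y - center[1]) ** 2
    lam = cell.noise_rate_hz + cell.peak_rate_hz * np.exp(-d2 / (2.0 * cell.sigma_cm**2))
    if trial_context == "B":
        lam = lam * (rate_gain ** cell.gain_sign)
    counts = rng.poisson(lam * traj.frame_dt)
    times = np.repeat(traj.t, counts)
    return ActivityTrain(cell_id=cell.cell_id, times=times, weights=np.ones_like(times))


def _sample_field_center(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    lo = np.array([_FIELD_MARGIN_CM, _FIELD_MARGIN_CM])
    hi = np.array([config.chamber_x_cm - _FIELD_MARGIN_CM,
                   config.chamber_y_cm - _FIELD_MARGIN_CM])
    center = np.array(geom.CHAMBER_CENTER)
    for _ in range(1000):
        p = rng.uniform(lo, hi)
        if np.linalg.norm(p - center) >= _MIN_FIELD_RADIUS_CM:
            return p
    raise ConfigurationError("could not place a field center; margins too tight")


def _sample_fs_center_b(rng: np.random.Generator, config: SimConfig,
                        center_a: np.ndarray) -> np.ndarray:
    """Context-B field for an FS cell: at ``fs_remap_shift_cm`` from the
    rotated image of the context-A field, kept inside the margins and far
    from the context-A field itself so that neither 0 nor 180 deg alignment
    can absorb the remapping."""
    lo = np.array([_FIELD_MARGIN_CM, _FIELD_MARGIN_CM])
    hi = np.array([config.chamber_x_cm - _FIELD_MARGIN_CM,
                   config.chamber_y_cm - _FIELD_MARGIN_CM])
    anchor = np.asarray(
        geom.rotate_about_center(center_a, config.fs_context_offset_deg), float)
    shift = config.fs_remap_shift_cm
    for min_dist_a in (shift * 1.3, shift):
        for _ in range(200):
            ang = rng.uniform(0, 2 * np.pi)
            p = anchor + shift * np.array([np.cos(ang), np.sin(ang)])
            if np.all(p >= lo) and np.all(p <= hi) \
                    and np.linalg.norm(p - center_a) >= min_dist_a:
                return p
    # The anchor circle can be infeasible when the field sits near the
    # chamber center; fall back to plain location remapping anywhere in the
    # margins, still far from the context-A field so similarity stays low.
    for min_dist_a in (shift * 1.2, shift):
        for _ in range(500):
            p = rng.uniform(lo, hi)
            if np.linalg.norm(p - center_a) >= min_dist_a:
                return p
    return np.clip(anchor + np.array([shift, 0.0]), lo, hi)


def _draw_cells(rng: np.random.Generator, config: SimConfig) -> list[CellSpec]:
    """Base (day-1) cell population; FI first, then FS."""
    cells = []
    for cid in range(config.n_cells):
        cls = "FI" if cid < config.n_fi_cells else "FS"
        ca = _sample_field_center(rng, config)
        cb = ca if cls == "FI" else _sample_fs_center_b(rng, config, ca)
        cells.append(CellSpec(
            cell_id=cid, cell_class=cls,
            center_a=tuple(ca), center_b=tuple(np.asarray(cb)),
            sigma_cm=config.field_sigma_cm,
            peak_rate_hz=config.peak_rate_hz,
            noise_rate_hz=config.noise_rate_hz,
            gain_sign=int(rng.choice([-1, 1])),
        ))
    return cells


def _sample_dig(rng: np.random.Generator, probs: Sequence[float],
                orientation_deg: float, p_follow: float) -> tuple[str, str]:
    """First and second dig.  A rewarded-axis first dig matches the ensemble
    orientation (0 -> C, 180 -> G) with probability ``p_follow``, otherwise
    the opposite corner of the axis — so 0.5 means the C-vs-G choice is
    independent of the orientation and 1.0 means perfect coupling."""
    cat = DIG_LABELS[rng.choice(4, p=np.asarray(probs, float))]
    if cat in ("C", "G"):
        oriented = "C" if orientation_deg == 0 else "G"
        dig1 = oriented if rng.random() < p_follow else ("G" if oriented == "C" else "C")
    else:
        dig1 = cat
    others = [d for d in DIG_LABELS if d != dig1]
    dig2 = others[rng.integers(0, 3)]
    return dig1, dig2


def generate_study(config: SimConfig) -> list[SessionBundle]:
    """Full synthetic study: one :class:`SessionBundle` per animal per day.

    FI identities persist across days; an FS cell keeps FS behavior on the
    next day with probability ``fs_identity_retention`` (otherwise it behaves
    FI that day), and FS context-B fields are resampled each day.
    """
    bundles = []
    for animal in range(config.n_animals):
        cell_rng = _rng(config.seed, animal, 0)
        base_cells = _draw_cells(cell_rng, config)
        for day in range(1, config.n_days + 1):
            day_rng = _rng(config.seed, animal, day, 0)
            cells = []
            for c in base_cells:
                if c.cell_class == "FS":
                    if day == 1 or day_rng.random() < config.fs_identity_retention:
                        cb = _sample_fs_center_b(day_rng, config, np.asarray(c.center_a))
                        cells.append(replace(c, center_b=tuple(cb)))
                    else:
                        cells.append(replace(c, cell_class="FI", center_b=c.center_a))
                else:
                    cells.append(c)
            bundles.append(_generate_session(config, animal, day, cells))
    return bundles


def _generate_session(config: SimConfig, animal: int, day: int,
                      cells: list[CellSpec]) -> SessionBundle:
    di = day - 1
    coherence = config.coherence_by_day[di]
    gain = config.rate_gain_by_day[di]
    trials, trajectories, activity = [], {}, {}
    orientation_by_trial, applied = {}, {}
    for k in range(config.trials_per_day):
        trial_id = k
        context = "A" if k % 2 == 0 else "B"
        trial_rng = _rng(config.seed, animal, day, trial_id, 1)
        orientation = float(trial_rng.choice([0.0, 180.0]))
        orientation_by_trial[trial_id] = orientation
        trajectories[trial_id] = simulate_trajectory(
            config, _rng(config.seed, animal, day, trial_id, 2))
        act_rng = _rng(config.seed, animal, day, trial_id, 3)
        trains = {}
        for c in cells:
            rot = orientation if act_rng.random() < coherence \
                else (orientation + 180.0) % 360.0
            applied[(trial_id, c.cell_id)] = rot
            trains[c.cell_id] = simulate_activity(
                trajectories[trial_id], c, context, rot, act_rng, rate_gain=gain)
        activity[trial_id] = trains
        dig_rng = _rng(config.seed, animal, day, trial_id, 4)
        dig1, dig2 = _sample_dig(dig_rng, config.dig_probs_by_day[di],
                                 orientation, config.p_dig_follows_orientation)
        trials.append(TrialRecord(
            trial_id=trial_id, day=day, context=context,
            dig_sequence=(dig1, dig2),
            reward_corner=0 if context == "A" else 2,
            chamber_orientation_deg=float(dig_rng.choice([0.0, 90.0, 180.0, 270.0])),
            animal=animal,
        ))
    cells_df = pd.DataFrame([
        {"cell_id": c.cell_id, "cell_class": c.cell_class,
         "center_a_x": c.center_a[0], "center_a_y": c.center_a[1],
         "center_b_x": c.center_b[0], "center_b_y": c.center_b[1],
         "gain_sign": c.gain_sign}
        for c in cells
    ])
    gt = GroundTruth(cells=cells_df, orientation_by_trial=orientation_by_trial,
                     applied_rotation=applied,
                     identity_map={c.cell_id: c.cell_id for c in cells})
    return SessionBundle(animal=animal, day=day, config=config, trials=trials,
                         trajectories=trajectories, activity=activity,
                         ground_truth=gt)
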