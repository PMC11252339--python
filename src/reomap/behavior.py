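"""Digging-behavior scoring and Bernoulli Bayes-factor models.

A reorientation trial ends with the animal digging in one of the four corner
cups: C (the rewarded corner), G (its geometric equivalent across the
diagonal), and N / F (the two corners on the unrewarded axis).  Learning is
quantified with Bayes factors under two Bernoulli models:

* the **C/G model** asks whether the animal digs on the rewarded geometric
  axis (first dig in {C, G}) more often than the 50% expected by chance, with
  the alternative integrating the success probability uniformly over
  (0.5, 0.9);
* the **C model** asks whether the animal digs in the rewarded corner itself
  (first dig = C) more often than the 25% four-corner chance, integrating
  over (0.25, 0.9).

For ``z`` successes in ``N`` trials the Bayes factor is

    BF = [1/(b-a) * int_a^b theta^z (1-theta)^(N-z) dtheta]
         / [theta0^z (1-theta0)^(N-z)]

evaluated in closed form through regularized incomplete-beta differences.
Natural logarithms are used throughout; |log BF| > ln 3 (~1.1) is read as
substantial evidence for the alternative (positive) or the null (negative).
Group evidence multiplies across animals, i.e. log BFs add.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc, betaln

from .errors import DomainError

DIG_LABELS = ("C", "G", "N", "F")

#: Decision bound: ln 3, used exactly (not the rounded 1.1).
LOG_BF_BOUND = math.log(3.0)


@dataclass(frozen=True)
class TrialRecord:
    """One reorientation trial.

    ``dig_sequence`` holds the ordered dig labels (first dig, second dig, ...)
    drawn from {C, G, N, F}.  ``chamber_orientation_deg`` is the physical
    placement of the chamber in the room and is metadata only.
    """

    trial_id: int
    day: int
    context: str
    dig_sequence: tuple[str, ...]
    reward_corner: int = 0
    chamber_orientation_deg: float = 0.0
    animal: int | None = None

    def __post_init__(self) -> None:
        for d in self.dig_sequence:
            if d not in DIG_LABELS:
                raise DomainError(f"dig label {d!r} not in {DIG_LABELS}")
        if self.context not in ("A", "B"):
            raise DomainError(f"context must be 'A' or 'B', got {self.context!r}")

    def dig(self, rank: int = 1) -> str | None:
        """The rank-th dig label (1-based), or None if fewer digs occurred."""
        return self.dig_sequence[rank - 1] if len(self.dig_sequence) >= rank else None


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records (one row per trial, dig1/dig2 columns)."""
    rows = []
    for tr in trials:
        rows.append(
            {
                "animal": tr.animal,
                "trial_id": tr.trial_id,
                "day": tr.day,
                "context": tr.context,
                "dig1": tr.dig(1),
                "dig2": tr.dig(2),
                "reward_corner": tr.reward_corner,
                "chamber_orientation_deg": tr.chamber_orientation_deg,
            }
        )
    return pd.DataFrame(rows)


def dig_proportions(
    trials: Sequence[TrialRecord] | pd.DataFrame,
    group_by: Sequence[str] = ("day",),
    dig_rank: int = 1,
) -> pd.DataFrame:
    """Proportion of digs in each corner, per group.

    Returns one row per group with columns C/G/N/F summing to 1, the trial
    count ``n``, and a ``defined`` flag.  Groups requested but empty (e.g. a
    context with no trials) are flagged rather than silently zeroed.
    """
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    if df.empty:
        raise DomainError("no trials provided")
    col = f"dig{dig_rank}"
    if col not in df:
        df = df.copy()
        df[col] = None
    out = []
    for key, grp in df.groupby(list(group_by), dropna=False, observed=False):
        key = key if isinstance(key, tuple) else (key,)
        digs = grp[col].dropna()
        row = dict(zip(group_by, key))
        row["n"] = len(digs)
        row["defined"] = len(digs) > 0
        for lab in DIG_LABELS:
            row[lab] = (digs == lab).mean() if len(digs) else np.nan
        out.append(row)
    return pd.DataFrame(out)


def axis_proportions(trials: Sequence[TrialRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-context share of first digs on the rewarded (C+G) vs unrewarded
    (N+F) axis.  The two shares sum to 1 within each context."""
    props = dig_proportions(trials, group_by=("context",), dig_rank=1)
    props["rewarded_axis"] = props["C"] + props["G"]
    props["unrewarded_axis"] = props["N"] + props["F"]
    return props[["context", "n", "defined", "rewarded_axis", "unrewarded_axis"]]


# ---------------------------------------------------------------------------
# Bayes-factor models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BernoulliDigModel:
    """Bernoulli success counts plus the null/alternative used to judge them."""

    z: int
    N: int
    theta_null: float
    theta_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.N < 1:
            raise DomainError("N must be >= 1")
        if not 0 <= self.z <= self.N:
            raise DomainError(f"need 0 <= z <= N, got z={self.z}, N={self.N}")
        a, b = self.theta_range
        if not (0.0 < a < b < 1.0) or not (0.0 < self.theta_null < 1.0):
            raise DomainError("theta_null and theta_range must lie in (0, 1)")

    @classmethod
    def cg(cls, z: int, N: int) -> "BernoulliDigModel":
        """Rewarded-axis (C or G first dig) model: null 0.5, alt (0.5, 0.9)."""
        return cls(z=z, N=N, theta_null=0.5, theta_range=(0.5, 0.9))

    @classmethod
    def c(cls, z: int, N: int) -> "BernoulliDigModel":
        """Rewarded-corner (C first dig) model: null 0.25, alt (0.25, 0.9)."""
        return cls(z=z, N=N, theta_null=0.25, theta_range=(0.25, 0.9))

    @classmethod
    def from_trials(
        cls, trials: Sequence[TrialRecord] | pd.DataFrame, model: Literal["cg", "c"]
    ) -> "BernoulliDigModel":
        """Count successes from first digs.  Trials without a first dig are
        excluded from both z and N."""
        df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
        digs = df["dig1"].dropna()
        if digs.empty:
            raise DomainError("no trials with a first dig")
        if model == "cg":
            return cls.cg(z=int(digs.isin(["C", "G"]).sum()), N=len(digs))
        if model == "c":
            return cls.c(z=int((digs == "C").sum()), N=len(digs))
        raise DomainError(f"unknown model {model!r}")


def _log_power_integral(z: int, n_minus_z: int, a: float, b: float) -> float:
    """log of int_a^b theta^z (1-theta)^(n-z) dtheta in closed form.

    The integrand is an unnormalized Beta(z+1, n-z+1) density, so the
    integral is B(z+1, n-z+1) * [I_b(z+1, n-z+1) - I_a(z+1, n-z+1)] with I
    the regularized incomplete beta function.
    """
    p, q = z + 1, n_minus_z + 1
    diff = betainc(p, q, b) - betainc(p, q, a)
    if diff <= 0.0:  # underflow for extreme z/N; integrate the tail directly
        from scipy.integrate import quad

        val, _ = quad(
            lambda th: np.exp(
                z * np.log(th) + n_minus_z * np.log1p(-th)
            ),
            a,
            b,
        )
        return math.log(val) if val > 0 else -math.inf
    return betaln(p, q) + math.log(diff)


def bayes_factor(model: BernoulliDigModel) -> float:
    """Natural-log Bayes factor of the interval alternative vs the point null.

    Closed-form incomplete-beta evaluation; finite for all valid (z, N).
    """
    a, b = model.theta_range
    z, N = model.z, model.N
    log_alt = _log_power_integral(z, N - z, a, b) - math.log(b - a)
    log_null = z * math.log(model.theta_null) + (N - z) * math.log(1.0 - model.theta_null)
    return log_alt - log_null


def group_bayes_factor(log_bfs: Sequence[float]) -> float:
    """Group-level log BF: the product of per-animal BFs, i.e. sum of logs."""
    arr = np.asarray(list(log_bfs), dtype=float)
    if arr.size == 0:
        raise DomainError("empty list of Bayes factors")
    if not np.all(np.isfinite(arr)):
        raise DomainError("non-finite log Bayes factor in group")
    return float(arr.sum())


def bf_decision(log_bf: float) -> Literal["alt", "null", "inconclusive"]:
    """Three-way evidence call at the exact ln 3 bound."""
    if not math.isfinite(log_bf):
        raise DomainError("log BF must be finite")
    if log_bf > LOG_BF_BOUND:
        return "alt"
    if log_bf < -LOG_BF_BOUND:
        return "null"
    return "inconclusive"


@dataclass
class BFResult:
    """Per-animal and group log Bayes factors with decisions."""

    log_bf_per_animal: list[float]
    animals: list = field(default_factory=list)
    model: str = ""

    @property
    def log_bf_group(self) -> float:
        return group_bayes_factor(self.log_bf_per_animal)

    @property
    def decisions(self) -> list[str]:
        return [bf_decision(v) for v in self.log_bf_per_animal]

    @property
    def group_decision(self) -> str:
        return bf_decision(self.log_bf_group)

    def ecdf(self) -> pd.DataFrame:
        """Cumulative proportion of animals at or below each log BF."""
        vals = np.sort(np.asarray(self.log_bf_per_animal))
        return pd.DataFrame(
            {"log_bf": vals, "cum_prop": np.arange(1, vals.size + 1) / vals.size}
        )


def bayes_factor_by_animal(
    trials: Sequence[TrialRecord] | pd.DataFrame,
    model: Literal["cg", "c"],
    group_by: Sequence[str] = ("animal",),
) -> BFResult:
    """Fit the chosen Bernoulli model per animal (optionally per extra keys)
    and collect per-animal log BFs into a :class:`BFResult`."""
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    if df.empty:
        raise DomainError("no trials provided")
    log_bfs, keys = [], []
    for key, grp in df.groupby(list(group_by), observed=False):
        m = BernoulliDigModel.from_trials(grp, model)
        log_bfs.append(bayes_factor(m))
        keys.append(key)
    return BFResult(log_bf_per_animal=log_bfs, animals=keys, model=model)
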