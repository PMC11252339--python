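"""Context similarity: geometric alignment, FI/FS classification, and the
decile-curve threshold-selection model.

In a rectangular chamber a disoriented animal's map can adopt either of two
geometrically equivalent orientations, so a cell's trial maps within one
context are first brought to a common orientation by searching the per-trial
0/180 deg assignments that maximize the mean pairwise correlation
(exhaustive over 2^(k-1) assignments; the first trial anchors 0 deg).  The
per-context average aligned maps are then compared at 0 and 180 deg; the
best of the two correlations is the cell's **context similarity**.  Cells
at or below the similarity threshold (default 0.3) are classified
feature-sensitive (FS), the rest feature-insensitive (FI); the score is
defined only for cells with at least one place field in each context.

The threshold itself can be recomputed from the data: cells are split into
deciles of the similarity distribution; within each decile the Pearson
correlation between cells' average within-context and across-context
correlations gives a 10-point curve which is fit with the asymptotic
regression y(x) = a - (a - b) exp(-c x).  The decile containing the fitted
curve's half-life / root / maximal-relative-growth locus marks the boundary
between remapping and stable cells, and its empirical upper edge is the
selected threshold.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError
from .rate_maps import RateMap, masked_pearson
from .rotation import rotate_square

SIMILARITY_THRESHOLD = 0.3
GEOMETRIC_ROTATIONS = (0, 180)


@dataclass
class AlignedMapSet:
    """Per-trial geometric rotations and the resulting average map."""

    rotations: dict[int, int]          # trial_id -> 0 or 180
    average: np.ndarray                # pixelwise mean over aligned maps
    mask: np.ndarray                   # sampled in >= 1 aligned map
    trial_count: np.ndarray            # per-pixel number of contributing maps
    mean_pairwise_corr: float          # the within-context correlation


@dataclass
class ContextSimilarityScore:
    """Across-context similarity of one cell with its FI/FS label."""

    cell_id: int
    value: float
    rotation: int                      # across-context alignment, 0 or 180
    cell_class: str                    # "FI", "FS", or "undefined"
    threshold: float = SIMILARITY_THRESHOLD


def _aligned(m: RateMap, rot: int) -> tuple[np.ndarray, np.ndarray]:
    grid = np.where(m.sampled_mask, m.rate, 0.0)
    return rotate_square(grid, rot), rotate_square(m.sampled_mask, rot)


def align_within_context(trial_maps: dict[int, RateMap]) -> AlignedMapSet:
    """Exhaustively choose per-trial 0/180 rotations maximizing the mean
    pairwise correlation among the aligned maps.

    Requires at least two trials with defined maps.  The average uses the
    union of sampled pixels (pixelwise mean over maps sampled there), with
    the per-pixel count retained.
    """
    ids = sorted(t for t, m in trial_maps.items() if not m.empty)
    if len(ids) < 2:
        raise DomainError("need >= 2 defined maps to align a context")
    maps = [trial_maps[t] for t in ids]
    best_score, best_assign = -np.inf, None
    for rest in product(GEOMETRIC_ROTATIONS, repeat=len(ids) - 1):
        assign = (0,) + rest
        grids_masks = [_aligned(m, r) for m, r in zip(maps, assign)]
        rs = []
        for (ga, ma), (gb, mb) in combinations(grids_masks, 2):
            r, _ = masked_pearson(ga, gb, ma, mb)
            if np.isfinite(r):
                rs.append(r)
        score = np.mean(rs) if rs else -np.inf
        if score > best_score:
            best_score, best_assign = score, assign
    if best_assign is None:
        # no assignment has a defined pairwise correlation (e.g. constant
        # maps): leave everything unrotated
        best_assign = (0,) * len(ids)
    grids_masks = [_aligned(m, r) for m, r in zip(maps, best_assign)]
    stack = np.stack([g for g, _ in grids_masks])
    masks = np.stack([m for _, m in grids_masks])
    count = masks.sum(axis=0)
    with np.errstate(invalid="ignore"):
        avg = np.where(count > 0, (stack * masks).sum(axis=0) / np.maximum(count, 1), 0.0)
    return AlignedMapSet(
        rotations=dict(zip(ids, best_assign)),
        average=avg,
        mask=count > 0,
        trial_count=count,
        mean_pairwise_corr=float(best_score) if np.isfinite(best_score) else float("nan"),
    )


def context_similarity(avg_a: AlignedMapSet, avg_b: AlignedMapSet,
                       cell_id: int = -1,
                       threshold: float = SIMILARITY_THRESHOLD,
                       ) -> ContextSimilarityScore:
    """Best-of-{0, 180} correlation between the two context averages.

    The caller enforces the inclusion rule (a place field in each context);
    an undefined correlation at both rotations yields class ``undefined``.
    """
    best_r, best_rot = float("nan"), 0
    for rot in GEOMETRIC_ROTATIONS:
        gb, mb = rotate_square(avg_b.average, rot), rotate_square(avg_b.mask, rot)
        r, _ = masked_pearson(avg_a.average, gb, avg_a.mask, mb)
        if np.isfinite(r) and (not np.isfinite(best_r) or r > best_r):
            best_r, best_rot = r, rot
    if not np.isfinite(best_r):
        return ContextSimilarityScore(cell_id, best_r, best_rot, "undefined", threshold)
    cls = "FS" if best_r <= threshold else "FI"
    return ContextSimilarityScore(cell_id, best_r, best_rot, cls, threshold)


# ---------------------------------------------------------------------------
# Threshold selection: decile curve + asymptotic regression
# ---------------------------------------------------------------------------

MIN_CELLS_PER_DECILE = 3


def within_across_decile_curve(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-decile correlation between within- and across-context stability.

    ``scores`` needs columns ``cell_id``, ``across`` (the context-similarity
    value) and ``within`` (the cell's average within-context pairwise
    correlation); only cells meeting the two-trials-per-context rule should
    be passed in.  Cells are cut into deciles of ``across``; each decile
    with at least :data:`MIN_CELLS_PER_DECILE` members gets the Pearson R
    between its members' within and across values, others are flagged
    undefined.  Returns a 10-row frame (decile 1..10, boundaries, R, n).
    """
    df = scores.dropna(subset=["within", "across"]).copy()
    if df.empty:
        raise DomainError("no cells with defined within/across correlations")
    edges = np.quantile(df["across"], np.linspace(0, 1, 11))
    rows = []
    for d in range(1, 11):
        lo, hi = edges[d - 1], edges[d]
        sel = (df["across"] >= lo) & (df["across"] <= hi) if d == 10 else \
              (df["across"] >= lo) & (df["across"] < hi)
        sub = df[sel]
        defined = len(sub) >= MIN_CELLS_PER_DECILE
        r = float(np.corrcoef(sub["within"], sub["across"])[0, 1]) if defined else np.nan
        if defined and not np.isfinite(r):
            defined = False
            r = np.nan
        rows.append({"decile": d, "lower": lo, "upper": hi,
                     "n_cells": len(sub), "R": r, "defined": defined})
    return pd.DataFrame(rows)


@dataclass
class AsymptoticFit:
    """y(x) = a - (a - b) exp(-c x) with goodness-of-fit and shape features."""

    a: float
    b: float
    c: float
    rss: float
    n: int
    log_likelihood: float
    aic: float
    rse: float

    @property
    def half_life(self) -> float:
        """x at which the gap to the asymptote has halved: ln 2 / c."""
        return float(np.log(2.0) / self.c)

    @property
    def root(self) -> float | None:
        """x where y = 0; exists only when b and a have opposite signs
        (the curve starts on one side of zero and ends on the other)."""
        if self.a == self.b or self.a * self.b >= 0:
            return None
        return float(-np.log(self.a / (self.a - self.b)) / self.c)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a - (self.a - self.b) * np.exp(-self.c * np.asarray(x, float))

    def max_relative_growth(self, x_min: float = 0.0, x_max: float = 10.0) -> float:
        """Location of the maximum of y'(x)/|y(x)| on [x_min, x_max].

        For a curve rising through zero this sits just past the root (the
        relative growth rate diverges there); for an all-positive curve the
        growth rate y' decays monotonically and the maximum is at the left
        edge.  Evaluated on a fine grid; the divergence is capped by the
        grid resolution, which is all the decile-locating use requires.
        """
        xs = np.linspace(x_min, x_max, 2001)
        y = self.predict(xs)
        dy = self.c * (self.a - self.b) * np.exp(-self.c * xs)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(dy) / np.maximum(np.abs(y), 1e-9)
        return float(xs[np.argmax(rel)])


def fit_asymptotic_regression(x: Sequence[float], y: Sequence[float],
                              n_starts: int = 16) -> AsymptoticFit:
    """Nonlinear least squares for y = a - (a - b) exp(-c x), c > 0.

    Multi-start over a deterministic log-spaced grid of rate constants;
    Gaussian log-likelihood with the ML noise variance, AIC = 2k - 2 logL
    with k = 4 (a, b, c, sigma^2), RSE = sqrt(RSS / (n - 3)).  Raises
    :class:`DomainError` when no start converges (e.g. constant input, for
    which c is unidentifiable).
    """
    x = np.asarray([xi for xi, yi in zip(x, y) if np.isfinite(yi)], float)
    yv = np.asarray([yi for yi in y if np.isfinite(yi)], float)
    if x.size < 4:
        raise DomainError("need >= 4 defined points for the asymptotic fit")
    if np.ptp(yv) < 1e-12:
        raise DomainError("constant series: rate constant is unidentifiable")

    def model(xx, a, b, c):
        return a - (a - b) * np.exp(-c * xx)

    best = None
    span = max(np.ptp(x), 1.0)
    for c0 in np.logspace(-2, 1.2, n_starts) / span * 5.0:
        try:
            popt, _ = curve_fit(model, x, yv, p0=[yv[-1], yv[0], c0],
                                bounds=([-np.inf, -np.inf, 1e-8],
                                        [np.inf, np.inf, np.inf]),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((yv - model(x, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise DomainError("asymptotic regression did not converge from any start")
    rss, (a, b, c) = best
    n = x.size
    sigma2 = max(rss / n, 1e-300)
    log_lik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = 4
    aic = 2 * k - 2 * log_lik
    rse = float(np.sqrt(rss / max(n - 3, 1)))
    return AsymptoticFit(a=float(a), b=float(b), c=float(c), rss=rss, n=n,
                         log_likelihood=float(log_lik), aic=float(aic), rse=rse)


def compare_model_families(x: Sequence[float], y: Sequence[float],
                           extra_models: dict | None = None) -> pd.DataFrame:
    """AIC comparison hook: the asymptotic regression plus any caller-supplied
    model families given as name -> (func(x, *params), p0 list)."""
    rows = []
    fit = fit_asymptotic_regression(x, y)
    rows.append({"model": "asymptotic_regression", "aic": fit.aic,
                 "rse": fit.rse, "log_likelihood": fit.log_likelihood})
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    for name, (func, p0) in (extra_models or {}).items():
        try:
            popt, _ = curve_fit(func, xv, yv, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError):
            rows.append({"model": name, "aic": np.nan, "rse": np.nan,
                         "log_likelihood": np.nan})
            continue
        rss = float(np.sum((yv - func(xv, *popt)) ** 2))
        n = xv.size
        sigma2 = max(rss / n, 1e-300)
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        k = len(p0) + 1
        rows.append({"model": name, "aic": 2 * k - 2 * ll,
                     "rse": float(np.sqrt(rss / max(n - len(p0), 1))),
                     "log_likelihood": ll})
    return pd.DataFrame(rows)


@dataclass
class ThresholdSelection:
    """Outcome of the data-driven threshold choice."""

    decile: int
    threshold: float
    half_life_decile: int
    root_decile: int | None
    growth_decile: int
    consistent: bool
    flagged: bool = False


def _decile_of(x: float) -> int:
    """Decile index (1..10) containing a location on the decile axis, where
    decile d spans (d-1, d]."""
    return int(np.clip(np.ceil(x), 1, 10))


def select_threshold(fit: AsymptoticFit, curve: pd.DataFrame) -> ThresholdSelection:
    """Pick the remapping-threshold decile from the fitted curve's features.

    Each of half-life, root and maximal-relative-growth locus is mapped to
    the decile (on the 1..10 fit axis) containing it; when they agree the
    common (lowest) decile is selected, otherwise the half-life decile is
    used and the selection is flagged.  The returned threshold is the
    empirical upper boundary of the selected decile.
    """
    hl_d = _decile_of(fit.half_life)
    root = fit.root
    root_d = _decile_of(root) if root is not None else None
    growth_d = _decile_of(fit.max_relative_growth())
    candidates = {hl_d, growth_d} | ({root_d} if root_d is not None else set())
    consistent = len(candidates) == 1
    decile = min(candidates) if consistent else hl_d
    flagged = (root is None) or not consistent
    upper = float(curve.loc[curve["decile"] == decile, "upper"].iloc[0])
    return ThresholdSelection(decile=decile, threshold=upper,
                              half_life_decile=hl_d, root_decile=root_d,
                              growth_decile=growth_d, consistent=consistent,
                              flagged=flagged)
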