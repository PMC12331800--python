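"""Signal-detection Weber-fraction fitting, exclusion rules, cue-combination
prediction, and bright-congruent trial selection.

The psychometric model is a lapse-mixed Gaussian signal-detection model for
2AFC magnitude choice::

    P(choose comparison) = Phi((c - s) / sqrt((w s)^2 + (w c)^2)) * .97 + .015

where ``s`` and ``c`` are the standard and comparison magnitudes and ``w``
the Weber fraction: each magnitude is perceived with Gaussian noise whose
SD is proportional to the magnitude, and on a fixed 3% of trials the
observer guesses at random (the .97/.015 lapse constants are part of the
model, not free parameters). The only free parameter per participant x
trial type is ``w``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

__all__ = [
    "ChoiceRecord",
    "WeberFit",
    "AboveChanceResult",
    "choice_probability",
    "fit_weber",
    "combination_prediction",
    "above_chance_filter",
    "outlier_filter",
    "select_bright_congruent",
    "LAPSE_SCALE",
    "LAPSE_FLOOR",
    "AUGMENT_RATIO",
    "W_BOUNDS",
]

LAPSE_SCALE = 0.97
LAPSE_FLOOR = 0.015

#: the regularizing half-trial: ratio 11/12 with the comparison chosen
AUGMENT_RATIO = (11, 12)
AUGMENT_WEIGHT = 0.5

W_BOUNDS = (1e-4, 2.0)
OUTLIER_FACTOR = 3.0


@dataclass
class ChoiceRecord:
    """One behavioral response. ``standard``/``comparison`` hold the
    task-relevant magnitude (area in units for area tasks, dot count for
    number tasks)."""

    participant_id: str
    experiment: str
    condition: str
    standard: float
    comparison: float
    chose_comparison: bool
    is_training: bool = False
    white_fraction_standard: float = float("nan")
    white_fraction_comparison: float = float("nan")
    luminance_standard: float = float("nan")
    luminance_comparison: float = float("nan")
    weight: float = 1.0


@dataclass
class WeberFit:
    participant_id: str
    condition: str
    w: float
    neg_log_lik: float
    n_trials_effective: float
    converged: bool


@dataclass
class AboveChanceResult:
    keep: bool
    p_value: float
    n_correct: int
    n_trials: int


def choice_probability(s, c, w):
    """Probability of choosing the comparison under the lapse-mixed
    signal-detection model. Vectorized over ``s`` and ``c``; bounded in
    [.015, .985] and strictly increasing in ``c``."""
    w = float(w)
    if w <= 0:
        raise ValueError("Weber fraction w must be positive")
    s = np.asarray(s, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(s <= 0) or np.any(c <= 0):
        raise ValueError("magnitudes must be positive")
    sigma = w * np.sqrt(s**2 + c**2)
    p = ndtr((c - s) / sigma) * LAPSE_SCALE + LAPSE_FLOOR
    return p if p.ndim else float(p)


def _records_to_arrays(records):
    if isinstance(records, pd.DataFrame):
        s = records["standard"].to_numpy(float)
        c = records["comparison"].to_numpy(float)
        y = records["chose_comparison"].to_numpy(bool)
        w = (
            records["weight"].to_numpy(float)
            if "weight" in records.columns
            else np.ones(len(records))
        )
        return s, c, y, w
    s = np.array([r.standard for r in records], float)
    c = np.array([r.comparison for r in records], float)
    y = np.array([r.chose_comparison for r in records], bool)
    w = np.array([r.weight for r in records], float)
    return s, c, y, w


def _nll(w, s, c, y, weights):
    p = choice_probability(s, c, w)
    return -float(np.sum(weights * np.where(y, np.log(p), np.log1p(-p))))


def fit_weber(records, augment: bool = True, participant_id=None, condition=None) -> WeberFit:
    """Maximum-likelihood Weber fraction for one participant x trial type.

    ``records`` is a sequence of ChoiceRecord (or an equivalent DataFrame)
    of testing trials only. With ``augment`` (the default), a half-weight
    trial at ratio 11/12 with the comparison chosen is appended before
    fitting; it keeps the likelihood bounded away from the degenerate
    w -> 0 solution when a participant never errs.
    """
    n_in = len(records)
    if n_in == 0:
        raise ValueError("cannot fit an empty record list")
    s, c, y, weights = _records_to_arrays(records)
    if participant_id is None:
        participant_id = (
            str(records["participant_id"].iloc[0])
            if isinstance(records, pd.DataFrame)
            else records[0].participant_id
        )
    if condition is None:
        condition = (
            str(records["condition"].iloc[0])
            if isinstance(records, pd.DataFrame)
            else records[0].condition
        )
    if augment:
        base = float(np.median(s))
        num, den = AUGMENT_RATIO
        s = np.append(s, base)
        c = np.append(c, base * num / den)
        y = np.append(y, True)
        weights = np.append(weights, AUGMENT_WEIGHT)

    res = optimize.minimize_scalar(
        _nll,
        bounds=W_BOUNDS,
        args=(s, c, y, weights),
        method="bounded",
        options={"xatol": 1e-8},
    )
    w_hat, nll, converged = float(res.x), float(res.fun), bool(res.success)
    if not converged or not math.isfinite(nll):
        # coarse-to-fine grid fallback
        grid = np.geomspace(W_BOUNDS[0], W_BOUNDS[1], 4000)
        vals = [_nll(g, s, c, y, weights) for g in grid]
        k = int(np.argmin(vals))
        w_hat, nll, converged = float(grid[k]), float(vals[k]), True
    if not math.isfinite(nll):
        raise RuntimeError(
            f"non-finite likelihood for participant {participant_id!r} / {condition!r}"
        )
    return WeberFit(
        participant_id=str(participant_id),
        condition=str(condition),
        w=w_hat,
        neg_log_lik=nll,
        n_trials_effective=float(np.sum(weights)),
        converged=converged,
    )


def combination_prediction(w_a: float, w_n: float) -> float:
    """Best achievable Weber fraction from optimally fusing two independent
    cues with Weber fractions ``w_a`` and ``w_n``: (w_a^-2 + w_n^-2)^(-1/2).
    Symmetric, and never larger than the better single cue."""
    if w_a <= 0 or w_n <= 0:
        raise ValueError("Weber fractions must be positive")
    return (w_a**-2 + w_n**-2) ** -0.5


def _correct_mask(s, c, y):
    return y == (c > s)


def above_chance_filter(records, alpha: float = 0.05) -> AboveChanceResult:
    """One-sided exact binomial test that a participant's pooled testing
    accuracy exceeds chance (0.5); ``keep`` is True when p <= alpha."""
    s, c, y, _ = _records_to_arrays(records)
    if len(s) == 0:
        raise ValueError("no records to test")
    k = int(np.sum(_correct_mask(s, c, y)))
    n = len(s)
    p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    return AboveChanceResult(keep=bool(p <= alpha), p_value=float(p), n_correct=k, n_trials=n)


def outlier_filter(fits, scope: str = "observation") -> np.ndarray:
    """Keep-mask over fitted Weber fractions: per condition, a fit is an
    outlier when w is strictly more than three times the condition median
    (computed once over all supplied fits). ``observation`` scope drops the
    offending fit only; ``participant`` scope drops every fit of any
    participant with at least one offending fit."""
    if scope not in ("observation", "participant"):
        raise ValueError(f"unknown scope {scope!r}")
    fits = list(fits)
    conds = np.array([f.condition for f in fits])
    ws = np.array([f.w for f in fits], float)
    keep = np.ones(len(fits), bool)
    for cond in np.unique(conds):
        m = conds == cond
        keep[m] = ws[m] <= OUTLIER_FACTOR * np.median(ws[m])
    if scope == "participant":
        pids = np.array([f.participant_id for f in fits])
        for pid in np.unique(pids[~keep]):
            keep[pids == pid] = False
    return keep


def _lum_arrays(records):
    if isinstance(records, pd.DataFrame):
        return (
            records["lum_std"].to_numpy(float)
            if "lum_std" in records.columns
            else records["luminance_standard"].to_numpy(float),
            records["lum_cmp"].to_numpy(float)
            if "lum_cmp" in records.columns
            else records["luminance_comparison"].to_numpy(float),
        )
    return (
        np.array([r.luminance_standard for r in records], float),
        np.array([r.luminance_comparison for r in records], float),
    )


def select_bright_congruent(records):
    """Subset of area_number testing trials whose larger-area side also has
    the higher mean luminance.

    Note the selection is on luminance, not on white-dot counts: a side can
    hold more white dots yet be darker because its white *percentage* and
    square geometry matter, so this is not "every trial with more white
    dots on the larger side".
    """
    is_df = isinstance(records, pd.DataFrame)
    if is_df:
        sub = records[(records["condition"] == "area_number") & (~records["is_training"].astype(bool))]
        s = sub["standard"].to_numpy(float)
        c = sub["comparison"].to_numpy(float)
    else:
        sub = [r for r in records if r.condition == "area_number" and not r.is_training]
        s = np.array([r.standard for r in sub], float)
        c = np.array([r.comparison for r in sub], float)
    lum_s, lum_c = _lum_arrays(sub)
    if len(s) and (np.isnan(lum_s).any() or np.isnan(lum_c).any()):
        raise ValueError(
            "luminance metadata missing; recompute it with stimulus_design.mean_luminance"
        )
    larger_is_cmp = c > s
    lum_larger = np.where(larger_is_cmp, lum_c, lum_s)
    lum_smaller = np.where(larger_is_cmp, lum_s, lum_c)
    mask = lum_larger > lum_smaller
    if is_df:
        return sub[mask]
    return [r for r, m in zip(sub, mask) if m]
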