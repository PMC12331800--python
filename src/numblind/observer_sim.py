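"""Synthetic 2AFC observers embodying the two competing perceptual
architectures.

A *number-primary* observer estimates area and number as independent
primary dimensions: on density-equated trials the two cues carry
independent noise, so fusing them improves discrimination toward the
inverse-variance combination bound. A *density-primary* observer estimates
area and density, deriving each side's number estimate as density x area;
its "number" cue on density-equated trials is then essentially a noisy
photocopy of the area cue, and fusing the two cannot help (the extra
density noise can even hurt).

Each magnitude m is perceived as m(1 + w z) with z ~ N(0, 1) — Gaussian
noise with SD proportional to the magnitude (Weber noise). On a fraction
``lapse_rate`` of trials the observer guesses at random. All decision
variables are inverse-variance-weighted evidence:

    area task      dA / var(dA)
    number task    dN / var(dN)
    area & number  dA / var(dA) + dN / var(dN)      (+ brightness term)

where dA, dN are perceived comparison-minus-standard differences and the
variances are the observer's channel reliabilities. An optional
``brightness_weight`` adds evidence proportional to the luminance
difference, modeling incidental cross-magnitude influence of brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .psychofit import ChoiceRecord
from . import stimulus_design as sd

__all__ = [
    "ObserverParams",
    "CohortConfig",
    "simulate_choice",
    "simulate_cohort",
    "analytic_choice_probability",
    "latent_evidence",
    "number_primary_observer",
    "density_primary_observer",
]

ARCHITECTURES = ("number_primary", "density_primary")


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated observer. Exactly the
    architecture-appropriate noise parameter must be set: ``w_number`` for
    number_primary, ``w_density`` for density_primary."""

    architecture: str
    w_area: float
    w_number: float | None = None
    w_density: float | None = None
    lapse_rate: float = 0.03
    brightness_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.w_area <= 0:
            raise ValueError("w_area must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if self.architecture == "number_primary":
            if self.w_number is None or self.w_number <= 0:
                raise ValueError("number_primary requires w_number > 0")
            if self.w_density is not None:
                raise ValueError("number_primary must not set w_density")
        else:
            if self.w_density is None or self.w_density <= 0:
                raise ValueError("density_primary requires w_density > 0")
            if self.w_number is not None:
                raise ValueError("density_primary must not set w_number")

    @property
    def w_number_effective(self) -> float:
        """Weber fraction of the number channel as the observer's fusion
        stage weighs it: w_number directly, or sqrt(w_area^2 + w_density^2)
        for a derived (density x area) number estimate."""
        if self.architecture == "number_primary":
            return float(self.w_number)
        return float(np.hypot(self.w_area, self.w_density))


def number_primary_observer(
    w_area: float = 0.074, w_number: float = 0.13, **kw
) -> ObserverParams:
    return ObserverParams("number_primary", w_area=w_area, w_number=w_number, **kw)


def density_primary_observer(
    w_area: float = 0.074, w_density: float = 0.105, **kw
) -> ObserverParams:
    return ObserverParams("density_primary", w_area=w_area, w_density=w_density, **kw)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation settings. ``heterogeneity`` is the SD of the
    log of each Weber fraction across participants (log-normal, keeping
    fractions positive)."""

    n_participants: int
    seed: int
    heterogeneity: float = 0.3
    experiment: str = "exp1"
    full_stimuli: bool = False
    dot_area: float = sd.DEFAULT_DOT_AREA

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        if self.experiment not in sd.EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")


def _perceived(m, w, rng):
    return m * (1.0 + w * rng.standard_normal(np.shape(m)))


def _latent(observer, area_s, area_c, num_s, num_c, rng):
    """Perceived area and number differences (comparison - standard)."""
    a_s = _perceived(area_s, observer.w_area, rng)
    a_c = _perceived(area_c, observer.w_area, rng)
    if observer.architecture == "number_primary":
        n_s = _perceived(num_s, observer.w_number, rng)
        n_c = _perceived(num_c, observer.w_number, rng)
    else:
        d_s = _perceived(num_s / area_s, observer.w_density, rng)
        d_c = _perceived(num_c / area_c, observer.w_density, rng)
        n_s = d_s * a_s  # derived number re-uses the same side's area estimate
        n_c = d_c * a_c
    return a_c - a_s, n_c - n_s


def latent_evidence(observer, area_s, area_c, num_s, num_c, n: int, rng):
    """Draw ``n`` paired (area-difference, number-difference) latent signals
    for one stimulus; exposes the photocopy mechanism (their correlation is
    high for density_primary observers, near zero for number_primary)."""
    shape = np.broadcast_shapes(np.shape(area_s), (n,))
    area_s, area_c = np.broadcast_to(area_s, shape), np.broadcast_to(area_c, shape)
    num_s, num_c = np.broadcast_to(num_s, shape), np.broadcast_to(num_c, shape)
    return _latent(observer, area_s, area_c, num_s, num_c, rng)


def _channel_variances(observer, area_s, area_c, num_s, num_c):
    va = observer.w_area**2 * (np.asarray(area_s, float) ** 2 + np.asarray(area_c, float) ** 2)
    wn = observer.w_number_effective
    vn = wn**2 * (np.asarray(num_s, float) ** 2 + np.asarray(num_c, float) ** 2)
    return va, vn


def _decide(observer, condition, area_s, area_c, num_s, num_c, lum_s, lum_c, rng):
    """Vectorized choice simulation; returns a boolean chose-comparison array."""
    condition = np.asarray(condition)
    area_s = np.asarray(area_s, float)
    area_c = np.asarray(area_c, float)
    num_s = np.asarray(num_s, float)
    num_c = np.asarray(num_c, float)
    da, dn = _latent(observer, area_s, area_c, np.maximum(num_s, 1e-12), np.maximum(num_c, 1e-12), rng)
    va, vn = _channel_variances(
        observer, area_s, area_c, np.maximum(num_s, 1e-12), np.maximum(num_c, 1e-12)
    )
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # unselected np.where branches may evaluate on degenerate magnitudes
        dv = np.where(
            condition == "area_only",
            da / va,
            np.where(condition == "number_only", dn / vn, da / va + dn / vn),
        )
    if observer.brightness_weight != 0.0:
        dlum = np.nan_to_num(np.asarray(lum_c, float) - np.asarray(lum_s, float))
        dv = dv + observer.brightness_weight * dlum
    choice = dv > 0
    ties = dv == 0
    if np.any(ties):
        choice = np.where(ties, rng.random(choice.shape) < 0.5, choice)
    if observer.lapse_rate > 0:
        lapse = rng.random(choice.shape) < observer.lapse_rate
        choice = np.where(lapse, rng.random(choice.shape) < 0.5, choice)
    return choice


def analytic_choice_probability(observer, condition, area_s, area_c, num_s=None, num_c=None):
    """Closed-form P(choose comparison) for channels that are independent
    (any area_only trial; number_primary observers on all trial types).

    The fused decision variable dA/va + dN/vn is Gaussian with mean
    dA_true/va + dN_true/vn and variance 1/va + 1/vn, so the choice
    probability is a normal CDF, mixed with the lapse coin-flip. Raises for
    density_primary dot trials, where the channels are correlated (use
    Monte Carlo there)."""
    if condition == "area_only":
        va = observer.w_area**2 * (area_s**2 + area_c**2)
        z = (area_c - area_s) / np.sqrt(va)
    else:
        if observer.architecture != "number_primary":
            raise NotImplementedError(
                "no closed form for density_primary dot trials (correlated channels)"
            )
        va, vn = _channel_variances(observer, area_s, area_c, num_s, num_c)
        if condition == "number_only":
            z = (num_c - num_s) / np.sqrt(vn)
        elif condition == "area_number":
            mean = (area_c - area_s) / va + (num_c - num_s) / vn
            z = mean / np.sqrt(1.0 / va + 1.0 / vn)
        else:
            raise ValueError(f"unknown condition {condition!r}")
    p = ndtr(z)
    return p * (1.0 - observer.lapse_rate) + 0.5 * observer.lapse_rate


def _pair_magnitudes(pair) -> tuple:
    spec = pair.spec
    return (
        pair.standard.square_area,
        pair.comparison.square_area,
        pair.standard.n_dots,
        pair.comparison.n_dots,
    )


def simulate_choice(pair, observer: ObserverParams, rng) -> ChoiceRecord:
    """Simulate one response to a StimulusPair; luminance is computed only
    when the observer actually weighs brightness."""
    rng = np.random.default_rng(rng)
    area_s, area_c, num_s, num_c = _pair_magnitudes(pair)
    if observer.brightness_weight != 0.0:
        lum_s = sd.mean_luminance(pair.standard)
        lum_c = sd.mean_luminance(pair.comparison)
    else:
        lum_s = lum_c = np.nan
    spec = pair.spec
    choice = _decide(
        observer,
        np.array([spec.condition]),
        [area_s],
        [area_c],
        [num_s],
        [num_c],
        [lum_s],
        [lum_c],
        rng,
    )[0]
    if spec.condition == "number_only":
        s_mag, c_mag = float(num_s), float(num_c)
    else:
        s_mag, c_mag = float(area_s), float(area_c)
    return ChoiceRecord(
        participant_id="sim",
        experiment=spec.experiment,
        condition=spec.condition,
        standard=s_mag,
        comparison=c_mag,
        chose_comparison=bool(choice),
        is_training=spec.is_training,
        white_fraction_standard=pair.standard.white_fraction,
        white_fraction_comparison=pair.comparison.white_fraction,
        luminance_standard=float(lum_s),
        luminance_comparison=float(lum_c),
    )


def _draw_participant(template: ObserverParams, heterogeneity: float, rng) -> ObserverParams:
    def jitter(w):
        return float(w * np.exp(heterogeneity * rng.standard_normal()))

    kw = dict(
        architecture=template.architecture,
        w_area=jitter(template.w_area),
        lapse_rate=template.lapse_rate,
        brightness_weight=template.brightness_weight,
    )
    if template.architecture == "number_primary":
        kw["w_number"] = jitter(template.w_number)
    else:
        kw["w_density"] = jitter(template.w_density)
    return ObserverParams(**kw)


def _analytic_side_luminance(square_area, n_dots, n_white, condition, experiment, dot_area):
    """Whole-side mean luminance from composition alone (dot positions do
    not affect the area-weighted mean)."""
    if experiment == "exp1":
        lum_bg, lum_sq = 0.5, float(np.mean(sd.EXP1_SQUARE_RGB))
        dots_sum = n_white * dot_area  # white 1, black 0
    else:
        lum_bg = (
            0.5 if condition == "number_only" else float(np.mean(sd.EXP2_BACKGROUND_RGB))
        )
        lum_sq = 0.5
        dots_sum = 0.5 * n_dots * dot_area  # ring dots
    drawn = condition != "number_only"
    sq = lum_sq if drawn else lum_bg
    total = (
        (sd.VOID_AREA - square_area) * lum_bg
        + (square_area - n_dots * dot_area) * sq
        + dots_sum
    )
    return total / sd.VOID_AREA


def _fast_block(condition, experiment, observer, dot_area, rng):
    """One simulated block without explicit dot geometry: magnitudes, color
    composition and analytic luminance only. Trial order is randomized the
    same way as build_block_schedule (training first)."""
    counts = (
        sd.TESTING_COUNTS_UNIFORM if condition == "number_only" else sd.TESTING_COUNTS_SKEWED
    )
    nums, training, inverted = [], [], []
    for n in sd.RATIO_NUMERATORS:
        nums.append(n)
        training.append(True)
        inverted.append(bool(rng.integers(2)) if condition == "number_only" else False)
    for n, k in counts.items():
        for i in range(k):
            nums.append(n)
            training.append(False)
            inverted.append((i % 2 == 1) if condition == "number_only" else False)
    nums = np.array(nums)
    training = np.array(training)
    inverted = np.array(inverted)
    order = np.concatenate([rng.permutation(7), 7 + rng.permutation(len(nums) - 7)])
    nums, training, inverted = nums[order], training[order], inverted[order]

    ratio = nums / sd.RATIO_DENOMINATOR
    area_s = np.full(len(nums), sd.STANDARD_AREA)
    if condition == "area_only":
        area_c = ratio * sd.STANDARD_AREA
        dots_s = np.zeros(len(nums), int)
        dots_c = np.zeros(len(nums), int)
    elif condition == "number_only":
        area_ratio = np.where(inverted, 1.0 / ratio, ratio)
        area_c = area_ratio * sd.STANDARD_AREA
        dots_s = np.full(len(nums), sd.STANDARD_DOTS)
        dots_c = np.rint(ratio * sd.STANDARD_DOTS).astype(int)
    else:
        area_c = ratio * sd.STANDARD_AREA
        dots_s = np.full(len(nums), sd.STANDARD_DOTS)
        dots_c = np.rint(ratio * sd.STANDARD_DOTS).astype(int)

    def white_counts(n_dots):
        if experiment == "exp2" or condition == "area_only":
            wf = np.where(n_dots > 0, 0.5, np.nan) if experiment == "exp2" else np.full(len(n_dots), np.nan)
            return np.zeros(len(n_dots), int), wf
        frac = rng.uniform(*sd.WHITE_FRACTION_RANGE, size=len(n_dots))
        n_white = np.rint(frac * n_dots).astype(int)
        with np.errstate(invalid="ignore"):
            realized = np.where(n_dots > 0, n_white / np.maximum(n_dots, 1), np.nan)
        return n_white, realized

    nw_s, wf_s = white_counts(dots_s)
    nw_c, wf_c = white_counts(dots_c)
    lum_s = _analytic_side_luminance(area_s, dots_s, nw_s, condition, experiment, dot_area)
    lum_c = _analytic_side_luminance(area_c, dots_c, nw_c, condition, experiment, dot_area)

    cond_arr = np.full(len(nums), condition, dtype=object)
    choice = _decide(observer, cond_arr, area_s, area_c, dots_s, dots_c, lum_s, lum_c, rng)
    if condition == "number_only":
        s_mag, c_mag = dots_s.astype(float), dots_c.astype(float)
    else:
        s_mag, c_mag = area_s, area_c
    return pd.DataFrame(
        {
            "condition": condition,
            "is_training": training,
            "ratio_num": nums,
            "ratio_den": sd.RATIO_DENOMINATOR,
            "standard": s_mag,
            "comparison": c_mag,
            "chose_comparison": choice,
            "correct": choice == (c_mag > s_mag),
            "white_frac_std": wf_s,
            "white_frac_cmp": wf_c,
            "lum_std": lum_s,
            "lum_cmp": lum_c,
        }
    )


def _geometry_block(pairs, observer, rng):
    rows = []
    for pair in pairs:
        rec = simulate_choice(pair, observer, rng)
        if np.isnan(rec.luminance_standard):
            rec.luminance_standard = sd.mean_luminance(pair.standard)
            rec.luminance_comparison = sd.mean_luminance(pair.comparison)
        rows.append(
            {
                "condition": rec.condition,
                "is_training": rec.is_training,
                "ratio_num": pair.spec.ratio_num,
                "ratio_den": pair.spec.ratio_den,
                "standard": rec.standard,
                "comparison": rec.comparison,
                "chose_comparison": rec.chose_comparison,
                "correct": rec.chose_comparison == (rec.comparison > rec.standard),
                "white_frac_std": rec.white_fraction_standard,
                "white_frac_cmp": rec.white_fraction_comparison,
                "lum_std": rec.luminance_standard,
                "lum_cmp": rec.luminance_comparison,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: CohortConfig, observer_template: ObserverParams) -> pd.DataFrame:
    """Simulate a full cohort: one session (three 49-trial blocks, block
    order randomized) per participant, per-participant Weber fractions drawn
    log-normally around the template. Returns the trial-level ChoiceTable.

    By default magnitudes and luminances are drawn analytically, without
    explicit dot placement (positions never enter the decision model);
    ``full_stimuli=True`` runs the complete geometric stimulus generator
    including area_number square re-use.
    """
    root = np.random.default_rng(config.seed)
    tables = []
    for p in range(config.n_participants):
        rng = np.random.default_rng(root.integers(2**31))
        observer = _draw_participant(observer_template, config.heterogeneity, rng)
        block_order = list(rng.permutation(np.array(sd.CONDITIONS)))
        blocks = []
        if config.full_stimuli:
            session = sd.build_session_stimuli(
                config.experiment, int(rng.integers(2**31)), dot_area=config.dot_area
            )
            for cond in block_order:
                blocks.append(_geometry_block(session[cond], observer, rng))
        else:
            for cond in block_order:
                blocks.append(
                    _fast_block(cond, config.experiment, observer, config.dot_area, rng)
                )
        table = pd.concat(blocks, ignore_index=True)
        table.insert(0, "participant_id", f"p{p:03d}")
        table.insert(1, "experiment", config.experiment)
        table.insert(4, "trial_index", np.arange(len(table)))
        tables.append(table)
    out = pd.concat(tables, ignore_index=True)
    cols = [
        "participant_id",
        "experiment",
        "condition",
        "trial_index",
        "is_training",
        "ratio_num",
        "ratio_den",
        "standard",
        "comparison",
        "chose_comparison",
        "correct",
        "white_frac_std",
        "white_frac_cmp",
        "lum_std",
        "lum_cmp",
    ]
    return out[cols]
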