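"""Trial schedules and abstract stimulus descriptors for 2AFC magnitude-choice displays.

A session has three blocks, one per trial type:

``area_only``
    Which of two rotated squares has the larger area? No dots.
``number_only``
    Which of two dot sets has more dots? The dots are confined to an
    *undrawn* square; on half of the testing trials the constraining
    area covaries with number, on the other half it is inverted, so
    number cannot be read off the occupied area alone.
``area_number``
    An area judgement in which the comparison's dot count matches its
    area ratio exactly, holding dot density equal on both sides.

All sizes are in abstract area units: the void (one half of the display)
has area 32, the standard square area 12, and the standard dot count 12.
Comparison/standard ratios span 9/12 to 16/12, excluding 1, keeping every
display above the subitizing range (>= 9 dots) and below texture-like
densities (<= 16 dots).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "TrialSpec",
    "StimulusSide",
    "StimulusPair",
    "DotPlacementError",
    "build_block_schedule",
    "make_stimulus_pair",
    "build_session_stimuli",
    "mean_luminance",
    "pairs_to_jsonl",
    "schedule_to_csv",
    "RATIO_NUMERATORS",
    "RATIO_DENOMINATOR",
    "VOID_AREA",
    "STANDARD_AREA",
    "STANDARD_DOTS",
    "DEFAULT_DOT_AREA",
]

CONDITIONS = ("area_only", "number_only", "area_number")
EXPERIMENTS = ("exp1", "exp2")

RATIO_NUMERATORS = (9, 10, 11, 13, 14, 15, 16)
RATIO_DENOMINATOR = 12

VOID_AREA = 32.0
STANDARD_AREA = 12.0
STANDARD_DOTS = 12

#: testing-trial counts per ratio numerator for area_only / area_number blocks:
#: lowest two ratios 3 each, the two nearest to 1 get 12 each, highest three 4 each.
TESTING_COUNTS_SKEWED = {9: 3, 10: 3, 11: 12, 13: 12, 14: 4, 15: 4, 16: 4}
#: number_only blocks distribute 42 testing trials evenly, 6 per ratio.
TESTING_COUNTS_UNIFORM = {n: 6 for n in RATIO_NUMERATORS}

N_TRAINING = 7
N_TESTING = 42

WHITE_FRACTION_RANGE = (0.20, 0.80)
DEFAULT_DOT_AREA = 0.05  # units^2; 16 such dots always fit the smallest (9-unit) square
MAX_PLACEMENT_ATTEMPTS = 10_000

# colors as RGB in [0, 1]
EXP1_SQUARE_RGB = (0.25, 0.25, 0.50)  # HSV (2/3, 1/2, 1/2): mid blue
EXP1_BACKGROUND_RGB = (0.5, 0.5, 0.5)  # mid grey void
EXP2_SQUARE_RGB = (0.5, 0.5, 0.5)
EXP2_BACKGROUND_RGB = (38 / 255, 132 / 255, 212 / 255)  # lightness-matched blue-green
EXP2_NUMBER_BACKGROUND_RGB = (0.5, 0.5, 0.5)

# presentation timing, retained as metadata only (ms)
FIXATION_MS = 1000
PRESENTATION_MS = 500
FEEDBACK_CORRECT_MS = 250
FEEDBACK_INCORRECT_MS = 2000


class DotPlacementError(RuntimeError):
    """Raised when non-overlapping dot placement fails; the dot area is too
    large for the smallest constraining square."""


@dataclass(frozen=True)
class TrialSpec:
    """Abstract description of one 2AFC trial.

    ``area_ratio_inverted`` applies to number_only trials only: when True
    the constraining-square area ratio is the reciprocal of the dot-count
    ratio.
    """

    condition: str
    ratio_num: int
    is_training: bool
    experiment: str
    comparison_side: str = "left"
    ratio_den: int = RATIO_DENOMINATOR
    standard_area: float = STANDARD_AREA
    standard_dots: int = STANDARD_DOTS
    area_ratio_inverted: bool = False
    trial_index: int = -1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.ratio_num not in RATIO_NUMERATORS or self.ratio_den != RATIO_DENOMINATOR:
            raise ValueError(
                f"ratio {self.ratio_num}/{self.ratio_den} outside the design set"
            )
        if self.comparison_side not in ("left", "right"):
            raise ValueError(f"comparison_side must be left/right, got {self.comparison_side!r}")

    @property
    def ratio(self) -> float:
        return self.ratio_num / self.ratio_den


@dataclass
class StimulusSide:
    """One half of a display: a (possibly undrawn) rotated square in a void,
    optionally filled with non-overlapping dots.

    ``dots`` holds (x, y, color) with color in {"white", "black", "ring"};
    a ring dot is a white disc inside a black annulus of equal area, mean
    luminance 0.5 by construction. Coordinates are in display units with
    the square centered at the origin.
    """

    square_area: float
    square_rotation: float
    square_drawn: bool
    dots: list = field(default_factory=list)
    white_fraction: float = float("nan")
    background_color: tuple = EXP1_BACKGROUND_RGB
    square_color: tuple = EXP1_SQUARE_RGB
    dot_area: float = DEFAULT_DOT_AREA

    @property
    def n_dots(self) -> int:
        return len(self.dots)


@dataclass
class StimulusPair:
    standard: StimulusSide
    comparison: StimulusSide
    spec: TrialSpec


def _testing_counts(condition: str) -> dict:
    return TESTING_COUNTS_UNIFORM if condition == "number_only" else TESTING_COUNTS_SKEWED


def build_block_schedule(condition: str, experiment: str, seed: int) -> list:
    """Return the 49 TrialSpecs of one block: 7 training trials (one per
    ratio) followed by 42 testing trials, each sub-list in randomized order
    with randomized comparison side.

    For number_only blocks, the 6 testing trials at each ratio split 3/3
    between congruent and inverted constraining-square area; training trials
    flip a fair coin.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    rng = np.random.default_rng(seed)

    def spec(ratio_num, training, inverted):
        return dict(
            condition=condition,
            ratio_num=ratio_num,
            is_training=training,
            experiment=experiment,
            area_ratio_inverted=inverted,
        )

    training = []
    for num in RATIO_NUMERATORS:
        inv = bool(rng.integers(2)) if condition == "number_only" else False
        training.append(spec(num, True, inv))
    testing = []
    for num, count in _testing_counts(condition).items():
        for i in range(count):
            inv = (i % 2 == 1) if condition == "number_only" else False
            testing.append(spec(num, False, inv))

    rng.shuffle(training)
    rng.shuffle(testing)
    out = []
    for idx, d in enumerate(training + testing):
        side = "left" if rng.integers(2) else "right"
        out.append(TrialSpec(comparison_side=side, trial_index=idx, **d))
    return out


def _comparison_geometry(spec: TrialSpec) -> tuple:
    """(square_area, n_dots) of the comparison side implied by a TrialSpec."""
    ratio = spec.ratio
    if spec.condition == "area_only":
        return ratio * spec.standard_area, 0
    n_dots = round(ratio * spec.standard_dots)
    if spec.condition == "number_only":
        area_ratio = 1.0 / ratio if spec.area_ratio_inverted else ratio
        return area_ratio * spec.standard_area, n_dots
    return ratio * spec.standard_area, n_dots  # area_number: density-equating


def _place_dots(n: int, square_area: float, dot_area: float, rng) -> np.ndarray:
    """Rejection-sample n non-overlapping dot centers with every disc fully
    inside the axis-aligned square (rotation is applied afterwards)."""
    if n == 0:
        return np.empty((0, 2))
    r = math.sqrt(dot_area / math.pi)
    half = math.sqrt(square_area) / 2.0 - r
    if half <= 0:
        raise DotPlacementError(
            f"dot radius {r:.4g} does not fit a square of area {square_area:.4g}"
        )
    centers = np.empty((n, 2))
    placed = 0
    for _ in range(MAX_PLACEMENT_ATTEMPTS):
        cand = rng.uniform(-half, half, size=2)
        if placed and np.any(np.sum((centers[:placed] - cand) ** 2, axis=1) <= (2 * r) ** 2):
            continue
        centers[placed] = cand
        placed += 1
        if placed == n:
            return centers
    raise DotPlacementError(
        f"placed {placed}/{n} dots after {MAX_PLACEMENT_ATTEMPTS} attempts; "
        f"dot_area={dot_area} too large for square_area={square_area}"
    )


def _side_colors(spec: TrialSpec) -> tuple:
    if spec.experiment == "exp1":
        return EXP1_BACKGROUND_RGB, EXP1_SQUARE_RGB
    if spec.condition == "number_only":
        return EXP2_NUMBER_BACKGROUND_RGB, EXP2_SQUARE_RGB
    return EXP2_BACKGROUND_RGB, EXP2_SQUARE_RGB


def _build_side(
    spec: TrialSpec,
    square_area: float,
    n_dots: int,
    rng,
    dot_area: float,
    rotation: float | None = None,
) -> StimulusSide:
    if square_area > VOID_AREA:
        raise ValueError(f"square_area {square_area} exceeds the void area {VOID_AREA}")
    if rotation is None:
        rotation = float(rng.uniform(0.0, math.pi / 2.0))  # square symmetry
    background, square_color = _side_colors(spec)
    side = StimulusSide(
        square_area=float(square_area),
        square_rotation=rotation,
        square_drawn=spec.condition != "number_only",
        background_color=background,
        square_color=square_color,
        dot_area=dot_area,
    )
    if n_dots == 0:
        return side
    local = _place_dots(n_dots, square_area, dot_area, rng)
    cos, sin = math.cos(rotation), math.sin(rotation)
    xy = local @ np.array([[cos, sin], [-sin, cos]])
    if spec.experiment == "exp2":
        colors = ["ring"] * n_dots
        side.white_fraction = 0.5  # ring dots are half white by area
    else:
        frac = float(rng.uniform(*WHITE_FRACTION_RANGE))
        n_white = int(round(frac * n_dots))
        colors = ["white"] * n_white + ["black"] * (n_dots - n_white)
        rng.shuffle(colors)
        side.white_fraction = n_white / n_dots
    side.dots = [(float(x), float(y), c) for (x, y), c in zip(xy, colors)]
    return side


def make_stimulus_pair(
    spec: TrialSpec,
    seed: int | None = None,
    rng=None,
    dot_area: float = DEFAULT_DOT_AREA,
    square_rotations: tuple | None = None,
) -> StimulusPair:
    """Realize a TrialSpec as a concrete standard/comparison display pair.

    ``square_rotations=(standard, comparison)`` re-uses square geometry, as
    area_number trials re-use the squares of their paired area_only trials.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rot_s, rot_c = square_rotations if square_rotations is not None else (None, None)
    cmp_area, cmp_dots = _comparison_geometry(spec)
    std_dots = 0 if spec.condition == "area_only" else spec.standard_dots
    standard = _build_side(spec, spec.standard_area, std_dots, rng, dot_area, rot_s)
    comparison = _build_side(spec, cmp_area, cmp_dots, rng, dot_area, rot_c)
    return StimulusPair(standard=standard, comparison=comparison, spec=spec)


def build_session_stimuli(
    experiment: str, seed: int, dot_area: float = DEFAULT_DOT_AREA
) -> dict:
    """Generate all three blocks of one session, pairing each area_number
    trial with the area_only trial of the same ratio and within-ratio index
    so that it re-uses that trial's square rotations.

    Returns {condition: list[StimulusPair]}.
    """
    root = np.random.default_rng(seed)
    seeds = root.integers(2**31, size=4)
    out = {}
    for cond, s in zip(("area_only", "number_only"), seeds[:2]):
        rng = np.random.default_rng(s)
        out[cond] = [
            make_stimulus_pair(t, rng=rng, dot_area=dot_area)
            for t in build_block_schedule(cond, experiment, int(s))
        ]
    # index area_only squares by (ratio, occurrence among same-role trials)
    rotations: dict = {}
    for pair in out["area_only"]:
        key = (pair.spec.ratio_num, pair.spec.is_training)
        rotations.setdefault(key, []).append(
            (pair.standard.square_rotation, pair.comparison.square_rotation)
        )
    seen: dict = {}
    rng = np.random.default_rng(seeds[2])
    schedule = build_block_schedule("area_number", experiment, int(seeds[3]))
    block = []
    for t in schedule:
        key = (t.ratio_num, t.is_training)
        i = seen.get(key, 0)
        seen[key] = i + 1
        block.append(
            make_stimulus_pair(t, rng=rng, dot_area=dot_area, square_rotations=rotations[key][i])
        )
    out["area_number"] = block
    return out


def _scalar_luminance(rgb, model: str) -> float:
    if model == "rgb_mean":
        return float(np.mean(rgb))
    if model == "cielab_L":
        from skimage.color import rgb2lab  # local import: only this model needs it

        return float(rgb2lab(np.asarray(rgb, dtype=float).reshape(1, 1, 3))[0, 0, 0]) / 100.0
    raise ValueError(f"unknown luminance model {model!r}")


_DOT_LUM = {"white": 1.0, "black": 0.0}


def mean_luminance(
    side: StimulusSide,
    model: str = "rgb_mean",
    dot_area: float | None = None,
    region: str = "whole",
) -> float:
    """Analytic area-weighted mean luminance of one display side.

    The void (area 32) is background, the square region square-colored when
    drawn, and each dot replaces ``dot_area`` units with its own luminance
    (white 1, black 0; ring dots 0.5 because their white disc and black
    annulus have equal area — under ``cielab_L`` the ring is likewise the
    mean of white and black L*). ``region="square"`` averages over the
    square only; the default averages the whole side.
    """
    if dot_area is None:
        dot_area = side.dot_area
    if dot_area <= 0:
        raise ValueError("dot_area must be positive")
    lum_bg = _scalar_luminance(side.background_color, model)
    lum_sq = _scalar_luminance(side.square_color, model) if side.square_drawn else lum_bg
    white = _scalar_luminance((1.0, 1.0, 1.0), model)
    black = _scalar_luminance((0.0, 0.0, 0.0), model)
    dot_lum = {"white": white, "black": black, "ring": 0.5 * (white + black)}
    dots_total = side.n_dots * dot_area
    dots_sum = sum(dot_lum[c] * dot_area for _, _, c in side.dots)
    if region == "square":
        total = (side.square_area - dots_total) * lum_sq + dots_sum
        return total / side.square_area
    if region != "whole":
        raise ValueError(f"unknown region {region!r}")
    total = (
        (VOID_AREA - side.square_area) * lum_bg
        + (side.square_area - dots_total) * lum_sq
        + dots_sum
    )
    return total / VOID_AREA


def _pair_dict(pair: StimulusPair) -> dict:
    d = {"spec": asdict(pair.spec)}
    for role in ("standard", "comparison"):
        side = getattr(pair, role)
        d[role] = {
            "square_area": side.square_area,
            "square_rotation": side.square_rotation,
            "square_drawn": side.square_drawn,
            "white_fraction": side.white_fraction,
            "background_color": list(side.background_color),
            "square_color": list(side.square_color),
            "dot_area": side.dot_area,
            "dots": [[x, y, c] for x, y, c in side.dots],
        }
    return d


def pairs_to_jsonl(pairs, path) -> None:
    """Serialize stimulus pairs as JSON-lines, one pair per line; output is
    byte-identical for identical inputs (sorted keys, repr floats)."""
    with open(path, "w") as fh:
        for pair in pairs:
            fh.write(json.dumps(_pair_dict(pair), sort_keys=True) + "\n")


def schedule_to_csv(specs, path, seed: int) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["trial_index", "condition", "ratio_num", "ratio_den", "is_training", "comparison_side", "seed"]
        )
        for t in specs:
            writer.writerow(
                [t.trial_index, t.condition, t.ratio_num, t.ratio_den, int(t.is_training), t.comparison_side, seed]
            )
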