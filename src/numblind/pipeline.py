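"""End-to-end analysis pipeline for trial-level 2AFC choice tables.

The chain mirrors the pre-registered analysis: drop training trials, drop
participants not above chance (pooled exact binomial), fit the lapse-mixed
signal-detection Weber fraction per participant x trial type (with the
regularizing half-trial), optionally refit the bright-congruent subset of
area & number trials, apply the 3x-median outlier rule, derive each
participant's cue-combination prediction from their own area-only and
number-only fits (never from aggregated fits), then run the one-sided
paired t-tests and one-sided JZS Bayes factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import psychofit as pf
from . import inference as inf
from . import stimulus_design as sd

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "CANONICAL_COLUMNS",
    "read_choice_csv",
    "write_choice_csv",
    "validate_choice_table",
    "run_analysis",
    "summary_table",
    "plot_psychometric",
]

CANONICAL_COLUMNS = [
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

REQUIRED_COLUMNS = CANONICAL_COLUMNS[:10]

BRIGHT_LABEL = "bright_congruent"


@dataclass
class AnalysisConfig:
    """Analysis settings; defaults reproduce the pre-registered chain.

    ``outlier_scope`` None resolves to observation-level for exp1-style
    analyses and participant-level for exp2-style. Bright-congruent
    selection runs only where luminance metadata exists (and by default
    only for exp1, whose black/white dot mix actually varies brightness).
    """

    experiment: str = "exp1"
    alpha: float = 0.05
    augment: bool = True
    outlier_scope: str | None = None
    include_bright_congruent: bool | None = None
    prior_scale: float = 0.707
    luminance_region: str = "whole"

    def resolved_outlier_scope(self) -> str:
        if self.outlier_scope is not None:
            return self.outlier_scope
        return "observation" if self.experiment == "exp1" else "participant"

    def resolved_bright(self) -> bool:
        if self.include_bright_congruent is not None:
            return self.include_bright_congruent
        return self.experiment == "exp1"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "AnalysisConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class AnalysisReport:
    n_input_participants: int
    n_analysed_participants: int
    summaries: dict
    tests: dict
    exclusions: list
    config: dict
    fits: list = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)


def validate_choice_table(df: pd.DataFrame) -> None:
    """Schema validation; raises ValueError naming offending columns/rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choice table is missing required columns: {missing}")
    bad_cond = df.loc[~df["condition"].isin(sd.CONDITIONS)]
    if len(bad_cond):
        raise ValueError(
            f"unknown condition values at rows {bad_cond.index.tolist()[:10]}: "
            f"{sorted(bad_cond['condition'].unique())}"
        )
    ratio_ok = df["ratio_num"].isin(sd.RATIO_NUMERATORS) & (df["ratio_den"] == sd.RATIO_DENOMINATOR)
    if not ratio_ok.all():
        rows = df.index[~ratio_ok].tolist()
        raise ValueError(
            f"ratios outside the design set (9/12..16/12, never 12/12) at rows {rows[:10]}"
        )
    expected = df["standard"] * df["ratio_num"] / df["ratio_den"]
    mism = ~np.isclose(df["comparison"], expected, rtol=1e-6)
    if mism.any():
        raise ValueError(
            f"comparison magnitude inconsistent with ratio at rows {df.index[mism].tolist()[:10]}"
        )


def read_choice_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a trial-level choice CSV, renaming columns via
    ``column_map={canonical_name: file_column}``; extra columns are kept as
    metadata. Raises a named error for any missing mapped column."""
    df = pd.read_csv(path)
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ValueError(f"mapped columns absent from {path}: {missing}")
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    for col in ("is_training", "chose_comparison", "correct"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    for col in ("white_frac_std", "white_frac_cmp", "lum_std", "lum_cmp"):
        if col not in df.columns:
            df[col] = np.nan
    validate_choice_table(df)
    return df


def write_choice_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _fit_group(sub: pd.DataFrame, pid, condition, augment):
    return pf.fit_weber(sub, augment=augment, participant_id=pid, condition=condition)


def run_analysis(choices: pd.DataFrame, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full pre-registered + post-hoc chain on a choice table."""
    if config is None:
        config = AnalysisConfig()
    validate_choice_table(choices)
    testing = choices.loc[~choices["is_training"].astype(bool)].copy()
    exclusions = []

    # 1. above-chance filter, pooled over all of a participant's testing trials
    keep_pids = []
    for pid, sub in testing.groupby("participant_id", sort=True):
        res = pf.above_chance_filter(sub, alpha=config.alpha)
        if res.keep:
            keep_pids.append(pid)
        else:
            exclusions.append(
                {
                    "participant_id": str(pid),
                    "reason": "not_above_chance",
                    "detail": f"{res.n_correct}/{res.n_trials} correct, p={res.p_value:.4g}",
                }
            )
    testing = testing[testing["participant_id"].isin(keep_pids)]

    # 2. per participant x trial type Weber fits (+ bright-congruent refit)
    fits = []
    for (pid, cond), sub in testing.groupby(["participant_id", "condition"], sort=True):
        fits.append(_fit_group(sub, pid, cond, config.augment))
    if config.resolved_bright() and testing["lum_std"].notna().any():
        bright = pf.select_bright_congruent(testing)
        for pid, sub in bright.groupby("participant_id", sort=True):
            if len(sub):
                fits.append(_fit_group(sub, pid, BRIGHT_LABEL, config.augment))

    # 3. outlier rule: strictly more than 3x the per-condition median
    scope = config.resolved_outlier_scope()
    keep_mask = pf.outlier_filter(fits, scope=scope)
    for f, keep in zip(fits, keep_mask):
        if not keep:
            exclusions.append(
                {
                    "participant_id": f.participant_id,
                    "reason": f"outlier_{scope}",
                    "detail": f"{f.condition}: w={f.w:.4g} > 3 x condition median",
                }
            )
    kept = [f for f, k in zip(fits, keep_mask) if k]

    w = {}  # condition -> {pid: w}
    for f in kept:
        w.setdefault(f.condition, {})[f.participant_id] = f.w

    # 4. per-participant combination prediction (never from aggregated fits)
    comb = {
        pid: pf.combination_prediction(w["area_only"][pid], w["number_only"][pid])
        for pid in set(w.get("area_only", {})) & set(w.get("number_only", {}))
    }
    if comb:
        w["combination"] = comb

    def summarize(values):
        arr = np.array(sorted(values), float)
        return {
            "n": int(len(arr)),
            "median": float(np.median(arr)),
            "mean": float(np.mean(arr)),
            "sd": float(np.std(arr, ddof=1)) if len(arr) > 1 else float("nan"),
        }

    summaries = {cond: summarize(list(vals.values())) for cond, vals in w.items() if vals}

    # 5. one-sided tests: hypothesized direction positive for x - y
    def paired(cond_x, cond_y, name):
        x_map, y_map = w.get(cond_x, {}), w.get(cond_y, {})
        pids = sorted(set(x_map) & set(y_map))
        if len(pids) < 2:
            return
        x = np.array([x_map[p] for p in pids])
        y = np.array([y_map[p] for p in pids])
        try:
            tt = inf.paired_one_sided_t(x, y)
        except ValueError as exc:  # degenerate pairs: report, don't abort the chain
            tests[name] = {"comparison": name, "error": str(exc), "n": len(pids)}
            return
        bf = inf.jzs_bf(tt.t, tt.n, prior_scale=config.prior_scale, sided="positive")
        tests[name] = {
            "comparison": name,
            "t": tt.t,
            "df": tt.df,
            "p": tt.p_one_sided,
            "d": tt.d,
            "n": tt.n,
            "bf10": bf.bf10,
            "bf01": bf.bf01,
            "prior_scale": bf.prior_scale,
            "sided": bf.sided,
        }

    tests: dict = {}
    # area & number better than area-only <=> w(area_only) - w(area_number) > 0
    paired("area_only", "area_number", "area_vs_area_number")
    # area & number worse than the combination <=> w(area_number) - w(combination) > 0
    paired("area_number", "combination", "area_number_vs_combination")
    # bright-congruent better than area-only
    paired("area_only", BRIGHT_LABEL, "bright_congruent_vs_area_only")

    return AnalysisReport(
        n_input_participants=int(choices["participant_id"].nunique()),
        n_analysed_participants=int(testing["participant_id"].nunique()),
        summaries=summaries,
        tests=tests,
        exclusions=exclusions,
        config=asdict(config),
        fits=[asdict(f) for f in kept],
    )


_ROW_ORDER = ["area_only", "number_only", "area_number", "combination", BRIGHT_LABEL]
_ROW_NAMES = {
    "area_only": "Area-only",
    "number_only": "Number-only",
    "area_number": "Area & Number",
    "combination": "Combination",
    BRIGHT_LABEL: "Bright-Congruent Area & Number",
}


def summary_table(report: AnalysisReport) -> pd.DataFrame:
    """Descriptive-statistics table (median/mean/SD of fitted Weber
    fractions per trial type, plus derived rows)."""
    rows = []
    for cond in _ROW_ORDER:
        if cond in report.summaries:
            s = report.summaries[cond]
            rows.append(
                {
                    "trial_type": _ROW_NAMES[cond],
                    "median": s["median"],
                    "mean": s["mean"],
                    "sd": s["sd"],
                    "n": s["n"],
                }
            )
    return pd.DataFrame(rows)


def plot_psychometric(choices: pd.DataFrame, report: AnalysisReport, path) -> None:
    """Aggregate choice rates by ratio with the median-w model curve, one
    panel per trial type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    testing = choices.loc[~choices["is_training"].astype(bool)]
    conds = [c for c in sd.CONDITIONS if c in report.summaries]
    fig, axes = plt.subplots(1, len(conds), figsize=(4 * len(conds), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    ratios = np.array(sd.RATIO_NUMERATORS) / sd.RATIO_DENOMINATOR
    grid = np.linspace(ratios.min(), ratios.max(), 200)
    for ax, cond in zip(axes, conds):
        sub = testing[testing["condition"] == cond]
        rate = sub.groupby("ratio_num")["chose_comparison"].mean()
        ax.plot(rate.index / sd.RATIO_DENOMINATOR, rate.values, "o", label="observed")
        w_med = report.summaries[cond]["median"]
        ax.plot(grid, pf.choice_probability(12.0, 12.0 * grid, w_med), "-", label=f"median w={w_med:.3f}")
        ax.axhline(0.5, color="0.8", lw=0.8)
        ax.set_title(_ROW_NAMES[cond])
        ax.set_xlabel("comparison / standard ratio")
    axes[0].set_ylabel("P(choose comparison)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
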