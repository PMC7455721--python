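"""qPCR quantification and mRNA decay kinetics.

Covers the delta-delta-CT relative quantification, actinomycin-D
time-course normalization (0 h set to 100%), exponential half-life fitting
with confidence intervals, genotype comparison of decay rates, RNA
immunoprecipitation enrichment (% input and fold over IgG), and the
morphometric beta-cell mass formula.

Amplification efficiency is fixed at 2.0 (plain ddCT); an
efficiency-corrected variant is exposed via the ``efficiency`` argument but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConfigError, FormatError

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# ddCT
# ---------------------------------------------------------------------------

def ddct(
    ct: pd.DataFrame,
    calibrator_group: str,
    target_col: str = "ct_target",
    ref_col: str = "ct_ref",
    group_col: str = "group",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative expression per sample by the delta-delta-CT method.

    dCT = Ct_target - Ct_reference per sample; ddCT = dCT - mean dCT of the
    calibrator group; expression = efficiency**(-ddCT). The calibrator
    group's mean log-expression is 0 by construction.
    """
    for col in (target_col, ref_col, group_col):
        if col not in ct.columns:
            raise FormatError(f"Ct table lacks column {col!r}")
    if ct[ref_col].isna().any():
        bad = ct.index[ct[ref_col].isna()].tolist()
        raise FormatError(f"missing reference Ct for sample row(s) {bad}")
    if ct[target_col].isna().any():
        bad = ct.index[ct[target_col].isna()].tolist()
        raise FormatError(f"missing target Ct for sample row(s) {bad}")
    cal = ct[ct[group_col] == calibrator_group]
    if cal.empty:
        raise ConfigError(f"calibrator group {calibrator_group!r} is empty")
    out = ct.copy()
    out["dct"] = out[target_col] - out[ref_col]
    out["ddct"] = out["dct"] - (cal[target_col] - cal[ref_col]).mean()
    out["rel_expr"] = float(efficiency) ** (-out["ddct"])
    return out


# ---------------------------------------------------------------------------
# Act-D decay
# ---------------------------------------------------------------------------

def normalize_decay(
    raw: pd.DataFrame,
    value_col: str = "value",
    time_col: str = "time_hr",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Set each replicate series to 100% at t = 0.

    ``raw`` holds one row per (replicate, timepoint) with a relative
    expression value (already reference-normalized); each replicate is
    divided by its own t = 0 value and multiplied by 100, making the series
    invariant to per-replicate gain.
    """
    extra = [c for c in raw.columns if c not in (value_col, time_col, replicate_col)]
    out = []
    for rep, sub in raw.groupby(replicate_col, sort=False):
        t0 = sub.loc[sub[time_col] == 0, value_col]
        if t0.empty:
            raise FormatError(f"replicate {rep!r} lacks a t=0 measurement")
        v0 = float(t0.iloc[0])
        if v0 <= 0:
            raise FormatError(f"replicate {rep!r}: t=0 value {v0} is not positive")
        sub = sub.copy()
        sub["relative_abundance"] = sub[value_col] / v0 * 100.0
        out.append(sub[[replicate_col, time_col, "relative_abundance", *extra]])
    return pd.concat(out, ignore_index=True)


@dataclass
class HalfLifeFit:
    """Exponential decay fit: slope in log2 units/hr, t_half = -1/slope."""

    slope: float
    t_half_hr: float
    ci_lower_hr: float
    ci_upper_hr: float
    r_squared: float
    stable: bool

    @property
    def k_per_hr(self) -> float:
        """First-order decay rate; t_half * k = ln 2 exactly."""
        return LN2 / self.t_half_hr


def _origin_slope(t: np.ndarray, z: np.ndarray) -> float:
    return float(np.sum(t * z) / np.sum(t * t))


def fit_half_life(
    course: pd.DataFrame,
    time_col: str = "time_hr",
    value_col: str = "relative_abundance",
    replicate_col: str = "replicate",
    conf: float = 0.95,
) -> HalfLifeFit:
    """Least squares of log2(abundance / 100) on time, through the origin.

    After 0-h normalization the t = 0 points are identically zero and carry
    no information, so only t > 0 points enter the fit. Normalizing by each
    replicate's own 0-h value also correlates that replicate's residuals, so
    when replicate labels are available the slope standard error comes from
    the between-replicate spread of per-replicate slopes (which are
    independent), with a t-interval on ``n_reps - 1`` df; without replicate
    structure it falls back to the pooled residual SE. The CI maps
    monotonically to the half-life scale; a non-negative slope is flagged
    ``stable`` with unbounded t_half.
    """
    t = course[time_col].to_numpy(float)
    y = course[value_col].to_numpy(float)
    if (y <= 0).any():
        raise FormatError("abundances must be positive for log-scale fitting")
    if len(np.unique(t)) < 3 or 0.0 not in t:
        raise ConfigError("need >= 3 timepoints including 0")
    pos = t > 0
    tt, z = t[pos], np.log2(y[pos] / 100.0)
    slope = _origin_slope(tt, z)
    resid = z - slope * tt
    tss = float(np.sum(z * z))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else 1.0

    rep_slopes = None
    if replicate_col in course.columns:
        reps = course.loc[pos, replicate_col].to_numpy()
        labels = pd.unique(reps)
        if len(labels) >= 2:
            rep_slopes = np.array(
                [_origin_slope(tt[reps == r], z[reps == r]) for r in labels]
            )
    if rep_slopes is not None:
        df = len(rep_slopes) - 1
        se = float(rep_slopes.std(ddof=1) / np.sqrt(len(rep_slopes)))
    else:
        df = len(tt) - 1
        se = (
            float(np.sqrt(np.sum(resid ** 2) / df / np.sum(tt * tt)))
            if df > 0
            else 0.0
        )
    if df > 0 and se > 0:
        tcrit = stats.t.ppf(0.5 + conf / 2.0, df)
        lo, hi = slope - tcrit * se, slope + tcrit * se
    else:
        lo = hi = slope
    if slope >= 0:
        return HalfLifeFit(slope, np.inf, np.nan, np.nan, r2, stable=True)

    def to_thalf(s: float) -> float:
        return -1.0 / s if s < 0 else np.inf

    # slope CI maps monotonically: steeper (more negative) slope -> shorter t_half
    return HalfLifeFit(slope, to_thalf(slope), to_thalf(lo), to_thalf(hi), r2, stable=False)


def compare_decay(
    control: pd.DataFrame,
    ko: pd.DataFrame,
    time_col: str = "time_hr",
    value_col: str = "relative_abundance",
    replicate_col: str = "replicate",
) -> dict:
    """Genotype x time interaction on the log2 decay slopes.

    The interaction term of the joint log-linear model (genotype-specific
    slope difference) is tested as a pooled two-sample t on per-replicate
    through-origin slopes; per-replicate slopes are independent even though
    the 0-h normalization correlates residuals within a replicate.
    Direction is ``stabilized`` when the knockout slope is shallower (less
    negative).
    """
    for df_, name in ((control, "control"), (ko, "ko")):
        if df_[replicate_col].nunique() < 2:
            raise ConfigError(f"{name} arm needs >= 2 replicates")
    if set(control[time_col]) != set(ko[time_col]):
        raise ConfigError("genotypes must share timepoints")

    def rep_slopes(df_: pd.DataFrame) -> np.ndarray:
        t = df_[time_col].to_numpy(float)
        z = np.log2(df_[value_col].to_numpy(float) / 100.0)
        reps = df_[replicate_col].to_numpy()
        pos = t > 0
        return np.array(
            [
                _origin_slope(t[pos & (reps == r)], z[pos & (reps == r)])
                for r in pd.unique(reps)
            ]
        )

    s1, s2 = rep_slopes(control), rep_slopes(ko)
    b1, b2 = float(s1.mean()), float(s2.mean())
    df = len(s1) + len(s2) - 2
    pooled = ((len(s1) - 1) * s1.var(ddof=1) + (len(s2) - 1) * s2.var(ddof=1)) / df
    se = np.sqrt(pooled * (1.0 / len(s1) + 1.0 / len(s2)))
    if se == 0:
        tstat, p = 0.0, 1.0
    else:
        tstat = (b2 - b1) / se
        p = 2.0 * stats.t.sf(abs(tstat), df)
    direction = "stabilized" if b2 > b1 else ("destabilized" if b2 < b1 else "none")
    return {
        "p_value": float(p),
        "t_stat": float(tstat),
        "direction": direction,
        "slope_control": b1,
        "slope_ko": b2,
    }


# ---------------------------------------------------------------------------
# RIP and morphometry
# ---------------------------------------------------------------------------

def rip_enrichment(
    input_ct: float,
    igg_ct: float,
    ab_ct: float,
    input_fraction: float,
    efficiency: float = 2.0,
) -> dict:
    """Percent-of-input recovery for each antibody and fold over IgG.

    The input Ct is adjusted by -log2(1/input_fraction) cycles so it
    represents 100% of the material; %input = 100 x eff**(Ct_input_adjusted
    - Ct_IP) and fold = %input(antibody) / %input(IgG).
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ConfigError(f"input_fraction must be in (0, 1], got {input_fraction}")
    adj = input_ct - np.log2(1.0 / input_fraction) / np.log2(efficiency)
    pct_ab = 100.0 * float(efficiency) ** (adj - ab_ct)
    pct_igg = 100.0 * float(efficiency) ** (adj - igg_ct)
    return {
        "percent_input_ab": pct_ab,
        "percent_input_igg": pct_igg,
        "fold_over_igg": pct_ab / pct_igg,
        "input_ct_adjusted": float(adj),
    }


def beta_cell_mass(
    insulin_area: float, total_area: float, pancreas_weight_mg: float
) -> float:
    """Beta-cell mass (mg) = (insulin-positive area / total area) x weight."""
    if total_area == 0:
        raise ConfigError("total pancreatic area must be non-zero")
    if not 0 <= insulin_area <= total_area:
        raise ConfigError("need 0 <= insulin_area <= total_area")
    if pancreas_weight_mg <= 0:
        raise ConfigError("pancreas weight must be positive")
    return insulin_area / total_area * pancreas_weight_mg


def group_compare(x, y, method: str = "ttest") -> dict:
    """Two-sample comparison utility: two-tailed Student's t or Mann-Whitney."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if method == "ttest":
        stat, p = stats.ttest_ind(x, y, equal_var=True)
    elif method == "mannwhitney":
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ConfigError(f"unknown method {method!r}")
    return {"statistic": float(stat), "p_value": float(p), "method": method}
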