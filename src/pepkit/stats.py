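"""RMS / peak summaries and the split-plot (repeated-measures mixed) ANOVA.

The magnitude statistic is the epoch RMS, sqrt(mean(x^2)); per subject,
channel and condition (unpredictable vs predictable) the mean RMS over valid
epochs forms the tidy ``RmsTable`` that all statistics consume.

The design is a split plot: age group (young/elder) and sex (male/female) are
between-subject factors; perturbation type is a 2-level within-subject factor.
With a 2-level within factor the univariate split-plot ANOVA decomposes
exactly into two ordinary linear models:

* between stratum — subject condition-means ``(u_i + p_i)/2`` regressed on
  age * sex; tests age, sex, age:sex against subject-within-group error
  (df_den = N - 4 in the balanced default);
* within stratum — subject condition-differences ``u_i - p_i`` regressed on
  age * sex; the intercept tests the perturbation-type main effect and the
  factor terms its interactions, against the condition x subject error
  (df_den = N - 4).

Sums of squares are Type III (sum-to-zero contrasts), so mildly unbalanced
cells (listwise-dropped subjects) are handled. Post-hoc pairwise comparisons
use Tukey's HSD on the studentized-range distribution; effect sizes are
classical pooled-SD Cohen's d (within-subject effects use the pooled SD of
the two condition columns, not the SD of differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .epochs import EpochSet
from .simulate import SubjectProfile

CONDITIONS = ("unpredictable", "predictable")
ANALYSIS_CHANNELS = ("Cz", "Fz", "mastoid")

BETWEEN_EFFECTS = ("age", "sex", "age:sex")
WITHIN_EFFECTS = ("condition", "condition:age", "condition:sex", "condition:age:sex")


# ---------------------------------------------------------------------------
# Epoch-level statistics
# ---------------------------------------------------------------------------

def compute_rms(samples: np.ndarray) -> float:
    """Root-mean-square of an epoch: sqrt(mean(x^2))."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute RMS of an empty epoch")
    return float(np.sqrt(np.mean(np.square(x))))


class PeakMagnitude(NamedTuple):
    value: float
    positive_peak: bool


def compute_peak_magnitude(samples: np.ndarray) -> PeakMagnitude:
    """Highest positive peak within the epoch (maximum signed value).

    If every sample is negative the (negative) maximum is returned with
    ``positive_peak=False``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute the peak of an empty epoch")
    peak = float(x.max())
    return PeakMagnitude(value=peak, positive_peak=peak > 0)


# ---------------------------------------------------------------------------
# RMS table
# ---------------------------------------------------------------------------

def summarize_rms(
    epoch_set: EpochSet, subject_profiles: dict[str, SubjectProfile]
) -> pd.DataFrame:
    """Tidy per subject x channel x condition summary of normalized epochs.

    Columns: subject_id, age_group, sex, channel, condition, mean_rms,
    n_epochs, mean_peak. Only valid normalized epochs with an analyzable label
    enter; a subject x channel x condition cell with no valid epochs yields no
    row (the subject is later dropped listwise from that channel's ANOVA).
    """
    rows = []
    for sid in epoch_set.subjects:
        prof = subject_profiles[sid]
        for ch in epoch_set.channels:
            group = [
                e for e in epoch_set.group(sid, ch)
                if e.valid and e.analysis_label in CONDITIONS
            ]
            for e in group:
                if e.state != "normalized":
                    raise ValueError("summarize_rms expects normalized epochs")
            for cond in CONDITIONS:
                eps = [e for e in group if e.analysis_label == cond]
                if not eps:
                    continue
                rows.append(
                    {
                        "subject_id": sid,
                        "age_group": prof.age_group,
                        "sex": prof.sex,
                        "channel": ch,
                        "condition": cond,
                        "mean_rms": float(
                            np.mean([compute_rms(e.samples) for e in eps])
                        ),
                        "n_epochs": len(eps),
                        "mean_peak": float(
                            np.mean(
                                [compute_peak_magnitude(e.samples).value for e in eps]
                            )
                        ),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "age_group", "sex", "channel", "condition",
            "mean_rms", "n_epochs", "mean_peak",
        ],
    )


def _wide_table(table: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Subjects with both condition cells at ``channel``, in wide form."""
    sub = table[table["channel"] == channel]
    if sub.empty:
        raise ValueError(f"no rows for channel {channel!r}")
    wide = sub.pivot_table(
        index=["subject_id", "age_group", "sex"],
        columns="condition", values="mean_rms",
    ).reset_index()
    complete = wide.dropna(subset=list(CONDITIONS))
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        import logging
        logging.getLogger(__name__).info(
            "channel %s: %d subject(s) dropped listwise (incomplete condition "
            "cells)", channel, n_dropped,
        )
    return complete.copy()


# ---------------------------------------------------------------------------
# Split-plot ANOVA
# ---------------------------------------------------------------------------

_FORMULA = "y ~ C(age_group, Sum) * C(sex, Sum)"
_TERM_MAP = {
    "C(age_group, Sum)": "age",
    "C(sex, Sum)": "sex",
    "C(age_group, Sum):C(sex, Sum)": "age:sex",
}


def _stratum_anova(data: pd.DataFrame) -> pd.DataFrame:
    fit = smf.ols(_FORMULA, data=data).fit()
    return anova_lm(fit, typ=3)


def _f_and_p(aov: pd.DataFrame, term: str) -> tuple[float, float]:
    """F and p for one term; an exactly-zero effect in noise-free data (0/0)
    is reported as F = 0, p = 1 rather than NaN."""
    F, p = float(aov.loc[term, "F"]), float(aov.loc[term, "PR(>F)"])
    ss = float(aov.loc[term, "sum_sq"])
    if not np.isfinite(F) and (not np.isfinite(ss) or ss <= 1e-300):
        return 0.0, 1.0
    return F, p


def split_plot_anova(table: pd.DataFrame, channel: str) -> pd.DataFrame:
    """3-way mixed ANOVA (age x sex between, perturbation type within).

    Returns one row per effect with F, df_num, df_den, p and the error
    stratum. Subjects missing a condition cell at this channel are dropped
    listwise (reducing df_den). Requires >= 2 subjects per age x sex cell.
    """
    wide = _wide_table(table, channel)
    cell_sizes = wide.groupby(["age_group", "sex"]).size()
    if len(cell_sizes) < 4 or (cell_sizes < 2).any():
        raise ValueError(
            f"channel {channel!r}: need >= 2 subjects in each of the 4 "
            f"age x sex cells, got {cell_sizes.to_dict()}"
        )
    n = len(wide)
    rows = []

    between = wide.assign(
        y=(wide["unpredictable"] + wide["predictable"]) / 2.0
    )
    aov_b = _stratum_anova(between)
    df_den = int(aov_b.loc["Residual", "df"])
    for term, label in _TERM_MAP.items():
        F, p = _f_and_p(aov_b, term)
        rows.append(
            {
                "effect": label, "stratum": "between",
                "F": F,
                "df_num": int(aov_b.loc[term, "df"]),
                "df_den": df_den,
                "p": p,
            }
        )

    within = wide.assign(y=wide["unpredictable"] - wide["predictable"])
    aov_w = _stratum_anova(within)
    F, p = _f_and_p(aov_w, "Intercept")
    rows.append(
        {
            "effect": "condition", "stratum": "within",
            "F": F,
            "df_num": int(aov_w.loc["Intercept", "df"]),
            "df_den": int(aov_w.loc["Residual", "df"]),
            "p": p,
        }
    )
    for term, label in _TERM_MAP.items():
        F, p = _f_and_p(aov_w, term)
        rows.append(
            {
                "effect": f"condition:{label}" if label != "age:sex"
                else "condition:age:sex",
                "stratum": "within",
                "F": F,
                "df_num": int(aov_w.loc[term, "df"]),
                "df_den": int(aov_w.loc["Residual", "df"]),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "channel", channel)
    out.attrs["n_subjects"] = n
    return out


def between_subject_mse(table: pd.DataFrame, channel: str) -> tuple[float, int]:
    """Mean-square error and df of the between-subject stratum (subject
    condition-means about their age x sex cell means); Tukey HSD input."""
    wide = _wide_table(table, channel)
    y = (wide["unpredictable"] + wide["predictable"]) / 2.0
    data = wide.assign(y=y)
    fit = smf.ols(_FORMULA, data=data).fit()
    return float(fit.mse_resid), int(fit.df_resid)


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosthocResult:
    """One Tukey HSD pairwise comparison."""

    pair: tuple[str, str]
    mean_difference: float
    q: float
    p_adjusted: float
    significant: bool


def tukey_hsd(
    cell_means: dict[str, float],
    mse: float,
    df: int,
    n_per_cell: dict[str, int],
    alpha: float = 0.05,
) -> list[PosthocResult]:
    """All-pairs Tukey HSD from cell means and an ANOVA error mean square.

    q = |m_i - m_j| / sqrt(MSE / n_h) with n_h the harmonic mean of the two
    cell sizes; adjusted p from the studentized-range distribution with
    ``len(cell_means)`` groups and the error df.
    """
    if mse <= 0:
        raise ValueError("degenerate data: error mean square must be positive")
    if len(cell_means) < 2:
        raise ValueError("need at least two cells for pairwise comparisons")
    labels = list(cell_means)
    k = len(labels)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            n_h = 2.0 / (1.0 / n_per_cell[a] + 1.0 / n_per_cell[b])
            diff = cell_means[a] - cell_means[b]
            q = abs(diff) / np.sqrt(mse / n_h)
            p = float(sps.studentized_range.sf(q, k, df))
            out.append(
                PosthocResult(
                    pair=(a, b), mean_difference=float(diff), q=float(q),
                    p_adjusted=p, significant=p < alpha,
                )
            )
    return out


def tukey_age_sex(
    table: pd.DataFrame, channel: str, alpha: float = 0.05
) -> list[PosthocResult]:
    """Tukey HSD follow-up over the four age x sex cells of subject
    condition-mean RMS at one channel (the age-by-sex interaction probe)."""
    wide = _wide_table(table, channel)
    y = (wide["unpredictable"] + wide["predictable"]) / 2.0
    data = wide.assign(y=y)
    cells = data.groupby(["age_group", "sex"])["y"]
    means = {f"{a}-{s}": float(m) for (a, s), m in cells.mean().items()}
    ns = {f"{a}-{s}": int(n) for (a, s), n in cells.size().items()}
    mse, df = between_subject_mse(table, channel)
    return tukey_hsd(means, mse, df, ns, alpha=alpha)


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with its standardization convention.

    Sign conventions: condition = unpredictable - predictable; age = elder -
    young; sex = male - female.
    """

    effect: str
    channel: str
    cohens_d: float
    definition: str  # between-pooled | within-subject


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    return float(
        np.sqrt(
            ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
            / (na + nb - 2)
        )
    )


def cohens_d(table: pd.DataFrame, effect: str, channel: str) -> EffectSize:
    """Cohen's d for one main effect at one channel.

    ``condition``: classical within-subject d — mean(u - p) over subjects
    divided by the pooled SD of the two condition columns (not the SD of the
    differences). ``age`` / ``sex``: between-subject d on subject
    condition-mean RMS with pooled-SD standardization.
    """
    wide = _wide_table(table, channel)
    if effect == "condition":
        u = wide["unpredictable"].to_numpy()
        p = wide["predictable"].to_numpy()
        sd = float(np.sqrt((np.var(u, ddof=1) + np.var(p, ddof=1)) / 2.0))
        if sd <= 0:
            raise ValueError("degenerate data: zero pooled SD")
        return EffectSize(effect, channel, float(np.mean(u - p) / sd),
                          "within-subject")
    if effect in ("age", "sex"):
        col, first, second = {
            "age": ("age_group", "elder", "young"),
            "sex": ("sex", "male", "female"),
        }[effect]
        y = (wide["unpredictable"] + wide["predictable"]) / 2.0
        g1 = y[wide[col] == first].to_numpy()
        g2 = y[wide[col] == second].to_numpy()
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError("each compared group needs >= 2 observations")
        sd = _pooled_sd(g1, g2)
        if sd <= 0:
            raise ValueError("degenerate data: zero pooled SD")
        return EffectSize(effect, channel, float((g1.mean() - g2.mean()) / sd),
                          "between-pooled")
    raise ValueError(f"unknown effect {effect!r}")
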