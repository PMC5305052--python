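"""Group-level statistics over per-subject psychometric fits.

Aggregates subject-level PSEs into the study's statistics: per-subject
combined shifts, paired t-tests across stimulus durations, a two-way
mixed-design ANOVA (population as the between-subject factor, duration as
the within-subject factor, subjects nested in population), Pearson
correlations and between-subject variances.

The ANOVA is computed from sequential nested-projection sums of squares
(residual sums of squares of increasingly rich least-squares fits), which
guarantees the partition SS_total = SS_population + SS_subject +
SS_duration + SS_interaction + SS_error exactly.  F-ratios use the
conventional mixed-design error terms: population is tested against
subject-within-population, everything else against the within-subject
residual.  No sphericity correction is applied by default; a
Greenhouse-Geisser correction is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, UndefinedCorrelationError, UnsupportedDesignError
from .psychometric_fit import combined_shift

__all__ = [
    "TTestResult",
    "AnovaResult",
    "summarize_subjects",
    "paired_t",
    "two_way_rm_anova",
    "pearson_r",
    "group_variance",
]


@dataclass(frozen=True)
class TTestResult:
    """Paired t-test outcome; degenerate flags zero-variance differences."""

    t: float
    p: float
    df: int
    degenerate: bool = False

    def __iter__(self):  # allows  t, p = paired_t(a, b)
        return iter((self.t, self.p))


@dataclass(frozen=True)
class AnovaResult:
    """Mixed-design ANOVA table.

    ``table`` has one row per effect (population, subject, duration,
    interaction, error) with columns ss, df, ms, F, p.
    """

    table: pd.DataFrame
    sphericity_corrected: bool = False
    gg_epsilon: float | None = None

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def F(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])


# ---------------------------------------------------------------------------


def summarize_subjects(
    fit_table: pd.DataFrame, certainty_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per (subject, duration) with CW/CCW PSEs and combined shift.

    Parameters
    ----------
    fit_table : DataFrame
        Long-format per-condition fits with columns ``subject_id``,
        ``group``, ``duration``, ``vfm_direction`` ("CW"/"CCW") and
        ``pse`` (optionally ``threshold``).
    certainty_table : DataFrame, optional
        Per-condition mean certainty with columns ``subject_id``,
        ``duration``, ``vfm_direction``, ``certainty``.

    Raises
    ------
    SchemaError
        If any subject is missing a CW or CCW fit for a duration present
        in the table; the message names the gaps.
    """
    required = {"subject_id", "group", "duration", "vfm_direction", "pse"}
    missing_cols = required - set(fit_table.columns)
    if missing_cols:
        raise SchemaError(f"fit table is missing columns: {sorted(missing_cols)}")

    durations = sorted(fit_table["duration"].unique())
    gaps = []
    for (sid, d), sub in fit_table.groupby(["subject_id", "duration"]):
        have = set(sub["vfm_direction"])
        for need in ("CW", "CCW"):
            if need not in have:
                gaps.append((sid, d, need))
    by_subject = fit_table.groupby("subject_id")["duration"].apply(set)
    for sid, have in by_subject.items():
        for d in durations:
            if d not in have:
                gaps.extend([(sid, d, "CW"), (sid, d, "CCW")])
    if gaps:
        raise SchemaError(f"missing subject/condition fits: {sorted(set(gaps))[:20]}")

    wide = fit_table.pivot_table(
        index=["subject_id", "group", "duration"],
        columns="vfm_direction",
        values="pse",
        aggfunc="first",
    ).reset_index()
    wide = wide.rename(columns={"CW": "pse_cw", "CCW": "pse_ccw"})
    wide["combined_shift"] = [
        combined_shift(cw, ccw) for cw, ccw in zip(wide["pse_cw"], wide["pse_ccw"])
    ]
    if certainty_table is not None:
        ce = certainty_table.pivot_table(
            index=["subject_id", "duration"],
            columns="vfm_direction",
            values="certainty",
            aggfunc="mean",
        ).reset_index()
        ce = ce.rename(columns={"CW": "ce_cw", "CCW": "ce_ccw"})
        wide = wide.merge(ce, on=["subject_id", "duration"], how="left")
    return wide.sort_values(["subject_id", "duration"]).reset_index(drop=True)


def paired_t(values_a, values_b) -> TTestResult:
    """Classical paired t-test (two-sided, n-1 degrees of freedom).

    Zero-variance differences are flagged degenerate: t is +/-inf with p
    reported as 0.0 (below any machine floor) when the mean difference is
    nonzero, and t = 0, p = 1 when the vectors are identical.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TTestResult(t=0.0, p=1.0, df=a.size - 1, degenerate=True)
        return TTestResult(
            t=float(np.sign(d.mean()) * np.inf), p=0.0, df=a.size - 1, degenerate=True
        )
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=a.size - 1)


# ---------------------------------------------------------------------------
# mixed-design ANOVA


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of the least-squares projection of y on X."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _dummies(codes: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((codes.size, k))
    out[np.arange(codes.size), codes] = 1.0
    return out


def two_way_rm_anova(
    data: pd.DataFrame,
    dv: str = "combined_shift",
    within: str = "duration",
    between: str = "group",
    subject: str = "subject_id",
    sphericity_correction: bool = False,
) -> AnovaResult:
    """Two-way mixed-design ANOVA (between: population, within: duration).

    Requires a complete balanced table: every subject observed once at
    every within-factor level.  Raises UnsupportedDesignError otherwise.
    """
    for col in (dv, within, between, subject):
        if col not in data.columns:
            raise SchemaError(f"ANOVA table is missing column {col!r}")
    counts = data.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        raise UnsupportedDesignError("each subject needs exactly one value per duration")
    levels = sorted(data[within].unique())
    per_subject = data.groupby(subject, observed=True)[within].nunique()
    if (per_subject != len(levels)).any():
        raise UnsupportedDesignError(
            "unbalanced design: every subject must be observed at every duration"
        )
    grp_of = data.groupby(subject, observed=True)[between].nunique()
    if (grp_of != 1).any():
        raise UnsupportedDesignError("each subject must belong to exactly one group")

    y = data[dv].to_numpy(dtype=float)
    subj_codes, subj_idx = pd.factorize(data[subject])
    grp_codes, grp_idx = pd.factorize(data[between])
    dur_codes, dur_idx = pd.factorize(data[within], sort=True)
    n_subj, n_grp, n_dur = len(subj_idx), len(grp_idx), len(dur_idx)

    ones = np.ones((y.size, 1))
    A = _dummies(grp_codes, n_grp)
    S = _dummies(subj_codes, n_subj)
    Bm = _dummies(dur_codes, n_dur)
    AB = np.einsum("ij,ik->ijk", A, Bm).reshape(y.size, -1)
    SB = np.einsum("ij,ik->ijk", S, Bm).reshape(y.size, -1)

    r0 = _rss(y, ones)
    rA = _rss(y, A)
    rS = _rss(y, S)
    rSB_ = _rss(y, np.hstack([S, Bm]))
    rFull = _rss(y, np.hstack([S, Bm, AB]))

    ss = {
        "population": r0 - rA,
        "subject": rA - rS,
        "duration": rS - rSB_,
        "interaction": rSB_ - rFull,
        "error": rFull,
    }
    df = {
        "population": n_grp - 1,
        "subject": n_subj - n_grp,
        "duration": n_dur - 1,
        "interaction": (n_grp - 1) * (n_dur - 1),
        "error": (n_subj - n_grp) * (n_dur - 1),
    }

    gg_eps = None
    if sphericity_correction:
        gg_eps = _gg_epsilon(data, dv, within, between, subject)

    rows = []
    ms_subject = ss["subject"] / df["subject"] if df["subject"] else np.nan
    ms_error = ss["error"] / df["error"] if df["error"] else np.nan
    for effect in ("population", "subject", "duration", "interaction", "error"):
        ms = ss[effect] / df[effect] if df[effect] else np.nan
        if effect == "error":
            F = p = np.nan
        else:
            denom = ms_subject if effect == "population" else ms_error
            df_num, df_den = df[effect], (
                df["subject"] if effect == "population" else df["error"]
            )
            if sphericity_correction and gg_eps is not None and effect in (
                "duration",
                "interaction",
            ):
                df_num, df_den = df_num * gg_eps, df_den * gg_eps
            if not np.isfinite(denom) or denom == 0.0:
                # degenerate table (e.g. all zeros): no evidence either way
                F = 0.0 if ss[effect] == 0.0 else np.inf
                p = 1.0 if ss[effect] == 0.0 else 0.0
            else:
                F = ms / denom
                p = float(stats.f.sf(F, df_num, df_den))
        rows.append({"effect": effect, "ss": ss[effect], "df": df[effect], "ms": ms, "F": F, "p": p})
    table = pd.DataFrame(rows).set_index("effect")
    return AnovaResult(table=table, sphericity_corrected=sphericity_correction, gg_epsilon=gg_eps)


def _gg_epsilon(data, dv, within, between, subject) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="first")
    groups = data.groupby(subject, observed=True)[between].first()
    centered = wide.copy()
    for g, idx in groups.groupby(groups).groups.items():
        centered.loc[idx] = wide.loc[idx] - wide.loc[idx].mean(axis=0)
    S = np.cov(centered.to_numpy(), rowvar=False, ddof=1)
    k = S.shape[0]
    # double-centre
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc * Sc)
    return float(num / den) if den > 0 else 1.0


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient.

    Raises UndefinedCorrelationError if either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def group_variance(values) -> float:
    """Sample variance (n-1 denominator) of per-subject values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    return float(np.var(v, ddof=1))
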