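"""Group-level inference on movement/SNR measure tables.

Mixed ANOVAs with listener group as a between-participants factor and
environment as a within-participant factor, Greenhouse-Geisser correction
when sphericity is violated, Benjamini-Hochberg control of the false
discovery rate across the whole family of ANOVA p-values run in one
pipeline invocation, and Bonferroni-corrected pairwise group comparisons
per environment.  Effect sizes are partial eta-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "mixed_anova",
    "bh_adjust",
    "pairwise_bonferroni",
    "anova_family_table",
]


@dataclass
class AnovaResult:
    """One ANOVA effect: F, (possibly GG-corrected, non-integer) df, p."""

    factor: str
    measure: str
    F: float
    df: tuple[float, float]
    p: float
    effect_size: float  # partial eta-squared
    p_adj: Optional[float] = None  # filled by family-wise BH adjustment
    sphericity_corrected: bool = False

    def as_dict(self) -> dict:
        return {
            "factor": self.factor, "measure": self.measure, "F": self.F,
            "df1": self.df[0], "df2": self.df[1], "p": self.p,
            "p_adj": self.p_adj, "effect_size": self.effect_size,
        }


def _drop_sparse_subjects(df: pd.DataFrame, dv: str, subject: str,
                          within: str) -> pd.DataFrame:
    """Listwise exclusion: drop subjects missing the dv in more than half
    of the environments (with a warning), and remaining incomplete cells."""
    df = df.dropna(subset=[dv])
    n_env = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    bad = counts[counts < n_env / 2.0].index
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} participant(s) missing more than half "
            f"of the environments for {dv}", stacklevel=2)
        df = df[~df[subject].isin(bad)]
    # pingouin needs complete cases per subject; drop the rest listwise
    complete = df.groupby(subject)[within].nunique()
    keep = complete[complete == df[within].nunique()].index
    return df[df[subject].isin(keep)]


def mixed_anova(table: pd.DataFrame, dv: str = "value",
                between: str = "group", within: str = "environment_id",
                subject: str = "participant_id",
                alpha_sphericity: float = 0.05) -> list[AnovaResult]:
    """Mixed ANOVA: between-group main effect and group x environment
    interaction, with Greenhouse-Geisser-corrected df and p when Mauchly's
    test rejects sphericity at ``alpha_sphericity``.

    ``table`` is long-format with one row per subject x environment.
    Returns the main effect of ``between`` and the interaction (the
    within main effect is carried along in pingouin's output but, like
    the study design this mirrors, only group and interaction are
    reported).
    """
    df = _drop_sparse_subjects(table, dv, subject, within)
    if df[between].nunique() < 2:
        raise ValueError("need at least two groups")
    if float(np.var(df[dv].to_numpy())) < 1e-24:
        # degenerate: dv constant across all cells -> no effect anywhere
        n_subj = df[subject].nunique()
        k_grp = df[between].nunique()
        k_env = df[within].nunique()
        return [
            AnovaResult("group", dv, 0.0, (k_grp - 1.0, n_subj - k_grp),
                        1.0, 0.0),
            AnovaResult("group*environment", dv,
                        0.0, ((k_grp - 1.0) * (k_env - 1.0),
                              (n_subj - k_grp) * (k_env - 1.0)), 1.0, 0.0),
        ]
    try:
        aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                             between=between, correction=True, effsize="np2")
    except KeyError:
        # near-degenerate data can break the sphericity-correction path
        aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                             between=between, correction=False, effsize="np2")
    # sphericity decision from Mauchly's test on the within factor
    spher = pg.sphericity(df, dv=dv, within=within, subject=subject)
    spher_ok = bool(spher[0]) if isinstance(spher, tuple) else bool(spher.spher)
    spher_p = float(spher[-1]) if isinstance(spher, tuple) else float(spher.pval)
    violated = (not spher_ok) and (spher_p < alpha_sphericity)

    results = []
    for _, row in aov.iterrows():
        if row["Source"] == between:
            factor = "group"
        elif row["Source"] == "Interaction":
            factor = "group*environment"
        else:
            continue
        p_unc = row.get("p_unc", row.get("p-unc"))
        df1, df2, p, corrected = float(row["DF1"]), float(row["DF2"]), \
            float(p_unc), False
        if factor == "group*environment" and violated:
            eps = float(pg.epsilon(df, dv=dv, within=within, subject=subject,
                                   correction="gg"))
            df1c, df2c = df1 * eps, df2 * eps
            p_gg = row.get("p_GG_corr", row.get("p-GG-corr", np.nan))
            if p_gg is not None and not np.isnan(p_gg):
                p = float(p_gg)
            else:
                p = float(sps.f.sf(row["F"], df1c, df2c))
            df1, df2, corrected = df1c, df2c, True
        results.append(AnovaResult(
            factor=factor, measure=dv, F=float(row["F"]), df=(df1, df2),
            p=p, effect_size=float(row["np2"]),
            sphericity_corrected=corrected))
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    Raises ``ValueError`` on an empty family or p-values outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def anova_family_table(results: Sequence[AnovaResult]) -> pd.DataFrame:
    """Adjust one family of ANOVA effects with Benjamini-Hochberg and
    return the report table (factor, measure, F, df, p, p_adj, effect
    size) — the family is all main and interaction p-values of the
    grouped ANOVAs run in one pipeline invocation."""
    results = list(results)
    adj = bh_adjust([r.p for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
    return pd.DataFrame([r.as_dict() for r in results])


def pairwise_bonferroni(table: pd.DataFrame, dv: str = "value",
                        between: str = "group",
                        within: str = "environment_id") -> pd.DataFrame:
    """Bonferroni-corrected two-sample comparisons of all group pairs
    within each environment.

    ``p_adj = min(1, p * m)`` with m the number of comparisons actually
    performed; groups with fewer than two observations in an environment
    are skipped with a warning.
    """
    frames = []
    for env, sub in table.dropna(subset=[dv]).groupby(within):
        groups = {g: d[dv].to_numpy() for g, d in sub.groupby(between)}
        rows = []
        for a, b in combinations(sorted(groups), 2):
            xa, xb = groups[a], groups[b]
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(
                    f"skipping {a} vs {b} in {env}: group with n < 2",
                    stacklevel=2)
                continue
            t, p = sps.ttest_ind(xa, xb)
            rows.append({"environment_id": env, "A": a, "B": b,
                         "t": float(t), "p": float(p),
                         "mean_A": float(np.mean(xa)),
                         "mean_B": float(np.mean(xb))})
        env_df = pd.DataFrame(rows)
        if len(env_df):
            # Bonferroni family = the pairs tested within this environment
            m = len(env_df)
            env_df["p_adj"] = np.minimum(1.0, env_df["p"] * m)
            env_df["n_comparisons"] = m
        frames.append(env_df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
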