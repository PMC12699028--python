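"""Mixed (split-plot) and repeated-measures ANOVA models.

Both models follow the fit-then-results idiom: construct from a long
DataFrame, call :meth:`fit`, and read estimates off the returned results
object. The sums-of-squares engine is pingouin's; this module enforces the
balanced-design preconditions, normalizes the output table (F, df,
uncorrected and Greenhouse-Geisser-corrected p, partial eta squared,
sphericity epsilon) and provides a ``summary()`` rendering.

Partial eta squared is SS_effect / (SS_effect + SS_error), with the error
term matched to each effect (subject-within-group error for the between
effect; subject x within residual for the within and interaction effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg

__all__ = ["MixedAnova", "RepeatedMeasuresAnova", "AnovaResults"]


class UnbalancedDesignError(ValueError):
    """Every participant must have every within-subject level (no imputation)."""


class DegenerateModelError(ValueError):
    """The error variance is zero; F statistics are undefined."""


@dataclass
class AnovaResults:
    """ANOVA estimates: one row per effect.

    ``table`` columns: ``effect`` (between / within / interaction), ``F``,
    ``df1``, ``df2``, ``p`` (uncorrected), ``p_gg`` (Greenhouse-Geisser
    corrected, within effects only), ``eta_p_sq``, ``eps`` (GG epsilon).
    """

    table: pd.DataFrame
    dv: str
    design: str

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect {name!r} in {list(self.table['effect'])}")
        return row.iloc[0]

    def summary(self) -> str:
        lines = [f"{self.design} ANOVA, dependent variable: {self.dv}", ""]
        header = f"{'effect':<12} {'F':>9} {'df':>9} {'p':>8} {'p(GG)':>8} {'eta_p^2':>8} {'eps':>6}"
        lines.append(header)
        lines.append("-" * len(header))
        for _, r in self.table.iterrows():
            p_gg = f"{r['p_gg']:.4f}" if np.isfinite(r.get("p_gg", np.nan)) else "     -"
            eps = f"{r['eps']:.3f}" if np.isfinite(r.get("eps", np.nan)) else "    -"
            df_str = "({:g},{:g})".format(r["df1"], r["df2"])
            lines.append(
                f"{r['effect']:<12} {r['F']:>9.3f} {df_str:>9} "
                f"{r['p']:>8.4f} {p_gg:>8} {r['eta_p_sq']:>8.4f} {eps:>6}"
            )
        return "\n".join(lines)


def _check_balance(data: pd.DataFrame, subject: str, within: str) -> None:
    counts = data.groupby(subject, observed=True)[within].nunique()
    n_levels = data[within].nunique()
    per_cell = data.groupby([subject, within], observed=True).size()
    if (counts != n_levels).any() or (per_cell != 1).any():
        bad = counts[counts != n_levels].index.tolist()
        raise UnbalancedDesignError(
            f"unbalanced within design (subjects missing levels: {bad or 'duplicated cells'}); "
            "no imputation is performed"
        )


class MixedAnova:
    """Split-plot ANOVA: one between-subject and one within-subject factor.

    Parameters
    ----------
    data
        Long DataFrame, one row per subject x within-level.
    dv, within, subject, between
        Column names of the dependent variable, the within-subject factor,
        the subject identifier, and the between-subject group factor.
    """

    def __init__(
        self, data: pd.DataFrame, dv: str, within: str, subject: str, between: str
    ) -> None:
        self.data = data.copy()
        self.dv, self.within, self.subject, self.between = dv, within, subject, between
        for col in (dv, within, subject, between):
            if col not in data.columns:
                raise KeyError(f"column {col!r} not in data")
        _check_balance(self.data, subject, within)
        groups_per_subject = self.data.groupby(subject, observed=True)[between].nunique()
        if (groups_per_subject != 1).any():
            raise UnbalancedDesignError("each subject must belong to exactly one group")
        n_per_group = self.data.groupby(between, observed=True)[subject].nunique()
        if (n_per_group < 2).any():
            raise UnbalancedDesignError("need at least 2 subjects per group")

    def fit(self) -> AnovaResults:
        aov = pg.mixed_anova(
            data=self.data,
            dv=self.dv,
            within=self.within,
            subject=self.subject,
            between=self.between,
            correction=True,
            effsize="np2",
        )
        if not np.isfinite(aov["F"]).all():
            raise DegenerateModelError("zero error variance; F undefined")
        aov = aov.set_index("Source")
        rows = []
        for effect, src in (
            ("between", self.between),
            ("within", self.within),
            ("interaction", "Interaction"),
        ):
            r = aov.loc[src]
            rows.append(
                dict(
                    effect=effect,
                    F=float(r["F"]),
                    df1=float(r["DF1"]),
                    df2=float(r["DF2"]),
                    p=float(r["p_unc"]),
                    p_gg=float(r.get("p_GG_corr", np.nan))
                    if np.isfinite(r.get("p_GG_corr", np.nan))
                    else np.nan,
                    eta_p_sq=float(r["np2"]),
                    eps=float(r.get("eps", np.nan)),
                )
            )
        return AnovaResults(pd.DataFrame(rows), self.dv, "mixed (split-plot)")


class RepeatedMeasuresAnova:
    """One-way repeated-measures ANOVA (within-subject factor only)."""

    def __init__(self, data: pd.DataFrame, dv: str, within: str, subject: str) -> None:
        self.data = data.copy()
        self.dv, self.within, self.subject = dv, within, subject
        for col in (dv, within, subject):
            if col not in data.columns:
                raise KeyError(f"column {col!r} not in data")
        _check_balance(self.data, subject, within)

    def fit(self) -> AnovaResults:
        try:
            aov = pg.rm_anova(
                data=self.data,
                dv=self.dv,
                within=self.within,
                subject=self.subject,
                correction=True,
                detailed=True,
            )
        except ZeroDivisionError:
            # sphericity correction undefined at n = 2 subjects
            aov = pg.rm_anova(
                data=self.data,
                dv=self.dv,
                within=self.within,
                subject=self.subject,
                correction=False,
                detailed=True,
            )
        aov = aov.set_index("Source")
        eff = aov.loc[self.within]
        err = aov.loc["Error"]
        if eff["SS"] == 0:
            # no within-subject variation at all: the effect is exactly null
            f_val, p_val, eta_p_sq = 0.0, 1.0, 0.0
        elif err["SS"] == 0:
            raise DegenerateModelError("zero error variance; F undefined")
        else:
            f_val = float(eff["F"])
            p_val = float(eff["p_unc"])
            eta_p_sq = float(eff["SS"] / (eff["SS"] + err["SS"]))
        rows = [
            dict(
                effect="within",
                F=f_val,
                df1=float(eff["DF"]),
                df2=float(err["DF"]),
                p=p_val,
                p_gg=float(eff.get("p_GG_corr", np.nan)),
                eta_p_sq=eta_p_sq,
                eps=float(eff.get("eps", np.nan)),
            )
        ]
        return AnovaResults(pd.DataFrame(rows), self.dv, "repeated-measures")
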