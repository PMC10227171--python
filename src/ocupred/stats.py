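"""Within-subject statistics for participant x condition score tables.

Implements the repeated-measures ANOVA used throughout this paradigm (one
or two within-subject factors), with Greenhouse-Geisser sphericity
correction, Mauchly's test, partial eta squared effect sizes, Holm- or
Bonferroni-adjusted pairwise contrasts, and the exploratory regression of
time-to-contact prediction timing on response time.

The ANOVA follows the classic univariate decomposition: for factors A and B
with a and b levels and n subjects (cell means per subject),

    F_A  = MS_A  / MS_{A x S},   df = (a-1), (a-1)(n-1)
    F_B  = MS_B  / MS_{B x S}
    F_AB = MS_AB / MS_{AB x S}

and the Greenhouse-Geisser epsilon for an effect with orthonormal contrast
basis C is  eps = tr(M)^2 / (d * tr(M^2))  with  M = C' S C,  S the
between-subject covariance of the cell scores and d the effect's degrees of
freedom.  Corrected p values use F with both dfs multiplied by eps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RepeatedMeasuresANOVA",
    "RMAnovaResults",
    "holm_adjust",
    "bonferroni_adjust",
    "pairwise_contrasts",
    "rt_ttc_regression",
]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p values.

    Sorted ascending, the i-th smallest p is multiplied by (m - i); a
    running maximum enforces monotonicity and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum(1.0, np.maximum.accumulate(p[order] * (m - np.arange(m))))
    out = np.empty(m)
    out[order] = adj
    return out


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni adjustment (each p multiplied by the family size)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A k x (k-1) orthonormal basis of the contrast (sum-to-zero) space."""
    c = np.eye(k) - 1.0 / k
    q, _r = np.linalg.qr(c)
    return q[:, : k - 1]


def _gg_epsilon(Y: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for cell scores Y (n x k) and basis C."""
    d = C.shape[1]
    if d <= 1:
        return 1.0
    S = np.cov(Y, rowvar=False, ddof=1)
    M = C.T @ S @ C
    tr = np.trace(M)
    denom = d * np.sum(M * M)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / d, tr * tr / denom)))


def _mauchly(Y: np.ndarray, C: np.ndarray) -> float:
    """Mauchly's sphericity test p value (chi-square approximation)."""
    n, _k = Y.shape
    d = C.shape[1]
    if d <= 1 or n <= d:
        return 1.0
    S = np.cov(Y, rowvar=False, ddof=1)
    M = C.T @ S @ C
    eig = np.linalg.eigvalsh(M)
    if np.any(eig <= 0):
        return 0.0
    W = np.prod(eig) / (np.mean(eig) ** d)
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1.0))
    chi2 = -(n - 1.0) * f * np.log(W)
    df = d * (d + 1) / 2.0 - 1.0
    return float(sps.chi2.sf(chi2, df))


@dataclass
class RMAnovaResults:
    """Fitted repeated-measures ANOVA.

    ``anova_table`` has one row per effect with sums of squares, F, raw and
    Greenhouse-Geisser-corrected dfs and p values, epsilon, Mauchly's p and
    partial eta squared.
    """

    anova_table: pd.DataFrame
    dv: str
    within: list[str]
    subject: str
    n_subjects: int
    gg_policy: str

    def p_value(self, effect: str) -> float:
        """The p value the fitting policy selects for ``effect``."""
        row = self.anova_table.loc[effect]
        use_gg = self.gg_policy == "always" or (
            self.gg_policy == "when_violated" and row["mauchly_p"] < 0.05
        )
        return float(row["p_gg"] if use_gg else row["p_unc"])

    def summary(self) -> str:
        lines = [
            f"Repeated-measures ANOVA: {self.dv} ~ {' * '.join(self.within)}"
            f"  (n = {self.n_subjects} subjects, GG policy = {self.gg_policy})",
            "",
        ]
        with pd.option_context("display.width", 120, "display.float_format", "{:0.4f}".format):
            lines.append(self.anova_table.to_string())
        return "\n".join(lines)


class RepeatedMeasuresANOVA:
    """One- or two-way fully within-subject ANOVA on a long-format table.

    Parameters
    ----------
    data : DataFrame
        Long format with one or more observations per subject and cell
        (replicates are averaged to the cell mean before decomposition).
    dv : str
        Dependent-variable column.
    within : str or list of str
        One or two within-subject factor columns.
    subject : str
        Subject identifier column.

    Examples
    --------
    >>> res = RepeatedMeasuresANOVA(df, dv="percent_correct",
    ...                             within=["speed", "occlusion_delay"],
    ...                             subject="participant").fit()
    >>> print(res.summary())
    """

    def __init__(self, data: pd.DataFrame, dv: str, within, subject: str):
        self.within = [within] if isinstance(within, str) else list(within)
        if len(self.within) not in (1, 2):
            raise ValueError("within must name one or two factors")
        self.dv, self.subject = dv, subject
        cols = [subject, *self.within, dv]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing columns: {missing}")
        self.data = data[cols].dropna(subset=[dv])

    @classmethod
    def from_score_table(cls, score_table, measure: str, within=None):
        """Build directly from a :class:`~ocupred.trial_scoring.ScoreTable`."""
        within = within or ["speed", "occlusion_delay"]
        return cls(
            score_table.measure_frame(measure), dv=measure, within=within,
            subject="participant",
        )

    def _cell_array(self) -> tuple[np.ndarray, list, list[list]]:
        """Cell means as an (n_subjects, a[, b]) array; errors on missing cells."""
        g = self.data.groupby([self.subject, *self.within], dropna=False)[self.dv].mean()
        wide = g.unstack(self.within) if len(self.within) > 1 else g.unstack(self.within[0])
        if wide.isna().any().any():
            miss = wide.stack(list(range(wide.columns.nlevels)), future_stack=True)
            miss = miss[miss.isna()].index.tolist()
            raise ValueError(f"missing cells (subject, {self.within}): {miss[:5]}")
        levels = (
            [list(wide.columns.levels[0]), list(wide.columns.levels[1])]
            if len(self.within) == 2
            else [list(wide.columns)]
        )
        subjects = list(wide.index)
        if len(self.within) == 2:
            a, b = len(levels[0]), len(levels[1])
            wide = wide.reindex(
                columns=pd.MultiIndex.from_product(levels), copy=False
            )
            arr = wide.to_numpy().reshape(len(subjects), a, b)
        else:
            arr = wide.to_numpy()
        return arr, subjects, levels

    def fit(self, gg: str = "always") -> RMAnovaResults:
        """Run the decomposition.

        ``gg`` selects when Greenhouse-Geisser-corrected p values are the
        reported ones: ``"always"`` (conservative default), ``"never"``, or
        ``"when_violated"`` (only when Mauchly's test rejects at 0.05).
        """
        if gg not in ("always", "never", "when_violated"):
            raise ValueError(f"unknown gg policy: {gg!r}")
        arr, subjects, levels = self._cell_array()
        n = len(subjects)
        if n < 2:
            raise ValueError("need at least 2 subjects")
        rows = (
            self._one_way(arr, levels) if len(self.within) == 1 else self._two_way(arr, levels)
        )
        table = pd.DataFrame(rows).set_index("effect")
        return RMAnovaResults(
            anova_table=table, dv=self.dv, within=self.within, subject=self.subject,
            n_subjects=n, gg_policy=gg,
        )

    @staticmethod
    def _effect_row(name, ss_eff, ss_err, df1, df2, Yflat, C) -> dict:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ss_eff <= 1e-12 * max(1.0, abs(ss_eff) + abs(ss_err)):
            F, p = 0.0, 1.0
        elif ms_err == 0:
            F, p = np.inf, 0.0
        else:
            F = ms_eff / ms_err
            p = float(sps.f.sf(F, df1, df2))
        eps = _gg_epsilon(Yflat, C)
        p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) and F > 0 else (
            1.0 if F == 0 else 0.0
        )
        return {
            "effect": name,
            "ss_effect": ss_eff,
            "ss_error": ss_err,
            "df_num": df1,
            "df_den": df2,
            "F": F,
            "p_unc": p,
            "eps_gg": eps,
            "df_num_gg": df1 * eps,
            "df_den_gg": df2 * eps,
            "p_gg": p_gg,
            "mauchly_p": _mauchly(Yflat, C),
            "partial_eta_sq": ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
        }

    def _one_way(self, Y: np.ndarray, levels) -> list[dict]:
        n, a = Y.shape
        grand = Y.mean()
        m_a = Y.mean(axis=0)
        m_s = Y.mean(axis=1)
        ss_a = n * np.sum((m_a - grand) ** 2)
        resid = Y - m_a[None, :] - m_s[:, None] + grand
        ss_as = np.sum(resid**2)
        C = _orthonormal_contrasts(a)
        return [
            self._effect_row(self.within[0], ss_a, ss_as, a - 1, (a - 1) * (n - 1), Y, C)
        ]

    def _two_way(self, Y: np.ndarray, levels) -> list[dict]:
        n, a, b = Y.shape
        grand = Y.mean()
        m_s = Y.mean(axis=(1, 2))
        m_a = Y.mean(axis=(0, 2))
        m_b = Y.mean(axis=(0, 1))
        m_ab = Y.mean(axis=0)
        m_sa = Y.mean(axis=2)
        m_sb = Y.mean(axis=1)

        ss_a = n * b * np.sum((m_a - grand) ** 2)
        ss_b = n * a * np.sum((m_b - grand) ** 2)
        ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
        ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
        ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
        ss_total = np.sum((Y - grand) ** 2)
        ss_s = a * b * np.sum((m_s - grand) ** 2)
        ss_sab = ss_total - ss_a - ss_b - ss_ab - ss_s - ss_sa - ss_sb

        nameA, nameB = self.within
        Ca = _orthonormal_contrasts(a)
        Cb = _orthonormal_contrasts(b)
        ones_a = np.full((a, 1), 1.0 / np.sqrt(a))
        ones_b = np.full((b, 1), 1.0 / np.sqrt(b))
        Yflat = Y.reshape(n, a * b)
        return [
            self._effect_row(
                nameA, ss_a, ss_sa, a - 1, (a - 1) * (n - 1), Yflat, np.kron(Ca, ones_b)
            ),
            self._effect_row(
                nameB, ss_b, ss_sb, b - 1, (b - 1) * (n - 1), Yflat, np.kron(ones_a, Cb)
            ),
            self._effect_row(
                f"{nameA}:{nameB}", ss_ab, ss_sab, (a - 1) * (b - 1),
                (a - 1) * (b - 1) * (n - 1), Yflat, np.kron(Ca, Cb),
            ),
        ]


def pairwise_contrasts(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Paired-t pairwise comparisons of one factor's levels.

    Observations are averaged to subject x level means first; ``adjust`` is
    ``"holm"`` (default), ``"bonferroni"`` or ``"none"``.
    """
    means = data.groupby([subject, within], dropna=False)[dv].mean().unstack(within)
    if means.isna().any().any():
        raise ValueError("missing subject x level cells in contrast data")
    rows = []
    for lo, hi in combinations(means.columns, 2):
        t, p = sps.ttest_rel(means[lo], means[hi])
        rows.append(
            {
                "pair": f"{lo} vs {hi}",
                "t": float(t),
                "df": len(means) - 1,
                "p_raw": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "holm":
        out["p_adjusted"] = holm_adjust(out["p_raw"])
    elif adjust == "bonferroni":
        out["p_adjusted"] = bonferroni_adjust(out["p_raw"])
    elif adjust == "none":
        out["p_adjusted"] = out["p_raw"]
    else:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    return out


def rt_ttc_regression(
    scores: pd.DataFrame,
    x: str = "saccadic_rt",
    y: str = "relative_ttc",
    by: str | list[str] = "speed",
) -> pd.DataFrame:
    """Per-condition OLS of TTC prediction timing on response time.

    Returns slope, intercept, Pearson r, p and n for every level of ``by``.
    Requires at least 3 trials and non-degenerate x variance per condition.
    """
    by = [by] if isinstance(by, str) else list(by)
    rows = []
    for key, g in scores.dropna(subset=[x, y]).groupby(by, dropna=False):
        if len(g) < 3:
            raise ValueError(f"condition {key}: need >= 3 trials, got {len(g)}")
        if np.isclose(np.var(g[x].to_numpy()), 0.0):
            raise ValueError(f"condition {key}: degenerate variance in {x}")
        fit = sps.linregress(g[x], g[y])
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(by, key))
            | {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r": fit.rvalue,
                "p": fit.pvalue,
                "n": len(g),
            }
        )
    return pd.DataFrame(rows)
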