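"""Scalp-level group inference on subject-level entrainment summaries.

Each subject is reduced upstream to a scalp-averaged zITC at the word and
syllable frequencies plus a word precision index (WPI).  Group questions:
(i) does each group show entrainment above the surrogate chance level
(one-sample t against 0, two-tailed), (ii) do the groups differ (one-way
ANOVA between groups; for two groups F is exactly the square of the pooled
two-sample t, asserted internally), and (iii) do the groups differ in WPI
(two-sample t, pooled variance by default with a Welch option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaResult",
    "one_sample_entrainment_test",
    "group_anova",
    "wpi_group_test",
    "group_report",
]

GROUPS = ("TDC", "FXS")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def one_sample_entrainment_test(values, mu: float = 0.0) -> TTestResult:
    """Two-tailed one-sample t-test of mean entrainment against ``mu``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if np.allclose(values.std(ddof=1), 0):
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(values, mu)
    return TTestResult(t=float(res.statistic), df=values.size - 1,
                       p=float(res.pvalue))


def _group_values(summaries: pd.DataFrame, measure: str):
    out = []
    for g in GROUPS:
        vals = summaries.loc[summaries["group"] == g, measure].to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
        out.append(vals)
    return out


def group_anova(summaries: pd.DataFrame, measure: str) -> AnovaResult:
    """One-way between-subject ANOVA on a subject-level measure.

    With two groups, F must equal the square of the pooled two-sample t;
    this identity is asserted as an internal consistency check.
    """
    a, b = _group_values(summaries, measure)
    F, p = sps.f_oneway(a, b)
    df1, df2 = 1, a.size + b.size - 2
    t_pooled = sps.ttest_ind(a, b, equal_var=True).statistic
    if np.isfinite(F) and not np.isclose(F, t_pooled**2, atol=1e-8):
        raise AssertionError("ANOVA F does not equal pooled t^2")
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=float(p))


def wpi_group_test(summaries: pd.DataFrame, welch: bool = False,
                   measure: str = "wpi") -> TTestResult:
    """Two-sample t-test on the word precision index between groups."""
    a, b = _group_values(summaries, measure)
    pooled_var = (
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if np.allclose(pooled_var, 0):
        raise ValueError("zero pooled variance: t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else a.size + b.size - 2
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def group_report(summaries: pd.DataFrame) -> dict:
    """Full scalp-level report: per-group one-sample tests, group ANOVAs at
    both tagged frequencies, and the WPI group contrast."""
    report: dict = {"n": {g: int((summaries["group"] == g).sum()) for g in GROUPS}}
    for measure in ("zitc_word", "zitc_syllable"):
        anova = group_anova(summaries, measure)
        entry = {
            "anova": {"F": anova.F, "df1": anova.df1, "df2": anova.df2,
                      "p": anova.p},
            "one_sample": {},
        }
        for g in GROUPS:
            vals = summaries.loc[summaries["group"] == g, measure]
            t = one_sample_entrainment_test(vals)
            entry["one_sample"][g] = {"t": t.t, "df": t.df, "p": t.p,
                                      "mean": float(vals.mean())}
        report[measure] = entry
    wpi = wpi_group_test(summaries)
    report["wpi"] = {
        "t": wpi.t, "df": wpi.df, "p": wpi.p,
        "mean": {g: float(summaries.loc[summaries["group"] == g, "wpi"].mean())
                 for g in GROUPS},
    }
    return report


def plot_group_spectra(z_by_group: dict[str, np.ndarray], freqs: np.ndarray,
                       word_bin: int, syllable_bin: int, path=None):
    """Group-mean zITC spectra with the tagged bins marked (optional figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for group, spectra in z_by_group.items():
        mean = spectra.mean(axis=0)
        sem = spectra.std(axis=0, ddof=1) / np.sqrt(spectra.shape[0])
        ax.plot(freqs, mean, label=group)
        ax.fill_between(freqs, mean - sem, mean + sem, alpha=0.25)
    for b, lab in ((word_bin, "word"), (syllable_bin, "syllable")):
        ax.axvline(freqs[b], ls="--", c="gray", lw=0.8)
        ax.text(freqs[b], ax.get_ylim()[1], lab, ha="center", va="bottom",
                fontsize=8)
    ax.set_xlabel("Frequency (Hz)")
    ax.set_ylabel("zITC")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
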