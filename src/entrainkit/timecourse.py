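"""Leave-one-out jackknife ITC pseudovalues and the learning time-course model.

ITC is undefined for a single epoch, so per-epoch estimates are obtained by
the jackknife: recompute ITC leaving out each epoch in turn, normalize each
replication by subtracting the mean jackknifed ITC over baseline bins
(0.66–5.0 Hz excluding the tagged frequencies and their harmonics at 1.11,
2.22, 3.33 and 4.44 Hz), and convert to pseudovalues

    pv_i = N * ITC_all − (N − 1) * JK_i

where ITC_all is the all-epoch ITC normalized by the same baseline rule.
A pseudovalue measures how much epoch i pulls the overall ITC up or down.
Because single-epoch estimates are noisy, the pseudovalue series is smoothed
with a centered 5-point moving average, which drops the first two and last
two epochs.  The group-level question — does word-rate entrainment grow
with exposure, and does that growth differ between groups? — is answered by
a linear mixed model:  smoothed_pv ~ epoch_number * group + (1 | subject),
with the control group as the reference level, fitted on the first half of
exposure where entrainment growth is expected to be approximately linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entrainment import identify_bin, unit_phasors
from .preprocess import EpochSet

__all__ = [
    "BASELINE_RANGE_HZ",
    "baseline_bins",
    "jackknife_itc",
    "normalize_jackknife",
    "pseudovalues",
    "smooth_pseudovalues",
    "pseudovalue_series",
    "PseudovalueSeries",
    "TimecourseFit",
    "fit_timecourse",
]

#: Frequency range (Hz) whose bins form the normalization baseline.
BASELINE_RANGE_HZ = (0.66, 5.0)


def baseline_bins(
    freqs: np.ndarray,
    word_rate: float,
    lo: float = BASELINE_RANGE_HZ[0],
    hi: float = BASELINE_RANGE_HZ[1],
    n_harmonics: int = 4,
) -> np.ndarray:
    """Bins in [lo, hi] Hz excluding the word rate and its harmonics.

    For 9.0 s epochs and a 1.11 Hz word rate this is bins 6–45 minus
    {10, 20, 30, 40} (2.22 Hz is the first word harmonic, 3.33 Hz is both
    the syllable rate and the second harmonic).
    """
    in_range = np.nonzero((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))[0]
    excluded = {
        identify_bin(freqs, k * word_rate) for k in range(1, n_harmonics + 1)
    }
    bins = np.array([b for b in in_range if b not in excluded])
    if bins.size == 0:
        raise ValueError("baseline bin set is empty")
    return bins


def jackknife_itc(
    epochs: EpochSet, bin_index: int | np.ndarray, channels=None
) -> tuple[np.ndarray, np.ndarray]:
    """All-epoch ITC and leave-one-out replications at the given bin(s).

    Uses the phasor-sum identity |S − u_i| / (N − 1) so the N replications
    cost one FFT pass.  Per-channel ITCs are averaged over the channel
    selection (default: all channels) before returning, matching a
    scalp-average analysis.

    Returns
    -------
    itc_all : ndarray, shape of ``bin_index``
    jk : ndarray, (N,) + shape of ``bin_index`` — element i is the ITC with
        epoch i left out.
    """
    n = epochs.n_epochs
    if n < 3:
        raise ValueError("jackknife requires at least 3 epochs")
    phasors = unit_phasors(epochs)[:, :, bin_index]  # epochs x channels x ...
    if channels is not None:
        ch_idx = [
            epochs.channel_labels.index(c) if isinstance(c, str) else int(c)
            for c in channels
        ]
        phasors = phasors[:, ch_idx]
    total = phasors.sum(axis=0)
    itc_all = np.abs(total / n).mean(axis=0)
    jk = np.abs((total[None] - phasors) / (n - 1)).mean(axis=1)
    return itc_all, jk


def normalize_jackknife(
    raw_target: np.ndarray, raw_baseline: np.ndarray
) -> np.ndarray:
    """Subtract, per replication, the mean jackknifed ITC over baseline bins."""
    raw_target = np.asarray(raw_target, dtype=float)
    raw_baseline = np.asarray(raw_baseline, dtype=float)
    if raw_baseline.ndim != 2 or raw_baseline.shape[1] == 0:
        raise ValueError("baseline must be replications x bins, non-empty")
    if raw_baseline.shape[0] != raw_target.shape[0]:
        raise ValueError("target and baseline replication counts differ")
    return raw_target - raw_baseline.mean(axis=1)


def pseudovalues(itc_all: float, jk: np.ndarray, n: int) -> np.ndarray:
    """Jackknife pseudovalues: pv_i = N*ITC_all − (N−1)*JK_i."""
    jk = np.asarray(jk, dtype=float)
    if jk.shape[0] != n:
        raise ValueError("N must equal the number of jackknife replications")
    return n * itc_all - (n - 1) * jk


def smooth_pseudovalues(series: np.ndarray, span: int = 5) -> np.ndarray:
    """Centered moving average; drops (span−1)/2 points at each end."""
    series = np.asarray(series, dtype=float)
    if span % 2 != 1 or span < 3:
        raise ValueError("span must be an odd integer >= 3")
    if series.size < span:
        raise ValueError(f"series shorter than the smoothing span ({span})")
    return np.convolve(series, np.ones(span) / span, mode="valid")


@dataclass(frozen=True)
class PseudovalueSeries:
    """Per-epoch jackknife quantities for one subject and tagged frequency."""

    subject_id: str
    frequency: str  # "word" | "syllable"
    epoch_index: np.ndarray  # 1..N
    onsets: np.ndarray  # epoch onsets, seconds
    raw_jackknife: np.ndarray
    normalized_jackknife: np.ndarray
    pseudovalue: np.ndarray
    smoothed_pseudovalue: np.ndarray  # length N−4, epochs 3..N−2
    itc_all_normalized: float

    def to_frame(self, group: str | None = None,
                 stream_duration: float | None = None) -> pd.DataFrame:
        """Tidy frame over the smoothed epochs (3..N−2)."""
        n = self.epoch_index.size
        inner = slice(2, n - 2)
        df = pd.DataFrame(
            {
                "subject": self.subject_id,
                "frequency": self.frequency,
                "epoch_index": self.epoch_index[inner],
                "onset": self.onsets[inner],
                "pseudovalue": self.pseudovalue[inner],
                "smoothed_pseudovalue": self.smoothed_pseudovalue,
            }
        )
        if group is not None:
            df.insert(1, "group", group)
        if stream_duration is not None:
            df["onset_frac"] = df["onset"] / stream_duration
        return df


def pseudovalue_series(
    epochs: EpochSet,
    frequency: str,
    word_rate: float,
    syllable_rate: float,
    channels=None,
    span: int = 5,
) -> PseudovalueSeries:
    """Full jackknife pipeline for one subject at one tagged frequency."""
    freqs = epochs.freqs
    target_hz = word_rate if frequency == "word" else syllable_rate
    target_bin = identify_bin(freqs, target_hz)
    base_bins = baseline_bins(freqs, word_rate)

    all_bins = np.concatenate(([target_bin], base_bins))
    itc_all_vec, jk_mat = jackknife_itc(epochs, all_bins, channels=channels)
    raw_jk = jk_mat[:, 0]
    norm_jk = normalize_jackknife(raw_jk, jk_mat[:, 1:])
    itc_all_norm = float(itc_all_vec[0] - itc_all_vec[1:].mean())
    n = epochs.n_epochs
    pv = pseudovalues(itc_all_norm, norm_jk, n)
    smoothed = smooth_pseudovalues(pv, span=span)
    return PseudovalueSeries(
        subject_id=epochs.subject_id or "sub-01",
        frequency=frequency,
        epoch_index=np.arange(1, n + 1),
        onsets=epochs.onsets,
        raw_jackknife=raw_jk,
        normalized_jackknife=norm_jk,
        pseudovalue=pv,
        smoothed_pseudovalue=smoothed,
        itc_all_normalized=itc_all_norm,
    )


@dataclass(frozen=True)
class TimecourseFit:
    """Fixed effects and per-group marginal slopes of the time-course model."""

    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    slopes: dict[str, dict[str, float]]  # group -> estimate/se/t/p
    method: str  # "mixedlm" | "ols_fallback"
    converged: bool
    n_obs: int


def _slope_test(est: float, se: float, df: float) -> dict[str, float]:
    from scipy import stats as sps

    t = est / se if se > 0 else np.nan
    p = 2 * sps.t.sf(abs(t), df) if np.isfinite(t) else np.nan
    return {"estimate": est, "se": se, "t": t, "p": p}


def fit_timecourse(
    table: pd.DataFrame,
    first_half_only: bool = True,
    reference_group: str = "TDC",
    value_col: str = "smoothed_pseudovalue",
) -> TimecourseFit:
    """Mixed model smoothed_pv ~ epoch_index * group + (1 | subject).

    ``table`` is the tidy cohort frame (one row per subject x epoch) with
    columns subject, group, epoch_index, ``value_col`` and, when
    ``first_half_only`` is set, onset_frac (epoch onset as a fraction of the
    stream duration; the first half of exposure is onset_frac < 0.5).

    p-values use a t distribution on residual degrees of freedom.  If the
    mixed model fails to converge or is singular, falls back to per-subject
    OLS slopes compared by a two-sample t-test (flagged in ``method``).
    """
    import statsmodels.formula.api as smf

    df = table.copy()
    if first_half_only:
        if "onset_frac" not in df.columns:
            raise ValueError("first_half_only requires an onset_frac column")
        df = df[df["onset_frac"] < 0.5]
    groups = sorted(df["group"].unique(), key=lambda g: g != reference_group)
    if len(groups) != 2:
        raise ValueError("time-course model expects exactly 2 groups")
    other = groups[1]
    per_group_counts = df.groupby("group")["subject"].nunique()
    if (per_group_counts < 2).any():
        return _ols_fallback(df, reference_group, other, value_col)

    formula = (
        f"{value_col} ~ epoch_index * C(group, Treatment('{reference_group}'))"
    )
    fit = None
    for fit_kwargs in ({"reml": True}, {"reml": True, "method": "powell"}):
        try:
            model = smf.mixedlm(formula, df, groups=df["subject"])
            candidate = model.fit(**fit_kwargs)
            if candidate.converged and np.all(np.isfinite(candidate.bse_fe)):
                fit = candidate
                break
        except Exception:
            continue
    if fit is None:
        return _ols_fallback(df, reference_group, other, value_col)

    names = list(fit.fe_params.index)
    resid_df = len(df) - len(names)
    inter_name = next(
        n for n in names if ":" in n and "epoch_index" in n
    )
    grp_key = f"C(group, Treatment('{reference_group}'))[T.{other}]"

    cov = fit.cov_params().loc[names, names].to_numpy()
    i_slope = names.index("epoch_index")
    i_inter = names.index(inter_name)
    b = fit.fe_params
    slope_ref = _slope_test(
        float(b["epoch_index"]), float(np.sqrt(cov[i_slope, i_slope])), resid_df
    )
    est_other = float(b["epoch_index"] + b[inter_name])
    var_other = cov[i_slope, i_slope] + cov[i_inter, i_inter] + 2 * cov[i_slope, i_inter]
    slope_other = _slope_test(est_other, float(np.sqrt(max(var_other, 0))), resid_df)

    from scipy import stats as sps

    pvals = {
        n: float(2 * sps.t.sf(abs(fit.fe_params[n] / fit.bse_fe[n]), resid_df))
        for n in names
    }
    return TimecourseFit(
        params={n: float(fit.fe_params[n]) for n in names},
        bse={n: float(fit.bse_fe[n]) for n in names},
        tvalues={n: float(fit.fe_params[n] / fit.bse_fe[n]) for n in names},
        pvalues=pvals,
        slopes={reference_group: slope_ref, other: slope_other},
        method="mixedlm",
        converged=True,
        n_obs=len(df),
    )


def _ols_fallback(
    df: pd.DataFrame, ref: str, other: str, value_col: str
) -> TimecourseFit:
    """Per-subject OLS slopes, compared between groups with Student's t."""
    from scipy import stats as sps

    slopes: dict[str, list[float]] = {ref: [], other: []}
    for (subj, grp), sub in df.groupby(["subject", "group"]):
        if sub["epoch_index"].nunique() < 2:
            continue
        beta = np.polyfit(sub["epoch_index"], sub[value_col], 1)[0]
        slopes[grp].append(float(beta))

    out_slopes = {}
    for grp, vals in slopes.items():
        vals = np.asarray(vals)
        if vals.size >= 2:
            t, p = sps.ttest_1samp(vals, 0.0)
            out_slopes[grp] = {
                "estimate": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                "t": float(t),
                "p": float(p),
            }
        else:
            out_slopes[grp] = {
                "estimate": float(vals.mean()) if vals.size else np.nan,
                "se": np.nan, "t": np.nan, "p": np.nan,
            }
    a, bvals = np.asarray(slopes[ref]), np.asarray(slopes[other])
    if a.size >= 2 and bvals.size >= 2:
        t_int, p_int = sps.ttest_ind(bvals, a)
    else:
        t_int, p_int = np.nan, np.nan
    key = "epoch_index:group"
    return TimecourseFit(
        params={key: float(bvals.mean() - a.mean()) if a.size and bvals.size else np.nan},
        bse={},
        tvalues={key: float(t_int)},
        pvalues={key: float(p_int)},
        slopes=out_slopes,
        method="ols_fallback",
        converged=False,
        n_obs=len(df),
    )
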