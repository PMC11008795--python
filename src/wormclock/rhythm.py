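"""Periodogram-based rhythmicity analysis and group statistics.

Rhythm power is the classical variance-normalized Lomb-Scargle power
(Horne-Baliunas normalization: raw least-squares spectral power divided by
the series variance), evaluated on a period grid restricted to the circadian
band (default 20-28 h).  The rhythmic/arrhythmic call follows a fixed power
threshold applied to the LD and DD phases jointly, with an explicit
visual-inspection override channel.

Absolute power values depend on the periodogram normalization of the software
that produced a given threshold; a ``power_scale`` factor (calibrated on
labelled data via :func:`calibrate_power_scale`) maps this implementation's
scale onto an external threshold convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .behavior import ActivityTrace, BinnedActivity, bin_activity

__all__ = [
    "Periodogram",
    "RhythmClassification",
    "DielActivityBins",
    "lomb_scargle",
    "circadian_power",
    "significance_level",
    "classify_rhythmicity",
    "calibrate_power_scale",
    "diel_bins",
    "compare_groups",
]


@dataclass
class Periodogram:
    periods_h: np.ndarray
    power: np.ndarray
    n_samples: int
    method_params: dict
    constant_input: bool = False


@dataclass
class RhythmClassification:
    power_ld: float
    power_dd: float
    period_ld: float
    period_dd: float
    call: str  # rhythmic | arrhythmic | intermediate
    override_applied: bool = False
    note: str = ""


@dataclass
class DielActivityBins:
    """Cumulative activity in morning (ZT0-8), afternoon (ZT8-16), night (ZT16-24)."""

    phase: str
    early_day: float
    late_day: float
    night: float

    @property
    def total(self) -> float:
        return self.early_day + self.late_day + self.night


def _series_from(series, phase: str | None, prebin_min: float):
    """Extract (t_hours, values) from a trace (pre-binned) or BinnedActivity."""
    if isinstance(series, BinnedActivity):
        b = series
        t = np.concatenate([
            d * 24.0 + b.zt_of_bin + b.bin_width_min / 120.0
            for d in range(b.bins.shape[0])
        ])
        return t, b.bins.ravel().astype(float)
    if isinstance(series, ActivityTrace):
        trace = series.restrict_phase(phase) if phase is not None else series
        b = bin_activity(trace, bin_width_min=prebin_min,
                         phase=phase if phase is not None else trace.phase[0])
        t = np.concatenate([
            d * 24.0 + b.zt_of_bin + b.bin_width_min / 120.0
            for d in range(b.bins.shape[0])
        ])
        mask = np.repeat(b.complete, b.n_bins)
        # incomplete days contribute their recorded bins only
        counts = b.bins.ravel()
        return t, counts
    raise TypeError(f"unsupported series type {type(series)!r}")


def lomb_scargle(series, period_range_h=(20.0, 28.0), grid_step_h: float = 0.1,
                 phase: str | None = None, prebin_min: float = 10.0) -> Periodogram:
    """Normalized Lomb-Scargle periodogram on a circadian period grid.

    Input may be an :class:`ActivityTrace` (binned to ``prebin_min`` minutes
    first; pass ``phase`` to select LD or DD) or a ready
    :class:`BinnedActivity`.  The series is mean-subtracted and the raw
    spectral power divided by its variance, so a pure sinusoid of amplitude A
    in noise of variance s2 peaks near N*A^2/(4*s2).
    """
    t_h, y = _series_from(series, phase, prebin_min)
    lo, hi = period_range_h
    if not lo < hi:
        raise ValueError("period_range_h must be increasing")
    periods = np.arange(lo, hi + grid_step_h / 2, grid_step_h)
    y = y.astype(float)
    var = y.var()
    if var == 0:
        warnings.warn("constant input series: zero power everywhere")
        return Periodogram(periods, np.zeros_like(periods), y.size,
                           {"period_range_h": period_range_h, "grid_step_h": grid_step_h},
                           constant_input=True)
    yc = y - y.mean()
    omega = 2 * np.pi / periods
    power = signal.lombscargle(t_h, yc, omega) / var
    return Periodogram(periods, power, y.size,
                       {"period_range_h": period_range_h, "grid_step_h": grid_step_h})


def circadian_power(pg: Periodogram, band_h=(20.0, 28.0)):
    """(period_h, power) at the band-restricted power maximum.

    Equal maxima resolve to the shorter period (the grid is ascending and the
    first argmax wins).
    """
    eps = 1e-9
    m = (pg.periods_h >= band_h[0] - eps) & (pg.periods_h <= band_h[1] + eps)
    if not m.any():
        raise ValueError("periodogram grid does not cover the requested band")
    idx = np.flatnonzero(m)
    k = idx[int(np.argmax(pg.power[idx]))]
    return float(pg.periods_h[k]), float(pg.power[k])


def significance_level(pg: Periodogram, alpha: float = 0.01,
                       duration_h: float | None = None) -> float:
    """Approximate (1-alpha) significance level for the band maximum.

    Under Gaussian white noise the normalized power at one frequency is
    Exp(1); the band maximum over M effectively independent frequencies
    exceeds z with probability 1-(1-exp(-z))^M.  M is the number of
    Fourier-resolution elements the band spans for a record of the given
    duration; when the duration is unknown the grid length is used (a
    conservative, larger M).
    """
    lo, hi = pg.method_params["period_range_h"]
    if duration_h is not None:
        band_width = 1.0 / lo - 1.0 / hi
        m = max(1, int(np.ceil(band_width * duration_h)))
    else:
        m = len(pg.periods_h)
    return float(-np.log(1.0 - (1.0 - alpha) ** (1.0 / m)))


def classify_rhythmicity(power_ld: float | None, power_dd: float | None,
                         threshold: float = 150.0, power_scale: float = 1.0,
                         visual_override: str | None = None) -> RhythmClassification:
    """Threshold rule: rhythmic if scaled power > threshold in LD and/or DD,
    arrhythmic if below in both; a visual override may force either call
    (mirroring actogram inspection) and is logged, but never 'intermediate'.

    A missing phase (None) is treated as failing its clause.
    """
    if visual_override not in (None, "rhythmic", "arrhythmic"):
        raise ValueError("visual_override must be 'rhythmic' or 'arrhythmic'")
    p_ld = -np.inf if power_ld is None else power_ld * power_scale
    p_dd = -np.inf if power_dd is None else power_dd * power_scale
    call = "rhythmic" if (p_ld > threshold or p_dd > threshold) else "arrhythmic"
    note = ""
    override_applied = False
    if visual_override is not None and visual_override != call:
        note = f"rule call {call!r} overridden to {visual_override!r} by visual inspection"
        call = visual_override
        override_applied = True
    return RhythmClassification(
        power_ld=np.nan if power_ld is None else float(power_ld),
        power_dd=np.nan if power_dd is None else float(power_dd),
        period_ld=np.nan, period_dd=np.nan,
        call=call, override_applied=override_applied, note=note,
    )


def calibrate_power_scale(powers, labels, threshold: float = 150.0) -> float:
    """Map this implementation's power scale onto a threshold convention.

    ``powers`` is, per individual, the max of the LD and DD circadian powers;
    ``labels`` the known rhythmic/arrhythmic status of a calibration cohort.
    Returns the factor s such that ``s * power`` best separates the classes at
    ``threshold`` (geometric midpoint of the class boundary when separable,
    otherwise the error-minimizing cut).
    """
    powers = np.asarray(powers, float)
    labels = np.asarray(labels)
    rh = powers[labels == "rhythmic"]
    ar = powers[labels == "arrhythmic"]
    if rh.size == 0 or ar.size == 0:
        raise ValueError("calibration needs both rhythmic and arrhythmic labels")
    lo, hi = ar.max(), rh.min()
    if lo < hi and lo > 0:
        cut = float(np.sqrt(lo * hi))
    else:
        cands = np.sort(np.unique(powers))
        mids = (cands[:-1] + cands[1:]) / 2.0
        errs = [np.sum(rh <= c) + np.sum(ar > c) for c in mids]
        cut = float(mids[int(np.argmin(errs))])
    if cut <= 0:
        raise ValueError("degenerate calibration cut")
    return threshold / cut


def diel_bins(trace: ActivityTrace, phase: str = "LD") -> DielActivityBins:
    """Cumulative activity in the three 8-h diel bins, pooled over all days.

    Bins are half-open in ZT (LD) or CT (DD): morning [0,8), afternoon [8,16),
    night [16,24).
    """
    sub = trace.restrict_phase(phase)
    zt = sub.zt_hours()
    a = sub.activity
    return DielActivityBins(
        phase=phase,
        early_day=float(a[(zt >= 0) & (zt < 8)].sum()),
        late_day=float(a[(zt >= 8) & (zt < 16)].sum()),
        night=float(a[(zt >= 16) & (zt < 24)].sum()),
    )


# ---------------------------------------------------------------------------
# Test-selection logic for group comparisons


def _dunn_posthoc(groups, labels):
    """Dunn's z tests on pooled ranks, Holm-adjusted."""
    all_vals = np.concatenate(groups)
    ranks = stats.rankdata(all_vals)
    n = all_vals.size
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    splits = np.cumsum([len(g) for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ni, nj = len(groups[i]), len(groups[j])
            diff = group_ranks[i].mean() - group_ranks[j].mean()
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
            z = diff / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "statistic": z, "p_raw": p})
    df = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests
    df["p_adj"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def _pairwise_welch(groups, labels, adjust):
    """Pairwise Welch t tests; 'holm-sidak' (equal-var pairs handled upstream)
    or 'sidak' adjustment (the Dunnett-T3-style correction)."""
    from statsmodels.stats.multitest import multipletests
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t, p = stats.ttest_ind(groups[i], groups[j], equal_var=False)
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "statistic": float(t), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"], method=adjust)[1]
    return df


def compare_groups(samples: dict, alpha_diag: float = 0.05, paired: bool = False):
    """Diagnostic-driven test selection for 2+ groups.

    Normality is checked per group with Shapiro-Wilk, homoscedasticity with
    Brown-Forsythe (Levene on medians), both at ``alpha_diag``.  Selection:

    ====================  ==========================  ==============================
    groups                diagnostics pass            diagnostics fail
    ====================  ==========================  ==============================
    2                     unpaired two-sided t        Mann-Whitney U
    >=3, normal+eq var    one-way ANOVA + Holm-Sidak  --
    >=3, normal, uneq     Welch ANOVA + Dunnett-T3    --
    >=3, non-normal       --                          Kruskal-Wallis + Dunn
    ====================  ==========================  ==============================

    Groups with n < 3 refuse the parametric branch (Shapiro is undefined).
    Returns a dict report with diagnostics, selected test, statistic, p and a
    post-hoc table for >= 3 groups.
    """
    labels = list(samples.keys())
    groups = [np.asarray(samples[k], float) for k in labels]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    small = any(len(g) < 3 for g in groups)
    if small:
        normal = False
        normality_p = [np.nan] * len(groups)
    else:
        normality_p = [float(stats.shapiro(g).pvalue) for g in groups]
        normal = all(p > alpha_diag for p in normality_p)
    bf = stats.levene(*groups, center="median")
    homoscedastic = bf.pvalue > alpha_diag
    report = {
        "normality_p": dict(zip(labels, normality_p)),
        "normal": normal,
        "brown_forsythe_p": float(bf.pvalue),
        "homoscedastic": bool(homoscedastic),
        "posthoc": None,
    }
    if len(groups) == 2:
        if paired:
            if normal:
                t, p = stats.ttest_rel(groups[0], groups[1])
                report.update(test="paired t", statistic=float(t), p=float(p))
            else:
                t, p = stats.wilcoxon(groups[0], groups[1])
                report.update(test="wilcoxon signed-rank", statistic=float(t), p=float(p))
        elif normal and homoscedastic:
            t, p = stats.ttest_ind(groups[0], groups[1])
            report.update(test="unpaired two-sided t", statistic=float(t), p=float(p))
        else:
            u, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            report.update(test="mann-whitney u", statistic=float(u), p=float(p))
        return report
    # 3+ groups
    if normal and homoscedastic:
        f, p = stats.f_oneway(*groups)
        report.update(test="one-way anova + holm-sidak", statistic=float(f), p=float(p),
                      posthoc=_pairwise_welch(groups, labels, "holm-sidak"))
    elif normal:
        import pingouin as pg
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(labels, [len(g) for g in groups]),
        })
        aov = pg.welch_anova(dv="y", between="g", data=df)
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        report.update(test="welch anova + dunnett-t3",
                      statistic=float(aov["F"].iloc[0]),
                      p=float(aov[pcol].iloc[0]),
                      posthoc=_pairwise_welch(groups, labels, "sidak"))
    else:
        h, p = stats.kruskal(*groups)
        report.update(test="kruskal-wallis + dunn", statistic=float(h), p=float(p),
                      posthoc=_dunn_posthoc(groups, labels))
    return report
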