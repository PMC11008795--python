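"""Phenotype-stratified detection of 24-h cycling transcripts.

The detector is a waveform-agnostic, rank-based cyclic umbrella test for
independent-samples diel designs (each timepoint = independent pools of
animals).  For each admissible peak timepoint p* (fractional position within
``peak_border`` of the period), the alternative is a cyclic umbrella
ordering: expression rises from the first timepoint to p*, falls afterwards,
and wraps around the period back to the first timepoint.  Each shape is
scored by summing, over consecutive (cyclic) timepoint pairs, the one-sided
Mann-Whitney count of sample pairs ordered in the hypothesized direction
(ties counted half).  The statistic depends on the data only through
within-transcript ranks, so p-values are invariant under any strictly
increasing transformation of a transcript's values.

Significance is assessed against the permutation null (random reassignment
of samples to timepoints), Monte-Carlo sampled with a shared, seeded set of
permutations; per-shape mid-p-values are combined across shapes by
minimum-with-Bonferroni.  Mid-p (half weight on ties with the observed
statistic) keeps the null p distribution close to uniform despite the
statistic's discreteness.

Downstream: Benjamini-Hochberg correction per phenotype, the four-way
category partition (cycling in the rhythmic phenotype only / the arrhythmic
only / both / none), peak-phase estimation, joint heatmap normalization to
[-1, 1], and the replicate-variance comparison separating phase
desynchronization across individuals (scenario A: higher replicate spread)
from genuine absence of cycling (scenario B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_transcripts",
    "normalize",
    "detect_cycling",
    "umbrella_shapes",
    "adjust_and_categorize",
    "partition_summary",
    "PartitionSummary",
    "peak_phase",
    "heatmap_normalize",
    "variance_scenarios",
]


def _check_design(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    if set(counts.columns) != set(design["sample_id"]):
        raise ValueError("count matrix columns and design sample_ids do not match")


def filter_transcripts(counts: pd.DataFrame, design: pd.DataFrame,
                       lengths: pd.Series, min_len_bp: int = 500,
                       min_timepoints: int = 2, rule: str = "keep",
                       log: dict | None = None) -> pd.DataFrame:
    """Expression and length pre-filter.

    A timepoint counts as "expressed" when the summed counts over its
    replicates are nonzero.  Under the default ``rule='keep'`` a transcript
    is retained iff it is expressed at >= ``min_timepoints`` timepoints in
    EACH phenotype group and its length is >= ``min_len_bp``.  The
    alternative reading of the removal sentence (``rule='remove'``: drop only
    transcripts with < ``min_timepoints`` expressed timepoints in BOTH
    groups) is available behind the flag.

    Pass a dict as ``log`` to receive a per-transcript removal reason.
    """
    _check_design(counts, design)
    if rule not in ("keep", "remove"):
        raise ValueError("rule must be 'keep' or 'remove'")
    expressed_ok = {}
    for pheno, sub in design.groupby("phenotype"):
        per_tp = (
            counts[sub["sample_id"]]
            .T.groupby(sub.set_index("sample_id")["zt_h"]).sum().T
        )
        expressed_ok[pheno] = (per_tp > 0).sum(axis=1) >= min_timepoints
    ok = pd.DataFrame(expressed_ok)
    expr_keep = ok.all(axis=1) if rule == "keep" else ok.any(axis=1)
    len_keep = lengths.reindex(counts.index) >= min_len_bp
    keep = expr_keep & len_keep
    if log is not None:
        for t in counts.index[~keep]:
            reasons = []
            if not expr_keep.loc[t]:
                reasons.append(f"expressed at <{min_timepoints} timepoints")
            if not len_keep.loc[t]:
                reasons.append(f"length <{min_len_bp} bp")
            log[t] = "; ".join(reasons)
    return counts.loc[keep]


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios size factors followed by log2(count/sf + 1).

    The reference is the per-transcript geometric mean over samples,
    computed on transcripts with all-nonzero counts; if none exists, falls
    back to total-count size factors (scaled to geometric mean 1) with a
    warning.  Downstream rank-based testing is invariant to any monotone
    per-transcript transform, so the choice matters only for the variance
    analyses, which compare phenotypes under identical treatment.
    """
    if counts.size == 0:
        raise ValueError("empty count matrix")
    x = counts.to_numpy(float)
    all_nonzero = (x > 0).all(axis=1)
    if all_nonzero.any():
        logs = np.log(x[all_nonzero])
        ref = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - ref, axis=0))
    else:
        warnings.warn("no transcript with all-nonzero counts; "
                      "using total-count size factors")
        tot = x.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(tot)))
    norm = np.log2(x / sf + 1.0)
    return pd.DataFrame(norm, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Umbrella cycling test


def umbrella_shapes(zts: np.ndarray, period_h: float, peak_border=(0.3, 0.7)):
    """Admissible cyclic umbrella shapes as (trough, peak) index pairs.

    A shape rises from the trough timepoint to the peak timepoint (going
    cyclically) and falls back around the wrap.  ``peak_border`` constrains
    the waveform asymmetry: the fraction of the period spent rising must lie
    within ``[peak_border[0], peak_border[1]]``.  The peak position itself is
    scanned over all timepoints, so every phase is detectable.
    """
    zts = np.asarray(zts, float)
    m = zts.size
    shapes = []
    for j in range(m):  # trough
        for k in range(m):  # peak
            if j == k:
                continue
            rise = ((zts[k] - zts[j]) % period_h) / period_h
            if peak_border[0] <= rise <= peak_border[1]:
                shapes.append((j, k))
    if not shapes:
        raise ValueError(
            f"no (trough, peak) pair has rise fraction within {peak_border}")
    return shapes


def _edge_direction_matrix(n_tp: int, shapes: list) -> np.ndarray:
    """directions[s, e] = +1 if cyclic edge e (t_e -> t_{e+1 mod n}) rises
    under shape s (lies on the trough -> peak arc), else -1."""
    d = np.empty((len(shapes), n_tp), dtype=float)
    for s, (j, k) in enumerate(shapes):
        for e in range(n_tp):
            on_rise = ((e - j) % n_tp) < ((k - j) % n_tp)
            d[s, e] = 1.0 if on_rise else -1.0
    return d


def _edge_u(ranks: np.ndarray, groups: list) -> np.ndarray:
    """Directed Mann-Whitney counts per cyclic edge.

    ranks: (..., n_samples) midranks.  Returns U of shape (..., n_edges)
    where U[..., e] counts pairs (a in group e, b in group e+1) with
    rank_a < rank_b, ties 0.5.
    """
    n_tp = len(groups)
    out = []
    for e in range(n_tp):
        ia = groups[e]
        ib = groups[(e + 1) % n_tp]
        a = ranks[..., ia][..., :, None]
        b = ranks[..., ib][..., None, :]
        u = (a < b).sum(axis=(-2, -1)) + 0.5 * (a == b).sum(axis=(-2, -1))
        out.append(u)
    return np.stack(out, axis=-1)


def detect_cycling(norm: pd.DataFrame, design: pd.DataFrame,
                   period_h: float = 24.0, peak_border=(0.3, 0.7),
                   n_perm: int = 1999, seed: int = 0,
                   chunk: int = 64, exact_limit: int = 45000) -> pd.Series:
    """Per-transcript raw p-values for 24-h cycling in one phenotype's samples.

    ``design`` must be restricted to a single phenotype and cover
    ``norm``'s columns; >= 4 distinct timepoints with >= 2 replicates each
    are required.  Returns a Series of raw (mid-)p-values indexed like
    ``norm``.

    Multiplicity over umbrella shapes is absorbed into the permutation
    calibration: the transcript statistic is the minimum per-shape mid-p, and
    its p-value is the mid-p of that minimum within its own permutation
    distribution (the observed arrangement counts as one member of the null
    set).  Under the null the result is uniform up to the permutation grid,
    regardless of how strongly the shapes overlap.

    For small designs (n! <= ``exact_limit``, e.g. 4 timepoints x 2
    replicates) the full permutation group is enumerated instead of sampled,
    making the p-values exact; ``n_perm`` and ``seed`` are then ignored.
    """
    if design["phenotype"].nunique() != 1:
        raise ValueError("design must be restricted to one phenotype")
    sample_order = list(design.sort_values(["zt_h", "replicate"])["sample_id"])
    if not set(sample_order) <= set(norm.columns):
        raise ValueError("design samples missing from matrix")
    x = norm[sample_order].to_numpy(float)
    zt_sorted = design.sort_values(["zt_h", "replicate"])["zt_h"].to_numpy()
    zts, counts_per_tp = np.unique(zt_sorted, return_counts=True)
    if zts.size < 4:
        raise ValueError("need at least 4 distinct timepoints")
    if counts_per_tp.min() < 2:
        raise ValueError("need at least 2 replicates per timepoint")
    groups = []
    start = 0
    for c in counts_per_tp:
        groups.append(np.arange(start, start + c))
        start += c
    n = x.shape[1]
    shapes = umbrella_shapes(zts, period_h, peak_border)
    dirs = _edge_direction_matrix(zts.size, shapes)  # (S, E)
    rise = (dirs > 0).astype(float)
    fall = (dirs < 0).astype(float)
    mn = np.array([len(groups[e]) * len(groups[(e + 1) % zts.size])
                   for e in range(zts.size)], dtype=float)

    import itertools
    import math

    exact = math.factorial(n) <= exact_limit
    if exact:
        perms = np.array(list(itertools.permutations(range(n))))  # identity first
        M = len(perms)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])  # shared
        M = n_perm + 1  # sampled permutations + the observed arrangement

    ranks = stats.rankdata(x, axis=1)  # midranks per transcript
    pvals = np.empty(x.shape[0])
    chunk = max(1, min(chunk, int(4_000_000 / max(M * n, 1))))
    for lo in range(0, x.shape[0], chunk):
        r = ranks[lo:lo + chunk]  # (C, n)
        if exact:
            rp = r[:, perms]  # (C, M, n); identity arrangement at index 0
        else:
            rp = np.concatenate([r[:, None, :], r[:, perms]], axis=1)  # (C, M, n)
        u = _edge_u(rp, groups)  # (C, M, E)
        # directed statistic per shape: rising edges count concordant pairs,
        # falling edges the reverse ordering
        s = np.einsum("cme,se->cms", u, rise) + \
            np.einsum("cme,se->cms", mn[None, None, :] - u, fall)
        # per-shape mid-p of every arrangement within the pooled null set
        rk = stats.rankdata(s, axis=1, method="average")  # high s -> high rank
        p_shape = (M - rk + 0.5) / M
        minp = p_shape.min(axis=2)  # (C, M)
        rk_min = stats.rankdata(minp, axis=1, method="average")  # low minp extreme
        p_final = (rk_min - 0.5) / M
        pvals[lo:lo + chunk] = p_final[:, 0]
    return pd.Series(pvals, index=norm.index, name="p")


# ---------------------------------------------------------------------------
# FDR, categories, phases, heatmaps, variance


@dataclass
class PartitionSummary:
    n_rhythmic_only: int
    n_arrhythmic_only: int
    n_both: int
    n_universe: int

    @property
    def union(self) -> int:
        return self.n_rhythmic_only + self.n_arrhythmic_only + self.n_both

    @property
    def union_pct_of_universe(self) -> float:
        return round(100.0 * self.union / self.n_universe, 2)

    @property
    def shared_pct_of_union(self) -> int:
        return int(round(100.0 * self.n_both / self.union))


def partition_summary(n_rhythmic_only: int, n_arrhythmic_only: int,
                      n_both: int, n_universe: int) -> PartitionSummary:
    """Summary arithmetic of the four-way category partition."""
    return PartitionSummary(n_rhythmic_only, n_arrhythmic_only, n_both, n_universe)


def adjust_and_categorize(p_rh: pd.Series, p_ar: pd.Series,
                          alpha: float = 0.05, n_universe: int | None = None):
    """BH-correct per phenotype and assign the four-way category.

    Returns ``(table, summary)``: a DataFrame (p/q per phenotype + category)
    and a :class:`PartitionSummary` over ``n_universe`` (defaults to the
    shared transcript universe size).
    """
    if not p_rh.index.equals(p_ar.index):
        p_ar = p_ar.reindex(p_rh.index)
        if p_ar.isna().any():
            raise ValueError("phenotypes tested on different transcript universes")
    q_rh = pd.Series(multipletests(p_rh, method="fdr_bh")[1], index=p_rh.index)
    q_ar = pd.Series(multipletests(p_ar, method="fdr_bh")[1], index=p_ar.index)
    sig_rh = q_rh < alpha
    sig_ar = q_ar < alpha
    category = np.select(
        [sig_rh & sig_ar, sig_rh & ~sig_ar, ~sig_rh & sig_ar],
        ["both", "rhythmic_only", "arrhythmic_only"], default="none",
    )
    table = pd.DataFrame({
        "p_rhythmic": p_rh, "q_rhythmic": q_rh,
        "p_arrhythmic": p_ar, "q_arrhythmic": q_ar,
        "category": category,
    })
    summary = partition_summary(
        int((category == "rhythmic_only").sum()),
        int((category == "arrhythmic_only").sum()),
        int((category == "both").sum()),
        n_universe if n_universe is not None else len(table),
    )
    return table, summary


def peak_phase(norm: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """ZT of maximum mean normalized expression per transcript.

    Ties resolve to the earliest ZT; requires >= 2 timepoints.
    """
    means = (
        norm[design["sample_id"]]
        .T.groupby(design.set_index("sample_id")["zt_h"]).mean().T
    )
    if means.shape[1] < 2:
        raise ValueError("peak phase needs at least 2 timepoints")
    zts = means.columns.to_numpy(float)
    return pd.Series(zts[np.argmax(means.to_numpy(), axis=1)],
                     index=norm.index, name="peak_zt_h")


def heatmap_normalize(norm: pd.DataFrame, design: pd.DataFrame,
                      transcripts=None) -> pd.DataFrame:
    """Min-max map of per-(phenotype, timepoint) mean expression to [-1, 1].

    Both phenotypes are normalized jointly per transcript, so amplitudes stay
    directly comparable between phenotypes; the smaller-amplitude phenotype
    then occupies a sub-interval of [-1, 1].  Rows are sorted by peak phase
    (rhythmic-phenotype samples).  Constant rows are emitted as zeros.
    """
    if transcripts is not None:
        norm = norm.loc[list(transcripts)]
    key = design.set_index("sample_id")[["phenotype", "zt_h"]]
    means = norm.T.groupby([key["phenotype"], key["zt_h"]]).mean().T
    lo = means.min(axis=1)
    hi = means.max(axis=1)
    span = hi - lo
    const = span == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant row(s) emitted as zeros")
    span = span.replace(0, np.nan)
    scaled = ((means.sub(lo, axis=0)).div(span, axis=0) * 2.0 - 1.0).fillna(0.0)
    rh_design = design[design["phenotype"] == "rhythmic"]
    order = peak_phase(norm, rh_design).sort_values(kind="stable").index
    return scaled.loc[order]


def variance_scenarios(norm: pd.DataFrame, design: pd.DataFrame,
                       transcripts=None):
    """Replicate-spread comparison between phenotypes (scenario A vs B).

    Per transcript and phenotype: SD across replicates at each timepoint,
    then the mean of those SDs across timepoints.  A paired two-sided t test
    across the transcript set compares phenotypes; phase desynchronization
    across individuals (scenario A) inflates the spread in the phenotype that
    lost population-level cycling, genuine non-cycling (scenario B) does not.

    Returns ``(per_transcript, p)``; p is None (descriptives only) for sets
    smaller than 3 or degenerate (zero-variance) differences.
    """
    if transcripts is not None:
        norm = norm.loc[list(transcripts)]
    key = design.set_index("sample_id")[["phenotype", "zt_h"]]
    sds = norm.T.groupby([key["phenotype"], key["zt_h"]]).std(ddof=1).T
    mean_sd = sds.T.groupby(level="phenotype").mean().T
    per_transcript = mean_sd.rename(columns=lambda c: f"mean_sd_{c}")
    p = None
    if len(per_transcript) >= 3:
        d = per_transcript["mean_sd_rhythmic"] - per_transcript["mean_sd_arrhythmic"]
        if np.allclose(d.var(ddof=1), 0.0):
            warnings.warn("degenerate paired differences; test not performed")
        else:
            p = float(stats.ttest_rel(per_transcript["mean_sd_rhythmic"],
                                      per_transcript["mean_sd_arrhythmic"]).pvalue)
    else:
        warnings.warn("fewer than 3 transcripts; descriptives only")
    return per_transcript, p
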