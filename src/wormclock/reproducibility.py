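"""Individual behavioral reproducibility statistics.

Two fully independent procedures quantify whether repeat recordings of the
same animal resemble each other more than recordings of other animals:

1. **Binary overlap**: each run is reduced to a 0/1 vector over 30-min bins
   (1 = any activity above threshold); similarity of two runs is the Jaccard
   overlap of their active bins ("overlap activity score").  Per individual,
   the score against its own repeat is paired with the mean score against all
   other repeats, and a one-tailed Wilcoxon matched-pairs signed-rank test
   asks whether self-similarity exceeds cross-similarity.

2. **KS profile similarity**: each run's days are pooled to one 24-h, 48-bin
   profile; a two-sample Kolmogorov-Smirnov test compares profiles, its
   p-value read as a similarity proxy (higher p = more similar).  Per
   individual, the matching-run p is located within the distribution of
   control p-values (vs every other repeat) by a one-sample Wilcoxon
   signed-rank test, and p-values are Benjamini-Hochberg corrected across
   individuals within each phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import BinnedActivity

__all__ = [
    "BinaryActivityVector",
    "OverlapScorePair",
    "SimilarityResult",
    "binarize",
    "overlap_activity_score",
    "paired_overlap_test",
    "ks_similarity",
    "individual_reproducibility_test",
]


@dataclass
class BinaryActivityVector:
    individual_id: str
    run_id: str
    phase: str
    bits: np.ndarray
    threshold_used: float


@dataclass
class OverlapScorePair:
    individual_id: str
    phase: str
    same_score: float
    mean_other_score: float
    n_others: int


@dataclass
class SimilarityResult:
    individual_id: str
    phase: str
    p_matching: float
    p_controls: np.ndarray
    wilcoxon_p: float
    wilcoxon_p_adj: float = np.nan
    direction: str = "ns"


def binarize(binned: BinnedActivity, threshold: float = 0.0,
             run_id: str = "run") -> BinaryActivityVector:
    """0/1 per 30-min bin over the complete days of the phase.

    A bin is active (1) iff its summed activity exceeds ``threshold``; the
    default 0 counts any movement at all.
    """
    if binned.bin_width_min != 30.0:
        raise ValueError("binary activity vectors are defined on 30-min bins")
    bits = (binned.bins[binned.complete].ravel() > threshold).astype(np.int8)
    return BinaryActivityVector(binned.individual_id, run_id, binned.phase,
                                bits, float(threshold))


def overlap_activity_score(a: BinaryActivityVector, b: BinaryActivityVector) -> float:
    """Jaccard overlap of active bins: |a AND b| / |a OR b|.

    Two fully inactive runs score 1.0 (maximally similar) with a warning.
    """
    if a.bits.size != b.bits.size:
        raise ValueError(f"length mismatch: {a.bits.size} vs {b.bits.size}")
    if a.phase != b.phase:
        raise ValueError("vectors from different phases are not comparable")
    inter = int(np.sum((a.bits == 1) & (b.bits == 1)))
    union = int(np.sum((a.bits == 1) | (b.bits == 1)))
    if union == 0:
        warnings.warn("both runs empty; overlap score defined as 1.0")
        return 1.0
    return inter / union


def paired_overlap_test(initial: dict, repeats: dict):
    """Self- vs cross-individual overlap, one-tailed matched-pairs signed-rank.

    ``initial`` and ``repeats`` map individual_id -> BinaryActivityVector for
    one phase.  Individuals missing a repeat are dropped.  Returns
    ``{"pairs": [OverlapScorePair...], "p": p}`` with p from a one-tailed
    (self > other) Wilcoxon matched-pairs signed-rank test.
    """
    ids = [i for i in initial if i in repeats]
    if len(ids) < 5:
        raise ValueError("need at least 5 individuals with both runs")
    pairs = []
    for i in ids:
        phase = initial[i].phase
        same = overlap_activity_score(initial[i], repeats[i])
        others = [overlap_activity_score(initial[i], repeats[j]) for j in ids if j != i]
        pairs.append(OverlapScorePair(i, phase, same, float(np.mean(others)), len(others)))
    same = np.array([p.same_score for p in pairs])
    other = np.array([p.mean_other_score for p in pairs])
    d = same - other
    if np.all(d == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(same, other, alternative="greater").pvalue)
    return {"pairs": pairs, "p": p}


def ks_similarity(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Two-sample KS p-value between two pooled 24-h bin profiles.

    Read as a similarity proxy: the higher the p, the more similar the diel
    patterns.  A pair of zero-variance profiles returns 1.0 with a warning.
    """
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    if a.size != b.size:
        raise ValueError("profiles must have equal length")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        warnings.warn("zero-variance profile pair; p = 1")
        return 1.0
    return float(stats.ks_2samp(a, b).pvalue)


def individual_reproducibility_test(initial_profiles: dict, repeat_profiles: dict,
                                    alpha: float = 0.05):
    """KS-based self-similarity test per individual, BH-corrected per phase.

    For each individual: p_matching = KS p of its initial run vs its own
    repeat; p_controls = KS p vs every other repeat.  A one-sample Wilcoxon
    signed-rank test (two-sided) locates p_matching in the control
    distribution; the direction (more_similar / less_similar) is reported when
    the BH-adjusted p falls below ``alpha``.  Individuals with fewer than 3
    controls are skipped with a warning.
    """
    ids = [i for i in initial_profiles if i in repeat_profiles]
    results = []
    for i in ids:
        controls = np.array([
            ks_similarity(initial_profiles[i], repeat_profiles[j])
            for j in ids if j != i
        ])
        if controls.size < 3:
            warnings.warn(f"{i}: fewer than 3 control repeats, skipped")
            continue
        p_match = ks_similarity(initial_profiles[i], repeat_profiles[i])
        d = controls - p_match
        if np.all(d == 0):
            wp = 1.0
        else:
            wp = float(stats.wilcoxon(d, alternative="two-sided").pvalue)
        results.append(SimilarityResult(i, "", p_match, controls, wp))
    if not results:
        return results
    adj = multipletests([r.wilcoxon_p for r in results], method="fdr_bh")[1]
    for r, pa in zip(results, adj):
        r.wilcoxon_p_adj = float(pa)
        if pa < alpha:
            r.direction = ("more_similar" if r.p_matching > np.median(r.p_controls)
                           else "less_similar")
        else:
            r.direction = "ns"
    return results
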