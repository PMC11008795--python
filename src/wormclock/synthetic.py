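"""Synthetic data with the statistical structure the pipeline assumes.

Three generators:

* nocturnal locomotor cohorts on a rhythmic-to-arrhythmic continuum, with an
  individual-stable 24-h bout profile (the behavioral "personality") that
  persists across repeat runs, plus acute light masking under LD;
* transcript count matrices for two behavioral phenotypes with cosine-mean
  negative-binomial transcripts in planted truth categories, including a
  phase-desynchronized-replicates scenario (population-level loss of cycling
  despite per-individual rhythmicity);
* four-parameter-logistic dose-response measurements for receptor
  deorphanization assays.

All randomness flows from explicit seeds; identical config + seed gives
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import ActivityTrace, MIN_PER_DAY

__all__ = [
    "IndividualParams",
    "CohortConfig",
    "CountSimConfig",
    "simulate_locomotor_cohort",
    "simulate_repeat_run",
    "simulate_count_matrix",
    "simulate_dose_response",
    "expected_rate",
]

NIGHT_START_ZT = 16.0  # lights-off under the default 16:8 photoperiod


@dataclass
class IndividualParams:
    """Generative parameters of one simulated animal.

    ``bout_profile`` is a frozen per-bin activity propensity over 24 h (sums
    to 1); drawing it once per individual and reusing it in repeat runs is
    what makes behavior reproducible at the individual level.
    ``rhythm_strength`` positions the animal on the continuum from fully
    arrhythmic (0) to strongly nocturnal-rhythmic (1).  ``masking_factor`` is
    the fraction of activity acutely suppressed while lights are on under LD.
    """

    individual_id: str
    rhythm_strength: float
    phase_offset_h: float
    baseline_rate: float
    bout_profile: np.ndarray
    masking_factor: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rhythm_strength <= 1.0:
            raise ValueError("rhythm_strength must lie in [0, 1]")
        if not 0.0 <= self.masking_factor <= 1.0:
            raise ValueError("masking_factor must lie in [0, 1]")
        self.bout_profile = np.asarray(self.bout_profile, dtype=float)
        if np.any(self.bout_profile < 0):
            raise ValueError("bout_profile must be non-negative")
        if MIN_PER_DAY % self.bout_profile.size != 0:
            raise ValueError("bout_profile length must divide 1440 minutes")


@dataclass
class CohortConfig:
    """Recording design for a simulated cohort.

    Defaults emulate an entrained 16 h:8 h light/dark block of 4 days followed
    by 4 days of constant darkness, sampled once per minute.  ``bout_gain``
    scales the rhythmic component relative to baseline (dimensionless mean
    multiplier at rhythm_strength 1); ``noise_dispersion`` is the gamma-Poisson
    overdispersion of per-sample activity (0 switches noise off entirely).
    """

    n_individuals: int = 30
    days_ld: int = 4
    days_dd: int = 4
    photoperiod: tuple = (16, 8)
    sampling_dt_s: float = 60.0
    noise_dispersion: float = 1.0
    seed: int = 0
    baseline_rate: float = 0.05  # mean activity per minute, arbitrary units
    bout_gain: float = 8.0
    masking_factor: float = 0.5
    profile_bins: int = 48  # 30-min propensity bins
    profile_concentration: float = 1.0
    phase_offset_range_h: float = 3.0

    def __post_init__(self) -> None:
        if self.days_ld < 0 or self.days_dd < 0:
            raise ValueError("day counts must be non-negative")
        if sum(self.photoperiod) != 24:
            raise ValueError(f"photoperiod must sum to 24 h, got {self.photoperiod}")
        if self.sampling_dt_s <= 0:
            raise ValueError("sampling_dt_s must be positive")


def _draw_individual(rng: np.random.Generator, individual_id: str,
                     config: CohortConfig, rhythm_strength: float | None) -> IndividualParams:
    if rhythm_strength is None:
        rhythm_strength = float(rng.uniform(0.0, 1.0))
    r = config.phase_offset_range_h
    phase_offset_h = float(rng.uniform(-r, r))
    nb = config.profile_bins
    bin_h = 24.0 / nb
    zt = (np.arange(nb) + 0.5) * bin_h
    night_start = (NIGHT_START_ZT + phase_offset_h) % 24.0
    # Sparse Dirichlet propensities concentrated in the individual's preferred
    # night window.  Low concentration makes the profile spiky, so each animal
    # has its own stable set of preferred bout bins (the "personality"), not
    # just a phase.
    in_night = ((zt - night_start) % 24.0) < 8.0
    alpha = np.where(in_night, 1.5 * config.profile_concentration,
                     0.15 * config.profile_concentration)
    profile = rng.dirichlet(alpha)
    return IndividualParams(
        individual_id=individual_id,
        rhythm_strength=rhythm_strength,
        phase_offset_h=phase_offset_h,
        baseline_rate=config.baseline_rate,
        bout_profile=profile,
        masking_factor=config.masking_factor,
    )


def expected_rate(params: IndividualParams, config: CohortConfig) -> np.ndarray:
    """Noise-free mean activity per sample over the full recording.

    lambda(t) = baseline * (1 + strength * gain * nbins * profile[bin(t)]),
    multiplied by (1 - masking_factor) while lights are on in LD.  This is
    the analytic mean the gamma-Poisson noise is wrapped around, exposed so
    tests can integrate it without simulating.
    """
    time_s, light, phase = _recording_grid(config)
    nb = params.bout_profile.size
    zt = (time_s / 3600.0) % 24.0
    b = np.floor(zt / (24.0 / nb)).astype(int) % nb
    per_min = params.baseline_rate * (
        1.0 + params.rhythm_strength * config.bout_gain * nb * params.bout_profile[b]
    )
    mask = (light == "L") & (phase == "LD")
    per_min = np.where(mask, per_min * (1.0 - params.masking_factor), per_min)
    return per_min * (config.sampling_dt_s / 60.0)


def _recording_grid(config: CohortConfig):
    total_s = (config.days_ld + config.days_dd) * 86400
    time_s = np.arange(0, total_s, config.sampling_dt_s)
    hod = (time_s / 3600.0) % 24.0
    in_ld = time_s < config.days_ld * 86400
    light = np.where(in_ld & (hod < config.photoperiod[0]), "L", "D").astype(object)
    phase = np.where(in_ld, "LD", "DD").astype(object)
    return time_s, light, phase


def _simulate_trace(params: IndividualParams, config: CohortConfig,
                    rng: np.random.Generator) -> ActivityTrace:
    """Gamma-Poisson burst noise around the mean function.

    The gamma intensity multiplier (mean 1, variance = noise_dispersion) is
    drawn once per 30-min bout window, not per sample: locomotor activity
    comes in bouts lasting minutes to tens of minutes, so neighboring samples
    share the bout state, and windows that miss a bout stay fully quiescent.
    """
    time_s, light, phase = _recording_grid(config)
    mu = expected_rate(params, config)
    if config.noise_dispersion <= 0:
        activity = mu.copy()
    else:
        bout_s = 24.0 * 3600.0 / config.profile_bins
        bout_idx = np.floor(time_s / bout_s).astype(int)
        shape = 1.0 / config.noise_dispersion
        mult = rng.gamma(shape, config.noise_dispersion,
                         size=bout_idx.max() + 1)
        activity = rng.poisson(mu * mult[bout_idx]).astype(float)
    return ActivityTrace(
        individual_id=params.individual_id,
        time_s=time_s,
        activity=activity,
        light=light,
        phase=phase,
        zt0_offset_s=0.0,
    )


def simulate_locomotor_cohort(config: CohortConfig,
                              rhythm_strengths=None):
    """Simulate a cohort; returns a list of ``(IndividualParams, ActivityTrace)``.

    ``rhythm_strengths`` optionally fixes each individual's continuum position
    (length ``n_individuals``); otherwise strengths are drawn uniformly, giving
    the full rhythmic-to-arrhythmic continuum.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_individuals)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        strength = None if rhythm_strengths is None else float(rhythm_strengths[i])
        params = _draw_individual(rng, f"worm{i + 1:03d}", config, strength)
        trace = _simulate_trace(params, config, rng)
        out.append((params, trace))
    return out


def simulate_repeat_run(params: IndividualParams, config: CohortConfig,
                        run_seed: int) -> ActivityTrace:
    """Re-record the same individual: frozen bout profile and phase, fresh noise."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=run_seed))
    return _simulate_trace(params, config, rng)


# ---------------------------------------------------------------------------
# Transcript count matrices


@dataclass
class CountSimConfig:
    """Design of a simulated diel RNA-seq experiment.

    Truth categories (keys of ``n_transcripts_per_category``):

    * ``rhythmic_only`` / ``arrhythmic_only`` - 24-h cosine mean in that
      behavioral phenotype only, flat in the other;
    * ``both`` - cycling in both phenotypes (independent phases);
    * ``none`` - flat everywhere;
    * ``desync_A`` - cycling in the rhythmic phenotype; in the arrhythmic
      phenotype each replicate carries its own random phase, so averaging
      across individuals flattens the population-level waveform while the
      per-timepoint replicate spread grows (scenario A).

    Counts are negative-binomial around mu(t) = base_mean * (1 +
    amplitude_rel * cos(2*pi*(t - phi)/24)).
    """

    n_transcripts_per_category: dict = field(default_factory=lambda: {
        "rhythmic_only": 50, "arrhythmic_only": 50, "both": 50,
        "none": 200, "desync_A": 25,
    })
    timepoints_zt: tuple = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_replicates: int = 3
    amplitude_rel: float = 0.8
    base_mean: float = 500.0
    nb_dispersion: float = 0.05
    length_range_bp: tuple = (200, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        zt = np.asarray(self.timepoints_zt, float)
        if not (np.all(np.diff(zt) > 0) and zt.min() >= 0 and zt.max() < 24):
            raise ValueError("timepoints_zt must be strictly increasing within [0, 24)")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 <= self.amplitude_rel <= 1.0:
            raise ValueError("amplitude_rel must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


def _nb_draw(rng, mu, dispersion):
    """NB(mean=mu, var=mu + dispersion*mu^2) via gamma-Poisson mixing."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_count_matrix(config: CountSimConfig):
    """Simulate counts for both phenotypes; returns (counts, lengths, design, truth).

    * ``counts``: DataFrame transcripts x samples (integer);
    * ``lengths``: Series of transcript lengths in bp;
    * ``design``: DataFrame (sample_id, phenotype, zt_h, replicate);
    * ``truth``: DataFrame (transcript_id, category, phase_rhythmic_h,
      phase_arrhythmic_h) recording the planted structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    zts = np.asarray(config.timepoints_zt, float)
    reps = range(1, config.n_replicates + 1)
    design_rows = [
        {"sample_id": f"{ph}_ZT{zt:g}_r{r}", "phenotype": ph, "zt_h": zt, "replicate": r}
        for ph in ("rhythmic", "arrhythmic") for zt in zts for r in reps
    ]
    design = pd.DataFrame(design_rows)

    d_zt = design["zt_h"].to_numpy(float)
    d_rh = (design["phenotype"] == "rhythmic").to_numpy()
    records, rows, ids = [], [], []
    tix = 0
    for category, n in config.n_transcripts_per_category.items():
        if category not in ("rhythmic_only", "arrhythmic_only", "both", "none", "desync_A"):
            raise ValueError(f"unknown truth category {category!r}")
        for _ in range(int(n)):
            tix += 1
            tid = f"tx{tix:05d}"
            phase_rh = float(rng.uniform(0.0, 24.0))
            phase_ar = float(rng.uniform(0.0, 24.0))
            amp_rh = config.amplitude_rel if category in ("rhythmic_only", "both", "desync_A") else 0.0
            amp_ar = config.amplitude_rel if category in ("arrhythmic_only", "both") else 0.0
            amp = np.where(d_rh, amp_rh, amp_ar)
            phase = np.where(d_rh, phase_rh, phase_ar)
            if category == "desync_A":
                # in the arrhythmic phenotype each replicate is a different
                # pool of individuals with its own phase: cycling persists per
                # replicate but the population average flattens
                amp = np.where(d_rh, amp, config.amplitude_rel)
                phase = np.where(d_rh, phase,
                                 rng.uniform(0.0, 24.0, size=len(design)))
            mu = config.base_mean * (1.0 + amp * np.cos(2 * np.pi * (d_zt - phase) / 24.0))
            rows.append(_nb_draw(rng, np.maximum(mu, 1e-9), config.nb_dispersion))
            ids.append(tid)
            records.append({
                "transcript_id": tid, "category": category,
                "phase_rhythmic_h": phase_rh if amp_rh else np.nan,
                "phase_arrhythmic_h": phase_ar if amp_ar else np.nan,
            })
    counts = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(design)), int),
                          index=ids, columns=design["sample_id"])
    lo, hi = config.length_range_bp
    lengths = pd.Series(rng.integers(lo, hi + 1, size=len(ids)), index=ids, name="length_bp")
    truth = pd.DataFrame(records).set_index("transcript_id") if records else pd.DataFrame()
    return counts, lengths, design, truth


# ---------------------------------------------------------------------------
# Dose-response


def simulate_dose_response(ec50_M: float, hill: float = 1.0, floor_pct: float = 0.0,
                           ceil_pct: float = 100.0, concentrations_M=None,
                           n_per_conc: int = 12, noise_sd_pct: float = 5.0,
                           seed: int = 0) -> pd.DataFrame:
    """Simulate percent-activation measurements around a 4PL mean curve.

    Default concentrations span 1e-13 to 1e-4 M in decade steps (a typical
    deorphanization titration); noise is additive Gaussian in percent units.
    """
    if concentrations_M is None:
        concentrations_M = 10.0 ** np.arange(-13.0, -3.9, 1.0)
    conc = np.asarray(concentrations_M, float)
    if conc.size == 0:
        raise ValueError("concentrations_M must be non-empty")
    if ceil_pct <= floor_pct:
        raise ValueError("ceil_pct must exceed floor_pct")
    if not (conc.min() <= ec50_M <= conc.max()):
        raise ValueError("ec50_M outside the tested concentration range")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for c in conc:
        mean = floor_pct + (ceil_pct - floor_pct) / (
            1.0 + 10.0 ** (hill * (np.log10(ec50_M) - np.log10(c)))
        )
        y = mean + rng.normal(0.0, noise_sd_pct, size=n_per_conc)
        for v in y:
            rows.append({"concentration_M": c, "activation_pct": float(v), "group": "receptor"})
    return pd.DataFrame(rows)
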