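"""Cohort-level evaluations of the full analysis pipeline.

These routines exercise generator -> signal analysis -> statistics end to
end on synthetic cohorts and measure whether the built-in phenotype
structure is recovered: avoidance-test classification accuracy, the
ordering of slow-wave-energy recovery times, and the detectability of the
infralimbic-coherence vs interaction-ratio relationship.

Problem sizes are scaled for desk-scale runs: cohort signals are
synthesized at 100 Hz (every modelled component lies below 30 Hz, and the
0.1 Hz epoch-FFT and 0.5 Hz coherence resolutions depend only on epoch
and chunk duration, not on the rate) and coherence cohorts use 20-min
recordings in place of full days.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import behavior
from .coherence import band_coherence_average, chunk_coherence, coherence_ratio_regression
from .core import ChannelMeta, Hypnogram
from .simulate import (PhenotypeParams, StudyDesign, enforced_wake_window,
                       generate_avoidance_trial, generate_hypnogram,
                       generate_signals)
from .spectral import epoch_spectra, slow_wave_energy, swe_recovery_time

COHORT_FS = 100.0


def _cohort_phenotypes(n_mice: int) -> list[PhenotypeParams]:
    half = n_mice // 2
    return ([PhenotypeParams.resilient()] * half
            + [PhenotypeParams.susceptible()] * (n_mice - half))


def phenotype_classification(n_cohorts: int = 20, n_mice: int = 16,
                             seed: int = 0) -> dict:
    """Classify post-defeat avoidance trials; report recovery accuracy.

    Accuracy counts UNDEFINED classifications as misses.
    """
    rng = np.random.default_rng(seed)
    correct = 0
    total = 0
    per_cohort = []
    for _ in range(n_cohorts):
        hits = 0
        phenos = _cohort_phenotypes(n_mice)
        for pheno in phenos:
            trial = generate_avoidance_trial(pheno, post_defeat=True,
                                             rng_seed=int(rng.integers(2**31)))
            result = behavior.analyze_trial(trial)
            hits += result.label == pheno.label
        per_cohort.append(hits / n_mice)
        correct += hits
        total += n_mice
    return {"accuracy": correct / total, "per_cohort": per_cohort,
            "n_mice": total}


def _restriction_day_swe(pheno: PhenotypeParams, seed: int, channel_role: str,
                         fs: float) -> float:
    """SWE recovery time (min after restriction end) for one mouse.

    Simulates a baseline day and a 6-h-restriction day, accumulates
    delta-band SWE from ZT0 on both (so the restriction-window deficit is
    part of the trace), and measures when the recovery-day trace reaches
    the baseline trace.
    """
    design = StudyDesign(days=("BASELINE", "RESTRICTION_6H"))
    meta = ChannelMeta(role=channel_role, sampling_rate=fs, hardware_lowpass=1000.0)
    traces = {}
    for k, day in enumerate(design.days):
        hyp = generate_hypnogram(design, pheno, day, rng_seed=seed * 4099 + k)
        window = enforced_wake_window(day)
        rec = generate_signals(hyp, pheno, [meta], rng_seed=seed * 8191 + k,
                               restriction_end_zt_s=window[1] if window else None)
        spectra = epoch_spectra(rec, hyp, channel_role, f_max=30.0)
        traces[day] = slow_wave_energy(spectra, condition=day)
    return swe_recovery_time(traces["RESTRICTION_6H"], traces["BASELINE"],
                             bin_min=120.0, t0_zt_s=6 * 3600.0)


def swe_recovery_comparison(n_pairs: int = 20, seed: int = 0,
                            channel_role: str = "LFP_PRL",
                            fs: float = COHORT_FS) -> dict:
    """Paired resilient-vs-susceptible SWE recovery times on the vmPFC LFP."""
    res_times = []
    sus_times = []
    for p in range(n_pairs):
        res_times.append(_restriction_day_swe(
            PhenotypeParams.resilient(), seed * 65537 + 2 * p, channel_role, fs))
        sus_times.append(_restriction_day_swe(
            PhenotypeParams.susceptible(), seed * 65537 + 2 * p + 1, channel_role, fs))
    res = np.asarray(res_times)
    sus = np.asarray(sus_times)
    return {
        "fraction_resilient_faster": float(np.mean(res < sus)),
        "resilient_times_min": res_times,
        "susceptible_times_min": sus_times,
        "n_pairs": n_pairs,
    }


@dataclass
class CoherenceCohort:
    coherence: np.ndarray
    ratios: np.ndarray
    mixing_weights: np.ndarray


def _short_hypnogram(design: StudyDesign, pheno: PhenotypeParams, seed: int,
                     n_epochs: int) -> Hypnogram:
    full = generate_hypnogram(design, pheno, "BASELINE", rng_seed=seed)
    return Hypnogram(labels=full.labels[:n_epochs], epoch_s=full.epoch_s,
                     zt_start_s=full.zt_start_s)


def simulate_coherence_cohort(n_mice: int = 16, seed: int = 0,
                              duration_min: float = 20.0,
                              fs: float = COHORT_FS) -> CoherenceCohort:
    """IL-LFP/EEG delta coherence and interaction ratio per synthetic mouse.

    Per-mouse infralimbic mixing weights are drawn around the phenotype
    default so the cohort carries a continuous coherence gradient, as the
    regression analysis assumes.
    """
    rng = np.random.default_rng(seed)
    design = StudyDesign(days=("BASELINE",))
    channels = [
        ChannelMeta(role="LFP_IL", sampling_rate=fs, hardware_lowpass=1000.0),
        ChannelMeta(role="EEG_FRONTAL", sampling_rate=fs, hardware_lowpass=1000.0),
    ]
    n_epochs = int(duration_min * 60.0 / design.epoch_s)
    coh_vals, ratios, weights = [], [], []
    for pheno in _cohort_phenotypes(n_mice):
        w = float(np.clip(rng.normal(pheno.il_mixing_weight, 0.06), 0.05, 0.95))
        mouse = pheno.with_(il_mixing_weight=w)
        hyp = _short_hypnogram(design, mouse, int(rng.integers(2**31)), n_epochs)
        rec = generate_signals(hyp, mouse, channels,
                               rng_seed=int(rng.integers(2**31)))
        spect = chunk_coherence(rec.get("LFP_IL").data, rec.get("EEG_FRONTAL").data,
                                fs=fs, pair=("LFP_IL", "EEG_FRONTAL"))
        coh_vals.append(band_coherence_average(spect, band=(0.5, 4.0)))
        trial = generate_avoidance_trial(mouse, post_defeat=True,
                                         rng_seed=int(rng.integers(2**31)))
        result = behavior.analyze_trial(trial)
        ratios.append(result.ratio)
        weights.append(w)
    return CoherenceCohort(coherence=np.asarray(coh_vals),
                           ratios=np.asarray(ratios),
                           mixing_weights=np.asarray(weights))


def coherence_regression_power(n_cohorts: int = 20, n_mice: int = 16,
                               seed: int = 0, alpha: float = 0.05,
                               duration_min: float = 20.0,
                               fs: float = COHORT_FS) -> dict:
    """Rate at which the built-in positive coherence-ratio slope is detected."""
    detections = 0
    slopes = []
    for c in range(n_cohorts):
        cohort = simulate_coherence_cohort(n_mice=n_mice, seed=seed * 7919 + c,
                                           duration_min=duration_min, fs=fs)
        fit = coherence_ratio_regression(cohort.coherence, cohort.ratios)
        slopes.append(fit.slope)
        detections += (fit.p_value < alpha) and (fit.slope > 0)
    return {"detection_rate": detections / n_cohorts, "slopes": slopes,
            "n_cohorts": n_cohorts}


def permutation_type1_rate(cohort: CoherenceCohort, n_permutations: int = 1000,
                           seed: int = 0, alpha: float = 0.05) -> float:
    """Type-I calibration: rejection rate of the slope test under random
    permutation of the interaction ratios."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(cohort.ratios)
        fit = coherence_ratio_regression(cohort.coherence, perm)
        hits += fit.p_value < alpha
    return hits / n_permutations
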