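"""Synthetic polysomnography for the social-defeat resilience paradigm.

Generates ground-truth hypnograms, multichannel EEG/LFP/EMG signals and
social-avoidance trajectories whose statistical structure matches what the
downstream analyses assume, so every stage of the pipeline is testable
without animal data.

Model summary
-------------
* **State process** — a semi-Markov chain over WAKE/NREM/REM with
  geometric dwell distributions. NREM bout mean is a phenotype parameter;
  wake dwell means are derived from common target sleep fractions (light
  period 0.62, dark 0.36) so baseline sleep *amount* is matched across
  phenotypes while bout *lengths* differ.
* **Homeostat** — a two-process-style slow variable S that rises
  exponentially toward saturation during wake (tau 8 h) and decays during
  NREM (tau 2.2 h). NREM delta amplitude follows S, producing the
  declining light-period slow-wave activity and the post-restriction
  rebound.
* **Signals** — state-dependent filtered noise plus band-limited
  oscillators: NREM-dominant delta (0.5-4 Hz), REM-dominant theta
  (6-10 Hz), low-voltage high-EMG wake, and discrete negative 2-6 Hz
  half-waves in wake whose density increases after sleep restriction.
  LFP channels share a common delta source with the EEG; the mixing
  weight sets the EEG-LFP coherence and is higher in the infralimbic
  channel of resilient phenotypes.
* **Behavior** — social-avoidance trials are Ornstein-Uhlenbeck
  trajectories alternating between an attractor near the cage and a far
  attractor, with near-dwell fractions tuned so post-defeat interaction
  ratios center above 1.1 (resilient) or below 0.9 (susceptible).

All generators are deterministic for a fixed seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .behavior import ArenaTrial
from .core import (ARTIFACT, EMG, NREM, REM, SECONDS_PER_DAY, WAKE, Channel,
                   ChannelMeta, Hypnogram, Recording)

DAY_TYPES = ("BASELINE", "DEFEAT", "RESTRICTION_6H", "RESTRICTION_8H", "RECOVERY")

RESILIENT = "RESILIENT"
SUSCEPTIBLE = "SUSCEPTIBLE"

# state-process shape constants (epochs of 10 s)
_REM_BOUT_EPOCHS = 6.0
_P_NREM_TO_REM = 0.35
_P_REM_TO_NREM = 0.2
_LIGHT_SLEEP_FRACTION = 0.62
_DARK_SLEEP_FRACTION = 0.36
_LEAKAGE_RATE = 0.02        # brief sleep intrusions during enforced wake
_ARTIFACT_RATE = 0.015
_REBOUND_BOOST_H = 6.0      # hours of elevated sleep drive after restriction

# signal-model amplitudes (microvolt scale)
_A_DELTA_NREM = 40.0
_A_DELTA_REST = 6.0
_A_THETA = {WAKE: 12.0, NREM: 6.0, REM: 30.0, ARTIFACT: 0.0}
_NOISE_SD = {WAKE: 14.0, NREM: 22.0, REM: 12.0, ARTIFACT: 120.0}
_EMG_SD = {WAKE: 40.0, NREM: 8.0, REM: 4.0, ARTIFACT: 120.0}
_TAU_RISE_S = 8.0 * 3600.0
_TAU_DECAY_S = 2.2 * 3600.0
_S0 = 0.4
_WAKE_WAVE_RATE_PER_MIN = 25.0
_MAX_OSCILLATOR_HZ = 10.0

# avoidance-trial interaction-ratio targets (lognormal mu, sigma)
_RATIO_TARGETS = {
    (RESILIENT, True): (np.log(1.6), 0.22),
    (SUSCEPTIBLE, True): (np.log(0.55), 0.18),
    (RESILIENT, False): (0.0, 0.12),
    (SUSCEPTIBLE, False): (0.0, 0.12),
}


@dataclass(frozen=True)
class PhenotypeParams:
    """Generative parameters of one behavioral phenotype.

    Gains are dimensionless multipliers on the corresponding baseline
    amplitude or rate; ``post_defeat_dark_sleep_shift`` is minutes of NREM
    moved from the light into the dark period on post-defeat days (zero
    for the susceptible default, whose architecture barely changes).
    EEG and vmPFC-LFP channels carry separate baseline/rebound gains
    because the phenotype contrast runs in opposite directions at the two
    recording sites (susceptible mice show higher EEG baseline SWA and a
    larger EEG rebound, while resilient mice show higher vmPFC baseline
    power and a faster vmPFC slow-wave-energy recovery).
    """

    label: str
    baseline_swa_gain: float = 1.0
    rebound_gain: float = 1.0
    post_defeat_dark_sleep_shift: float = 0.0
    mean_nrem_bout_epochs: float = 10.0
    wave_incidence_gain: float = 1.0
    vmpfc_baseline_gain: float = 1.0
    vmpfc_rebound_gain: float = 1.0
    il_mixing_weight: float = 0.5
    prl_mixing_weight: float = 0.55

    def __post_init__(self) -> None:
        if self.label not in (RESILIENT, SUSCEPTIBLE):
            raise ValueError(f"label must be RESILIENT or SUSCEPTIBLE, got {self.label!r}")
        for name in ("baseline_swa_gain", "rebound_gain", "mean_nrem_bout_epochs",
                     "wave_incidence_gain", "vmpfc_baseline_gain",
                     "vmpfc_rebound_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.post_defeat_dark_sleep_shift < 0:
            raise ValueError("post_defeat_dark_sleep_shift must be >= 0")
        for name in ("il_mixing_weight", "prl_mixing_weight"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def resilient(cls, **overrides) -> "PhenotypeParams":
        base = dict(
            label=RESILIENT,
            baseline_swa_gain=1.0,
            rebound_gain=1.1,
            post_defeat_dark_sleep_shift=60.0,
            mean_nrem_bout_epochs=12.0,
            wave_incidence_gain=1.6,
            vmpfc_baseline_gain=1.3,
            vmpfc_rebound_gain=1.5,
            il_mixing_weight=0.75,
            prl_mixing_weight=0.55,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def susceptible(cls, **overrides) -> "PhenotypeParams":
        base = dict(
            label=SUSCEPTIBLE,
            baseline_swa_gain=1.2,
            rebound_gain=1.35,
            post_defeat_dark_sleep_shift=0.0,
            mean_nrem_bout_epochs=9.0,
            wave_incidence_gain=1.0,
            vmpfc_baseline_gain=1.0,
            vmpfc_rebound_gain=1.05,
            il_mixing_weight=0.45,
            prl_mixing_weight=0.55,
        )
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "PhenotypeParams":
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class StudyDesign:
    """Cohort-level design: group sizes, day sequence and the ZT clock."""

    n_per_group: int = 8
    days: tuple[str, ...] = ("BASELINE", "RESTRICTION_6H", "DEFEAT")
    epoch_s: float = 10.0
    light_onset_zt: float = 0.0
    dark_onset_zt: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.days) - set(DAY_TYPES)
        if unknown:
            raise ValueError(f"unknown day specs {sorted(unknown)}; expected {DAY_TYPES}")
        if SECONDS_PER_DAY % self.epoch_s != 0:
            raise ValueError("epoch_s must divide 86400")
        if self.dark_onset_zt - self.light_onset_zt != 12:
            raise ValueError("12:12 light:dark cycle required "
                             "(dark_onset_zt - light_onset_zt must be 12)")


@dataclass
class GroundTruth:
    """What the generator knows about one simulated mouse."""

    phenotype: str
    params: PhenotypeParams
    hypnograms: dict = field(default_factory=dict)
    recordings: dict = field(default_factory=dict)
    enforced_windows: dict = field(default_factory=dict)


def enforced_wake_window(day_spec: str) -> tuple[float, float] | None:
    """ZT window (s) of enforced wakefulness for a day spec, if any."""
    if day_spec == "RESTRICTION_6H":
        return (0.0, 6 * 3600.0)
    if day_spec == "RESTRICTION_8H":
        return (0.0, 8 * 3600.0)
    return None


def _expected_sleep_run_epochs(pheno: PhenotypeParams) -> float:
    # expected epochs per consolidated sleep run, including NREM->REM->NREM
    # continuations of the chain
    return (pheno.mean_nrem_bout_epochs + _P_NREM_TO_REM * _REM_BOUT_EPOCHS) / (
        1.0 - _P_NREM_TO_REM * _P_REM_TO_NREM
    )


def _convert_runs(labels: np.ndarray, region: np.ndarray, from_state: str,
                  to_state: str, n_target: int, rng: np.random.Generator) -> int:
    """Flip whole runs of ``from_state`` inside ``region`` until ~n_target
    epochs are converted (the last run is trimmed to hit the target
    exactly). Returns the number converted."""
    eligible = region & (labels == from_state)
    if not eligible.any():
        return 0
    idx = np.flatnonzero(eligible)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    order = rng.permutation(len(runs))
    converted = 0
    for k in order:
        run = runs[k]
        take = min(len(run), n_target - converted)
        labels[run[:take]] = to_state
        converted += take
        if converted >= n_target:
            break
    return converted


def generate_hypnogram(design: StudyDesign, pheno: PhenotypeParams,
                       day_spec: str, rng_seed: int) -> Hypnogram:
    """Simulate one 24-h ground-truth hypnogram.

    Circadian bias places the majority of sleep in the light period on
    baseline days. Restriction days enforce wakefulness over their ZT
    window (with a small leakage of brief sleep intrusions, since enforced
    wakefulness is never perfect) followed by a few hours of elevated
    sleep drive scaled by ``rebound_gain``. Post-defeat (DEFEAT) days move
    ``post_defeat_dark_sleep_shift`` minutes of NREM from the light into
    the dark period — the resilient-only sleep reorganization.
    """
    if day_spec not in design.days:
        raise ValueError(
            f"day spec {day_spec!r} is not part of this design (days: {design.days})"
        )
    rng = np.random.default_rng(rng_seed)
    n_epochs = int(SECONDS_PER_DAY / design.epoch_s)
    labels = np.full(n_epochs, WAKE, dtype="U8")

    run = _expected_sleep_run_epochs(pheno)
    wake_mean_light = run * (1 - _LIGHT_SLEEP_FRACTION) / _LIGHT_SLEEP_FRACTION
    wake_mean_dark = run * (1 - _DARK_SLEEP_FRACTION) / _DARK_SLEEP_FRACTION

    window = enforced_wake_window(day_spec)
    win_lo = win_hi = None
    if window is not None:
        win_lo = int(window[0] / design.epoch_s)
        win_hi = int(window[1] / design.epoch_s)
    boost_until = None
    if window is not None:
        boost_until = win_hi + int(_REBOUND_BOOST_H * 3600 / design.epoch_s)

    def dwell_mean(state: str, i: int) -> float:
        zt_h = (i * design.epoch_s / 3600.0) % 24.0
        light = design.light_onset_zt <= zt_h < design.dark_onset_zt
        if state == WAKE:
            m = wake_mean_light if light else wake_mean_dark
            if boost_until is not None and win_hi <= i < boost_until:
                # post-restriction sleep drive, decaying over the boost window
                frac = 1.0 - (i - win_hi) / (boost_until - win_hi)
                m /= 1.0 + 2.0 * (pheno.rebound_gain - 0.5) * frac
            return m
        if state == NREM:
            m = pheno.mean_nrem_bout_epochs
            if boost_until is not None and win_hi <= i < boost_until:
                frac = 1.0 - (i - win_hi) / (boost_until - win_hi)
                m *= 1.0 + 0.5 * (pheno.rebound_gain - 1.0) * frac + 0.3 * frac
            return m
        return _REM_BOUT_EPOCHS

    i = 0
    state = WAKE
    while i < n_epochs:
        if win_lo is not None and win_lo <= i < win_hi:
            labels[i:win_hi] = WAKE
            i = win_hi
            state = NREM  # strong sleep pressure at restriction end
            continue
        d = int(rng.geometric(1.0 / max(dwell_mean(state, i), 1.0)))
        if state != WAKE and win_lo is not None and i < win_lo < i + d:
            d = win_lo - i
        d = min(d, n_epochs - i)
        labels[i:i + d] = state
        i += d
        if state == WAKE:
            state = NREM
        elif state == NREM:
            state = REM if rng.random() < _P_NREM_TO_REM else WAKE
        else:
            state = NREM if rng.random() < _P_REM_TO_NREM else WAKE

    if win_lo is not None:
        leak = rng.random(win_hi - win_lo) < _LEAKAGE_RATE
        labels[win_lo:win_hi][leak] = NREM

    if day_spec == "DEFEAT" and pheno.post_defeat_dark_sleep_shift > 0:
        n_shift = int(round(pheno.post_defeat_dark_sleep_shift * 60 / design.epoch_s))
        zt_h = (np.arange(n_epochs) * design.epoch_s / 3600.0) % 24.0
        dark = (zt_h >= design.dark_onset_zt) | (zt_h < design.light_onset_zt)
        moved = _convert_runs(labels, dark, WAKE, NREM, n_shift, rng)
        _convert_runs(labels, ~dark, NREM, WAKE, moved, rng)

    art = rng.random(n_epochs) < _ARTIFACT_RATE
    labels[art] = ARTIFACT

    return Hypnogram(labels=labels, epoch_s=design.epoch_s, zt_start_s=0.0)


def homeostatic_pressure(hyp: Hypnogram, s0: float = _S0,
                         tau_rise_s: float = _TAU_RISE_S,
                         tau_decay_s: float = _TAU_DECAY_S) -> np.ndarray:
    """Per-epoch slow homeostatic variable S in [0, 1].

    Rises exponentially toward 1 during wake, decays during NREM, holds
    during REM and artifact.
    """
    s = np.empty(hyp.n_epochs)
    cur = s0
    dt = hyp.epoch_s
    up = dt / tau_rise_s
    down = np.exp(-dt / tau_decay_s)
    for k, lab in enumerate(hyp.labels):
        if lab == WAKE:
            cur = cur + (1.0 - cur) * up
        elif lab == NREM:
            cur = cur * down
        s[k] = cur
    return s


def _unit_band_noise(n: int, fs: float, f_lo: float, f_hi: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [f_lo, f_hi] Hz.

    Synthesized in the frequency domain (random phase and amplitude on the
    band's FFT bins, zero elsewhere) — a single inverse FFT, float32
    throughout.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    spec = np.zeros(freqs.size, dtype=np.complex64)
    m = int(band.sum())
    spec[band] = (rng.standard_normal(m, dtype=np.float32)
                  + 1j * rng.standard_normal(m, dtype=np.float32))
    x = np.fft.irfft(spec, n).astype(np.float32, copy=False)
    sd = float(x.std())
    return x / sd if sd > 0 else x


def _insert_wake_waves(data: np.ndarray, hyp: Hypnogram, fs: float,
                       gain_from_zt_s: float | None, gain: float,
                       rng: np.random.Generator) -> None:
    """Add discrete negative 2-6 Hz half-waves during wake epochs."""
    spe = int(round(hyp.epoch_s * fs))
    zt = hyp.epoch_zt_start_s()
    wake_idx = np.flatnonzero(hyp.labels == WAKE)
    if wake_idx.size == 0:
        return
    lam = np.full(wake_idx.size, _WAKE_WAVE_RATE_PER_MIN * hyp.epoch_s / 60.0)
    if gain_from_zt_s is not None:
        lam[zt[wake_idx] >= gain_from_zt_s] *= gain
    counts = rng.poisson(lam)
    for k, c in zip(wake_idx, counts):
        for _ in range(c):
            f = rng.uniform(2.0, 6.0)
            nh = int(fs / (2 * f))
            half = np.sin(np.pi * np.arange(nh, dtype=np.float32)
                          * np.float32(2 * f / fs))
            amp = np.float32(rng.lognormal(np.log(40.0), 0.45))
            start = k * spe + int(rng.integers(0, max(spe - nh, 1)))
            stop = min(start + nh, data.size)
            data[start:stop] -= amp * half[: stop - start]


def generate_signals(hyp: Hypnogram, pheno: PhenotypeParams,
                     channels: list[ChannelMeta], rng_seed: int,
                     restriction_end_zt_s: float | None = None) -> Recording:
    """Synthesize a multichannel recording consistent with a hypnogram.

    ``restriction_end_zt_s``, when given, marks the end of an enforced-wake
    window: delta amplitude is transiently boosted afterwards (the SWA
    rebound, channel-class-specific gain) and the density of waking 2-6 Hz
    waves is multiplied by ``wave_incidence_gain``.
    """
    if hyp.n_epochs == 0:
        return Recording(channels=[], zt_start_s=hyp.zt_start_s)
    for meta in channels:
        if meta.sampling_rate < 2 * _MAX_OSCILLATOR_HZ:
            raise ValueError(
                f"channel {meta.role}: sampling rate {meta.sampling_rate} Hz is "
                f"below twice the highest oscillator frequency "
                f"({_MAX_OSCILLATOR_HZ} Hz)"
            )

    rng = np.random.default_rng(rng_seed)
    s_var = homeostatic_pressure(hyp)
    zt = hyp.epoch_zt_start_s()

    def rebound_mult(gain: float) -> np.ndarray:
        m = np.ones(hyp.n_epochs)
        if restriction_end_zt_s is not None and gain != 1.0:
            frac = 1.0 - (zt - restriction_end_zt_s) / (_REBOUND_BOOST_H * 3600.0)
            frac = np.clip(frac, 0.0, 1.0)
            frac[zt < restriction_end_zt_s] = 0.0
            m += (gain - 1.0) * frac
        return m

    is_nrem = hyp.labels == NREM
    is_art = hyp.labels == ARTIFACT

    # per-epoch amplitude schedules, per channel class
    def delta_amp(base_gain: float, reb_gain: float) -> np.ndarray:
        amp = np.full(hyp.n_epochs, _A_DELTA_REST)
        amp[is_nrem] = (_A_DELTA_NREM * base_gain * (0.35 + 1.3 * s_var[is_nrem])
                        * rebound_mult(reb_gain)[is_nrem])
        amp[is_art] = 0.0
        return amp

    theta_amp = np.array([_A_THETA[l] for l in hyp.labels])
    noise_sd = np.array([_NOISE_SD[l] for l in hyp.labels])
    emg_sd = np.array([_EMG_SD[l] for l in hyp.labels])

    # one shared delta source per distinct sampling rate (coherence is only
    # computed between same-rate channels)
    shared: dict[float, np.ndarray] = {}
    out_channels = []
    for meta in channels:
        fs = meta.sampling_rate
        spe = int(round(hyp.epoch_s * fs))
        n = hyp.n_epochs * spe
        if fs not in shared:
            shared[fs] = _unit_band_noise(
                n, fs, 0.5, 4.0, np.random.default_rng(rng.integers(2**31)))
        ch_rng = np.random.default_rng(rng.integers(2**31))

        if meta.role == EMG:
            cutoff = min(100.0, 0.45 * fs)
            noise = _unit_band_noise(n, fs, 0.05, cutoff, ch_rng)
            data = np.repeat(emg_sd.astype(np.float32), spe) * noise
            out_channels.append(Channel(meta=meta, data=data))
            continue

        if meta.role in ("LFP_PRL", "LFP_IL"):
            base_gain, reb_gain = pheno.vmpfc_baseline_gain, pheno.vmpfc_rebound_gain
            w = (pheno.il_mixing_weight if meta.role == "LFP_IL"
                 else pheno.prl_mixing_weight)
            own = _unit_band_noise(n, fs, 0.5, 4.0, ch_rng)
            delta_src = w * shared[fs] + np.sqrt(1.0 - w * w) * own
        else:
            base_gain, reb_gain = pheno.baseline_swa_gain, pheno.rebound_gain
            delta_src = shared[fs]

        theta_src = _unit_band_noise(n, fs, 6.0, 10.0, ch_rng)
        cutoff = min(meta.hardware_lowpass, 0.45 * fs)
        broadband = _unit_band_noise(n, fs, 0.05, cutoff, ch_rng)

        data = (
            np.repeat(delta_amp(base_gain, reb_gain).astype(np.float32), spe) * delta_src
            + np.repeat(theta_amp.astype(np.float32), spe) * theta_src
            + np.repeat(noise_sd.astype(np.float32), spe) * broadband
        )
        _insert_wake_waves(data, hyp, fs, restriction_end_zt_s,
                           pheno.wave_incidence_gain, ch_rng)
        out_channels.append(Channel(meta=meta, data=data))

    return Recording(channels=out_channels, zt_start_s=hyp.zt_start_s)


# --- social-avoidance trial ------------------------------------------------

_ARENA_CM = 30.0
_CAGE_CM = 9.0
_SESSION_S = 180.0


def generate_avoidance_trial(pheno: PhenotypeParams, post_defeat: bool,
                             rng_seed: int, sample_rate: float = 10.0) -> ArenaTrial:
    """Simulate the two 3-min sessions of a social-avoidance test.

    Session 1 has an empty cage, session 2 the caged novel target. The
    expected interaction ratio (time near the occupied cage / time near
    the empty cage) is > 1.1 for resilient post-defeat phenotypes, < 0.9
    for susceptible post-defeat, and near 1 pre-defeat.
    """
    rng = np.random.default_rng(rng_seed)
    mu, sigma = _RATIO_TARGETS[(pheno.label, bool(post_defeat))]
    ratio_target = rng.lognormal(mu, sigma)
    f_empty = float(np.clip(rng.normal(0.35, 0.05), 0.10, 0.70))
    f_target = float(np.clip(f_empty * ratio_target, 0.02, 0.92))

    sessions = []
    for f in (f_empty, f_target):
        sessions.append(_ou_session(f, sample_rate, rng))
    return ArenaTrial(
        sessions=tuple(sessions),
        sample_rate=sample_rate,
        arena_cm=_ARENA_CM,
        cage_cm=_CAGE_CM,
    )


def _ou_session(near_fraction: float, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """One 3-min (x, y) trajectory alternating near-cage and far dwells."""
    n = int(_SESSION_S * fs)
    dt = 1.0 / fs
    near_pt = np.array([15.0, 22.0])   # just outside the cage wall
    # the 15-cm zone reaches deep into the arena, so the far attractor sits
    # in the corner with a tight wander to keep far dwells outside the zone
    far_pt = np.array([3.0, 3.0])
    mean_far = 5.0
    mean_near = mean_far * near_fraction / max(1.0 - near_fraction, 1e-6)

    def dwell(mean: float) -> float:
        # mild jitter: many short dwells keep the realized near-fraction
        # close to its target without looking metronomic
        return mean * rng.uniform(0.6, 1.4)

    pos = np.empty((n, 2))
    cur = far_pt + rng.normal(0, 2, size=2)
    near = rng.random() < near_fraction
    t_left = dwell(mean_near if near else mean_far)
    k, sd = 2.0, 5.0
    for t in range(n):
        target = near_pt if near else far_pt
        cur = cur + (target - cur) * k * dt + sd * np.sqrt(dt) * rng.normal(size=2)
        cur = np.clip(cur, 0.5, _ARENA_CM - 0.5)
        pos[t] = cur
        t_left -= dt
        if t_left <= 0:
            near = not near
            t_left = dwell(mean_near if near else mean_far)
    return pos


# --- study-level convenience ------------------------------------------------

def simulate_mouse(design: StudyDesign, pheno: PhenotypeParams, mouse_seed: int,
                   channels: list[ChannelMeta] | None = None,
                   with_signals: bool = False) -> GroundTruth:
    """Generate all study days for one mouse; signals optional."""
    gt = GroundTruth(phenotype=pheno.label, params=pheno)
    for d, day in enumerate(design.days):
        hyp = generate_hypnogram(design, pheno, day, rng_seed=mouse_seed * 1009 + d)
        gt.hypnograms[day] = hyp
        gt.enforced_windows[day] = enforced_wake_window(day)
        if with_signals and channels:
            window = enforced_wake_window(day)
            gt.recordings[day] = generate_signals(
                hyp, pheno, channels, rng_seed=mouse_seed * 2027 + d,
                restriction_end_zt_s=window[1] if window else None,
            )
    return gt
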