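"""Per-epoch power spectra, band timecourses, and slow-wave energy.

One FFT is taken per scoring epoch: 10-s epochs give exactly the 0.1 Hz
frequency resolution of the analysis convention (bin spacing is always
``1/epoch_s``). Spectra are one-sided power densities (signal-unit^2/Hz)
with a Hann window and the standard window-power correction, so the
integral of the density over frequency equals the window-corrected
time-domain power (Parseval). Band integration is inclusive of the band's
edge bins.

Slow-wave activity (SWA) is delta-band (0.5-4 Hz) power during NREM; its
cumulative sum times epoch duration over NREM epochs is slow-wave energy
(SWE), the quantity whose post-restriction recovery time separates
resilient from susceptible phenotypes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import ARTIFACT, DELTA, NREM, TOTAL, BandDefinition, Hypnogram, Recording

_CHUNK_EPOCHS = 512


@dataclass
class EpochSpectra:
    """One-sided power spectral density per scored epoch.

    Rows of ``psd`` at artifact epochs are NaN and are excluded from every
    downstream statistic.
    """

    freqs: np.ndarray            # Hz, spacing 1/epoch_s
    psd: np.ndarray              # (n_epochs, n_freqs), unit^2/Hz
    states: np.ndarray
    epoch_s: float
    zt_start_s: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def epoch_zt_start_s(self) -> np.ndarray:
        return self.zt_start_s + np.arange(self.psd.shape[0]) * self.epoch_s


def epoch_spectra(rec: Recording, hyp: Hypnogram, channel: str,
                  f_max: float | None = 30.0, window: str = "hann") -> EpochSpectra:
    """Windowed FFT power density of every non-artifact epoch of a channel.

    Raises ``KeyError`` when the channel role is absent from the recording.
    """
    ch = rec.get(channel)
    fs = ch.meta.sampling_rate
    spe = int(round(hyp.epoch_s * fs))
    if spe * hyp.n_epochs > ch.data.size:
        raise ValueError(
            f"recording provides {ch.data.size} samples but hypnogram needs "
            f"{spe * hyp.n_epochs}"
        )
    w = sps.get_window(window, spe, fftbins=True).astype(np.float64)
    u = float(np.sum(w * w))
    freqs = np.fft.rfftfreq(spe, d=1.0 / fs)
    keep = slice(None) if f_max is None else freqs <= f_max + 1e-12

    scale = np.full(freqs.size, 2.0 / (fs * u))
    scale[0] = 1.0 / (fs * u)
    if spe % 2 == 0:
        scale[-1] = 1.0 / (fs * u)

    n_freq = freqs[keep].size
    psd = np.empty((hyp.n_epochs, n_freq))
    for lo in range(0, hyp.n_epochs, _CHUNK_EPOCHS):
        hi = min(lo + _CHUNK_EPOCHS, hyp.n_epochs)
        seg = ch.data[lo * spe: hi * spe].astype(np.float64).reshape(hi - lo, spe)
        spec = np.abs(np.fft.rfft(seg * w, axis=1)) ** 2 * scale
        psd[lo:hi] = spec[:, keep]
    psd[hyp.labels == ARTIFACT] = np.nan
    return EpochSpectra(freqs=freqs[keep], psd=psd, states=hyp.labels.copy(),
                        epoch_s=hyp.epoch_s, zt_start_s=hyp.zt_start_s)


def band_power(spectra: EpochSpectra, band: BandDefinition) -> np.ndarray:
    """Per-epoch band power: density integrated over the band (edge bins
    inclusive). NaN at artifact epochs."""
    if band.f_lo < spectra.freqs[0] - 1e-9 or band.f_hi > spectra.freqs[-1] + 1e-9:
        raise ValueError(
            f"band {band.name} ({band.f_lo}-{band.f_hi} Hz) exceeds stored "
            f"spectrum range {spectra.freqs[0]}-{spectra.freqs[-1]} Hz"
        )
    sel = (spectra.freqs >= band.f_lo - 1e-9) & (spectra.freqs <= band.f_hi + 1e-9)
    return spectra.psd[:, sel].sum(axis=1) * spectra.df


@dataclass
class BandPowerTimecourse:
    """Mean band power per time bin, restricted to one vigilance state.

    Bins with no qualifying epoch are NaN with ``missing=True`` — a bin
    without NREM epochs is unknown, not zero. ``normalization`` records
    provenance: "absolute", "baseline_24h" or "pct_total".
    """

    table: pd.DataFrame      # bin_start_zt_h, power, total_power, n_epochs, missing
    band: BandDefinition
    state_filter: str | None
    bin_min: float
    normalization: str = "absolute"

    @property
    def values(self) -> np.ndarray:
        return self.table["power"].to_numpy()

    @property
    def all_missing(self) -> bool:
        return bool(self.table["missing"].all())


def band_power_timecourse(spectra: EpochSpectra, band: BandDefinition,
                          bin_min: float = 120.0,
                          state_filter: str | None = NREM,
                          total_band: BandDefinition = TOTAL) -> BandPowerTimecourse:
    """Bin-averaged band power over epochs of one state.

    Also carries the matching total-band power per bin so that
    percentage-of-total normalization can be applied afterwards.
    """
    bp = band_power(spectra, band)
    tp = band_power(spectra, total_band)
    zt = spectra.epoch_zt_start_s()
    n = spectra.psd.shape[0]
    epb = bin_min * 60.0 / spectra.epoch_s
    if epb != int(epb):
        raise ValueError("bin width must be a whole number of epochs")
    epb = int(epb)
    qualifies = ~np.isnan(bp)
    if state_filter is not None:
        qualifies &= spectra.states == state_filter

    rows = []
    for b in range(math.ceil(n / epb)):
        sel = np.zeros(n, dtype=bool)
        sel[b * epb:(b + 1) * epb] = True
        sel &= qualifies
        k = int(sel.sum())
        rows.append({
            "bin_start_zt_h": (spectra.zt_start_s + b * bin_min * 60.0) / 3600.0,
            "power": float(bp[sel].mean()) if k else np.nan,
            "total_power": float(tp[sel].mean()) if k else np.nan,
            "n_epochs": k,
            "missing": k == 0,
        })
    return BandPowerTimecourse(table=pd.DataFrame(rows), band=band,
                               state_filter=state_filter, bin_min=bin_min)


def normalize_power(tc: BandPowerTimecourse, mode: str,
                    baseline: BandPowerTimecourse | None = None) -> BandPowerTimecourse:
    """Normalize a band-power timecourse.

    ``baseline_24h``: each bin as a percentage of the paired baseline-day
    timecourse's epoch-weighted 24-h mean. ``pct_total``: each bin's band
    power as a percentage of the same bin's total-band (0.5-30 Hz) power.
    Zero denominators yield NaN (flagged missing), never infinities.
    """
    table = tc.table.copy()
    if mode == "baseline_24h":
        if baseline is None:
            raise ValueError("baseline_24h normalization requires a baseline timecourse")
        bt = baseline.table
        weight = bt["n_epochs"].to_numpy(dtype=float)
        vals = bt["power"].to_numpy()
        denom = (np.nansum(vals * weight) / weight.sum()) if weight.sum() else np.nan
    elif mode == "pct_total":
        denom = table["total_power"].to_numpy()
    else:
        raise ValueError("mode must be 'baseline_24h' or 'pct_total'")
    with np.errstate(divide="ignore", invalid="ignore"):
        table["power"] = np.where(
            np.asarray(denom) > 0, 100.0 * table["power"] / denom, np.nan)
    table["missing"] = table["missing"] | ~np.isfinite(table["power"])
    return replace(tc, table=table, normalization=mode)


@dataclass
class SWETrace:
    """Cumulative slow-wave energy (power x seconds) over NREM epochs."""

    zt_end_s: np.ndarray         # ZT time at the end of each epoch
    cumulative: np.ndarray       # nondecreasing when power is nonnegative
    condition: str = ""
    band: BandDefinition = DELTA


def slow_wave_energy(spectra: EpochSpectra, band: BandDefinition = DELTA,
                     interval_zt_h: tuple[float, float] | None = None,
                     condition: str = "") -> SWETrace:
    """Cumulative sum of (delta-band power x epoch duration) over NREM epochs.

    Epochs outside NREM (and artifact epochs) contribute zero. The
    optional ZT interval restricts accumulation to a sub-window.
    """
    bp = band_power(spectra, band)
    zt = spectra.epoch_zt_start_s()
    contrib = np.where((spectra.states == NREM) & ~np.isnan(bp), bp, 0.0)
    contrib = contrib * spectra.epoch_s
    if interval_zt_h is not None:
        lo, hi = interval_zt_h[0] * 3600.0, interval_zt_h[1] * 3600.0
        if lo < zt[0] - 1e-9 or hi > zt[-1] + spectra.epoch_s + 1e-9:
            raise ValueError("interval lies outside the recording")
        sel = (zt >= lo) & (zt < hi)
        zt = zt[sel]
        contrib = contrib[sel]
    return SWETrace(zt_end_s=zt + spectra.epoch_s,
                    cumulative=np.cumsum(contrib), condition=condition, band=band)


NOT_RECOVERED = math.inf


def swe_recovery_time(recovery: SWETrace, baseline: SWETrace,
                      bin_min: float = 120.0,
                      t0_zt_s: float | None = None) -> float:
    """Minutes until cumulative recovery SWE reaches the baseline trace.

    Both traces must share the same ZT grid. Cumulative values are
    compared at successive bin ends; the recovery time is the elapsed time
    at the start of the first bin whose end satisfies
    ``recovery >= baseline`` (0 when the very first bin already does, as
    for identical traces). ``t0_zt_s`` shifts the clock origin — pass the
    restriction end to express the result as minutes after restriction.
    Returns ``NOT_RECOVERED`` (inf) when the trace never catches up within
    the window.
    """
    if recovery.zt_end_s.shape != baseline.zt_end_s.shape or not np.allclose(
            recovery.zt_end_s, baseline.zt_end_s):
        raise ValueError("recovery and baseline traces are not ZT-aligned")
    epoch_s = (float(recovery.zt_end_s[1] - recovery.zt_end_s[0])
               if recovery.zt_end_s.size > 1 else 0.0)
    start = float(recovery.zt_end_s[0]) - epoch_s
    end = float(recovery.zt_end_s[-1])
    bin_s = bin_min * 60.0
    t = start + bin_s
    while t <= end + 1e-9:
        idx = np.searchsorted(recovery.zt_end_s, t + 1e-9) - 1
        if recovery.cumulative[idx] >= baseline.cumulative[idx]:
            crossed_zt = t - bin_s
            origin = start if t0_zt_s is None else t0_zt_s
            return max((crossed_zt - origin) / 60.0, 0.0)
        t += bin_s
    return NOT_RECOVERED
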