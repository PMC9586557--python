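"""Chunked phase coherence between LFP and EEG channels.

Squared-magnitude coherence is computed in time bins (10 min by default),
each bin averaged over successive non-overlapping chunks (2 s by default,
so M = 300 chunks per bin and the frequency resolution is
1/chunk_s = 0.5 Hz). Per bin and frequency:

    coh2(f) = |sum_i F(x_i) F(y_i)*|^2 /
              ( sum_i |F(x_i)|^2 * sum_i |F(y_i)|^2 )

with a Hann window per chunk and per-chunk mean removal. This
normalization (root-mean cross-power over the per-channel powers) bounds
the value in [0, 1] by Cauchy-Schwarz and makes identical inputs exactly
1 at every populated frequency. For two independent Gaussian processes
the expected squared coherence is 1/M.

A literal-formula variant without the per-frequency square-root
normalization is available for comparison via ``literal=True``; its
values are not bounded by 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import NREM, Hypnogram

logger = logging.getLogger(__name__)


@dataclass
class CoherenceSpectrogram:
    """Squared coherence magnitude per frequency x time bin."""

    freqs: np.ndarray            # Hz, spacing 1/chunk_s
    bin_start_s: np.ndarray      # seconds from recording start
    coh2: np.ndarray             # (n_freqs, n_bins), in [0, 1]
    chunks_per_bin: int          # M
    chunk_s: float
    bin_min: float
    pair: tuple[str, str] = ("", "")
    n_dropped_samples: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coh2, index=pd.Index(self.freqs, name="freq_hz"),
                            columns=pd.Index(self.bin_start_s, name="bin_start_s"))


def chunk_coherence(x: np.ndarray, y: np.ndarray, fs: float, chunk_s: float = 2.0,
                    bin_min: float = 10.0, f_range: tuple[float, float] = (0.5, 20.0),
                    literal: bool = False,
                    pair: tuple[str, str] = ("", "")) -> CoherenceSpectrogram:
    """Coherence spectrogram between two same-rate channels.

    A trailing partial bin is dropped (and logged), mirroring the
    fixed-M averaging convention.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have identical shape")
    n_chunk = chunk_s * fs
    if abs(n_chunk - round(n_chunk)) > 1e-9:
        raise ValueError(f"chunk_s x rate = {n_chunk} is not an integer sample count")
    n_chunk = int(round(n_chunk))
    m = int(round(bin_min * 60.0 / chunk_s))
    bin_samples = m * n_chunk
    n_bins = x.size // bin_samples
    dropped = x.size - n_bins * bin_samples
    if dropped:
        logger.info("dropping trailing partial bin of %d samples", dropped)
    if n_bins == 0:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one {bin_min}-min bin"
        )

    w = sps.get_window("hann", n_chunk, fftbins=True)
    freqs = np.fft.rfftfreq(n_chunk, d=1.0 / fs)
    keep = (freqs >= f_range[0] - 1e-12) & (freqs <= f_range[1] + 1e-12)

    def chunk_fft(sig: np.ndarray) -> np.ndarray:
        c = sig[: n_bins * bin_samples].reshape(n_bins, m, n_chunk)
        c = c - c.mean(axis=2, keepdims=True)
        return np.fft.rfft(c * w, axis=2)

    fx = chunk_fft(x)
    fy = chunk_fft(y)
    sxy = np.sum(fx * np.conj(fy), axis=1)
    sxx = np.sum(np.abs(fx) ** 2, axis=1)
    syy = np.sum(np.abs(fy) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if literal:
            coh = sxy / (sxx * syy)
            coh2 = np.abs(coh) ** 2
        else:
            coh2 = np.abs(sxy) ** 2 / (sxx * syy)
    coh2 = np.where((sxx > 0) & (syy > 0), coh2, 0.0)

    return CoherenceSpectrogram(
        freqs=freqs[keep],
        bin_start_s=np.arange(n_bins) * bin_min * 60.0,
        coh2=coh2[:, keep].T,
        chunks_per_bin=m,
        chunk_s=chunk_s,
        bin_min=bin_min,
        pair=pair,
        n_dropped_samples=int(dropped),
    )


def bin_majority_state(hyp: Hypnogram, bin_min: float, n_bins: int,
                       state: str = NREM) -> np.ndarray:
    """True for time bins where > 50% of scored epochs are in ``state``."""
    epb = int(round(bin_min * 60.0 / hyp.epoch_s))
    out = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        chunk = hyp.labels[b * epb:(b + 1) * epb]
        if chunk.size:
            out[b] = np.count_nonzero(chunk == state) > chunk.size / 2
    return out


def band_coherence_average(spect: CoherenceSpectrogram,
                           band: tuple[float, float] = (0.5, 4.0),
                           hyp: Hypnogram | None = None,
                           state_filter: str | None = None) -> float:
    """Mean squared coherence over a frequency band and all time bins.

    With a hypnogram and ``state_filter``, only bins whose majority state
    matches are averaged ("NREM coherence"). Raises on an empty selection
    or on a band outside the stored frequency range.
    """
    if band[0] < spect.freqs[0] - 1e-9 or band[1] > spect.freqs[-1] + 1e-9:
        raise ValueError(
            f"band {band} lies outside stored range "
            f"({spect.freqs[0]}-{spect.freqs[-1]} Hz)"
        )
    fsel = (spect.freqs >= band[0] - 1e-9) & (spect.freqs <= band[1] + 1e-9)
    bsel = np.ones(spect.bin_start_s.size, dtype=bool)
    if state_filter is not None:
        if hyp is None:
            raise ValueError("state filtering requires a hypnogram")
        bsel = bin_majority_state(hyp, spect.bin_min, spect.bin_start_s.size,
                                  state_filter)
    if not bsel.any():
        raise ValueError(f"no bins with majority state {state_filter!r}")
    return float(spect.coh2[np.ix_(fsel, bsel)].mean())


@dataclass
class RegressionResult:
    """OLS fit of interaction ratio on band coherence."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    df: tuple[int, int]
    n: int
    conf_int_slope: tuple[float, float]


def coherence_ratio_regression(coherence_values, interaction_ratios) -> RegressionResult:
    """Least-squares regression of interaction ratios on per-mouse band
    coherence, with the F-test for a non-zero slope on (1, n-2) df."""
    import statsmodels.api as sm

    x = np.asarray(coherence_values, dtype=float)
    y = np.asarray(interaction_ratios, dtype=float)
    if x.size != y.size:
        raise ValueError("coherence and ratio arrays differ in length")
    if x.size < 3:
        raise ValueError("regression requires at least 3 mice")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in coherence predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        p_value=float(model.f_pvalue),
        df=(1, int(model.df_resid)),
        n=int(x.size),
        conf_int_slope=(float(ci[1][0]), float(ci[1][1])),
    )
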