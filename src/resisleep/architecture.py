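"""Sleep-architecture metrics: state amounts, bouts, sleep lost and recovery.

"Total sleep" is NREM + REM throughout. Artifact epochs are excluded from
state minutes (and reported separately), never interpolated, so per-bin
state minutes sum to the bin width minus artifact minutes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NREM, REM, STATES, Hypnogram

SLEEP_STATES = (NREM, REM)


@dataclass
class StateTimecourse:
    """Per-bin minutes of each state over a recording."""

    table: pd.DataFrame      # columns: bin_start_zt_h, WAKE, NREM, REM, ARTIFACT, TOTAL_SLEEP
    bin_min: float
    epoch_s: float

    def totals(self, light_onset_zt: float = 0.0,
               dark_onset_zt: float = 12.0) -> pd.DataFrame:
        """Light-period, dark-period and 24-h totals per state.

        Only defined for full 24-h timecourses.
        """
        covered = len(self.table) * self.bin_min
        if abs(covered - 1440.0) > 1e-6:
            raise ValueError(
                f"totals require a 24-h hypnogram; this one covers {covered} min"
            )
        h = self.table["bin_start_zt_h"] % 24.0
        light = (h >= light_onset_zt) & (h < dark_onset_zt)
        cols = list(STATES) + ["TOTAL_SLEEP"]
        out = pd.DataFrame({
            "light": self.table.loc[light, cols].sum(),
            "dark": self.table.loc[~light, cols].sum(),
        })
        out["total_24h"] = out["light"] + out["dark"]
        return out


def state_minutes(hyp: Hypnogram, bin_min: float = 120.0) -> StateTimecourse:
    """Minutes of each state per time bin.

    ``bin_min`` must divide the 12-h light period so light/dark totals are
    sums of whole bins.
    """
    if 720.0 % bin_min != 0:
        raise ValueError(f"bin_min must divide 720, got {bin_min}")
    epochs_per_bin = bin_min * 60.0 / hyp.epoch_s
    if epochs_per_bin != int(epochs_per_bin):
        raise ValueError("bin width must be a whole number of epochs")
    epochs_per_bin = int(epochs_per_bin)
    n_bins = int(np.ceil(hyp.n_epochs / epochs_per_bin))

    rows = []
    for b in range(n_bins):
        chunk = hyp.labels[b * epochs_per_bin:(b + 1) * epochs_per_bin]
        row = {"bin_start_zt_h": (hyp.zt_start_s + b * bin_min * 60.0) / 3600.0}
        for st in STATES:
            row[st] = float(np.count_nonzero(chunk == st)) * hyp.epoch_s / 60.0
        row["TOTAL_SLEEP"] = row[NREM] + row[REM]
        rows.append(row)
    return StateTimecourse(table=pd.DataFrame(rows), bin_min=bin_min,
                           epoch_s=hyp.epoch_s)


def detect_bouts(hyp: Hypnogram) -> pd.DataFrame:
    """Maximal same-state runs of a hypnogram.

    Artifact epochs form their own runs and therefore terminate
    surrounding state bouts. Concatenating the rows reconstructs the
    hypnogram exactly.
    """
    cols = ["state", "start_epoch", "n_epochs", "duration_s"]
    if hyp.n_epochs == 0:
        return pd.DataFrame(columns=cols)
    change = np.flatnonzero(hyp.labels[1:] != hyp.labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [hyp.n_epochs]])
    return pd.DataFrame({
        "state": hyp.labels[starts],
        "start_epoch": starts,
        "n_epochs": stops - starts,
        "duration_s": (stops - starts) * hyp.epoch_s,
    })[cols]


def mean_bout_length(hyp: Hypnogram, state: str) -> float:
    """Mean bout duration (epochs) of one state; NaN when absent."""
    bouts = detect_bouts(hyp)
    sel = bouts[bouts["state"] == state]
    return float(sel["n_epochs"].mean()) if len(sel) else float("nan")


def _window_minutes(hyp: Hypnogram, window_zt_h: tuple[float, float]) -> dict:
    lo, hi = (window_zt_h[0] * 3600.0, window_zt_h[1] * 3600.0)
    zt = hyp.epoch_zt_start_s()
    if zt.size == 0 or lo < zt[0] - 1e-9 or hi > zt[-1] + hyp.epoch_s + 1e-9:
        raise ValueError(
            f"hypnogram (ZT {zt[0] if zt.size else 0:.0f}-"
            f"{(zt[-1] + hyp.epoch_s) if zt.size else 0:.0f} s) does not cover "
            f"window ZT {window_zt_h[0]}-{window_zt_h[1]} h"
        )
    sel = (zt >= lo) & (zt < hi)
    return {st: float(np.count_nonzero(hyp.labels[sel] == st)) * hyp.epoch_s / 60.0
            for st in STATES}


def sleep_lost(restriction_hyp: Hypnogram, baseline_hyp: Hypnogram,
               window_zt_h: tuple[float, float] = (0.0, 6.0)) -> dict:
    """Minutes of each sleep state lost during a restriction window.

    Lost = baseline-day state minutes minus restriction-day state minutes
    within the same ZT window, floored at zero per state.
    """
    if restriction_hyp.epoch_s != baseline_hyp.epoch_s:
        raise ValueError("hypnograms have different epoch lengths")
    base = _window_minutes(baseline_hyp, window_zt_h)
    restr = _window_minutes(restriction_hyp, window_zt_h)
    return {st: max(base[st] - restr[st], 0.0) for st in SLEEP_STATES}


@dataclass
class RecoveryCurve:
    """Cumulative recovered sleep relative to baseline, normalized to loss."""

    table: pd.DataFrame      # bin_start_zt_h, cumulative_diff_min, percent_recovered
    state: str
    sleep_lost_min: float


def percent_recovered(recovery_hyp: Hypnogram, baseline_hyp: Hypnogram,
                      lost_min: float, window_zt_h: tuple[float, float] = (6.0, 24.0),
                      bin_min: float = 120.0, state: str = NREM) -> RecoveryCurve:
    """Cumulative (recovery - baseline) state minutes as % of sleep lost.

    Matched-ZT baseline comparison: each bin of the recovery day is
    compared with the same ZT bin of the baseline day. Negative cumulative
    recovery is reported as a negative percentage, not clipped.
    """
    if lost_min <= 0:
        raise ValueError("percent_recovered is undefined when sleep lost is <= 0")
    if recovery_hyp.epoch_s != baseline_hyp.epoch_s:
        raise ValueError("hypnograms have different epoch lengths")
    lo, hi = window_zt_h
    n_bins = (hi - lo) * 60.0 / bin_min
    if n_bins != int(n_bins):
        raise ValueError("window is not a whole number of bins")
    rows = []
    cum = 0.0
    for b in range(int(n_bins)):
        w = (lo + b * bin_min / 60.0, lo + (b + 1) * bin_min / 60.0)
        rec = _window_minutes(recovery_hyp, w)[state]
        base = _window_minutes(baseline_hyp, w)[state]
        cum += rec - base
        rows.append({
            "bin_start_zt_h": w[0],
            "cumulative_diff_min": cum,
            "percent_recovered": 100.0 * cum / lost_min,
        })
    return RecoveryCurve(table=pd.DataFrame(rows), state=state,
                         sleep_lost_min=lost_min)
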