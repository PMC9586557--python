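"""Recording/hypnogram I/O and artifact exclusion.

Signals travel as EDF with channel labels encoding their role
(``EEG_FRONTAL``, ``EEG_PARIETAL``, ``LFP_PRL``, ``LFP_IL``, ``EMG``) and a
``LP:<cutoff>Hz`` prefilter note. Hypnograms are sidecar CSV files with the
documented schema ``epoch_index, zt_start_s, label`` rather than embedded
EDF annotations, keeping the signal container dialect-independent. Study
manifests are YAML.

Artifact-scored epochs (interference from scratching, movement, eating or
drinking in real recordings) are excluded from every per-epoch statistic;
they are never interpolated, and denominators count only retained epochs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .core import ARTIFACT, ROLES, Channel, ChannelMeta, Hypnogram, Recording
from .edf import EdfSignal, read_edf, write_edf

logger = logging.getLogger(__name__)

HYPNOGRAM_COLUMNS = ["epoch_index", "zt_start_s", "label"]


def write_recording(rec: Recording, path, record_s: float = 1.0) -> None:
    """Write a recording to ``path`` as EDF (one label per channel role)."""
    signals = [
        EdfSignal(
            label=ch.meta.role,
            sampling_rate=ch.meta.sampling_rate,
            data=ch.data,
            prefilter=f"LP:{ch.meta.hardware_lowpass:g}Hz",
        )
        for ch in rec.channels
    ]
    write_edf(path, signals, zt_start_s=rec.zt_start_s, record_s=record_s)


def read_recording(path) -> Recording:
    """Read an EDF written by :func:`write_recording`.

    Raises ``ValueError`` for channels whose label is not a recognized
    role, naming the offending channel and listing accepted roles.
    """
    signals, zt_start_s = read_edf(path)
    channels = []
    for sig in signals:
        if sig.label not in ROLES:
            raise ValueError(
                f"{path}: channel label {sig.label!r} does not encode a known "
                f"role; accepted roles: {ROLES}"
            )
        lowpass = 30.0
        if sig.prefilter.startswith("LP:") and sig.prefilter.endswith("Hz"):
            lowpass = float(sig.prefilter[3:-2])
        meta = ChannelMeta(role=sig.label, sampling_rate=sig.sampling_rate,
                           hardware_lowpass=lowpass)
        channels.append(Channel(meta=meta, data=sig.data))
    return Recording(channels=channels, zt_start_s=zt_start_s)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    df = pd.DataFrame({
        "epoch_index": np.arange(hyp.n_epochs),
        "zt_start_s": hyp.epoch_zt_start_s(),
        "label": hyp.labels,
    })
    df.to_csv(path, index=False)


def read_hypnogram(path, epoch_s: float | None = None) -> Hypnogram:
    df = pd.read_csv(path)
    missing = [c for c in HYPNOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: hypnogram CSV missing columns {missing}")
    if len(df) == 0:
        return Hypnogram(labels=np.array([], dtype="U8"), epoch_s=epoch_s or 10.0)
    zt = df["zt_start_s"].to_numpy(dtype=float)
    if epoch_s is None:
        epoch_s = float(zt[1] - zt[0]) if len(zt) > 1 else 10.0
    return Hypnogram(labels=df["label"].to_numpy(dtype="U8"), epoch_s=epoch_s,
                     zt_start_s=float(zt[0]))


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass
class ArtifactFiltered:
    """Per-epoch series with artifact epochs removed.

    ``values`` holds only retained epochs (indexed by ``epoch_index``);
    ``all_artifact`` flags the degenerate every-epoch-excluded case so it is
    never mistaken for a silent zero.
    """

    values: np.ndarray
    epoch_index: np.ndarray
    n_excluded: int
    all_artifact: bool


def exclude_artifacts(hyp: Hypnogram, series_per_epoch) -> ArtifactFiltered:
    """Drop values at ARTIFACT epochs from a per-epoch series.

    The series must have one entry per hypnogram epoch. The number of
    exclusions is logged; downstream denominators (e.g. minutes of NREM)
    must count only retained epochs.
    """
    values = np.asarray(series_per_epoch)
    if values.shape[0] != hyp.n_epochs:
        raise ValueError(
            f"series has {values.shape[0]} entries for {hyp.n_epochs} epochs"
        )
    keep = hyp.labels != ARTIFACT
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d artifact epochs of %d", n_excluded, hyp.n_epochs)
    return ArtifactFiltered(
        values=values[keep],
        epoch_index=np.flatnonzero(keep),
        n_excluded=n_excluded,
        all_artifact=bool(hyp.n_epochs > 0 and not keep.any()),
    )


def validate_pair(rec: Recording, hyp: Hypnogram) -> dict:
    """Check recording/hypnogram pairing invariants; returns a report dict.

    Raises ``ValueError`` when the hypnogram grid does not tile the
    recording duration exactly.
    """
    if abs(hyp.duration_s - rec.duration_s) > 1e-6:
        raise ValueError(
            f"hypnogram covers {hyp.duration_s} s but recording lasts "
            f"{rec.duration_s} s"
        )
    return {
        "n_epochs": hyp.n_epochs,
        "epoch_s": hyp.epoch_s,
        "duration_s": rec.duration_s,
        "channels": rec.roles,
        "artifact_fraction": hyp.artifact_fraction(),
    }
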