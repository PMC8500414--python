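"""Epoch preprocessing: filtering, artifact rejection, baseline, averaging.

The stages mirror a conventional ERP pipeline for this paradigm:
band-pass 0.1-30 Hz (24 dB/octave, zero phase) with a 50 Hz notch,
min-max artifact rejection (>500 uV within any 100 ms window, padded
+-100 ms), average re-reference (a pass-through on pooled two-cluster
data), dual-window baseline correction tied to the step-4 and step-5
stimulus onsets, and per-condition x visual-field averaging of the two
pooled hemisphere channels.

Epoch time convention: t = 0 at the final (step-5) stimulus onset;
step-k onset at (k-5) x 500 ms; epochs span -2100 ms (100 ms before the
first stimulus) to +500 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import ndimage

from .synthetic_eeg import EpochSet

_ALLOWED_ROLLOFFS = (6, 12, 24, 48)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass plus optional notch. Rolloff in dB/octave maps to
    Butterworth order = rolloff/6; applied forward-backward (zero phase),
    which doubles the effective rolloff, as mainstream ERP software does."""

    band_low: float = 0.1
    band_high: float = 30.0
    rolloff: int = 24
    notch: float | None = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ParameterError("require 0 < band_low < band_high")
        if self.rolloff not in _ALLOWED_ROLLOFFS:
            raise ParameterError(f"rolloff must be one of {_ALLOWED_ROLLOFFS}")


@dataclass(frozen=True)
class RejectionSpec:
    """Min-max artifact rejection parameters (all ms / uV, all positive)."""

    minmax_threshold: float = 500.0
    window_ms: float = 100.0
    pad_ms: float = 100.0

    def __post_init__(self) -> None:
        if min(self.minmax_threshold, self.window_ms, self.pad_ms) <= 0:
            raise ParameterError("rejection parameters must be positive")


@dataclass
class ErpWaveform:
    """One averaged waveform: a condition x role (hemisphere or laterality)."""

    condition: str
    role: str                      # 'LH' | 'RH' | 'contra' | 'ipsi' | 'diff'
    time_ms: np.ndarray
    amplitude_uv: np.ndarray
    n_epochs: int
    visual_field: str = "pooled"   # 'left' | 'right' | 'pooled'
    subject: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.amplitude_uv)):
            raise ValueError("waveform amplitudes must be finite")
        if self.n_epochs < 1:
            raise ValueError("an average needs at least one epoch")


def bandpass_notch(
    x: np.ndarray, spec: FilterSpec, sampling_rate: float, axis: int = -1
) -> np.ndarray:
    """Zero-phase Butterworth band-pass plus notch along `axis`."""
    nyquist = sampling_rate / 2.0
    if spec.band_high >= nyquist:
        raise ParameterError(
            f"band_high {spec.band_high} Hz >= Nyquist {nyquist} Hz"
        )
    order = spec.rolloff // 6
    sos = sps.butter(
        order, [spec.band_low, spec.band_high], btype="bandpass",
        output="sos", fs=sampling_rate,
    )
    y = sps.sosfiltfilt(sos, x, axis=axis)
    if spec.notch is not None and spec.notch < nyquist:
        b, a = sps.iirnotch(spec.notch, Q=30.0, fs=sampling_rate)
        y = sps.filtfilt(b, a, y, axis=axis)
    return y


def filter_epochs(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    data = bandpass_notch(epochs.data, spec, epochs.sampling_rate, axis=-1)
    return EpochSet(
        subject_id=epochs.subject_id,
        time_ms=epochs.time_ms,
        data=data,
        meta=epochs.meta.copy(),
        sampling_rate=epochs.sampling_rate,
        channels=epochs.channels,
    )


@dataclass
class RejectionLog:
    """Record of rejected epochs and the bad spans that caused them."""

    n_input: int
    rejected: list = field(default_factory=list)  # (epoch_id, [(start_ms, end_ms), ...])

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_rejected


def reject_artifacts(
    epochs: EpochSet, spec: RejectionSpec = RejectionSpec()
) -> tuple[EpochSet, RejectionLog]:
    """Drop epochs whose peak-to-peak range within any sliding window
    exceeds the threshold on any channel; bad spans are padded +-pad_ms.

    Windows slide sample by sample. Kept epochs are returned unmodified.
    """
    fs = epochs.sampling_rate
    win = max(2, int(round(spec.window_ms / 1000.0 * fs)))
    pad = spec.pad_ms
    rng_ = ndimage.maximum_filter1d(
        epochs.data, size=win, axis=-1
    ) - ndimage.minimum_filter1d(epochs.data, size=win, axis=-1)
    bad_any = (rng_ > spec.minmax_threshold).any(axis=1)  # (n_epochs, n_times)
    log = RejectionLog(n_input=epochs.n_epochs)
    keep = np.ones(epochs.n_epochs, dtype=bool)
    for e in np.nonzero(bad_any.any(axis=-1))[0]:
        keep[e] = False
        idx = np.nonzero(bad_any[e])[0]
        # merge consecutive bad samples into spans
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.r_[idx[0], idx[breaks + 1]]
        ends = np.r_[idx[breaks], idx[-1]]
        spans = [
            (
                float(epochs.time_ms[s] - pad),
                float(epochs.time_ms[t] + pad),
            )
            for s, t in zip(starts, ends)
        ]
        log.rejected.append((int(epochs.meta["epoch_id"].iloc[e]), spans))
    return epochs.select(keep), log


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the channel average.

    On the pooled two-cluster representation this is an explicit
    pass-through, retained as a stage hook: with a full montage
    (> 2 channels) the cross-channel mean is subtracted sample-wise.
    """
    if len(epochs.channels) <= 2:
        return epochs
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return EpochSet(
        subject_id=epochs.subject_id,
        time_ms=epochs.time_ms,
        data=data,
        meta=epochs.meta.copy(),
        sampling_rate=epochs.sampling_rate,
        channels=epochs.channels,
    )


#: baseline windows, ms relative to the final stimulus onset: [-150, 0] of
#: both the fourth (onset -500 ms) and fifth (onset 0 ms) step
BASELINE_WINDOWS_MS = ((-650.0, -500.0), (-150.0, 0.0))


def baseline_correct(
    epochs: EpochSet, windows: tuple = BASELINE_WINDOWS_MS
) -> EpochSet:
    """Subtract, per epoch and channel, the scalar mean over the pooled
    baseline windows. Idempotent: recomputing the pooled mean afterwards
    gives zero."""
    t = epochs.time_ms
    masks = []
    for lo, hi in windows:
        m = (t >= lo) & (t <= hi)
        if not m.any():
            raise ValueError(
                f"epoch time axis does not cover baseline window [{lo}, {hi}] ms"
            )
        masks.append(m)
    pooled = np.logical_or.reduce(masks)
    base = epochs.data[:, :, pooled].mean(axis=-1, keepdims=True)
    return EpochSet(
        subject_id=epochs.subject_id,
        time_ms=epochs.time_ms,
        data=epochs.data - base,
        meta=epochs.meta.copy(),
        sampling_rate=epochs.sampling_rate,
        channels=epochs.channels,
    )


def drop_red_dot(epochs: EpochSet) -> EpochSet:
    """Discard vigilance (red-dot) sequences before averaging."""
    return epochs.select(~epochs.meta["is_red_dot"].to_numpy(bool))


@dataclass
class SubjectAverages:
    """Per-subject condition x visual-field x hemisphere average waveforms."""

    subject: str
    time_ms: np.ndarray
    waves: dict            # (condition, vf, hemisphere) -> ndarray
    n_epochs: dict         # (condition, vf) -> int

    def conditions(self) -> list[str]:
        return sorted({k[0] for k in self.waves})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cond, vf, hemi), wave in self.waves.items():
            rows.append(
                pd.DataFrame(
                    {
                        "subject": self.subject,
                        "condition": cond,
                        "visual_field": vf,
                        "hemisphere": hemi,
                        "time_ms": self.time_ms,
                        "amplitude_uv": wave,
                        "n_epochs": self.n_epochs[(cond, vf)],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SubjectAverages":
        subject = str(df["subject"].iloc[0])
        time_ms = np.sort(df["time_ms"].unique())
        waves, n_ep = {}, {}
        for (cond, vf, hemi), sub in df.groupby(
            ["condition", "visual_field", "hemisphere"]
        ):
            sub = sub.sort_values("time_ms")
            waves[(cond, vf, hemi)] = sub["amplitude_uv"].to_numpy()
            n_ep[(cond, vf)] = int(sub["n_epochs"].iloc[0])
        return cls(subject=subject, time_ms=time_ms, waves=waves, n_epochs=n_ep)


def pool_and_average(epochs: EpochSet) -> SubjectAverages:
    """Average epochs per condition x endpoint visual field, per hemisphere.

    Four conditions x two visual fields give eight averages per hemisphere
    role. A cell with zero surviving epochs is an error naming the cell.
    """
    meta = epochs.meta
    waves, n_ep = {}, {}
    conditions = sorted(meta["condition"].unique())
    for cond in conditions:
        for vf in ("left", "right"):
            mask = (
                (meta["condition"] == cond) & (meta["endpoint_vf"] == vf)
            ).to_numpy()
            if not mask.any():
                raise ValueError(
                    f"no surviving epochs for cell condition={cond}, "
                    f"visual_field={vf}"
                )
            mean = epochs.data[mask].mean(axis=0)  # (n_channels, n_times)
            for c_idx, hemi in enumerate(epochs.channels):
                waves[(cond, vf, hemi)] = mean[c_idx]
            n_ep[(cond, vf)] = int(mask.sum())
    return SubjectAverages(
        subject=epochs.subject_id,
        time_ms=epochs.time_ms,
        waves=waves,
        n_epochs=n_ep,
    )


def preprocess_subject(
    epochs: EpochSet,
    filter_spec: FilterSpec | None = FilterSpec(),
    rejection_spec: RejectionSpec | None = RejectionSpec(),
) -> tuple[SubjectAverages, RejectionLog]:
    """Full preprocessing chain for one subject's epochs.

    filter -> artifact rejection -> average reference -> drop red-dot
    sequences -> dual-window baseline -> condition x VF averaging.
    Passing ``None`` for a spec skips that stage (useful for noiseless
    template-fidelity checks).
    """
    if filter_spec is not None:
        epochs = filter_epochs(epochs, filter_spec)
    if rejection_spec is not None:
        epochs, log = reject_artifacts(epochs, rejection_spec)
    else:
        log = RejectionLog(n_input=epochs.n_epochs)
    epochs = average_reference(epochs)
    epochs = drop_red_dot(epochs)
    epochs = baseline_correct(epochs)
    return pool_and_average(epochs), log
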