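"""Scalar ERP component measures: P1 and N170 peaks, peak-to-peak N170,
and the N2pc contralateral-minus-ipsilateral mean amplitude.

Conventions
-----------
* Windows (ms, relative to final stimulus onset): P1 80-130, N170
  140-210, N2pc 200-300; endpoints inclusive at sample resolution.
* Peaks are sample-wise extrema, ties broken by the earliest sample;
  P1 is the window maximum, N170 the window minimum, and the
  peak-to-peak N170 is N170 minus P1 (negative when the N170 dips
  below the P1), matching the sign convention of reported means.
* N170 measures are taken on the average pooled over both hemispheres
  and both visual fields per condition; the N2pc is the mean, over
  200-300 ms, of the contra-minus-ipsi difference wave pooled over the
  two visual fields (left-visual-field stimuli are contralateral to the
  right hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import SubjectAverages, ErpWaveform


@dataclass(frozen=True)
class MeasureWindows:
    p1: tuple = (80.0, 130.0)
    n170: tuple = (140.0, 210.0)
    n2pc: tuple = (200.0, 300.0)

    def __post_init__(self) -> None:
        for name in ("p1", "n170", "n2pc"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"window {name} must satisfy lo < hi")


def _window_indices(time_ms: np.ndarray, window: tuple) -> np.ndarray:
    lo, hi = window
    idx = np.nonzero((time_ms >= lo) & (time_ms <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"waveform does not cover window [{lo}, {hi}] ms")
    return idx

def measure_p1(
    time_ms: np.ndarray, wave: np.ndarray, windows: MeasureWindows = MeasureWindows()
) -> tuple[float, float]:
    """(amplitude, latency) of the P1: maximum within its window."""
    idx = _window_indices(time_ms, windows.p1)
    k = idx[np.argmax(wave[idx])]   # argmax returns the first maximum
    return float(wave[k]), float(time_ms[k])


def measure_n170(
    time_ms: np.ndarray, wave: np.ndarray, windows: MeasureWindows = MeasureWindows()
) -> tuple[float, float]:
    """(amplitude, latency) of the N170: minimum within its window."""
    idx = _window_indices(time_ms, windows.n170)
    k = idx[np.argmin(wave[idx])]
    return float(wave[k]), float(time_ms[k])


def n170_peak_to_peak(
    time_ms: np.ndarray, wave: np.ndarray, windows: MeasureWindows = MeasureWindows()
) -> float:
    """N170 window minimum minus P1 window maximum (uV); offset-invariant."""
    n170_amp, _ = measure_n170(time_ms, wave, windows)
    p1_amp, _ = measure_p1(time_ms, wave, windows)
    return n170_amp - p1_amp


#: hemisphere contralateral to each endpoint visual field
CONTRA_OF_VF = {"left": "RH", "right": "LH"}


def n2pc_difference(
    waves_by_vf: dict, time_ms: np.ndarray, condition: str = "", subject: str = ""
) -> ErpWaveform:
    """Pooled contra-minus-ipsi difference wave for one condition.

    ``waves_by_vf`` maps (visual_field, hemisphere) -> waveform for both
    visual fields and both hemispheres; the two visual fields' difference
    waves are pooled by pointwise mean.  Swapping contra and ipsi inputs
    negates the output.
    """
    diffs = []
    n = 0
    for vf in ("left", "right"):
        contra_h = CONTRA_OF_VF[vf]
        ipsi_h = "LH" if contra_h == "RH" else "RH"
        try:
            contra = waves_by_vf[(vf, contra_h)]
            ipsi = waves_by_vf[(vf, ipsi_h)]
        except KeyError as err:
            raise ValueError(
                f"missing hemisphere average for cell visual_field={vf}, "
                f"hemisphere={err.args[0]}"
            ) from None
        diffs.append(np.asarray(contra) - np.asarray(ipsi))
        n += 1
    pooled = np.mean(diffs, axis=0)
    return ErpWaveform(
        condition=condition,
        role="diff",
        time_ms=time_ms,
        amplitude_uv=pooled,
        n_epochs=max(1, n),
        visual_field="pooled",
        subject=subject,
    )


def n2pc_mean_amplitude(
    time_ms: np.ndarray, diff: np.ndarray, windows: MeasureWindows = MeasureWindows()
) -> float:
    """Arithmetic mean of the difference wave within the N2pc window (uV)."""
    idx = _window_indices(time_ms, windows.n2pc)
    return float(np.asarray(diff)[idx].mean())


# ---------------------------------------------------------------------------
# per-subject tables

def pooled_condition_wave(avg: SubjectAverages, condition: str) -> np.ndarray:
    """Condition average pooled over both visual fields and both hemispheres."""
    keys = [
        (condition, vf, hemi)
        for vf in ("left", "right")
        for hemi in ("LH", "RH")
    ]
    missing = [k for k in keys if k not in avg.waves]
    if missing:
        raise ValueError(f"missing averages for cells {missing}")
    return np.mean([avg.waves[k] for k in keys], axis=0)


def subject_diff_wave(avg: SubjectAverages, condition: str) -> ErpWaveform:
    """Pooled N2pc difference wave for one subject and condition."""
    waves_by_vf = {}
    for vf in ("left", "right"):
        for hemi in ("LH", "RH"):
            key = (condition, vf, hemi)
            if key not in avg.waves:
                raise ValueError(f"missing average for cell {key}")
            waves_by_vf[(vf, hemi)] = avg.waves[key]
    return n2pc_difference(
        waves_by_vf, avg.time_ms, condition=condition, subject=avg.subject
    )


def component_table(
    averages: list[SubjectAverages], windows: MeasureWindows = MeasureWindows()
) -> pd.DataFrame:
    """Long table of scalar measures: one row per subject x condition x measure.

    Measures: ``p1_peak`` and ``n170_peak`` (with latencies), ``n170_p2p``
    and ``n2pc_mean``.
    """
    rows = []
    for avg in averages:
        for cond in avg.conditions():
            pooled = pooled_condition_wave(avg, cond)
            p1_amp, p1_lat = measure_p1(avg.time_ms, pooled, windows)
            n170_amp, n170_lat = measure_n170(avg.time_ms, pooled, windows)
            diff = subject_diff_wave(avg, cond)
            n2pc = n2pc_mean_amplitude(avg.time_ms, diff.amplitude_uv, windows)
            rows += [
                dict(subject=avg.subject, condition=cond, measure="p1_peak",
                     value=p1_amp, latency_ms=p1_lat),
                dict(subject=avg.subject, condition=cond, measure="n170_peak",
                     value=n170_amp, latency_ms=n170_lat),
                dict(subject=avg.subject, condition=cond, measure="n170_p2p",
                     value=n170_amp - p1_amp, latency_ms=np.nan),
                dict(subject=avg.subject, condition=cond, measure="n2pc_mean",
                     value=n2pc, latency_ms=np.nan),
            ]
    return pd.DataFrame(rows)


def measure_cell_matrix(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Pivot the component table into a subjects x conditions cell matrix."""
    sub = table[table["measure"] == measure]
    if sub.empty:
        raise ValueError(f"measure {measure!r} not present in table")
    return sub.pivot(index="subject", columns="condition", values="value")
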