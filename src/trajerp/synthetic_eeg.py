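"""Synthetic multi-subject EEG epochs with known ERP structure.

Real recordings for this paradigm are not public, so the package ships a
generator that emulates their statistical structure: pooled left- and
right-hemisphere occipito-temporal cluster signals carrying a P1
(positive, ~100 ms), an N170 (negative, ~175 ms, modulated by stimulus
predictability and by cueing) and a contralateral-specific N2pc
negativity (~250 ms, modulated by predictability only), on top of 1/f
plus white noise, with between-subject variability in both component
amplitudes and effect sizes.

Components are Gaussian bumps on the time axis, not biophysical dipole
projections, and only the two pooled cluster channels are simulated:
the downstream analysis never touches unpooled electrodes.  Default
condition means are the grand means reported for this paradigm
(peak-to-peak N170 around -2.2 uV; N2pc window means of +0.19 uV for
predictable and -0.10 uV for unpredictable endpoints), and the
generator calibrates template peak amplitudes so that the *measured*
quantities -- peak-to-peak N170 on the hemisphere-pooled average,
window-mean N2pc on the contralateral-minus-ipsilateral difference --
hit those targets exactly in the noiseless limit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import SessionPlan, generate_session

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: step-k stimulus onset relative to the final (step-5) onset, ms
STEP_ONSETS_MS = {k: (k - 5) * 500.0 for k in range(1, 6)}

CHANNELS = ("LH", "RH")


class ParameterError(ValueError):
    """Raised for invalid generator parameters."""


def component_template(
    kind: str,
    latency_ms: float,
    width_ms: float,
    amplitude_uv: float,
    time_ms: np.ndarray,
) -> np.ndarray:
    """Gaussian-bump model of an ERP component.

    Parameters
    ----------
    kind : {'P1', 'N170', 'N2pc'}
        Label only; all components share the same functional form.
    latency_ms : float
        Time of the signed peak.
    width_ms : float
        Full width at half maximum of the bump.  Must be positive.
    amplitude_uv : float
        Signed peak amplitude in microvolts.
    time_ms : ndarray
        Time axis on which to evaluate the template.
    """
    if kind not in ("P1", "N170", "N2pc"):
        raise ParameterError(f"unknown component kind {kind!r}")
    if width_ms <= 0:
        raise ParameterError(f"component width must be positive, got {width_ms}")
    sigma = width_ms * _FWHM_TO_SIGMA
    return amplitude_uv * np.exp(-0.5 * ((np.asarray(time_ms) - latency_ms) / sigma) ** 2)


@dataclass
class GenerativeConfig:
    """Parameters of the synthetic cohort.

    Component amplitudes are stated on the scale on which they are
    analysed: ``n170_amplitude`` is the grand-mean *peak-to-peak* N170
    (window minimum minus P1 window maximum) and ``n2pc_amplitude`` the
    grand-mean 200-300 ms *window mean* of the contralateral-minus-
    ipsilateral difference wave.  Condition effects are full
    predictable-vs-unpredictable (and cued-vs-non-cued) differences,
    split +-half around the grand mean.
    """

    n_subjects: int = 36
    trials_per_condition: int = 108
    red_dot_total: int = 48
    sampling_rate: float = 256.0
    epoch_start_ms: float = -2100.0
    epoch_end_ms: float = 500.0

    p1_latency: float = 100.0
    p1_width: float = 30.0
    p1_amplitude: float = 1.0
    n170_latency: float = 175.0
    n170_width: float = 35.0
    n170_amplitude: float = -2.155     # grand-mean peak-to-peak, uV
    n2pc_latency: float = 250.0
    n2pc_width: float = 100.0          # FWHM; 50 ms half-width each side
    n2pc_amplitude: float = 0.045      # grand-mean window mean, uV

    delta_n170_expectation: float = -0.27   # unpredictable minus predictable
    delta_n170_cueing: float = -0.21        # cued minus non-cued
    delta_n2pc_expectation: float = -0.29   # unpredictable minus predictable

    subject_sd_p1: float = 0.5
    subject_sd_n170: float = 1.25
    subject_sd_n2pc: float = 0.2
    subject_sd_n170_expectation: float = 0.46
    subject_sd_n170_cueing: float = 0.28
    subject_sd_n2pc_expectation: float = 0.47

    noise_white_sd: float = 3.0
    noise_pink_scale: float = 4.0
    blink_rate: float = 0.02
    blink_amplitude: float = 800.0
    blink_width_ms: float = 200.0
    latency_jitter_sd: float = 0.0

    # measurement windows used for amplitude calibration, ms
    p1_window: tuple = (80.0, 130.0)
    n170_window: tuple = (140.0, 210.0)
    n2pc_window: tuple = (200.0, 300.0)

    seed: int = 0

    def __post_init__(self) -> None:
        # windows may arrive as lists from YAML; normalise for hashing
        self.p1_window = tuple(self.p1_window)
        self.n170_window = tuple(self.n170_window)
        self.n2pc_window = tuple(self.n2pc_window)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.trials_per_condition < 1:
            raise ParameterError("trials_per_condition must be >= 1")
        for name in ("p1_width", "n170_width", "n2pc_width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    def time_axis(self) -> np.ndarray:
        n = int(round((self.epoch_end_ms - self.epoch_start_ms) / 1000.0
                      * self.sampling_rate)) + 1
        return self.epoch_start_ms + np.arange(n) / self.sampling_rate * 1000.0

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: GenerativeConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# cell means implied by the grand means and effect deltas

_EXPECTATION_CODE = {"predictable": -0.5, "unpredictable": +0.5}
_CUEING_CODE = {"cued": +0.5, "noncued": -0.5}


def split_condition(condition: str) -> tuple[str, str]:
    """('predictable'|'unpredictable', 'cued'|'noncued') from a condition name."""
    expectation, status = condition.split("_")
    return expectation, status


def n170_cell_means(config: GenerativeConfig) -> dict[str, float]:
    """Target peak-to-peak N170 per condition (uV)."""
    out = {}
    for exp_ in _EXPECTATION_CODE:
        for cue in _CUEING_CODE:
            out[f"{exp_}_{cue}"] = (
                config.n170_amplitude
                + config.delta_n170_expectation * _EXPECTATION_CODE[exp_]
                + config.delta_n170_cueing * _CUEING_CODE[cue]
            )
    return out


def n2pc_cell_means(config: GenerativeConfig) -> dict[str, float]:
    """Target N2pc window mean per condition (uV); no cueing effect injected."""
    out = {}
    for exp_ in _EXPECTATION_CODE:
        for cue in _CUEING_CODE:
            out[f"{exp_}_{cue}"] = (
                config.n2pc_amplitude
                + config.delta_n2pc_expectation * _EXPECTATION_CODE[exp_]
            )
    return out


# ---------------------------------------------------------------------------
# amplitude calibration: template peak <-> measured quantity

def _window_slice(time_ms: np.ndarray, window: tuple) -> slice:
    lo, hi = window
    idx = np.nonzero((time_ms >= lo) & (time_ms <= hi))[0]
    return slice(idx[0], idx[-1] + 1)


def n2pc_window_gain(config: GenerativeConfig, time_ms: np.ndarray) -> float:
    """Window mean of the unit-peak N2pc template over the analysis window."""
    unit = component_template("N2pc", config.n2pc_latency, config.n2pc_width, 1.0, time_ms)
    return float(unit[_window_slice(time_ms, config.n2pc_window)].mean())


def _calibrated_n170_peak(
    target_p2p: float,
    context: np.ndarray,
    n170_unit: np.ndarray,
    p1_slice: slice,
    n170_slice: slice,
) -> float:
    """Template peak giving the target peak-to-peak measure in `context`.

    `context` is the noiseless hemisphere-pooled waveform without the final
    N170 (P1 plus the pooled share of the contralateral N2pc).  The map from
    peak to measured peak-to-peak is solved by fixed-point iteration; it is
    linear with slope ~1 because the window extrema sit near the template
    peaks, so two or three iterations reach float precision.
    """
    a = target_p2p + context[p1_slice].max()  # ignore-overlap starting point
    for _ in range(4):
        wave = context + a * n170_unit
        measured = wave[n170_slice].min() - wave[p1_slice].max()
        a -= measured - target_p2p
    return a


# ---------------------------------------------------------------------------
# noise

def pink_noise(rng: np.random.Generator, shape: tuple, rms: float) -> np.ndarray:
    """1/f-amplitude noise with the requested per-sample RMS, along the last axis."""
    if rms == 0:
        return np.zeros(shape)
    n = shape[-1]
    w = rng.standard_normal(shape)
    spec = np.fft.rfft(w, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    # exact expected per-sample variance of the shaped series
    weights = np.full_like(f, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    expected_var = float((weights * scale**2).sum()) / n
    return x * (rms / np.sqrt(expected_var))


# ---------------------------------------------------------------------------
# epoch container

@dataclass
class EpochSet:
    """Per-subject pooled-cluster epochs with condition labels.

    ``data`` has shape (n_epochs, n_channels, n_times); channels are the
    pooled left- and right-hemisphere clusters in that order.
    """

    subject_id: str
    time_ms: np.ndarray
    data: np.ndarray
    meta: pd.DataFrame
    sampling_rate: float
    channels: tuple = CHANNELS

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_times)")
        if self.data.shape[0] != len(self.meta):
            raise ValueError("meta rows must match number of epochs")
        if self.data.shape[2] != len(self.time_ms):
            raise ValueError("time axis length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            subject_id=self.subject_id,
            time_ms=self.time_ms,
            data=self.data[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            sampling_rate=self.sampling_rate,
            channels=self.channels,
        )

    def to_long_dataframe(self) -> pd.DataFrame:
        n_e, n_c, n_t = self.data.shape
        meta = self.meta
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "epoch_id": np.repeat(meta["epoch_id"].to_numpy(), n_c * n_t),
                "condition": np.repeat(meta["condition"].to_numpy(), n_c * n_t),
                "endpoint_vf": np.repeat(meta["endpoint_vf"].to_numpy(), n_c * n_t),
                "lateral_shape_status": np.repeat(
                    meta["lateral_shape_status"].to_numpy(), n_c * n_t
                ),
                "hemisphere": np.tile(np.repeat(self.channels, n_t), n_e),
                "time_ms": np.tile(self.time_ms, n_e * n_c),
                "amplitude_uv": self.data.reshape(-1),
            }
        )

    @classmethod
    def from_long_dataframe(cls, df: pd.DataFrame, sampling_rate: float) -> "EpochSet":
        subject = str(df["subject"].iloc[0])
        time_ms = np.sort(df["time_ms"].unique())
        channels = tuple(sorted(df["hemisphere"].unique()))
        epoch_ids = df["epoch_id"].unique()
        n_e, n_c, n_t = len(epoch_ids), len(channels), len(time_ms)
        df = df.sort_values(["epoch_id", "hemisphere", "time_ms"], kind="stable")
        data = df["amplitude_uv"].to_numpy().reshape(n_e, n_c, n_t)
        first = df.groupby("epoch_id", sort=True).first().reset_index()
        meta = first[
            ["epoch_id", "condition", "endpoint_vf", "lateral_shape_status"]
        ].copy()
        if "is_red_dot" not in meta:
            meta["is_red_dot"] = False
        # groupby sorts epoch_ids; data was reshaped in the same sorted order
        order = np.argsort(epoch_ids, kind="stable")
        assert np.array_equal(np.sort(epoch_ids), meta["epoch_id"].to_numpy())
        del order
        return cls(
            subject_id=subject,
            time_ms=time_ms,
            data=data,
            meta=meta,
            sampling_rate=sampling_rate,
            channels=channels,
        )

    def save(self, directory, stem: str | None = None) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or f"epochs_{self.subject_id}"
        csv_path = directory / f"{stem}.csv"
        self.to_long_dataframe().to_csv(csv_path, index=False)
        sidecar = {
            "subject_id": self.subject_id,
            "sampling_rate": self.sampling_rate,
            "channels": list(self.channels),
            "n_epochs": int(self.n_epochs),
            "is_red_dot": self.meta["is_red_dot"].astype(bool).tolist(),
        }
        with open(directory / f"{stem}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
        return csv_path

    @classmethod
    def load(cls, csv_path) -> "EpochSet":
        csv_path = Path(csv_path)
        with open(csv_path.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        out = cls.from_long_dataframe(pd.read_csv(csv_path), sidecar["sampling_rate"])
        out.meta["is_red_dot"] = sidecar["is_red_dot"]
        return out


# ---------------------------------------------------------------------------
# simulation

def simulate_subject(
    config: GenerativeConfig, plan: SessionPlan, subject_seed: int
) -> EpochSet:
    """Simulate one subject's epochs for every sequence in the session plan.

    Each epoch carries bilateral step-evoked P1/N170 responses for steps
    1-4, a final-step P1 and condition-dependent N170 on both channels, a
    condition-dependent N2pc added only to the channel contralateral to
    the lateral endpoint, 1/f + white noise, and (at the configured rate)
    a square blink artifact large enough to trip min-max rejection.
    Reproducible for a given (config.seed, subject_seed).
    """
    if len(plan.sequences) == 0:
        raise ValueError("session plan contains no sequences")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, subject_seed]))
    time_ms = config.time_axis()
    n_t = len(time_ms)
    n_e = len(plan.sequences)

    p1_slice = _window_slice(time_ms, config.p1_window)
    n170_slice = _window_slice(time_ms, config.n170_window)

    jitter = (
        float(rng.normal(0.0, config.latency_jitter_sd))
        if config.latency_jitter_sd > 0
        else 0.0
    )
    p1_unit = component_template("P1", config.p1_latency + jitter, config.p1_width, 1.0, time_ms)
    n170_unit = component_template(
        "N170", config.n170_latency + jitter, config.n170_width, 1.0, time_ms
    )
    n2pc_unit = component_template(
        "N2pc", config.n2pc_latency + jitter, config.n2pc_width, 1.0, time_ms
    )
    gain = float(n2pc_unit[_window_slice(time_ms, config.n2pc_window)].mean())

    # subject random effects
    shift_p1 = float(rng.normal(0.0, config.subject_sd_p1))
    shift_n170 = float(rng.normal(0.0, config.subject_sd_n170))
    shift_n2pc = float(rng.normal(0.0, config.subject_sd_n2pc))
    eff_n170_exp = config.delta_n170_expectation + float(
        rng.normal(0.0, config.subject_sd_n170_expectation)
    )
    eff_n170_cue = config.delta_n170_cueing + float(
        rng.normal(0.0, config.subject_sd_n170_cueing)
    )
    eff_n2pc_exp = config.delta_n2pc_expectation + float(
        rng.normal(0.0, config.subject_sd_n2pc_expectation)
    )
    p1_amp = config.p1_amplitude + shift_p1

    # this subject's target measures per condition
    p2p_targets, n2pc_peaks = {}, {}
    for cond in n170_cell_means(config):
        exp_, cue = split_condition(cond)
        p2p_targets[cond] = (
            config.n170_amplitude
            + shift_n170
            + eff_n170_exp * _EXPECTATION_CODE[exp_]
            + eff_n170_cue * _CUEING_CODE[cue]
        )
        n2pc_mean = (
            config.n2pc_amplitude + shift_n2pc + eff_n2pc_exp * _EXPECTATION_CODE[exp_]
        )
        n2pc_peaks[cond] = n2pc_mean / gain

    # calibrate final-N170 peaks so hemisphere-pooled measures hit the targets
    n170_peaks = {}
    for cond in p2p_targets:
        context = p1_amp * p1_unit + 0.5 * n2pc_peaks[cond] * n2pc_unit
        n170_peaks[cond] = _calibrated_n170_peak(
            p2p_targets[cond], context, n170_unit, p1_slice, n170_slice
        )

    # bilateral step-evoked background: steps 1-4 get base-amplitude P1+N170
    background = np.zeros(n_t)
    base_n170_peak = _calibrated_n170_peak(
        config.n170_amplitude + shift_n170,
        p1_amp * p1_unit,
        n170_unit,
        p1_slice,
        n170_slice,
    )
    for k in range(1, 5):
        onset = STEP_ONSETS_MS[k]
        background += component_template(
            "P1", config.p1_latency + onset, config.p1_width, p1_amp, time_ms
        )
        background += component_template(
            "N170", config.n170_latency + onset, config.n170_width, base_n170_peak, time_ms
        )
    background += p1_amp * p1_unit  # final-step P1

    data = np.empty((n_e, 2, n_t))
    data[:] = background
    conditions = np.array([s.condition for s in plan.sequences])
    vfs = np.array([s.endpoint_vf for s in plan.sequences])
    n170_amp = np.array([n170_peaks[c] for c in conditions])
    n2pc_amp = np.array([n2pc_peaks[c] for c in conditions])
    data += n170_amp[:, None, None] * n170_unit[None, None, :]
    contra = np.where(vfs == "left", 1, 0)  # left VF -> right hemisphere
    data[np.arange(n_e), contra, :] += n2pc_amp[:, None] * n2pc_unit[None, :]

    if config.noise_white_sd > 0:
        data += rng.normal(0.0, config.noise_white_sd, size=data.shape)
    if config.noise_pink_scale > 0:
        data += pink_noise(rng, data.shape, config.noise_pink_scale)

    if config.blink_rate > 0:
        blink_mask = rng.random(n_e) < config.blink_rate
        width = max(1, int(round(config.blink_width_ms / 1000.0 * config.sampling_rate)))
        for e in np.nonzero(blink_mask)[0]:
            start = int(rng.integers(0, max(1, n_t - width)))
            data[e, :, start : start + width] += config.blink_amplitude

    meta = pd.DataFrame(
        {
            "epoch_id": np.arange(n_e),
            "condition": conditions,
            "endpoint_vf": vfs,
            "lateral_shape_status": [s.lateral_shape for s in plan.sequences],
            "is_red_dot": [s.is_red_dot for s in plan.sequences],
        }
    )
    return EpochSet(
        subject_id=f"S{subject_seed:03d}",
        time_ms=time_ms,
        data=data,
        meta=meta,
        sampling_rate=config.sampling_rate,
    )


def generate_cohort(
    config: GenerativeConfig,
    plan: SessionPlan | None = None,
    out_dir=None,
) -> tuple[list[EpochSet], dict]:
    """Simulate all subjects; optionally write epoch CSVs plus a manifest.

    Every subject views the same balanced session plan (fresh random
    presentation order per subject would not change any average), with
    subject seeds 1..n_subjects derived from the master seed.
    """
    if plan is None:
        plan = generate_session(
            per_condition=config.trials_per_condition,
            red_dot_total=config.red_dot_total,
            seed=config.seed,
        )
    subjects = []
    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "subject_seeds": list(range(1, config.n_subjects + 1)),
    }
    for s in manifest["subject_seeds"]:
        subjects.append(simulate_subject(config, plan, subject_seed=s))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for es in subjects:
            es.save(out_dir)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return subjects, manifest
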