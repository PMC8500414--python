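"""Synthetic EEG generator: templates, noiseless limits, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from trajerp import GenerativeConfig, generate_session, simulate_subject
from trajerp.synthetic_eeg import (
    EpochSet,
    component_template,
    generate_cohort,
    n170_cell_means,
    n2pc_cell_means,
    pink_noise,
    ParameterError,
)
from trajerp.preprocessing import (
    RejectionSpec,
    preprocess_subject,
    reject_artifacts,
)
from trajerp.erp_measures import component_table


TIME = np.arange(-100.0, 500.5, 1.0)


class TestComponentTemplate:
    def test_zero_amplitude_is_flat(self):
        assert not component_template("P1", 100, 30, 0.0, TIME).any()

    def test_signed_peak_at_latency(self):
        wave = component_template("N170", 175, 35, -3.0, TIME)
        k = np.argmin(wave)
        assert wave[k] == pytest.approx(-3.0)
        assert TIME[k] == pytest.approx(175, abs=2)

    def test_summed_templates_have_expected_window_extrema(self):
        wave = component_template("P1", 100, 20, 2.0, TIME) + component_template(
            "N170", 175, 20, -3.0, TIME
        )
        p1win = (TIME >= 80) & (TIME <= 130)
        n170win = (TIME >= 140) & (TIME <= 210)
        assert wave[p1win].max() == pytest.approx(2.0, abs=0.01)
        assert wave[n170win].min() == pytest.approx(-3.0, abs=0.01)

    @pytest.mark.parametrize("width", [0.0, -5.0])
    def test_nonpositive_width_rejected(self, width):
        with pytest.raises(ParameterError):
            component_template("P1", 100, width, 1.0, TIME)


def test_pink_noise_rms_and_spectrum():
    rng = np.random.default_rng(0)
    x = pink_noise(rng, (200, 1024), rms=2.0)
    assert x.std() == pytest.approx(2.0, rel=0.05)
    # spectral power should fall with frequency (1/f amplitude shaping)
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    mean_spec = spec.mean(axis=0)
    low = mean_spec[2:20].mean()
    high = mean_spec[200:400].mean()
    assert low > 10 * high


def test_zero_noise_zero_effects_epochs_identical_across_conditions(
    noiseless_config, small_plan
):
    cfg = dataclasses.replace(
        noiseless_config,
        delta_n170_expectation=0.0,
        delta_n170_cueing=0.0,
        delta_n2pc_expectation=0.0,
        n2pc_amplitude=0.0,
    )
    es = simulate_subject(cfg, small_plan, subject_seed=1)
    ref = es.data[0]
    assert np.allclose(es.data - ref[None], 0.0, atol=1e-12)
    # with no contralateral component the hemispheres are identical
    assert np.allclose(es.data[:, 0] - es.data[:, 1], 0.0, atol=1e-12)


def test_noiseless_diff_wave_equals_pure_n2pc_template(noiseless_config, small_plan):
    cfg = dataclasses.replace(noiseless_config, delta_n2pc_expectation=0.0)
    es = simulate_subject(cfg, small_plan, subject_seed=1)
    avg, _ = preprocess_subject(es, filter_spec=None, rejection_spec=None)
    from trajerp.erp_measures import subject_diff_wave

    diff = subject_diff_wave(avg, "predictable_cued")
    gain_t = component_template(
        "N2pc", cfg.n2pc_latency, cfg.n2pc_width, 1.0, avg.time_ms
    )
    window = (avg.time_ms >= 200) & (avg.time_ms <= 300)
    peak = cfg.n2pc_amplitude / gain_t[window].mean()
    assert np.allclose(diff.amplitude_uv, peak * gain_t, atol=1e-6)


def test_noiseless_cohort_recovers_injected_condition_means(
    noiseless_config, small_plan
):
    """Measured condition means equal the configured targets in the
    noiseless limit, within template-discretisation error."""
    es = simulate_subject(noiseless_config, small_plan, subject_seed=1)
    avg, _ = preprocess_subject(es, filter_spec=None, rejection_spec=None)
    table = component_table([avg])
    for measure, targets in (
        ("n170_p2p", n170_cell_means(noiseless_config)),
        ("n2pc_mean", n2pc_cell_means(noiseless_config)),
    ):
        got = table[table.measure == measure].set_index("condition")["value"]
        for cond, target in targets.items():
            assert got[cond] == pytest.approx(target, abs=0.01), (measure, cond)


def test_blink_rate_one_marks_every_epoch_for_rejection(
    noiseless_config, small_plan
):
    cfg = dataclasses.replace(noiseless_config, blink_rate=1.0, blink_amplitude=600.0)
    es = simulate_subject(cfg, small_plan, subject_seed=2)
    kept, log = reject_artifacts(es, RejectionSpec())
    assert kept.n_epochs == 0
    assert log.n_rejected == es.n_epochs


def test_simulation_reproducible_per_seed_pair(small_plan):
    cfg = GenerativeConfig(n_subjects=1, trials_per_condition=8, red_dot_total=4, seed=5)
    a = simulate_subject(cfg, small_plan, subject_seed=3)
    b = simulate_subject(cfg, small_plan, subject_seed=3)
    c = simulate_subject(cfg, small_plan, subject_seed=4)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_cohort_outputs_byte_identical(tmp_path, small_plan):
    cfg = GenerativeConfig(n_subjects=2, trials_per_condition=8, red_dot_total=4, seed=9)
    generate_cohort(cfg, plan=small_plan, out_dir=tmp_path / "a")
    generate_cohort(cfg, plan=small_plan, out_dir=tmp_path / "b")
    for name in ("epochs_S001.csv", "epochs_S002.csv", "manifest.json"):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes()


def test_epoch_labels_follow_plan_and_roundtrip(noiseless_config, small_plan):
    es = simulate_subject(noiseless_config, small_plan, subject_seed=1)
    assert list(es.meta["condition"]) == [s.condition for s in small_plan.sequences]
    assert list(es.meta["is_red_dot"]) == [s.is_red_dot for s in small_plan.sequences]
    df = es.to_long_dataframe()
    assert set(df.columns) == {
        "subject", "epoch_id", "condition", "endpoint_vf",
        "lateral_shape_status", "hemisphere", "time_ms", "amplitude_uv",
    }
    back = EpochSet.from_long_dataframe(df, es.sampling_rate)
    assert np.allclose(back.data, es.data)
    assert list(back.meta["condition"]) == list(es.meta["condition"])


def test_white_noise_level_does_not_bias_condition_means(small_plan):
    """Doubling the white-noise SD inflates variance but leaves the mean
    N170 measure unbiased (checked against the noiseless truth)."""
    means = {}
    for sd in (2.0, 4.0):
        vals = []
        for seed in range(6):
            cfg = GenerativeConfig(
                n_subjects=1, trials_per_condition=8, red_dot_total=4,
                subject_sd_p1=0, subject_sd_n170=0, subject_sd_n2pc=0,
                subject_sd_n170_expectation=0, subject_sd_n170_cueing=0,
                subject_sd_n2pc_expectation=0, noise_pink_scale=0.0,
                blink_rate=0.0, noise_white_sd=sd, seed=100 + seed,
            )
            es = simulate_subject(cfg, small_plan, subject_seed=1)
            avg, _ = preprocess_subject(es, filter_spec=None, rejection_spec=None)
            t = component_table([avg])
            vals.append(
                t[(t.measure == "n2pc_mean")]["value"].mean()
            )
        means[sd] = np.mean(vals)
    truth = GenerativeConfig().n2pc_amplitude
    # both noise levels centred on the injected grand mean
    assert means[2.0] == pytest.approx(truth, abs=0.25)
    assert means[4.0] == pytest.approx(truth, abs=0.5)
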