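"""Ground-truth generators and the pseudo-LFP study simulator."""

import numpy as np
import pytest

import iistruct as ii
from iistruct.synthetic import (
    ContinuousStudy,
    SyntheticStudyConfig,
    desk_study_config,
)


class TestFeedforwardTPM:
    def test_perfect_copy_is_deterministic(self):
        tpm = ii.make_feedforward_tpm(2, 1.0)
        for s in range(4):
            assert tpm.probs[s, 1] == (1.0 if s & 1 else 0.0)

    def test_half_fidelity_copy_carries_no_information(self):
        tpm = ii.make_feedforward_tpm(2, 0.5)
        assert np.all(tpm.probs[:, 1] == 0.5)

    def test_source_node_is_a_coin_flip(self):
        tpm = ii.make_feedforward_tpm(3, 0.9)
        assert np.all(tpm.probs[:, 0] == 0.5)

    @pytest.mark.parametrize("n,fid", [(2, 0.7), (3, 0.9), (4, 0.6), (5, 1.0)])
    def test_passes_structural_feedforward_check(self, n, fid):
        assert ii.is_feedforward(ii.make_feedforward_tpm(n, fid))

    @pytest.mark.parametrize("n", [1, 6])
    def test_size_out_of_range_rejected(self, n):
        with pytest.raises(ValueError):
            ii.make_feedforward_tpm(n, 0.9)

    def test_fidelity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ii.make_feedforward_tpm(3, 0.4)


class TestRecurrentTPM:
    def test_zero_coupling_is_fully_unconstrained(self):
        tpm = ii.make_recurrent_tpm(4, 0.0, seed=3)
        assert np.all(tpm.probs == 0.5)

    def test_deterministic_under_fixed_seed(self):
        a = ii.make_recurrent_tpm(3, 1.5, seed=9)
        b = ii.make_recurrent_tpm(3, 1.5, seed=9)
        assert np.array_equal(a.probs, b.probs)

    def test_strong_coupling_is_not_feedforward(self):
        assert not ii.is_feedforward(ii.make_recurrent_tpm(4, 3.0, seed=1))

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            ii.make_recurrent_tpm(3, -0.1, seed=0)


class TestSampleTimeSeries:
    def test_deterministic_self_flip_alternates(self):
        # single node that always flips: p(on | off) = 1, p(on | on) = 0
        tpm = ii.StateByNodeTPM(np.array([[1.0], [0.0]]), n_nodes=1)
        data = ii.sample_time_series(tpm, 6, seed=0).data[:, 0]
        assert np.all(data[1:] != data[:-1])

    def test_unconstrained_tpm_gives_balanced_nodes(self):
        tpm = ii.StateByNodeTPM(np.full((4, 2), 0.5), n_nodes=2)
        data = ii.sample_time_series(tpm, 100_000, seed=1).data
        se = 0.5 / np.sqrt(100_000)
        assert np.all(np.abs(data.mean(axis=0) - 0.5) < 3 * se)

    def test_deterministic_under_fixed_seed(self):
        tpm = ii.make_recurrent_tpm(3, 1.0, seed=2)
        a = ii.sample_time_series(tpm, 500, seed=4)
        b = ii.sample_time_series(tpm, 500, seed=4)
        assert np.array_equal(a.data, b.data)


class TestPseudoLFP:
    def test_dimensions_match_config(self):
        config = SyntheticStudyConfig(
            n_subjects=2, n_channels=5, samples_per_epoch=300, seed=0
        )
        study = ii.generate_pseudo_lfp(config)
        assert len(study.epochs) == 2 * 2 * 8
        for rec in study.epochs.values():
            assert rec.data.shape == (300, 5)

    def test_default_config_mirrors_study_dimensions(self):
        config = SyntheticStudyConfig()
        assert config.n_subjects == 13
        assert config.n_epochs_per_condition == 8
        assert config.n_channels == 15
        assert config.samples_per_epoch == 2250
        assert config.sampling_rate == 1000.0
        assert config.coupling_anesthesia < config.coupling_wake

    def test_bit_identical_under_fixed_seed(self):
        config = SyntheticStudyConfig(
            n_subjects=1, n_channels=3, samples_per_epoch=100, seed=5
        )
        a = ii.generate_pseudo_lfp(config)
        b = ii.generate_pseudo_lfp(config)
        for key in a.epochs:
            assert np.array_equal(a.epochs[key].data, b.epochs[key].data)

    def test_epochs_have_independent_noise(self):
        config = SyntheticStudyConfig(
            n_subjects=1, n_channels=3, samples_per_epoch=100, seed=5
        )
        study = ii.generate_pseudo_lfp(config)
        e1 = study.recording(1, "wake", 1).data
        e2 = study.recording(1, "wake", 2).data
        assert not np.array_equal(e1, e2)

    def test_inverted_couplings_rejected(self):
        with pytest.raises(ValueError):
            SyntheticStudyConfig(coupling_wake=0.1, coupling_anesthesia=0.2)

    def test_save_load_roundtrip(self, tmp_path):
        config = SyntheticStudyConfig(
            n_subjects=1, n_channels=3, samples_per_epoch=50, seed=2
        )
        study = ii.generate_pseudo_lfp(config)
        study.save(tmp_path)
        loaded = ContinuousStudy.load(tmp_path)
        for key in study.epochs:
            assert np.allclose(
                study.epochs[key].data, loaded.epochs[key].data, atol=1e-9
            )


def test_desk_study_config_null_variant_has_equal_couplings():
    coupled = desk_study_config(seed=1)
    null = desk_study_config(seed=1, coupled=False)
    assert coupled.n_channels == 6
    assert coupled.coupling_anesthesia < coupled.coupling_wake
    assert null.coupling_anesthesia == null.coupling_wake
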