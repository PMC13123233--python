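import dataclasses

import numpy as np
import pytest

from ergflash.data_model import Adaptation, Genotype, RunConfig, read_waveforms, write_waveforms
from ergflash.errors import ConfigurationError
from ergflash.processing import isolate_ops, spectrum
from ergflash.quantify import quantify_pair
from ergflash.synth import (
    PANEL_N_ANIMALS,
    PRESETS,
    CohortSpec,
    WaveformModelParams,
    calibrate_preset,
    generate_cohort,
    generate_panel,
    waveform,
)
from tests.conftest import make_waveform


def measure_trace(trace, flash, adaptation=Adaptation.DA, config=None):
    config = config or RunConfig()
    w = make_waveform(trace, flash=flash, adaptation=adaptation)
    return quantify_pair(isolate_ops(w, config.op_split), config)


class TestWaveformModel:
    def test_zero_amplitudes_give_flat_trace(self):
        model = WaveformModelParams(a_max=0.0, b_max=0.0, op_max=0.0, la_b_max=0.0)
        tr = waveform(model, PRESETS[Genotype.WT], 0.3, Adaptation.DA)
        np.testing.assert_array_equal(tr, 0.0)

    def test_preonset_is_zero(self, model):
        tr = waveform(model, PRESETS[Genotype.WT], 0.3, Adaptation.DA)
        np.testing.assert_array_equal(tr[:33], 0.0)  # kernels start at t > 0

    def test_flash_outside_protocol_rejected(self, model):
        with pytest.raises(ConfigurationError):
            waveform(model, PRESETS[Genotype.WT], -1.0, Adaptation.DA)

    def test_weakest_flash_has_no_a_wave(self, model):
        for flash in (-3.7, -2.7):
            m = measure_trace(
                waveform(model, PRESETS[Genotype.WT], flash, Adaptation.DA), flash
            )
            assert m.a_amplitude is None
            assert "a_undetected" in m.flags

    def test_component_amplitudes_monotone_in_model(self, model):
        fracs_b = [model.nr_b.fraction(f) for f in (-3.7, -2.7, -1.7, -0.7, 0.3)]
        assert np.all(np.diff(fracs_b) > 0)
        lat_b = [model.b_peak_ms(f) for f in (-3.7, -2.7, -1.7, -0.7, 0.3)]
        assert np.all(np.diff(lat_b) < 0)

    def test_op_energy_concentrated_in_band(self, model):
        # OP component alone: ≥ 90 % of its spectral energy in 60–100 Hz
        op_only = dataclasses.replace(model, a_max=0.0, b_max=0.0)
        for flash in (-3.7, -0.7, 0.3):
            tr = waveform(op_only, PRESETS[Genotype.WT], flash, Adaptation.DA)
            sd = spectrum(make_waveform(tr, flash=flash))
            energy = sd.magnitudes ** 2
            in_band = (sd.frequencies >= 60.0) & (sd.frequencies <= 100.0)
            assert energy[in_band].sum() / energy.sum() >= 0.90

    def test_la_trace_is_pure_b(self, model):
        tr = waveform(model, PRESETS[Genotype.WT], 0.3, Adaptation.LA)
        assert tr.min() >= -1e-12  # no negative lobe
        m = measure_trace(tr, 0.3, Adaptation.LA)
        assert m.b_amplitude > 0 and m.a_amplitude is None


class TestCalibration:
    def test_wt_preset_is_identity(self, model, config):
        cal = calibrate_preset(model, PRESETS[Genotype.WT], config)
        for f in cal.da.values():
            assert f.m_a == f.m_b == f.m_op == 1.0
            assert f.d_a_ms == f.d_b_ms == 0.0
        assert cal.m_b_la == 1.0

    @pytest.mark.parametrize(
        "genotype,k_b", [(Genotype.mdx2Cv, 0.767), (Genotype.dmd_null, 0.4549)]
    )
    def test_noise_free_pooled_b_ratio(self, model, config, genotype, k_b):
        cal = calibrate_preset(model, PRESETS[genotype], config)
        ratios = []
        for flash in (-3.7, -2.7, -1.7, -0.7, 0.3):
            mut = measure_trace(
                waveform(model, PRESETS[genotype], flash, Adaptation.DA,
                         factors=cal.da[flash]), flash, config=config
            )
            wt = measure_trace(
                waveform(model, PRESETS[Genotype.WT], flash, Adaptation.DA),
                flash, config=config,
            )
            ratios.append(mut.b_amplitude / wt.b_amplitude)
        assert np.mean(ratios) == pytest.approx(k_b, abs=0.005)

    def test_noise_free_pooled_b_delay(self, model, config):
        cal = calibrate_preset(model, PRESETS[Genotype.dmd_null], config)
        delays = []
        for flash in (-3.7, -2.7, -1.7, -0.7, 0.3):
            mut = measure_trace(
                waveform(model, PRESETS[Genotype.dmd_null], flash, Adaptation.DA,
                         factors=cal.da[flash]), flash, config=config
            )
            wt = measure_trace(
                waveform(model, PRESETS[Genotype.WT], flash, Adaptation.DA),
                flash, config=config,
            )
            delays.append(mut.b_implicit_time - wt.b_implicit_time)
        assert np.mean(delays) == pytest.approx(18.87, abs=0.5)

    def test_dmd_null_electronegative_top_flash(self, model, config):
        cal = calibrate_preset(model, PRESETS[Genotype.dmd_null], config)
        m = measure_trace(
            waveform(model, PRESETS[Genotype.dmd_null], 0.3, Adaptation.DA,
                     factors=cal.da[0.3]), 0.3, config=config
        )
        assert m.a_amplitude is not None
        assert m.b_amplitude < m.a_amplitude

    def test_mutant_monotonicity_preserved(self, model, config):
        cal = calibrate_preset(model, PRESETS[Genotype.mdx2Cv], config)
        b_amps, b_its = [], []
        for flash in (-3.7, -2.7, -1.7, -0.7, 0.3):
            m = measure_trace(
                waveform(model, PRESETS[Genotype.mdx2Cv], flash, Adaptation.DA,
                         factors=cal.da[flash]), flash, config=config
            )
            b_amps.append(m.b_amplitude)
            b_its.append(m.b_implicit_time)
        assert np.all(np.diff(b_amps) > 0)
        assert np.all(np.diff(b_its) < 0)


class TestGenerateCohort:
    def test_same_seed_identical(self):
        spec = CohortSpec(genotype=Genotype.mdx, n_animals=2, rng_seed=42)
        c1 = generate_cohort(spec)
        c2 = generate_cohort(spec)
        assert len(c1) == len(c2)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.traces, b.traces)

    def test_different_seed_differs(self):
        c1 = generate_cohort(CohortSpec(genotype=Genotype.mdx, n_animals=1, rng_seed=1))
        c2 = generate_cohort(CohortSpec(genotype=Genotype.mdx, n_animals=1, rng_seed=2))
        assert not np.array_equal(c1[0].traces, c2[0].traces)

    def test_noise_free_sweeps_equal_base_waveform(self, clean_cohort, model, config):
        cal = calibrate_preset(model, PRESETS[Genotype.WT], config)
        for ss in clean_cohort:
            assert np.ptp(ss.traces, axis=0).max() == 0.0  # all sweeps identical
            if ss.condition.adaptation is Adaptation.DA:
                expected = waveform(
                    model, PRESETS[Genotype.WT], ss.condition.flash_strength,
                    Adaptation.DA, factors=cal.da[ss.condition.flash_strength],
                )
                np.testing.assert_allclose(ss.traces[0], expected, atol=1e-12)

    def test_paper_scale_structure(self):
        spec = CohortSpec(genotype=Genotype.mdx, n_animals=17, noise_sd=0.0,
                          animal_effect_cv=0.0, eye_effect_cv=0.0, rng_seed=0)
        cohort = generate_cohort(spec)
        eyes = {(ss.animal_id, ss.eye_id) for ss in cohort}
        assert len(eyes) == 34
        assert len(cohort) == 34 * 6

    def test_sweep_counts_follow_protocol(self, small_cohort):
        expected = {-3.7: 12, -2.7: 10, -1.7: 8, -0.7: 8}
        for ss in small_cohort:
            if ss.condition.adaptation is Adaptation.DA:
                exp = expected.get(ss.condition.flash_strength, 4)
            else:
                exp = 24
            assert ss.n_sweeps == exp


@pytest.fixture(scope="module")
def tiny_panel():
    return generate_panel(seed=5, noise_sd=0.0, animal_effect_cv=0.0,
                          eye_effect_cv=0.0)


class TestGeneratePanel:
    def test_ten_cohorts(self, tiny_panel):
        assert len(tiny_panel) == 5
        for mut, wt in tiny_panel.values():
            assert mut and wt

    def test_dmd_null_group_sizes(self, tiny_panel):
        mut, wt = tiny_panel[Genotype.dmd_null]
        assert len({ss.animal_id for ss in mut}) == 14
        assert len({ss.animal_id for ss in wt}) == 12
        assert len({(ss.animal_id, ss.eye_id) for ss in mut}) == 28
        assert len({(ss.animal_id, ss.eye_id) for ss in wt}) == 24
        assert PANEL_N_ANIMALS[Genotype.dmd_null] == (14, 12)

    def test_file_round_trip(self, tmp_path, tiny_panel):
        mut, _ = tiny_panel[Genotype.mdx]
        subset = mut[:12]  # two eyes' worth
        path = tmp_path / "panel.csv"
        write_waveforms(subset, path)
        back = read_waveforms(path)
        assert len(back) == len(subset)
        key = lambda s: (s.animal_id, s.eye_id, s.condition.adaptation.value,
                         s.condition.flash_strength)
        for orig, rt in zip(sorted(subset, key=key), sorted(back, key=key)):
            np.testing.assert_array_equal(orig.traces, rt.traces)
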