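import numpy as np
import pandas as pd
import pytest

from ergflash.data_model import (
    Adaptation,
    ComponentMeasures,
    Genotype,
    RunConfig,
    StimulusCondition,
    SweepSet,
    measures_to_frame,
    read_measures,
    read_waveforms,
    write_measures,
    write_waveforms,
)
from ergflash.errors import ConfigurationError, FormatError, IntegrityError


class TestStimulusCondition:
    @pytest.mark.parametrize(
        "flash,n_sweeps,isi",
        [(-3.7, 12, 1.0), (-2.7, 10, 2.0), (-1.7, 8, 5.0), (-0.7, 8, 10.0), (0.3, 4, 20.0)],
    )
    def test_da_protocol_table(self, flash, n_sweeps, isi):
        cond = StimulusCondition.da(flash)
        assert cond.n_sweeps_nominal == n_sweeps
        assert cond.isi_s == isi
        assert cond.background_luminance == 0.0

    def test_la_protocol(self):
        cond = StimulusCondition.la()
        assert cond.n_sweeps_nominal == 24
        assert cond.isi_s == 1.0
        assert cond.background_luminance == 25.0

    def test_off_protocol_flash_rejected(self):
        with pytest.raises(ConfigurationError):
            StimulusCondition.da(-1.0)

    def test_wrong_sweep_count_rejected(self):
        with pytest.raises(ConfigurationError):
            StimulusCondition(Adaptation.DA, -3.7, 0.0, 99, 1.0)


class TestSweepSet:
    def _make(self, **kw):
        defaults = dict(
            eye_id="L", animal_id="a0", genotype=Genotype.WT,
            condition=StimulusCondition.da(0.3),
            traces=np.zeros((4, 128)), onset_index=32,
        )
        defaults.update(kw)
        return SweepSet(**defaults)

    def test_valid(self):
        ss = self._make()
        assert ss.n_sweeps == 4 and ss.n_samples == 128

    def test_wrong_sample_count(self):
        with pytest.raises(IntegrityError):
            self._make(traces=np.zeros((4, 100)))

    def test_onset_needs_16ms_preonset(self):
        # ceil(0.016 × 512) = 9 samples minimum
        with pytest.raises(ConfigurationError):
            self._make(onset_index=8)
        self._make(onset_index=9)

    def test_onset_out_of_record(self):
        with pytest.raises(ConfigurationError):
            self._make(onset_index=200)


class TestWaveformIO:
    def _table(self, n_eyes=2, flashes=(-3.7, -2.7, -1.7, -0.7, 0.3), n_sweeps=2,
               n_samples=128):
        rows = []
        for e in range(n_eyes):
            for flash in flashes:
                for s in range(n_sweeps):
                    rows.append(
                        pd.DataFrame({
                            "animal_id": f"a{e}",
                            "eye_id": "L",
                            "genotype": "WT",
                            "adaptation": "DA",
                            "flash_strength": flash,
                            "sweep": s,
                            "sample_index": np.arange(n_samples),
                            "voltage_uv": np.random.default_rng(s).normal(size=n_samples),
                            "onset_index": 32,
                            "sampling_rate": 512.0,
                        })
                    )
        return pd.concat(rows, ignore_index=True)

    def test_two_eyes_five_conditions(self, tmp_path):
        path = tmp_path / "w.csv"
        self._table().to_csv(path, index=False)
        sets = read_waveforms(path)
        assert len(sets) == 10

    def test_sweep_count_preserved(self, tmp_path):
        path = tmp_path / "w.csv"
        self._table(n_eyes=1, flashes=(-3.7,), n_sweeps=12).to_csv(path, index=False)
        (ss,) = read_waveforms(path)
        assert ss.n_sweeps == 12
        assert ss.condition.n_sweeps_nominal == 12

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "w.csv"
        self._table().drop(columns=["voltage_uv"]).to_csv(path, index=False)
        with pytest.raises(FormatError, match="voltage_uv"):
            read_waveforms(path)

    def test_unknown_genotype_rejected(self, tmp_path):
        df = self._table()
        df.loc[0, "genotype"] = "mdx99"
        path = tmp_path / "w.csv"
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match="mdx99"):
            read_waveforms(path)

    def test_ragged_sweeps_rejected(self, tmp_path):
        df = self._table(n_eyes=1, flashes=(0.3,))
        df = df.drop(df[(df["sweep"] == 1) & (df["sample_index"] > 100)].index)
        path = tmp_path / "w.csv"
        df.to_csv(path, index=False)
        with pytest.raises(IntegrityError):
            read_waveforms(path)

    def test_onset_not_inferable(self, tmp_path):
        path = tmp_path / "w.csv"
        self._table().drop(columns=["onset_index"]).to_csv(path, index=False)
        with pytest.raises(ConfigurationError):
            read_waveforms(path)

    def test_round_trip_bit_exact(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_waveforms(small_cohort, path)
        back = read_waveforms(path)
        assert len(back) == len(small_cohort)
        key = lambda s: (s.animal_id, s.eye_id, s.condition.adaptation.value,
                         s.condition.flash_strength)
        for orig, rt in zip(sorted(small_cohort, key=key), sorted(back, key=key)):
            assert orig.genotype == rt.genotype
            assert orig.onset_index == rt.onset_index
            np.testing.assert_array_equal(orig.traces, rt.traces)


class TestMeasuresIO:
    def _measures(self):
        return [
            ComponentMeasures(
                eye_id="L", animal_id="a0", genotype=Genotype.WT,
                adaptation=Adaptation.DA, flash_strength=-3.7, baseline=0.2,
                b_amplitude=50.0, b_implicit_time=85.0,
                op_spectral_amplitude=2.5, flags=frozenset({"a_undetected"}),
            ),
            ComponentMeasures(
                eye_id="L", animal_id="a0", genotype=Genotype.WT,
                adaptation=Adaptation.DA, flash_strength=0.3, baseline=-0.1,
                a_amplitude=150.0, a_implicit_time=16.0,
                b_amplitude=300.0, b_implicit_time=50.0,
                op_spectral_amplitude=10.0,
            ),
        ]

    def test_absent_a_wave_is_empty_cell(self, tmp_path):
        path = tmp_path / "m.csv"
        write_measures(self._measures(), path)
        lines = path.read_text().splitlines()
        weak = lines[1].split(",")
        header = lines[0].split(",")
        assert weak[header.index("a_amp_uv")] == ""
        assert weak[header.index("b_amp_uv")] != ""

    def test_single_measure_single_row(self, tmp_path):
        path = tmp_path / "m.csv"
        write_measures(self._measures()[:1], path)
        assert len(path.read_text().splitlines()) == 2

    def test_write_read_write_identical_bytes(self, tmp_path):
        p1, p2 = tmp_path / "m1.csv", tmp_path / "m2.csv"
        write_measures(self._measures(), p1)
        df = read_measures(p1)
        df.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_collection_rejected(self, tmp_path):
        with pytest.raises(IntegrityError):
            write_measures([], tmp_path / "m.csv")

    def test_row_ordering_deterministic(self):
        ms = self._measures()
        df1 = measures_to_frame(ms)
        df2 = measures_to_frame(list(reversed(ms)))
        pd.testing.assert_frame_equal(df1, df2)


class TestComponentMeasuresInvariants:
    def test_a_implicit_time_bounds(self):
        with pytest.raises(IntegrityError):
            ComponentMeasures(
                eye_id="L", animal_id="a", genotype=Genotype.WT,
                adaptation=Adaptation.DA, flash_strength=0.3, baseline=0.0,
                a_amplitude=10.0, a_implicit_time=60.0,
                b_amplitude=20.0, b_implicit_time=80.0,
            )

    def test_b_after_a(self):
        with pytest.raises(IntegrityError):
            ComponentMeasures(
                eye_id="L", animal_id="a", genotype=Genotype.WT,
                adaptation=Adaptation.DA, flash_strength=0.3, baseline=0.0,
                a_amplitude=10.0, a_implicit_time=20.0,
                b_amplitude=20.0, b_implicit_time=15.0,
            )

    def test_negative_amplitude_rejected(self):
        with pytest.raises(IntegrityError):
            ComponentMeasures(
                eye_id="L", animal_id="a", genotype=Genotype.WT,
                adaptation=Adaptation.DA, flash_strength=0.3, baseline=0.0,
                b_amplitude=-1.0, b_implicit_time=50.0,
            )


class TestRunConfig:
    def test_defaults_valid(self):
        cfg = RunConfig()
        assert cfg.baseline_window_ms == 16.0
        assert cfg.a_search_ms == 50.0
        assert cfg.op_band_hz == (60.0, 100.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            RunConfig(op_band_hz=(60.0, 300.0))

    @pytest.mark.parametrize("suffix", ["yaml", "json"])
    def test_file_round_trip(self, tmp_path, suffix):
        cfg = RunConfig(a_search_ms=40.0, analysis_unit="animal")
        path = tmp_path / f"cfg.{suffix}"
        cfg.to_file(path)
        assert RunConfig.from_file(path) == cfg

    def test_bad_analysis_unit(self):
        with pytest.raises(ConfigurationError):
            RunConfig(analysis_unit="retina")
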