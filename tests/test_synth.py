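"""Synthetic cohort generator: protocol structure, mixing, determinism."""

import numpy as np
import pytest

from iemg.impedance import OPEN, is_open
from iemg.io import REST_LABEL, write_recording
from iemg.synth import (CROSSTALK_MASS, ImpedanceScene, MixingModel, Movement,
                        ProtocolSpec, crosstalk_mixing, generate_cohort,
                        generate_impedance_measurements, generate_recording,
                        load_templates, make_crosstalk_scene,
                        one_hot_activation, template_mixing, template_protocol)


class TestGenerateRecording:
    def test_annotation_counts_and_interleaving(self, small_protocol,
                                                small_mixing):
        rec = generate_recording(small_protocol, small_mixing, seed=0)
        contractions = [a for a in rec.annotations if a.label != REST_LABEL]
        rests = [a for a in rec.annotations if a.label == REST_LABEL]
        assert len(contractions) == 3 * 2          # movements x repetitions
        assert len(rests) == len(contractions) + 1  # leading rest + one after each
        # strict alternation rest / contraction
        labels = [a.label == REST_LABEL for a in rec.annotations]
        assert labels == [True, False] * len(contractions) + [True]

    def test_zero_noise_identity_mixing_isolates_sources(self, small_protocol):
        mixing = MixingModel(
            mixing_matrix=np.eye(3),
            activation_map=one_hot_activation(small_protocol.movements, 3),
            noise_rms=0.0)
        rec = generate_recording(small_protocol, mixing, seed=1)
        fs = rec.sampling_rate_hz
        for ann in rec.annotations:
            if ann.label == REST_LABEL:
                continue
            k = [m.label for m in small_protocol.movements].index(ann.label)
            lo, hi = ann.sample_range(fs)
            for j in range(3):
                if j != k:
                    assert np.all(rec.samples[j, lo:hi] == 0.0)

    def test_identical_seed_bit_identical(self, small_protocol, small_mixing):
        a = generate_recording(small_protocol, small_mixing, seed=5)
        b = generate_recording(small_protocol, small_mixing, seed=5)
        assert np.array_equal(a.samples, b.samples)
        c = generate_recording(small_protocol, small_mixing, seed=6)
        assert not np.array_equal(a.samples, c.samples)

    def test_dimension_mismatch_rejected(self, small_protocol):
        mixing = MixingModel(
            mixing_matrix=crosstalk_mixing(2, 0.1),
            activation_map=one_hot_activation(["only_one"], 2))
        with pytest.raises(ValueError, match="activation map lacks"):
            generate_recording(small_protocol, mixing, seed=0)

    def test_nonpositive_durations_rejected(self, small_protocol):
        with pytest.raises(ValueError, match="positive"):
            ProtocolSpec(movements=small_protocol.movements,
                         contraction_duration_s=0.0)


class TestImpedanceForwardModel:
    def test_ohms_law_voltage(self):
        scene = ImpedanceScene(direct_ohm={"E1": 1000.0}, cross_ohm={})
        ms = generate_impedance_measurements(scene, noise_rel=0.0, seed=0)
        at_1k = [m for m in ms if m.frequency_hz == 1000.0]
        assert at_1k[0].voltage_amp_V == pytest.approx(38.4e-6)
        at_500 = [m for m in ms if m.frequency_hz == 500.0]
        assert at_500[0].current_amp_A == pytest.approx(19.2e-9)

    def test_open_entries_set_flag(self):
        scene = ImpedanceScene(direct_ohm={"E1": 100.0, "E2": 100.0},
                               cross_ohm={("E1", "E2"): OPEN})
        ms = generate_impedance_measurements(scene, 0.0, 0)
        opens = [m for m in ms if m.open_flag]
        assert len(opens) == 2 and all(m.pair == ("E1", "E2") for m in opens)

    def test_pair_count_per_frequency(self):
        n = 5
        ids = [f"E{i}" for i in range(n)]
        scene = ImpedanceScene(
            direct_ohm={e: 100.0 for e in ids},
            cross_ohm={(a, b): 1e4 for i, a in enumerate(ids)
                       for b in ids[i + 1:]})
        ms = generate_impedance_measurements(scene, 0.0, 0)
        per_freq = len(ms) / len(scene.frequencies_hz)
        assert per_freq == n * (n - 1) / 2 + n

    def test_empty_scene_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            generate_impedance_measurements(
                ImpedanceScene(direct_ohm={}, cross_ohm={}), 0.0, 0)

    def test_crosstalk_scene_ratio_tracks_mixing_mass(self):
        ids = ["A", "B", "C"]
        hi = make_crosstalk_scene(ids, 0.2)
        lo = make_crosstalk_scene(ids, 0.6)
        assert hi.cross_ohm[("A", "B")] > lo.cross_ohm[("A", "B")]
        sealed = make_crosstalk_scene(ids, 0.0)
        assert is_open(sealed.cross_ohm[("A", "B")])


class TestCohortTemplates:
    def test_tr1_layout(self):
        cohort = generate_cohort("TR1-like", seed=0, repetitions=2,
                                 contraction_s=0.5, rest_s=0.3)
        entry = cohort["TR1-like"]
        etypes = [e.etype for e in entry.electrode_map]
        assert etypes.count("epimysial") == 4
        assert etypes.count("intramuscular") == 8
        assert entry.recording.sampling_rate_hz == 500

    def test_tr2_layout_is_intramuscular_only(self):
        cohort = generate_cohort("TR2-like", seed=0, repetitions=2,
                                 contraction_s=0.5, rest_s=0.3)
        etypes = {e.etype for e in cohort["TR2-like"].electrode_map}
        assert etypes == {"intramuscular"}
        assert len(cohort["TR2-like"].electrode_map) == 12

    def test_unknown_template_rejected(self):
        with pytest.raises(KeyError, match="unknown cohort template"):
            generate_cohort("TH9-like", seed=0)

    def test_intramuscular_rows_more_diagonally_dominant(self):
        templates = load_templates()
        template = templates["TR1-like"]
        protocol = template_protocol(template, repetitions=1,
                                     contraction_s=0.5, rest_s=0.3)
        mixing = template_mixing(template, protocol)
        m = mixing.mixing_matrix
        for i, e in enumerate(template["electrodes"]):
            offdiag = m[i].sum() - m[i, i]
            assert offdiag == pytest.approx(CROSSTALK_MASS[e["etype"]])
        assert CROSSTALK_MASS["intramuscular"] < CROSSTALK_MASS["epimysial"]

    def test_cohort_serialization_is_deterministic(self, tmp_path):
        kw = dict(seed=9, repetitions=2, contraction_s=0.5, rest_s=0.3)
        a = generate_cohort("TR2-like", **kw)["TR2-like"]
        b = generate_cohort("TR2-like", **kw)["TR2-like"]
        pa = write_recording(a.recording, tmp_path / "a")
        pb = write_recording(b.recording, tmp_path / "b")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert pa.read_text().replace('"a.csv"', '"b.csv"') == pb.read_text()
        assert a.measurements == b.measurements
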