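"""Generator contracts: morphology, seed scoping, determinism, and the
class-effect separability dial."""

import numpy as np
import pytest

from minet.records import CLASSES, LEADS, LSB_UV
from minet.synthetic import (
    BeatTemplate,
    ClassEffect,
    CohortSpec,
    DEFAULT_WAVES,
    DEFAULT_LEAD_SCALE,
    cohort_manifest,
    default_class_effects,
    generate_record,
    patient_template,
    render_beat,
    table1_cohort_spec,
    tiny_cohort_spec,
)


def frozen_spec(**overrides):
    """Spec with every random influence switched off except what a test enables."""
    base = dict(noise_sd_uv=0.0, wander_amp_uv=0.0, riv_sd=0.0, aiv_sd=0.0, hr_sd_bpm=0.0)
    base.update(overrides)
    return tiny_cohort_spec(seed=0, **base)


class TestTemplateInvariants:
    def test_default_template_is_valid(self):
        BeatTemplate(DEFAULT_WAVES, DEFAULT_LEAD_SCALE, np.zeros(12))

    def test_unordered_centers_rejected(self):
        waves = dict(DEFAULT_WAVES)
        waves["Q"] = (waves["Q"][0], 0.1, waves["Q"][2])  # Q after R
        with pytest.raises(ValueError, match="ordered"):
            BeatTemplate(waves, DEFAULT_LEAD_SCALE, np.zeros(12))

    def test_nonpositive_width_rejected(self):
        waves = dict(DEFAULT_WAVES)
        waves["T"] = (waves["T"][0], waves["T"][1], 0.0)
        with pytest.raises(ValueError, match="width"):
            BeatTemplate(waves, DEFAULT_LEAD_SCALE, np.zeros(12))

    def test_hc_effect_must_be_empty(self):
        with pytest.raises(ValueError, match="HC"):
            ClassEffect("HC", ("II",), st_shift=10.0)

    def test_mi_effect_needs_leads(self):
        with pytest.raises(ValueError, match="lead set"):
            ClassEffect("IMI", ())

    def test_aiv_smaller_than_riv_by_default(self):
        spec = tiny_cohort_spec()
        assert 0 <= spec.aiv_sd < spec.riv_sd


class TestGenerateRecord:
    def test_noiseless_record_is_periodic(self):
        """Without noise, wander or beat jitter, every interior beat is an
        exact copy of the patient template beat."""
        spec = frozen_spec(hr_mean_bpm=60.0)  # integer-millisecond RR
        rec = generate_record("HC", 7, 1, spec)
        r = rec.r_peaks
        rr = np.diff(r)
        assert np.all(rr == rr[0])
        w = 300
        windows = [rec.signals[:, p - w : p + w] for p in r[2:-2]]
        for win in windows[1:]:
            np.testing.assert_array_equal(win, windows[0])

    def test_st_shift_matches_configured_value(self):
        """The IMI-vs-HC difference of the mean signal on the ST interval in
        the affected leads equals the configured shift, recomputed from the
        generator's own template parameters."""
        shift = 150.0
        effects = default_class_effects(0.0)
        effects["IMI"] = ClassEffect("IMI", ("II", "III", "aVF"), st_shift=shift)
        spec = frozen_spec(effects=effects)
        rec_mi = generate_record("IMI", 7, 1, spec)
        rec_hc = generate_record("HC", 7, 1, spec)
        template, _, _, _ = patient_template("HC", 7, spec)
        lo_s, hi_s = template.st_interval
        fs = spec.fs
        for r in rec_mi.r_peaks[2:-2]:
            sl = slice(r + int(lo_s * fs), r + int(hi_s * fs) + 1)
            for lead in ("II", "III", "aVF"):
                i = LEADS.index(lead)
                diff = rec_mi.signals[i, sl].mean() - rec_hc.signals[i, sl].mean()
                assert diff == pytest.approx(shift, abs=2 * LSB_UV)
        # unaffected lead: no shift
        i = LEADS.index("V2")
        r = rec_mi.r_peaks[3]
        sl = slice(r + int(lo_s * fs), r + int(hi_s * fs) + 1)
        assert rec_mi.signals[i, sl].mean() - rec_hc.signals[i, sl].mean() == pytest.approx(
            0.0, abs=2 * LSB_UV
        )

    def test_seed_scoping_patient_vs_beat(self, tiny_spec):
        a = generate_record("AMI", 21, 1, tiny_spec)
        b = generate_record("AMI", 21, 2, tiny_spec)
        ta = patient_template("AMI", 21, tiny_spec)
        tb = patient_template("AMI", 21, tiny_spec)
        assert ta[0].wave_params == tb[0].wave_params
        assert not np.array_equal(a.signals, b.signals)

    def test_bit_exact_reproducibility(self, tiny_spec):
        a = generate_record("ILMI", 4, 9, tiny_spec)
        b = generate_record("ILMI", 4, 9, tiny_spec)
        np.testing.assert_array_equal(a.signals, b.signals)
        np.testing.assert_array_equal(a.r_peaks, b.r_peaks)

    def test_r_annotation_marks_absolute_maximum(self):
        """Annotated R indices sit at the |amplitude| maximum of the
        noiseless beat to within 2 ms."""
        spec = frozen_spec()
        rec = generate_record("HC", 3, 1, spec)
        lead = rec.signals[LEADS.index("II")]
        for r in rec.r_peaks[1:-1]:
            win = lead[r - 100 : r + 100]
            assert abs(int(np.argmax(np.abs(win))) - 100) <= 2

    def test_unknown_class_rejected(self, tiny_spec):
        with pytest.raises(ValueError, match="XMI"):
            generate_record("XMI", 0, 0, tiny_spec)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_record("HC", 0, 0, tiny_cohort_spec(duration_s=10.0))

    def test_signals_quantized_and_in_range(self, hc_record):
        assert np.all(np.abs(hc_record.signals) <= 16384.0)
        np.testing.assert_array_equal(
            hc_record.signals, np.round(hc_record.signals / LSB_UV) * LSB_UV
        )


class TestClassEffects:
    def test_zero_scale_removes_class_differences(self):
        """With all effects dialled to zero, per-class mean template beats
        coincide up to patient-sampling Monte-Carlo error."""
        spec = tiny_cohort_spec(seed=0, effect_scale=0.0)
        means = {}
        for label in ("HC", "IMI", "AMI"):
            beats = []
            for ps in range(40):
                template, effect, inverted, _ = patient_template(label, 1000 + ps, spec)
                beat, _ = render_beat(template, effect, inverted, spec.fs)
                beats.append(beat[:, :700])
            means[label] = np.mean([b for b in beats], axis=0)
        # patient draws are identical across labels at equal seeds, so the
        # zero-effect means must agree exactly
        np.testing.assert_allclose(means["IMI"], means["HC"], atol=1e-9)
        np.testing.assert_allclose(means["AMI"], means["HC"], atol=1e-9)

    def test_st_distance_monotone_in_shift(self):
        """Raising st_shift strictly widens the HC-vs-IMI separation of mean
        ST-interval level in the affected leads."""
        distances = []
        for shift in (50.0, 150.0, 300.0):
            effects = default_class_effects(0.0)
            effects["IMI"] = ClassEffect("IMI", ("II", "III", "aVF"), st_shift=shift)
            spec = frozen_spec(effects=effects, noise_sd_uv=10.0)
            rec_mi = generate_record("IMI", 7, 1, spec)
            rec_hc = generate_record("HC", 7, 1, spec)
            template, _, _, _ = patient_template("HC", 7, spec)
            lo_s, hi_s = template.st_interval
            i = LEADS.index("II")
            vals = []
            for rec in (rec_mi, rec_hc):
                per_beat = [
                    rec.signals[i, r + int(lo_s * 1000) : r + int(hi_s * 1000)].mean()
                    for r in rec.r_peaks[2:-2]
                ]
                vals.append(np.mean(per_beat))
            distances.append(vals[0] - vals[1])
        assert distances[0] < distances[1] < distances[2]

    def test_t_inversion_flips_t_wave(self):
        effects = default_class_effects(0.0)
        effects["IMI"] = ClassEffect("IMI", ("II",), t_inversion_prob=1.0)
        spec = frozen_spec(effects=effects)
        template, effect, inverted, _ = patient_template("IMI", 5, spec)
        assert inverted[LEADS.index("II")]
        assert not inverted[LEADS.index("V1")]


class TestCohort:
    def test_cohort_arithmetic(self):
        spec = CohortSpec(class_counts={c: (10, 40) for c in CLASSES}, seed=1)
        manifest = cohort_manifest(spec)
        assert len(manifest) == 240
        assert manifest["patient_id"].nunique() == 60

    def test_table1_multiplicities(self):
        manifest = cohort_manifest(table1_cohort_spec(seed=2))
        assert len(manifest) == 240
        assert manifest["patient_id"].nunique() == 96
        hc = manifest[manifest["class"] == "HC"]
        assert len(hc) == 40
        assert hc["patient_id"].nunique() == 25

    def test_manifest_deterministic(self):
        a = cohort_manifest(table1_cohort_spec(seed=3))
        b = cohort_manifest(table1_cohort_spec(seed=3))
        assert a.equals(b)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="records >= subjects"):
            CohortSpec(class_counts={"HC": (5, 3)})
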