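"""Synthetic PTB-like 12-lead ECG cohorts with class-conditioned MI morphology.

The beat model is a minimal sum-of-Gaussians PQRST template projected through
a fixed 12-lead scaling vector.  Each of the five MI localization classes
perturbs a conventional ECG territory lead set along the three classic
abnormality axes: ST-segment displacement, pathological (amplified) Q waves,
and T-wave inversion.  Two seeded jitter levels reproduce the two variability
scales of real ECG: patient-level template jitter (inter-individual, RIV) and
beat-level jitter (intra-individual, AIV), with AIV smaller than RIV by
default.  Baseline wander and white measurement noise are added on top, and
the output is quantized to the 16-bit, 0.5 uV/LSB storage convention.

Seed scoping: ``patient_seed`` drives every patient-level draw (template
jitter, heart rate, T-inversion flags); ``beat_seed`` drives per-beat
amplitude/RR jitter, wander phase and noise.  A record is a pure function of
(class, patient_seed, beat_seed, cohort spec).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import CLASSES, LEADS, LEAD_INDEX, MI_CLASSES, EcgRecord, quantize

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: (amplitude uV, center s relative to R, width s) for each PQRST wave.
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (120.0, -0.200, 0.025),
    "Q": (-100.0, -0.045, 0.010),
    "R": (1100.0, 0.000, 0.012),
    "S": (-250.0, 0.040, 0.012),
    "T": (300.0, 0.300, 0.060),
}

#: Dimensionless per-lead projection of the base waveform, ordered as LEADS.
#: Signs and magnitudes follow the usual frontal/precordial progression
#: (aVR inverted, V1 mostly negative, R-wave growth toward V4).
DEFAULT_LEAD_SCALE = np.array(
    [0.60, 1.00, 0.50, -0.75, 0.35, 0.80, -0.45, 0.60, 0.85, 1.15, 1.00, 0.85]
)

#: Number of width multiples that bound a wave: the ST plateau runs from
#: S center + 2*width(S) to T center - 2*width(T).
ST_EDGE_SIGMA = 2.0
#: Cosine ramp length (s) attaching the ST plateau to the baseline.
ST_RAMP_S = 0.020


@dataclass
class BeatTemplate:
    """Patient-level PQRST beat template.

    ``wave_params`` maps each wave to an (amplitude uV, center s, width s)
    triple; ``lead_scale`` projects the scalar waveform onto the 12 leads;
    ``st_offset_per_lead`` is a uV offset added uniformly between S-wave end
    and T-wave onset.
    """

    wave_params: dict[str, tuple[float, float, float]]
    lead_scale: np.ndarray
    st_offset_per_lead: np.ndarray

    def __post_init__(self) -> None:
        self.lead_scale = np.asarray(self.lead_scale, dtype=float)
        self.st_offset_per_lead = np.asarray(self.st_offset_per_lead, dtype=float)
        if set(self.wave_params) != set(WAVE_NAMES):
            raise ValueError(f"wave_params must define exactly {WAVE_NAMES}")
        centers = [self.wave_params[w][1] for w in WAVE_NAMES]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError(f"wave centers must be strictly ordered P<Q<R<S<T; got {centers}")
        if any(self.wave_params[w][2] <= 0 for w in WAVE_NAMES):
            raise ValueError("wave widths must be positive")
        r_amp = self.wave_params["R"][0] * self.lead_scale
        limb, precordial = r_amp[:6], r_amp[6:]
        if not (np.any(limb > 0) and np.any(precordial > 0)):
            raise ValueError("R amplitude must be positive in a limb and a precordial lead")

    @property
    def st_interval(self) -> tuple[float, float]:
        """(S-wave end, T-wave onset) in seconds relative to the R peak."""
        s_amp, s_c, s_w = self.wave_params["S"]
        t_amp, t_c, t_w = self.wave_params["T"]
        return (s_c + ST_EDGE_SIGMA * s_w, t_c - ST_EDGE_SIGMA * t_w)


@dataclass(frozen=True)
class ClassEffect:
    """Lead-group-specific morphology perturbation for one diagnostic class."""

    label: str
    leads: tuple[str, ...]
    st_shift: float = 0.0          # uV added on the ST interval
    q_amplification: float = 1.0   # multiplier on Q amplitude, >= 1
    t_inversion_prob: float = 0.0  # per-lead probability of T-wave inversion

    def __post_init__(self) -> None:
        unknown = set(self.leads) - set(LEADS)
        if unknown:
            raise ValueError(f"unknown leads in effect: {sorted(unknown)}")
        if self.label == "HC":
            if self.leads or self.st_shift or self.q_amplification != 1.0 or self.t_inversion_prob:
                raise ValueError("HC effect must be empty")
        elif not self.leads:
            raise ValueError(f"MI class {self.label} needs a non-empty lead set")
        if self.q_amplification < 1.0:
            raise ValueError("q_amplification must be >= 1")
        if not 0.0 <= self.t_inversion_prob <= 1.0:
            raise ValueError("t_inversion_prob must be in [0, 1]")

    @property
    def lead_mask(self) -> np.ndarray:
        mask = np.zeros(len(LEADS), dtype=bool)
        for name in self.leads:
            mask[LEAD_INDEX[name]] = True
        return mask


#: Conventional ECG territory lead sets for the five MI locations.
TERRITORY_LEADS: dict[str, tuple[str, ...]] = {
    "ALMI": ("I", "aVL", "V5", "V6"),
    "AMI": ("V1", "V2", "V3", "V4"),
    "ASMI": ("V1", "V2", "V3"),
    "ILMI": ("II", "III", "aVF", "V5", "V6"),
    "IMI": ("II", "III", "aVF"),
}

DEFAULT_ST_SHIFT_UV = 200.0
DEFAULT_Q_AMPLIFICATION = 3.0
DEFAULT_T_INVERSION_PROB = 0.5


def default_class_effects(effect_scale: float = 1.0) -> dict[str, ClassEffect]:
    """Default per-class effects; ``effect_scale`` is a separability dial.

    At scale 0 every class-conditional perturbation vanishes (classes become
    statistically identical); at scale 1 the defaults apply.
    """
    effects = {"HC": ClassEffect("HC", ())}
    for label in MI_CLASSES:
        effects[label] = ClassEffect(
            label,
            TERRITORY_LEADS[label],
            st_shift=DEFAULT_ST_SHIFT_UV * effect_scale,
            q_amplification=1.0 + (DEFAULT_Q_AMPLIFICATION - 1.0) * effect_scale,
            t_inversion_prob=DEFAULT_T_INVERSION_PROB * effect_scale,
        )
    return effects


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``class_counts`` maps a class label to (number of subjects, total number
    of records); records are distributed round-robin so subject multiplicity
    can be uneven, as in the real database.
    """

    class_counts: dict[str, tuple[int, int]]
    duration_s: float = 40.0
    hr_mean_bpm: float = 70.0
    hr_sd_bpm: float = 5.0
    riv_sd: float = 0.10
    aiv_sd: float = 0.03
    wander_amp_uv: float = 100.0
    wander_band_hz: tuple[float, float] = (0.15, 0.45)
    noise_sd_uv: float = 25.0
    fs: float = 1000.0
    seed: int = 0
    effects: dict[str, ClassEffect] = field(default_factory=default_class_effects)

    def __post_init__(self) -> None:
        for label, (n_subj, n_rec) in self.class_counts.items():
            if label not in self.effects:
                raise ValueError(f"unknown class label {label!r}")
            if n_subj < 1 or n_rec < n_subj:
                raise ValueError(
                    f"{label}: need subjects >= 1 and records >= subjects, got {n_subj}/{n_rec}"
                )
        for name in ("riv_sd", "aiv_sd", "wander_amp_uv", "noise_sd_uv", "hr_sd_bpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def min_plausible_hr(self) -> float:
        return max(40.0, self.hr_mean_bpm - 3.0 * self.hr_sd_bpm)

    @property
    def n_records(self) -> int:
        return sum(n for _, n in self.class_counts.values())

    @property
    def n_subjects(self) -> int:
        return sum(s for s, _ in self.class_counts.values())


def table1_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Full-scale cohort with the study's subject/record multiplicities:
    96 subjects, 40 records per class, 240 records in total."""
    counts = {
        "HC": (25, 40),
        "ALMI": (14, 40),
        "AMI": (14, 40),
        "ASMI": (13, 40),
        "ILMI": (16, 40),
        "IMI": (14, 40),
    }
    return CohortSpec(class_counts=counts, seed=seed, **overrides)


def tiny_cohort_spec(seed: int = 0, effect_scale: float = 1.0, **overrides) -> CohortSpec:
    """Reduced smoke-scale cohort: 8 subjects and 12 records per class.

    Small enough for minute-scale end-to-end runs, but with enough patients
    per class that subject-disjoint folds remain meaningful."""
    counts = {label: (8, 12) for label in CLASSES}
    overrides.setdefault("effects", default_class_effects(effect_scale))
    return CohortSpec(class_counts=counts, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# patient-level template construction


def _seed_int(*entropy: int) -> int:
    """Derive a sub-2^31 integer seed from an entropy tuple."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] & 0x7FFFFFFF)


def patient_template(
    class_label: str, patient_seed: int, spec: CohortSpec
) -> tuple[BeatTemplate, ClassEffect, np.ndarray, float]:
    """Draw the patient-level state: jittered template, class effect,
    T-inversion flags per lead, and heart rate (bpm)."""
    if class_label not in spec.effects:
        raise ValueError(f"unknown class label {class_label!r}")
    effect = spec.effects[class_label]
    rng = np.random.default_rng(np.random.SeedSequence([int(patient_seed)]))

    hr = float(np.clip(rng.normal(spec.hr_mean_bpm, spec.hr_sd_bpm), 45.0, 150.0))

    waves: dict[str, tuple[float, float, float]] = {}
    for name in WAVE_NAMES:
        amp, center, width = DEFAULT_WAVES[name]
        amp *= 1.0 + rng.normal(0.0, spec.riv_sd)
        width *= float(np.clip(1.0 + rng.normal(0.0, spec.riv_sd), 0.3, 2.0))
        if name != "R":  # R anchors the time origin
            center *= float(np.clip(1.0 + rng.normal(0.0, spec.riv_sd / 2.0), 0.5, 1.5))
        waves[name] = (amp, center, width)

    lead_scale = DEFAULT_LEAD_SCALE * (1.0 + rng.normal(0.0, spec.riv_sd / 2.0, len(LEADS)))
    st_offset = np.where(effect.lead_mask, effect.st_shift, 0.0)
    template = BeatTemplate(waves, lead_scale, st_offset)

    inverted = effect.lead_mask & (rng.random(len(LEADS)) < effect.t_inversion_prob)
    return template, effect, inverted, hr


def _lead_wave_amplitudes(
    template: BeatTemplate, effect: ClassEffect, inverted: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-lead amplitude vector for each wave, with Q amplification and
    T inversion applied on the affected leads."""
    amps: dict[str, np.ndarray] = {}
    mask = effect.lead_mask
    for name in WAVE_NAMES:
        vec = template.wave_params[name][0] * template.lead_scale
        if name == "Q":
            vec = np.where(mask, vec * effect.q_amplification, vec)
        elif name == "T":
            vec = np.where(inverted, -vec, vec)
        amps[name] = vec
    return amps


def _st_course(t: np.ndarray, template: BeatTemplate) -> np.ndarray:
    """Unit ST plateau over the (S end, T onset) interval with cosine ramps
    outside it, so the plateau mean over the interval is exactly 1."""
    lo, hi = template.st_interval
    course = np.zeros_like(t)
    course[(t >= lo) & (t <= hi)] = 1.0
    rising = (t > lo - ST_RAMP_S) & (t < lo)
    course[rising] = 0.5 * (1.0 + np.cos(np.pi * (lo - t[rising]) / ST_RAMP_S))
    falling = (t > hi) & (t < hi + ST_RAMP_S)
    course[falling] = 0.5 * (1.0 + np.cos(np.pi * (t[falling] - hi) / ST_RAMP_S))
    return course


def render_beat(
    template: BeatTemplate,
    effect: ClassEffect,
    inverted: np.ndarray,
    fs: float,
    amp_jitter: dict[str, float] | None = None,
) -> tuple[np.ndarray, int]:
    """Render one noiseless beat as a (12, W) matrix.

    Returns the beat and the index of the R-wave center within the window.
    ``amp_jitter`` optionally scales each wave's amplitude (beat-level AIV).
    """
    p_amp, p_c, p_w = template.wave_params["P"]
    t_amp, t_c, t_w = template.wave_params["T"]
    t_lo = p_c - 4.0 * p_w - 0.02
    t_hi = t_c + 4.0 * t_w + ST_RAMP_S + 0.02
    n_lo = int(np.ceil(-t_lo * fs))
    n_hi = int(np.ceil(t_hi * fs))
    t = (np.arange(-n_lo, n_hi + 1)) / fs

    amps = _lead_wave_amplitudes(template, effect, inverted)
    beat = np.zeros((len(LEADS), t.size))
    for name in WAVE_NAMES:
        _, center, width = template.wave_params[name]
        jitter = 1.0 if amp_jitter is None else amp_jitter[name]
        course = np.exp(-0.5 * ((t - center) / width) ** 2)
        beat += np.outer(amps[name] * jitter, course)
    beat += np.outer(template.st_offset_per_lead, _st_course(t, template))
    return beat, n_lo


# ---------------------------------------------------------------------------
# record and cohort generation


def generate_record(
    class_label: str,
    patient_seed: int,
    beat_seed: int,
    spec: CohortSpec,
    patient_id: str | None = None,
    record_id: str | None = None,
) -> EcgRecord:
    """Generate one 12-lead record with ground-truth R-peak annotations.

    The record is a pure function of (class_label, patient_seed, beat_seed,
    spec): identical inputs reproduce it bit-exactly.
    """
    min_beats = 35
    min_duration = min_beats * 60.0 / spec.min_plausible_hr
    if spec.duration_s < min_duration:
        raise ValueError(
            f"duration {spec.duration_s:.1f}s too short: need >= {min_duration:.1f}s "
            f"for {min_beats} beats at {spec.min_plausible_hr:.0f} bpm"
        )

    template, effect, inverted, hr = patient_template(class_label, patient_seed, spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(patient_seed), int(beat_seed)]))
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    signals = np.zeros((len(LEADS), n))

    # beat-level RR jitter at half the amplitude-jitter scale
    rr_mean = 60.0 / hr
    r_times = []
    t_r = 0.4
    while t_r < spec.duration_s - 0.1:
        r_times.append(t_r)
        rr = rr_mean * (1.0 + rng.normal(0.0, spec.aiv_sd / 2.0))
        t_r += max(rr, 0.3)

    r_indices = []
    for t_r in r_times:
        jitter = {name: 1.0 + rng.normal(0.0, spec.aiv_sd) for name in WAVE_NAMES}
        beat, r_off = render_beat(template, effect, inverted, fs, jitter)
        r_idx = int(round(t_r * fs))
        lo = r_idx - r_off
        hi = lo + beat.shape[1]
        b_lo, b_hi = max(0, -lo), beat.shape[1] - max(0, hi - n)
        signals[:, max(0, lo) : min(n, hi)] += beat[:, b_lo:b_hi]
        r_indices.append(r_idx)

    if spec.wander_amp_uv > 0:
        t = np.arange(n) / fs
        for frac in (0.6, 0.4):
            freq = rng.uniform(*spec.wander_band_hz)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            signals += frac * spec.wander_amp_uv * np.sin(2.0 * np.pi * freq * t + phase)
    if spec.noise_sd_uv > 0:
        signals += rng.normal(0.0, spec.noise_sd_uv, signals.shape)

    return EcgRecord(
        patient_id=patient_id or f"p{patient_seed}",
        record_id=record_id or f"p{patient_seed}r{beat_seed}",
        signals=quantize(signals),
        fs=fs,
        class_label=class_label,
        r_peaks=np.asarray(r_indices, dtype=int),
        meta={"hr_bpm": hr, "patient_seed": int(patient_seed), "beat_seed": int(beat_seed)},
    )


def cohort_manifest(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic record plan: one row per record with patient/record IDs,
    class label, and the derived seeds."""
    rows = []
    subj_counter = 0
    for class_idx, label in enumerate(c for c in CLASSES if c in spec.class_counts):
        n_subj, n_rec = spec.class_counts[label]
        base, extra = divmod(n_rec, n_subj)
        for s in range(n_subj):
            patient_id = f"p{subj_counter:03d}"
            patient_seed = _seed_int(spec.seed, class_idx, s)
            n_for_subject = base + (1 if s < extra else 0)
            for r in range(n_for_subject):
                rows.append(
                    {
                        "patient_id": patient_id,
                        "record_id": f"{patient_id}r{r}",
                        "class": label,
                        "patient_seed": patient_seed,
                        "beat_seed": _seed_int(spec.seed, class_idx, s, r),
                    }
                )
            subj_counter += 1
    return pd.DataFrame(rows)


def iter_cohort(spec: CohortSpec):
    """Yield the cohort's records one at a time (memory-friendly)."""
    manifest = cohort_manifest(spec)
    for row in manifest.to_dict("records"):
        yield generate_record(
            row["class"],
            row["patient_seed"],
            row["beat_seed"],
            spec,
            patient_id=row["patient_id"],
            record_id=row["record_id"],
        )


def generate_cohort(spec: CohortSpec) -> tuple[list[EcgRecord], pd.DataFrame]:
    """Materialize the full cohort plus its manifest table."""
    manifest = cohort_manifest(spec)
    records = list(iter_cohort(spec))
    return records, manifest[["patient_id", "record_id", "class"]].copy()
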