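"""Signal preprocessing chain: anti-aliased downsampling to 100 Hz,
median-filter baseline removal, R-peak detection, and fixed-window beat
segmentation.

Processing order is downsample -> baseline removal -> detection ->
segmentation.  Each beat window spans 50 samples before the R peak, the R
sample itself, and 349 samples after it (400 samples at 100 Hz); peaks too
close to a record edge are dropped, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .christov import ChristovConfig, christov_detect
from .records import LEADS, EcgRecord


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 100.0
    median_window_s: float = 0.857  # covers one cardiac cycle at 70 bpm
    pre_samples: int = 50
    post_samples: int = 349
    detection_lead: str = "II"
    include_r_sample: bool = True   # window length = pre + 1 + post if True
    christov: ChristovConfig = field(default_factory=ChristovConfig)

    def __post_init__(self) -> None:
        if self.pre_samples < 0 or self.post_samples < 1:
            raise ValueError("need pre_samples >= 0 and post_samples >= 1")
        if round(self.median_window_s * self.target_fs) < 3:
            raise ValueError("median window must span at least 3 samples")
        if self.detection_lead not in LEADS:
            raise ValueError(f"unknown detection lead {self.detection_lead!r}")

    @property
    def segment_length(self) -> int:
        return self.pre_samples + int(self.include_r_sample) + self.post_samples


@dataclass
class BeatSegment:
    """One beat-aligned 12 x L window with provenance."""

    matrix: np.ndarray          # (12, L) in uV
    patient_id: str
    record_id: str
    beat_index: int
    class_label: str
    r_index_in_segment: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(LEADS):
            raise ValueError(f"segment must be (12, L); got {self.matrix.shape}")


def antialias_downsample(x: np.ndarray, fs_in: float, fs_out: float = 100.0) -> np.ndarray:
    """Anti-aliased integer-ratio decimation along the last axis.

    Polyphase FIR (Kaiser window) with unity DC gain; output length is
    floor(N * fs_out / fs_in).
    """
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(f"decimation ratio {ratio} is not a positive integer")
    x = np.asarray(x, dtype=float)
    if q == 1:
        return x.copy()
    out = signal.resample_poly(x, up=1, down=q, axis=-1, padtype="line")
    n_out = x.shape[-1] // q
    return out[..., :n_out]


def median_window_samples(window_s: float, fs: float) -> int:
    """Window length in samples: round(window_s * fs), forced odd downward
    (0.857 s at 100 Hz -> 85 samples)."""
    w = int(round(window_s * fs))
    return w if w % 2 == 1 else w - 1


def remove_baseline(x: np.ndarray, fs: float, window_s: float = 0.857) -> np.ndarray:
    """Subtract a running median (reflected edges) to remove baseline wander."""
    x = np.asarray(x, dtype=float)
    w = median_window_samples(window_s, fs)
    if w >= x.shape[-1]:
        raise ValueError(f"median window ({w} samples) must be shorter than the signal")
    size = (1,) * (x.ndim - 1) + (w,)
    baseline = ndimage.median_filter(x, size=size, mode="reflect")
    return x - baseline


def detect_r_peaks(
    x: np.ndarray, fs: float, config: ChristovConfig | None = None
) -> np.ndarray:
    """Adaptive-threshold R-peak detection on one baseline-removed lead."""
    return christov_detect(x, fs, config)


def segment_beats(
    record: EcgRecord, r_indices: np.ndarray, config: PreprocessConfig | None = None
) -> tuple[list[BeatSegment], int]:
    """Cut fixed windows around each R index; out-of-bounds peaks are dropped.

    Returns (segments, n_dropped).  For a peak at sample r the window covers
    samples [r - pre, r + post] inclusive, with the R sample at segment index
    ``pre``.
    """
    config = config or PreprocessConfig()
    pre, post = config.pre_samples, config.post_samples
    n = record.n_samples
    segments: list[BeatSegment] = []
    dropped = 0
    for k, r in enumerate(np.asarray(r_indices, dtype=int)):
        if r - pre < 0 or r + post > n - 1:
            dropped += 1
            continue
        window = record.signals[:, r - pre : r + post + 1]
        if not config.include_r_sample:
            window = np.delete(window, pre, axis=1)
        segments.append(
            BeatSegment(
                matrix=window.astype(np.float32),
                patient_id=record.patient_id,
                record_id=record.record_id,
                beat_index=k,
                class_label=record.class_label,
                r_index_in_segment=pre,
            )
        )
    return segments, dropped


def preprocess_record(
    record: EcgRecord,
    config: PreprocessConfig | None = None,
    use_annotated_peaks: bool = False,
) -> tuple[EcgRecord, np.ndarray, list[BeatSegment], int]:
    """Run the full chain on one record.

    Returns the denoised 100 Hz record, the R-peak indices (at the target
    rate), the beat segments, and the count of boundary-dropped peaks.
    ``use_annotated_peaks`` bypasses detection with the record's ground-truth
    annotation (diagnostics only).
    """
    config = config or PreprocessConfig()
    down = antialias_downsample(record.signals, record.fs, config.target_fs)
    clean = remove_baseline(down, config.target_fs, config.median_window_s)
    ratio = record.fs / config.target_fs
    annotated = None
    if record.r_peaks is not None:
        annotated = np.round(record.r_peaks / ratio).astype(int)
    processed = EcgRecord(
        patient_id=record.patient_id,
        record_id=record.record_id,
        signals=clean,
        fs=config.target_fs,
        class_label=record.class_label,
        r_peaks=annotated,
        meta=dict(record.meta),
    )
    if use_annotated_peaks:
        if annotated is None:
            raise ValueError("record carries no R-peak annotation")
        r_idx = annotated
    else:
        lead = clean[LEADS.index(config.detection_lead)]
        r_idx = detect_r_peaks(lead, config.target_fs, config.christov)
    segments, dropped = segment_beats(processed, r_idx, config)
    return processed, r_idx, segments, dropped
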