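"""Core record container and study-wide constants.

The standard 12-lead order and the six diagnostic classes (healthy control
plus five MI locations) are fixed study-wide; every module indexes leads and
classes through these tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard 12-lead order: limb leads, augmented leads, precordial leads.
LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Healthy control plus the five MI localization classes.
CLASSES: tuple[str, ...] = ("HC", "ALMI", "AMI", "ASMI", "ILMI", "IMI")
MI_CLASSES: tuple[str, ...] = CLASSES[1:]

#: Label for records whose diagnosis does not map to the six study classes.
EXCLUDED = "excluded"

#: Storage quantization: 0.5 uV per least-significant bit.
LSB_UV = 0.5
#: Nominal full-scale range of the 16-bit recording, in uV.
FULL_SCALE_UV = 16384.0
#: Largest positive value representable at 0.5 uV/LSB in signed 16-bit.
MAX_STORABLE_UV = 32767 * LSB_UV

LEAD_INDEX = {name: i for i, name in enumerate(LEADS)}
CLASS_INDEX = {name: i for i, name in enumerate(CLASSES)}


@dataclass
class EcgRecord:
    """One subject's one 12-lead ECG recording.

    Parameters
    ----------
    patient_id, record_id : str
        Subject and recording identifiers; several records may share a
        patient_id.
    signals : ndarray, shape (12, N)
        Lead voltages in microvolts, ordered as :data:`LEADS`.
    fs : float
        Sampling rate in Hz.
    class_label : str
        One of :data:`CLASSES` or ``"excluded"``.
    r_peaks : ndarray of int, optional
        R-peak sample indices (annotation; ground truth for generated
        records).
    """

    patient_id: str
    record_id: str
    signals: np.ndarray
    fs: float
    class_label: str
    lead_names: tuple[str, ...] = LEADS
    r_peaks: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] != len(self.lead_names):
            raise ValueError(
                f"signals must be ({len(self.lead_names)}, N); got {self.signals.shape}"
            )
        if self.signals.shape[1] == 0:
            raise ValueError("record has zero samples")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.r_peaks is not None:
            self.r_peaks = np.asarray(self.r_peaks, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's signal by name."""
        return self.signals[self.lead_names.index(name)]


def quantize(signals: np.ndarray) -> np.ndarray:
    """Clip to the representable 16-bit range and round to 0.5 uV steps."""
    clipped = np.clip(signals, -FULL_SCALE_UV, MAX_STORABLE_UV)
    return np.round(clipped / LSB_UV) * LSB_UV
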