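"""PTB-dialect WFDB record I/O and header-diagnosis classification.

Covers exactly the subset of the WFDB format the study database uses: a text
header (``.hea``) plus a format-16 signal file (``.dat``, interleaved
little-endian int16), 12 standard leads at a fixed gain of 2 ADC units per uV
(0.5 uV/LSB).  Frank leads (vx, vy, vz), if present, are dropped on read.
Multi-segment records and variable layouts are out of scope.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .records import (
    EXCLUDED,
    FULL_SCALE_UV,
    LEADS,
    LSB_UV,
    MAX_STORABLE_UV,
    EcgRecord,
)

GAIN_ADU_PER_UV = 1.0 / LSB_UV  # 2 ADC units per microvolt
FRANK_LEADS = ("vx", "vy", "vz")

#: Diagnosis text written for each class (and recognized on read).
CLASS_DIAGNOSIS = {
    "HC": "Healthy control",
    "ALMI": "Myocardial infarction / antero-lateral",
    "AMI": "Myocardial infarction / anterior",
    "ASMI": "Myocardial infarction / antero-septal",
    "ILMI": "Myocardial infarction / infero-lateral",
    "IMI": "Myocardial infarction / inferior",
}

# Localization synonym table.  Matching is case-insensitive on text with
# hyphens/whitespace squashed; first match wins, so composite localizations
# that are NOT one of the five study locations (e.g. infero-postero-lateral)
# are rejected before their substrings can match.
_RULES: tuple[tuple[str, str], ...] = (
    ("healthycontrol", "HC"),
    ("inferoposterolateral", EXCLUDED),
    ("inferoposterior", EXCLUDED),
    ("inferolateroposterior", EXCLUDED),
    ("posterolateral", EXCLUDED),
    ("posteroseptal", EXCLUDED),
    ("posterior", EXCLUDED),
    ("postero", EXCLUDED),
    ("anteroseptal", "ASMI"),
    ("anterolateral", "ALMI"),
    ("inferolateral", "ILMI"),
    ("anterior", "AMI"),
    ("inferior", "IMI"),
    ("lateral", EXCLUDED),
    ("septal", EXCLUDED),
    ("apical", EXCLUDED),
)


def classify_header(header_text: str) -> str:
    """Map free header diagnosis text to a study class label.

    Total and deterministic: any text not matching the healthy-control marker
    or exactly one of the five MI localizations yields ``"excluded"``.
    """
    squashed = re.sub(r"[\s\-_]+", "", header_text.lower())
    for pattern, label in _RULES:
        if pattern in squashed:
            return label
    return EXCLUDED


def write_record(record: EcgRecord, path: str | Path) -> tuple[Path, Path]:
    """Write ``record`` as a WFDB-dialect header + format-16 signal pair.

    ``path`` is the record base name (no extension).  Values must lie within
    the nominal +/-16,384 uV range; +16,384.0 uV saturates to the largest
    representable code (+16,383.5 uV).
    """
    base = Path(path)
    if np.any(np.abs(record.signals) > FULL_SCALE_UV):
        worst = float(np.max(np.abs(record.signals)))
        raise ValueError(
            f"signal exceeds +/-{FULL_SCALE_UV:.0f} uV (max |value| {worst:.1f}); clip upstream"
        )
    adc = np.round(np.clip(record.signals, -FULL_SCALE_UV, MAX_STORABLE_UV) * GAIN_ADU_PER_UV)
    adc = adc.astype(np.int16)

    n_sig, n_samp = adc.shape
    lines = [f"{base.name} {n_sig} {record.fs:g} {n_samp}"]
    checksums = (adc.astype(np.int64).sum(axis=1) % 65536).astype(int)
    for i, lead in enumerate(record.lead_names):
        lines.append(
            f"{base.name}.dat 16 {GAIN_ADU_PER_UV:g}(0)/uV 16 0 "
            f"{int(adc[i, 0])} {int(checksums[i])} 0 {lead}"
        )
    lines.append(f"# patient_id: {record.patient_id}")
    diagnosis = CLASS_DIAGNOSIS.get(record.class_label, record.class_label)
    lines.append(f"# diagnosis: {diagnosis}")
    if record.r_peaks is not None:
        lines.append("# r_peaks: " + ",".join(str(int(r)) for r in record.r_peaks))

    base.parent.mkdir(parents=True, exist_ok=True)
    hea = base.with_suffix(".hea")
    dat = base.with_suffix(".dat")
    hea.write_text("\n".join(lines) + "\n")
    adc.T.reshape(-1).tofile(dat)  # sample-major interleaving
    return hea, dat


def read_record(path: str | Path) -> EcgRecord:
    """Read a WFDB-dialect record written in the PTB subset.

    Signals are converted to uV at the header-declared gain; Frank leads are
    dropped; the 12 standard leads are reordered to the fixed study order.
    A record missing any standard lead, or using an unsupported storage
    format, is rejected.
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    dat_expected = base.with_suffix(".dat")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = hea.read_text().splitlines()
    head = lines[0].split()
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])

    lead_rows: list[tuple[str, float]] = []
    comments: list[str] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        if line.startswith("#"):
            comments.append(line.lstrip("# ").rstrip())
            continue
        parts = line.split()
        fmt = parts[1]
        if fmt != "16":
            raise ValueError(f"unsupported storage format {fmt!r} (only format 16)")
        gain_field = parts[2].split("/")[0]
        gain = float(re.match(r"([-0-9.eE+]+)", gain_field).group(1))
        if gain <= 0:
            raise ValueError(f"non-positive gain {gain} in header")
        lead_rows.append((parts[-1], gain))
    if len(lead_rows) != n_sig:
        raise ValueError(f"header declares {n_sig} signals but lists {len(lead_rows)}")

    raw = np.fromfile(dat_expected, dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise ValueError(
            f"signal file length {raw.size} inconsistent with header ({n_sig} x {n_samp})"
        )
    adc = raw.reshape(n_samp, n_sig).T.astype(float)

    names = [name for name, _ in lead_rows]
    lower = [n.lower() for n in names]
    missing = [lead for lead in LEADS if lead.lower() not in lower]
    if missing:
        raise ValueError(f"record is missing standard lead(s): {missing}")
    order = [lower.index(lead.lower()) for lead in LEADS]  # drops Frank leads
    signals = np.stack([adc[i] / lead_rows[i][1] for i in order])

    meta = {}
    for comment in comments:
        if ":" in comment:
            key, value = comment.split(":", 1)
            meta[key.strip().lower()] = value.strip()
    patient_id = meta.get("patient_id") or base.parent.name or base.name
    header_text = " ".join(comments)
    r_peaks = None
    if meta.get("r_peaks"):
        r_peaks = np.array([int(v) for v in meta["r_peaks"].split(",") if v], dtype=int)

    return EcgRecord(
        patient_id=patient_id,
        record_id=base.name,
        signals=signals,
        fs=fs,
        class_label=classify_header(header_text),
        r_peaks=r_peaks,
        meta=meta,
    )
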