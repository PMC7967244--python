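"""Christov adaptive-threshold R-peak detection.

Single-lead implementation of the combined adaptive-threshold QRS detector:
the signal is band-enhanced into a "complex lead" (moving-average smoothed
absolute first difference), and a QRS is declared where the complex lead
exceeds the sum of three adaptive components:

* ``M`` — steep-slope threshold, refreshed from the complex-lead maximum in
  the 200 ms after each detection, held for 200 ms, then decaying linearly to
  0.6 M over the following second;
* ``F`` — slowly integrating noise-follower updated each sample from the
  difference between recent and older 50 ms complex-lead maxima;
* ``R`` — beat-expectation component that turns negative once two thirds of
  the expected RR interval has elapsed without a detection, lowering the
  combined threshold.

All constants are exposed in :class:`ChristovConfig`.  Detections are
relocated to the raw-lead absolute-amplitude maximum within a +/-50 ms
neighbourhood so that the returned index marks the R wave itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ChristovConfig:
    smooth_powerline_s: float = 0.02   # moving average suppressing 50 Hz
    smooth_emg_s: float = 0.028        # moving average suppressing EMG noise
    smooth_complex_s: float = 0.04     # moving average on the rectified difference
    init_s: float = 2.0                # threshold initialization interval
    m_fraction: float = 0.6            # M = fraction * complex-lead QRS maximum
    m_hold_s: float = 0.2              # post-QRS plateau of M
    m_decay_s: float = 1.0             # linear decay of M to m_fraction*M
    m_buffer: int = 5                  # M values averaged
    f_window_s: float = 0.35           # F update look-back
    f_peak_s: float = 0.05             # width of the two F maxima windows
    f_rate: float = 150.0              # divisor of the F increment
    rr_buffer: int = 5                 # RR intervals averaged for beat expectation
    r_start_fraction: float = 2.0 / 3.0  # of expected RR before R kicks in
    r_slope_fraction: float = 0.4      # R drops by this fraction of M over m_decay_s
    refractory_s: float = 0.2
    relocate_s: float = 0.05           # +/- window for raw-lead R relocation


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def complex_lead(x: np.ndarray, fs: float, cfg: ChristovConfig) -> np.ndarray:
    """Rectified, band-enhanced detection signal."""
    y = _moving_average(np.asarray(x, dtype=float), max(1, round(cfg.smooth_powerline_s * fs)))
    y = _moving_average(y, max(1, round(cfg.smooth_emg_s * fs)))
    dy = np.abs(np.diff(y, prepend=y[0]))
    return _moving_average(dy, max(1, round(cfg.smooth_complex_s * fs)))


def christov_detect(
    x: np.ndarray, fs: float, cfg: ChristovConfig | None = None
) -> np.ndarray:
    """Detect R peaks in one baseline-removed lead; returns sorted indices.

    Raises ``ValueError`` on signals shorter than the threshold
    initialization interval (2 s).
    """
    cfg = cfg or ChristovConfig()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < cfg.init_s * fs:
        raise ValueError(f"signal too short for detection: {n / fs:.2f}s < {cfg.init_s}s")

    y = complex_lead(x, fs, cfg)
    init = int(cfg.init_s * fs)
    hold = int(cfg.m_hold_s * fs)
    decay_len = int(cfg.m_decay_s * fs)
    refractory = int(cfg.refractory_s * fs)
    f_win = int(cfg.f_window_s * fs)
    f_peak = int(cfg.f_peak_s * fs)
    reloc = int(cfg.relocate_s * fs)

    m0 = cfg.m_fraction * float(np.max(y[:init]))
    mm = [m0] * cfg.m_buffer
    m_avg = m0
    f = float(np.mean(y[: min(f_win, n)]))
    rr_avg = fs  # expect ~60 bpm until measured
    rr_buf: list[float] = []

    peaks: list[int] = []
    last = -n  # index of last detection
    for i in range(n):
        elapsed = i - last
        # M component: plateau, linear decay, floor
        if elapsed <= hold:
            m = m_avg
        elif elapsed <= hold + decay_len:
            frac = (elapsed - hold) / decay_len
            m = m_avg * (1.0 - (1.0 - cfg.m_fraction) * frac)
        else:
            m = cfg.m_fraction * m_avg
        # F component: integrate the local noise level
        if i >= f_win:
            f += (np.max(y[i - f_peak : i + 1]) - np.max(y[i - f_win : i - f_win + f_peak])) / cfg.f_rate
        # R component: lower the threshold when a beat is overdue
        overdue = elapsed - cfg.r_start_fraction * rr_avg
        if overdue > 0:
            r = -cfg.r_slope_fraction * m_avg * min(overdue / decay_len, 1.0)
        else:
            r = 0.0
        mfr = m + f + r
        if elapsed > refractory and mfr > 0 and y[i] > mfr:
            if peaks:
                rr_buf.append(i - last)
                rr_buf = rr_buf[-cfg.rr_buffer :]
                rr_avg = float(np.mean(rr_buf))
            last = i
            peaks.append(i)
            m_new = cfg.m_fraction * float(np.max(y[i : min(n, i + hold)]))
            m_new = min(m_new, 1.5 * mm[-1])
            mm = mm[1:] + [m_new]
            m_avg = float(np.mean(mm))

    # relocate each threshold crossing to the raw-lead |amplitude| maximum
    relocated = []
    for p in peaks:
        lo, hi = max(0, p - reloc), min(n, p + reloc + 1)
        relocated.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    out = np.array(sorted(set(relocated)), dtype=int)
    # collapse relocations that merged closer than the refractory period
    if out.size > 1:
        keep = np.concatenate([[True], np.diff(out) > refractory])
        out = out[keep]
    return out
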