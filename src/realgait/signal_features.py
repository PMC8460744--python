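"""Signal enhancement and per-second biomechanical feature extraction.

The raw tri-axial signal is reduced to its Euclidean norm and band-pass
filtered (default 0.25–10 Hz, 4th-order Butterworth, zero-phase) to remove
the gravity offset — the "enhanced" signal. From it, one feature record
per full second of recording is computed:

========== =============================================================
intensity   SD of the enhanced norm within the second (g)
periodicity max normalized autocorrelation over lags 0.25–2 s, in [0, 1]
posture     forearm tilt: angle between the low-frequency raw mean vector
            and the gravity reference axis (degrees)
noisiness   fraction of context-window spectral power above 4 Hz within
            the 0.1–10 Hz band, in [0, 1]
energy      mean squared enhanced norm within the second (g²)
step_freq   spectral peak in 1.0–3.5 Hz over the context window (Hz);
            NaN when no sufficiently prominent peak exists
mean_acc    mean raw norm within the second (g)
swing       arm-swing band power, [step_freq/2 ± 0.25] Hz (g²)
========== =============================================================

Spectral/autocorrelation features use a centered context window (default
5 s); windows truncated at the recording edges are flagged.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthetic_data import SignalRecording

__all__ = ["enhance_signal", "extract_features", "DETECTION_FEATURES", "SPEED_FEATURES"]

DETECTION_FEATURES = ["intensity", "periodicity", "posture", "noisiness"]
SPEED_FEATURES = ["energy", "step_freq", "mean_acc", "swing"]

#: step-frequency search band (Hz) and peak-prominence floor
STEP_BAND_HZ = (1.0, 3.5)
PEAK_PROMINENCE_RATIO = 8.0
NFFT = 1024


def enhance_signal(
    recording: SignalRecording,
    low_hz: float = 0.25,
    high_hz: float = 10.0,
    order: int = 4,
) -> np.ndarray:
    """Band-pass filtered acceleration norm, one value per raw sample."""
    fs = recording.sampling_rate
    if fs < 20:
        raise ValueError("sampling rate must be at least 20 Hz")
    norm = np.linalg.norm(recording.acceleration, axis=1)
    sos = sps.butter(order, (low_hz, high_hz), btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if len(norm) <= padlen:
        raise ValueError("recording shorter than the filter warm-up window")
    return sps.sosfiltfilt(sos, norm)


def _parabolic_peak(logp: np.ndarray, k: int) -> float:
    """Sub-bin peak offset from a parabola through three log-power bins."""
    if k <= 0 or k >= len(logp) - 1:
        return 0.0
    a, b, c = logp[k - 1], logp[k], logp[k + 1]
    denom = a - 2 * b + c
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def extract_features(
    enhanced: np.ndarray,
    recording: SignalRecording,
    context_s: int = 5,
) -> pd.DataFrame:
    """Per-second feature records for detection and speed estimation.

    Returns a DataFrame with one row per full second (columns above plus a
    boolean ``edge`` flag for truncated context windows).
    """
    if context_s < 3:
        raise ValueError("context_s must be at least 3 seconds")
    fs = recording.sampling_rate
    n = len(enhanced)
    if recording.acceleration.shape[0] != n:
        raise ValueError("enhanced series and recording length differ")
    n_sec = n // fs
    raw_norm = np.linalg.norm(recording.acceleration, axis=1)

    half = (context_s * fs - fs) // 2  # context samples on each side
    freqs = np.fft.rfftfreq(NFFT, d=1.0 / fs)
    band = (freqs >= STEP_BAND_HZ[0]) & (freqs <= STEP_BAND_HZ[1])
    band_idx = np.nonzero(band)[0]
    noise_den = (freqs >= 0.1) & (freqs <= 10.0)
    noise_num = (freqs > 4.0) & (freqs <= 10.0)
    lag0, lag1 = int(round(0.25 * fs)), int(round(2.0 * fs))
    df_hz = fs / NFFT
    gravity_ref = np.array([0.0, 0.0, 1.0])

    cols = {
        name: np.full(n_sec, np.nan)
        for name in DETECTION_FEATURES + SPEED_FEATURES
    }
    edge = np.zeros(n_sec, dtype=bool)

    for i in range(n_sec):
        s0, s1 = i * fs, (i + 1) * fs
        seg = enhanced[s0:s1]
        cols["intensity"][i] = np.std(seg)
        cols["energy"][i] = np.mean(seg**2)
        cols["mean_acc"][i] = np.mean(raw_norm[s0:s1])

        w0, w1 = s0 - half, s1 + half
        if w0 < 0 or w1 > n:
            edge[i] = True
            w0, w1 = max(w0, 0), min(w1, n)
        win = enhanced[w0:w1]
        W = len(win)

        # posture: context-window mean raw vector approximates the < 0.25 Hz
        # gravity component over a 5 s window
        v = recording.acceleration[w0:w1].mean(axis=0)
        nv = np.linalg.norm(v)
        if nv > 0:
            cosang = np.clip(np.dot(v, gravity_ref) / nv, -1.0, 1.0)
            cols["posture"][i] = np.degrees(np.arccos(cosang))

        wc = win - win.mean()
        spec = np.abs(np.fft.rfft(wc, NFFT)) ** 2

        den = spec[noise_den].sum()
        cols["noisiness"][i] = float(spec[noise_num].sum() / den) if den > 0 else 0.0

        # periodicity: normalized linear autocorrelation via the spectrum
        ac = np.fft.irfft(spec, NFFT)
        hi = min(lag1, W - 1)
        if ac[0] > 0 and hi >= lag0:
            cols["periodicity"][i] = float(
                np.clip(ac[lag0 : hi + 1].max() / ac[0], 0.0, 1.0)
            )
        else:
            cols["periodicity"][i] = 0.0

        # step frequency: prominent spectral peak in the gait band
        bspec = spec[band_idx]
        mean_band = bspec.mean()
        k_rel = int(np.argmax(bspec))
        if mean_band > 0 and bspec[k_rel] >= PEAK_PROMINENCE_RATIO * mean_band:
            k = band_idx[k_rel]
            with np.errstate(divide="ignore"):
                logp = np.log(np.maximum(spec, 1e-300))
            f_peak = (k + _parabolic_peak(logp, k)) * df_hz
            cols["step_freq"][i] = f_peak
            sw = (freqs >= f_peak / 2 - 0.25) & (freqs <= f_peak / 2 + 0.25)
            # one-sided spectrum: double interior bins; scale to mean square
            cols["swing"][i] = float(2.0 * spec[sw].sum() / (NFFT * W))

    out = pd.DataFrame(cols)
    out["edge"] = edge
    return out
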