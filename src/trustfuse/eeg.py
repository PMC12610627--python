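"""EEG trust scoring: preprocessing, band decomposition, Welch band power,
and the standardized alpha/beta-ratio to trust-score mapping.

The pipeline mirrors a forehead single-channel setup sampled at 500 Hz:

1. zero-phase band-pass 1-45 Hz (4th-order Butterworth, forward-backward),
2. wavelet artifact suppression (db4, 5 levels, soft universal threshold),
3. 5-sample median filter,
4. per-event 3 s epochs (-1 s to +2 s around each decision point),
5. Welch band power (2 s Hann windows, 50% overlap) integrated over the
   alpha (8-13 Hz) and beta (13-30 Hz) bands,
6. Z-standardization of the epoch alpha/beta ratios across the session and
   the bounded mapping ``score = 5 + 2.5 * tanh(Z)`` onto the trust scale.

The mapping keeps scores in the open interval (2.5, 7.5) with Z = 0 at the
scale midpoint 5, which mitigates floor/ceiling effects of raw ratios.
"""
from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pywt
from scipy import signal

from .errors import DegenerateInputError, InvalidArgumentError, InvalidSamplingRateError
from .types import BandPowerEpoch, EEGRecording, EventTimeline, TrustCurve, TrustCurvePoint

#: Classic EEG frequency bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

_BP_LOW, _BP_HIGH = 1.0, 45.0
_WAVELET = "db4"
_WAVELET_LEVEL = 5
_MEDFILT_KERNEL = 5
_EPOCH_PRE_S, _EPOCH_POST_S = 1.0, 2.0
_WELCH_WINDOW_S = 2.0
_BETA_FLOOR = 1e-12  # µV²; below this the ratio is flagged invalid


def trust_score_from_z(z):
    """Map a standardized alpha/beta ratio onto the trust scale.

    ``score = 5 + 2.5 * tanh(Z)``: Z = 0 gives the midpoint 5, the range is
    the open interval (2.5, 7.5), and Z of roughly +/-2 covers about 3-8.
    """
    return 5.0 + 2.5 * np.tanh(z)


def _wavelet_denoise(x: np.ndarray) -> np.ndarray:
    """Soft-threshold db4 detail coefficients with the universal threshold.

    The noise scale is the MAD of the finest detail level divided by 0.6745;
    the approximation coefficients are left untouched.
    """
    coeffs = pywt.wavedec(x, _WAVELET, level=_WAVELET_LEVEL)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    if sigma > 0:
        thr = sigma * np.sqrt(2.0 * np.log(x.size))
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(coeffs, _WAVELET)[: x.size]


def preprocess(recording: EEGRecording) -> EEGRecording:
    """Band-pass, wavelet-denoise, and median-filter a raw recording.

    Output has the same length and sampling rate as the input.
    """
    fs = recording.fs
    if fs < 2.0 * _BP_HIGH:
        raise InvalidSamplingRateError(
            f"fs = {fs} Hz cannot represent the {_BP_HIGH} Hz band edge"
        )
    if recording.duration_s < 2.0:
        raise InvalidArgumentError("recording shorter than 2 s")
    sos = signal.butter(4, (_BP_LOW, _BP_HIGH), btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, recording.samples)
    x = _wavelet_denoise(x)
    x = signal.medfilt(x, kernel_size=_MEDFILT_KERNEL)
    return recording.with_samples(x)


def _fir_taps(band: tuple[float, float], fs: float) -> np.ndarray:
    # Hamming-window FIR; transition width 25% of the lower cut-off gives
    # >50 dB stopband attenuation. Order rounded up to odd for a type-I filter.
    low, high = band
    trans = 0.25 * low
    numtaps = int(np.ceil(3.3 * fs / trans))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, (low, high), fs=fs, pass_zero=False, window="hamming")


def band_decompose(recording: EEGRecording) -> dict[str, np.ndarray]:
    """Zero-phase FIR band-pass outputs for the five classic bands.

    Used for quality control (e.g. delta-dominant motion artifacts); the
    trust score itself integrates the broadband Welch PSD over band limits.
    """
    x = recording.samples
    out: dict[str, np.ndarray] = {}
    for name, band in BANDS.items():
        taps = _fir_taps(band, recording.fs)
        padlen = min(3 * len(taps), x.size - 1)
        out[name] = signal.filtfilt(taps, 1.0, x, padlen=padlen)
    return out


def welch_band_power(segment: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Band power (µV²) from Welch's PSD with 2 s Hann windows, 50% overlap.

    The window shrinks to the segment length for segments under 2 s, in which
    case the estimate equals a single Hann-tapered periodogram. Power is the
    trapezoidal integral of the PSD over the band.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise InvalidArgumentError("empty segment")
    nperseg = min(int(round(_WELCH_WINDOW_S * fs)), segment.size)
    freqs, psd = signal.welch(segment, fs=fs, nperseg=nperseg)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise InvalidArgumentError(
            f"segment too short to resolve the {lo}-{hi} Hz band (df = {freqs[1] - freqs[0]:.3g} Hz)"
        )
    return float(np.trapezoid(psd[mask], freqs[mask]))


def band_power_epoch(segment: np.ndarray, fs: float, event_id: str = "") -> BandPowerEpoch:
    """All five band powers plus the alpha/beta ratio for one epoch."""
    powers = {name: welch_band_power(segment, fs, band) for name, band in BANDS.items()}
    ratio = powers["alpha"] / powers["beta"] if powers["beta"] > _BETA_FLOOR else None
    return BandPowerEpoch(event_id=event_id, ratio=ratio, **powers)


def baseline_ratio(recording: EEGRecording) -> float | None:
    """Alpha/beta ratio of the resting-state prefix (the session's reference state)."""
    n_rest = int(round(recording.rest_end_s * recording.fs))
    epoch = band_power_epoch(recording.samples[:n_rest], recording.fs, event_id="baseline")
    return epoch.ratio


def compute_trust_curve(
    recording: EEGRecording,
    events: EventTimeline,
    *,
    apply_preprocessing: bool = True,
) -> TrustCurve:
    """Full EEG scoring pipeline for one session.

    Epoch alpha/beta ratios are standardized across the session's task epochs
    (``Z = (X - mu) / sigma``) and mapped with ``5 + 2.5 * tanh(Z)``. Events
    whose -1/+2 s epoch does not fit inside the task segment, or whose beta
    power is numerically zero, are skipped with a warning.
    """
    if len(events) < 2:
        raise InvalidArgumentError("need at least 2 events to standardize epoch ratios")
    rec = preprocess(recording) if apply_preprocessing else recording
    fs = rec.fs
    n = rec.samples.size
    rest_n = int(round(rec.rest_end_s * fs))
    base_ratio = baseline_ratio(rec)

    kept: list[tuple[str, float, float]] = []  # (event_id, t, ratio)
    skipped: list[str] = []
    for ev in events.events:
        i0 = int(round((ev.t_start_s - _EPOCH_PRE_S) * fs))
        i1 = int(round((ev.t_start_s + _EPOCH_POST_S) * fs))
        if i0 < rest_n or i1 > n:
            warnings.warn(
                f"event {ev.event_id}: epoch [{ev.t_start_s - _EPOCH_PRE_S:.2f}, "
                f"{ev.t_start_s + _EPOCH_POST_S:.2f}] s outside task segment; skipped",
                stacklevel=2,
            )
            skipped.append(ev.event_id)
            continue
        epoch = band_power_epoch(rec.samples[i0:i1], fs, event_id=ev.event_id)
        if epoch.ratio is None:
            warnings.warn(f"event {ev.event_id}: beta power ~ 0, ratio undefined; skipped", stacklevel=2)
            skipped.append(ev.event_id)
            continue
        kept.append((ev.event_id, ev.t_start_s, epoch.ratio))

    if len(kept) < 2:
        raise DegenerateInputError("fewer than 2 valid epochs; cannot standardize")
    ratios = np.array([r for _, _, r in kept])
    mu = float(np.mean(ratios))
    sigma = float(np.std(ratios, ddof=1))
    if sigma == 0.0:
        raise DegenerateInputError("epoch ratios have zero standard deviation")
    z = (ratios - mu) / sigma
    scores = trust_score_from_z(z)
    points = [
        TrustCurvePoint(event_id=eid, t_s=t, score=float(s))
        for (eid, t, _), s in zip(kept, scores)
    ]
    return TrustCurve(
        modality="eeg",
        points=points,
        standardization={"mu": mu, "sigma": sigma},
        baseline_ratio=base_ratio,
        skipped_events=skipped,
    )
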