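"""Modality featurizers: raw recordings -> model-ready [channels, time] tensors.

Three protocols are implemented:

* **EEG** — bipolar re-referencing onto the standard 22-pair transverse
  central parietal (TCP) montage, then per-channel MFCCs: resample to 100 Hz,
  2000-point FFT frames hopped every 100 samples (centred framing), a 40-band
  mel filterbank, log compression and a DCT keeping all 40 coefficients.
  A 22-channel 5-minute 250 Hz recording becomes an (880, 301) tensor.
* **single-lead ECG** — resample to 125 Hz, split into non-overlapping 10 s
  windows min–max normalised to [0, 1], detect R-peaks as thresholded local
  maxima with a refractory gap, and cut one fixed-length vector per beat
  spanning 1.2x the window's median R–R interval.
* **EHR** — bucket an irregular (timestamp, feature, value) episode onto a
  uniform grid (default 76 features x 256 steps of 2 h), last observation
  per bin, forward fill, per-feature default for leading gaps.

All featurizers are deterministic: identical input gives identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft
from scipy.signal import find_peaks, get_window, resample_poly

logger = logging.getLogger(__name__)

__all__ = [
    "MontageSpec",
    "SequenceSample",
    "DEFAULT_TCP_PAIRS",
    "TCP_ELECTRODES",
    "EHR_FEATURE_CATALOG",
    "tcp_montage",
    "eeg_mfcc_features",
    "extract_beats",
    "ehr_tensorize",
    "read_edf",
    "mel_filterbank",
]

# The standard 22-pair clinical TCP (double banana, averaged-reference input)
# bipolar montage, 10-20 electrode names.  Editable: pass your own MontageSpec.
DEFAULT_TCP_PAIRS: tuple[tuple[str, str], ...] = (
    ("FP1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("FP2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("A1", "T3"), ("T3", "C3"), ("C3", "CZ"), ("CZ", "C4"),
    ("C4", "T4"), ("T4", "A2"),
    ("FP1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("FP2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
)

TCP_ELECTRODES: tuple[str, ...] = tuple(
    sorted({e for pair in DEFAULT_TCP_PAIRS for e in pair})
)

# 76-name measurement catalog for the EHR grid: common ICU vitals/scores plus
# expanded categorical levels and numbered lab channels.
EHR_FEATURE_CATALOG: tuple[str, ...] = tuple(
    [
        "heart_rate", "systolic_bp", "diastolic_bp", "mean_bp",
        "respiratory_rate", "oxygen_saturation", "temperature", "weight",
        "height", "ph", "glucose", "fraction_inspired_o2",
        "glasgow_coma_eye", "glasgow_coma_motor", "glasgow_coma_verbal",
        "glasgow_coma_total", "capillary_refill",
    ]
    + [f"gcs_eye_level_{i}" for i in range(1, 5)]
    + [f"gcs_motor_level_{i}" for i in range(1, 7)]
    + [f"gcs_verbal_level_{i}" for i in range(1, 6)]
    + [f"lab_{i:02d}" for i in range(1, 45)]
)
assert len(EHR_FEATURE_CATALOG) == 76


@dataclass(frozen=True)
class MontageSpec:
    """Ordered (anode, cathode) electrode pairs in 10-20 naming."""

    pairs: tuple[tuple[str, str], ...] = DEFAULT_TCP_PAIRS

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("montage must contain at least one pair")
        norm = tuple((a.upper(), c.upper()) for a, c in self.pairs)
        object.__setattr__(self, "pairs", norm)


@dataclass
class SequenceSample:
    """One featurized multichannel series with its label and provenance."""

    values: np.ndarray               # [channels, timesteps]
    label: int | np.ndarray
    modality: str                    # 'eeg' | 'ecg-beat' | 'ehr'
    sampling_rate: float | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be [channels, timesteps]")
        if not np.isfinite(self.values).all():
            raise ValueError("featurized values must be finite")


def tcp_montage(
    recording: np.ndarray,
    electrode_names: Sequence[str],
    spec: MontageSpec | None = None,
) -> np.ndarray:
    """Bipolar montage: row p = recording[anode_p] - recording[cathode_p].

    ``recording`` is ``[E, T]`` with one row per named electrode.  Raises a
    ``ValueError`` naming the first electrode the recording lacks.
    """
    spec = spec if spec is not None else MontageSpec()
    recording = np.asarray(recording, dtype=float)
    if recording.ndim != 2 or recording.shape[0] != len(electrode_names):
        raise ValueError("recording must be [E, T] with one row per electrode name")
    index = {str(n).upper(): i for i, n in enumerate(electrode_names)}
    rows = []
    for anode, cathode in spec.pairs:
        for name in (anode, cathode):
            if name not in index:
                raise ValueError(f"electrode {name!r} missing from the recording")
        rows.append(recording[index[anode]] - recording[index[cathode]])
    return np.stack(rows, axis=0)


def _resample(x: np.ndarray, source_rate: float, target_rate: float) -> np.ndarray:
    """Polyphase rational resampling along the last axis (anti-aliased)."""
    frac = Fraction(target_rate / source_rate).limit_denominator(1000)
    if frac == 1:
        return np.asarray(x, dtype=float)
    return resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def mel_filterbank(n_mels: int, n_fft: int, rate: float) -> np.ndarray:
    """Triangular mel filters ``[n_mels, n_fft // 2 + 1]`` spanning 0..rate/2."""

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    edges_hz = mel_to_hz(np.linspace(0.0, hz_to_mel(rate / 2.0), n_mels + 2))
    freqs = np.linspace(0.0, rate / 2.0, n_fft // 2 + 1)
    fb = np.zeros((n_mels, freqs.size))
    for m in range(n_mels):
        lo, mid, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def eeg_mfcc_features(
    montaged: np.ndarray,
    source_rate: float,
    target_rate: float = 100.0,
    n_fft: int = 2000,
    hop: int = 100,
    n_mels: int = 40,
    log_floor: float = 1e-10,
) -> np.ndarray:
    """Per-channel MFCCs stacked channel-major: ``[P, T] -> [P * n_mels, F]``.

    Centred framing pads each resampled channel by ``n_fft // 2`` on both
    sides, so the frame count is ``1 + floor(T_resampled / hop)`` — 301 for a
    5-minute signal at 100 Hz.  The log is floored at ``log_floor`` so silent
    input still featurizes to finite values.
    """
    montaged = np.asarray(montaged, dtype=float)
    if montaged.ndim != 2:
        raise ValueError("montaged input must be [P, T]")
    resampled = _resample(montaged, source_rate, target_rate)
    p, t = resampled.shape
    if t < hop:
        raise ValueError(f"signal of {t} samples at {target_rate} Hz is shorter than one hop")
    n_frames = 1 + t // hop
    window = get_window("hann", n_fft, fftbins=True)
    fb = mel_filterbank(n_mels, n_fft, target_rate)
    pad = n_fft // 2
    padded = np.pad(resampled, ((0, 0), (pad, pad + hop)))
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    out = np.empty((p * n_mels, n_frames))
    for ch in range(p):
        frames = padded[ch][idx] * window          # [F, n_fft]
        power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
        mel_energy = power @ fb.T                   # [F, n_mels]
        logmel = np.log(np.maximum(mel_energy, log_floor))
        coeffs = dct(logmel, type=2, axis=1, norm="ortho")[:, :n_mels]
        out[ch * n_mels : (ch + 1) * n_mels] = coeffs.T
    return out


def extract_beats(
    lead: np.ndarray,
    source_rate: float,
    beat_length: int = 187,
    target_rate: float = 125.0,
    window_s: float = 10.0,
    peak_threshold: float = 0.9,
    refractory_s: float = 0.36,
    rr_factor: float = 1.2,
    smooth_samples: int = 3,
    return_peaks: bool = False,
):
    """Cut fixed-length normalized heartbeat vectors out of a single lead.

    The lead is resampled to ``target_rate``, split into non-overlapping
    ``window_s`` windows, each min–max normalised to [0, 1]; R-peaks are local
    maxima above ``peak_threshold`` separated by at least ``refractory_s``,
    detected on a ``smooth_samples``-wide moving average of the normalised
    window so single-sample noise cannot drop a peak below threshold (the
    beats themselves are cut from the unsmoothed window).
    Each beat starts at a peak and spans ``rr_factor`` times the window's
    median R–R interval, truncated/zero-padded to ``beat_length`` samples.
    A window with no dynamic range is skipped with a logged warning; a window
    with a single peak has no R–R interval, so the beat is cut at
    ``beat_length`` directly.
    """
    lead = np.asarray(lead, dtype=float).ravel()
    if lead.size < window_s * source_rate:
        raise ValueError(
            f"lead of {lead.size} samples is shorter than {window_s} s at {source_rate} Hz"
        )
    sig = _resample(lead, source_rate, target_rate)
    wlen = int(round(window_s * target_rate))
    refractory = max(1, int(round(refractory_s * target_rate)))
    beats: list[np.ndarray] = []
    peak_positions: list[int] = []
    for start in range(0, sig.size - wlen + 1, wlen):
        window = sig[start : start + wlen]
        lo, hi = window.min(), window.max()
        if hi - lo <= 0:
            logger.warning("skipping zero-dynamic-range window at sample %d", start)
            continue
        norm = (window - lo) / (hi - lo)
        if smooth_samples > 1:
            kernel = np.ones(smooth_samples) / smooth_samples
            smoothed = np.convolve(norm, kernel, mode="same")
            smoothed /= max(smoothed.max(), 1e-12)  # renormalise peak to 1
        else:
            smoothed = norm
        peaks, _ = find_peaks(smoothed, height=peak_threshold, distance=refractory)
        if peaks.size == 0:
            continue
        peak_positions.extend(int(p) + start for p in peaks)
        if peaks.size >= 2:
            span = int(round(rr_factor * float(np.median(np.diff(peaks)))))
        else:
            span = beat_length
        span = max(span, 1)
        for p in peaks:
            beat = norm[p : p + span][:beat_length]
            if beat.size < beat_length:
                beat = np.pad(beat, (0, beat_length - beat.size))
            beats.append(beat)
    if return_peaks:
        return beats, np.array(peak_positions, dtype=int)
    return beats


def ehr_tensorize(
    episode: pd.DataFrame,
    feature_catalog: Sequence[str] = EHR_FEATURE_CATALOG,
    num_steps: int = 256,
    bin_hours: float = 2.0,
) -> np.ndarray:
    """Bucket an irregular episode onto a uniform ``[F, num_steps]`` grid.

    ``episode`` has columns (timestamp, feature, value); timestamps may be
    ISO-8601 strings/datetimes or numeric hours.  Bins are anchored at the
    episode's first timestamp; the last observation inside a bin wins, gaps
    are forward-filled, and leading gaps take the per-feature default 0
    (values are assumed standardized per feature).  Observations past the
    grid horizon are ignored.
    """
    if episode is None or len(episode) == 0:
        raise ValueError("episode is empty")
    if num_steps < 1 or bin_hours <= 0:
        raise ValueError("num_steps must be >= 1 and bin_hours > 0")
    required = {"timestamp", "feature", "value"}
    if not required.issubset(episode.columns):
        raise ValueError(f"episode must have columns {sorted(required)}")
    catalog_index = {name: i for i, name in enumerate(feature_catalog)}
    unknown = set(episode["feature"]) - set(catalog_index)
    if unknown:
        raise ValueError(f"unknown feature name(s): {sorted(unknown)}")

    ts = episode["timestamp"]
    if np.issubdtype(ts.dtype, np.number):
        hours = ts.to_numpy(dtype=float)
    else:
        dt = pd.to_datetime(ts)
        hours = (dt - dt.min()).dt.total_seconds().to_numpy() / 3600.0
    hours = hours - hours.min()
    bins = np.floor(hours / bin_hours).astype(int)

    grid = np.zeros((len(feature_catalog), num_steps))
    filled = np.zeros((len(feature_catalog), num_steps), dtype=bool)
    order = np.argsort(hours, kind="stable")  # last-in-time wins within a bin
    feats = episode["feature"].to_numpy()
    vals = episode["value"].to_numpy(dtype=float)
    for i in order:
        b = bins[i]
        if 0 <= b < num_steps:
            f = catalog_index[feats[i]]
            grid[f, b] = vals[i]
            filled[f, b] = True
    for f in range(len(feature_catalog)):
        last = 0.0
        seen = False
        for b in range(num_steps):
            if filled[f, b]:
                last, seen = grid[f, b], True
            elif seen:
                grid[f, b] = last
            # else: leading gap keeps the per-feature default 0
    return grid


def read_edf(path: str) -> tuple[np.ndarray, list[str], float]:
    """Load an EDF recording as ``(data [E, T], electrode_names, rate)``.

    Uses :mod:`mne` when available; install the ``edf`` extra.  Array input
    is the primary interface — this is a convenience for on-disk recordings.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF files requires mne (install the 'edf' extra)") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = [n.upper().removeprefix("EEG ").split("-")[0] for n in raw.ch_names]
    return raw.get_data(), names, float(raw.info["sfreq"])
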