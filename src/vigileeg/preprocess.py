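"""Preprocessing chain: zero-phase filtering, 1-s segmentation, artifact
screening, ICA-based removal of stereotyped artifacts, and screening for
sleep graphoelements (spindles, K-complexes).

Visual artifact inspection is replaced by deterministic amplitude /
gradient / flatline rules, and the analyst's choice of ICA components to
discard is replaced by an EOG/ECG correlation criterion; both thresholds
are configurable.

Segment tables are pandas DataFrames with one row per 1-s segment and
columns ``segment`` (1-based index, the convention used in all reports),
``start_sample``, ``artifact`` (bool), ``artifact_reason`` (str) and
``graphoelement`` (bool).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .channels import ROI_CENTRAL
from .recording import Recording

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.5, 70.0)
DEFAULT_NOTCH = 50.0


def bandpass_notch(
    recording: Recording,
    band: tuple[float, float] = DEFAULT_BAND,
    notch: float = DEFAULT_NOTCH,
    order: int = 4,
    notch_q: float = 30.0,
    eog_highpass: float = 0.1,
) -> Recording:
    """Zero-phase Butterworth band-pass plus notch filter.

    EEG and ECG channels get the full ``band`` (default 0.5–70 Hz)
    band-pass; the EOG channel keeps a lower high-pass edge
    (``eog_highpass``, default 0.1 Hz) so that slow eye movements —
    which the vigilance classifier needs to separate stage 0 from B1 —
    survive preprocessing.  All channels are notch-filtered.  Filtering
    is forward-backward (``filtfilt``), hence zero-phase.
    """
    fs = recording.sampling_rate
    if fs < 2 * band[1]:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    min_samples = int(3 * fs / band[0])
    if recording.n_samples < min_samples:
        raise ValueError(
            f"recording too short to filter: {recording.n_samples} samples "
            f"< {min_samples} (3× the {band[0]} Hz impulse-response scale)"
        )
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    sos_eog = signal.butter(
        order, (eog_highpass, band[1]), btype="bandpass", fs=fs, output="sos"
    )
    b_notch, a_notch = signal.iirnotch(notch, notch_q, fs=fs)

    out = np.empty_like(recording.signals)
    for ci in range(recording.n_channels):
        use = sos_eog if recording.channel_roles[ci] == "EOG" else sos
        x = signal.sosfiltfilt(use, recording.signals[ci])
        out[ci] = signal.filtfilt(b_notch, a_notch, x)
    return recording.copy_with(out)


def segment(recording: Recording) -> pd.DataFrame:
    """Tile the recording into consecutive non-overlapping 1-s segments.

    A trailing partial second is discarded (floor rule).
    """
    fs = int(round(recording.sampling_rate))
    n_seg = recording.n_samples // fs
    if n_seg == 0:
        warnings.warn("recording shorter than 1 s: zero segments", stacklevel=2)
    return pd.DataFrame(
        {
            "segment": np.arange(1, n_seg + 1),
            "start_sample": np.arange(n_seg) * fs,
            "artifact": np.zeros(n_seg, dtype=bool),
            "artifact_reason": [""] * n_seg,
            "graphoelement": np.zeros(n_seg, dtype=bool),
        }
    )


def detect_artifacts(
    recording: Recording,
    segments: pd.DataFrame,
    amplitude_threshold: float = 100.0,
    gradient_threshold: float = 50.0,
    flatline_range: float = 0.5,
) -> pd.DataFrame:
    """Flag 1-s segments violating amplitude/gradient/flatline rules.

    A segment is an artifact if on *any* EEG channel the absolute
    amplitude exceeds ``amplitude_threshold`` µV, a sample-to-sample jump
    exceeds ``gradient_threshold`` µV, or the channel is flat (range
    below ``flatline_range`` µV over the second).
    """
    fs = int(round(recording.sampling_rate))
    eeg = recording.signals[recording.eeg_indices]
    out = segments.copy()
    reasons = []
    flags = np.zeros(len(out), dtype=bool)
    for i, start in enumerate(out["start_sample"].to_numpy()):
        seg = eeg[:, start : start + fs]
        why = []
        if np.abs(seg).max() > amplitude_threshold:
            why.append("amplitude")
        if np.abs(np.diff(seg, axis=1)).max() > gradient_threshold:
            why.append("gradient")
        if (seg.max(axis=1) - seg.min(axis=1)).min() < flatline_range:
            why.append("flatline")
        flags[i] = bool(why)
        reasons.append(",".join(why))
    out["artifact"] = out["artifact"].to_numpy() | flags
    prior = out["artifact_reason"].to_numpy(dtype=object)
    out["artifact_reason"] = [
        ",".join(filter(None, [p, r])) for p, r in zip(prior, reasons)
    ]
    return out


def remove_stereotyped_artifacts(
    recording: Recording,
    correlation_threshold: float = 0.6,
    seed: int = 0,
    max_iter: int = 1000,
) -> Recording:
    """ICA-based removal of blink / eye-movement / cardioballistic leakage.

    EEG channels are decomposed with FastICA; components whose time
    course correlates with the EOG or ECG channel beyond
    ``correlation_threshold`` (absolute Pearson r) are zeroed before
    reconstruction.  EOG and ECG channels pass through unchanged.
    """
    from sklearn.decomposition import FastICA

    fs = recording.sampling_rate
    if recording.n_samples < 60 * fs:
        raise ValueError("need at least 60 s of data for ICA")
    if recording.eog_index is None or recording.ecg_index is None:
        raise ValueError("EOG and ECG channels are required for component scoring")

    eeg_idx = recording.eeg_indices
    X = recording.signals[eeg_idx].T  # samples × channels
    ica = FastICA(
        n_components=len(eeg_idx),
        whiten="unit-variance",
        max_iter=max_iter,
        tol=1e-4,
        random_state=seed,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sources = ica.fit_transform(X)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "ICA decomposition failed (rank-deficient data); "
            "retry on a channel subset"
        ) from exc

    # band-split EOG references: slow band captures eye movements/drift,
    # the faster band blinks — a blink component correlates weakly with
    # raw EOG whenever slow activity dominates the reference variance
    eog = recording.signals[recording.eog_index]
    sos_slow = signal.butter(3, (0.1, 1.0), btype="bandpass", fs=fs, output="sos")
    sos_fast = signal.butter(3, (1.0, 15.0), btype="bandpass", fs=fs, output="sos")
    refs = np.vstack(
        [
            signal.sosfiltfilt(sos_slow, eog),
            signal.sosfiltfilt(sos_fast, eog),
            recording.signals[recording.ecg_index],
        ]
    )
    refs_c = refs - refs.mean(axis=1, keepdims=True)
    src_c = sources - sources.mean(axis=0, keepdims=True)
    denom = np.sqrt(
        (src_c**2).sum(axis=0)[:, None] * (refs_c**2).sum(axis=1)[None, :]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(src_c.T @ refs_c.T) / denom
    corr = np.nan_to_num(corr)
    exclude = np.where(corr.max(axis=1) > correlation_threshold)[0]
    logger.info(
        "ICA: excluding %d of %d components (|r| > %.2f with EOG/ECG)",
        len(exclude),
        sources.shape[1],
        correlation_threshold,
    )
    kept = sources.copy()
    kept[:, exclude] = 0.0
    cleaned = kept @ ica.mixing_.T + ica.mean_

    out = recording.signals.copy()
    out[eeg_idx] = cleaned.T
    return recording.copy_with(out)


def _moving_rms(x: np.ndarray, win: int) -> np.ndarray:
    kernel = np.hanning(win + 2)[1:-1]
    kernel /= kernel.sum()
    return np.sqrt(np.maximum(signal.fftconvolve(x**2, kernel, mode="same"), 0.0))


def screen_graphoelements(
    recording: Recording,
    segments: pd.DataFrame,
    spindle_band: tuple[float, float] = (12.0, 16.0),
    spindle_multiplier: float = 2.0,
    spindle_min_duration: float = 0.5,
    spindle_max_duration: float = 3.0,
    spindle_min_amplitude: float = 10.0,
    kcomplex_p2p: float = 100.0,
    kcomplex_duration: tuple[float, float] = (0.5, 1.5),
    channels: tuple[str, ...] = ROI_CENTRAL,
) -> pd.DataFrame:
    """Flag segments containing sleep spindles or K-complexes.

    Spindles: the sigma-band (12–16 Hz) RMS envelope on a central channel
    exceeds ``spindle_multiplier`` × its recording-wide median — and an
    absolute floor of ``spindle_min_amplitude`` µV RMS — for at least
    ``spindle_min_duration`` s.  Exceedances longer than
    ``spindle_max_duration`` s are rejected as sustained fast background
    activity rather than spindle transients.  K-complexes: a biphasic slow
    deflection larger than ``kcomplex_p2p`` µV peak-to-peak whose
    positive and negative lobes together span 0.5–1.5 s.  Flagged
    segments become eligible for vigilance stage C.
    """
    fs = int(round(recording.sampling_rate))
    flagged = np.zeros(len(segments), dtype=bool)
    starts = segments["start_sample"].to_numpy()
    min_run = int(spindle_min_duration * fs)

    sos_sigma = signal.butter(4, spindle_band, btype="bandpass", fs=fs, output="sos")
    sos_slow = signal.butter(4, (0.5, 4.0), btype="bandpass", fs=fs, output="sos")

    # events overlapping artifact-flagged segments are artifact energy,
    # not graphoelements
    artifact = segments["artifact"].to_numpy()

    def mark(i0: int, i1: int) -> None:
        sel = (starts + fs > i0) & (starts < i1)
        if not artifact[sel].any():
            flagged[sel] = True

    for lab in channels:
        if lab not in recording.channel_labels:
            continue
        x = recording.get_channel(lab)
        # --- spindles ---
        env = _moving_rms(signal.sosfiltfilt(sos_sigma, x), min_run)
        thresh = max(spindle_multiplier * np.median(env), spindle_min_amplitude)
        above = env > thresh
        max_run = int(spindle_max_duration * fs)
        edges = np.flatnonzero(np.diff(above.astype(int)))
        bounds = np.concatenate([[0], edges + 1, [len(above)]])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if above[b0] and min_run <= b1 - b0 <= max_run:
                mark(b0, b1)
        # --- K-complexes ---
        slow = signal.sosfiltfilt(sos_slow, x)
        lobe_floor = 0.4 * kcomplex_p2p
        pos, _ = signal.find_peaks(slow, height=lobe_floor)
        neg, _ = signal.find_peaks(-slow, height=lobe_floor)
        for p in pos:
            if not len(neg):
                break
            q = neg[np.argmin(np.abs(neg - p))]
            gap = abs(int(q) - int(p)) / fs
            p2p = slow[p] + (-slow[q])
            lo, hi = kcomplex_duration
            if p2p > kcomplex_p2p and lo / 2 <= gap <= hi:
                mark(min(p, q), max(p, q) + 1)
    out = segments.copy()
    out["graphoelement"] = out["graphoelement"].to_numpy() | flagged
    return out


def preprocess(
    recording: Recording,
    run_ica: bool = True,
    ica_seed: int = 0,
    **artifact_kwargs,
) -> tuple[Recording, pd.DataFrame]:
    """Full chain: filter → (ICA) → segment → artifact flags → graphoelements."""
    filtered = bandpass_notch(recording)
    if run_ica:
        filtered = remove_stereotyped_artifacts(filtered, seed=ica_seed)
    table = segment(filtered)
    table = detect_artifacts(filtered, table, **artifact_kwargs)
    table = screen_graphoelements(filtered, table)
    return filtered, table
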