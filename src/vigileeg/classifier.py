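"""Per-second vigilance staging from sensor-space band power.

A channel-space region-of-interest approximation of the VIGALL staging
logic: per artifact-free 1-s segment the classifier computes posterior
and frontal alpha power, all-channel delta-theta power and an EOG slow
eye movement (SEM) flag, normalizes against per-recording adaptive
thresholds, and applies a fixed decision list::

    1. graphoelement flag                              → C
    2. delta-theta above threshold and above alpha     → B2/3
    3. posterior alpha above threshold                 → A1/A2/A3 by the
       frontal/posterior alpha ratio (anterior shift)
    4. otherwise: SEM present → B1, else → 0

Source localization of the original tool is deliberately not replicated;
the anterior-posterior alpha shift that defines the A-substages survives
in sensor space, and all region-of-interest channel sets and thresholds
are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .channels import ROI_ALPHA_FRONTAL, ROI_ALPHA_POSTERIOR
from .recording import Recording
from .stages import (
    ARTIFACT,
    STAGE_0,
    STAGE_A1,
    STAGE_A2,
    STAGE_A3,
    STAGE_B1,
    STAGE_B23,
    STAGE_C,
)

logger = logging.getLogger(__name__)

ALPHA_BAND = (8.0, 12.0)
DELTA_THETA_BAND = (2.0, 7.0)
TOTAL_BAND = (0.5, 70.0)
SEM_BAND = (0.1, 1.0)


def _segment_psd(segments: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered periodogram of 1-s segments, 1 Hz resolution.

    ``segments`` has shape (..., n_samples); returns (freqs, psd) where
    psd integrates to signal power (µV²) over frequency.
    """
    freqs, psd = signal.periodogram(
        segments, fs=fs, window="hann", detrend="constant", axis=-1
    )
    return freqs, psd


def band_power_from_psd(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    df = freqs[1] - freqs[0]
    sel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    return psd[..., sel].sum(axis=-1) * df


def compute_band_power(
    segment: np.ndarray,
    band: tuple[float, float],
    fs: float = 200.0,
) -> float:
    """Mean band power (µV²) of a 1-s segment over its channels.

    ``segment`` is (n_channels, n_samples) or (n_samples,).  Power is the
    Hann-tapered periodogram integrated over ``band`` (edges inclusive at
    the 1 Hz grid), averaged across channels.
    """
    if band[1] > fs / 2:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {fs / 2}")
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    freqs, psd = _segment_psd(seg, fs)
    return float(band_power_from_psd(freqs, psd, band).mean())


def detect_sem(
    eog: np.ndarray,
    segment_index: int,
    fs: float = 200.0,
    p2p_threshold: float = 100.0,
    window: float = 3.0,
) -> bool:
    """Slow-eye-movement flag for one 1-s segment.

    True iff the 0.1–1 Hz filtered EOG has peak-to-peak amplitude above
    ``p2p_threshold`` µV in a ``window``-s window centred on the segment.
    """
    slow = _slow_eog(eog, fs)
    return bool(_sem_flags(slow, fs, 1, segment_index, p2p_threshold, window)[0])


def _slow_eog(eog: np.ndarray, fs: float) -> np.ndarray:
    sos = signal.butter(3, SEM_BAND, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(eog, dtype=float))


def _sem_window_p2p(
    slow: np.ndarray, fs: float, n_segments: int, window: float = 3.0
) -> np.ndarray:
    fsi = int(round(fs))
    half = (window - 1.0) / 2.0
    out = np.empty(n_segments)
    for s in range(n_segments):
        i0 = max(0, int((s - half) * fsi))
        i1 = min(len(slow), int((s + 1 + half) * fsi))
        out[s] = np.ptp(slow[i0:i1]) if i1 > i0 else 0.0
    return out


def _sem_flags(slow, fs, n_segments, first_segment, p2p_threshold, window):
    fsi = int(round(fs))
    flags = np.zeros(n_segments, dtype=bool)
    half = (window - 1.0) / 2.0
    for k in range(n_segments):
        s = first_segment + k
        i0 = max(0, int((s - half) * fsi))
        i1 = min(len(slow), int((s + 1 + half) * fsi))
        flags[k] = i1 > i0 and np.ptp(slow[i0:i1]) > p2p_threshold
    return flags


@dataclass
class StageThresholds:
    """Per-recording adaptive decision thresholds (µV² / µV)."""

    alpha_threshold: float
    delta_theta_threshold: float
    a_substage_ratios: tuple[float, float] = (1.0, 1.5)
    sem_p2p_threshold: float = 100.0

    def __post_init__(self) -> None:
        r1, r2 = self.a_substage_ratios
        if not r1 < r2:
            raise ValueError("substage ratio cut points must satisfy r1 < r2")
        if min(self.alpha_threshold, self.delta_theta_threshold) <= 0:
            raise ValueError("thresholds must be positive")


def extract_features(
    recording: Recording,
    segments: pd.DataFrame,
    posterior_channels: tuple[str, ...] = ROI_ALPHA_POSTERIOR,
    frontal_channels: tuple[str, ...] = ROI_ALPHA_FRONTAL,
    sem_p2p_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-segment spectral and EOG features for the staging decision list.

    Columns: ``alpha_posterior``, ``alpha_frontal``, ``delta_theta``,
    ``total_power`` (µV²), ``sem_p2p`` (µV, 3-s window) and
    ``sem_present`` when an absolute SEM threshold is supplied.
    """
    fs = recording.sampling_rate
    fsi = int(round(fs))
    starts = segments["start_sample"].to_numpy()
    n_seg = len(starts)

    idx = np.array(
        [starts + k for k in range(fsi)]
    ).T  # (n_seg, fs) sample indices
    eeg_idx = recording.eeg_indices
    eeg = recording.signals[eeg_idx]
    seg_block = eeg[:, idx]  # (n_eeg, n_seg, fs)
    freqs, psd = _segment_psd(seg_block, fs)

    labels = [recording.channel_labels[i] for i in eeg_idx]
    post = [labels.index(c) for c in posterior_channels if c in labels]
    front = [labels.index(c) for c in frontal_channels if c in labels]

    alpha = band_power_from_psd(freqs, psd, ALPHA_BAND)
    dt = band_power_from_psd(freqs, psd, DELTA_THETA_BAND)
    total = band_power_from_psd(freqs, psd, TOTAL_BAND)

    feats = pd.DataFrame(
        {
            "segment": segments["segment"].to_numpy(),
            "alpha_posterior": alpha[post].mean(axis=0),
            "alpha_frontal": alpha[front].mean(axis=0),
            "delta_theta": dt.mean(axis=0),
            "total_power": total.mean(axis=0),
        }
    )

    eog_i = recording.eog_index
    if eog_i is None:
        logger.warning(
            "no EOG channel: slow-eye-movement detection disabled; "
            "stages 0 and B1 collapse to 0"
        )
        feats["sem_p2p"] = 0.0
    else:
        slow = _slow_eog(recording.signals[eog_i], fs)
        feats["sem_p2p"] = _sem_window_p2p(slow, fs, n_seg)
    if sem_p2p_threshold is not None:
        feats["sem_present"] = feats["sem_p2p"] > sem_p2p_threshold
    return feats


def fit_thresholds(
    features: pd.DataFrame,
    artifact_free: np.ndarray | None = None,
    alpha_multiplier: float = 2.0,
    delta_theta_multiplier: float = 2.0,
    a_substage_ratios: tuple[float, float] = (1.0, 1.5),
    sem_multiplier: float = 5.0,
    reference_quantile: float = 0.25,
) -> StageThresholds:
    """Adaptive per-recording thresholds from artifact-free segments.

    Each threshold is a multiple of a low reference quantile (default
    the 25th percentile) of the respective feature — a noise-floor
    statistic.  A floor quantile is preferred over the median because in
    alpha-rich recordings (the clinical norm: relaxed wakefulness can
    occupy well over half of a resting recording) the median lands
    inside the A-stage alpha mass and the threshold overshoots.  All
    statistics are scale-equivariant, so staging is invariant under
    global amplitude rescaling.
    """
    if artifact_free is not None:
        features = features.loc[~np.asarray(artifact_free)]
    if len(features) < 60:
        raise ValueError(
            f"need at least 60 artifact-free segments to fit thresholds, "
            f"got {len(features)}"
        )
    q = reference_quantile

    def ref(col: str) -> float:
        return float(features[col].quantile(q))

    return StageThresholds(
        alpha_threshold=alpha_multiplier * ref("alpha_posterior"),
        delta_theta_threshold=delta_theta_multiplier * ref("delta_theta"),
        a_substage_ratios=a_substage_ratios,
        sem_p2p_threshold=sem_multiplier * ref("sem_p2p"),
    )


def classify_segment(
    features: pd.Series | dict,
    thresholds: StageThresholds,
    graphoelement: bool = False,
) -> str:
    """Stage one artifact-free segment by the decision list (first match wins)."""
    if graphoelement:
        return STAGE_C
    alpha_post = features["alpha_posterior"]
    dt = features["delta_theta"]
    if dt > thresholds.delta_theta_threshold and dt > alpha_post:
        return STAGE_B23
    if alpha_post > thresholds.alpha_threshold:
        rho = features["alpha_frontal"] / alpha_post
        r1, r2 = thresholds.a_substage_ratios
        if rho <= r1:
            return STAGE_A1
        if rho <= r2:
            return STAGE_A2
        return STAGE_A3
    if "sem_present" in features:
        sem = bool(features["sem_present"])
    else:
        sem = features["sem_p2p"] > thresholds.sem_p2p_threshold
    return STAGE_B1 if sem else STAGE_0


def classify_recording(
    recording: Recording,
    segments: pd.DataFrame,
    thresholds: StageThresholds | None = None,
    **threshold_kwargs,
) -> pd.DataFrame:
    """Stage every segment of a preprocessed recording.

    Returns the segment table with ``stage`` and feature columns added;
    artifact segments carry the ``ARTIFACT`` symbol.  When ``thresholds``
    is omitted they are fitted adaptively on the artifact-free segments.
    """
    feats = extract_features(recording, segments)
    artifact = segments["artifact"].to_numpy()
    if thresholds is None:
        thresholds = fit_thresholds(feats, artifact_free=artifact, **threshold_kwargs)
    grapho = segments["graphoelement"].to_numpy()
    labels = []
    for i in range(len(segments)):
        if artifact[i]:
            labels.append(ARTIFACT)
        else:
            labels.append(
                classify_segment(feats.iloc[i], thresholds, graphoelement=grapho[i])
            )
    out = segments.copy()
    for col in ("alpha_posterior", "alpha_frontal", "delta_theta",
                "total_power", "sem_p2p"):
        out[col] = feats[col].to_numpy()
    out["sem_present"] = feats["sem_p2p"].to_numpy() > thresholds.sem_p2p_threshold
    out["stage"] = labels
    return out


def write_stage_table(table: pd.DataFrame, path) -> None:
    """Emit the per-segment stage sequence as TSV (1-based segment index)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_stage_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
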