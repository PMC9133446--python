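"""Synthetic resting-state EEG with a known latent vigilance trajectory.

The generator draws a per-second vigilance stage sequence from a
first-order Markov chain and renders it as 27-channel EEG/EOG/ECG:
each EEG channel is a sum of band-limited Gaussian noise components
(delta-theta 2–7 Hz, alpha 8–12 Hz, beta 13–30 Hz) whose per-second RMS
follows a stage × scalp-region gain table, cross-faded at second
boundaries with a raised-cosine envelope.  The EOG channel carries slow
eye movements (SEM) during drowsy (B) seconds and blink transients
during wake (0/A) seconds; the ECG channel carries a QRS-like impulse
train.  Gross high-amplitude artifact seconds are injected at a
configurable rate and recorded in the ground truth, so every downstream
stage (artifact screening, ICA, staging, metrics) can be validated
against known labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .channels import DEFAULT_MONTAGE, REGIONS, region_of
from .recording import Recording
from .stages import (
    STAGE_0,
    STAGE_A1,
    STAGE_A2,
    STAGE_A3,
    STAGE_B1,
    STAGE_B23,
    STAGE_C,
    STAGE_INDEX,
    STAGES,
    A_STAGES,
    B_STAGES,
)
from . import edf as edfio

#: Band edges (Hz) of the three noise components, inclusive.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta_theta": (2.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}

#: Default stationary stage mix of the transition chain.  Stage C is
#: absent by default (sleep onset is not reached in a 20-min resting
#: recording of an awake participant).
DEFAULT_STATIONARY: dict[str, float] = {
    STAGE_0: 0.18,
    STAGE_A1: 0.26,
    STAGE_A2: 0.08,
    STAGE_A3: 0.05,
    STAGE_B1: 0.14,
    STAGE_B23: 0.29,
    STAGE_C: 0.0,
}

# Per-stage RMS gains in µV, per band and region.  A scalar stands for
# "same gain in every region".  The A-substage alpha topography encodes
# the posterior-to-anterior alpha shift; B2/3 is delta-theta dominant;
# stage 0 is low-amplitude and beta-dominant.
DEFAULT_STAGE_SPECTRA: dict[str, dict[str, object]] = {
    STAGE_0: {"delta_theta": 4.0, "alpha": 4.0, "beta": 8.0},
    STAGE_A1: {
        "delta_theta": 4.0,
        "alpha": {"frontal": 5.0, "central": 12.0, "posterior": 20.0},
        "beta": 3.0,
    },
    STAGE_A2: {
        "delta_theta": 4.0,
        "alpha": {"frontal": 14.0, "central": 12.0, "posterior": 12.0},
        "beta": 3.0,
    },
    STAGE_A3: {
        "delta_theta": 4.0,
        "alpha": {"frontal": 16.0, "central": 12.0, "posterior": 10.0},
        "beta": 3.0,
    },
    STAGE_B1: {"delta_theta": 5.0, "alpha": 3.0, "beta": 3.0},
    STAGE_B23: {"delta_theta": 18.0, "alpha": 4.0, "beta": 3.0},
    STAGE_C: {"delta_theta": 20.0, "alpha": 4.0, "beta": 3.0},
}


def default_transition_matrix(
    stationary: dict[str, float] | None = None, stickiness: float = 0.9
) -> np.ndarray:
    """Sticky chain ``T = s·I + (1−s)·1πᵀ`` with stationary vector π.

    The construction makes the stationary distribution explicit (it is
    exactly π) and gives geometric stage dwell times of roughly
    ``1/((1−s)(1−π_i))`` seconds — about 12 s at the defaults, i.e. the
    slow waxing and waning of arousal the staging operates on.
    """
    if stationary is None:
        stationary = DEFAULT_STATIONARY
    pi = np.array([stationary.get(s, 0.0) for s in STAGES], dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
        raise ValueError("stationary mix must be a probability vector")
    T = stickiness * np.eye(len(STAGES)) + (1.0 - stickiness) * pi[None, :]
    return T / T.sum(axis=1, keepdims=True)


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix by eigen-analysis."""
    w, v = np.linalg.eig(transition_matrix.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _normalize_spectra(spectra) -> dict[str, dict[str, dict[str, float]]]:
    out: dict[str, dict[str, dict[str, float]]] = {}
    for stage in STAGES:
        try:
            bands = spectra[stage]
        except KeyError:
            raise ValueError(f"stage_spectra missing stage {stage!r}") from None
        out[stage] = {}
        for band in BAND_EDGES:
            gain = bands.get(band, 0.0)
            if np.isscalar(gain):
                gain = {r: float(gain) for r in REGIONS}
            else:
                gain = {r: float(gain[r]) for r in REGIONS}
            if any(g < 0 for g in gain.values()):
                raise ValueError("band gains must be non-negative")
            out[stage][band] = gain
    return out


@dataclass
class SimulationConfig:
    """Parameters of one synthetic 20-min resting-state recording.

    Rates are events per minute; gains are µV RMS.  ``sem_rate`` applies
    per minute of drowsy (B-stage) time, ``blink_rate`` per minute of
    wake (0/A) time, ``artifact_rate`` per minute of recording.
    """

    duration: float = 1200.0
    sampling_rate: float = 200.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    initial_distribution: np.ndarray | None = None
    stage_spectra: dict = field(
        default_factory=lambda: {
            s: dict(b) for s, b in DEFAULT_STAGE_SPECTRA.items()
        }
    )
    sem_rate: float = 10.0
    blink_rate: float = 12.0
    artifact_rate: float = 1.0
    seed: int = 0
    # secondary knobs
    blink_leakage: float = 0.6      # blink waveform gain into Fp1/Fp2
    ecg_leakage: float = 0.05       # ECG gain into every EEG channel
    heart_rate: float = 70.0        # beats/min
    eog_noise_rms: float = 8.0      # broadband EOG floor, µV RMS
    eog_drift_rms: float = 5.0     # slow (0.1–1 Hz) EOG floor, µV RMS
    artifact_peak: tuple[float, float] = (600.0, 1000.0)  # µV burst peaks
    spindle_rms: float = 15.0       # 13.5 Hz sigma burst during C seconds

    def validate(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.shape != (len(STAGES), len(STAGES)):
            raise ValueError("transition_matrix must be 7×7 over the stage order")
        if (T < 0).any() or np.abs(T.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition_matrix rows must be non-negative and sum to 1")
        if self.initial_distribution is not None:
            p0 = np.asarray(self.initial_distribution, dtype=float)
            if p0.shape != (len(STAGES),) or (p0 < 0).any() or abs(p0.sum() - 1) > 1e-9:
                raise ValueError("initial_distribution must be a 7-vector summing to 1")
        n_samples = self.duration * self.sampling_rate
        if abs(n_samples - round(n_samples)) > 1e-6:
            raise ValueError("duration × sampling_rate must be an integer sample count")
        if min(self.sem_rate, self.blink_rate, self.artifact_rate) < 0:
            raise ValueError("event rates must be non-negative")
        _normalize_spectra(self.stage_spectra)

    @property
    def n_seconds(self) -> int:
        return int(round(self.duration))


@dataclass
class GroundTruth:
    """Latent state of a synthetic recording, at 1-s resolution."""

    stage_labels: list[str]
    sem_events: list[tuple[float, float]]
    artifact_seconds: set[int]
    blink_times: list[float]


def sample_stage_trajectory(config: SimulationConfig) -> list[str]:
    """Draw the per-second stage sequence from the configured Markov chain."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    T = np.asarray(config.transition_matrix, dtype=float)
    if config.initial_distribution is None:
        p0 = stationary_distribution(T)
    else:
        p0 = np.asarray(config.initial_distribution, dtype=float)
    n = config.n_seconds
    cum = np.cumsum(T, axis=1)
    u = rng.random(n)
    states = np.empty(n, dtype=int)
    states[0] = int(np.searchsorted(np.cumsum(p0), u[0], side="right"))
    for t in range(1, n):
        states[t] = int(np.searchsorted(cum[states[t - 1]], u[t], side="right"))
    states = np.minimum(states, len(STAGES) - 1)
    return [STAGES[s] for s in states]


def _band_noise(rng, n_samples: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _crossfade_envelope(per_second: np.ndarray, fs: int, fade: float = 0.05) -> np.ndarray:
    """Per-sample gain envelope with raised-cosine cross-fade at boundaries."""
    env = np.repeat(per_second, fs)
    k = 2 * int(round(fade * fs)) + 1
    kernel = np.hanning(k + 2)[1:-1]
    kernel /= kernel.sum()
    return signal.fftconvolve(env, kernel, mode="same")


def _stage_runs(labels: list[str], members: frozenset[str]) -> list[tuple[int, int]]:
    """Maximal runs [start, end) of seconds whose stage is in `members`."""
    runs, start = [], None
    for i, lab in enumerate(labels):
        inside = lab in members
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(labels)))
    return runs


def synthesize_recording(
    trajectory: list[str], config: SimulationConfig
) -> tuple[Recording, GroundTruth]:
    """Render a stage trajectory as a multichannel µV recording."""
    config.validate()
    for sec, lab in enumerate(trajectory):
        if lab not in STAGE_INDEX:
            raise ValueError(f"unknown stage label {lab!r} at second {sec}")
    fs = int(round(config.sampling_rate))
    n_sec = len(trajectory)
    n_samp = n_sec * fs
    rng = np.random.default_rng([config.seed, 9151])
    spectra = _normalize_spectra(config.stage_spectra)
    labels = list(config.montage)
    stage_idx = np.array([STAGE_INDEX[s] for s in trajectory])

    eeg_labels = [lab for lab in labels if lab not in ("EOG", "ECG")]
    signals = np.zeros((len(labels), n_samp))

    # per-(stage, band, region) RMS lookup → per-second gain arrays
    for ci, lab in enumerate(labels):
        if lab in ("EOG", "ECG"):
            continue
        region = region_of(lab)
        chan = np.zeros(n_samp)
        for band, (lo, hi) in BAND_EDGES.items():
            gains = np.array(
                [spectra[s][band][region] for s in STAGES], dtype=float
            )[stage_idx]
            if not gains.any():
                continue
            env = _crossfade_envelope(gains, fs)
            chan += env * _band_noise(rng, n_samp, fs, lo, hi)
        signals[ci] = chan

    # sleep-spindle bursts on central channels during C seconds
    if config.spindle_rms > 0 and STAGE_C in trajectory:
        t = np.arange(fs) / fs
        burst = np.sin(2 * np.pi * 13.5 * t) * np.hanning(fs)
        burst *= config.spindle_rms / np.sqrt(np.mean(burst**2))
        for sec, lab in enumerate(trajectory):
            if lab == STAGE_C:
                for ch in ("C3", "C4", "Cz"):
                    if ch in labels:
                        signals[labels.index(ch), sec * fs : (sec + 1) * fs] += burst

    t_all = np.arange(n_samp) / fs

    # ---- EOG ----------------------------------------------------------
    eog = np.zeros(n_samp)
    if "EOG" in labels:
        if config.eog_noise_rms > 0:
            eog += config.eog_noise_rms * _band_noise(rng, n_samp, fs, 0.5, 15.0)
        if config.eog_drift_rms > 0:
            eog += config.eog_drift_rms * _band_noise(rng, n_samp, fs, 0.1, 1.0)

    sem_events: list[tuple[float, float]] = []
    b_runs = _stage_runs(trajectory, B_STAGES)
    b_seconds = sum(e - s for s, e in b_runs)
    if b_seconds and config.sem_rate > 0:
        n_events = rng.poisson(config.sem_rate * b_seconds / 60.0)
        run_weights = np.array([e - s for s, e in b_runs], dtype=float)
        run_weights /= run_weights.sum()
        for _ in range(n_events):
            s, e = b_runs[rng.choice(len(b_runs), p=run_weights)]
            start = rng.uniform(s, max(s, e - 1))
            dur = min(rng.uniform(3.0, 8.0), e - start)
            if dur < 1.5:
                continue
            f = rng.uniform(0.2, 0.6)
            amp = rng.uniform(140.0, 200.0) / 2.0  # p2p → amplitude
            i0, i1 = int(start * fs), int((start + dur) * fs)
            tt = t_all[i0:i1] - start
            taper = signal.windows.tukey(i1 - i0, alpha=0.3)
            eog[i0:i1] += amp * np.sin(2 * np.pi * f * tt) * taper
            sem_events.append((start, start + dur))

    blink_times: list[float] = []
    wake_seconds = [i for i, lab in enumerate(trajectory) if lab in A_STAGES | {STAGE_0}]
    if wake_seconds and config.blink_rate > 0:
        n_blinks = rng.poisson(config.blink_rate * len(wake_seconds) / 60.0)
        blink_targets = {"Fp1": 1.0, "Fp2": 1.0, "F3": 0.4, "F4": 0.4}
        for _ in range(n_blinks):
            sec = int(rng.choice(wake_seconds))
            width = rng.uniform(0.2, 0.35)  # blink duration, s
            center = sec + rng.uniform(width / 2, 1.0 - width / 2)
            amp = rng.uniform(180.0, 220.0)
            half = int(width * fs / 2)
            i0 = max(0, int(center * fs) - half)
            i1 = min(n_samp, int(center * fs) + half)
            pulse = amp * np.hanning(i1 - i0)
            eog[i0:i1] += pulse
            if config.blink_leakage > 0:
                for ch, w in blink_targets.items():
                    if ch in labels:
                        signals[labels.index(ch), i0:i1] += (
                            config.blink_leakage * w * pulse
                        )
            blink_times.append(center)
    if "EOG" in labels:
        signals[labels.index("EOG")] = eog

    # ---- ECG ----------------------------------------------------------
    if "ECG" in labels:
        ecg = np.zeros(n_samp)
        period = 60.0 / config.heart_rate
        qrs_w = int(0.08 * fs)
        tq = np.linspace(-1, 1, qrs_w)
        qrs = tq * np.exp(-(tq**2) * 8)  # biphasic QRS-like wavelet
        qrs *= 800.0 / np.abs(qrs).max()  # ±800 µV peak
        beat = rng.uniform(0, period)
        while beat < n_sec:
            i0 = int(beat * fs)
            i1 = min(n_samp, i0 + qrs_w)
            ecg[i0:i1] += qrs[: i1 - i0]
            beat += period * rng.uniform(0.95, 1.05)
        signals[labels.index("ECG")] = ecg
        if config.ecg_leakage > 0:
            # cardioballistic coupling is mechanically low-passed
            sos_cb = signal.butter(4, 15.0, btype="lowpass", fs=fs, output="sos")
            cardio = signal.sosfiltfilt(sos_cb, ecg)
            for ci, lab in enumerate(labels):
                if lab in eeg_labels:
                    signals[ci] += config.ecg_leakage * cardio

    # ---- gross artifacts ----------------------------------------------
    artifact_seconds: set[int] = set()
    if config.artifact_rate > 0:
        k = min(n_sec, rng.poisson(config.artifact_rate * n_sec / 60.0))
        secs = rng.choice(n_sec, size=k, replace=False)
        eeg_idx = [labels.index(lab) for lab in eeg_labels]
        for sec in np.sort(secs):
            burst = _band_noise(rng, fs, fs, 1.0, 10.0) * np.hanning(fs)
            peak = rng.uniform(*config.artifact_peak)
            burst *= peak / np.max(np.abs(burst))
            n_hit = max(8, len(eeg_idx) // 2)
            hit = rng.choice(eeg_idx, size=n_hit, replace=False)
            scales = rng.uniform(0.7, 1.0, size=n_hit)
            for ci, sc in zip(hit, scales):
                signals[ci, sec * fs : (sec + 1) * fs] += sc * burst
            artifact_seconds.add(int(sec))

    rec = Recording(
        signals=signals, sampling_rate=float(fs), channel_labels=labels
    )
    gt = GroundTruth(
        stage_labels=list(trajectory),
        sem_events=sem_events,
        artifact_seconds=artifact_seconds,
        blink_times=blink_times,
    )
    return rec, gt


def simulate(config: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Convenience wrapper: trajectory + rendering in one call."""
    return synthesize_recording(sample_stage_trajectory(config), config)


def write_recording(recording: Recording, ground_truth: GroundTruth, path) -> dict:
    """Write an EDF file plus a ground-truth TSV sidecar.

    ``path`` may be a directory (files named ``recording.edf`` /
    ``recording_stages.tsv``) or a basename without extension.
    """
    path = Path(path)
    if path.is_dir():
        base = path / "recording"
    else:
        base = path.with_suffix("") if path.suffix else path
        base.parent.mkdir(parents=True, exist_ok=True)
    edf_path = base.with_suffix(".edf")
    tsv_path = base.parent / (base.name + "_stages.tsv")
    edfio.write_edf(
        recording.signals,
        recording.sampling_rate,
        recording.channel_labels,
        edf_path,
    )
    n_sec = len(ground_truth.stage_labels)
    table = pd.DataFrame(
        {
            "second": np.arange(1, n_sec + 1),  # 1-based, reporting convention
            "stage": ground_truth.stage_labels,
            "artifact": [
                int(i in ground_truth.artifact_seconds) for i in range(n_sec)
            ],
        }
    )
    table.to_csv(tsv_path, sep="\t", index=False)
    return {"edf": edf_path, "stages": tsv_path}


def read_recording(edf_path) -> Recording:
    """Read an EDF file back into a µV :class:`Recording` (via mne)."""
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    return Recording(
        signals=raw.get_data() * 1e6,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def read_sidecar(tsv_path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t")
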