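"""In-memory container for a multichannel resting-state recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channels import ROLE_ECG, ROLE_EEG, ROLE_EOG, default_roles


@dataclass
class Recording:
    """A multichannel signal block in microvolts.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Signal matrix in µV.
    sampling_rate : float
        Samples per second.
    channel_labels : list of str
        One label per row of ``signals``.
    channel_roles : list of str, optional
        ``"EEG"``, ``"EOG"`` or ``"ECG"`` per channel; inferred from the
        labels when omitted.
    """

    signals: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    channel_roles: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a (channels, samples) matrix")
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signals.shape[0]} signal rows"
            )
        if self.channel_roles is None:
            self.channel_roles = default_roles(self.channel_labels)
        if len(self.channel_roles) != self.signals.shape[0]:
            raise ValueError("one role per channel required")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.signals[self.channel_index(label)]

    def indices_by_role(self, role: str) -> np.ndarray:
        return np.asarray(
            [i for i, r in enumerate(self.channel_roles) if r == role],
            dtype=int,
        )

    @property
    def eeg_indices(self) -> np.ndarray:
        return self.indices_by_role(ROLE_EEG)

    @property
    def eog_index(self) -> int | None:
        idx = self.indices_by_role(ROLE_EOG)
        return int(idx[0]) if idx.size else None

    @property
    def ecg_index(self) -> int | None:
        idx = self.indices_by_role(ROLE_ECG)
        return int(idx[0]) if idx.size else None

    def copy_with(self, signals: np.ndarray) -> "Recording":
        return replace(self, signals=np.asarray(signals, dtype=float))
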