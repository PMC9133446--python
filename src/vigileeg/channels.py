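"""Default 10/20 montage, channel roles and scalp-region groupings."""

from __future__ import annotations

#: 25 EEG channels of the extended 10/20 montage plus EOG and ECG,
#: in recording order.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "CP1", "CP2", "CP5", "CP6", "Fz", "Cz", "Pz",
    "FC5", "FC6", "T7", "T8", "FC1", "FC2",
)
DEFAULT_MONTAGE: tuple[str, ...] = EEG_CHANNELS + ("EOG", "ECG")

ROLE_EEG = "EEG"
ROLE_EOG = "EOG"
ROLE_ECG = "ECG"


def default_roles(labels) -> list[str]:
    """Infer channel roles from labels (EOG/ECG by name, EEG otherwise)."""
    roles = []
    for lab in labels:
        up = lab.upper()
        if "EOG" in up:
            roles.append(ROLE_EOG)
        elif "ECG" in up or "EKG" in up:
            roles.append(ROLE_ECG)
        else:
            roles.append(ROLE_EEG)
    return roles


#: Scalp regions used by the synthetic generator's per-region band gains.
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
                "FC1", "FC2", "FC5", "FC6"),
    "central": ("C3", "C4", "Cz", "T7", "T8", "CP1", "CP2", "CP5", "CP6"),
    "posterior": ("P3", "P4", "Pz", "O1", "O2"),
}

#: Region-of-interest channel sets used by the vigilance classifier in
#: sensor space (a channel-space surrogate for source-level band analysis).
ROI_ALPHA_POSTERIOR: tuple[str, ...] = ("P3", "P4", "Pz", "O1", "O2")
ROI_ALPHA_FRONTAL: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "Fz")
ROI_CENTRAL: tuple[str, ...] = ("C3", "C4", "Cz")


def region_of(label: str) -> str:
    for region, chans in REGIONS.items():
        if label in chans:
            return region
    raise KeyError(f"channel {label!r} has no region assignment")
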