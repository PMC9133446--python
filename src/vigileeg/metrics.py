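"""Per-recording vigilance outcomes.

Three summary measures per staged recording:

* **relative occurrence** — fraction of artifact-free 1-s segments per
  stage;
* **mean vigilance level** — average of the numeric arousal values
  (0 → 7 down to C → 1) over artifact-free segments, bounded by [1, 7];
* **arousal stability index** — an ordinal 1–8 score of how early and
  how deeply vigilance declines, evaluated on sliding 1-min interval
  labels (interval 1 = segments 1–60, interval 2 = segments 2–61, …)
  partitioned into three equal thirds of the recording.  Lower scores
  mean earlier arousal decline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stages import (
    ARTIFACT,
    STAGE_A1,
    STAGE_B1,
    STAGE_B23,
    STAGE_0,
    STAGE_INDEX,
    STAGE_VALUE,
    STAGES,
    UNSCORABLE,
    WAKE_STAGES,
)

#: Stability-index criteria in ascending score order: (score, stage set,
#: third index or None for "all intervals", required fraction, strict).
_STABILITY_CRITERIA = [
    (1, {STAGE_B23}, 0, 1 / 3, False),
    (2, {STAGE_B23}, 1, 1 / 3, False),
    (3, {STAGE_B23}, 2, 1 / 3, False),
    (4, {STAGE_B1}, 0, 1 / 3, False),
    (5, {STAGE_B1}, 1, 1 / 3, False),
    (6, {STAGE_B1}, 2, 1 / 3, False),
    (7, WAKE_STAGES, None, 2 / 3, False),
    (8, {STAGE_0, STAGE_A1}, None, 2 / 3, True),
]


@dataclass
class VigilanceSummary:
    """Occurrence fractions, mean vigilance and stability for one recording."""

    occurrence: dict[str, float]
    mean_vigilance: float
    stability_index: int
    n_artifact_free: int


def _clean_labels(labels) -> list[str]:
    labels = list(labels)
    for lab in labels:
        if lab != ARTIFACT and lab not in STAGE_INDEX:
            raise ValueError(f"unknown stage label {lab!r}")
    return labels


def relative_occurrence(labels) -> dict[str, float]:
    """Stage → fraction of artifact-free segments.

    ARTIFACT segments are excluded from numerator and denominator; the
    returned fractions cover all seven stages and sum to 1.
    """
    labels = _clean_labels(labels)
    clean = [lab for lab in labels if lab != ARTIFACT]
    if not clean:
        raise ValueError("no artifact-free segments")
    n = len(clean)
    return {s: sum(lab == s for lab in clean) / n for s in STAGES}


def mean_vigilance(labels) -> float:
    """Mean numeric arousal value over artifact-free segments (in [1, 7])."""
    labels = _clean_labels(labels)
    values = [STAGE_VALUE[lab] for lab in labels if lab != ARTIFACT]
    if not values:
        raise ValueError("no artifact-free segments")
    return float(np.mean(values))


def interval_labels(
    labels,
    interval_length: int = 60,
    min_scorable: int = 30,
) -> list[str]:
    """Sliding 1-min interval labels (modal stage per window).

    Interval ``k`` covers segments ``k..k+59`` (1-based).  The label is
    the modal stage among the window's artifact-free segments, ties
    broken toward the drowsier stage (lower numeric value); windows with
    fewer than ``min_scorable`` artifact-free segments are UNSCORABLE.
    """
    labels = _clean_labels(labels)
    n = len(labels)
    if n < interval_length:
        raise ValueError(
            f"need at least {interval_length} segments, got {n}"
        )
    n_stages = len(STAGES)
    onehot = np.zeros((n, n_stages), dtype=np.int32)
    for i, lab in enumerate(labels):
        if lab != ARTIFACT:
            onehot[i, STAGE_INDEX[lab]] = 1
    cum = np.vstack([np.zeros(n_stages, dtype=np.int32), np.cumsum(onehot, axis=0)])
    counts = cum[interval_length:] - cum[: n - interval_length + 1]  # windows × stages
    totals = counts.sum(axis=1)
    # tie-break toward the drowsier stage = the larger stage value index
    # within the STAGES ordering (later index is drowsier): scan reversed.
    order = np.arange(n_stages - 1, -1, -1)
    rev = counts[:, order]
    best_rev = np.argmax(rev, axis=1)
    modal = order[best_rev]
    out = []
    for k in range(counts.shape[0]):
        if totals[k] < min_scorable:
            out.append(UNSCORABLE)
        else:
            out.append(STAGES[modal[k]])
    return out


def _thirds(seq: list[str]) -> list[list[str]]:
    n = len(seq)
    cut1, cut2 = round(n / 3), round(2 * n / 3)
    return [seq[:cut1], seq[cut1:cut2], seq[cut2:]]


def _fraction(part: list[str], members: set[str]) -> float | None:
    scorable = [lab for lab in part if lab != UNSCORABLE]
    if not scorable:
        return None
    return sum(lab in members for lab in scorable) / len(scorable)


def arousal_stability_index(
    labels,
    order: str = "ascending",
    windowing: str = "thirds",
    use_intervals: bool = True,
) -> int:
    """Arousal stability score 1–8 (lower = earlier arousal decline).

    The timeline of 1-min interval labels (or raw segments when
    ``use_intervals`` is False) is split into three parts standing for
    the first/second/last ten minutes — equal thirds by default
    (``windowing="thirds"``) or literal 10-min windows
    (``windowing="minutes"``).  Criteria are evaluated in ascending score
    order by default, returning the first satisfied score:

    ====== =======================================================
    score  criterion
    ====== =======================================================
    1/2/3  ≥ 1/3 of the first/second/last part labelled B2/3
    4/5/6  ≥ 1/3 of the first/second/last part labelled B1
    7      ≥ 2/3 of all intervals labelled 0/A1/A2/A3
    8      > 2/3 of all intervals labelled 0 or A1
    ====== =======================================================

    ``order="descending"`` evaluates 8 first (the printed-table order).
    If no criterion matches, scores 4–6 are re-evaluated with B1 and
    B2/3 pooled; if still nothing matches the score is 7.
    """
    if order not in ("ascending", "descending"):
        raise ValueError("order must be 'ascending' or 'descending'")
    if use_intervals:
        seq = interval_labels(labels)
    else:
        seq = [lab for lab in _clean_labels(labels)]
        seq = [lab if lab != ARTIFACT else UNSCORABLE for lab in seq]
    scorable = [lab for lab in seq if lab != UNSCORABLE]
    if not scorable:
        raise ValueError("all intervals are unscorable")

    if windowing == "thirds":
        parts = _thirds(seq)
    elif windowing == "minutes":
        per = 600  # 10 min of 1-s starts
        parts = [seq[:per], seq[per : 2 * per], seq[2 * per :]]
        if not parts[2]:
            parts[2] = parts[1]  # 20-min recording: "last 10 min" = second window
    else:
        raise ValueError("windowing must be 'thirds' or 'minutes'")

    def satisfied(score, members, third, frac_req, strict) -> bool:
        if third is None:
            frac = _fraction(seq, members)
        else:
            frac = _fraction(parts[third], members)
        if frac is None:
            return False
        return frac > frac_req if strict else frac >= frac_req

    criteria = _STABILITY_CRITERIA
    if order == "descending":
        criteria = list(reversed(criteria))
    for crit in criteria:
        if satisfied(*crit):
            return crit[0]
    pooled = {STAGE_B1, STAGE_B23}
    for score, third in ((4, 0), (5, 1), (6, 2)):
        if satisfied(score, pooled, third, 1 / 3, False):
            return score
    return 7


def summarize(labels, **stability_kwargs) -> VigilanceSummary:
    """Occurrence, mean vigilance and stability index in one pass."""
    occ = relative_occurrence(labels)
    return VigilanceSummary(
        occurrence=occ,
        mean_vigilance=mean_vigilance(labels),
        stability_index=arousal_stability_index(labels, **stability_kwargs),
        n_artifact_free=sum(lab != ARTIFACT for lab in labels),
    )
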