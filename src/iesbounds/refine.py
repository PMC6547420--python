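"""Base-exact deletion calls from candidate intervals and clip profiles.

A structural-variant caller localizes a deletion only approximately; reads
spanning the junction are clipped (soft or hard) exactly at the breakpoint,
so the pileup of clip positions pinpoints it.  Each candidate end is
refined to the position inside a window around the prediction that carries
the highest clip count, subject to a per-(strain, contig) false-positive
threshold equal to the mean clip count over positions with at least one
clipped read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ClipProfile:
    """Per-position clipped-read counts for one strain on one contig."""

    strain: str
    contig: str
    counts: dict[int, int] = field(default_factory=dict)

    def nonzero_counts(self) -> list[int]:
        return [c for c in self.counts.values() if c > 0]


@dataclass(frozen=True)
class RefinedCall:
    """A base-exact deletion call with clip support at both ends."""

    strain: str
    contig: str
    A: int
    B: int
    support_A: int
    support_B: int
    source_id: str | None = None


class NoEvidenceError(ValueError):
    """A clip profile contains no position with clipped reads."""


def clip_profiles(clips: pd.DataFrame) -> dict[tuple[str, str], ClipProfile]:
    """Group a (strain, contig, pos, clip_count) table into ClipProfiles."""
    profiles: dict[tuple[str, str], ClipProfile] = {}
    for row in clips.itertuples(index=False):
        key = (row.strain, row.contig)
        prof = profiles.setdefault(key, ClipProfile(strain=row.strain, contig=row.contig))
        prof.counts[int(row.pos)] = prof.counts.get(int(row.pos), 0) + int(row.clip_count)
    return profiles


def compute_clip_threshold(profile: ClipProfile, include_zeros: bool = False) -> float:
    """Mean clip count per position — the false-positive removal threshold.

    By default the mean is over positions with count ≥ 1 (a pileup has no
    record for the overwhelmingly many untouched positions).  With
    include_zeros=True the denominator would need a contig length, so that
    mode instead averages over the recorded positions including explicit
    zeros.
    """
    values = (
        [c for c in profile.counts.values()]
        if include_zeros
        else profile.nonzero_counts()
    )
    if not values:
        raise NoEvidenceError(
            f"no clipped reads for strain {profile.strain} on {profile.contig}"
        )
    return sum(values) / len(values)


def _window_positions(
    predicted: int, profile: ClipProfile, window: int, threshold: float
) -> list[tuple[int, int]]:
    half = window // 2
    return [
        (p, c)
        for p, c in profile.counts.items()
        if abs(p - predicted) <= half and c >= threshold
    ]


def refine_end(
    predicted: int,
    profile: ClipProfile,
    window: int = 200,
    threshold: float = 0.0,
) -> int | None:
    """The position near `predicted` with the highest clip count, or None.

    Candidates are positions within ±window/2 of the prediction with count
    ≥ threshold.  Ties on count are broken by minimal distance to the
    prediction, then by the smaller coordinate.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    passing = _window_positions(predicted, profile, window, threshold)
    if not passing:
        return None
    return min(passing, key=lambda pc: (-pc[1], abs(pc[0] - predicted), pc[0]))[0]


def window_peaks(
    predicted: int,
    profile: ClipProfile,
    window: int = 200,
    threshold: float = 0.0,
) -> list[tuple[int, int]]:
    """All (position, count) pairs tied for the maximal count in the window.

    Equal clip maxima represent alternative boundaries; refine_calls keeps
    them all as separate forms.
    """
    passing = _window_positions(predicted, profile, window, threshold)
    if not passing:
        return []
    best = max(c for _, c in passing)
    return sorted((p, c) for p, c in passing if c == best)


def refine_calls(
    candidates: pd.DataFrame,
    clips: pd.DataFrame | Mapping[tuple[str, str], ClipProfile],
    window: int = 200,
    include_zeros: bool = False,
    drop_log: list | None = None,
) -> list[RefinedCall]:
    """Refine every candidate interval to base-exact deletion calls.

    A candidate yields a call iff both of its ends refine to a position
    passing the threshold and the refined interval is non-empty (A < B).
    When several positions tie for the clip maximum at an end, every
    resulting distinct (A, B) pair is kept as an alternative intra-strain
    form.  Dropped candidates are appended to `drop_log` (and logged) with
    a reason.
    """
    profiles = clips if isinstance(clips, Mapping) else clip_profiles(clips)
    thresholds = {key: compute_clip_threshold(p, include_zeros) for key, p in profiles.items()}

    calls: list[RefinedCall] = []
    seen: set[tuple[str, str, int, int]] = set()
    for row in candidates.itertuples(index=False):
        key = (row.strain, row.contig)
        if key not in profiles:
            raise KeyError(f"no clip profile for strain/contig {key}")
        prof = profiles[key]
        thr = thresholds[key]
        peaks_a = window_peaks(int(row.start), prof, window, thr)
        peaks_b = window_peaks(int(row.end), prof, window, thr)
        if not peaks_a or not peaks_b:
            _drop(drop_log, row, "no position passed the clip threshold at one end")
            continue
        emitted = False
        for a, ca in peaks_a:
            for b, cb in peaks_b:
                if a >= b:
                    continue
                ident = (row.strain, row.contig, a, b)
                if ident in seen:
                    continue
                seen.add(ident)
                calls.append(
                    RefinedCall(
                        strain=row.strain,
                        contig=row.contig,
                        A=a,
                        B=b,
                        support_A=ca,
                        support_B=cb,
                        source_id=getattr(row, "source_id", None) or None,
                    )
                )
                emitted = True
        if not emitted:
            _drop(drop_log, row, "refined ends crossed (A >= B)")
    return calls


def _drop(drop_log: list | None, row, reason: str) -> None:
    record = {
        "strain": row.strain,
        "contig": row.contig,
        "start": int(row.start),
        "end": int(row.end),
        "reason": reason,
    }
    logger.info("dropped candidate %s", record)
    if drop_log is not None:
        drop_log.append(record)
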