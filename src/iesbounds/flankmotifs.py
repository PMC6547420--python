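"""Flanking regulatory sequence (FRS) discovery around IES boundaries.

For each locus the W-bp (default 100) flank upstream of the A-end and the
reverse complement of the W-bp flank downstream of the B-end are extracted;
identical k-mers in the two processed flanks then correspond to inverted
repeats (IR) in genome orientation, while identical k-mers between the left
flank and the *un*-complemented right flank are direct repeats (DR).

Distances dA and dB run from the IES end to the motif copy's IES-proximal
base (0 = motif abuts the junction); pairs are kept when |dA − dB| does not
exceed a tolerance (default 10 bp).  A k-mer group's positional
*concentricity* is the interquartile range of its dA values; groups with
IQR ≤ 10 and ≥ 3 contributing pairs are flagged as candidate FRSs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import complement, revcomp
from .catalog import IESForm, IESLocus

logger = logging.getLogger(__name__)


class FlankExtractionError(ValueError):
    """A locus whose flanks cannot be extracted (boundary or missing reference)."""


@dataclass(frozen=True)
class FlankPair:
    """Processed flanks of one locus: upstream, and reverse-complemented downstream."""

    locus_id: str
    left: str  # W bases 5'→3' ending immediately before the A-end
    right_rc: str  # reverse complement of the W bases starting at the B-end
    A: int
    B: int

    @property
    def W(self) -> int:
        return len(self.left)


@dataclass(frozen=True)
class MotifPairHit:
    """One k-mer present in both flanks at junction-proximal distances dA/dB."""

    locus_id: str
    kmer: str
    dA: int
    dB: int
    orientation: str  # "IR" or "DR"

    @property
    def dist_diff(self) -> int:
        return abs(self.dA - self.dB)


# Field-facing aliases: an IRHit/DRHit is a MotifPairHit of that orientation.
IRHit = MotifPairHit
DRHit = MotifPairHit


@dataclass(frozen=True)
class ConcentricityStat:
    label: str
    count: int
    iqr: float
    median_dA: float
    iqr_dB: float
    median_dB: float
    selected: bool


def reference_form(locus: IESLocus, reference_strain: str | None = None) -> IESForm:
    """The form whose ends anchor distances: the reference strain's
    lexicographically smallest (A, B), or the overall smallest if no
    reference strain is designated."""
    forms = locus.forms_of([reference_strain]) if reference_strain else locus.forms
    if not forms:
        raise FlankExtractionError(
            f"{locus.locus_id}: no form for reference strain {reference_strain!r}"
        )
    return min(forms, key=lambda f: f.interval)


def extract_flanks(
    locus: IESLocus,
    sequences: Mapping[str, str],
    W: int = 100,
    reference_strain: str | None = None,
) -> FlankPair:
    """Upstream flank and reverse-complemented downstream flank of a locus."""
    ref = reference_form(locus, reference_strain)
    seq = sequences[locus.contig]
    if ref.A < W or ref.B + W > len(seq):
        raise FlankExtractionError(
            f"{locus.locus_id}: flank of {W} bp crosses a contig boundary"
        )
    return FlankPair(
        locus_id=locus.locus_id,
        left=seq[ref.A - W : ref.A].upper(),
        right_rc=revcomp(seq[ref.B : ref.B + W]).upper(),
        A=ref.A,
        B=ref.B,
    )


def _kmer_distances(flank: str, k: int, proximal_right: bool) -> dict[str, list[int]]:
    """Map k-mer → distances of its occurrences to the junction.

    With proximal_right=True the junction sits at the string's right end
    (the left flank and the reverse-complemented right flank), so a k-mer
    starting at index i lies at distance W − k − i; otherwise the junction
    is at the left end and the distance is i.  N-containing k-mers are
    skipped.
    """
    W = len(flank)
    out: dict[str, list[int]] = {}
    for i in range(W - k + 1):
        kmer = flank[i : i + k]
        if "N" in kmer:
            continue
        d = W - k - i if proximal_right else i
        out.setdefault(kmer, []).append(d)
    return out


def find_ir_pairs(fp: FlankPair, k: int = 5, max_dist_diff: int = 10) -> list[MotifPairHit]:
    """All inverted-repeat k-mer pairs with near-equal boundary distances.

    Because the downstream flank is stored reverse-complemented, a literal
    k-mer match between `left` and `right_rc` is an inverted repeat in
    genome coordinates.  Every qualifying (dA, dB) pair is returned.
    """
    if k > fp.W:
        raise ValueError("k exceeds flank width")
    left = _kmer_distances(fp.left, k, proximal_right=True)
    right = _kmer_distances(fp.right_rc, k, proximal_right=True)
    return _pair_up(fp.locus_id, left, right, max_dist_diff, "IR")


def find_dr_pairs(fp: FlankPair, k: int = 5, max_dist_diff: int = 10) -> list[MotifPairHit]:
    """As find_ir_pairs but matching the un-complemented downstream flank
    (direct repeats in genome orientation); dB is measured from the B-end."""
    if k > fp.W:
        raise ValueError("k exceeds flank width")
    left = _kmer_distances(fp.left, k, proximal_right=True)
    right = _kmer_distances(revcomp(fp.right_rc), k, proximal_right=False)
    return _pair_up(fp.locus_id, left, right, max_dist_diff, "DR")


def _pair_up(
    locus_id: str,
    left: dict[str, list[int]],
    right: dict[str, list[int]],
    max_dist_diff: int,
    orientation: str,
) -> list[MotifPairHit]:
    hits = []
    for kmer in sorted(set(left) & set(right)):
        for dA in left[kmer]:
            for dB in right[kmer]:
                if abs(dA - dB) <= max_dist_diff:
                    hits.append(MotifPairHit(locus_id, kmer, dA, dB, orientation))
    return hits


def _stat(
    label: str,
    dAs: Sequence[int],
    dBs: Sequence[int],
    max_iqr: float,
    min_count: int,
    quantile_method: str,
) -> ConcentricityStat:
    qa1, qa3 = np.percentile(dAs, [25, 75], method=quantile_method)
    qb1, qb3 = np.percentile(dBs, [25, 75], method=quantile_method)
    iqr = float(qa3 - qa1)
    count = len(dAs)
    return ConcentricityStat(
        label=label,
        count=count,
        iqr=iqr,
        median_dA=float(np.median(dAs)),
        iqr_dB=float(qb3 - qb1),
        median_dB=float(np.median(dBs)),
        selected=(iqr <= max_iqr and count >= min_count),
    )


def concentricity(
    hits: Iterable[MotifPairHit],
    max_iqr: float = 10.0,
    min_count: int = 3,
    quantile_method: str = "linear",
) -> list[ConcentricityStat]:
    """Per-k-mer positional concentration of paired hits.

    The IQR of each group's dA values (linear-interpolation quantiles by
    default) measures how tightly the motif sits at one distance from the
    boundary; a group is selected when IQR ≤ max_iqr and it has at least
    min_count contributing pairs.  dB statistics are reported alongside.
    Groups are returned sorted by descending count.
    """
    grouped: dict[str, list[MotifPairHit]] = {}
    for h in hits:
        grouped.setdefault(h.kmer, []).append(h)
    stats = [
        _stat(
            kmer,
            [h.dA for h in hs],
            [h.dB for h in hs],
            max_iqr,
            min_count,
            quantile_method,
        )
        for kmer, hs in grouped.items()
    ]
    return sorted(stats, key=lambda s: (-s.count, s.label))


def _core_matches(kmer: str, core: str) -> bool:
    """Does `kmer` contain `core` as a substring, with N in the core
    matching any base?"""
    n, m = len(kmer), len(core)
    for i in range(n - m + 1):
        if all(c == "N" or kmer[i + j] == c for j, c in enumerate(core)):
            return True
    return False


def group_by_core(
    hits: Iterable[MotifPairHit],
    core: str,
    max_iqr: float = 10.0,
    min_count: int = 3,
    quantile_method: str = "linear",
) -> ConcentricityStat:
    """Pool hits of all k-mers containing `core` (N = wildcard) and compute
    the concentricity statistics of the merged distance lists."""
    pooled = [h for h in hits if _core_matches(h.kmer, core)]
    if not pooled:
        return ConcentricityStat(core, 0, float("nan"), float("nan"), float("nan"), float("nan"), False)
    return _stat(
        core,
        [h.dA for h in pooled],
        [h.dB for h in pooled],
        max_iqr,
        min_count,
        quantile_method,
    )


def stats_frame(stats: Sequence[ConcentricityStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": s.label,
                "count": s.count,
                "median_dA": s.median_dA,
                "iqr": s.iqr,
                "median_dB": s.median_dB,
                "iqr_dB": s.iqr_dB,
                "selected": s.selected,
            }
            for s in stats
        ]
    )


def composition_profile(
    loci: Sequence[IESLocus],
    sequences: Mapping[str, str],
    span: int = 500,
    align: str = "both",
    reference_strain: str | None = None,
) -> pd.DataFrame:
    """Per-position base fractions around IES boundaries.

    Positions −span…−1 lie inside the IES (counting back from the
    junction) and 0…span−1 lie in the flank, counting outward from the
    junction.  With align="both" each locus contributes both ends, the
    B-end sequence reverse-complemented so both are read in a common
    IES-to-flank orientation.  Ns are excluded from the denominator; each
    row's four fractions sum to 1.  Loci whose span would cross a contig
    end are skipped.
    """
    if align not in ("A-end", "B-end", "both"):
        raise ValueError("align must be 'A-end', 'B-end' or 'both'")
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((2 * span, 4), dtype=np.int64)

    def add(window: str) -> None:
        # window: 2*span bases, IES side first, flank side second
        for offset, base in enumerate(window):
            j = base_idx.get(base)
            if j is not None:
                counts[offset, j] += 1

    for locus in loci:
        try:
            ref = reference_form(locus, reference_strain)
        except FlankExtractionError:
            continue
        seq = sequences[locus.contig]
        A, B = ref.A, ref.B
        if align in ("A-end", "both"):
            if A - span >= 0 and A + span <= len(seq):
                # inside-IES bases seq[A..A+span) read back toward the
                # junction, then flank bases seq[A-1], seq[A-2], ...
                inside = seq[A : A + span].upper()[::-1]
                flank = seq[A - span : A].upper()[::-1]
                add(inside + flank)
        if align in ("B-end", "both"):
            if B - span >= 0 and B + span <= len(seq):
                inside = seq[B - span : B].upper()
                flank = seq[B : B + span].upper()
                window = inside + flank
                if align == "both":
                    # positions already count by distance from the junction,
                    # so only the strand complement remains to be applied
                    window = complement(window)
                add(window)

    totals = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = counts / totals
    positions = list(range(-span, 0)) + list(range(span))
    return pd.DataFrame(
        {
            "position": positions,
            "frac_A": fractions[:, 0],
            "frac_C": fractions[:, 1],
            "frac_G": fractions[:, 2],
            "frac_T": fractions[:, 3],
        }
    )
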