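"""Position-weight-matrix scanning of IES flanks and FRS assignment.

A PWM built from aligned motif instances (pseudocount 1, log-odds against
a uniform background) scores every window of a flank; scores are rescaled
between the matrix's minimal and maximal achievable scores so that a
*similarity* of 1 is the consensus and 0 the anti-consensus.  A G-rich IR
is called when both processed flanks (the left flank and the
reverse-complemented right flank) carry a window at or above the
similarity threshold at near-equal junction distances; a C-rich IR is the
same call with the reverse-complement matrix.  When both qualify at one
locus, the pair with the smaller distance difference is assigned as the
locus's flanking regulatory sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from ._seq import revcomp
from .flankmotifs import FlankExtractionError, FlankPair, extract_flanks

logger = logging.getLogger(__name__)

_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass(frozen=True)
class PWM:
    label: str
    weights: np.ndarray  # shape (4, width), rows A/C/G/T

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def s_min(self) -> float:
        return float(self.weights.min(axis=0).sum())

    @property
    def s_max(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=0))

    def reverse_complement(self, label: str | None = None) -> "PWM":
        return PWM(label or f"{self.label}_rc", self.weights[::-1, ::-1].copy())


@dataclass(frozen=True)
class MotifHit:
    """One above-threshold PWM window in one processed flank."""

    locus_id: str
    side: str  # "left" or "right"
    orientation: str  # "forward" (matrix as given) or "reverse" (its complement)
    position: int  # window start in the processed flank
    distance: int  # junction distance of the window's IES-proximal base
    similarity: float


@dataclass(frozen=True)
class PWMPair:
    """A same-orientation hit in both flanks — an IR call of one matrix."""

    locus_id: str
    label: str  # "G-IR" or "C-IR"
    dA: int
    dB: int
    similarity_left: float
    similarity_right: float

    @property
    def dist_diff(self) -> int:
        return abs(self.dA - self.dB)


@dataclass(frozen=True)
class FRSAssignment:
    locus_id: str
    frs_type: str  # "G-IR" | "C-IR" | "other-IR" | "none"
    dA: int | None = None
    dB: int | None = None
    dist_diff: int | None = None


def build_pwm_from_counts(counts: np.ndarray, label: str = "pwm") -> PWM:
    """Log-odds matrix from a 4×width base-count matrix.

    A pseudocount of 1 per base per position is added and the resulting
    frequencies are scored against a uniform 0.25 background:
    w[b, i] = log2(4 · (c[b, i] + 1) / (n_i + 4)).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("counts must be a 4×width matrix (rows A/C/G/T)")
    totals = counts.sum(axis=0) + 4.0
    weights = np.log2(4.0 * (counts + 1.0) / totals)
    return PWM(label=label, weights=weights)


def build_pwm(instances: Sequence[str], label: str = "pwm") -> PWM:
    """PWM from ≥2 equal-length instances over {A,C,G,T}."""
    if len(instances) < 2:
        raise ValueError("at least two motif instances required")
    width = len(instances[0])
    if any(len(s) != width for s in instances):
        raise ValueError("motif instances must have equal length")
    counts = np.zeros((4, width))
    for s in instances:
        for i, base in enumerate(s.upper()):
            if base not in _ROW:
                raise ValueError(f"invalid base {base!r} in motif instance")
            counts[_ROW[base], i] += 1
    return build_pwm_from_counts(counts, label=label)


def load_pfm(path_or_text, label: str | None = None) -> PWM:
    """Read a plain-text JASPAR-style count matrix (4 rows, A/C/G/T)."""
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    rows: dict[str, list[float]] = {}
    name = label
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = name or line[1:].split()[0]
            continue
        token, _, rest = line.partition(" ")
        base = token.strip(":|")
        values = [float(v) for v in rest.replace("[", " ").replace("]", " ").split()]
        if base in _ROW:
            rows[base] = values
    if set(rows) != set(_BASES):
        raise ValueError("PFM must provide rows for all of A, C, G, T")
    counts = np.array([rows[b] for b in _BASES])
    return build_pwm_from_counts(counts, label=name or "pwm")


def default_g_pwm() -> PWM:
    """The packaged synthetic G-rich (A5G5-like polypurine) count matrix.

    A stand-in consensus for a Lia3p-type G-rich FRS, shipped for worked
    examples and synthetic runs; real analyses should supply their own
    instance-derived matrix via --pwm.
    """
    ref = resources.files("iesbounds.data").joinpath("g_rich_ir_synthetic.pfm")
    return load_pfm(ref.open(), label="G-rich")


def pwm_score(pwm: PWM, window: str) -> float | None:
    """Raw log-odds score of one window; None when the window contains N."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    score = 0.0
    for i, base in enumerate(window.upper()):
        row = _ROW.get(base)
        if row is None:
            return None
        score += pwm.weights[row, i]
    return score


def pwm_similarity(pwm: PWM, window: str) -> float | None:
    """Min–max rescaled score: (score − s_min) / (s_max − s_min) ∈ [0, 1]."""
    score = pwm_score(pwm, window)
    if score is None:
        return None
    return (score - pwm.s_min) / (pwm.s_max - pwm.s_min)


def scan_sequence(
    sequence: str, pwm: PWM, threshold: float
) -> list[tuple[int, int, float]]:
    """(position, junction distance, similarity) of every window with
    similarity ≥ threshold, distances counted with the junction at the
    sequence's right end (the processed-flank convention)."""
    W, width = len(sequence), pwm.width
    out = []
    for i in range(W - width + 1):
        sim = pwm_similarity(pwm, sequence[i : i + width])
        if sim is not None and sim >= threshold:
            out.append((i, W - width - i, sim))
    return out


def scan_flanks(
    fp: FlankPair,
    pwm: PWM,
    threshold: float,
    max_dist_diff: int = 10,
) -> tuple[list[PWMPair], list[PWMPair], list[MotifHit]]:
    """G-rich and C-rich IR calls on one flank pair, plus all single hits.

    Both processed flanks are scanned with the matrix and with its reverse
    complement.  Forward/forward co-occurrence within the distance
    tolerance is a G-rich IR (the right flank's prior
    reverse-complementation turns a genomic IR into same-orientation
    matches); reverse/reverse co-occurrence is a C-rich IR.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    pwm_rc = pwm.reverse_complement()
    hits: list[MotifHit] = []
    per = {}
    for side, seq in (("left", fp.left), ("right", fp.right_rc)):
        for orientation, matrix in (("forward", pwm), ("reverse", pwm_rc)):
            found = scan_sequence(seq, matrix, threshold)
            per[(side, orientation)] = found
            hits.extend(
                MotifHit(fp.locus_id, side, orientation, pos, dist, sim)
                for pos, dist, sim in found
            )

    def pairs(orientation: str, label: str) -> list[PWMPair]:
        out = []
        for _, dA, simL in per[("left", orientation)]:
            for _, dB, simR in per[("right", orientation)]:
                if abs(dA - dB) <= max_dist_diff:
                    out.append(PWMPair(fp.locus_id, label, dA, dB, simL, simR))
        return out

    return pairs("forward", "G-IR"), pairs("reverse", "C-IR"), hits


def representative_pair(pairs: Sequence[PWMPair]) -> PWMPair | None:
    """The single pair standing for a locus: minimal distance difference,
    ties broken by the smaller mean distance."""
    if not pairs:
        return None
    return min(pairs, key=lambda p: (p.dist_diff, p.dA + p.dB))


def assign_frs(
    locus_id: str,
    g_pairs: Sequence[PWMPair],
    c_pairs: Sequence[PWMPair],
    has_other_ir: bool = False,
) -> FRSAssignment:
    """Resolve a locus's FRS type.

    G- vs C-rich is decided by the representative pair with the lesser
    distance difference (a tie goes to G-rich, logged).  A locus with
    neither matrix hit but with a selected concentric k-mer IR is
    "other-IR"; otherwise "none".
    """
    g = representative_pair(g_pairs)
    c = representative_pair(c_pairs)
    if g and c:
        if g.dist_diff == c.dist_diff:
            logger.info("%s: G/C distance-difference tie, assigning G-IR", locus_id)
            chosen = g
        else:
            chosen = g if g.dist_diff < c.dist_diff else c
    else:
        chosen = g or c
    if chosen is not None:
        return FRSAssignment(locus_id, chosen.label, chosen.dA, chosen.dB, chosen.dist_diff)
    if has_other_ir:
        return FRSAssignment(locus_id, "other-IR")
    return FRSAssignment(locus_id, "none")


def assign_loci(
    loci,
    sequences,
    pwm: PWM,
    threshold: float = 0.75,
    max_dist_diff: int = 10,
    reference_strain: str | None = None,
    other_ir_loci: Iterable[str] = (),
    W: int = 100,
) -> dict[str, FRSAssignment]:
    """FRS assignment for every locus whose flanks can be extracted.

    `other_ir_loci` lists loci carrying a selected concentric k-mer IR,
    used for the "other-IR" fallback when neither matrix qualifies.
    """
    other = set(other_ir_loci)
    out: dict[str, FRSAssignment] = {}
    for locus in loci:
        try:
            fp = extract_flanks(locus, sequences, W=W, reference_strain=reference_strain)
        except FlankExtractionError as exc:
            logger.info("skipping locus: %s", exc)
            continue
        g_pairs, c_pairs, _ = scan_flanks(fp, pwm, threshold, max_dist_diff)
        out[locus.locus_id] = assign_frs(
            locus.locus_id, g_pairs, c_pairs, locus.locus_id in other
        )
    return out
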