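"""Cross-strain IES catalogue: junction normalization, filtering, locus clustering.

An *IES form* is one deletion interval observed in one strain, in 0-based
half-open MIC coordinates [A, B).  Terminal direct repeats (junction
microhomology) make the breakpoint representation ambiguous; forms are
canonicalized by left-aligning the deleted interval so the retained
microhomology copy abuts the A-end.  Forms from all strains that overlap by
at least 1 bp (transitively) are grouped into one *IES locus*, the unit on
which boundary-variation and motif statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class IESForm:
    """One deletion event in one strain, left-aligned to the A-end."""

    strain: str
    contig: str
    A: int
    B: int
    mh_len: int = 0
    source_id: str | None = None  # truth linkage for synthetic data; not used by the pipeline

    def __post_init__(self) -> None:
        if self.B <= self.A:
            raise ValueError(f"empty or inverted interval [{self.A}, {self.B})")

    @property
    def length(self) -> int:
        return self.B - self.A

    @property
    def interval(self) -> tuple[int, int]:
        return (self.A, self.B)


@dataclass
class IESLocus:
    """Cluster of ≥1-bp-overlapping forms across strains at one location."""

    locus_id: str
    contig: str
    forms: list[IESForm]

    @property
    def span(self) -> tuple[int, int]:
        """Hull interval of all forms."""
        return (min(f.A for f in self.forms), max(f.B for f in self.forms))

    @property
    def strains(self) -> frozenset[str]:
        return frozenset(f.strain for f in self.forms)

    def forms_of(self, strains: Iterable[str] | None = None) -> list[IESForm]:
        if strains is None:
            return list(self.forms)
        wanted = set(strains)
        return [f for f in self.forms if f.strain in wanted]


def _microhomology_length(sequence: str, A: int, B: int) -> int:
    """Longest m with sequence[A:A+m] == sequence[B:B+m] (terminal direct repeat)."""
    limit = min(B - A, len(sequence) - B)
    m = 0
    while m < limit and sequence[A + m] == sequence[B + m]:
        m += 1
    return m


def normalize_junction(call, sequence: str) -> IESForm:
    """Left-align a deletion call and record its junction microhomology.

    The interval [A, B) is shifted to [A-1, B-1) for as long as the base
    entering the deletion on the left equals the base leaving it on the
    right (sequence[A-1] == sequence[B-1]); the rejoined MAC product string
    is invariant under these shifts.  After shifting, mh_len is the maximal
    m with sequence[A:A+m] == sequence[B:B+m].

    Accepts any object with strain/contig/A/B attributes (a RefinedCall or
    an IESForm).
    """
    A, B = call.A, call.B
    while A > 0 and sequence[A - 1] == sequence[B - 1]:
        A -= 1
        B -= 1
    return IESForm(
        strain=call.strain,
        contig=call.contig,
        A=A,
        B=B,
        mh_len=_microhomology_length(sequence, A, B),
        source_id=getattr(call, "source_id", None),
    )


def mac_product(sequence: str, A: int, B: int) -> str:
    """The somatic (MAC) sequence produced by deleting [A, B) and rejoining."""
    return sequence[:A] + sequence[B:]


def filter_calls(
    forms: Sequence[IESForm],
    sequences: Mapping[str, str],
    min_len: int = 100,
    n_guard: int = 5,
) -> list[IESForm]:
    """Drop forms shorter than min_len and forms with N near either junction.

    The N check covers the first and last `n_guard` bases inside the IES and
    `n_guard` flanking bases on each side (clamped at contig bounds).
    Order is preserved; output is a subset of the input.
    """
    kept: list[IESForm] = []
    for f in forms:
        if f.length < min_len:
            continue
        seq = sequences[f.contig]
        inner = seq[f.A : f.A + n_guard] + seq[max(f.B - n_guard, f.A) : f.B]
        flank = seq[max(f.A - n_guard, 0) : f.A] + seq[f.B : f.B + n_guard]
        if "N" in (inner + flank).upper():
            continue
        kept.append(f)
    return kept


def intervals_overlap(a1: int, b1: int, a2: int, b2: int) -> bool:
    """≥1-bp overlap of half-open intervals [a1,b1) and [a2,b2)."""
    return a1 < b2 and a2 < b1


def cluster_forms(forms: Sequence[IESForm]) -> list[IESLocus]:
    """Single-linkage clustering of forms into loci by ≥1-bp interval overlap.

    Duplicate identical (strain, contig, A, B) forms are collapsed first.
    The partition is independent of input order; locus ids derive from the
    contig and the hull start.
    """
    unique: dict[tuple[str, str, int, int], IESForm] = {}
    for f in forms:
        unique.setdefault((f.strain, f.contig, f.A, f.B), f)

    by_contig: dict[str, list[IESForm]] = {}
    for f in unique.values():
        by_contig.setdefault(f.contig, []).append(f)

    loci: list[IESLocus] = []
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda f: (f.A, f.B, f.strain))
        cluster: list[IESForm] = []
        hull_end = None
        for f in members:
            if cluster and f.A < hull_end:
                cluster.append(f)
                hull_end = max(hull_end, f.B)
            else:
                if cluster:
                    loci.append(_make_locus(contig, cluster))
                cluster = [f]
                hull_end = f.B
        if cluster:
            loci.append(_make_locus(contig, cluster))
    return loci


def _make_locus(contig: str, forms: list[IESForm]) -> IESLocus:
    hull_start = min(f.A for f in forms)
    return IESLocus(locus_id=f"IES.{contig}.{hull_start}", contig=contig, forms=forms)


def build_catalog(
    calls: Sequence,
    sequences: Mapping[str, str],
    min_len: int = 100,
    n_guard: int = 5,
) -> list[IESLocus]:
    """Normalize, filter and cluster refined calls into the IES catalogue."""
    normalized = [normalize_junction(c, sequences[c.contig]) for c in calls]
    return cluster_forms(filter_calls(normalized, sequences, min_len, n_guard))


def shared_locus_counts(
    loci: Sequence[IESLocus], strains: Sequence[str]
) -> dict[frozenset[str], int]:
    """Venn-region counts: loci whose strain set equals each non-empty subset.

    Strains outside `strains` are ignored when forming a locus's strain set.
    The counts over all non-empty subsets sum to the number of loci that
    have at least one form in the queried strains.
    """
    if not strains:
        raise ValueError("at least one strain required")
    universe = set(strains)
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(strains) + 1):
        for subset in combinations(sorted(universe), r):
            counts[frozenset(subset)] = 0
    for locus in loci:
        present = frozenset(s for s in locus.strains if s in universe)
        if present:
            counts[present] += 1
    return counts
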