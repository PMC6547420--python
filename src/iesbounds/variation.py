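"""Boundary-variation statistics across IES forms.

The distance between two forms S_i, S_j of the same locus is the summed
end difference |A_i − A_j| + |B_i − B_j|; the locus's *maximum boundary
variation* is the maximum of this over all form pairs (0 for a single
form).  Variations are binned into the standard reporting classes
0, 1–10, …, 91–100, >100.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .catalog import IESForm, IESLocus

CLASS_LABELS = (
    "0",
    "1–10",
    "11–20",
    "21–30",
    "31–40",
    "41–50",
    "51–60",
    "61–70",
    "71–80",
    "81–90",
    "91–100",
    ">100",
)


@dataclass(frozen=True)
class VariationRecord:
    locus_id: str
    max_variation: int
    n_forms: int
    class_label: str


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching printed table precision."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def form_difference(f1: IESForm, f2: IESForm) -> int:
    """Summed end difference |A1 − A2| + |B1 − B2| between two forms."""
    if f1.contig != f2.contig:
        raise ValueError("forms on different contigs are not comparable")
    return abs(f1.A - f2.A) + abs(f1.B - f2.B)


def max_boundary_variation(
    forms_or_locus: IESLocus | Sequence[IESForm],
    strains: Iterable[str] | None = None,
) -> int:
    """Maximum of form_difference over all unordered form pairs.

    Intra-strain alternative forms participate like any others.  With
    `strains` given, only forms of those strains are considered; a single
    (or no) form gives 0.
    """
    forms = (
        forms_or_locus.forms_of(strains)
        if isinstance(forms_or_locus, IESLocus)
        else list(forms_or_locus)
        if strains is None
        else [f for f in forms_or_locus if f.strain in set(strains)]
    )
    unique = sorted({f.interval for f in forms})
    if len(unique) < 2:
        return 0
    return max(
        abs(a1 - a2) + abs(b1 - b2) for (a1, b1), (a2, b2) in combinations(unique, 2)
    )


def classify_variation(v: int) -> str:
    """Reporting class of a max-variation value (bins closed on both ends)."""
    if v < 0:
        raise ValueError("variation cannot be negative")
    if v == 0:
        return "0"
    if v > 100:
        return ">100"
    return CLASS_LABELS[1 + (v - 1) // 10]


def variation_records(
    loci: Sequence[IESLocus], strains: Iterable[str] | None = None
) -> list[VariationRecord]:
    records = []
    for locus in loci:
        forms = locus.forms_of(strains)
        if not forms:
            continue
        v = max_boundary_variation(forms)
        records.append(
            VariationRecord(
                locus_id=locus.locus_id,
                max_variation=v,
                n_forms=len(forms),
                class_label=classify_variation(v),
            )
        )
    return records


def class_histogram(records: Sequence[VariationRecord]) -> pd.DataFrame:
    """Per-class locus counts and percentages (half-up, 2 decimals)."""
    counts = {label: 0 for label in CLASS_LABELS}
    for r in records:
        counts[r.class_label] += 1
    total = len(records)
    return pd.DataFrame(
        {
            "class": CLASS_LABELS,
            "count": [counts[c] for c in CLASS_LABELS],
            "percent": [
                round_half_up(100.0 * counts[c] / total) if total else float("nan")
                for c in CLASS_LABELS
            ],
        }
    )


def ratio_table(
    all_records: Sequence[VariationRecord] | dict[str, int],
    flagged: Sequence[VariationRecord] | dict[str, int],
) -> pd.DataFrame:
    """Per-class totals, flagged counts and flagged/total ratios, plus a
    Total row — the layout of the published variation-class ratio table.

    Accepts either VariationRecord lists or precomputed class→count
    mappings, so printed counts can be fed straight through the same
    arithmetic.  Empty classes get an empty (NaN) ratio rather than a
    division error.  Ratios are rounded half-up to 2 decimals.
    """
    totals = _as_class_counts(all_records)
    flags = _as_class_counts(flagged)
    rows = []
    for label in CLASS_LABELS:
        t, fl = totals.get(label, 0), flags.get(label, 0)
        rows.append(
            {
                "class": label,
                "total": t,
                "flagged": fl,
                "ratio": round_half_up(fl / t) if t else float("nan"),
            }
        )
    t_sum, f_sum = sum(totals.values()), sum(flags.values())
    rows.append(
        {
            "class": "Total",
            "total": t_sum,
            "flagged": f_sum,
            "ratio": round_half_up(f_sum / t_sum) if t_sum else float("nan"),
        }
    )
    return pd.DataFrame(rows, columns=["class", "total", "flagged", "ratio"])


def _as_class_counts(records) -> dict[str, int]:
    if isinstance(records, dict):
        return dict(records)
    counts: dict[str, int] = {}
    for r in records:
        counts[r.class_label] = counts.get(r.class_label, 0) + 1
    return counts
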