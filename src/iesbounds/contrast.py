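"""Mutant-vs-wild-type boundary contrast (LIA3-knockout analysis).

A locus is *LIA3-affected* when its boundaries are tightly controlled in
wild-type strains (maximum boundary variation at most a WT cap, default
100 bp; stringent variant 20 bp) and pooling the mutant strains' forms
raises the maximum variation by at least `min_increase` (default 100 bp).
Only loci with at least one form in every wild-type and every mutant
strain are considered.  Downstream reports cross the flagged set with
per-strain FRS assignments (G-rich / C-rich IR enrichment) and survey
alternative-boundary loci for multiple FRS copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import revcomp
from .catalog import IESLocus
from .flankmotifs import FlankPair
from .pwmscan import PWM, representative_pair, scan_flanks
from .variation import max_boundary_variation, round_half_up


@dataclass(frozen=True)
class ContrastConfig:
    wt_strains: tuple[str, ...]
    mut_strains: tuple[str, ...]
    wt_max_variation: int = 100
    min_increase: int = 100
    strict_increase: bool = False  # ">" instead of "≥" for the increase

    def __post_init__(self) -> None:
        if not self.wt_strains or not self.mut_strains:
            raise ValueError("both strain sets must be non-empty")
        if set(self.wt_strains) & set(self.mut_strains):
            raise ValueError("wild-type and mutant strain sets must be disjoint")


def lia3_affected(
    loci: Sequence[IESLocus], cfg: ContrastConfig
) -> tuple[set[str], set[str]]:
    """(flagged locus ids, considered locus ids).

    Considered loci have at least one form in every wild-type and every
    mutant strain; loci missing a strain are excluded, not errored.  A
    considered locus is flagged when WT max variation ≤ wt_max_variation
    and pooled-minus-WT max variation reaches min_increase.  The
    background for enrichment reports is considered − flagged.
    """
    required = set(cfg.wt_strains) | set(cfg.mut_strains)
    flagged: set[str] = set()
    considered: set[str] = set()
    for locus in loci:
        if not required <= locus.strains:
            continue
        considered.add(locus.locus_id)
        wt_var = max_boundary_variation(locus, cfg.wt_strains)
        if wt_var > cfg.wt_max_variation:
            continue
        pooled_var = max_boundary_variation(locus, required)
        increase = pooled_var - wt_var
        hit = increase > cfg.min_increase if cfg.strict_increase else increase >= cfg.min_increase
        if hit:
            flagged.add(locus.locus_id)
    return flagged, considered


AT_LEAST_ONE = "at least one strain"
ALL_STRAINS = "all strains"


def enrichment_counts(
    group: Iterable[str],
    assignments: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Per-strain G-IR / C-IR locus counts within a locus-id group,
    plus the "at least one strain" and "all strains" aggregations.

    `assignments` maps strain → (locus_id → frs_type).  For the
    aggregations a locus counts as G-IR (resp. C-IR) when at least one /
    every strain assigns it that type.
    """
    group = set(group)
    strains = list(assignments)
    rows = []
    for strain in strains:
        a = assignments[strain]
        rows.append(
            {
                "strain": strain,
                "g_ir": sum(1 for lid in group if a.get(lid) == "G-IR"),
                "c_ir": sum(1 for lid in group if a.get(lid) == "C-IR"),
            }
        )
    for name, agg in ((AT_LEAST_ONE, any), (ALL_STRAINS, all)):
        rows.append(
            {
                "strain": name,
                "g_ir": sum(
                    1
                    for lid in group
                    if agg(assignments[s].get(lid) == "G-IR" for s in strains)
                ),
                "c_ir": sum(
                    1
                    for lid in group
                    if agg(assignments[s].get(lid) == "C-IR" for s in strains)
                ),
            }
        )
    return pd.DataFrame(rows, columns=["strain", "g_ir", "c_ir"])


def enrichment_table(counts: pd.DataFrame, n_group: int) -> pd.DataFrame:
    """Totals and percentages from per-strain G/C IR counts.

    The FRS assignment is exclusive per locus, so total = G + C, and the
    percentage is total / n_group × 100, rounded half-up to two decimals.
    A zero-sized group yields empty (NaN) percentages.  Printed report
    counts can be fed straight through this arithmetic.
    """
    out = counts.copy()
    out["total"] = out["g_ir"] + out["c_ir"]
    out["percent"] = [
        round_half_up(100.0 * t / n_group) if n_group else float("nan")
        for t in out["total"]
    ]
    out["n_group"] = n_group
    return out


def tabulate_enrichment(
    flagged: Iterable[str],
    background: Iterable[str],
    assignments: Mapping[str, Mapping[str, str]],
) -> dict[str, pd.DataFrame]:
    """Mutant-affected vs background FRS enrichment, per strain and pooled."""
    flagged, background = set(flagged), set(background)
    return {
        "affected": enrichment_table(enrichment_counts(flagged, assignments), len(flagged)),
        "background": enrichment_table(
            enrichment_counts(background, assignments), len(background)
        ),
    }


def le20_percent(class_percents: Mapping[str, float]) -> float:
    """Share of loci with ≤20-bp variation: the "0" class plus the 1–20
    classes (accepts either a combined "1–20" entry or "1–10" + "11–20")."""
    total = class_percents.get("0", 0.0)
    if "1–20" in class_percents:
        total += class_percents["1–20"]
    else:
        total += class_percents.get("1–10", 0.0) + class_percents.get("11–20", 0.0)
    return round_half_up(total)


def headline_stats(
    wt_percents: Mapping[str, float], mut_percents: Mapping[str, float]
) -> dict[str, float]:
    """Summary numbers of the WT/mutant class histograms: the ≤20-bp share
    in each strain set and the difference of the >100-bp shares."""
    gt100_wt = wt_percents.get(">100", 0.0)
    gt100_mut = mut_percents.get(">100", 0.0)
    return {
        "wt_le20_percent": le20_percent(wt_percents),
        "mut_le20_percent": le20_percent(mut_percents),
        "wt_gt100_percent": round_half_up(gt100_wt),
        "mut_gt100_percent": round_half_up(gt100_mut),
        "gt100_difference": round_half_up(gt100_mut - gt100_wt),
    }


def per_end_variation(
    locus: IESLocus, strains: Iterable[str] | None = None
) -> tuple[int, int]:
    """Maximum pairwise difference at each end separately (A, B)."""
    forms = locus.forms_of(strains)
    As = sorted({f.A for f in forms})
    Bs = sorted({f.B for f in forms})
    return (
        (As[-1] - As[0]) if len(As) > 1 else 0,
        (Bs[-1] - Bs[0]) if len(Bs) > 1 else 0,
    )


def percent_le_at_one_end(
    loci: Sequence[IESLocus],
    strains: Iterable[str] | None = None,
    cutoff: int = 20,
) -> float:
    """Percent of loci whose variation is ≤ cutoff at at least one end."""
    if not loci:
        return float("nan")
    n = sum(1 for locus in loci if min(per_end_variation(locus, strains)) <= cutoff)
    return round_half_up(100.0 * n / len(loci))


def multiple_frs_survey(
    loci: Sequence[IESLocus],
    assignments: Mapping[str, str],
    sequences: Mapping[str, str],
    pwm: PWM,
    threshold: float = 0.75,
    max_dist_diff: int = 10,
    min_variation: int = 20,
    W: int = 100,
) -> pd.DataFrame:
    """Alternative-FRS usage at variable loci.

    For each locus with more than `min_variation` bp of boundary variation
    and an assigned G-/C-rich FRS, every distinct boundary form is scanned
    for a same-type IR pair; a form qualifies when its pair sits within
    `max_dist_diff` of the locus's modal (median) motif distance.  A locus
    is "multiple-FRS" when at least two alternative forms each have their
    own qualifying pair — boundary variation that reflects controlled
    alternative boundaries rather than loss of control.
    """
    rows = []
    for locus in loci:
        frs_type = assignments.get(locus.locus_id)
        if frs_type not in ("G-IR", "C-IR"):
            continue
        if max_boundary_variation(locus) <= min_variation:
            continue
        seq = sequences[locus.contig]
        distinct = sorted({f.interval for f in locus.forms})
        reps = {}
        for A, B in distinct:
            if A < W or B + W > len(seq):
                continue
            fp = FlankPair(
                locus_id=locus.locus_id,
                left=seq[A - W : A].upper(),
                right_rc=revcomp(seq[B : B + W]).upper(),
                A=A,
                B=B,
            )
            g_pairs, c_pairs, _ = scan_flanks(fp, pwm, threshold, max_dist_diff)
            rep = representative_pair(g_pairs if frs_type == "G-IR" else c_pairs)
            if rep is not None:
                reps[(A, B)] = rep
        if reps:
            distances = sorted(r.dA for r in reps.values())
            modal = distances[len(distances) // 2]
            qualifying = [
                form for form, r in reps.items() if abs(r.dA - modal) <= max_dist_diff
            ]
        else:
            qualifying = []
        rows.append(
            {
                "locus_id": locus.locus_id,
                "frs_type": frs_type,
                "max_variation": max_boundary_variation(locus),
                "n_forms": len(distinct),
                "n_forms_with_frs": len(qualifying),
                "multiple_frs": len(qualifying) >= 2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "frs_type",
            "max_variation",
            "n_forms",
            "n_forms_with_frs",
            "multiple_frs",
        ],
    )
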