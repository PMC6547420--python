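"""LIA3-affected flagging, enrichment arithmetic, headlines, multiple-FRS survey."""

import math

import numpy as np
import pandas as pd
import pytest

from iesbounds._seq import revcomp
from iesbounds.catalog import IESForm, cluster_forms
from iesbounds.contrast import (
    ContrastConfig,
    enrichment_counts,
    enrichment_table,
    headline_stats,
    le20_percent,
    lia3_affected,
    multiple_frs_survey,
    per_end_variation,
    percent_le_at_one_end,
    tabulate_enrichment,
)
from iesbounds.pwmscan import default_g_pwm
from iesbounds.variation import max_boundary_variation
from conftest import random_dna

WT = ("w1", "w2", "w3")
MUT = ("m1", "m2", "m3")
CFG = ContrastConfig(wt_strains=WT, mut_strains=MUT)


def locus_from(intervals_by_strain, contig="c"):
    forms = [
        IESForm(strain=s, contig=contig, A=a, B=b)
        for s, pairs in intervals_by_strain.items()
        for a, b in pairs
    ]
    return cluster_forms(forms)


class TestLia3Affected:
    def test_low_wt_high_pooled_is_flagged(self):
        loci = locus_from(
            {
                "w1": [(100, 400)], "w2": [(105, 410)], "w3": [(100, 400)],
                "m1": [(100, 400)], "m2": [(60, 500)], "m3": [(100, 400)],
            }
        )
        # WT maxvar 15, pooled 140: increase 125 ≥ 100
        assert max_boundary_variation(loci[0], WT) == 15
        assert max_boundary_variation(loci[0]) == 140
        flagged, considered = lia3_affected(loci, CFG)
        assert flagged == {loci[0].locus_id} and considered == flagged

    def test_high_wt_variation_excluded_from_flagging(self):
        loci = locus_from(
            {
                "w1": [(100, 400)], "w2": [(130, 520)], "w3": [(100, 400)],
                "m1": [(100, 400)], "m2": [(0, 700)], "m3": [(100, 400)],
            }
        )
        assert max_boundary_variation(loci[0], WT) == 150
        flagged, considered = lia3_affected(loci, CFG)
        assert not flagged and considered

    def test_locus_missing_a_strain_is_excluded_not_errored(self):
        loci = locus_from({s: [(100, 400)] for s in WT + MUT[:2]})
        flagged, considered = lia3_affected(loci, CFG)
        assert not considered

    def test_pooled_never_below_wt_and_min_increase_monotone(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            per_strain = {
                s: [(int(100 + rng.integers(0, 80)), int(500 + rng.integers(0, 80)))]
                for s in WT + MUT
            }
            loci = locus_from(per_strain)
            locus = loci[0]
            assert max_boundary_variation(locus) >= max_boundary_variation(locus, WT)
            flag_loose, _ = lia3_affected(
                loci, ContrastConfig(WT, MUT, min_increase=20)
            )
            flag_tight, _ = lia3_affected(
                loci, ContrastConfig(WT, MUT, min_increase=60)
            )
            assert flag_tight <= flag_loose

    def test_strict_increase_option(self):
        loci = locus_from(
            {
                **{s: [(100, 400)] for s in WT},
                "m1": [(100, 500)], "m2": [(100, 400)], "m3": [(100, 400)],
            }
        )
        flagged_ge, _ = lia3_affected(loci, ContrastConfig(WT, MUT, min_increase=100))
        flagged_gt, _ = lia3_affected(
            loci, ContrastConfig(WT, MUT, min_increase=100, strict_increase=True)
        )
        assert flagged_ge and not flagged_gt

    def test_overlapping_strain_sets_rejected(self):
        with pytest.raises(ValueError):
            ContrastConfig(("a",), ("a", "b"))


class TestEnrichmentArithmetic:
    def test_single_strain_counts_to_percent(self):
        counts = pd.DataFrame([{"strain": "CU427", "g_ir": 175, "c_ir": 62}])
        out = enrichment_table(counts, n_group=387)
        assert out.iloc[0]["total"] == 237
        assert out.iloc[0]["percent"] == 61.24

    def test_zero_hits_give_zero_percent(self):
        counts = pd.DataFrame([{"strain": "x", "g_ir": 0, "c_ir": 0}])
        assert enrichment_table(counts, n_group=100).iloc[0]["percent"] == 0.0

    def test_empty_group_gives_nan_percent(self):
        counts = pd.DataFrame([{"strain": "x", "g_ir": 0, "c_ir": 0}])
        assert math.isnan(enrichment_table(counts, n_group=0).iloc[0]["percent"])

    def test_aggregations_at_least_one_and_all(self):
        assignments = {
            "s1": {"L1": "G-IR", "L2": "C-IR", "L3": "none"},
            "s2": {"L1": "G-IR", "L2": "none", "L3": "none"},
        }
        counts = enrichment_counts({"L1", "L2", "L3"}, assignments)
        by = counts.set_index("strain")
        assert by.loc["s1", "g_ir"] == 1 and by.loc["s1", "c_ir"] == 1
        assert by.loc["at least one strain", "g_ir"] == 1
        assert by.loc["at least one strain", "c_ir"] == 1
        assert by.loc["all strains", "g_ir"] == 1
        assert by.loc["all strains", "c_ir"] == 0

    def test_tabulate_keeps_affected_and_background_separate(self):
        assignments = {"s": {"L1": "G-IR", "L2": "none"}}
        tables = tabulate_enrichment({"L1"}, {"L2"}, assignments)
        assert tables["affected"].iloc[0]["total"] == 1
        assert tables["background"].iloc[0]["total"] == 0


class TestHeadlines:
    def test_le20_share_combines_zero_and_1_20_classes(self):
        assert le20_percent({"0": 14.71, "1–20": 38.87}) == 53.58
        assert le20_percent({"0": 14.71, "1–10": 20.0, "11–20": 18.87}) == 53.58

    def test_gt100_difference(self):
        stats = headline_stats({">100": 27.79}, {">100": 38.87})
        assert stats["gt100_difference"] == 11.08

    def test_identical_strain_sets_give_zero_difference(self):
        stats = headline_stats({">100": 12.5}, {">100": 12.5})
        assert stats["gt100_difference"] == 0.0

    def test_per_end_variation_and_one_end_share(self):
        loci = locus_from({"a": [(100, 400)], "b": [(110, 700)]})
        assert per_end_variation(loci[0]) == (10, 300)
        assert percent_le_at_one_end(loci) == 100.0
        loci2 = locus_from({"a": [(100, 400)], "b": [(180, 700)]})
        assert percent_le_at_one_end(loci2) == 0.0


class TestMultipleFRS:
    def _two_boundary_locus(self, with_second_frs):
        rng = np.random.default_rng(23)
        pwm = default_g_pwm()
        cons = pwm.consensus
        seq = list(random_dna(rng, 3000))
        B = 1900
        lefts = [1000, 1300]  # two alternative left boundaries, 300 bp apart
        d = 45
        for A in lefts if with_second_frs else lefts[:1]:
            seq[A - d - len(cons) : A - d] = cons
        seq[B + d : B + d + len(cons)] = revcomp(cons)
        seq = "".join(seq)
        forms = [
            IESForm(strain="w1", contig="c", A=lefts[0], B=B),
            IESForm(strain="w2", contig="c", A=lefts[1], B=B),
        ]
        loci = cluster_forms(forms)
        return loci, {loci[0].locus_id: "G-IR"}, {"c": seq}, pwm

    def test_two_alternative_boundaries_each_with_own_pair(self):
        loci, assign, seqs, pwm = self._two_boundary_locus(with_second_frs=True)
        survey = multiple_frs_survey(loci, assign, seqs, pwm)
        assert survey.iloc[0]["multiple_frs"]
        assert survey.iloc[0]["n_forms_with_frs"] == 2

    def test_single_frs_high_variation_is_not_multiple(self):
        loci, assign, seqs, pwm = self._two_boundary_locus(with_second_frs=False)
        survey = multiple_frs_survey(loci, assign, seqs, pwm)
        assert not survey.iloc[0]["multiple_frs"]

    def test_low_variation_loci_are_skipped(self):
        loci, assign, seqs, pwm = self._two_boundary_locus(True)
        survey = multiple_frs_survey(
            loci, assign, seqs, pwm, min_variation=1000
        )
        assert survey.empty
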