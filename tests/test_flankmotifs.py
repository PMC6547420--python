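"""Flank extraction, IR/DR k-mer pairing, concentricity, composition profiles."""

import numpy as np
import pytest

from iesbounds._seq import revcomp
from iesbounds.catalog import IESForm, IESLocus, cluster_forms
from iesbounds.flankmotifs import (
    FlankExtractionError,
    FlankPair,
    composition_profile,
    concentricity,
    extract_flanks,
    find_dr_pairs,
    find_ir_pairs,
    group_by_core,
)
from conftest import random_dna


def make_flankpair(left, right_rc, locus_id="L"):
    return FlankPair(locus_id=locus_id, left=left, right_rc=right_rc, A=100, B=300)


def plant(flank_len, kmer, distance, rng):
    """Random flank with `kmer` whose junction-proximal base is at `distance`
    (junction at the string's right end)."""
    s = list(random_dna(rng, flank_len))
    i = flank_len - len(kmer) - distance
    s[i : i + len(kmer)] = kmer
    return "".join(s)


class TestExtractFlanks:
    def test_direct_construction(self):
        seq = "TTTTTGATTC" + "G" * 120 + "AGGTA" + "TTTTT"
        locus = cluster_forms([IESForm(strain="s", contig="c", A=10, B=130)])[0]
        fp = extract_flanks(locus, {"c": seq}, W=5)
        assert fp.left == "GATTC"
        assert fp.right_rc == revcomp("AGGTA") == "TACCT"

    def test_truncated_flank_excludes_locus(self):
        seq = "A" * 500
        locus = cluster_forms([IESForm(strain="s", contig="c", A=50, B=200)])[0]
        with pytest.raises(FlankExtractionError):
            extract_flanks(locus, {"c": seq}, W=100)

    def test_palindromic_flanks_coincide(self):
        pal = "ACGT" * 25  # revcomp("ACGT"*25) == "ACGT"*25
        seq = "T" * 100 + pal + "C" * 150 + pal + "T" * 100
        locus = cluster_forms([IESForm(strain="s", contig="c", A=200, B=350)])[0]
        fp = extract_flanks(locus, {"c": seq}, W=100)
        assert fp.left == fp.right_rc == pal

    def test_reference_strain_picks_smallest_interval(self):
        forms = [
            IESForm(strain="ref", contig="c", A=210, B=400),
            IESForm(strain="ref", contig="c", A=205, B=395),
            IESForm(strain="other", contig="c", A=202, B=390),
        ]
        locus = cluster_forms(forms)[0]
        seq = random_dna(np.random.default_rng(0), 600)
        fp = extract_flanks(locus, {"c": seq}, W=100, reference_strain="ref")
        assert (fp.A, fp.B) == (205, 395)


class TestPairFinding:
    def test_ir_hit_within_distance_tolerance(self):
        rng = np.random.default_rng(1)
        left = plant(100, "TACCG", 62, rng)
        right = plant(100, "TACCG", 58, rng)
        hits = [h for h in find_ir_pairs(make_flankpair(left, right)) if h.kmer == "TACCG"]
        assert any(h.dA == 62 and h.dB == 58 and h.dist_diff == 4 for h in hits)

    def test_ir_rejected_beyond_tolerance(self):
        rng = np.random.default_rng(2)
        left = plant(100, "CGCGC", 62, rng)
        right = plant(100, "CGCGC", 74, rng)
        hits = [h for h in find_ir_pairs(make_flankpair(left, right)) if h.kmer == "CGCGC"]
        assert not any(h.dA == 62 and h.dB == 74 for h in hits)

    def test_dr_hit_uses_uncomplemented_downstream(self):
        rng = np.random.default_rng(3)
        left = plant(100, "AAGGT", 40, rng)
        right_genome = list(random_dna(rng, 100))
        right_genome[45 : 50] = "AAGGT"  # dB = start offset from B-end
        right_rc = revcomp("".join(right_genome))
        hits = [h for h in find_dr_pairs(make_flankpair(left, right_rc)) if h.kmer == "AAGGT"]
        assert any(h.dA == 40 and h.dB == 45 and h.dist_diff == 5 for h in hits)

    def test_genomic_ir_is_not_reported_as_dr(self):
        # a non-palindromic k-mer planted as a genomic inverted repeat
        left = "A" * 95 + "GGGTC"  # dA = 0
        right_genome = revcomp("GGGTC") + "A" * 95  # inverted copy at dB = 0
        fp = make_flankpair(left, revcomp(right_genome))
        ir_kmers = {h.kmer for h in find_ir_pairs(fp)}
        dr_kmers = {h.kmer for h in find_dr_pairs(fp)}
        assert "GGGTC" in ir_kmers
        assert "GGGTC" not in dr_kmers

    def test_n_containing_kmers_skipped(self):
        left = "A" * 95 + "GGNTC"
        fp = make_flankpair(left, left)
        assert all("N" not in h.kmer for h in find_ir_pairs(fp))

    @pytest.mark.parametrize("finder,complement_right", [(find_ir_pairs, False), (find_dr_pairs, True)])
    def test_matches_bruteforce_double_loop(self, finder, complement_right):
        rng = np.random.default_rng(11)
        W, k, mdd = 40, 5, 10
        for _ in range(200):
            left = random_dna(rng, W, p_gc=0.5)
            right_rc = random_dna(rng, W, p_gc=0.5)
            fp = make_flankpair(left, right_rc)
            other = revcomp(right_rc) if complement_right else right_rc
            expected = set()
            for i in range(W - k + 1):
                for j in range(W - k + 1):
                    if left[i : i + k] != other[j : j + k]:
                        continue
                    dA = W - k - i
                    dB = j if complement_right else W - k - j
                    if abs(dA - dB) <= mdd:
                        expected.add((left[i : i + k], dA, dB))
            got = {(h.kmer, h.dA, h.dB) for h in finder(fp, k=k, max_dist_diff=mdd)}
            assert got == expected

    def test_revcomp_symmetry_swaps_distance_roles(self):
        rng = np.random.default_rng(13)
        left, right_rc = random_dna(rng, 60, 0.5), random_dna(rng, 60, 0.5)
        fp = make_flankpair(left, right_rc)
        # reverse-complementing the contig swaps the two flanks' roles
        flipped = make_flankpair(right_rc, left)
        direct = {(h.kmer, h.dA, h.dB) for h in find_ir_pairs(fp)}
        mirrored = {(h.kmer, h.dB, h.dA) for h in find_ir_pairs(flipped)}
        assert direct == mirrored


class TestConcentricity:
    def _hits(self, kmer, dAs, dBs=None):
        from iesbounds.flankmotifs import MotifPairHit

        dBs = dBs or dAs
        return [
            MotifPairHit(f"L{i}", kmer, dA, dB, "IR")
            for i, (dA, dB) in enumerate(zip(dAs, dBs))
        ]

    def test_linear_interpolation_quantiles(self):
        stats = concentricity(self._hits("TACCG", [60, 62, 62, 65]))
        s = stats[0]
        assert s.iqr == pytest.approx(1.25)
        assert s.count == 4
        assert s.selected

    def test_count_threshold(self):
        stats = concentricity(self._hits("TACCG", [50, 50]))
        assert stats[0].iqr == 0 and not stats[0].selected

    def test_identical_distances_have_zero_iqr(self):
        stats = concentricity(self._hits("AAATT", [45] * 6))
        assert stats[0].iqr == 0.0 and stats[0].selected

    def test_group_by_core_pools_counts_and_iqr(self):
        hits = (
            self._hits("TATAA", [60, 61])
            + self._hits("ATATA", [62, 63])
            + self._hits("TATAT", [64])
            + self._hits("GGGGG", [10, 90])
        )
        pooled = group_by_core(hits, "TATA")
        assert pooled.count == 5
        direct = np.percentile([60, 61, 62, 63, 64], [25, 75])
        assert pooled.iqr == pytest.approx(direct[1] - direct[0])

    def test_core_wildcard_matches_any_base(self):
        hits = self._hits("TACCGT", [45]) + self._hits("TACCAT", [46]) + self._hits("TACCCC", [47])
        pooled = group_by_core(hits, "TACCNT")
        assert pooled.count == 2


class TestCompositionProfile:
    def _loci(self, seqs, intervals):
        forms = [
            IESForm(strain="s", contig=c, A=a, B=b) for c, a, b in intervals
        ]
        return cluster_forms(forms)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 3000)
        loci = self._loci(None, [("c", 700, 1200), ("c", 1900, 2300)])
        prof = composition_profile(loci, {"c": seq}, span=200)
        sums = prof[["frac_A", "frac_C", "frac_G", "frac_T"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_all_a_flanks(self):
        seq = "A" * 200 + "C" * 100 + "T" * 200  # IES body C, flanks A then T
        loci = self._loci(None, [("c", 200, 300)])
        prof = composition_profile(loci, {"c": seq}, span=100, align="A-end")
        flank_rows = prof[prof["position"] >= 0]
        assert (flank_rows["frac_A"] == 1.0).all()

    def test_planted_g_run_peaks_at_planted_positions(self):
        rng = np.random.default_rng(9)
        intervals = []
        seqs = {}
        for i in range(12):
            s = list(random_dna(rng, 1200))
            A, B = 400, 800
            for p in range(40, 61):
                s[A - 1 - p] = "G"  # left flank G run
                s[B + p] = "C"  # complementary C run downstream
            seqs[f"c{i}"] = "".join(s)
            intervals.append((f"c{i}", A, B))
        loci = self._loci(None, intervals)
        prof = composition_profile(loci, seqs, span=100, align="both")
        flank = prof[prof["position"] >= 0].set_index("position")
        assert (flank.loc[40:60, "frac_G"] == 1.0).all()
        outside = flank.drop(index=range(40, 61))
        assert outside["frac_G"].max() < 1.0


def test_planted_motif_group_is_selected_and_centered(wt_experiment):
    cfg, (genome, truth, forms, _, _) = wt_experiment
    loci = cluster_forms(forms)
    hits = []
    for locus in loci:
        try:
            fp = extract_flanks(locus, genome, reference_strain="CU427")
        except FlankExtractionError:
            continue
        hits.extend(find_ir_pairs(fp))
    stats = {s.label: s for s in concentricity(hits)}
    pentamer = cfg.ir_motif[-5:]  # junction-proximal pentamer of the planted motif
    s = stats[pentamer]
    assert s.selected
    assert abs(s.median_dA - cfg.ir_distance) <= cfg.ir_jitter + cfg.boundary_jitter_wt
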