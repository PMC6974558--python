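"""Subgenome profiling: read assignment, copy number, heterozygosity, IBS."""

import numpy as np
import pandas as pd
import pytest

from hybripop.hybrid import (
    VariantSite,
    assign_reads,
    assign_reads_from_sam,
    classify_allelic_state,
    coverage_profile,
    detect_loh,
    hard_filter,
    het_density_windows,
    ibs_matrix,
    joint_genotypes,
    minor_allele_windows,
    pileup_genotype,
    read_vcf_sites,
    snp_pca,
    write_vcf_sites,
)
from hybripop.synthetic import (
    HybridPlan,
    Segment,
    simulate_hybrid_genome,
    simulate_parental_pair,
    simulate_reads,
)


class TestAssignReads:
    def test_labels_partition_reads(self, allotriploid_run):
        asg = allotriploid_run.assignment
        assert sum(asg.counts.values()) == asg.total == 2 * len(allotriploid_run.reads)

    def test_identical_references_all_ambiguous(self):
        pair = simulate_parental_pair(20_000, 0.0, seed=50)
        plan = HybridPlan([Segment(0, 20_000, 1, 1)])
        truth = simulate_hybrid_genome(pair, plan, seed=51)
        reads = simulate_reads(truth, coverage=3, error_rate=0.0, seed=52)
        asg = assign_reads(reads, pair.seq_a, pair.seq_b)
        assert asg.counts["A"] == asg.counts["B"] == 0
        assert asg.counts["ambiguous"] == asg.total

    def test_reads_with_diagnostic_sites_assigned_to_source(self):
        pair = simulate_parental_pair(50_000, 0.02, seed=53)
        plan = HybridPlan([Segment(0, 50_000, 1, 1)])
        truth = simulate_hybrid_genome(pair, plan, seed=54)
        reads = simulate_reads(truth, coverage=5, error_rate=0.0, seed=55)
        div = np.asarray(pair.divergence_map)
        correct = wrong = 0
        for rp in reads:
            asg = assign_reads([rp.seq1], pair.seq_a, pair.seq_b)
            label = asg.labels[0]
            has_diag = np.searchsorted(div, rp.start + 150) > np.searchsorted(div, rp.start)
            if not has_diag:
                assert label in ("ambiguous", rp.origin[0])
            elif label in "AB":
                correct += label == rp.origin[0]
                wrong += label != rp.origin[0]
            if correct + wrong > 300:
                break
        assert wrong == 0 and correct > 100


class TestCoverageProfile:
    def test_allodiploid_median_log2_near_zero(self, allodiploid_run):
        for sub in "AB":
            wins = [w.norm_log2 for w in allodiploid_run.profile.subgenome_windows(sub)
                    if not w.short]
            assert abs(np.median(wins)) < 0.1

    def test_allotriploid_log2_separation(self, allotriploid_run):
        prof = allotriploid_run.profile
        med = {sub: np.median([w.norm_log2 for w in prof.subgenome_windows(sub)
                               if not w.short]) for sub in "AB"}
        assert abs((med["A"] - med["B"]) - 1.0) < 0.15

    def test_no_unique_reads_rejected(self):
        from hybripop.hybrid import ReadAssignment
        empty = ReadAssignment(labels=["ambiguous"], placements={"A": [], "B": []},
                               ref_lengths={"A": 10_000, "B": 10_000})
        with pytest.raises(ValueError):
            coverage_profile(empty)

    def test_ploidy_estimated_when_absent(self, allotriploid_run):
        prof = coverage_profile(allotriploid_run.assignment, total_ploidy=None)
        assert prof.total_ploidy == 3 and prof.ploidy_estimated


class TestCopyNumber:
    def test_triploid_windows_recovered(self, allotriploid_run):
        cn = allotriploid_run.subprofile.copy_number
        full = cn[~cn.short]
        acc_a = (full[full.subgenome == "A"].cn == 2).mean()
        acc_b = (full[full.subgenome == "B"].cn == 1).mean()
        assert acc_a >= 0.95 and acc_b >= 0.95
        assert allotriploid_run.subprofile.parental_proportion == "2:1"

    def test_lost_and_quadruplicated_segment(self, allotetraploid_run):
        cn = allotetraploid_run.subprofile.copy_number
        full = cn[~cn.short]
        seg_a = full[(full.subgenome == "A") & (full.start >= 151_000)]
        seg_b = full[(full.subgenome == "B") & (full.start >= 151_000)]
        assert (seg_a.cn == 0).mean() >= 0.95
        assert (seg_b.cn == 4).mean() >= 0.95


class TestPileup:
    def test_planted_het_allele_fractions(self, allotriploid_run):
        """Het sites on one of two A copies: alt fraction near 1/2."""
        run = allotriploid_run
        sites = pileup_genotype(run.assignment, run.pair.seq_a, "A")
        by_pos = {s.pos - 1: s for s in sites}
        planted = [p for p in run.truth.planted_het_positions["A"]]
        fracs = []
        for p in planted:
            s = by_pos.get(p)
            if s is not None and s.is_het and len(s.ad) == 2:
                fracs.append(s.ad[1] / sum(s.ad))
        assert len(fracs) > 0.8 * len(planted)
        assert abs(np.mean(fracs) - 0.5) < 0.03

    def test_error_free_homozygous_region_silent(self):
        pair = simulate_parental_pair(20_000, 0.02, seed=60)
        plan = HybridPlan([Segment(0, 20_000, 1, 1)])
        truth = simulate_hybrid_genome(pair, plan, seed=61)
        reads = simulate_reads(truth, coverage=20, error_rate=0.0, seed=62)
        asg = assign_reads(reads, pair.seq_a, pair.seq_b)
        assert pileup_genotype(asg, pair.seq_a, "A") == []

    def test_one_of_three_copies_fraction(self, triploid_a_run):
        run = triploid_a_run
        sites = pileup_genotype(run.assignment, run.pair.seq_a, "A")
        het = [s for s in sites if s.is_het and len(s.ad) == 2]
        fracs = [s.ad[1] / sum(s.ad) for s in het]
        assert abs(np.mean(fracs) - 1 / 3) < 0.03


def _site(gt, ad, **ann):
    alts = tuple("CGT"[:max(gt)]) if max(gt) else ("C",)
    return VariantSite(chrom="A", pos=100, ref="A", alts=alts,
                       gt=gt, ad=ad, annotations=ann)


class TestHardFilter:
    def test_threshold_boundaries(self):
        keep = _site((0, 1), (10, 12), QD=5.0, FS=55.0, SOR=2.0, MQ=40.0)
        drop_qd = _site((0, 1), (10, 12), QD=4.9)
        drop_fs = _site((0, 1), (10, 12), FS=56.0)
        out = hard_filter([keep, drop_qd, drop_fs])
        assert out == [keep]

    def test_missing_annotations_pass(self):
        site = _site((0, 1), (10, 12))
        assert hard_filter([site]) == [site]

    def test_biallelic_restriction(self):
        bi = _site((0, 1), (10, 12))
        tri = _site((1, 2), (1, 20, 19))
        assert hard_filter([bi, tri], biallelic_only=True) == [bi]


class TestAllelicState:
    @pytest.mark.parametrize("gt,ad,expected", [
        ((0, 1), (12, 11), "biallelic"),
        ((1, 2), (1, 20, 19), "biallelic"),    # ref 2.5% < 5%
        ((1, 2), (6, 20, 18), "triallelic"),   # ref 13.6% >= 5%
    ])
    def test_rules(self, gt, ad, expected):
        assert classify_allelic_state(_site(gt, ad)) == expected

    def test_stable_under_depth_scaling(self):
        for gt, ad in [((0, 1), (12, 11)), ((1, 2), (1, 20, 19)),
                       ((1, 2), (6, 20, 18))]:
            base = classify_allelic_state(_site(gt, ad))
            scaled = classify_allelic_state(_site(gt, tuple(10 * d for d in ad)))
            assert base == scaled

    def test_missing_ad_rejected(self):
        with pytest.raises(ValueError):
            classify_allelic_state(VariantSite("A", 1, "A", ("C",),
                                               gt=(0, 1), ad=()))


class TestHetDensityAndLoh:
    def test_window_arithmetic(self):
        sites = [VariantSite("A", p, "A", ("C",), gt=(0, 1), ad=(5, 5))
                 for p in (1_000, 5_000, 15_000)]
        df, pct = het_density_windows(sites, ref_length=20_000)
        assert df.het_count.tolist() == [2, 1]
        assert pct == pytest.approx(100 * 3 / 20_000)

    def test_zero_sites_all_zero(self):
        df, pct = het_density_windows([], ref_length=30_000)
        assert df.het_count.sum() == 0 and pct == 0.0

    def test_planted_rate_recovered(self, allotriploid_run):
        run = allotriploid_run
        sites = hard_filter(pileup_genotype(run.assignment, run.pair.seq_a, "A"),
                            biallelic_only=True)
        df, _ = het_density_windows(sites, ref_length=200_000)
        outside = df[(df.end <= 60_000) | (df.start >= 140_000)]
        # planted 5 het/kb -> 50 per full 10-kb window
        assert abs(outside.het_count.mean() - 50) / 50 < 0.10

    def test_loh_tract_recovered(self, allotriploid_run):
        run = allotriploid_run
        sites = hard_filter(pileup_genotype(run.assignment, run.pair.seq_a, "A"),
                            biallelic_only=True)
        df, _ = het_density_windows(sites, ref_length=200_000)
        segments = detect_loh(df)
        assert len(segments) == 1
        s, e = segments[0]
        inter = min(e, 140_000) - max(s, 60_000)
        assert inter / (140_000 - 60_000) >= 0.8
        assert inter / (e - s) >= 0.8

    def test_uniform_high_het_no_segments(self):
        df = pd.DataFrame({"start": range(0, 100_000, 10_000),
                           "end": range(10_000, 110_000, 10_000),
                           "het_count": [40] * 10})
        assert detect_loh(df) == []

    def test_fully_homozygous_single_segment(self):
        df, _ = het_density_windows([], ref_length=100_000)
        assert detect_loh(df) == [(0, 100_000)]


class TestMinorAlleleWindows:
    def test_single_site_fraction(self):
        site = VariantSite("A", 10, "A", ("C",), gt=(0, 1), ad=(10, 20))
        df, mode, _ = minor_allele_windows([site], ref_length=2_000)
        assert df.minor_fraction.iloc[0] == pytest.approx(1 / 3)

    def test_diploid_mode_half(self, allotriploid_run):
        run = allotriploid_run
        sites = hard_filter(pileup_genotype(run.assignment, run.pair.seq_a, "A"),
                            biallelic_only=True)
        _, mode, verdict = minor_allele_windows(sites, ref_length=200_000)
        assert abs(mode - 0.5) <= 0.03
        assert verdict == "even balance (1/2)"

    def test_triploid_mode_third(self, triploid_a_run):
        run = triploid_a_run
        sites = hard_filter(pileup_genotype(run.assignment, run.pair.seq_a, "A"),
                            biallelic_only=True)
        _, mode, verdict = minor_allele_windows(sites, ref_length=100_000)
        assert abs(mode - 1 / 3) <= 0.04
        assert verdict == "triploid-like (1/3-2/3)"

    def test_empty_input(self):
        df, mode, verdict = minor_allele_windows([], ref_length=1_000)
        assert df.empty and verdict == "no biallelic sites"


class TestIbs:
    def _geno(self, rows):
        return pd.DataFrame(rows, columns=["s1", "s2"])

    def test_definition_cases(self):
        geno = self._geno([
            [("A", "A"), ("T", "T")],   # IBS0
            [("A", "T"), ("A", "A")],   # IBS1
            [("C", "C"), ("C", "C")],   # IBS2: counted in neither
        ])
        [pair] = ibs_matrix(geno)
        assert (pair.ibs0, pair.ibs1, pair.sites) == (1, 1, 3)

    def test_identical_strains_zero(self):
        geno = self._geno([[("A", "T"), ("A", "T")], [("C", "C"), ("C", "C")]])
        [pair] = ibs_matrix(geno)
        assert pair.ibs0 == pair.ibs1 == 0

    def test_symmetry_and_conservation(self):
        rng = np.random.default_rng(1)
        alleles = "ACGT"
        rows = [[tuple(sorted(rng.choice(list(alleles), 2))) for _ in range(3)]
                for _ in range(50)]
        geno = pd.DataFrame(rows, columns=["x", "y", "z"])
        pairs = ibs_matrix(geno)
        rev = ibs_matrix(geno[["z", "y", "x"]])
        fwd = {(frozenset((p.strain_a, p.strain_b))): (p.ibs0, p.ibs1) for p in pairs}
        bwd = {(frozenset((p.strain_a, p.strain_b))): (p.ibs0, p.ibs1) for p in rev}
        assert fwd == bwd
        for p in pairs:
            assert p.ibs0 + p.ibs1 <= p.sites

    def test_haploid_mode_ibs0_only(self):
        geno = self._geno([[("A", "A"), ("T", "T")], [("A", "T"), ("A", "A")]])
        [pair] = ibs_matrix(geno, haploid=True)
        assert pair.ibs0 == 1 and pair.ibs1 == 0

    def test_two_strains_required(self):
        with pytest.raises(ValueError):
            ibs_matrix(pd.DataFrame({"s1": [("A", "A")]}))


class TestPca:
    def _cluster_geno(self):
        rng = np.random.default_rng(2)
        n_sites = 120
        rows = []
        for j in range(n_sites):
            fixed_diff = j < 100
            row = {}
            for strain in ["a1", "a2", "a3", "b1", "b2", "b3"]:
                group_b = strain.startswith("b")
                if fixed_diff:
                    row[strain] = ("T", "T") if group_b else ("A", "A")
                else:
                    row[strain] = tuple(sorted(rng.choice(list("AC"), 2)))
            rows.append(row)
        return pd.DataFrame(rows, index=range(1, n_sites + 1))

    def test_planted_clusters_separate_on_pc1(self):
        coords, var_frac = snp_pca(self._cluster_geno())
        assert var_frac[0] > 0.9
        a = coords.loc[["a1", "a2", "a3"], "PC1"]
        b = coords.loc[["b1", "b2", "b3"], "PC1"]
        assert max(a) < min(b) or max(b) < min(a)

    def test_duplicated_strain_identical_coordinates(self):
        geno = self._cluster_geno()
        geno["a1_dup"] = geno["a1"]
        coords, _ = snp_pca(geno)
        assert np.allclose(coords.loc["a1"], coords.loc["a1_dup"])

    def test_variance_fractions_sum_to_one(self):
        _, var_frac = snp_pca(self._cluster_geno())
        assert var_frac.sum() == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        geno = pd.DataFrame({s: [("A", "A")] * 5 for s in ["x", "y", "z"]},
                            index=range(1, 6))
        with pytest.raises(ValueError):
            snp_pca(geno)


class TestJointGenotypes:
    def test_union_positions_with_ref_fill(self):
        ref = "ACGTACGTAC"
        s1 = [VariantSite("A", 3, "G", ("T",), gt=(0, 1), ad=(5, 5))]
        s2 = [VariantSite("A", 7, "G", ("C",), gt=(1, 1), ad=(0, 9))]
        geno = joint_genotypes({"x": s1, "y": s2}, ref)
        assert list(geno.index) == [3, 7]
        assert geno.loc[3, "x"] == ("G", "T")
        assert geno.loc[3, "y"] == ("G", "G")   # homozygous-reference fill
        assert geno.loc[7, "y"] == ("C", "C")


class TestSamAndVcfIo:
    def test_sam_import_uniqueness_rule(self, tmp_path):
        header = "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:1000\n"
        # r1 better in A; r2 mapped only in B; r3 tied -> ambiguous
        sam_a = header + (
            "r1\t0\tref\t10\t60\t20M\t*\t0\t0\tACGTACGTACGTACGTACGT\t*\tAS:i:0\n"
            "r3\t0\tref\t50\t60\t20M\t*\t0\t0\tACGTACGTACGTACGTACGT\t*\tAS:i:-2\n")
        sam_b = header + (
            "r1\t0\tref\t10\t60\t20M\t*\t0\t0\tACGTACGTACGTACGTACGT\t*\tAS:i:-5\n"
            "r2\t0\tref\t30\t60\t20M\t*\t0\t0\tACGTACGTACGTACGTACGT\t*\tAS:i:0\n"
            "r3\t0\tref\t50\t60\t20M\t*\t0\t0\tACGTACGTACGTACGTACGT\t*\tAS:i:-2\n")
        fa = tmp_path / "a.sam"
        fb = tmp_path / "b.sam"
        fa.write_text(sam_a)
        fb.write_text(sam_b)
        asg = assign_reads_from_sam(str(fa), str(fb))
        assert asg.counts == {"A": 1, "B": 1, "ambiguous": 1, "unmapped": 0}

    def test_vcf_roundtrip_with_annotations(self, tmp_path):
        sites = [
            VariantSite("chr1", 5, "A", ("C",), gt=(0, 1), ad=(12, 11),
                        annotations={"QD": 4.9, "FS": 10.0}),
            VariantSite("chr1", 9, "G", ("T", "A"), gt=(1, 2), ad=(1, 20, 19)),
        ]
        path = tmp_path / "calls.vcf"
        write_vcf_sites(sites, str(path), contigs={"chr1": 100})
        back = read_vcf_sites(str(path))
        assert [(s.pos, s.ref, s.alts, tuple(sorted(s.gt)), s.ad) for s in back] == \
               [(s.pos, s.ref, s.alts, tuple(sorted(s.gt)), s.ad) for s in sites]
        assert back[0].annotations["QD"] == pytest.approx(4.9)
        assert hard_filter(back) == back[1:]  # QD 4.9 < 5.0 removed
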