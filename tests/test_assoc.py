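"""QC, exact HWE/Fisher statistics, LD estimation, pruning, subsets."""

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pytest

from gannet.assoc import (
    AssociationResult,
    LDMatrix,
    QCThresholds,
    allelic_association,
    apply_qc,
    assign_risk_alleles,
    associate,
    bonferroni_threshold,
    fisher_exact_two_sided,
    hwe_exact_test,
    ld_prune,
    pairwise_r2,
    select_snp_subsets,
)
from gannet.genotype_data import MISSING_ALLELE, GenotypeDataset, SNPRecord
from gannet.simulate import SimSpec, simulate_genotypes


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def hwe_oracle(n_hom_a, n_het, n_hom_b):
    """Exact-rational enumeration of the conditional HWE distribution."""
    n = n_hom_a + n_het + n_hom_b
    rare = min(2 * n_hom_a + n_het, 2 * n_hom_b + n_het)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        ra, ca = (rare - h) // 2, n - (rare + h) // 2
        # multinomial count of genotype assignments times 2^het phase factor
        weights[h] = Fraction(
            factorial(n) * 2 ** h,
            factorial(ra) * factorial(ca) * factorial(h))
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


def fisher_oracle(a, b, c, d):
    """Exact-rational enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    probs = {}
    for x in range(0, min(r1, c1) + 1):
        if c1 - x < 0 or c1 - x > r2:
            continue
        probs[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), comb(r1 + r2, c1))
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


# --------------------------------------------------------------------------
# HWE exact test
# --------------------------------------------------------------------------

class TestHWE:
    def test_published_control_genotypes(self):
        # controls of the top IRF6 marker: printed HWE p = 0.58
        assert hwe_exact_test(30, 56, 33) == pytest.approx(0.58, abs=5e-3)

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(0, 0, 25) == 1.0
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_matches_enumeration_oracle_small_totals(self):
        for total in range(1, 31):
            for na in range(total + 1):
                for nh in range(total - na + 1):
                    nb = total - na - nh
                    rare = min(2 * na + nh, 2 * nb + nh)
                    if rare > 0 and nh % 2 != rare % 2:
                        continue  # unreachable configuration
                    assert hwe_exact_test(na, nh, nb) == pytest.approx(
                        hwe_oracle(na, nh, nb), abs=1e-12), (na, nh, nb)


# --------------------------------------------------------------------------
# Fisher / association
# --------------------------------------------------------------------------

class TestFisher:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            a, b, c, d = rng.integers(0, 21, size=4)
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12)

    def test_matches_scipy_cross_check(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                fisher_exact([[a, b], [c, d]]).pvalue, abs=1e-9)


class TestAllelicAssociation:
    def test_published_table_reproduced(self, table1_rows):
        for row in table1_rows:
            r = allelic_association(row.case_counts, row.control_counts,
                                    snp_id=row.snp_id)
            assert round(r.odds_ratio, 2) == row.odds_ratio, row.snp_id
            assert round(100 * r.raf_case, 1) == row.raf_case_pct
            assert round(100 * r.raf_control, 1) == row.raf_control_pct
            # CI bounds agree to within one unit in the last printed digit
            assert abs(r.ci_low - row.ci_low) <= 0.01 + 5e-3
            assert abs(r.ci_high - row.ci_high) <= 0.01 + 5e-3

    def test_symmetric_counts_give_null(self):
        r = allelic_association((10, 20, 10), (10, 20, 10))
        assert r.odds_ratio == 1.0
        assert r.fisher_p == 1.0

    def test_zero_cell_triggers_haldane_correction(self):
        r = allelic_association((0, 0, 10), (10, 0, 0))
        assert r.zero_cell_corrected
        assert np.isfinite(r.odds_ratio) and r.odds_ratio > 1

    def test_ci_brackets_or_and_narrows_with_n(self):
        narrow = allelic_association((40, 80, 40), (60, 70, 30))
        wide = allelic_association((4, 8, 4), (6, 7, 3))
        for r in (narrow, wide):
            assert r.ci_low <= r.odds_ratio <= r.ci_high
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)


class TestRiskAlleleAssignment:
    def test_case_enriched_allele_is_risk(self, paper_like):
        ds = assign_risk_alleles(paper_like[0])
        results = associate(ds)
        assert all(r.odds_ratio >= 1.0 - 1e-12 for r in results)

    def test_tie_goes_to_allele_b(self):
        snp = SNPRecord("rs1", "1", 1, "A", "G")
        a1 = np.array([["A"], ["G"], ["A"], ["G"]])
        a2 = np.array([["A"], ["G"], ["A"], ["G"]])
        ds = GenotypeDataset([snp], list("wxyz"), np.array([1, 1, 0, 0]), a1, a2)
        ds = assign_risk_alleles(ds)
        assert ds.snps[0].risk_allele == "G"


# --------------------------------------------------------------------------
# QC
# --------------------------------------------------------------------------

class TestQC:
    def _mk(self, a1, a2, phen):
        m = a1.shape[1]
        snps = []
        for j in range(m):
            obs = sorted((set(a1[:, j]) | set(a2[:, j])) - {MISSING_ALLELE})
            alleles = (obs + [c for c in "ACGT" if c not in obs])[:2]
            snps.append(SNPRecord(f"rs{j}", "1", j + 1, alleles[0], alleles[1]))
        ids = [f"s{i}" for i in range(a1.shape[0])]
        return GenotypeDataset(snps, ids, np.asarray(phen), a1, a2)

    def test_low_call_rate_snp_excluded(self):
        n = 40
        a1 = np.full((n, 2), "A")
        a2 = np.full((n, 2), "A")
        for j in range(2):  # both SNPs in HWE proportions
            a2[10:30, j] = "G"
            a1[30:, j] = "G"
            a2[30:, j] = "G"
        a1[:8, 0] = MISSING_ALLELE
        a2[:8, 0] = MISSING_ALLELE
        ds = self._mk(a1, a2, [1] * 20 + [0] * 20)
        clean, report = apply_qc(ds)
        reasons = {sid: reason for sid, reason, *_ in report.excluded_snps}
        assert reasons.get("rs0") == "call_rate"
        assert clean.snp_ids == ["rs1"]

    def test_monomorphic_snp_excluded_for_maf(self):
        n = 40
        a1 = np.full((n, 2), "A")
        a2 = np.full((n, 2), "A")
        # rs1 in HWE proportions (10 AA / 20 AG / 10 GG); rs0 monomorphic
        a2[10:30, 1] = "G"
        a1[30:, 1] = "G"
        a2[30:, 1] = "G"
        ds = self._mk(a1, a2, [1] * 20 + [0] * 20)
        clean, report = apply_qc(ds)
        reasons = {sid: reason for sid, reason, *_ in report.excluded_snps}
        assert reasons.get("rs0") == "maf"
        assert clean.snp_ids == ["rs1"]

    def test_exclusions_match_direct_tally(self, paper_like):
        dataset, _ = paper_like
        thresholds = QCThresholds()
        clean, report = apply_qc(dataset, thresholds)
        excluded = {sid for sid, *_ in report.excluded_snps}

        # independent per-SNP tally
        expected_excluded = set()
        controls = dataset.phenotypes == 0
        for j, snp in enumerate(dataset.snps):
            col_missing = dataset.missing_mask()[:, j]
            if 1 - col_missing.mean() < thresholds.min_call_rate:
                expected_excluded.add(snp.snp_id)
                continue
            counts = {"a": 0, "b": 0}
            tri = [0, 0, 0]
            tri_ctrl = [0, 0, 0]
            for i in range(dataset.n_samples):
                call = dataset.call(i, j)
                if call is None:
                    continue
                na = sum(1 for al in (dataset.allele1[i, j], dataset.allele2[i, j])
                         if al == snp.allele_a)
                counts["a"] += na
                counts["b"] += 2 - na
                tri[na] += 1
                if controls[i]:
                    tri_ctrl[na] += 1
            maf = min(counts.values()) / sum(counts.values())
            if maf <= thresholds.min_maf:
                expected_excluded.add(snp.snp_id)
                continue
            if hwe_exact_test(tri_ctrl[2], tri_ctrl[1], tri_ctrl[0]) <= thresholds.min_hwe_p:
                expected_excluded.add(snp.snp_id)
        assert excluded == expected_excluded
        assert set(clean.snp_ids) == set(dataset.snp_ids) - expected_excluded


def test_bonferroni_two_significant_figures():
    assert bonferroni_threshold(0.05, 92) == 5.4e-4


# --------------------------------------------------------------------------
# LD
# --------------------------------------------------------------------------

class TestPairwiseR2:
    def test_duplicated_snp_has_r2_one(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=50)
        a1 = np.where(dos >= 1, "G", "A").reshape(-1, 1)
        a2 = np.where(dos == 2, "G", "A").reshape(-1, 1)
        ds = GenotypeDataset(
            [SNPRecord("rs0", "1", 1, "A", "G"), SNPRecord("rs1", "1", 2, "A", "G")],
            [f"s{i}" for i in range(50)], np.zeros(50, dtype=int),
            np.hstack([a1, a1]), np.hstack([a2, a2]))
        ld = pairwise_r2(ds)
        assert ld.r2_between("rs0", "rs1") == pytest.approx(1.0, abs=1e-6)

    def test_independent_snps_near_zero(self):
        spec = SimSpec(n_snps=2, n_cases=10, n_controls=10000,
                       control_raf=np.array([0.5, 0.5]),
                       causal_or=np.ones(2), missing_rate=0.0, seed=123)
        ds, _ = simulate_genotypes(spec)
        ld = pairwise_r2(ds)
        assert ld.r2_between("snp001", "snp002") < 0.01

    def test_em_recovers_constructed_disequilibrium(self):
        # haplotype freqs with pA=0.6, pB=0.5, D=0.15 -> r² = 0.375
        f = {"GG": 0.45, "GA": 0.15, "AG": 0.05, "AA": 0.35}
        n_hap = 4000
        haps = []
        for pair, freq in f.items():
            haps += [pair] * int(freq * n_hap)
        rng = np.random.default_rng(9)
        rng.shuffle(haps)
        h1, h2 = haps[0::2], haps[1::2]
        a1 = np.array([[h[0] for h in h1], [h[1] for h in h1]]).T
        a2 = np.array([[h[0] for h in h2], [h[1] for h in h2]]).T
        ds = GenotypeDataset(
            [SNPRecord("rsA", "1", 1, "A", "G"), SNPRecord("rsB", "1", 2, "A", "G")],
            [f"s{i}" for i in range(len(h1))],
            np.zeros(len(h1), dtype=int), a1, a2)
        ld = pairwise_r2(ds)
        d = f["GG"] - 0.6 * 0.5
        expected = d * d / (0.6 * 0.4 * 0.5 * 0.5)
        assert ld.r2_between("rsA", "rsB") == pytest.approx(expected, abs=0.02)

    def test_monomorphic_pair_flagged_zero(self):
        a1 = np.array([["A", "A"]] * 30)
        a2 = np.array([["A", "G"]] * 15 + [["A", "A"]] * 15)
        ds = GenotypeDataset(
            [SNPRecord("rs0", "1", 1, "A", "G"), SNPRecord("rs1", "1", 2, "A", "G")],
            [f"s{i}" for i in range(30)], np.zeros(30, dtype=int), a1, a2)
        ld = pairwise_r2(ds)
        assert ld.monomorphic[0]
        assert ld.r2_between("rs0", "rs1") == 0.0


# --------------------------------------------------------------------------
# Pruning and subsets
# --------------------------------------------------------------------------

def _fake_result(snp_id, p):
    return AssociationResult(
        snp_id=snp_id, genotype_counts_case=(10, 10, 10),
        genotype_counts_control=(10, 10, 10), raf_case=0.5, raf_control=0.5,
        odds_ratio=1.0, ci_low=0.5, ci_high=2.0, fisher_p=p)


def _ld_from(snp_ids, pairs):
    m = len(snp_ids)
    r2 = np.zeros((m, m))
    np.fill_diagonal(r2, 1.0)
    pos = {s: i for i, s in enumerate(snp_ids)}
    for (a, b), v in pairs.items():
        r2[pos[a], pos[b]] = r2[pos[b], pos[a]] = v
    return LDMatrix(list(snp_ids), r2, np.zeros(m, dtype=bool))


class TestLdPrune:
    def test_r2_exactly_at_threshold_keeps_both(self):
        results = [_fake_result("rs2235373", 3.5e-4), _fake_result("rs2235371", 4.4e-4)]
        ld = _ld_from(["rs2235373", "rs2235371"], {("rs2235373", "rs2235371"): 0.80})
        assert ld_prune(results, ld) == ["rs2235373", "rs2235371"]

    def test_tight_pair_keeps_lower_p_member(self):
        results = [_fake_result("rs2013162", 1.5e-3), _fake_result("rs2235375", 2.1e-3)]
        ld = _ld_from(["rs2013162", "rs2235375"], {("rs2013162", "rs2235375"): 0.98})
        assert ld_prune(results, ld) == ["rs2013162"]

    def test_no_ld_keeps_all(self):
        results = [_fake_result(f"rs{i}", 0.01 * (i + 1)) for i in range(5)]
        ld = _ld_from([r.snp_id for r in results], {})
        assert len(ld_prune(results, ld)) == 5

    def test_output_max_r2_post_hoc(self, paper_like):
        ds = assign_risk_alleles(paper_like[0])
        results = associate(ds)
        ld = pairwise_r2(ds)
        kept = ld_prune(results, ld)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.r2_between(a, b) <= 0.8


class TestSubsets:
    def test_engineered_sizes_3_10_16(self):
        ps = ([0.001] * 3 + [0.02] * 7 + [0.07] * 6 + [0.5] * 10)
        results = [_fake_result(f"rs{i:02d}", p) for i, p in enumerate(ps)]
        ld = _ld_from([r.snp_id for r in results], {})
        subsets = {s.label: s for s in select_snp_subsets(results, ld)}
        assert (len(subsets["p001"]), len(subsets["p005"]), len(subsets["p01"])) == (3, 10, 16)
        assert len(subsets["all"]) == len(results)

    def test_empty_threshold_warns(self):
        results = [_fake_result("rs0", 0.9)]
        ld = _ld_from(["rs0"], {})
        with pytest.warns(UserWarning, match="empty"):
            subsets = select_snp_subsets(results, ld)
        assert len(subsets[0]) == 0

    def test_subsets_are_nested(self, paper_like):
        ds = assign_risk_alleles(paper_like[0])
        results = associate(ds)
        ld = pairwise_r2(ds)
        by_label = {s.label: set(s.snp_ids) for s in select_snp_subsets(results, ld)}
        assert by_label["p001"] <= by_label["p005"] <= by_label["p01"] <= by_label["all"]
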