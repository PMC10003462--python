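"""SNP quality control and single-marker association statistics.

Implements the classical case-control toolkit for a candidate-gene panel:

* exact Hardy-Weinberg equilibrium test (conditional on allele counts,
  summing configurations no more probable than the observed one);
* allelic Fisher's exact association on the 2x2 risk/non-risk allele table,
  with the cross-product sample odds ratio and a Woolf log-normal 95% CI;
* maximum-likelihood pairwise r² from unphased genotypes via the standard
  two-locus haplotype-frequency EM;
* greedy LD pruning and p-threshold subset selection.

Counts are always ordered (NN, NR, RR): non-risk homozygote, heterozygote,
risk homozygote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import comb

import numpy as np
import pandas as pd

from .genotype_data import MISSING_ALLELE, GenotypeDataset

__all__ = [
    "QCThresholds",
    "QCReport",
    "AssociationResult",
    "LDMatrix",
    "SNPSubsetSpec",
    "apply_qc",
    "hwe_exact_test",
    "fisher_exact_two_sided",
    "allelic_association",
    "associate",
    "assign_risk_alleles",
    "pairwise_r2",
    "ld_prune",
    "select_snp_subsets",
    "association_table",
    "bonferroni_threshold",
]


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Marker/sample inclusion thresholds.

    Defaults follow common practice for candidate-SNP panels: 95% call rate
    for both SNPs and samples, MAF > 1%, HWE exact p > 0.01 evaluated in
    controls.
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 0.01
    hwe_group: str = "controls_only"  # or "all"

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.hwe_group not in ("controls_only", "all"):
            raise ValueError(f"hwe_group must be 'controls_only' or 'all'")


@dataclass
class QCReport:
    """Exclusions with reasons; one row per removed SNP or sample."""

    excluded_snps: list[tuple[str, str, float, float]] = field(default_factory=list)
    excluded_samples: list[tuple[str, str, float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", *r) for r in self.excluded_snps]
        rows += [("sample", *r) for r in self.excluded_samples]
        return pd.DataFrame(rows, columns=["kind", "id", "reason", "value", "threshold"])


def _allele_counts(dataset: GenotypeDataset, j: int, mask=None) -> tuple[int, int]:
    """(count of allele_a, count of allele_b) at SNP j over masked samples."""
    snp = dataset.snps[j]
    a1 = dataset.allele1[:, j]
    a2 = dataset.allele2[:, j]
    if mask is not None:
        a1, a2 = a1[mask], a2[mask]
    n_a = int(np.sum(a1 == snp.allele_a) + np.sum(a2 == snp.allele_a))
    n_b = int(np.sum(a1 == snp.allele_b) + np.sum(a2 == snp.allele_b))
    return n_a, n_b


def _genotype_triple(dataset: GenotypeDataset, j: int, mask=None) -> tuple[int, int, int]:
    """(hom_a, het, hom_b) counts at SNP j over masked samples."""
    snp = dataset.snps[j]
    a1 = dataset.allele1[:, j]
    a2 = dataset.allele2[:, j]
    if mask is not None:
        a1, a2 = a1[mask], a2[mask]
    present = a1 != MISSING_ALLELE
    a1, a2 = a1[present], a2[present]
    hom_a = int(np.sum((a1 == snp.allele_a) & (a2 == snp.allele_a)))
    hom_b = int(np.sum((a1 == snp.allele_b) & (a2 == snp.allele_b)))
    het = int(a1.size - hom_a - hom_b)
    return hom_a, het, hom_b


def apply_qc(
    dataset: GenotypeDataset, thresholds: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Drop SNPs failing call-rate/MAF/HWE, then low-call-rate samples.

    SNP filters are applied first (on all samples); the sample call-rate
    filter then runs on the retained SNPs only. MAF uses all samples; the
    HWE test group is configurable (controls by default).
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if dataset.n_snps == 0 or dataset.n_samples == 0:
        raise ValueError("empty dataset")
    report = QCReport()
    missing = dataset.missing_mask()
    hwe_mask = None if thresholds.hwe_group == "all" else dataset.phenotypes == 0

    keep_snps = []
    for j, snp in enumerate(dataset.snps):
        call_rate = 1.0 - missing[:, j].mean()
        if call_rate < thresholds.min_call_rate:
            report.excluded_snps.append(
                (snp.snp_id, "call_rate", call_rate, thresholds.min_call_rate))
            continue
        n_a, n_b = _allele_counts(dataset, j)
        total = n_a + n_b
        maf = min(n_a, n_b) / total if total else 0.0
        if maf <= thresholds.min_maf:
            report.excluded_snps.append((snp.snp_id, "maf", maf, thresholds.min_maf))
            continue
        hwe_p = hwe_exact_test(*_genotype_triple(dataset, j, hwe_mask))
        if hwe_p <= thresholds.min_hwe_p:
            report.excluded_snps.append((snp.snp_id, "hwe", hwe_p, thresholds.min_hwe_p))
            continue
        keep_snps.append(snp.snp_id)
    if not keep_snps:
        raise ValueError("all SNPs excluded by QC")

    trimmed = dataset.subset_snps(keep_snps)
    miss2 = trimmed.missing_mask()
    keep_samples = []
    for i, sid in enumerate(trimmed.sample_ids):
        call_rate = 1.0 - miss2[i, :].mean()
        if call_rate < thresholds.min_call_rate:
            report.excluded_samples.append(
                (sid, "call_rate", call_rate, thresholds.min_call_rate))
        else:
            keep_samples.append(i)
    return trimmed.subset_samples(keep_samples), report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact two-sided HWE p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose probability under HWE does not exceed
    that of the observed count. Returns 1.0 when only one configuration is
    attainable (e.g. a monomorphic marker).
    """
    counts = (n_hom_a, n_het, n_hom_b)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype counts: {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotypes")
    rare = min(2 * n_hom_a + n_het, 2 * n_hom_b + n_het)
    if rare == 0:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    het_values = list(range(rare % 2, rare + 1, 2))
    # unnormalized probabilities via the standard ratio recurrence, anchored
    # at the mid-range het count for numerical stability
    probs = {h: 0.0 for h in het_values}
    mid = het_values[len(het_values) // 2]
    probs[mid] = 1.0
    h = mid
    while h + 2 <= rare:
        ra = (rare - h) // 2          # rare homozygotes at het = h
        ca = n - (rare + h) // 2      # common homozygotes at het = h
        probs[h + 2] = probs[h] * (4.0 * ra * ca) / ((h + 2.0) * (h + 1.0))
        h += 2
    h = mid
    while h - 2 >= het_values[0]:
        probs[h - 2] = probs[h] * (h * (h - 1.0)) / (
            4.0 * ((rare - h) // 2 + 1.0) * (n - (rare + h) // 2 + 1.0))
        h -= 2

    total = sum(probs.values())
    observed = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= observed * (1 + 1e-12)) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Allelic association
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the conditional (hypergeometric) probabilities of every table with
    the observed margins whose point probability does not exceed the
    observed table's. Small tables (total <= 500) use integer arithmetic, so
    tie comparisons are exact; larger tables fall back to the scipy routine
    (identical convention, float hypergeometric weights).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    if r1 + r2 > 500:
        from scipy.stats import fisher_exact as _scipy_fisher
        return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    total = sum(weights)
    num = sum(w for w in weights if w <= w_obs)
    return num / total


@dataclass
class AssociationResult:
    """Per-SNP allelic association summary (Table-style row)."""

    snp_id: str
    genotype_counts_case: tuple[int, int, int]
    genotype_counts_control: tuple[int, int, int]
    raf_case: float
    raf_control: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    fisher_p: float
    hwe_p: float = float("nan")
    zero_cell_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError(
                f"{self.snp_id}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket OR {self.odds_ratio}")


def _raf(counts: tuple[int, int, int]) -> float:
    nn, nr, rr = counts
    total = nn + nr + rr
    return (nr + 2 * rr) / (2 * total) if total else float("nan")


def allelic_association(
    case_counts: tuple[int, int, int],
    control_counts: tuple[int, int, int],
    *,
    snp_id: str = "",
    hwe_p: float = float("nan"),
) -> AssociationResult:
    """Allelic Fisher's exact association from genotype counts.

    Builds the 2x2 allele table (risk/non-risk x case/control), computes the
    two-sided Fisher exact p on the integer table, the cross-product odds
    ratio and its Woolf 95% CI. A zero allele cell triggers the Haldane-
    Anscombe +0.5 correction on all four cells (for OR and CI only) and is
    flagged on the result.
    """
    if sum(case_counts) == 0 or sum(control_counts) == 0:
        raise ValueError("both case and control groups must be non-empty")
    a = case_counts[1] + 2 * case_counts[2]        # case risk alleles
    b = 2 * case_counts[0] + case_counts[1]        # case non-risk
    c = control_counts[1] + 2 * control_counts[2]  # control risk
    d = 2 * control_counts[0] + control_counts[1]  # control non-risk

    p = fisher_exact_two_sided(a, b, c, d)

    corrected = 0 in (a, b, c, d)
    if corrected:
        af, bf, cf, df = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        af, bf, cf, df = float(a), float(b), float(c), float(d)
    odds_ratio = (af * df) / (bf * cf)
    se = np.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
    log_or = np.log(odds_ratio)
    ci_low = float(np.exp(log_or - 1.96 * se))
    ci_high = float(np.exp(log_or + 1.96 * se))

    return AssociationResult(
        snp_id=snp_id,
        genotype_counts_case=tuple(case_counts),
        genotype_counts_control=tuple(control_counts),
        raf_case=_raf(case_counts),
        raf_control=_raf(control_counts),
        odds_ratio=float(odds_ratio),
        ci_low=ci_low,
        ci_high=ci_high,
        fisher_p=float(p),
        hwe_p=hwe_p,
        zero_cell_corrected=corrected,
    )


def assign_risk_alleles(dataset: GenotypeDataset) -> GenotypeDataset:
    """Set each SNP's risk allele to the allele enriched in cases.

    The risk allele is the one with higher frequency in cases than in
    controls; exact ties go to ``allele_b``. After assignment, every SNP's
    allelic OR is >= 1 (equality only at a tie).
    """
    cases = dataset.phenotypes == 1
    controls = dataset.phenotypes == 0
    new_snps = []
    for j, snp in enumerate(dataset.snps):
        ca_a, ca_b = _allele_counts(dataset, j, cases)
        co_a, co_b = _allele_counts(dataset, j, controls)
        fa_case = ca_a / (ca_a + ca_b) if ca_a + ca_b else 0.0
        fa_ctrl = co_a / (co_a + co_b) if co_a + co_b else 0.0
        # allele_a is the risk allele iff it is strictly more case-enriched
        risk = snp.allele_a if fa_case - fa_ctrl > fa_ctrl - fa_case else snp.allele_b
        new_snps.append(replace(snp, risk_allele=risk))
    return GenotypeDataset(
        snps=new_snps,
        sample_ids=list(dataset.sample_ids),
        phenotypes=dataset.phenotypes.copy(),
        allele1=dataset.allele1.copy(),
        allele2=dataset.allele2.copy(),
    )


def associate(
    dataset: GenotypeDataset, *, hwe_group: str = "controls_only"
) -> list[AssociationResult]:
    """Run the allelic association over every SNP of a risk-assigned dataset."""
    cases = dataset.phenotypes == 1
    controls = dataset.phenotypes == 0
    hwe_mask = None if hwe_group == "all" else controls
    out = []
    for j, snp in enumerate(dataset.snps):
        if snp.risk_allele is None:
            raise ValueError(f"{snp.snp_id}: risk allele not assigned")
        case_triple = _oriented_triple(dataset, j, cases)
        ctrl_triple = _oriented_triple(dataset, j, controls)
        hwe_p = hwe_exact_test(*_genotype_triple(dataset, j, hwe_mask))
        out.append(allelic_association(
            case_triple, ctrl_triple, snp_id=snp.snp_id, hwe_p=hwe_p))
    return out


def _oriented_triple(dataset: GenotypeDataset, j: int, mask) -> tuple[int, int, int]:
    """(NN, NR, RR) counts oriented by the SNP's risk allele."""
    hom_a, het, hom_b = _genotype_triple(dataset, j, mask)
    snp = dataset.snps[j]
    if snp.risk_allele == snp.allele_a:
        return (hom_b, het, hom_a)
    return (hom_a, het, hom_b)


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Summary DataFrame with one row per SNP (TSV-friendly)."""
    rows = []
    for r in results:
        rows.append({
            "snp_id": r.snp_id,
            "raf_case_pct": round(100 * r.raf_case, 1),
            "raf_control_pct": round(100 * r.raf_control, 1),
            "hwe_p": r.hwe_p,
            "case_NN_NR_RR": "/".join(map(str, r.genotype_counts_case)),
            "control_NN_NR_RR": "/".join(map(str, r.genotype_counts_control)),
            "OR": round(r.odds_ratio, 2),
            "ci95_low": round(r.ci_low, 2),
            "ci95_high": round(r.ci_high, 2),
            "fisher_p": r.fisher_p,
        })
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 92) -> float:
    """Family-wise threshold alpha/n, rounded to two significant figures."""
    x = alpha / n_tests
    return float(f"{x:.1e}")


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDMatrix:
    """Symmetric pairwise r² with monomorphic-pair flags."""

    snp_ids: list[str]
    r2: np.ndarray
    monomorphic: np.ndarray  # per-SNP flag; pairs touching one are r²=0

    def __post_init__(self) -> None:
        self._pos = {sid: j for j, sid in enumerate(self.snp_ids)}

    def r2_between(self, snp1: str, snp2: str) -> float:
        return float(self.r2[self._pos[snp1], self._pos[snp2]])


def _em_haplotype_r2(c: np.ndarray, *, tol: float = 1e-8, max_iter: int = 1000) -> float:
    """r² from a 3x3 genotype-count table via the two-locus haplotype EM.

    ``c[i, j]`` counts samples with i copies of the reference allele at the
    first SNP and j at the second. Phase is ambiguous only for double
    heterozygotes; the EM splits them between cis and trans configurations.
    """
    n_hap = 2.0 * c.sum()
    # phase-known haplotype contributions
    base11 = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    base10 = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    base01 = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    base00 = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    dh = c[1, 1]

    f = np.array([base11 + dh / 2, base10 + dh / 2,
                  base01 + dh / 2, base00 + dh / 2]) / n_hap
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = np.array([
            base11 + dh * w, base10 + dh * (1 - w),
            base01 + dh * (1 - w), base00 + dh * w,
        ]) / n_hap
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return 0.0
    d = f[0] - p_a * p_b
    return float(min(1.0, d * d / denom))


def pairwise_r2(dataset: GenotypeDataset, *, group: str = "controls") -> LDMatrix:
    """Pairwise LD r² estimated by EM from unphased genotypes.

    By convention the estimate uses control samples only (``group`` may be
    "controls", "cases" or "all"). A monomorphic SNP yields r² = 0 with every
    partner and is flagged.
    """
    if group == "controls":
        mask = dataset.phenotypes == 0
    elif group == "cases":
        mask = dataset.phenotypes == 1
    elif group == "all":
        mask = np.ones(dataset.n_samples, dtype=bool)
    else:
        raise ValueError(f"unknown group {group!r}")

    m = dataset.n_snps
    # per-SNP dosage of allele_a within the group (-1 marks missing)
    dosages = np.full((int(mask.sum()), m), -1, dtype=np.int8)
    mono = np.zeros(m, dtype=bool)
    rows = np.nonzero(mask)[0]
    for j, snp in enumerate(dataset.snps):
        a1 = dataset.allele1[rows, j]
        a2 = dataset.allele2[rows, j]
        present = a1 != MISSING_ALLELE
        dos = (a1 == snp.allele_a).astype(np.int8) + (a2 == snp.allele_a).astype(np.int8)
        dos[~present] = -1
        dosages[:, j] = dos
        seen = dos[present]
        n_a_allele = int(seen.sum()) if seen.size else 0
        mono[j] = seen.size == 0 or n_a_allele == 0 or n_a_allele == 2 * seen.size

    r2 = np.zeros((m, m))
    np.fill_diagonal(r2, 1.0)
    r2[mono, :] = 0.0
    r2[:, mono] = 0.0
    for j in range(m):
        if mono[j]:
            continue
        for k in range(j + 1, m):
            if mono[k]:
                continue
            gj, gk = dosages[:, j], dosages[:, k]
            ok = (gj >= 0) & (gk >= 0)
            c = np.zeros((3, 3))
            np.add.at(c, (gj[ok], gk[ok]), 1.0)
            val = _em_haplotype_r2(c)
            r2[j, k] = r2[k, j] = val
    return LDMatrix(list(dataset.snp_ids), r2, mono)


# ---------------------------------------------------------------------------
# Pruning and subset selection
# ---------------------------------------------------------------------------

def ld_prune(
    results: list[AssociationResult], ld: LDMatrix, r2_max: float = 0.8
) -> list[str]:
    """Greedy LD pruning by ascending Fisher p.

    Visits SNPs from most to least significant (ties by snp_id) and keeps a
    SNP iff its r² with every already-kept SNP is <= ``r2_max`` (strictly
    greater values are excluded).
    """
    order = sorted(results, key=lambda r: (r.fisher_p, r.snp_id))
    kept: list[str] = []
    for r in order:
        if all(ld.r2_between(r.snp_id, k) <= r2_max for k in kept):
            kept.append(r.snp_id)
    return kept


@dataclass
class SNPSubsetSpec:
    """A p-threshold SNP subset, LD-pruned, ordered by ascending p."""

    label: str
    p_threshold: float | None
    snp_ids: list[str]

    def __len__(self) -> int:
        return len(self.snp_ids)


def select_snp_subsets(
    results: list[AssociationResult],
    ld: LDMatrix,
    thresholds: tuple[float, ...] = (0.01, 0.05, 0.1),
    *,
    r2_max: float = 0.8,
) -> list[SNPSubsetSpec]:
    """Build the p-threshold subsets plus the unpruned "all" subset.

    LD pruning (r² > ``r2_max`` excluded, keeping the lower-p member) runs
    once over all SNPs; each threshold subset is the pruned SNPs with
    fisher_p strictly below the threshold, so subsets are nested.
    """
    p_by_id = {r.snp_id: r.fisher_p for r in results}
    pruned = ld_prune(results, ld, r2_max)
    pruned_sorted = sorted(pruned, key=lambda sid: (p_by_id[sid], sid))
    out = []
    for thr in sorted(thresholds):
        members = [sid for sid in pruned_sorted if p_by_id[sid] < thr]
        label = "p" + f"{thr:g}".replace("0.", "0").replace(".", "")
        if not members:
            warnings.warn(f"no SNPs pass p < {thr}; subset {label} is empty")
        out.append(SNPSubsetSpec(label, thr, members))
    all_sorted = sorted(p_by_id, key=lambda sid: (p_by_id[sid], sid))
    out.append(SNPSubsetSpec("all", None, all_sorted))
    return out
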