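"""End-to-end convenience wiring: QC -> association -> LD -> dosage matrix.

These helpers chain the module-level operations in the canonical order so
the CLI, examples and experiment harnesses share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import assoc as assoc_mod
from .assoc import LDMatrix, QCReport, QCThresholds, SNPSubsetSpec
from .genotype_data import GenotypeDataset, GenotypeMatrix, encode_additive, impute_missing

__all__ = ["PreparedData", "prepare"]


@dataclass
class PreparedData:
    """Everything downstream modeling needs, derived from one dataset."""

    dataset: GenotypeDataset          # QC-passed, risk alleles assigned
    qc_report: QCReport
    results: list                     # AssociationResult per SNP
    ld: LDMatrix
    subsets: list[SNPSubsetSpec]
    matrix: GenotypeMatrix            # additive dosages, imputed

    def subset(self, label: str) -> SNPSubsetSpec:
        for s in self.subsets:
            if s.label == label:
                return s
        raise KeyError(f"no subset labelled {label!r}")


def prepare(
    dataset: GenotypeDataset,
    thresholds: QCThresholds | None = None,
    *,
    skip_qc: bool = False,
) -> PreparedData:
    """Run QC, assign risk alleles, associate, estimate LD, encode, impute."""
    if thresholds is None:
        thresholds = QCThresholds()
    if skip_qc:
        clean, report = dataset, QCReport()
    else:
        clean, report = assoc_mod.apply_qc(dataset, thresholds)
    clean = assoc_mod.assign_risk_alleles(clean)
    hwe_group = "all" if thresholds.hwe_group == "all" else "controls_only"
    results = assoc_mod.associate(clean, hwe_group=hwe_group)
    ld = assoc_mod.pairwise_r2(clean)
    subsets = assoc_mod.select_snp_subsets(results, ld)
    matrix = encode_additive(clean)
    if clean.missing_mask().any():
        matrix = impute_missing(matrix, ld)
    return PreparedData(clean, report, results, ld, subsets, matrix)
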