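"""Case-control genotype data model and I/O.

Genotypes are unordered biallelic allele pairs per (sample, SNP). Two text
dialects are supported: PLINK .ped/.map and a simple TSV matrix (samples x
SNPs, cells like "AG" or "NA"). The additive encoding counts copies of each
SNP's risk allele (0/1/2); missing calls stay missing (NaN) until imputed.

Missing data conventions: in allele space the PLINK code "0" marks a missing
allele; in dosage space missing is ``numpy.nan`` (never -1 or 3), so stray
arithmetic on missing entries propagates visibly instead of silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MISSING",
    "MISSING_ALLELE",
    "ParseError",
    "SNPRecord",
    "GenotypeDataset",
    "GenotypeMatrix",
    "read_plink_text",
    "write_plink_text",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "encode_additive",
    "decode_additive",
    "impute_missing",
]

#: Missing dosage sentinel (out-of-band: arithmetic with it propagates NaN).
MISSING = float("nan")

#: PLINK missing-allele code.
MISSING_ALLELE = "0"


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def is_missing(values) -> np.ndarray:
    """Elementwise mask of missing dosages."""
    return np.isnan(np.asarray(values, dtype=float))


@dataclass
class SNPRecord:
    """A biallelic marker: identity, position, alleles, optional risk allele."""

    snp_id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str
    risk_allele: str | None = None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(
                f"{self.snp_id}: alleles must differ (got {self.allele_a!r} twice)"
            )
        if self.risk_allele is not None and self.risk_allele not in (
            self.allele_a,
            self.allele_b,
        ):
            raise ValueError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} is not one of "
                f"({self.allele_a!r}, {self.allele_b!r})"
            )

    @property
    def non_risk_allele(self) -> str:
        if self.risk_allele is None:
            raise ValueError(f"{self.snp_id}: risk allele not assigned")
        return self.allele_b if self.risk_allele == self.allele_a else self.allele_a


@dataclass
class GenotypeDataset:
    """Samples x SNPs of unordered allele-pair calls with binary phenotypes.

    ``allele1``/``allele2`` are (n_samples, n_snps) single-character arrays;
    a call is missing iff both are :data:`MISSING_ALLELE`. Phenotype 1 = case,
    0 = control.
    """

    snps: list[SNPRecord]
    sample_ids: list[str]
    phenotypes: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int64)
        n, m = len(self.sample_ids), len(self.snps)
        if self.allele1.shape != (n, m) or self.allele2.shape != (n, m):
            raise ValueError(
                f"call matrix shape {self.allele1.shape} != ({n}, {m})"
            )
        if self.phenotypes.shape != (n,):
            raise ValueError("one phenotype per sample required")
        if not np.all(np.isin(self.phenotypes, (0, 1))):
            raise ValueError("phenotypes must be 0 (control) / 1 (case)")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self._validate_alleles()

    def _validate_alleles(self) -> None:
        for j, snp in enumerate(self.snps):
            ok = {snp.allele_a, snp.allele_b, MISSING_ALLELE}
            seen = set(self.allele1[:, j]) | set(self.allele2[:, j])
            bad = seen - ok
            if bad:
                raise ValueError(f"{snp.snp_id}: unexpected alleles {sorted(bad)}")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def missing_mask(self) -> np.ndarray:
        return (self.allele1 == MISSING_ALLELE) & (self.allele2 == MISSING_ALLELE)

    def call(self, i: int, j: int) -> frozenset[str] | None:
        """Unordered allele pair at (sample i, SNP j); None if missing."""
        a, b = self.allele1[i, j], self.allele2[i, j]
        if a == MISSING_ALLELE:
            return None
        return frozenset((a, b))

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = list(indices)
        return GenotypeDataset(
            snps=[replace(s) for s in self.snps],
            sample_ids=[self.sample_ids[i] for i in idx],
            phenotypes=self.phenotypes[idx],
            allele1=self.allele1[idx, :].copy(),
            allele2=self.allele2[idx, :].copy(),
        )

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeDataset":
        pos = {s.snp_id: j for j, s in enumerate(self.snps)}
        missing = [sid for sid in snp_ids if sid not in pos]
        if missing:
            raise KeyError(f"unknown SNP ids: {missing}")
        idx = [pos[sid] for sid in snp_ids]
        return GenotypeDataset(
            snps=[replace(self.snps[j]) for j in idx],
            sample_ids=list(self.sample_ids),
            phenotypes=self.phenotypes.copy(),
            allele1=self.allele1[:, idx].copy(),
            allele2=self.allele2[:, idx].copy(),
        )

    def genotype_counts(self, j: int, sample_mask=None) -> dict[frozenset, int]:
        """Tally of unordered genotype calls at SNP j (missing excluded)."""
        n = self.n_samples
        mask = np.ones(n, dtype=bool) if sample_mask is None else sample_mask
        out: dict[frozenset, int] = {}
        for i in np.nonzero(mask)[0]:
            g = self.call(int(i), j)
            if g is not None:
                out[g] = out.get(g, 0) + 1
        return out


@dataclass
class GenotypeMatrix:
    """Additive risk-allele dosages: entries in {0, 1, 2} or NaN (missing)."""

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    phenotypes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int64)
        n, m = len(self.sample_ids), len(self.snp_ids)
        if self.values.shape != (n, m):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {m})")
        finite = self.values[~np.isnan(self.values)]
        if not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self.snp_ids.index(snp_id)]

    def select(self, snp_ids: Sequence[str]) -> np.ndarray:
        pos = {sid: j for j, sid in enumerate(self.snp_ids)}
        missing = [sid for sid in snp_ids if sid not in pos]
        if missing:
            raise KeyError(f"SNPs absent from matrix: {missing}")
        return self.values[:, [pos[sid] for sid in snp_ids]]


# ---------------------------------------------------------------------------
# PLINK text I/O
# ---------------------------------------------------------------------------

def read_plink_text(
    ped_path, map_path, *, pheno_01: bool = False
) -> GenotypeDataset:
    """Read a PLINK text fileset (.ped/.map).

    Phenotype codes follow PLINK (1 = control, 2 = case) unless ``pheno_01``.
    Allele code "0" marks a missing call. Sample and SNP order from the files
    is preserved.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ParseError(f"{map_path}:{ln}: expected 3-4 fields, got {len(parts)}")
        chrom, snp_id = parts[0], parts[1]
        pos = int(parts[-1])
        map_rows.append((chrom, snp_id, pos))
    m = len(map_rows)

    sample_ids: list[str] = []
    phenotypes: list[int] = []
    a1_rows: list[list[str]] = []
    a2_rows: list[list[str]] = []
    accepted = {0, 1} if pheno_01 else {1, 2}
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{ped_path}:{ln}: expected {6 + 2 * m} fields for {m} SNPs, "
                f"got {len(parts)}"
            )
        iid = parts[1]
        try:
            pheno = int(parts[5])
        except ValueError:
            raise ParseError(f"{ped_path}:{ln}: non-integer phenotype {parts[5]!r}")
        if pheno not in accepted:
            raise ValueError(
                f"{ped_path}:{ln}: phenotype {pheno} not in accepted codes {sorted(accepted)}"
            )
        sample_ids.append(iid)
        phenotypes.append(pheno if pheno_01 else pheno - 1)
        alleles = parts[6:]
        a1_rows.append(alleles[0::2])
        a2_rows.append(alleles[1::2])

    a1 = np.array(a1_rows, dtype="<U1").reshape(len(sample_ids), m)
    a2 = np.array(a2_rows, dtype="<U1").reshape(len(sample_ids), m)
    # half-missing calls (one allele "0") are treated as fully missing
    half = (a1 == MISSING_ALLELE) ^ (a2 == MISSING_ALLELE)
    a1[half] = MISSING_ALLELE
    a2[half] = MISSING_ALLELE

    snps = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        obs = sorted((set(a1[:, j]) | set(a2[:, j])) - {MISSING_ALLELE})
        if len(obs) > 2:
            raise ParseError(f"{snp_id}: more than two alleles observed: {obs}")
        if len(obs) == 0:
            obs = ["A", "B"]  # no calls at all; placeholder alleles
        elif len(obs) == 1:
            obs = obs + [_other_allele(obs[0])]
        snps.append(SNPRecord(snp_id, chrom, pos, obs[0], obs[1]))
    return GenotypeDataset(snps, sample_ids, np.array(phenotypes), a1, a2)


def _other_allele(a: str) -> str:
    for c in "ACGT":
        if c != a:
            return c
    return "B"


def write_plink_text(
    dataset: GenotypeDataset, ped_path, map_path, *, pheno_01: bool = False
) -> None:
    """Write the PLINK text dialect read by :func:`read_plink_text`."""
    with open(map_path, "w") as fh:
        for snp in dataset.snps:
            fh.write(f"{snp.chromosome}\t{snp.snp_id}\t0\t{snp.position}\n")
    offset = 0 if pheno_01 else 1
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            pheno = int(dataset.phenotypes[i]) + offset
            fields = [sid, sid, "0", "0", "0", str(pheno)]
            for j in range(dataset.n_snps):
                fields.append(dataset.allele1[i, j])
                fields.append(dataset.allele2[i, j])
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_genotype_tsv(path) -> GenotypeDataset:
    """Read the TSV genotype dialect.

    Header: ``sample_id<TAB>phenotype<TAB><snp1><TAB><snp2>...``; cells are
    two-character allele pairs ("AG") or "NA" for missing; phenotype 0/1.
    """
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[:2] != ["sample_id", "phenotype"]:
        raise ParseError(f"{path}:1: header must start 'sample_id\\tphenotype'")
    snp_ids = header[2:]
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError(f"{path}: duplicate SNP column names")
    m = len(snp_ids)

    sample_ids, phenotypes = [], []
    a1_rows, a2_rows = [], []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2 + m:
            raise ParseError(f"{path}:{ln}: expected {2 + m} columns, got {len(parts)}")
        sample_ids.append(parts[0])
        phenotypes.append(int(parts[1]))
        r1, r2 = [], []
        for cell in parts[2:]:
            if cell == "NA":
                r1.append(MISSING_ALLELE)
                r2.append(MISSING_ALLELE)
            elif len(cell) == 2:
                r1.append(cell[0])
                r2.append(cell[1])
            else:
                raise ParseError(f"{path}:{ln}: bad genotype cell {cell!r}")
        a1_rows.append(r1)
        a2_rows.append(r2)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample ids")

    a1 = np.array(a1_rows, dtype="<U1").reshape(len(sample_ids), m)
    a2 = np.array(a2_rows, dtype="<U1").reshape(len(sample_ids), m)
    snps = []
    for j, snp_id in enumerate(snp_ids):
        obs = sorted((set(a1[:, j]) | set(a2[:, j])) - {MISSING_ALLELE})
        if len(obs) > 2:
            raise ParseError(f"{snp_id}: more than two alleles observed: {obs}")
        if len(obs) == 0:
            obs = ["A", "B"]
        elif len(obs) == 1:
            obs = obs + [_other_allele(obs[0])]
        snps.append(SNPRecord(snp_id, "0", j + 1, obs[0], obs[1]))
    return GenotypeDataset(snps, sample_ids, np.array(phenotypes), a1, a2)


def write_genotype_tsv(dataset: GenotypeDataset, path) -> None:
    """Write the TSV dialect (alleles within a cell in sorted order)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(dataset.snp_ids) + "\n")
        for i, sid in enumerate(dataset.sample_ids):
            cells = []
            for j in range(dataset.n_snps):
                a, b = sorted((dataset.allele1[i, j], dataset.allele2[i, j]))
                cells.append("NA" if a == MISSING_ALLELE else a + b)
            fh.write(f"{sid}\t{int(dataset.phenotypes[i])}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Additive encoding
# ---------------------------------------------------------------------------

def encode_additive(dataset: GenotypeDataset) -> GenotypeMatrix:
    """Encode each call as its risk-allele count (0/1/2); missing stays NaN.

    Every SNP must have its risk allele assigned first (see
    :func:`gannet.assoc.assign_risk_alleles`).
    """
    unset = [s.snp_id for s in dataset.snps if s.risk_allele is None]
    if unset:
        raise ValueError(f"risk allele unset for SNPs: {unset[:5]}")
    n, m = dataset.n_samples, dataset.n_snps
    values = np.full((n, m), np.nan)
    for j, snp in enumerate(dataset.snps):
        risk = snp.risk_allele
        a1, a2 = dataset.allele1[:, j], dataset.allele2[:, j]
        present = a1 != MISSING_ALLELE
        values[present, j] = (a1[present] == risk).astype(float) + (
            a2[present] == risk
        ).astype(float)
    return GenotypeMatrix(values, dataset.snp_ids, list(dataset.sample_ids),
                          dataset.phenotypes.copy())


def decode_additive(matrix: GenotypeMatrix, snps: Sequence[SNPRecord]) -> list[list[frozenset | None]]:
    """Invert the additive encoding back to unordered allele pairs."""
    by_id = {s.snp_id: s for s in snps}
    out = []
    for i in range(matrix.n_samples):
        row = []
        for j, sid in enumerate(matrix.snp_ids):
            v = matrix.values[i, j]
            snp = by_id[sid]
            if math.isnan(v):
                row.append(None)
            elif v == 0:
                row.append(frozenset((snp.non_risk_allele,)))
            elif v == 1:
                row.append(frozenset((snp.risk_allele, snp.non_risk_allele)))
            else:
                row.append(frozenset((snp.risk_allele,)))
        out.append(row)
    return out


# ---------------------------------------------------------------------------
# LD-aware imputation
# ---------------------------------------------------------------------------

def impute_missing(matrix: GenotypeMatrix, ld, *, min_partner_r2: float = 0.3) -> GenotypeMatrix:
    """Fill missing dosages with an LD-conditional modal genotype.

    For a missing entry at SNP *s* in sample *i*: find s's highest-r² partner
    SNP with r² >= ``min_partner_r2``; impute the modal genotype of *s* among
    samples sharing sample i's genotype at the partner. If no partner
    qualifies, the stratum is empty, or the partner genotype is itself
    missing, fall back to the overall mode of *s*. Ties break toward the
    smaller dosage. Non-missing entries are never altered.
    """
    values = matrix.values.copy()
    n, m = values.shape
    pos = {sid: j for j, sid in enumerate(matrix.snp_ids)}

    def _mode(col: np.ndarray) -> float:
        col = col[~np.isnan(col)]
        if col.size == 0:
            return np.nan
        counts = [(np.sum(col == g), -g) for g in (0.0, 1.0, 2.0)]
        best = max(counts)
        return -best[1]

    overall_mode = {j: _mode(matrix.values[:, j]) for j in range(m)}

    for j, sid in enumerate(matrix.snp_ids):
        missing_rows = np.nonzero(np.isnan(values[:, j]))[0]
        if missing_rows.size == 0:
            continue
        if np.isnan(overall_mode[j]):
            raise ValueError(f"{sid}: missing in every sample, no mode defined")
        # best LD partner at or above the cutoff
        partner, best_r2 = None, -1.0
        for other_sid in matrix.snp_ids:
            if other_sid == sid:
                continue
            r2 = ld.r2_between(sid, other_sid)
            if r2 >= min_partner_r2 and r2 > best_r2:
                partner, best_r2 = pos[other_sid], r2
        for i in missing_rows:
            fill = np.nan
            if partner is not None and not np.isnan(matrix.values[i, partner]):
                stratum = matrix.values[:, partner] == matrix.values[i, partner]
                fill = _mode(matrix.values[stratum, j])
            if np.isnan(fill):
                fill = overall_mode[j]
            values[i, j] = fill
    return GenotypeMatrix(values, list(matrix.snp_ids), list(matrix.sample_ids),
                          matrix.phenotypes.copy())
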