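"""Elution-matrix preprocessing.

Four steps, applied in a fixed order per (genotype, extract) condition:
zero-imputation of missing cells, removal of proteins identified in only one
fraction, averaging of the per-search-engine matrices (union alignment with
zero fill), and row/column normalization correcting for per-protein abundance
and per-fraction injection bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ElutionMatrix

NORMALIZE_MODES = ("row", "column", "both")


@dataclass
class PreprocessReport:
    n_input_proteins: int = 0
    n_removed_single_fraction: int = 0
    n_imputed_cells: int = 0
    normalization_mode: str = ""
    removed_proteins: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input_proteins": self.n_input_proteins,
            "n_removed_single_fraction": self.n_removed_single_fraction,
            "n_imputed_cells": self.n_imputed_cells,
            "normalization_mode": self.normalization_mode,
            "removed_proteins": sorted(self.removed_proteins),
        }


def impute_zeros(matrix: ElutionMatrix,
                 report: PreprocessReport | None = None) -> ElutionMatrix:
    """Replace every missing cell by 0; non-missing cells are untouched."""
    n_missing = int(matrix.data.isna().to_numpy().sum())
    if report is not None:
        report.n_imputed_cells += n_missing
    if n_missing == 0:
        return matrix
    return matrix.copy_with(matrix.data.fillna(0.0))


def filter_sparse(matrix: ElutionMatrix,
                  report: PreprocessReport | None = None) -> ElutionMatrix:
    """Drop proteins detected (value > 0) in at most one fraction.

    Pure row deletion: surviving values are never altered.
    """
    detected = (matrix.data.to_numpy(dtype=float) > 0).sum(axis=1)
    keep = detected > 1
    removed = [p for p, k in zip(matrix.proteins, keep) if not k]
    if report is not None:
        report.n_input_proteins = len(matrix.proteins)
        report.n_removed_single_fraction = len(removed)
        report.removed_proteins.extend(removed)
    if not removed:
        return matrix
    return matrix.copy_with(matrix.data.loc[keep])


def combine_engines(matrices: list[ElutionMatrix]) -> ElutionMatrix:
    """Average per-engine matrices cell-wise after union alignment.

    A protein absent from an engine contributes 0 to its mean, preserving
    sensitivity for proteins a single engine identified. Fraction label sets
    must agree across engines.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    fractions = matrices[0].fractions
    for m in matrices[1:]:
        if m.fractions != fractions:
            raise ValueError(
                f"conflicting fraction sets: {len(m.fractions)} vs {len(fractions)}")
    if len(matrices) == 1:
        m = matrices[0]
        return ElutionMatrix(m.data.copy(), m.genotype, m.extract, engine="combined")
    proteins = sorted(set().union(*(m.proteins for m in matrices)))
    acc = np.zeros((len(proteins), len(fractions)))
    for m in matrices:
        acc += m.data.reindex(index=proteins, fill_value=0.0).to_numpy(dtype=float)
    acc /= len(matrices)
    first = matrices[0]
    return ElutionMatrix(pd.DataFrame(acc, index=proteins, columns=fractions),
                         genotype=first.genotype, extract=first.extract,
                         engine="combined")


def normalize(matrix: ElutionMatrix, mode: str = "both") -> ElutionMatrix:
    """Scale rows and/or columns to unit sum.

    row: each nonzero row sums to 1. column: each nonzero column sums to 1.
    both: row pass, then column pass (fixed order). All-zero rows/columns are
    left unchanged, so the zero pattern is conserved exactly.
    """
    if mode not in NORMALIZE_MODES:
        raise ValueError(f"mode must be one of {NORMALIZE_MODES}, got {mode!r}")
    values = matrix.data.to_numpy(dtype=float).copy()
    if mode in ("row", "both"):
        sums = values.sum(axis=1, keepdims=True)
        np.divide(values, sums, out=values, where=sums > 0)
    if mode in ("column", "both"):
        sums = values.sum(axis=0, keepdims=True)
        np.divide(values, sums, out=values, where=sums > 0)
    return matrix.copy_with(
        pd.DataFrame(values, index=matrix.data.index, columns=matrix.data.columns))


def preprocess_condition(matrices: list[ElutionMatrix], mode: str = "both",
                         log2_transform: bool = False,
                         ) -> tuple[ElutionMatrix, PreprocessReport]:
    """Full fixed-order pipeline for one condition's per-engine matrices.

    Order: impute missing -> drop single-fraction proteins (per engine) ->
    average engines -> normalize. ``log2_transform`` applies log2(x + 1)
    first for engines reporting raw (non-log) intensities.
    """
    report = PreprocessReport(normalization_mode=mode)
    staged: list[ElutionMatrix] = []
    seen: set[str] = set()
    removed: set[str] = set()
    n_input = 0
    for m in matrices:
        if log2_transform:
            m = m.copy_with(np.log2(m.data + 1.0))
        m = impute_zeros(m, report)
        sub = PreprocessReport()
        m = filter_sparse(m, sub)
        n_input += sub.n_input_proteins
        removed.update(sub.removed_proteins)
        staged.append(m)
        seen.update(m.proteins)
    combined = combine_engines(staged)
    out = normalize(combined, mode)
    report.n_input_proteins = n_input
    report.removed_proteins = sorted(removed - seen)
    report.n_removed_single_fraction = len(report.removed_proteins)
    return out, report
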