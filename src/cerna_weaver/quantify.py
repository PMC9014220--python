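"""Per-class normalization of raw counts.

Three unit systems, one per RNA class:

* SRPBM — back-splicing junction reads per billion mapped reads (circRNA);
  ``count / library_size * 1e9``.
* TPM — for mature miRNAs, implemented as reads per million class-mapped
  reads: ``count / column_sum * 1e6``. Mature miRNAs are ~22 nt, so the
  length term of transcript-level TPM is a constant and is omitted, as is
  conventional for miRNA-seq.
* FPKM — fragments per kilobase of exon model per million mapped reads
  (mRNA); ``count / (length/1e3) / (library_size/1e6)``.
"""

from __future__ import annotations

import numpy as np

from .matrix import CountMatrix, ExpressionMatrix, MatrixError


def srpbm(counts: CountMatrix) -> ExpressionMatrix:
    """Back-splice junction reads per billion mapped reads."""
    lib = counts.library_size.astype(float)
    if (lib == 0).any():
        raise MatrixError("zero library size")
    values = counts.counts.astype(float).div(lib, axis=1) * 1e9
    return ExpressionMatrix(values, unit="SRPBM")


def tpm_mirna(counts: CountMatrix) -> ExpressionMatrix:
    """Reads per million class-mapped reads (mature-miRNA convention).

    Every output column sums to 1e6 up to float rounding.
    """
    colsum = counts.counts.sum(axis=0).astype(float)
    if (colsum == 0).any():
        zero = [s for s, v in colsum.items() if v == 0]
        raise MatrixError(f"all-zero sample column(s): {zero}")
    values = counts.counts.astype(float).div(colsum, axis=1) * 1e6
    return ExpressionMatrix(values, unit="TPM")


def fpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Fragments per kilobase of exon model per million mapped reads."""
    if counts.feature_length_bp is None:
        raise MatrixError("feature_length_bp required for FPKM")
    lengths = counts.feature_length_bp.astype(float)
    if (lengths <= 0).any():
        raise MatrixError("zero or negative feature length")
    lib = counts.library_size.astype(float)
    if (lib == 0).any():
        raise MatrixError("zero library size")
    values = (
        counts.counts.astype(float)
        .div(lengths / 1e3, axis=0)
        .div(lib / 1e6, axis=1)
    )
    return ExpressionMatrix(values, unit="FPKM")


def normalize(counts: CountMatrix, rna_class: str) -> ExpressionMatrix:
    """Dispatch to the unit system conventional for ``rna_class``."""
    if rna_class == "circ":
        return srpbm(counts)
    if rna_class == "mir":
        return tpm_mirna(counts)
    if rna_class == "mrna":
        return fpkm(counts)
    raise ValueError(f"unknown RNA class {rna_class!r}")
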