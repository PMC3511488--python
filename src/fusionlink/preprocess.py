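"""Detection-call trimming, log transform, replicate averaging and
reference normalization of raw array intensities."""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .matrix import INTENSITY, LOG2RATIO, PRESENT, ExpressionMatrix, MatrixError


class PreprocessError(ValueError):
    pass


def filter_present_calls(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep exactly the genes called Present in every sample column and
    in every reference duplicate; gene order is preserved.

    Idempotent: filtering an already-filtered matrix changes nothing.
    """
    if matrix.calls is None:
        raise PreprocessError("matrix carries no detection calls")
    if matrix.reference is not None and matrix.reference_calls is None:
        raise PreprocessError("reference channel present but has no detection calls")
    mask = (matrix.calls == PRESENT).all(axis=1)
    if matrix.reference_calls is not None:
        mask &= (matrix.reference_calls == PRESENT).all(axis=1)
    return matrix.subset_genes(matrix.gene_ids[mask])


def log_ratio(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-array log2 ratio to the reference profile (no averaging)."""
    if matrix.scale_tag != INTENSITY:
        raise PreprocessError("log_ratio expects an intensity-scale matrix")
    ref = matrix.reference_profile()  # raises if reference missing/non-positive
    vals = matrix.values.to_numpy(dtype=float)
    bad = np.nonzero((vals <= 0).any(axis=1))[0]
    if len(bad):
        raise PreprocessError(
            f"non-positive intensity for gene {matrix.gene_ids[bad[0]]!r}"
        )
    ratios = np.log2(vals / ref.to_numpy()[:, None])
    return dataclasses.replace(
        matrix,
        values=pd.DataFrame(ratios, index=matrix.gene_ids, columns=matrix.sample_ids),
        calls=None,
        reference=None,
        reference_calls=None,
        scale_tag=LOG2RATIO,
    )


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate columns of each patient in log space, yielding
    one column per patient."""
    if matrix.scale_tag != LOG2RATIO:
        raise PreprocessError("average_replicates expects log2-ratio values")
    averaged = matrix.values.T.groupby(matrix.patients, sort=False).mean().T
    averaged.columns.name = "patient_id"
    return dataclasses.replace(
        matrix,
        values=averaged,
        patients=pd.Series(list(averaged.columns), index=averaged.columns, name="patient"),
        calls=None,
        reference=None,
        reference_calls=None,
    )


def log_average_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(I / I_ref) per array, then replicate columns averaged in log
    space (the geometric mean of the replicate ratios)."""
    return average_replicates(log_ratio(matrix))


def pool_patients(matrix: ExpressionMatrix) -> pd.Series:
    """Arithmetic mean across patient columns in log space; one pooled
    value per gene."""
    if matrix.scale_tag != LOG2RATIO:
        raise PreprocessError("pool_patients expects log2-ratio values")
    if matrix.n_samples == 0 or matrix.n_genes == 0:
        raise PreprocessError("cannot pool an empty matrix")
    pooled = matrix.values.mean(axis=1)
    pooled.name = "pooled"
    return pooled
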