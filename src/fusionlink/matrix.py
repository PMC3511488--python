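"""Expression containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a genes x arrays table of
single-channel intensities (or, after normalization, log2 ratios to a
universal reference) together with per-value Present/Absent detection calls
and the matched reference channel hybridized on every array.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

#: scale tags
INTENSITY = "intensity"
RATIO = "ratio"
LOG2RATIO = "log2ratio"

#: detection calls
PRESENT = "P"
ABSENT = "A"

_VALID_SCALES = (INTENSITY, RATIO, LOG2RATIO)


class MatrixError(ValueError):
    """Raised when an ExpressionMatrix violates its contract."""


@dataclass
class ExpressionMatrix:
    """Genes x arrays expression values with optional calls and reference.

    Parameters
    ----------
    values
        Genes x samples table. Non-negative for ``intensity`` scale,
        strictly positive for ``ratio`` scale, unrestricted for
        ``log2ratio``.
    patients
        Maps each sample column to its patient (or biological-sample)
        identifier; replicate arrays of one patient share the identifier.
    calls
        Optional ``"P"``/``"A"`` detection call per value, same shape as
        ``values``.
    reference
        Optional universal-reference channel, one column per duplicate
        reference hybridization (rows = genes).
    reference_calls
        Detection calls for the reference duplicates, same shape as
        ``reference``.
    scale_tag
        One of ``intensity``, ``ratio``, ``log2ratio``.
    """

    values: pd.DataFrame
    patients: pd.Series
    calls: pd.DataFrame | None = None
    reference: pd.DataFrame | None = None
    reference_calls: pd.DataFrame | None = None
    scale_tag: str = INTENSITY

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.scale_tag not in _VALID_SCALES:
            raise MatrixError(f"unknown scale_tag {self.scale_tag!r}")
        if not self.values.index.is_unique:
            raise MatrixError("gene identifiers must be unique")
        if list(self.patients.index) != list(self.values.columns):
            raise MatrixError("patients must be indexed by the sample columns")
        if self.calls is not None:
            if self.calls.shape != self.values.shape:
                raise MatrixError("calls shape differs from values shape")
            if not self.calls.index.equals(self.values.index):
                raise MatrixError("calls gene index differs from values")
        if self.reference is not None:
            if not self.reference.index.equals(self.values.index):
                raise MatrixError("reference gene index differs from values")
            if self.reference_calls is not None and (
                self.reference_calls.shape != self.reference.shape
            ):
                raise MatrixError("reference_calls shape differs from reference")
        arr = self.values.to_numpy()
        if self.scale_tag == INTENSITY and np.any(arr < 0):
            raise MatrixError("intensity values must be non-negative")
        if self.scale_tag == RATIO and np.any(arr <= 0):
            raise MatrixError("ratio values must be strictly positive")

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    @property
    def patient_ids(self) -> list:
        """Distinct patient identifiers in column order."""
        seen: dict = {}
        for p in self.patients:
            seen.setdefault(p, None)
        return list(seen)

    # ------------------------------------------------------------------
    def reference_profile(self) -> pd.Series:
        """Per-gene reference intensity: geometric mean over duplicates."""
        if self.reference is None:
            raise MatrixError("matrix carries no reference channel")
        ref = self.reference.to_numpy(dtype=float)
        if np.any(ref <= 0):
            bad = self.reference.index[(ref <= 0).any(axis=1)][0]
            raise MatrixError(f"non-positive reference intensity for gene {bad!r}")
        return pd.Series(
            np.exp2(np.log2(ref).mean(axis=1)), index=self.values.index, name="reference"
        )

    def subset_genes(self, genes: Iterable) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` (order as given)."""
        idx = pd.Index(genes)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise MatrixError(f"unknown genes: {list(missing[:5])}")
        return replace(
            self,
            values=self.values.loc[idx],
            calls=None if self.calls is None else self.calls.loc[idx],
            reference=None if self.reference is None else self.reference.loc[idx],
            reference_calls=(
                None if self.reference_calls is None else self.reference_calls.loc[idx]
            ),
        )

    def replicate_groups(self) -> dict:
        """Patient identifier -> list of its sample columns."""
        groups: dict = {}
        for sample, patient in self.patients.items():
            groups.setdefault(patient, []).append(sample)
        return groups
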