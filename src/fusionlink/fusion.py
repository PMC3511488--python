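"""Tumor-fraction-free linear model linking expression to fusion transcript.

A biopsy intensity is a mixture ``I_ik = alpha*(f_i*E_tumor,k +
(1-f_i)*E_nontumor,k)`` and the fusion-transcript abundance satisfies
``R_i = f_i / beta``.  Substituting ``f_i = beta*R_i`` makes the intensity
an affine function of the observable ``R_i``:

    I_ik(R_i) = alpha_k + beta_k * R_i,
    sign(beta_k) = sign(r_k - 1),   r_k = E_tumor,k / E_nontumor,k

so the *sign* of the per-gene slope (equivalently of the Pearson
correlation) classifies gene ``k`` as tumor-enhanced or tumor-reduced
without ever estimating the per-patient tumor fractions ``f_i`` or the
conversion constants ``alpha``, ``beta``.  The slope sign is invariant to
rescaling ``R`` by any positive constant.  The model is qualitative: it
identifies the direction of tumor-associated expression, not its
magnitude.

The module also provides the exact observed-ratio correction valid when
the universal reference equals the non-tumor expression:

    <r> = f * (r - 1) + 1      and its inverse      r = (<r> - 1)/f + 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import INTENSITY, LOG2RATIO, ExpressionMatrix

POSITIVE = "positive"
NEGATIVE = "negative"
NULL = "null"


class FusionModelError(ValueError):
    pass


@dataclass
class FusionPanel:
    """Per-patient fusion-transcript abundance (RT-PCR, normalized to an
    arbitrary reference patient)."""

    R: pd.Series

    def __post_init__(self) -> None:
        if np.any(self.R.to_numpy() <= 0):
            raise FusionModelError("fusion abundances must be strictly positive")
        if not self.R.index.is_unique:
            raise FusionModelError("one fusion value per patient required")

    @property
    def patient_ids(self) -> pd.Index:
        return self.R.index


@dataclass
class GeneSlopeFit:
    """OLS fit of one gene's intensities against the fusion panel."""

    gene_id: str
    intercept: float  # alpha_k
    slope: float  # beta_k
    pcc: float
    p_value: float
    n_points: int
    slope_sign: str  # positive / negative / null


# ----------------------------------------------------------------------
def observed_to_tumor_ratio(observed_ratio, f):
    """Tumor-referenced ratio r from the observed ratio <r>: (<r>-1)/f + 1.

    Valid under the assumption that the reference RNA equals the
    non-tumor expression.  Accepts scalars or arrays.
    """
    observed_ratio = np.asarray(observed_ratio, dtype=float)
    f_arr = np.asarray(f, dtype=float)
    if np.any((f_arr <= 0) | (f_arr > 1)):
        raise FusionModelError("tumor fraction must lie in (0, 1]")
    if np.any(observed_ratio <= 0):
        raise FusionModelError("observed ratio must be > 0")
    out = (observed_ratio - 1.0) / f_arr + 1.0
    return float(out) if out.ndim == 0 else out


def tumor_to_observed_ratio(tumor_ratio, f):
    """Forward map <r> = f*(r-1) + 1, the inverse of
    :func:`observed_to_tumor_ratio`."""
    tumor_ratio = np.asarray(tumor_ratio, dtype=float)
    f_arr = np.asarray(f, dtype=float)
    if np.any((f_arr <= 0) | (f_arr > 1)):
        raise FusionModelError("tumor fraction must lie in (0, 1]")
    out = f_arr * (tumor_ratio - 1.0) + 1.0
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
def fit_gene_slope(
    intensities: pd.Series, panel: FusionPanel, sign_threshold: float = 0.05
) -> GeneSlopeFit:
    """Ordinary least squares of one gene's per-patient values on R.

    The p-value is the two-sided t-test of the Pearson correlation; the
    reported ``slope_sign`` is positive/negative only when the slope is
    non-zero and p <= ``sign_threshold``, else null.
    """
    common = intensities.index.intersection(panel.R.index)
    if len(common) < 3:
        raise FusionModelError("need at least 3 aligned patients")
    y = intensities.loc[common].to_numpy(dtype=float)
    x = panel.R.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise FusionModelError("fusion abundance is constant across patients")
    if np.ptp(y) == 0:
        fit = GeneSlopeFit(
            gene_id=str(intensities.name),
            intercept=float(y[0]),
            slope=0.0,
            pcc=0.0,
            p_value=1.0,
            n_points=len(common),
            slope_sign=NULL,
        )
        return fit
    res = stats.linregress(x, y)
    sign = NULL
    if res.pvalue <= sign_threshold and res.slope != 0:
        sign = POSITIVE if res.slope > 0 else NEGATIVE
    return GeneSlopeFit(
        gene_id=str(intensities.name),
        intercept=float(res.intercept),
        slope=float(res.slope),
        pcc=float(res.rvalue),
        p_value=float(res.pvalue),
        n_points=len(common),
        slope_sign=sign,
    )


def fit_gene_slopes(
    matrix: ExpressionMatrix,
    panel: FusionPanel,
    collapse_replicates: bool = True,
    sign_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene slope fits for a whole matrix.

    Replicate arrays are collapsed to one value per patient before
    fitting (geometric mean for intensities, arithmetic mean for log2
    ratios) so that replicate pseudo-replication does not inflate the
    correlation significance.  Set ``collapse_replicates=False`` to fit
    on every array, each carrying its patient's R.
    """
    per_column_r = matrix.patients.map(panel.R)
    if per_column_r.isna().any():
        missing = sorted(set(matrix.patients[per_column_r.isna()]))
        raise FusionModelError(f"patients missing from fusion panel: {missing}")

    if collapse_replicates:
        if matrix.scale_tag == INTENSITY:
            vals = matrix.values.to_numpy(dtype=float)
            if np.any(vals <= 0):
                raise FusionModelError("non-positive intensity; cannot average in log space")
            logv = pd.DataFrame(np.log2(vals), index=matrix.gene_ids,
                                columns=matrix.sample_ids)
            collapsed = np.exp2(logv.T.groupby(matrix.patients, sort=False).mean().T)
        else:
            collapsed = matrix.values.T.groupby(matrix.patients, sort=False).mean().T
        data = collapsed
        x_panel = panel
    else:
        data = matrix.values
        # each replicate column keeps its own patient's abundance
        x_panel = FusionPanel(
            R=pd.Series(per_column_r.to_numpy(), index=matrix.sample_ids,
                        name="fusion_value")
        )

    rows = []
    for gene in data.index:
        fit = fit_gene_slope(data.loc[gene], x_panel, sign_threshold=sign_threshold)
        rows.append(
            (fit.gene_id, fit.intercept, fit.slope, fit.pcc, fit.p_value,
             fit.n_points, fit.slope_sign)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "intercept", "slope", "pcc", "p_value", "n_points", "sign"],
    ).set_index("gene_id")


# ----------------------------------------------------------------------
def codebook_correlation_map(grid, panel: FusionPanel) -> np.ndarray:
    """Pearson correlation of each SOM codebook with the patient-aligned
    fusion abundances, as a rows x cols map (replicate columns carry
    their patient's R)."""
    if grid.patients is None:
        raise FusionModelError("SOM grid carries no patient alignment")
    r_vec = pd.Series(grid.patients).map(panel.R)
    if r_vec.isna().any():
        raise FusionModelError("SOM columns include patients missing from the panel")
    x = r_vec.to_numpy(dtype=float)
    if grid.codebooks.shape[1] != len(x):
        raise FusionModelError("codebook dimension does not match panel alignment")
    xc = x - x.mean()
    xn = np.linalg.norm(xc)
    out = np.empty(grid.codebooks.shape[0])
    for j, cb in enumerate(grid.codebooks):
        yc = cb - cb.mean()
        denom = xn * np.linalg.norm(yc)
        out[j] = 0.0 if denom == 0 else float(np.dot(xc, yc) / denom)
    return out.reshape(grid.rows, grid.cols)


# ----------------------------------------------------------------------
@dataclass
class TargetReport:
    """Genes partitioned by the sign of their fusion-transcript slope."""

    candidates: pd.DataFrame  # tumor-enhanced: positive slope
    controls: pd.DataFrame  # tumor-reduced: negative slope


def classify_targets(
    shared: pd.DataFrame, fits: pd.DataFrame, require_significance: bool = False
) -> TargetReport:
    """Partition the cross-route shared genes into candidate targets and
    controls by the sign of their fitted slope.

    ``shared`` is the co-occurring-pathway gene table (columns at least
    ``pathway`` and ``gene``).  By default genes are classified by the
    raw slope sign with the correlation p-value reported per gene;
    ``require_significance=True`` instead uses the thresholded
    ``sign`` column and drops null genes.
    """
    genes = pd.Index(sorted(shared["gene"].unique()))
    missing = genes.difference(fits.index)
    if len(missing):
        raise FusionModelError(f"genes without a slope fit: {list(missing[:5])}")
    pathway_map = (
        shared.groupby("gene")["pathway"].apply(lambda s: ",".join(sorted(set(s))))
    )
    rows_pos, rows_neg = [], []
    for gene in genes:
        fit = fits.loc[gene]
        if require_significance:
            sign = fit["sign"]
        else:
            slope = float(fit["slope"])
            sign = NULL if (slope == 0 or not np.isfinite(slope)) else (
                POSITIVE if slope > 0 else NEGATIVE
            )
        if sign == NULL:
            continue
        row = (gene, float(fit["slope"]), float(fit["pcc"]), float(fit["p_value"]),
               pathway_map.loc[gene])
        (rows_pos if sign == POSITIVE else rows_neg).append(row)
    cols = ["gene_id", "slope", "pcc", "p_value", "pathways"]
    return TargetReport(
        candidates=pd.DataFrame(rows_pos, columns=cols).set_index("gene_id"),
        controls=pd.DataFrame(rows_neg, columns=cols).set_index("gene_id"),
    )
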