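"""Synthetic cohort generator with known mixture ground truth.

Each simulated biopsy is a two-component mixture: a fraction ``f_i`` of
tumor cells and ``1 - f_i`` of non-tumor cells.  The single-channel array
intensity of gene ``k`` on patient ``i``'s array is

    I_ik = alpha * (f_i * E_tumor,k + (1 - f_i) * E_nontumor,k)

with ``alpha`` the RNA-to-signal conversion constant, while the matched
universal-reference channel reads ``alpha * E_ref,k``.  The per-patient
fusion-transcript abundance is proportional to the tumor fraction,
``R_i = f_i / beta``.  Measurement noise is multiplicative log-normal
(additive Gaussian in log2 space), the standard microarray error model;
it keeps intensities positive.

"Planted" gene modules carry a known tumor/non-tumor expression ratio
``r`` (``E_tumor = r * E_ref`` with ``E_nontumor = E_ref``), giving the
downstream analyses a ground truth: for those genes the noise-free
observed ratio to the reference is ``<r> = f * (r - 1) + 1``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import PathwayCollection
from .fusion import FusionPanel
from .matrix import ABSENT, INTENSITY, PRESENT, ExpressionMatrix

CELL_LINE_ID = "CELL"


class SimulationError(ValueError):
    """Raised for an invalid simulation configuration."""


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PlantedModule:
    """A block of genes with a known tumor/non-tumor expression ratio."""

    name: str
    genes: tuple[int, ...]  # gene indices into the simulated gene list
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise SimulationError(f"planted ratio must be > 0, got {self.ratio}")
        if len(set(self.genes)) != len(self.genes):
            raise SimulationError(f"module {self.name!r} lists duplicate genes")


def default_planted_modules(n_genes: int, module_size: int = 60) -> tuple[PlantedModule, ...]:
    """Two 6-fold modules (tumor-enhanced and tumor-reduced) at the head
    of the gene list.  Module size shrinks for very small simulations."""
    size = min(module_size, max(4, n_genes // 20))
    if 2 * size > n_genes:
        size = n_genes // 2
    up = tuple(range(size))
    down = tuple(range(size, 2 * size))
    return (
        PlantedModule("tumor_up_6x", up, 6.0),
        PlantedModule("tumor_down_6x", down, 1.0 / 6.0),
    )


@dataclass
class SimConfig:
    """Study conditions of the simulated cohort.

    Defaults mirror the cohort the analysis was designed for: seven
    patients measured in duplicate plus one isolated tumor-cell profile,
    with unknown per-patient tumor fractions.
    """

    n_patients: int = 7
    n_replicates: int = 2
    n_genes: int = 2000
    noise_sd: float = 0.25  # log2 units, multiplicative log-normal noise
    call_threshold: float = 5.0  # intensity below which a value is Absent
    alpha: float = 1.0
    beta: float = 1.0
    f_range: tuple[float, float] = (0.1, 0.7)
    baseline_sd: float = 1.0  # log2 spread of baseline expressions around E_ref
    tissue_cell_corr: float = 0.95  # corr of non-tumor vs tumor baseline (log2)
    ref_log2_mean: float = 7.0
    ref_log2_sd: float = 1.2
    nontumor_equals_reference: bool = False
    fusion_noise_sd: float = 0.0  # optional log-normal noise on R_i, off by default
    # planted modules emulate disease genes drawn from the *detected* set:
    # their reference expression is floored so detection calls cannot erase
    # the ground truth the recovery analyses are scored against.
    planted_ref_floor_log2: float = 6.0
    planted_modules: tuple[PlantedModule, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_modules is None:
            self.planted_modules = default_planted_modules(self.n_genes)
        self.planted_modules = tuple(self.planted_modules)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_replicates < 1 or self.n_genes < 1:
            raise SimulationError("counts must be positive")
        if self.noise_sd < 0 or self.fusion_noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.call_threshold < 0:
            raise SimulationError("call_threshold must be >= 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise SimulationError("alpha and beta must be > 0")
        lo, hi = self.f_range
        if not (0 < lo <= hi <= 1):
            raise SimulationError("f_range must lie within (0, 1]")
        if not (-1 <= self.tissue_cell_corr <= 1):
            raise SimulationError("tissue_cell_corr must be in [-1, 1]")
        seen: set[int] = set()
        for mod in self.planted_modules:
            idx = set(mod.genes)
            if idx & seen:
                raise SimulationError("planted module gene sets must be disjoint")
            if idx and max(idx) >= self.n_genes:
                raise SimulationError(f"module {mod.name!r} exceeds n_genes")
            seen |= idx


@dataclass
class MixtureGroundTruth:
    """Simulation truth: tumor fractions and the three expression vectors."""

    f: pd.Series  # per patient, in (0, 1]
    E_tumor: pd.Series
    E_nontumor: pd.Series
    E_ref: pd.Series
    alpha: float
    beta: float
    modules: tuple[PlantedModule, ...] = ()

    def __post_init__(self) -> None:
        if np.any((self.f.to_numpy() <= 0) | (self.f.to_numpy() > 1)):
            raise SimulationError("tumor fractions must lie in (0, 1]")
        for name, vec in (
            ("E_tumor", self.E_tumor),
            ("E_nontumor", self.E_nontumor),
            ("E_ref", self.E_ref),
        ):
            if np.any(vec.to_numpy() <= 0):
                raise SimulationError(f"{name} must be strictly positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise SimulationError("alpha and beta must be > 0")
        if not (
            self.E_tumor.index.equals(self.E_nontumor.index)
            and self.E_tumor.index.equals(self.E_ref.index)
        ):
            raise SimulationError("expression vectors must share one gene index")

    @property
    def gene_ids(self) -> pd.Index:
        return self.E_tumor.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.f.index

    def tumor_ratio(self) -> pd.Series:
        """Per-gene tumor/non-tumor expression ratio ``r``."""
        return self.E_tumor / self.E_nontumor

    def module_genes(self, name: str) -> pd.Index:
        for mod in self.modules:
            if mod.name == name:
                return self.gene_ids[list(mod.genes)]
        raise KeyError(name)


@dataclass
class Cohort:
    """Bundle returned by :func:`generate_cohort`."""

    tissue: ExpressionMatrix
    cell: ExpressionMatrix
    fusion: FusionPanel
    truth: MixtureGroundTruth


# ----------------------------------------------------------------------
def forward_intensity(truth: MixtureGroundTruth, patient, gene) -> float:
    """Noise-free mixture intensity alpha*(f*E_tumor + (1-f)*E_nontumor)."""
    f = truth.f.loc[patient]
    return float(
        truth.alpha
        * (f * truth.E_tumor.loc[gene] + (1.0 - f) * truth.E_nontumor.loc[gene])
    )


def reference_intensity(truth: MixtureGroundTruth, gene) -> float:
    """Noise-free reference-channel intensity alpha*E_ref."""
    return float(truth.alpha * truth.E_ref.loc[gene])


def forward_intensities(truth: MixtureGroundTruth) -> pd.DataFrame:
    """Noise-free genes x patients mixture intensities."""
    f = truth.f.to_numpy()
    mix = truth.alpha * (
        np.outer(truth.E_tumor.to_numpy(), f)
        + np.outer(truth.E_nontumor.to_numpy(), 1.0 - f)
    )
    return pd.DataFrame(mix, index=truth.gene_ids, columns=truth.patient_ids)


def assign_detection_calls(matrix: ExpressionMatrix, call_threshold: float) -> ExpressionMatrix:
    """Mark each value P if at/above the threshold, A otherwise."""
    if call_threshold < 0:
        raise SimulationError("call_threshold must be >= 0")
    calls = pd.DataFrame(
        np.where(matrix.values.to_numpy() >= call_threshold, PRESENT, ABSENT),
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    ref_calls = None
    if matrix.reference is not None:
        ref_calls = pd.DataFrame(
            np.where(matrix.reference.to_numpy() >= call_threshold, PRESENT, ABSENT),
            index=matrix.reference.index,
            columns=matrix.reference.columns,
        )
    return dataclasses.replace(matrix, calls=calls, reference_calls=ref_calls)


# ----------------------------------------------------------------------
def _lognormal_noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    if sd == 0:
        return np.ones(shape)
    return np.exp2(rng.normal(0.0, sd, size=shape))


def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate tissue and cell-line arrays, fusion panel and ground truth.

    All randomness flows from ``config.seed``; two calls with the same
    configuration are bit-identical.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)], name="gene_id")
    patients = pd.Index([f"P{i + 1}" for i in range(cfg.n_patients)], name="patient_id")

    # reference expression and correlated tumor/non-tumor baselines (log2)
    e_ref = np.exp2(rng.normal(cfg.ref_log2_mean, cfg.ref_log2_sd, cfg.n_genes))
    z1 = rng.normal(size=cfg.n_genes)
    z2 = rng.normal(size=cfg.n_genes)
    rho = cfg.tissue_cell_corr
    u = cfg.baseline_sd * z1  # non-tumor deviation from reference
    v = cfg.baseline_sd * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)  # tumor deviation
    if cfg.nontumor_equals_reference:
        u = np.zeros(cfg.n_genes)
    e_non = e_ref * np.exp2(u)
    e_tum = e_ref * np.exp2(v)
    # planted modules override the baseline draw: E_nontumor pinned to the
    # reference so the observed ratio follows <r> = f*(r-1)+1 exactly.
    for mod in cfg.planted_modules:
        idx = np.asarray(mod.genes, dtype=int)
        e_ref[idx] = np.maximum(e_ref[idx], 2.0**cfg.planted_ref_floor_log2)
        e_non[idx] = e_ref[idx]
        e_tum[idx] = mod.ratio * e_ref[idx]

    f = rng.uniform(cfg.f_range[0], cfg.f_range[1], cfg.n_patients)

    truth = MixtureGroundTruth(
        f=pd.Series(f, index=patients, name="f"),
        E_tumor=pd.Series(e_tum, index=genes, name="E_tumor"),
        E_nontumor=pd.Series(e_non, index=genes, name="E_nontumor"),
        E_ref=pd.Series(e_ref, index=genes, name="E_ref"),
        alpha=cfg.alpha,
        beta=cfg.beta,
        modules=cfg.planted_modules,
    )

    clean = forward_intensities(truth).to_numpy()

    # tissue arrays: n_patients x n_replicates columns
    sample_ids = []
    sample_patients = []
    cols = []
    for i, pid in enumerate(patients):
        for j in range(cfg.n_replicates):
            sample_ids.append(f"{pid}r{j + 1}")
            sample_patients.append(pid)
            cols.append(clean[:, i] * _lognormal_noise(rng, cfg.noise_sd, cfg.n_genes))
    tissue_values = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=pd.Index(sample_ids, name="sample_id")
    )
    tissue_ref = _make_reference(rng, cfg, genes, e_ref)
    tissue = ExpressionMatrix(
        values=tissue_values,
        patients=pd.Series(sample_patients, index=tissue_values.columns, name="patient"),
        reference=tissue_ref,
        scale_tag=INTENSITY,
    )
    tissue = assign_detection_calls(tissue, cfg.call_threshold)

    # cell-line arrays: a noisy readout of E_tumor alone
    cell_ids = [f"{CELL_LINE_ID}r{j + 1}" for j in range(cfg.n_replicates)]
    cell_cols = [
        cfg.alpha * e_tum * _lognormal_noise(rng, cfg.noise_sd, cfg.n_genes)
        for _ in range(cfg.n_replicates)
    ]
    cell_values = pd.DataFrame(
        np.column_stack(cell_cols), index=genes, columns=pd.Index(cell_ids, name="sample_id")
    )
    cell_ref = _make_reference(rng, cfg, genes, e_ref)
    cell = ExpressionMatrix(
        values=cell_values,
        patients=pd.Series([CELL_LINE_ID] * cfg.n_replicates, index=cell_values.columns,
                           name="patient"),
        reference=cell_ref,
        scale_tag=INTENSITY,
    )
    cell = assign_detection_calls(cell, cfg.call_threshold)

    r_values = (f / cfg.beta) * _lognormal_noise(rng, cfg.fusion_noise_sd, cfg.n_patients)
    fusion = FusionPanel(R=pd.Series(r_values, index=patients, name="fusion_value"))

    return Cohort(tissue=tissue, cell=cell, fusion=fusion, truth=truth)


def _make_reference(rng, cfg: SimConfig, genes: pd.Index, e_ref: np.ndarray) -> pd.DataFrame:
    dup_cols = [
        cfg.alpha * e_ref * _lognormal_noise(rng, cfg.noise_sd, cfg.n_genes)
        for _ in range(cfg.n_replicates)
    ]
    return pd.DataFrame(
        np.column_stack(dup_cols),
        index=genes,
        columns=[f"REF{j + 1}" for j in range(cfg.n_replicates)],
    )


# ----------------------------------------------------------------------
def make_planted_pathways(
    truth: MixtureGroundTruth,
    n_background: int = 25,
    background_size: int = 40,
    seed: int = 0,
) -> PathwayCollection:
    """A gene-set collection for the simulated cohort.

    One pathway per planted module (its exact gene block) plus
    ``n_background`` sets drawn at random from the non-planted genes, so
    over-representation tests have both true and decoy targets.
    """
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    pathways: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    planted: set = set()
    for mod in truth.modules:
        name = f"PW_{mod.name.upper()}"
        members = genes[list(mod.genes)]
        pathways[name] = frozenset(members)
        descriptions[name] = f"planted module, tumor/non-tumor ratio {mod.ratio:g}"
        planted |= set(members)
    pool = np.asarray([g for g in genes if g not in planted])
    size = min(background_size, len(pool))
    for b in range(n_background):
        name = f"PW_BACKGROUND_{b + 1:02d}"
        members = rng.choice(pool, size=size, replace=False)
        pathways[name] = frozenset(members)
        descriptions[name] = "random background gene set"
    return PathwayCollection(
        pathways=pathways, universe=frozenset(genes), descriptions=descriptions
    )
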