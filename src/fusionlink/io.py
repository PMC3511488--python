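"""File formats: tab-delimited expression tables with detection calls
and reference channel, GMT gene-set collections, fusion panels and
ground-truth sidecars.

Expression table layout (tab-delimited):
  header row 1: ``gene_id`` then one sample id per column
  header row 2: patient grouping per column (``REF`` for reference columns)
  header row 3: column role, one of value / call / ref_value / ref_call
followed by one row per gene.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import PathwayCollection
from .fusion import FusionPanel
from .matrix import ExpressionMatrix
from .synthetic import MixtureGroundTruth, PlantedModule

_ROLES = ("value", "call", "ref_value", "ref_call")
REF_GROUP = "REF"


class ParseError(ValueError):
    pass


# ----------------------------------------------------------------------
def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    samples = list(matrix.sample_ids)
    header1, header2, header3 = ["gene_id"], [""], [""]
    columns: list[tuple[str, str]] = []  # (kind, column id)
    for s in samples:
        header1.append(str(s))
        header2.append(str(matrix.patients[s]))
        header3.append("value")
        columns.append(("value", s))
        if matrix.calls is not None:
            header1.append(str(s))
            header2.append(str(matrix.patients[s]))
            header3.append("call")
            columns.append(("call", s))
    if matrix.reference is not None:
        for rc in matrix.reference.columns:
            header1.append(str(rc))
            header2.append(REF_GROUP)
            header3.append("ref_value")
            columns.append(("ref_value", rc))
            if matrix.reference_calls is not None:
                header1.append(str(rc))
                header2.append(REF_GROUP)
                header3.append("ref_call")
                columns.append(("ref_call", rc))
    with path.open("w") as fh:
        fh.write("\t".join(header1) + "\n")
        fh.write("\t".join(header2) + "\n")
        fh.write("\t".join(header3) + "\n")
        for gene in matrix.gene_ids:
            cells = [str(gene)]
            for kind, col in columns:
                if kind == "value":
                    cells.append(repr(float(matrix.values.at[gene, col])))
                elif kind == "call":
                    cells.append(str(matrix.calls.at[gene, col]))
                elif kind == "ref_value":
                    cells.append(repr(float(matrix.reference.at[gene, col])))
                else:
                    cells.append(str(matrix.reference_calls.at[gene, col]))
            fh.write("\t".join(cells) + "\n")


def read_expression_table(path, scale_tag: str = "intensity") -> ExpressionMatrix:
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4:
        raise ParseError(f"{path}: expected 3 header rows plus data")
    h1, h2, h3 = (line.split("\t") for line in lines[:3])
    if h1[0] != "gene_id":
        raise ParseError(f"{path}, line 1: first column must be 'gene_id'")
    if not (len(h1) == len(h2) == len(h3)):
        raise ParseError(f"{path}: header rows have inconsistent widths")
    n_cols = len(h1)
    roles = h3[1:]
    for j, role in enumerate(roles):
        if role not in _ROLES:
            raise ParseError(f"{path}, line 3, column {j + 2}: unknown role {role!r}")

    sample_ids: list[str] = []
    patients: dict[str, str] = {}
    sample_value_col: dict[str, int] = {}
    sample_call_col: dict[str, int] = {}
    ref_value_cols: list[tuple[str, int]] = []
    ref_call_cols: list[tuple[str, int]] = []
    for j, role in enumerate(roles):
        name, group = h1[j + 1], h2[j + 1]
        if role == "value":
            if name in sample_value_col:
                raise ParseError(f"{path}: duplicate sample column {name!r}")
            sample_ids.append(name)
            patients[name] = group
            sample_value_col[name] = j
        elif role == "call":
            sample_call_col[name] = j
        elif role == "ref_value":
            ref_value_cols.append((name, j))
        else:
            ref_call_cols.append((name, j))
    if sample_call_col and set(sample_call_col) != set(sample_value_col):
        raise ParseError(f"{path}: call columns do not pair with every sample")
    if ref_call_cols and len(ref_call_cols) != len(ref_value_cols):
        raise ParseError(f"{path}: ref_call columns do not pair with ref_value columns")

    genes: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise ParseError(
                f"{path}, line {lineno}: expected {n_cols} columns, got {len(cells)}"
            )
        genes.append(cells[0])
        rows.append(cells[1:])
    if not genes:
        raise ParseError(f"{path}: no data rows")
    table = np.asarray(rows, dtype=object)
    gene_index = pd.Index(genes, name="gene_id")

    def _floats(col_idx: list[int], names: list[str]) -> pd.DataFrame:
        try:
            block = table[:, col_idx].astype(float)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value column ({exc})") from None
        return pd.DataFrame(block, index=gene_index, columns=names)

    values = _floats([sample_value_col[s] for s in sample_ids], sample_ids)
    calls = None
    if sample_call_col:
        calls = pd.DataFrame(
            table[:, [sample_call_col[s] for s in sample_ids]],
            index=gene_index, columns=sample_ids,
        )
    reference = None
    reference_calls = None
    if ref_value_cols:
        reference = _floats([j for _, j in ref_value_cols], [n for n, _ in ref_value_cols])
        if ref_call_cols:
            reference_calls = pd.DataFrame(
                table[:, [j for _, j in ref_call_cols]],
                index=gene_index, columns=[n for n, _ in ref_call_cols],
            )
    return ExpressionMatrix(
        values=values,
        patients=pd.Series([patients[s] for s in sample_ids],
                           index=values.columns, name="patient"),
        calls=calls,
        reference=reference,
        reference_calls=reference_calls,
        scale_tag=scale_tag,
    )


# ----------------------------------------------------------------------
def write_fusion_panel(panel: FusionPanel, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("patient_id,fusion_value\n")
        for pid, val in panel.R.items():
            fh.write(f"{pid},{val!r}\n")


def read_fusion_panel(path) -> FusionPanel:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["patient_id", "fusion_value"]:
        raise ParseError(f"{path}: expected columns patient_id,fusion_value")
    return FusionPanel(R=pd.Series(df["fusion_value"].to_numpy(float),
                                   index=pd.Index(df["patient_id"], name="patient_id"),
                                   name="fusion_value"))


def write_truth_json(truth: MixtureGroundTruth, path) -> None:
    payload = {
        "alpha": truth.alpha,
        "beta": truth.beta,
        "f": {str(k): float(v) for k, v in truth.f.items()},
        "modules": [
            {"name": m.name, "genes": list(m.genes), "ratio": m.ratio}
            for m in truth.modules
        ],
        "gene_ids": [str(g) for g in truth.gene_ids],
        "E_tumor": [float(x) for x in truth.E_tumor],
        "E_nontumor": [float(x) for x in truth.E_nontumor],
        "E_ref": [float(x) for x in truth.E_ref],
    }
    with Path(path).open("w") as fh:
        json.dump(payload, fh, sort_keys=True)


def read_truth_json(path) -> MixtureGroundTruth:
    with Path(path).open() as fh:
        payload = json.load(fh)
    genes = pd.Index(payload["gene_ids"], name="gene_id")
    return MixtureGroundTruth(
        f=pd.Series(payload["f"], name="f"),
        E_tumor=pd.Series(payload["E_tumor"], index=genes, name="E_tumor"),
        E_nontumor=pd.Series(payload["E_nontumor"], index=genes, name="E_nontumor"),
        E_ref=pd.Series(payload["E_ref"], index=genes, name="E_ref"),
        alpha=payload["alpha"],
        beta=payload["beta"],
        modules=tuple(
            PlantedModule(m["name"], tuple(m["genes"]), m["ratio"])
            for m in payload["modules"]
        ),
    )


# ----------------------------------------------------------------------
def parse_gmt(path, universe=None) -> PathwayCollection:
    """Standard GMT: one pathway per line, name TAB description TAB gene ids.

    Duplicate genes within a line are deduplicated; empty lines skipped.
    If ``universe`` is omitted, the union of all pathway genes is used.
    """
    path = Path(path)
    pathways: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}, line {lineno}: expected name, description and >=1 gene"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}, line {lineno}: pathway {name!r} has no genes")
            pathways[name] = genes
            descriptions[name] = description
    if not pathways:
        raise ParseError(f"{path}: no pathways found")
    if universe is None:
        universe = frozenset().union(*pathways.values())
    return PathwayCollection(pathways=pathways, universe=frozenset(universe),
                             descriptions=descriptions)


def write_gmt(collection: PathwayCollection, path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(collection.pathways):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.pathways[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")
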