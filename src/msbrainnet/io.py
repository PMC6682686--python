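"""Readers and writers for all tabular products.

Dialects: subject-level tables are tab-delimited UTF-8 with a header line;
connectivity matrices are dense CSV with a leading label column and a label
header row. Floating fields round-trip to better than 1e-12 (written with
17 significant digits); integer and boolean fields round-trip exactly.
Asymmetric streamline counts are symmetrized on read by the maximum of the
(i, j)/(j, i) pair, and the rule is recorded in run metadata.
"""
from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .modularity import AdjacencyMatrix
from .types import (
    Cohort,
    DensityCurve,
    LymphocytePanel,
    Partition,
    StreamlineMatrix,
    Subject,
    ThicknessTable,
)

SYMMETRIZATION_RULE = "max of (i,j) and (j,i)"
_FLOAT_FMT = "%.17g"

_COHORT_COLUMNS = [
    "id",
    "arm",
    "age",
    "sex",
    "disease_duration",
    "followup_interval",
    "edss_baseline",
    "edss_followup",
    "relapse_flag",
    "mri_activity_flag",
    "lesion_volume_baseline",
    "lesion_volume_followup",
]
_BOOL_COLS = ("relapse_flag", "mri_activity_flag")
_PANEL_COLUMNS = [
    "subject_id",
    "timepoint",
    "cd3",
    "cd4",
    "cd8",
    "cd56",
    "cd19",
    "alc",
    "cd4_cd8_ratio",
]


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")


def write_cohort(cohort: Cohort, path) -> None:
    df = cohort.frame().reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_cohort(path) -> Cohort:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing mandatory columns: {missing}")
    subjects = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _COHORT_COLUMNS}
        for col in _BOOL_COLS:
            kwargs[col] = _parse_bool(kwargs[col])
        kwargs["id"] = str(kwargs["id"])
        kwargs["arm"] = str(kwargs["arm"])
        kwargs["sex"] = str(kwargs["sex"])
        subjects.append(Subject(**kwargs))
    extra_cols = [c for c in df.columns if c not in _COHORT_COLUMNS]
    annotations = None
    if extra_cols:
        annotations = df.set_index(df["id"].astype(str))[extra_cols]
        annotations.index.name = "id"
    return Cohort(subjects=subjects, annotations=annotations)


def write_thickness(table: ThicknessTable, path) -> None:
    rows = []
    for t, tp in enumerate(("baseline", "followup")):
        for i, sid in enumerate(table.subject_ids):
            rows.append([sid, tp, *table.values[i, :, t]])
    df = pd.DataFrame(rows, columns=["subject_id", "timepoint", *table.region_labels])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_thickness(path) -> ThicknessTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "timepoint"):
        if col not in df.columns:
            raise SchemaError(f"thickness table missing mandatory column: {col}")
    regions = [c for c in df.columns if c not in ("subject_id", "timepoint")]
    if not regions:
        raise SchemaError("thickness table has no region columns")
    df["subject_id"] = df["subject_id"].astype(str)
    base = df[df.timepoint == "baseline"].set_index("subject_id")
    follow = df[df.timepoint == "followup"].set_index("subject_id")
    if sorted(base.index) != sorted(follow.index):
        raise ValidationError("thickness table must have exactly 2 timepoints per subject")
    ids = list(base.index)
    values = np.stack(
        [base[regions].to_numpy(float), follow.loc[ids, regions].to_numpy(float)],
        axis=2,
    )
    return ThicknessTable(subject_ids=ids, region_labels=regions, values=values)


def write_panels(panels: list[LymphocytePanel], path) -> None:
    df = pd.DataFrame([vars(p) for p in panels])[_PANEL_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_panels(path) -> list[LymphocytePanel]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"panel table missing mandatory columns: {missing}")
    return [
        LymphocytePanel(
            subject_id=str(r.subject_id),
            timepoint=str(r.timepoint),
            cd3=float(r.cd3),
            cd4=float(r.cd4),
            cd8=float(r.cd8),
            cd56=float(r.cd56),
            cd19=float(r.cd19),
            alc=float(r.alc),
            cd4_cd8_ratio=float(r.cd4_cd8_ratio),
        )
        for r in df.itertuples()
    ]


def write_matrix(mat: StreamlineMatrix, path) -> None:
    df = pd.DataFrame(mat.counts, index=mat.node_labels, columns=mat.node_labels)
    df.index.name = f"{mat.subject_id}|{mat.timepoint}|{mat.samples_per_seed}"
    df.to_csv(path)


def read_matrix(
    path, subject_id: str | None = None, timepoint: str | None = None,
    samples_per_seed: int | None = None,
) -> StreamlineMatrix:
    """Dense CSV matrix with a leading label column; symmetrized by max.

    Subject/timepoint/samples metadata default to a ``subject|timepoint|samples``
    encoding in the corner header cell when not given explicitly.
    """
    df = pd.read_csv(path, index_col=0)
    corner = str(df.index.name or "")
    parts = corner.split("|")
    if subject_id is None:
        subject_id = parts[0] if parts[0] else Path(path).stem
    if timepoint is None:
        timepoint = parts[1] if len(parts) > 1 else "baseline"
    if samples_per_seed is None:
        samples_per_seed = int(parts[2]) if len(parts) > 2 else 5000
    if df.shape[0] != df.shape[1]:
        raise SchemaError(
            f"matrix is not square: {df.shape[0]} rows x {df.shape[1]} columns"
        )
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise SchemaError("matrix row labels do not match column labels")
    counts = df.to_numpy()
    if np.any(counts < 0):
        raise ValidationError("negative streamline counts")
    counts = np.maximum(counts, counts.T)  # documented symmetrization rule
    np.fill_diagonal(counts, 0)
    return StreamlineMatrix(
        subject_id=subject_id,
        timepoint=timepoint,
        node_labels=[str(c) for c in df.columns],
        counts=counts.astype(np.int64),
        samples_per_seed=samples_per_seed,
    )


def write_partition(partition: Partition, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# q\t{partition.q!r}\n")
        fh.write("node\tmodule\n")
        for node, module in partition.assignment.items():
            fh.write(f"{node}\t{module}\n")


def read_partition(path) -> Partition:
    q = float("nan")
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith("# q\t"):
            q = float(line.split("\t", 1)[1])
        elif line:
            body.append(line)
    if not body or body[0] != "node\tmodule":
        raise SchemaError("partition file must have a 'node<TAB>module' header")
    assignment = {}
    for line in body[1:]:
        node, module = line.split("\t")
        assignment[node] = int(module)
    return Partition(assignment=assignment, q=q)


def write_density_curve(curve: DensityCurve, path) -> None:
    pd.DataFrame(
        {
            "density": curve.densities,
            "q": curve.q_values,
            "n_modules": curve.module_counts,
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_density_curve(path) -> DensityCurve:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("density", "q", "n_modules") if c not in df.columns]
    if missing:
        raise SchemaError(f"density curve missing columns: {missing}")
    return DensityCurve(
        densities=df["density"].to_numpy(),
        q_values=df["q"].to_numpy(),
        module_counts=df["n_modules"].to_numpy(),
    )


def export_graphml(adj: AdjacencyMatrix, path) -> None:
    """Optional GraphML export of a (weighted) adjacency matrix."""
    g = nx.Graph()
    g.add_nodes_from(adj.node_labels)
    n = adj.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            w = adj.weights[i, j]
            if w > 0:
                g.add_edge(adj.node_labels[i], adj.node_labels[j], weight=float(w))
    nx.write_graphml(g, path)


def write_run_metadata(metadata: dict, path) -> None:
    record = dict(metadata)
    record.setdefault("symmetrization_rule", SYMMETRIZATION_RULE)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
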