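"""Reading, validating and writing association tables and disease-DAG inputs.

All tabular inputs and outputs are header-bearing, UTF-8, tab-separated
files.  Association tables need at least two columns (left entity, right
entity); extra columns such as evidence text are ignored, and rows that
repeat a pair with different evidence collapse to a single edge.
"""

from __future__ import annotations

import logging
import re
from os import PathLike
from typing import Mapping

import networkx as nx
import pandas as pd

from .entities import AssociationSet, EntityId, normalize_label

logger = logging.getLogger(__name__)

# Pre-mature miRNA names carry a trailing genomic-copy suffix
# (hsa-mir-125b-1, hsa-mir-125b-2 both yield mature hsa-mir-125b).  The
# stem must itself end in a numbered segment so that mature names like
# hsa-mir-21 are left alone; the capture group is the merged name.
_COPY_SUFFIX = re.compile(r"^(.+-\d+[a-z]*)-\d+$")


def _resolve_column(frame: pd.DataFrame, column: str | int, path: str) -> pd.Series:
    if isinstance(column, int):
        if column >= frame.shape[1]:
            raise ValueError(
                f"{path}: column index {column} out of range "
                f"({frame.shape[1]} columns present)"
            )
        return frame.iloc[:, column]
    if column not in frame.columns:
        raise ValueError(
            f"{path}: missing column {column!r}; present: {list(frame.columns)}"
        )
    return frame[column]


def read_association_table(
    path: str | PathLike,
    left_class: str,
    right_class: str,
    left_col: str | int = 0,
    right_col: str | int = 1,
    aliases: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> AssociationSet:
    """Read a two-class association table into a deduplicated edge set.

    Parameters
    ----------
    path
        TSV file with a header row and at least two columns.
    left_class, right_class
        Entity namespaces for the two columns.
    left_col, right_col
        Column names, or 0-based positional indices.
    aliases
        Optional synonym map applied to normalized labels (both sides);
        used to reconcile residual disease-name differences between
        source databases.
    """
    path = str(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    left = _resolve_column(frame, left_col, path)
    right = _resolve_column(frame, right_col, path)
    alias_map = {normalize_label(k): normalize_label(v) for k, v in (aliases or {}).items()}

    assoc = AssociationSet(
        left_class, right_class, provenance=provenance if provenance is not None else path
    )
    for a, b in zip(left, right):
        if pd.isna(a) or pd.isna(b):
            continue
        la = normalize_label(a)
        lb = normalize_label(b)
        la = alias_map.get(la, la)
        lb = alias_map.get(lb, lb)
        if not la or not lb:
            continue
        assoc.add(EntityId(left_class, la), EntityId(right_class, lb))
    if len(assoc) == 0:
        raise ValueError(f"{path}: no associations")
    return assoc


def write_association_table(assoc: AssociationSet, path: str | PathLike) -> None:
    """Write an association set as a two-column TSV (sorted, one edge per row)."""
    frame = pd.DataFrame(
        [(left.label, right.label) for left, right in assoc],
        columns=[assoc.left_class, assoc.right_class],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_alias_table(path: str | PathLike) -> dict[str, str]:
    """Read a two-column synonym TSV (from_label, to_label)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: alias table needs two columns")
    return {
        normalize_label(a): normalize_label(b)
        for a, b in zip(frame.iloc[:, 0], frame.iloc[:, 1])
        if not (pd.isna(a) or pd.isna(b))
    }


def merge_mirna_copies(
    assoc: AssociationSet, pattern: re.Pattern | str | None = None
) -> AssociationSet:
    """Merge genomic miRNA copies that produce the same mature miRNA.

    Labels on whichever side is the ``mirna`` class that fully match the
    copy pattern (default: a trailing ``-<digit>`` suffix after a
    numbered stem segment) are renamed to the pattern's first capture
    group — the common stem — and duplicate edges arising from the rename
    collapse.  A no-op when no label matches.
    """
    if pattern is None:
        pattern = _COPY_SUFFIX
    elif isinstance(pattern, str):
        pattern = re.compile(pattern)
    if "mirna" not in (assoc.left_class, assoc.right_class):
        raise ValueError("merge_mirna_copies requires a mirna side")

    def strip(entity: EntityId) -> EntityId:
        if entity.namespace != "mirna":
            return entity
        match = pattern.fullmatch(entity.label)
        if match is None or not match.group(1):
            return entity
        return EntityId("mirna", match.group(1))

    return AssociationSet(
        assoc.left_class,
        assoc.right_class,
        ((strip(a), strip(b)) for a, b in assoc.edges),
        provenance=assoc.provenance,
    )


def filter_to_universe(
    gold: AssociationSet,
    diseases: set[EntityId],
    lncrnas: set[EntityId],
) -> AssociationSet:
    """Restrict gold lncRNA-disease associations to entities in the datasets.

    Keeps only edges whose lncRNA appears in ``lncrnas`` and whose disease
    appears in ``diseases`` — gold associations involving entities absent
    from the miRNA-disease or lncRNA-miRNA data carry no signal for a
    shared-miRNA model and are removed before evaluation.
    """
    if {gold.left_class, gold.right_class} != {"lncrna", "disease"}:
        raise ValueError("filter_to_universe expects a lncrna-disease set")

    def keep(edge: tuple[EntityId, EntityId]) -> bool:
        for endpoint in edge:
            if endpoint.namespace == "lncrna" and endpoint not in lncrnas:
                return False
            if endpoint.namespace == "disease" and endpoint not in diseases:
                return False
        return True

    return AssociationSet(
        gold.left_class,
        gold.right_class,
        (e for e in gold.edges if keep(e)),
        provenance=gold.provenance,
    )


def read_disease_dag_inputs(
    mapping_path: str | PathLike, edges_path: str | PathLike
) -> tuple[dict[EntityId, set[EntityId]], nx.DiGraph]:
    """Read the disease→MeSH-term mapping and the MeSH parent→child edges.

    Returns
    -------
    mapping
        disease → set of mesh_term entities (a disease may occupy several
        tree positions).
    dag
        Directed term graph, edges parent → child, validated acyclic.

    Raises
    ------
    ValueError
        If the term graph contains a cycle (one cycle is named).
    """
    mapping_path, edges_path = str(mapping_path), str(edges_path)
    mapping_frame = pd.read_csv(mapping_path, sep="\t", dtype=str)
    if mapping_frame.shape[1] < 2:
        raise ValueError(f"{mapping_path}: expected two columns (disease, mesh_term)")
    mapping: dict[EntityId, set[EntityId]] = {}
    for disease, term in zip(mapping_frame.iloc[:, 0], mapping_frame.iloc[:, 1]):
        if pd.isna(disease) or pd.isna(term):
            continue
        d = EntityId("disease", disease)
        mapping.setdefault(d, set()).add(EntityId("mesh_term", term))

    edge_frame = pd.read_csv(edges_path, sep="\t", dtype=str)
    if edge_frame.shape[1] < 2:
        raise ValueError(f"{edges_path}: expected two columns (parent, child)")
    dag = nx.DiGraph()
    for parent, child in zip(edge_frame.iloc[:, 0], edge_frame.iloc[:, 1]):
        if pd.isna(parent) or pd.isna(child):
            continue
        dag.add_edge(EntityId("mesh_term", parent), EntityId("mesh_term", child))
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        pretty = " -> ".join(str(u.label) for u, _ in cycle) + f" -> {cycle[0][0].label}"
        raise ValueError(f"{edges_path}: term graph contains a cycle: {pretty}")
    return mapping, dag
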