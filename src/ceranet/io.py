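"""Readers and writers for the on-disk formats the pipeline touches.

All tabular files are UTF-8, tab-separated, with ``#`` comment lines
ignored.  Identifiers are plain strings (gene symbols or Ensembl IDs);
no identifier mapping is performed here — that is the caller's
responsibility, because mixed symbol/Ensembl inputs cannot be resolved
safely without an annotation source.

Formats
-------
expression matrix
    First column ``feature_id``, remaining columns sample IDs, values
    log2-scale expression.
sample sheet
    Columns ``sample_id``, ``patient_id``, ``condition`` with condition
    in {EC, EU} (ectopic / eutopic).
interaction table
    Columns ``mirna_id``, ``target_id``, ``target_class`` with
    target_class in {mRNA, lncRNA}.
GMT
    Standard gene-set dialect: name, description, members, tab-separated.
seed list
    One gene identifier per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("EC", "EU")
TARGET_CLASSES = ("mRNA", "lncRNA")


class FormatError(ValueError):
    """A file violates its declared format or an input invariant."""


# ---------------------------------------------------------------------------
# expression matrices and sample sheets
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet mapping sample -> (patient, condition)."""
    path = Path(path)
    sheet = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "patient_id", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet lacks columns {sorted(missing)}")
    bad = set(sheet["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"{path}: unknown condition values {sorted(bad)}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicated sample IDs {dupes}")
    return sheet.reset_index(drop=True)


def _validate_pairing(matrix: pd.DataFrame, sheet: pd.DataFrame, origin: str) -> None:
    known = set(sheet["sample_id"])
    unknown = [s for s in matrix.columns if s not in known]
    if unknown:
        raise FormatError(f"{origin}: samples {unknown} absent from sample sheet")
    sub = sheet[sheet["sample_id"].isin(matrix.columns)]
    for patient, grp in sub.groupby("patient_id"):
        conditions = sorted(grp["condition"])
        if conditions != sorted(CONDITIONS):
            raise FormatError(
                f"{origin}: patient {patient!r} does not have exactly one EC and "
                f"one EU sample (found {conditions})"
            )


def read_expression(
    matrix_path: str | Path, sample_sheet_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read one RNA class's expression matrix plus its sample sheet.

    Returns ``(matrix, sample_sheet)`` with the matrix indexed by feature
    ID (validated unique), every sample present in the sheet, and each
    patient carrying exactly one EC and one EU column.  Rows containing
    missing values are dropped with a logged count.
    """
    matrix_path = Path(matrix_path)
    raw = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{matrix_path}: duplicated feature ID {dup!r}")
    non_numeric = raw.columns[
        [not pd.api.types.is_numeric_dtype(raw[c]) for c in raw.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad_rows = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()]
        raise FormatError(
            f"{matrix_path}: non-numeric value in column {col!r}"
            f" (e.g. row {bad_rows[0]!r})"
        )
    n_na = int(raw.isna().any(axis=1).sum())
    if n_na:
        logger.warning("%s: dropped %d rows with missing values", matrix_path, n_na)
        raw = raw.dropna()
    raw = raw.astype(float)
    raw.index = raw.index.astype(str)
    raw.index.name = "feature_id"
    sheet = read_sample_sheet(sample_sheet_path)
    _validate_pairing(raw, sheet, str(matrix_path))
    return raw, sheet


@dataclass
class PairedExpressionSet:
    """Log2 expression matrices for up to three RNA classes with EC/EU
    pairing by patient.

    ``matrices`` maps an RNA class name (``mrna``, ``lncrna``, ``mirna``)
    to a features x samples DataFrame; ``sample_sheet`` holds the
    sample -> (patient, condition) assignment shared by the classes.
    """

    matrices: dict[str, pd.DataFrame]
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        for cls, mat in self.matrices.items():
            _validate_pairing(mat, self.sample_sheet, f"class {cls!r}")

    @property
    def classes(self) -> list[str]:
        return list(self.matrices)

    def patients(self) -> list[str]:
        return sorted(self.sample_sheet["patient_id"].unique())

    def paired_columns(self, rna_class: str) -> tuple[list[str], list[str]]:
        """Return (EC sample IDs, EU sample IDs) aligned by patient."""
        mat = self.matrices[rna_class]
        sub = self.sample_sheet[self.sample_sheet["sample_id"].isin(mat.columns)]
        by = sub.set_index(["patient_id", "condition"])["sample_id"]
        patients = sorted(sub["patient_id"].unique())
        ec = [by.loc[(p, "EC")] for p in patients]
        eu = [by.loc[(p, "EU")] for p in patients]
        return ec, eu

    def paired_differences(self, rna_class: str) -> pd.DataFrame:
        """Per-feature EC minus EU log2 differences, one column per patient."""
        mat = self.matrices[rna_class]
        ec, eu = self.paired_columns(rna_class)
        diffs = mat[ec].to_numpy() - mat[eu].to_numpy()
        sub = self.sample_sheet[self.sample_sheet["sample_id"].isin(mat.columns)]
        patients = sorted(sub["patient_id"].unique())
        return pd.DataFrame(diffs, index=mat.index, columns=patients)


# ---------------------------------------------------------------------------
# miRNA-target interaction tables
# ---------------------------------------------------------------------------


@dataclass
class InteractionSet:
    """Bipartite miRNA -> target edges typed by target class."""

    edges: pd.DataFrame  # columns mirna_id, target_id, target_class

    def __post_init__(self) -> None:
        required = {"mirna_id", "target_id", "target_class"}
        missing = required - set(self.edges.columns)
        if missing:
            raise FormatError(f"interaction table lacks columns {sorted(missing)}")
        bad = set(self.edges["target_class"]) - set(TARGET_CLASSES)
        if bad:
            raise FormatError(f"unknown target_class values {sorted(bad)}")
        n_dup = int(self.edges.duplicated().sum())
        if n_dup:
            logger.warning("collapsed %d duplicate interaction edges", n_dup)
            self.edges = self.edges.drop_duplicates()
        self.edges = self.edges.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def mirnas(self) -> set[str]:
        return set(self.edges["mirna_id"])

    def targets(self, target_class: str) -> set[str]:
        sel = self.edges["target_class"] == target_class
        return set(self.edges.loc[sel, "target_id"])

    def partner_map(self, target_class: str) -> dict[str, set[str]]:
        """Map each target of the given class to its set of miRNA partners."""
        sel = self.edges[self.edges["target_class"] == target_class]
        return {
            t: set(grp["mirna_id"]) for t, grp in sel.groupby("target_id", sort=True)
        }

    def mirna_partners(self, target_id: str) -> set[str]:
        sel = self.edges["target_id"] == target_id
        return set(self.edges.loc[sel, "mirna_id"])

    def subset(
        self,
        mirnas: Iterable[str] | None = None,
        targets_by_class: Mapping[str, Iterable[str]] | None = None,
    ) -> "InteractionSet":
        """Restrict edges to the given miRNAs and/or per-class target sets."""
        edges = self.edges
        if mirnas is not None:
            edges = edges[edges["mirna_id"].isin(set(mirnas))]
        if targets_by_class is not None:
            keep = pd.Series(False, index=edges.index)
            for cls, tgts in targets_by_class.items():
                keep |= (edges["target_class"] == cls) & edges["target_id"].isin(
                    set(tgts)
                )
            edges = edges[keep]
        return InteractionSet(edges.copy())


def read_interactions(path: str | Path) -> InteractionSet:
    """Read a miRNA-target interaction table, deduplicating edges."""
    path = Path(path)
    edges = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    iset = InteractionSet(edges)
    for cls in TARGET_CLASSES:
        n = int((iset.edges["target_class"] == cls).sum())
        logger.info("%s: %d %s-target edges", path, n, cls)
    return iset


def write_interactions(iset: InteractionSet, path: str | Path) -> None:
    iset.edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets, seed lists, networks
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members per line)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_seed_list(path: str | Path) -> list[str]:
    """Read a plain-text seed gene list, one identifier per line."""
    with open(path, encoding="utf-8") as fh:
        seeds = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return seeds


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "edgelist") -> None:
    """Write a ceRNA network as an edge-list TSV or GraphML.

    The edge list carries the hypergeometric evidence columns
    (T, t, N, r, p_value); GraphML nodes carry their ``node_class``
    attribute (mRNA/lncRNA).
    """
    path = Path(path)
    if fmt == "edgelist":
        rows = []
        for u, v, data in graph.edges(data=True):
            a, b = (u, v) if graph.nodes[u].get("node_class") == "lncRNA" else (v, u)
            rows.append(
                {
                    "lncrna_id": a,
                    "mrna_id": b,
                    "T": data.get("T"),
                    "t": data.get("t"),
                    "N": data.get("N"),
                    "r": data.get("r"),
                    "p_value": data.get("p_value"),
                    "shared_mirnas": ",".join(sorted(data.get("shared_mirnas", ()))),
                }
            )
        pd.DataFrame(
            rows,
            columns=["lncrna_id", "mrna_id", "T", "t", "N", "r", "p_value", "shared_mirnas"],
        ).sort_values(["lncrna_id", "mrna_id"]).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        g = graph.copy()
        for _, _, data in g.edges(data=True):
            if "shared_mirnas" in data:
                data["shared_mirnas"] = ",".join(sorted(data["shared_mirnas"]))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_edgelist(path: str | Path) -> nx.Graph:
    """Read an edge-list TSV written by :func:`write_network` back into a graph."""
    df = pd.read_csv(path, sep="\t", comment="#")
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        shared = row.shared_mirnas
        shared = frozenset() if pd.isna(shared) or shared == "" else frozenset(str(shared).split(","))
        graph.add_node(row.lncrna_id, node_class="lncRNA")
        graph.add_node(row.mrna_id, node_class="mRNA")
        graph.add_edge(
            row.lncrna_id,
            row.mrna_id,
            T=int(row.T),
            t=int(row.t),
            N=int(row.N),
            r=int(row.r),
            p_value=float(row.p_value),
            shared_mirnas=shared,
        )
    return graph
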