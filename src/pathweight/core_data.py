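"""Containers and file I/O for expression matrices, gene sets and phenotype labels.

The canonical in-memory layout is samples x genes.  Expression files are
plain TSV in either orientation (an explicit flag, never auto-detected);
gene sets are GMT lines; phenotypes are bare CLS files (positional) or a
two-column ``sample_id<TAB>label`` table (attached by name).

Expression values are assumed to be normalized upstream; no normalization
is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("pathweight")

__all__ = [
    "ExpressionDataset",
    "PathwayCollection",
    "PathwayEntry",
    "PathwayMatrix",
    "EmptyPathwayError",
    "FormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_cls",
    "write_cls",
    "read_label_table",
    "extract_pathway_matrix",
]


class FormatError(ValueError):
    """A file violated the expected dialect (ragged rows, duplicates, ...)."""


class EmptyPathwayError(ValueError):
    """No gene of the pathway is present in the dataset."""


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionDataset:
    """A samples x genes expression matrix with optional binary labels.

    ``labels`` codes 1 = disease, 0 = normal.  Labels are unset (None)
    until attached; operations that need a phenotype require them.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} columns")
        _check_unique(self.gene_ids, "gene ID")
        _check_unique(self.sample_ids, "sample ID")
        if self.labels is not None:
            self.labels = _validate_labels(self.labels, n)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def with_labels(self, labels) -> "ExpressionDataset":
        """Attach labels positionally (bare CLS convention)."""
        return replace(self, labels=np.asarray(labels, dtype=int))

    def with_labels_by_name(self, mapping: dict[str, int]) -> "ExpressionDataset":
        """Attach labels by sample-id match; every sample must be covered."""
        missing = [s for s in self.sample_ids if s not in mapping]
        if missing:
            raise FormatError(f"no label for sample(s): {missing[:5]}")
        return replace(
            self, labels=np.array([mapping[s] for s in self.sample_ids], dtype=int)
        )


def _validate_labels(labels, n: int) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if y.shape != (n,):
        raise ValueError(f"labels have shape {y.shape}, expected ({n},)")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must contain only 0 (normal) and 1 (disease)")
    return y


@dataclass
class PathwayEntry:
    pathway_id: str
    pathway_name: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"pathway {self.pathway_id!r} has no genes")


@dataclass
class PathwayCollection:
    """Ordered gene sets; ids unique, gene lists in file order."""

    entries: list[PathwayEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([e.pathway_id for e in self.entries], "pathway ID")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, pathway_id: str) -> PathwayEntry:
        for e in self.entries:
            if e.pathway_id == pathway_id:
                return e
        raise KeyError(pathway_id)


@dataclass
class PathwayMatrix:
    """The gene-subset matrix of one pathway, columns in pathway order."""

    values: np.ndarray
    gene_ids: list[str]
    labels: np.ndarray
    n_missing: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("pathway matrix must be n x m with m >= 1")
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError("gene_ids length does not match columns")
        self.labels = _validate_labels(self.labels, self.values.shape[0])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_tsv(path, orientation: str) -> ExpressionDataset:
    """Read a tab-delimited expression matrix.

    Parameters
    ----------
    path
        TSV file with one header row of IDs and one leading ID column.
    orientation
        ``"genes_in_rows"`` or ``"samples_in_rows"``; no auto-detection.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc
    _check_unique(list(df.index), "row ID")
    _check_unique(list(df.columns), "column ID")
    try:
        values = df.astype(float)
    except ValueError as exc:
        # name the offending cell for the error message
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise FormatError(
                    f"{path}: non-numeric value at row {row!r}, column {col!r}"
                ) from exc
        raise FormatError(f"{path}: non-numeric value") from exc
    if values.isna().any().any():
        raise FormatError(f"{path}: missing value in matrix")
    if orientation == "genes_in_rows":
        values = values.T  # canonical layout is samples x genes
    return ExpressionDataset(
        values=values.to_numpy(),
        gene_ids=list(values.columns),
        sample_ids=list(values.index),
    )


def write_expression_tsv(dataset: ExpressionDataset, path, orientation: str) -> None:
    df = pd.DataFrame(
        dataset.values, index=dataset.sample_ids, columns=dataset.gene_ids
    )
    if orientation == "genes_in_rows":
        df = df.T
        df.index.name = "gene_id"
    elif orientation == "samples_in_rows":
        df.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path) -> PathwayCollection:
    """Read a GMT gene-set file: name, description, genes, tab-separated.

    Duplicate genes within a line are dropped, keeping first occurrence.
    """
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            entries.append(PathwayEntry(fields[0], fields[1], genes))
    if not entries:
        raise FormatError(f"{path}: empty GMT file")
    return PathwayCollection(entries)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for e in collection:
            fh.write("\t".join([e.pathway_id, e.pathway_name, *e.gene_ids]) + "\n")


def read_cls(path) -> np.ndarray:
    """Read a bare CLS phenotype file into a 0/1 vector.

    The first-listed class maps to 0.  Bare CLS carries no sample names,
    so the result attaches positionally (the CLI warns about this).
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS needs 3 lines")
    header = lines[0].split()
    if len(header) != 3:
        raise FormatError(f"{path}: malformed CLS header {lines[0]!r}")
    n, k = int(header[0]), int(header[1])
    if k != 2:
        raise FormatError(f"{path}: expected exactly 2 classes, found {k}")
    tokens = lines[2].split()
    if len(tokens) != n:
        raise FormatError(f"{path}: {len(tokens)} labels for header n={n}")
    classes = list(dict.fromkeys(tokens))
    if len(classes) != 2:
        raise FormatError(f"{path}: label line has {len(classes)} distinct classes")
    first = classes[0]
    return np.array([0 if t == first else 1 for t in tokens], dtype=int)


def write_cls(labels, path, class_names: tuple[str, str] = ("normal", "disease")) -> None:
    y = np.asarray(labels, dtype=int)
    with open(path, "w") as fh:
        fh.write(f"{len(y)} 2 1\n")
        fh.write(f"# {class_names[0]} {class_names[1]}\n")
        fh.write(" ".join(class_names[v] for v in y) + "\n")


def read_label_table(path) -> dict[str, int]:
    """Read a two-column ``sample_id<TAB>label`` file for by-name attachment."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype=str)
    _check_unique(list(df["sample_id"]), "sample ID")
    try:
        labels = df["label"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: labels must be 0/1 integers") from exc
    if not labels.isin((0, 1)).all():
        raise FormatError(f"{path}: labels must be 0/1")
    return dict(zip(df["sample_id"], labels))


def extract_pathway_matrix(
    dataset: ExpressionDataset, entry: PathwayEntry
) -> PathwayMatrix:
    """Slice the columns of one pathway out of the dataset.

    Columns keep the pathway's gene order after dropping genes absent from
    the dataset (matching is exact, case-sensitive).  A pathway with no
    gene present raises :class:`EmptyPathwayError`, which screens treat as
    skip-with-warning.
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels attached")
    index = {g: j for j, g in enumerate(dataset.gene_ids)}
    cols = [index[g] for g in entry.gene_ids if g in index]
    n_missing = len(entry.gene_ids) - len(cols)
    if not cols:
        raise EmptyPathwayError(
            f"pathway {entry.pathway_id!r}: no gene present in dataset"
        )
    if n_missing:
        logger.warning(
            "pathway %s: %d of %d genes absent from dataset",
            entry.pathway_id, n_missing, len(entry.gene_ids),
        )
    return PathwayMatrix(
        values=dataset.values[:, cols],
        gene_ids=[dataset.gene_ids[j] for j in cols],
        labels=dataset.labels,
        n_missing=n_missing,
    )
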