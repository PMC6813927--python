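"""Readers and writers for the on-disk artifacts of the pipeline.

Everything is UTF-8 TSV with a header row: expression matrices (rows =
genes, columns = samples), sample metadata, homeolog-group tables, GMT
gene sets, GO annotation tables, BED-like genomic-compartment tables and
Cytoscape-compatible edge lists.  Validation failures raise
:class:`FormatError` with the offending location; nothing is silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleTable",
    "HomeologTable",
    "GeneSetCollection",
    "CompartmentTable",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_table",
    "write_sample_table",
    "read_homeolog_table",
    "write_homeolog_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_go_annotation",
    "read_compartments",
    "write_compartments",
    "write_edge_file",
    "read_edge_file",
]

VALID_UNITS = ("TPM", "count", "normalized")
VALID_SUBGENOMES = ("A", "B", "D", "U")
COMPARTMENT_LABELS = ("R1", "R2a", "C", "R2b", "R3")


class FormatError(ValueError):
    """A file violated its declared schema."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.
    unit : str
        One of ``TPM``, ``count`` or ``normalized``.
    """

    values: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise FormatError(f"unknown expression unit {self.unit!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        if self.unit in ("TPM", "count") and (arr < 0).any():
            raise FormatError(f"negative value in {self.unit} matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.unit)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.unit)


@dataclass
class SampleTable:
    """Sample metadata: sample_id, tissue, study."""

    frame: pd.DataFrame  # columns sample_id, tissue, study

    def __post_init__(self) -> None:
        required = {"sample_id", "tissue", "study"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"sample table missing columns {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in first-appearance order."""
        return list(dict.fromkeys(self.frame["tissue"]))

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.frame.loc[self.frame["tissue"] == tissue, "sample_id"])


@dataclass
class HomeologTable:
    """Homeolog-group membership: group_id, gene_id, subgenome (A/B/D/U)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group_id", "gene_id", "subgenome"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"homeolog table missing columns {sorted(missing)}")
        bad = set(self.frame["subgenome"]) - set(VALID_SUBGENOMES)
        if bad:
            raise FormatError(f"unknown subgenome labels {sorted(bad)}")
        if self.frame.duplicated(["group_id", "gene_id"]).any():
            raise FormatError("duplicate (group_id, gene_id) pair")
        if self.frame["gene_id"].duplicated().any():
            dup = self.frame.loc[self.frame["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"gene {dup!r} assigned to more than one group")

    @property
    def group_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["group_id"]))

    def members(self, group_id: str) -> pd.DataFrame:
        return self.frame.loc[self.frame["group_id"] == group_id]

    def copy_numbers(self) -> pd.DataFrame:
        """Per group: homeolog count on each subgenome (columns nA, nB, nD)."""
        counts = (
            self.frame.pivot_table(
                index="group_id", columns="subgenome", values="gene_id", aggfunc="count"
            )
            .reindex(columns=["A", "B", "D"])
            .fillna(0)
            .astype(int)
        )
        counts.columns = ["nA", "nB", "nD"]
        return counts


class GeneSetCollection(dict):
    """Mapping set name -> list of member gene ids (duplicates collapsed)."""

    def __init__(self, sets: Mapping[str, Iterable[str]] | None = None):
        super().__init__()
        if sets:
            for name, members in sets.items():
                self.add(name, members)

    def add(self, name: str, members: Iterable[str]) -> None:
        uniq = list(dict.fromkeys(members))
        if not uniq:
            raise FormatError(f"gene set {name!r} is empty")
        self[name] = uniq


@dataclass
class CompartmentTable:
    """Genomic compartment intervals, 0-based half-open (BED convention)."""

    frame: pd.DataFrame  # chromosome, start, end, label

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end", "label"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"compartment table missing columns {sorted(missing)}")
        bad = set(self.frame["label"]) - set(COMPARTMENT_LABELS)
        if bad:
            raise FormatError(f"unknown compartment labels {sorted(bad)}")
        frame = self.frame.sort_values(["chromosome", "start"]).reset_index(drop=True)
        if (frame["start"] >= frame["end"]).any():
            row = frame.loc[frame["start"] >= frame["end"]].iloc[0]
            raise FormatError(
                f"empty interval on {row['chromosome']}: [{row['start']}, {row['end']})"
            )
        for chrom, grp in frame.groupby("chromosome", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise FormatError(f"overlapping compartment intervals on {chrom}")
        self.frame = frame

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chromosome"]))


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_tsv(path: str | Path, unit: str = "TPM") -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    frame.index = frame.index.astype(str)
    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            gene = frame.index[converted.isna().to_numpy()][0]
            raise FormatError(
                f"{path.name}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        numeric[col] = converted
    return ExpressionMatrix(numeric, unit)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_sample_table(path: str | Path, tissue_labels: Sequence[str] | None = None) -> SampleTable:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    table = SampleTable(frame)
    if tissue_labels is not None:
        unknown = set(table.frame["tissue"]) - set(tissue_labels)
        if unknown:
            raise FormatError(f"unknown tissue labels {sorted(unknown)}")
    return table


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_homeolog_table(path: str | Path) -> HomeologTable:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return HomeologTable(frame)


def write_homeolog_table(table: HomeologTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member1 <tab> member2 ..."""
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            if name in collection:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            collection.add(name, [g for g in fields[2:] if g])
    return collection


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection.items():
            handle.write("\t".join([name, "na", *members]) + "\n")


def read_go_annotation(path: str | Path) -> pd.DataFrame:
    """Read a two-column gene_id / go_id annotation table."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"gene_id", "go_id"} - set(frame.columns)
    if missing:
        raise FormatError(f"GO annotation missing columns {sorted(missing)}")
    return frame.drop_duplicates()


def read_compartments(path: str | Path) -> CompartmentTable:
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"chromosome": str, "start": int, "end": int, "label": str},
        comment="#",
    )
    return CompartmentTable(frame)


def write_compartments(table: CompartmentTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


EDGE_COLUMNS = ["fromNode", "toNode", "weight", "direction", "fromAltName", "toAltName"]


def write_edge_file(edges: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    """Write a Cytoscape-compatible edge list.

    ``edges`` yields (fromNode, toNode, weight); direction is ``undirected``
    and alt names repeat the node ids, matching the WGCNA export layout.
    Weights are printed with 6 significant digits.
    """
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(EDGE_COLUMNS) + "\n")
        for a, b, w in edges:
            handle.write(f"{a}\t{b}\t{w:.6g}\tundirected\t{a}\t{b}\n")


def read_edge_file(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"fromNode": str, "toNode": str})
    missing = set(EDGE_COLUMNS[:3]) - set(frame.columns)
    if missing:
        raise FormatError(f"edge file missing columns {sorted(missing)}")
    return frame
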