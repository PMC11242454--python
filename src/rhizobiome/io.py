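"""Readers and writers for the package's plain-text formats.

Feature tables are tab-separated with samples as rows and taxa as columns
(the orientation is stated in a comment header); trees are Newick with
branch lengths; metadata, taxonomy and trait tables are plain TSV with the
identifier in the first column.  A BIOM table can be imported when the
``biom-format`` package is present.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import FeatureTable

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_biom_table",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_traits",
    "write_traits",
]

_ORIENTATION_HEADER = "# rhizobiome feature table; orientation: samples are rows, taxa are columns"


def _check_ids(ids, kind: str, lineno: int | None = None) -> None:
    where = f" (line {lineno})" if lineno is not None else ""
    seen = set()
    for i in ids:
        if i == "" or any(c.isspace() for c in i):
            raise ValueError(f"invalid {kind} id {i!r}: empty or contains whitespace{where}")
        if i in seen:
            raise ValueError(f"duplicate {kind} id {i!r}{where}")
        seen.add(i)


def read_feature_table(path: str, is_relative: bool = False) -> FeatureTable:
    """Read a samples × taxa TSV, validating shape and values with line numbers."""
    rows: list[list[str]] = []
    line_numbers: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
            line_numbers.append(lineno)
    if not rows:
        raise ValueError(f"{path}: empty feature table")
    header = rows[0]
    taxa = header[1:]
    _check_ids(taxa, "taxon", line_numbers[0])
    width = len(header)
    sample_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(taxa)))
    for r, (row, lineno) in enumerate(zip(rows[1:], line_numbers[1:])):
        if len(row) != width:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, expected {width})"
            )
        sample_ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            try:
                v = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {cell!r} for taxon {taxa[c]!r}"
                ) from exc
            if v < 0:
                raise ValueError(
                    f"{path}:{lineno}: negative count {cell} for taxon {taxa[c]!r}"
                )
            values[r, c] = v
    _check_ids(sample_ids, "sample")
    df = pd.DataFrame(values, index=sample_ids, columns=taxa)
    return FeatureTable(df, is_relative=is_relative)


def _format_value(v: float) -> str:
    fv = float(v)
    return str(int(fv)) if fv.is_integer() else repr(fv)


def write_feature_table(table: FeatureTable, path: str) -> None:
    """Write a feature table TSV; write∘read∘write is byte-identical."""
    with open(path, "w") as fh:
        fh.write(_ORIENTATION_HEADER + "\n")
        fh.write("sample_id\t" + "\t".join(map(str, table.taxon_ids)) + "\n")
        for sid, row in zip(table.sample_ids, table.to_numpy()):
            fh.write(str(sid) + "\t" + "\t".join(_format_value(v) for v in row) + "\n")


def read_biom_table(path: str) -> FeatureTable:
    """Import a BIOM-format table (observations × samples) as samples × taxa."""
    try:
        from biom import load_table
    except ImportError as exc:  # pragma: no cover
        raise ImportError("BIOM import requires the biom-format package") from exc
    bt = load_table(path)
    df = bt.to_dataframe(dense=True).T  # biom stores observations as rows
    return FeatureTable(df.astype(float), is_relative=False)


def read_tree(path: str) -> TreeNode:
    """Read a rooted Newick tree; every branch must carry a length."""
    tree = TreeNode.read(path, format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            name = node.name or "an internal node"
            raise ValueError(f"{path}: branch above {name} has no length "
                             "(lengths are required for UniFrac and βMNTD)")
    return tree


def write_tree(tree: TreeNode, path: str) -> None:
    tree.write(path, format="newick")


def read_metadata(path: str) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype={0: str})
    _check_ids(md.index.astype(str), "sample")
    return md


def write_metadata(metadata: pd.DataFrame, path: str) -> None:
    metadata.to_csv(path, sep="\t")


def read_taxonomy(path: str) -> pd.DataFrame:
    """Read a taxon → ranked-lineage TSV; missing ranks are explicit NA."""
    tx = pd.read_csv(path, sep="\t", index_col=0, comment="#", na_values=["NA"], keep_default_na=False)
    return tx.where(pd.notna(tx), None)


def write_taxonomy(taxonomy: pd.DataFrame, path: str) -> None:
    taxonomy.to_csv(path, sep="\t", na_rep="NA")


def read_traits(path: str) -> pd.DataFrame:
    tr = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    _check_ids(tr.index.astype(str), "cultivar")
    return tr


def write_traits(traits: pd.DataFrame, path: str) -> None:
    traits.to_csv(path, sep="\t")


def write_dataset(dataset, outdir: str) -> dict[str, str]:
    """Write every component of a simulated dataset plus a manifest of paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "table": os.path.join(outdir, "feature_table.tsv"),
        "tree": os.path.join(outdir, "tree.nwk"),
        "taxonomy": os.path.join(outdir, "taxonomy.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "traits": os.path.join(outdir, "traits.tsv"),
    }
    write_feature_table(dataset.table, paths["table"])
    write_tree(dataset.tree, paths["tree"])
    write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    write_metadata(dataset.metadata, paths["metadata"])
    write_traits(dataset.traits, paths["traits"])
    return paths
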