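"""Reading and writing the pipeline's on-disk formats.

Count matrices use the 10x triplet dialect: ``matrix.mtx`` (Matrix Market,
1-based indices, genes x cells), ``genes.tsv`` and ``barcodes.tsv``.
All tabular outputs are tab-separated with header rows.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, GeneExclusionSets

__all__ = [
    "read_10x_dir",
    "write_10x_dir",
    "read_annotation",
    "write_annotation",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_gene_family_lists",
    "write_gene_family_lists",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


def write_10x_dir(counts: CountMatrix, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(counts.values))
    pd.Series(counts.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    return out


def read_10x_dir(in_dir: str | Path) -> CountMatrix:
    d = Path(in_dir)
    mat = scipy.io.mmread(d / "matrix.mtx")
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0]
    return CountMatrix(mat, pd.Index(genes), pd.Index(barcodes))


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index_label="cell_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell_id")


def write_ortholog_map(orthologs: pd.Series, path: str | Path) -> None:
    orthologs.rename_axis("source_id").rename("target_id").to_csv(path, sep="\t")


def read_ortholog_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["target_id"].to_numpy(), index=pd.Index(df["source_id"]))


def write_gene_family_lists(sets: GeneExclusionSets, path: str | Path) -> None:
    rows = [
        {"family": fam, "gene_id": g}
        for fam in GeneExclusionSets.FAMILIES
        for g in sorted(getattr(sets, fam))
    ]
    pd.DataFrame(rows, columns=["family", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_gene_family_lists(path: str | Path) -> GeneExclusionSets:
    df = pd.read_csv(path, sep="\t")
    kwargs = {
        fam: frozenset(df.loc[df["family"] == fam, "gene_id"])
        for fam in GeneExclusionSets.FAMILIES
    }
    return GeneExclusionSets(**kwargs)


def write_matrix_tsv(frame: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
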