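"""Readers and writers for the pipeline's tab-delimited formats.

Expression matrix: TSV, UTF-8, first header cell ``gene``, remaining header
cells sample IDs, one gene per row, missing values written as ``NA``.
Phenotype, paired-region and ortholog tables are plain TSV with the column
names defined in :mod:`flowsig.datatypes`. The packaged 44-gene results
table ships as package data and loads through :func:`load_table1`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionDataset,
    OrthologMap,
    PairedRegionTable,
    PhenotypeTable,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

_TABLE1_N_RECORDS = 44
_TABLE1_QUERY_GENES = {"KLF2", "PKD2", "KLF4"}


def read_expression(
    path: str | Path,
    dataset_id: str | None = None,
    species: str = "human",
    input_scale: str = "log2",
) -> ExpressionDataset:
    """Read a gene-by-sample expression TSV into an :class:`ExpressionDataset`.

    Symbols are uppercased; duplicate symbols are collapsed by row mean with
    a logged warning. ``input_scale='linear'`` applies log2(x+1).

    Raises
    ------
    ValueError
        On an empty matrix or a non-numeric cell (named by row and column).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    gene_col = df.columns[0]
    genes = df[gene_col].map(normalize_symbol)
    mat = df.drop(columns=[gene_col])
    parsed = mat.apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna() & ~mat.isin(["NA", ""])
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {mat.iloc[r, c]!r} at gene "
            f"{genes.iloc[r]!r}, sample {mat.columns[c]!r}"
        )
    parsed.index = genes
    if parsed.index.has_duplicates:
        dupes = sorted(parsed.index[parsed.index.duplicated()].unique())
        logger.warning("%s: collapsing duplicate gene symbols by mean: %s", path, dupes)
        parsed = parsed.groupby(level=0, sort=False).mean()
    if input_scale == "linear":
        parsed = np.log2(parsed + 1.0)
    elif input_scale != "log2":
        raise ValueError("input_scale must be 'log2' or 'linear'")
    return ExpressionDataset(dataset_id or path.stem, species, parsed)


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset to TSV; NaNs become ``NA``. Round-trips exactly."""
    out = dataset.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False)


def read_paired_regions(path: str | Path) -> PairedRegionTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "animal_id": str})
    return PairedRegionTable(df)


def write_paired_regions(pairs: PairedRegionTable, path: str | Path) -> None:
    pairs.table.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Two-column TSV (human_symbol, rat_symbol); many-to-many entries error here."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["human_symbol", "rat_symbol"]:
        df.columns = ["human_symbol", "rat_symbol"] + list(df.columns[2:])
    return OrthologMap(df[["human_symbol", "rat_symbol"]])


def map_orthologs(
    genes: list[str], ortholog_map: OrthologMap, direction: str = "human_to_rat"
) -> tuple[list[str], list[str]]:
    """Translate symbols across species; unmapped symbols are reported, not dropped."""
    return ortholog_map.translate(genes, direction)


@dataclass
class Table1Record:
    """One row of the packaged 44-gene cross-species results table.

    ``rat_p``/``rat_fc`` are NaN where the rat array platform lacked the gene
    (p) or where no rat fold change was printed (fc, non-significant genes);
    ``same_direction`` flags genes moving the same way in BAV aorta and in
    disturbed-flow rat aorta; ``flow_annotation`` is the literature flag
    (``X`` shear-induced, ``X*2``/``X*4`` induced by KLF2/KLF4
    overexpression, ``?`` not cited).
    """

    gene: str
    rat_p: float
    rat_fc: float
    same_direction: bool | None
    asap_p: float
    asap_fc: float
    flow_annotation: str
    is_query: bool


def load_table1(as_frame: bool = False) -> list[Table1Record] | pd.DataFrame:
    """Load the packaged 44-gene results fixture.

    Raises
    ------
    ValueError
        If the packaged fixture fails its integrity checks (row count,
        query-gene flags, annotation vocabulary) — a corruption guard.
    """
    with resources.files("flowsig.data").joinpath("table1.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    if len(df) != _TABLE1_N_RECORDS:
        raise ValueError(f"table1 fixture corrupt: {len(df)} rows, expected 44")
    queries = set(df.loc[df["is_query"] == 1, "gene"])
    if queries != _TABLE1_QUERY_GENES:
        raise ValueError(f"table1 fixture corrupt: query genes {sorted(queries)}")
    if not set(df["flow_annotation"]) <= {"X", "X*2", "X*4", "?"}:
        raise ValueError("table1 fixture corrupt: bad flow annotation")
    if df["gene"].duplicated().any():
        raise ValueError("table1 fixture corrupt: duplicate genes")
    if not ((df["asap_p"] > 0) & (df["asap_p"] < 0.0140)).all():
        raise ValueError("table1 fixture corrupt: asap_p outside (0, 0.0140)")
    if as_frame:
        return df
    records = []
    for row in df.itertuples(index=False):
        same = None if pd.isna(row.same_direction) else bool(row.same_direction)
        records.append(
            Table1Record(
                gene=row.gene,
                rat_p=row.rat_p,
                rat_fc=row.rat_fc,
                same_direction=same,
                asap_p=row.asap_p,
                asap_fc=row.asap_fc,
                flow_annotation=row.flow_annotation,
                is_query=bool(row.is_query),
            )
        )
    return records
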