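"""Core containers shared by every pipeline stage.

All expression values are log2-scale and dimensionless; gene identifiers
are HGNC-style symbols, uppercase-normalized at construction time.
Cross-species matching always goes through an explicit :class:`OrthologMap`
(default: identity on uppercased symbols).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SPECIES = frozenset({"human", "rat", "mouse"})


def normalize_symbol(symbol: str) -> str:
    """Uppercase-strip a gene symbol. Idempotent by construction."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionDataset:
    """A gene-by-sample log2 expression matrix with a species tag.

    ``values`` is a DataFrame indexed by uppercased gene symbols with sample
    IDs as columns; missing measurements are NaN and are handled
    pairwise-complete in correlations and casewise in linear models.
    """

    dataset_id: str
    species: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValueError(
                f"species must be one of {sorted(VALID_SPECIES)}, got {self.species!r}"
            )
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError(f"dataset {self.dataset_id!r}: empty expression matrix")
        self.values.index = [normalize_symbol(g) for g in self.values.index]
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate gene symbols {dupes}"
            )
        if self.values.columns.has_duplicates:
            raise ValueError(f"dataset {self.dataset_id!r}: duplicate sample IDs")
        if np.isinf(self.values.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValueError(f"dataset {self.dataset_id!r}: non-finite values present")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        """Row-subset to ``genes`` (those present), preserving their order."""
        wanted = [normalize_symbol(g) for g in genes]
        present = [g for g in wanted if g in self.values.index]
        return ExpressionDataset(self.dataset_id, self.species, self.values.loc[present].copy())


@dataclass
class PhenotypeTable:
    """Per-sample valve morphology (BAV/TAV) and binary comorbidity covariates."""

    table: pd.DataFrame  # columns: sample_id, cuspidity, dilation, stenosis, regurgitation

    COVARIATES = ("dilation", "stenosis", "regurgitation")

    def __post_init__(self) -> None:
        required = {"sample_id", "cuspidity", *self.COVARIATES}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("phenotype table: duplicate sample IDs")
        bad = set(self.table["cuspidity"]) - {"BAV", "TAV"}
        if bad:
            raise ValueError(f"cuspidity must be BAV or TAV, got {sorted(bad)}")
        for cov in self.COVARIATES:
            vals = set(pd.to_numeric(self.table[cov]))
            if not vals <= {0, 1}:
                raise ValueError(f"covariate {cov!r} must be binary 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def aligned_to(self, dataset: ExpressionDataset) -> "PhenotypeTable":
        """Reorder rows to the dataset's sample order; every sample must be present."""
        idx = self.table.set_index("sample_id")
        missing = [s for s in dataset.samples if s not in idx.index]
        if missing:
            raise ValueError(f"phenotype table missing samples: {missing}")
        return PhenotypeTable(idx.loc[dataset.samples].reset_index())


@dataclass
class PairedRegionTable:
    """Sample → (animal, flow region) map for the paired rat design.

    Only complete disturbed/uniform pairs enter the paired test; incomplete
    animals are reported by :meth:`complete_pairs`, never silently used.
    """

    table: pd.DataFrame  # columns: sample_id, animal_id, region

    def __post_init__(self) -> None:
        required = {"sample_id", "animal_id", "region"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"paired table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("paired table: duplicate sample IDs")
        bad = set(self.table["region"]) - {"disturbed", "uniform"}
        if bad:
            raise ValueError(f"region must be disturbed or uniform, got {sorted(bad)}")
        counts = self.table.groupby(["animal_id", "region"]).size()
        if (counts > 1).any():
            raise ValueError("paired table: an animal has >1 sample in one region")

    def complete_pairs(self) -> tuple[pd.DataFrame, list[str]]:
        """Return (pairs, incomplete_animals).

        ``pairs`` has one row per animal with both regions, columns
        ``animal_id``, ``disturbed``, ``uniform`` (the sample IDs).
        """
        wide = self.table.pivot(index="animal_id", columns="region", values="sample_id")
        for col in ("disturbed", "uniform"):
            if col not in wide.columns:
                wide[col] = np.nan
        complete = wide.dropna(subset=["disturbed", "uniform"])
        incomplete = sorted(set(wide.index) - set(complete.index))
        return complete.reset_index()[["animal_id", "disturbed", "uniform"]], incomplete


@dataclass
class OrthologMap:
    """One-to-one human↔rat symbol map (uppercase-normalized)."""

    pairs: pd.DataFrame  # columns: human_symbol, rat_symbol

    def __post_init__(self) -> None:
        df = self.pairs.copy()
        df["human_symbol"] = df["human_symbol"].map(normalize_symbol)
        df["rat_symbol"] = df["rat_symbol"].map(normalize_symbol)
        df = df.drop_duplicates()
        if df["human_symbol"].duplicated().any() or df["rat_symbol"].duplicated().any():
            raise ValueError("ortholog map is not one-to-one after normalization")
        self.pairs = df.reset_index(drop=True)

    @classmethod
    def identity(cls, genes: list[str]) -> "OrthologMap":
        syms = [normalize_symbol(g) for g in genes]
        return cls(pd.DataFrame({"human_symbol": syms, "rat_symbol": syms}))

    def translate(
        self, genes: list[str], direction: str = "human_to_rat"
    ) -> tuple[list[str], list[str]]:
        """Order-preserving translation; returns (mapped, unmapped)."""
        if direction == "human_to_rat":
            lut = dict(zip(self.pairs["human_symbol"], self.pairs["rat_symbol"]))
        elif direction == "rat_to_human":
            lut = dict(zip(self.pairs["rat_symbol"], self.pairs["human_symbol"]))
        else:
            raise ValueError("direction must be 'human_to_rat' or 'rat_to_human'")
        mapped, unmapped = [], []
        for g in genes:
            g = normalize_symbol(g)
            if g in lut:
                mapped.append(lut[g])
            else:
                unmapped.append(g)
        return mapped, unmapped


@dataclass
class QuerySet:
    """A named anchor set of established shear-responsive genes."""

    name: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = [normalize_symbol(g) for g in self.genes]
        if len(set(self.genes)) < 2:
            raise ValueError("a query set needs at least 2 distinct genes")
        self.genes = list(dict.fromkeys(self.genes))


#: Main anchor set: the five canonical shear-stress-responsive genes.
PRIMARY_QUERIES = QuerySet("primary", ["KLF2", "KLF4", "PKD2", "THBD", "TIE1"])
#: Alternate set used to check robustness of the query-gene choice.
ALTERNATE_QUERIES = QuerySet("alternate", ["NOS3", "HMOX1", "SHC1", "SIRT1"])
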