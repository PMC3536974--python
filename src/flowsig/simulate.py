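"""Synthetic datasets with planted structure for every pipeline stage.

Three generators emulate the three data worlds the pipeline consumes:

* :func:`gen_compendium` — a collection of expression datasets in which a
  module of genes (including the query set) is co-expressed through a shared
  one-factor Gaussian model in an "informative" subset of datasets and pure
  noise elsewhere.  Under the one-factor model x_g = λ·f + ε with
  f ~ N(0,1) and ε ~ N(0, σ²), two module genes correlate at λ²/(λ²+σ²),
  which gives closed-form oracles for the screening tests.
* :func:`gen_aorta` — a two-group (BAV/TAV) human-aorta-like dataset where a
  subset of module genes carries a cuspidity shift on top of independent
  binary covariate effects (dilation, stenosis, regurgitation) and noise.
* :func:`gen_paired` — a rat-like paired design: each animal contributes one
  disturbed-flow and one uniform-flow sample sharing a random animal
  intercept; a region effect is added to disturbed samples of affected
  genes, with signs set against a human truth table at a controllable
  concordance rate.

All generators are pure functions of their config (the seed included):
identical configs give identical outputs.  Truth tables record exactly what
was planted, so downstream sensitivity / false-positive rates are computable
without re-reading configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, PairedRegionTable, PhenotypeTable, normalize_symbol

__all__ = [
    "CompendiumConfig",
    "AortaConfig",
    "PairedConfig",
    "Compendium",
    "gen_compendium",
    "gen_aorta",
    "gen_paired",
    "default_gene_universe",
]


def default_gene_universe(n_genes: int = 1000, module_size: int = 20) -> tuple[list[str], list[str]]:
    """A synthetic gene universe: both query sets (primary and alternate,
    all flow-responsive so all belong to the planted module), padded module
    genes, and numbered background genes. Returns (universe, module_genes)."""
    queries = ["KLF2", "KLF4", "PKD2", "THBD", "TIE1", "NOS3", "HMOX1", "SHC1", "SIRT1"]
    module = queries + [f"MOD{i:03d}" for i in range(max(module_size - len(queries), 0))]
    background = [f"GENE{i:05d}" for i in range(n_genes - len(module))]
    return module + background, module


@dataclass
class CompendiumConfig:
    n_datasets: int = 30
    informative_fraction: float = 0.5
    samples_per_dataset: int | tuple[int, int] = (20, 60)
    n_genes: int = 1000
    module_genes: list[str] = field(default_factory=lambda: default_gene_universe()[1])
    gene_universe: list[str] | None = None
    loading: float = 0.85
    noise_sd: float | None = None  # default sqrt(1 - loading^2): unit-variance genes
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.informative_fraction <= 1.0):
            raise ValueError("informative_fraction must be in [0, 1]")
        if not (0.0 <= self.loading < 1.0):
            raise ValueError("loading must be in [0, 1)")
        if self.noise_sd is None:
            self.noise_sd = float(np.sqrt(1.0 - self.loading**2))
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.module_genes = [normalize_symbol(g) for g in self.module_genes]
        if self.gene_universe is None:
            universe, _ = default_gene_universe(self.n_genes, len(self.module_genes))
            self.gene_universe = self.module_genes + [
                g for g in universe if g not in set(self.module_genes)
            ]
            self.gene_universe = self.gene_universe[: self.n_genes]
        else:
            self.gene_universe = [normalize_symbol(g) for g in self.gene_universe]
        if not set(self.module_genes) <= set(self.gene_universe):
            raise ValueError("module_genes must be a subset of the gene universe")
        if len(self.gene_universe) != self.n_genes:
            raise ValueError("gene_universe length must equal n_genes")


@dataclass
class Compendium:
    """An ordered collection of expression datasets (the screening substrate)."""

    datasets: list[ExpressionDataset]

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)


def gen_compendium(config: CompendiumConfig) -> tuple[Compendium, pd.DataFrame]:
    """Generate a compendium with a planted co-expression module.

    Informative datasets follow the one-factor model
    ``x_g = loading·f + noise`` for module genes (background genes are pure
    noise); uninformative datasets are pure noise throughout.

    Returns the compendium and a truth table with one row per
    (dataset, informative flag) plus module membership in the attrs.
    """
    rng = np.random.default_rng(config.seed)
    module = set(config.module_genes)
    n_info = int(round(config.n_datasets * config.informative_fraction))
    species_cycle = ["human", "mouse", "rat"]
    datasets: list[ExpressionDataset] = []
    truth_rows = []
    lam = np.array([config.loading if g in module else 0.0 for g in config.gene_universe])
    for d in range(config.n_datasets):
        if isinstance(config.samples_per_dataset, int):
            n_s = config.samples_per_dataset
        else:
            lo, hi = config.samples_per_dataset
            n_s = int(rng.integers(lo, hi + 1))
        informative = d < n_info
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_s))
        if informative:
            f = rng.normal(0.0, 1.0, size=n_s)
            x = lam[:, None] * f[None, :] + noise
        else:
            x = noise
        did = f"DS{d:03d}"
        values = pd.DataFrame(
            x, index=config.gene_universe, columns=[f"{did}_S{j:03d}" for j in range(n_s)]
        )
        datasets.append(ExpressionDataset(did, species_cycle[d % 3], values))
        truth_rows.append({"dataset_id": did, "informative": informative, "n_samples": n_s})
    truth = pd.DataFrame(truth_rows)
    truth.attrs["module_genes"] = list(config.module_genes)
    return Compendium(datasets), truth


@dataclass
class AortaConfig:
    n_bav: int = 81
    n_tav: int = 46
    gene_universe: list[str] = field(default_factory=lambda: default_gene_universe()[0])
    affected_genes: list[str] = field(default_factory=list)
    effect_size: float = -0.5  # mean log2 shift in BAV for affected genes
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"dilation": 0.3, "stenosis": 0.2, "regurgitation": 0.2}
    )
    covariate_prevalence: dict[str, float] = field(
        default_factory=lambda: {"dilation": 0.5, "stenosis": 0.4, "regurgitation": 0.3}
    )
    # Optional confounding: per-covariate prevalence in the BAV group only.
    covariate_prevalence_bav: dict[str, float] | None = None
    covariate_affected_genes: list[str] | None = None  # default: the affected genes
    # Co-expression: module genes (queries included) share a latent factor, so
    # the correlation filter sees the same co-expression structure as the
    # compendium.  module_loading=0 disables it.
    module_genes: list[str] = field(default_factory=list)
    module_loading: float = 0.6
    noise_sd: float = 0.5
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bav < 2 or self.n_tav < 2:
            raise ValueError("need at least 2 samples per cuspidity group")
        self.gene_universe = [normalize_symbol(g) for g in self.gene_universe]
        self.affected_genes = [normalize_symbol(g) for g in self.affected_genes]
        self.module_genes = [normalize_symbol(g) for g in self.module_genes]
        if not set(self.module_genes) <= set(self.gene_universe):
            raise ValueError("module_genes must be in the gene universe")
        if self.effect_size != 0 and not self.affected_genes:
            raise ValueError("affected_genes must be non-empty when effect_size != 0")
        if not set(self.affected_genes) <= set(self.gene_universe):
            raise ValueError("affected_genes must be in the gene universe")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def gen_aorta(
    config: AortaConfig,
) -> tuple[ExpressionDataset, PhenotypeTable, pd.DataFrame]:
    """Generate a two-group aorta-like dataset.

    Expression = baseline + cuspidity effect (affected genes, BAV samples)
    + covariate effects (covariate-affected genes) + Gaussian noise.
    Covariates are sampled independently of cuspidity unless
    ``covariate_prevalence_bav`` introduces confounding.

    Truth table: one row per gene with the planted cuspidity effect.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_bav + config.n_tav
    genes = config.gene_universe
    n_genes = len(genes)
    sample_ids = [f"ASAP{j:03d}" for j in range(n)]
    cuspidity = np.array(["BAV"] * config.n_bav + ["TAV"] * config.n_tav)
    bav = (cuspidity == "BAV").astype(float)

    cov_cols = {}
    for cov in PhenotypeTable.COVARIATES:
        p_base = config.covariate_prevalence.get(cov, 0.0)
        if config.covariate_prevalence_bav is not None and cov in config.covariate_prevalence_bav:
            p_bav = config.covariate_prevalence_bav[cov]
            p = np.where(bav == 1.0, p_bav, p_base)
        else:
            p = np.full(n, p_base)
        cov_cols[cov] = (rng.random(n) < p).astype(int)

    x = config.baseline + rng.normal(0.0, config.noise_sd, size=(n_genes, n))
    if config.module_genes and config.module_loading > 0:
        f = rng.normal(0.0, 1.0, size=n)
        mod_idx = np.array(
            [i for i, g in enumerate(genes) if g in set(config.module_genes)], dtype=int
        )
        x[mod_idx] += config.module_loading * f[None, :]
    affected = set(config.affected_genes)
    aff_idx = np.array([i for i, g in enumerate(genes) if g in affected], dtype=int)
    if aff_idx.size:
        x[np.ix_(aff_idx, np.where(bav == 1.0)[0])] += config.effect_size
    cov_targets = (
        config.affected_genes
        if config.covariate_affected_genes is None
        else [normalize_symbol(g) for g in config.covariate_affected_genes]
    )
    cov_idx = np.array([i for i, g in enumerate(genes) if g in set(cov_targets)], dtype=int)
    for cov, beta in config.covariate_effects.items():
        if beta != 0 and cov_idx.size:
            carriers = np.where(cov_cols[cov] == 1)[0]
            if carriers.size:
                x[np.ix_(cov_idx, carriers)] += beta

    dataset = ExpressionDataset(
        "aorta_synthetic", "human", pd.DataFrame(x, index=genes, columns=sample_ids)
    )
    pheno = PhenotypeTable(
        pd.DataFrame({"sample_id": sample_ids, "cuspidity": cuspidity, **cov_cols})
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "cuspidity_effect": [config.effect_size if g in affected else 0.0 for g in genes],
        }
    )
    return dataset, pheno, truth


@dataclass
class PairedConfig:
    n_animals: int = 14
    gene_universe: list[str] = field(default_factory=lambda: default_gene_universe()[0])
    region_affected_genes: list[str] = field(default_factory=list)
    region_effect: float = -0.46  # log2 shift in disturbed-flow samples
    concordance_rate: float = 1.0
    aorta_truth: pd.DataFrame | None = None  # gene, cuspidity_effect — sets "concordant" signs
    animal_sd: float = 0.5
    noise_sd: float = 0.3
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("need at least 2 animals")
        if not (0.0 <= self.concordance_rate <= 1.0):
            raise ValueError("concordance_rate must be in [0, 1]")
        self.gene_universe = [normalize_symbol(g) for g in self.gene_universe]
        self.region_affected_genes = [normalize_symbol(g) for g in self.region_affected_genes]
        if not set(self.region_affected_genes) <= set(self.gene_universe):
            raise ValueError("region_affected_genes must be in the gene universe")
        if self.animal_sd < 0 or self.noise_sd <= 0:
            raise ValueError("animal_sd must be >=0 and noise_sd > 0")


def gen_paired(
    config: PairedConfig,
) -> tuple[ExpressionDataset, PairedRegionTable, pd.DataFrame]:
    """Generate a paired rat-like dataset (two samples per animal).

    Each animal has a random intercept ~ N(0, animal_sd²) shared by both of
    its samples; affected genes get ``region_effect`` added to the disturbed
    sample.  The sign per gene is chosen so that a ``concordance_rate``
    fraction of affected genes move in the direction of the human effect in
    ``aorta_truth`` (defaults: sign of ``region_effect`` itself).

    Truth table: gene, region_effect (signed, 0 for unaffected), concordant flag.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_universe
    n_genes = len(genes)
    n_animals = config.n_animals

    human_sign = {}
    if config.aorta_truth is not None:
        for row in config.aorta_truth.itertuples(index=False):
            if row.cuspidity_effect != 0:
                human_sign[normalize_symbol(row.gene)] = float(np.sign(row.cuspidity_effect))

    affected = config.region_affected_genes
    n_conc = int(round(len(affected) * config.concordance_rate))
    effect = np.zeros(n_genes)
    concordant = np.zeros(n_genes, dtype=bool)
    gene_pos = {g: i for i, g in enumerate(genes)}
    magnitude = abs(config.region_effect) if config.region_effect != 0 else 0.0
    default_sign = float(np.sign(config.region_effect)) if config.region_effect != 0 else 1.0
    for k, g in enumerate(affected):
        target = human_sign.get(g, default_sign)
        sign = target if k < n_conc else -target
        effect[gene_pos[g]] = sign * magnitude
        concordant[gene_pos[g]] = k < n_conc

    animal_ids = [f"RAT{a:02d}" for a in range(n_animals)]
    intercepts = rng.normal(0.0, config.animal_sd, size=n_animals)
    cols, regions, animals = [], [], []
    x = np.empty((n_genes, 2 * n_animals))
    for a, aid in enumerate(animal_ids):
        for r, region in enumerate(("disturbed", "uniform")):
            j = 2 * a + r
            x[:, j] = (
                config.baseline
                + intercepts[a]
                + rng.normal(0.0, config.noise_sd, size=n_genes)
            )
            if region == "disturbed":
                x[:, j] += effect
            cols.append(f"{aid}_{region}")
            regions.append(region)
            animals.append(aid)

    dataset = ExpressionDataset(
        "rat_synthetic", "rat", pd.DataFrame(x, index=genes, columns=cols)
    )
    pairs = PairedRegionTable(
        pd.DataFrame({"sample_id": cols, "animal_id": animals, "region": regions})
    )
    truth = pd.DataFrame({"gene": genes, "region_effect": effect, "concordant": concordant})
    return dataset, pairs, truth
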