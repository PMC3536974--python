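"""Expression screening: compendium-wide co-expression meta-analysis.

Given a set of anchor ("query") genes, each dataset in a compendium is
weighted by how strongly the queries co-express within it, every other
gene's correlation with a composite query signature is turned into a
Gaussian log-likelihood ratio on the Fisher-z scale, and evidence is
integrated across datasets as a weighted naive-Bayes posterior probability
of module membership.  Genes with posterior strictly greater than 0.5 are
selected.

The construction, in order:

1. informativeness w_d = mean over query pairs of max(Pearson r, 0);
   0 if fewer than two queries are measured.
2. signature = per-sample mean of the z-scored query profiles.
3. For each gene, c_gd = Pearson(gene, signature); z_gd = atanh(c_gd).
   Null model: Gaussian fitted to all genes' z.  Positive model: Gaussian
   fitted to leave-one-out query-vs-remaining-signature z values (with <3
   queries: mean = null mean + 2·null sd, sd = null sd).
   llr_gd = log N(z_gd | positive) − log N(z_gd | null).
4. posterior logit L_g = logit(prior) + Σ_d w_d · llr_gd over weighted
   datasets measuring g; p_g = logistic(L_g).

Datasets with weight below a small floor (default 0.05) contribute nothing.
Query genes are scored but excluded from the selected list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import ExpressionDataset, QuerySet
from .simulate import Compendium

logger = logging.getLogger(__name__)

DEFAULT_PRIOR = 0.1
DEFAULT_WEIGHT_FLOOR = 0.05
POSTERIOR_CUTOFF = 0.5

_MAX_ABS_Z = np.arctanh(1.0 - 1e-12)  # cap Fisher z for |r| -> 1


def _pairwise_complete_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over positions where both vectors are finite; NaN if <3 or constant."""
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def informativeness(dataset: ExpressionDataset, queries: QuerySet) -> float:
    """Dataset weight: clipped mean pairwise Pearson correlation among queries.

    Each pairwise correlation is clipped below at 0 before averaging, so
    anti-correlated query pairs count as no evidence rather than negative
    evidence.  Returns 0.0 if fewer than two (non-constant) queries are
    measured in the dataset.
    """
    present = [g for g in queries.genes if g in dataset.values.index]
    rows = []
    for g in present:
        v = dataset.values.loc[g].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            logger.warning(
                "dataset %s: query %s has a constant profile, excluded", dataset.dataset_id, g
            )
            continue
        rows.append(v)
    if len(rows) < 2:
        return 0.0
    corrs = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            r = _pairwise_complete_corr(rows[i], rows[j])
            if np.isfinite(r):
                corrs.append(max(r, 0.0))
    if not corrs:
        return 0.0
    return float(np.mean(corrs))


def query_signature(dataset: ExpressionDataset, queries: QuerySet) -> np.ndarray | None:
    """Composite per-sample query signature: mean of z-scored query profiles.

    Returns None (dataset uninformative) when no non-constant query is
    present or the z-scored profiles cancel to a constant vector.
    """
    present = [g for g in queries.genes if g in dataset.values.index]
    if not present:
        return None
    zs = []
    for g in present:
        v = dataset.values.loc[g].to_numpy(dtype=float)
        mu, sd = np.nanmean(v), np.nanstd(v)
        if sd == 0 or not np.isfinite(sd):
            continue
        zs.append((v - mu) / sd)
    if not zs:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN sample slots
        sig = np.nanmean(np.vstack(zs), axis=0)
    if np.nanstd(sig) == 0:
        return None
    return sig


@dataclass
class DatasetEvidence:
    """Per-dataset screening evidence retained for audit."""

    dataset_id: str
    weight: float
    signature_corr: pd.Series  # per-gene r with the signature
    llr: pd.Series  # per-gene Gaussian log-likelihood ratio at Fisher-z


def _gaussian_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi * sd**2) - (x - mu) ** 2 / (2.0 * sd**2)


def evidence_llr(
    dataset: ExpressionDataset, queries: QuerySet, min_null_sd: float = 1e-8
) -> DatasetEvidence | None:
    """Per-gene co-expression log-likelihood ratios for one dataset.

    Returns None when the dataset carries no usable evidence (weight 0,
    missing signature, or degenerate null spread).
    """
    w = informativeness(dataset, queries)
    if w <= 0.0:
        return None
    sig = query_signature(dataset, queries)
    if sig is None:
        return None

    mat = dataset.values.to_numpy(dtype=float)
    corr = np.array([_pairwise_complete_corr(mat[i], sig) for i in range(mat.shape[0])])
    corr_s = pd.Series(corr, index=dataset.values.index)

    z_all = np.arctanh(np.clip(corr, -1 + 1e-12, 1 - 1e-12))
    finite = np.isfinite(z_all)
    if finite.sum() < 3:
        return None
    null_mu = float(np.mean(z_all[finite]))
    null_sd = float(np.std(z_all[finite]))
    if null_sd <= min_null_sd:
        logger.warning("dataset %s: degenerate null spread, skipped", dataset.dataset_id)
        return None

    # Positive model: each query correlated against the signature of the others.
    present = [g for g in queries.genes if g in dataset.values.index]
    loo_z = []
    if len(present) >= 3:
        for g in present:
            rest = QuerySet("loo", [q for q in present if q != g])
            rest_sig = query_signature(dataset, rest)
            if rest_sig is None:
                continue
            r = _pairwise_complete_corr(dataset.values.loc[g].to_numpy(dtype=float), rest_sig)
            if np.isfinite(r):
                loo_z.append(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))
    if len(loo_z) >= 3:
        pos_mu = float(np.mean(loo_z))
        # Floor the positive sd at the null sd: a handful of LOO points can
        # fit an arbitrarily tight Gaussian, which would penalize genes MORE
        # correlated than the queries themselves.  With pos_sd >= null_sd the
        # LLR is non-decreasing in Fisher-z beyond the crossover.
        pos_sd = float(max(np.std(loo_z), null_sd))
    else:
        pos_mu = null_mu + 2.0 * null_sd
        pos_sd = null_sd

    z = np.clip(z_all, -_MAX_ABS_Z, _MAX_ABS_Z)
    llr = _gaussian_logpdf(z, pos_mu, pos_sd) - _gaussian_logpdf(z, null_mu, null_sd)
    llr[~finite] = np.nan  # constant/unmeasured genes carry no evidence
    # Query genes are scored like any other gene (their posterior is
    # reported for audit) but never enter the selected list.
    llr_s = pd.Series(llr, index=dataset.values.index)
    return DatasetEvidence(dataset.dataset_id, w, corr_s, llr_s)


@dataclass
class ScreeningResult:
    """Posterior co-expression probabilities and the audit trail behind them."""

    posteriors: pd.Series  # per gene, in (0, 1)
    prior: float
    selected: list[str]  # posterior > cutoff, query genes excluded
    query_genes: list[str]
    evidence: list[DatasetEvidence] = field(default_factory=list)
    n_datasets_used: pd.Series | None = None
    no_evidence_genes: list[str] = field(default_factory=list)


def integrate_posterior(
    evidence: list[DatasetEvidence],
    gene_universe: list[str],
    queries: QuerySet,
    prior: float = DEFAULT_PRIOR,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
    posterior_cutoff: float = POSTERIOR_CUTOFF,
) -> ScreeningResult:
    """Weighted naive-Bayes integration of per-dataset evidence.

    L_g = logit(prior) + Σ_d w_d·llr_gd over datasets with weight above the
    floor where gene g carries evidence; p_g = logistic(L_g).  Genes with no
    weighted evidence stay at the prior and are flagged.
    """
    if not (0.0 < prior < 1.0):
        raise ValueError("prior must be in (0, 1)")
    used = [ev for ev in evidence if ev.weight >= weight_floor]
    total = pd.Series(0.0, index=pd.Index(gene_universe))
    n_used = pd.Series(0, index=pd.Index(gene_universe))
    for ev in used:
        llr = ev.llr.reindex(gene_universe)
        ok = llr.notna()
        total[ok] += ev.weight * llr[ok]
        n_used[ok] += 1
    logit_p = logit(prior) + total
    posteriors = pd.Series(expit(logit_p.to_numpy()), index=total.index)
    no_evidence = list(n_used.index[n_used == 0])
    qset = set(queries.genes)
    selected = [
        g for g in gene_universe if posteriors[g] > posterior_cutoff and g not in qset
    ]
    return ScreeningResult(
        posteriors=posteriors,
        prior=prior,
        selected=selected,
        query_genes=list(queries.genes),
        evidence=used,
        n_datasets_used=n_used,
        no_evidence_genes=no_evidence,
    )


def screen(
    compendium: Compendium,
    queries: QuerySet,
    prior: float = DEFAULT_PRIOR,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
    posterior_cutoff: float = POSTERIOR_CUTOFF,
) -> ScreeningResult:
    """Run the full screening stage: evidence per dataset, then integration."""
    universe: list[str] = []
    seen = set()
    for ds in compendium:
        for g in ds.genes:
            if g not in seen:
                seen.add(g)
                universe.append(g)
    evidence = []
    for ds in compendium:
        ev = evidence_llr(ds, queries)
        if ev is not None:
            evidence.append(ev)
    return integrate_posterior(
        evidence, universe, queries, prior=prior, weight_floor=weight_floor,
        posterior_cutoff=posterior_cutoff,
    )


@dataclass
class OverlapReport:
    n_a: int
    n_b: int
    n_intersection: int
    jaccard: float
    containment: float  # |A ∩ B| / |B|


def robustness_overlap(result_a: ScreeningResult, result_b: ScreeningResult) -> OverlapReport:
    """Overlap between two screening runs (e.g. primary vs alternate queries).

    Containment |A∩B|/|B| is the headline number: a robust query choice puts
    (nearly) every gene of the smaller alternate-query list inside the
    primary list.  Genes used as queries in either run are excluded from
    both lists before comparison — each run omits its own anchors from its
    selected list, so they cannot be compared symmetrically.
    """
    universe_a = set(result_a.posteriors.index)
    universe_b = set(result_b.posteriors.index)
    if universe_a.isdisjoint(universe_b):
        raise ValueError("screening results cover disjoint gene universes")
    anchors = set(result_a.query_genes) | set(result_b.query_genes)
    a = set(result_a.selected) - anchors
    b = set(result_b.selected) - anchors
    inter = a & b
    union = a | b
    return OverlapReport(
        n_a=len(a),
        n_b=len(b),
        n_intersection=len(inter),
        jaccard=len(inter) / len(union) if union else 1.0,
        containment=len(inter) / len(b) if b else 1.0,
    )
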