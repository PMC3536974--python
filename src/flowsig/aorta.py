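"""Correlation filtering and covariate-adjusted differential expression.

Steps 2–3 of the pipeline: screened candidate genes are first required to
correlate (|Pearson R| > 0.40 by default) with at least one query gene in
the target-vessel dataset, then tested for association with valve
morphology (BAV vs TAV) by a per-gene ordinary-least-squares fit of log2
expression on a cuspidity indicator plus three binary clinical covariates
(dilation, stenosis, regurgitation), with Benjamini–Hochberg FDR control
across genes.  The same path run on a control vessel not exposed to
valve-dependent flow (mammary artery) serves as a negative control.

Fold changes are reported in the signed ±ratio convention: 2^β for β ≥ 0
and −2^(−β) for β < 0, so |fc| ≥ 1 always and negative means lower in BAV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionDataset, PhenotypeTable, QuerySet, normalize_symbol

logger = logging.getLogger(__name__)

R_CUTOFF = 0.40
FDR_Q = 0.05


def signed_fold_change(beta: float) -> float:
    """Map a log2 coefficient to the ±ratio convention (|fc| ≥ 1)."""
    return float(2.0**beta) if beta >= 0 else float(-(2.0 ** (-beta)))


@dataclass
class AssociationRecord:
    """Per-gene outcome of the correlation filter and the adjusted DE test."""

    gene: str
    max_abs_r: float
    best_query: str | None
    passed_corr: bool
    p_cusp: float = np.nan
    fc_signed: float = np.nan
    fdr_pass: bool = False
    error: str | None = None


def _pairwise_corr(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def corr_filter(
    dataset: ExpressionDataset,
    candidates: list[str],
    queries: QuerySet,
    r_cutoff: float = R_CUTOFF,
    use_abs: bool = True,
) -> list[AssociationRecord]:
    """Keep candidates whose best per-query Pearson correlation exceeds the cutoff.

    With ``use_abs`` (default) the magnitude |R| is compared, so strongly
    anti-correlated partners pass too; the cutoff is strict (>).  Candidates
    absent from the dataset or with a constant profile are excluded with a
    warning and do not appear in the output.
    """
    query_rows = {
        q: dataset.values.loc[q].to_numpy(dtype=float)
        for q in queries.genes
        if q in dataset.values.index
    }
    if not query_rows:
        raise ValueError("no query gene present in the target dataset")
    records: list[AssociationRecord] = []
    for gene in candidates:
        gene = normalize_symbol(gene)
        if gene not in dataset.values.index:
            logger.warning("corr_filter: %s not measured, skipped", gene)
            continue
        v = dataset.values.loc[gene].to_numpy(dtype=float)
        best_r, best_q = np.nan, None
        for q, qv in query_rows.items():
            if gene == q:
                continue
            r = _pairwise_corr(v, qv)
            if not np.isfinite(r):
                continue
            stat = abs(r) if use_abs else r
            if not np.isfinite(best_r) or stat > best_r:
                best_r, best_q = stat, q
        if not np.isfinite(best_r):
            logger.warning("corr_filter: %s has no defined correlation, excluded", gene)
            continue
        records.append(
            AssociationRecord(
                gene=gene,
                max_abs_r=best_r,
                best_query=best_q,
                passed_corr=bool(best_r > r_cutoff),
            )
        )
    return records


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the exact t transform.

    t = r·sqrt((n−2)/(1−r²)) referred to Student's t with n−2 df.
    """
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not np.isfinite(r) or abs(r) >= 1:
        raise ValueError("r must satisfy |r| < 1")
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def de_covariate(
    dataset: ExpressionDataset,
    phenotypes: PhenotypeTable,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Cuspidity association per gene, adjusted for the three binary covariates.

    For each gene, OLS of log2 expression on [1, BAV, dilation, stenosis,
    regurgitation]; ``p_cusp`` is the two-sided t-test of the BAV
    coefficient β and ``fc_signed`` its ±ratio fold change.  Samples with a
    missing expression value are dropped casewise for that gene.  A
    collinear design yields a per-gene error record, not an exception.

    Returns a DataFrame indexed by gene with columns
    ``beta, se, p_cusp, fc_signed, n_used, error``.
    """
    pheno = phenotypes.aligned_to(dataset)
    t = pheno.table
    if set(t["cuspidity"]) != {"BAV", "TAV"}:
        raise ValueError("both cuspidity levels must be present")
    bav = (t["cuspidity"] == "BAV").to_numpy(dtype=float)
    covs = {c: t[c].to_numpy(dtype=float) for c in PhenotypeTable.COVARIATES}

    def build_design(mask: np.ndarray) -> np.ndarray | None:
        """Design for the retained samples; constant covariate columns are
        dropped (they carry no information), cuspidity always at column 1.
        Returns None when the cuspidity contrast is unidentifiable."""
        b = bav[mask]
        if b.min() == b.max():
            return None
        cols = [np.ones(mask.sum()), b]
        for c in PhenotypeTable.COVARIATES:
            v = covs[c][mask]
            if v.min() != v.max():
                cols.append(v)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            return None
        return X

    if genes is None:
        genes = dataset.genes
    genes = [normalize_symbol(g) for g in genes]
    Y = dataset.values.reindex(genes).to_numpy(dtype=float)
    complete = np.isfinite(Y).all(axis=1)
    rows = []

    def fit(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float, str | None]:
        n, p_cols = X.shape
        if n <= p_cols:
            return np.nan, np.nan, np.nan, "underdetermined design"
        XtX_inv = np.linalg.inv(X.T @ X)
        b = XtX_inv @ X.T @ y
        resid = y - X @ b
        s2 = resid @ resid / (n - p_cols)
        se = float(np.sqrt(s2 * XtX_inv[1, 1]))
        if se > 0:
            p = float(2.0 * stats.t.sf(abs(b[1] / se), df=n - p_cols))
        else:
            p = 1.0 if b[1] == 0 else 0.0
        return float(b[1]), se, p, None

    all_mask = np.ones(Y.shape[1], dtype=bool)
    X_full = build_design(all_mask)
    if complete.all():
        if X_full is None:
            for g in genes:
                rows.append((g, np.nan, np.nan, np.nan, 0, "collinear design"))
        else:
            # one solve for all genes at once
            n, p_cols = X_full.shape
            XtX_inv = np.linalg.inv(X_full.T @ X_full)
            B = XtX_inv @ X_full.T @ Y.T
            resid = Y.T - X_full @ B
            s2 = (resid**2).sum(axis=0) / (n - p_cols)
            se = np.sqrt(s2 * XtX_inv[1, 1])
            beta = B[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = np.where(se > 0, np.abs(beta) / np.where(se > 0, se, 1.0), np.inf)
            p = 2.0 * stats.t.sf(tstat, df=n - p_cols)
            p = np.where(se > 0, p, np.where(beta == 0, 1.0, 0.0))
            for i, g in enumerate(genes):
                rows.append((g, beta[i], se[i], p[i], n, None))
    else:
        for i, g in enumerate(genes):
            mask = np.isfinite(Y[i])
            n_used = int(mask.sum())
            if n_used < 3:
                rows.append((g, np.nan, np.nan, np.nan, n_used, "too few samples"))
                continue
            logger.info("gene %s: %d missing values dropped casewise", g, int((~mask).sum()))
            X = X_full if mask.all() else build_design(mask)
            if X is None:
                rows.append((g, np.nan, np.nan, np.nan, n_used, "collinear design"))
                continue
            b, s, p, err = fit(Y[i][mask], X)
            rows.append((g, b, s, p, n_used, err))

    out = pd.DataFrame(
        rows, columns=["gene", "beta", "se", "p_cusp", "n_used", "error"]
    ).set_index("gene")
    out["fc_signed"] = [
        signed_fold_change(b) if np.isfinite(b) else np.nan for b in out["beta"]
    ]
    return out[["beta", "se", "p_cusp", "fc_signed", "n_used", "error"]]


def bh_select(pvalues: pd.Series | np.ndarray, q: float = FDR_Q) -> tuple[set, float]:
    """Benjamini–Hochberg step-up selection.

    Returns (rejected gene/index set, realized threshold = largest rejected
    p, 0.0 if none).  NaN p-values are never rejected.
    """
    if isinstance(pvalues, pd.Series):
        names = pvalues.index.to_numpy()
        p = pvalues.to_numpy(dtype=float)
    else:
        p = np.asarray(pvalues, dtype=float)
        names = np.arange(len(p))
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return set(), 0.0
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    rejected = np.zeros(len(p), dtype=bool)
    rejected[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    if not rejected.any():
        return set(), 0.0
    threshold = float(p[rejected].max())
    return set(names[rejected]), threshold


@dataclass
class ControlReport:
    """Stage-by-stage accounting of the negative-control (mammary) path."""

    n_screened: int
    n_corr_passed: int
    n_fdr_rejected: int
    realized_threshold: float
    rejected_genes: list[str]

    @property
    def is_clean(self) -> bool:
        return self.n_fdr_rejected == 0


def negative_control(
    dataset: ExpressionDataset,
    phenotypes: PhenotypeTable,
    screened_genes: list[str],
    queries: QuerySet,
    r_cutoff: float = R_CUTOFF,
    q: float = FDR_Q,
) -> ControlReport:
    """Run filter → adjusted DE → BH on a control vessel and report the funnel.

    On a vessel shielded from valve-dependent flow the final rejected set is
    expected to be empty; the report states it either way.
    """
    if not screened_genes:
        return ControlReport(0, 0, 0, 0.0, [])
    records = corr_filter(dataset, screened_genes, queries, r_cutoff=r_cutoff)
    passed = [r.gene for r in records if r.passed_corr]
    if not passed:
        return ControlReport(len(screened_genes), 0, 0, 0.0, [])
    de = de_covariate(dataset, phenotypes, passed)
    usable = de[de["error"].isna()]
    rejected, thr = bh_select(usable["p_cusp"], q=q)
    return ControlReport(
        n_screened=len(screened_genes),
        n_corr_passed=len(passed),
        n_fdr_rejected=len(rejected),
        realized_threshold=thr,
        rejected_genes=sorted(rejected),
    )
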