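"""End-to-end orchestration: simulate → screen → filter → DE → paired test →
concordance → report.

Stages communicate through TSV files in the run directory so each stage is
independently inspectable and re-runnable; a :class:`RunManifest` records
the config snapshot, per-stage output checksums and gene counts, making a
run auditable and exactly reproducible (same config + seed → byte-identical
outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aorta import bh_select, corr_filter, de_covariate, negative_control
from .datatypes import OrthologMap, QuerySet, PRIMARY_QUERIES, ALTERNATE_QUERIES
from .io import (
    load_table1,
    write_expression,
    write_paired_regions,
    write_phenotypes,
)
from .screening import robustness_overlap, screen
from .simulate import (
    AortaConfig,
    CompendiumConfig,
    PairedConfig,
    gen_aorta,
    gen_compendium,
    gen_paired,
)
from .validation import concordance, paired_region_test, table1_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single config for a full synthetic run.

    Cutoffs default to the pipeline's canonical values: screening posterior
    0.5, correlation 0.40, FDR q 0.05, screening prior 0.1.
    """

    out_dir: str | Path = "pipeline_run"
    seed: int = 0
    prior: float = 0.1
    posterior_cutoff: float = 0.5
    r_cutoff: float = 0.40
    q: float = 0.05
    n_affected: int = 10  # module genes carrying the cuspidity effect
    effect_size: float = -0.7  # log2 shift in BAV; |fc| 1.62, inside the observed range
    region_effect: float = -0.46
    concordance_rate: float = 0.8
    run_robustness: bool = False
    run_control: bool = True
    compendium: CompendiumConfig | None = None
    queries: QuerySet = field(default_factory=lambda: PRIMARY_QUERIES)
    alt_queries: QuerySet = field(default_factory=lambda: ALTERNATE_QUERIES)

    def __post_init__(self) -> None:
        for name, v, lo, hi in [
            ("prior", self.prior, 0.0, 1.0),
            ("posterior_cutoff", self.posterior_cutoff, 0.0, 1.0),
            ("r_cutoff", self.r_cutoff, 0.0, 1.0),
            ("q", self.q, 0.0, 1.0),
        ]:
            if not (lo < v < hi):
                raise ValueError(f"{name} must be in ({lo}, {hi})")


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, checksums, stage gene counts."""

    config: dict
    version: str
    stage_counts: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "stage_counts": self.stage_counts,
                "checksums": self.checksums,
                "summaries": self.summaries,
            },
            indent=2,
            sort_keys=True,
            default=str,
        ))


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a flat YAML key-value file.

    Keys mirror the dataclass fields; a nested ``compendium:`` mapping
    builds the :class:`~flowsig.simulate.CompendiumConfig`. Unknown keys
    are rejected so typos do not silently fall back to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of config keys")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "compendium" in raw and raw["compendium"] is not None:
        raw["compendium"] = CompendiumConfig(**raw["compendium"])
    if "queries" in raw:
        raw["queries"] = QuerySet("primary", raw["queries"])
    if "alt_queries" in raw:
        raw["alt_queries"] = QuerySet("alternate", raw["alt_queries"])
    return PipelineConfig(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    snap["out_dir"] = str(snap["out_dir"])
    return snap


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage on synthetic data and return the manifest.

    The planted world: a compendium where the query genes sit inside a
    co-expressed module, an aorta-like cohort where ``n_affected`` module
    genes carry a cuspidity effect, an (optional) null control vessel, and
    a paired rat-like cohort where the same genes carry a flow-region effect
    whose sign agrees with the human effect at ``concordance_rate``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_snapshot(config), version=__version__)
    counts = manifest.stage_counts

    # --- simulate -----------------------------------------------------------
    comp_cfg = config.compendium or CompendiumConfig(seed=config.seed)
    compendium, comp_truth = gen_compendium(comp_cfg)
    module = comp_truth.attrs["module_genes"]
    affected = [g for g in module if g not in set(config.queries.genes)][: config.n_affected]
    aorta_cfg = AortaConfig(
        gene_universe=comp_cfg.gene_universe,
        affected_genes=affected,
        effect_size=config.effect_size,
        module_genes=module,
        seed=config.seed + 1,
    )
    aorta_ds, pheno, aorta_truth = gen_aorta(aorta_cfg)
    paired_cfg = PairedConfig(
        gene_universe=comp_cfg.gene_universe,
        region_affected_genes=affected,
        region_effect=config.region_effect,
        concordance_rate=config.concordance_rate,
        aorta_truth=aorta_truth,
        seed=config.seed + 2,
    )
    rat_ds, rat_pairs, rat_truth = gen_paired(paired_cfg)
    write_expression(aorta_ds, out / "aorta.tsv")
    write_phenotypes(pheno, out / "phenotypes.tsv")
    write_expression(rat_ds, out / "rat.tsv")
    write_paired_regions(rat_pairs, out / "rat_pairs.tsv")
    counts["universe"] = comp_cfg.n_genes
    counts["module"] = len(module)
    logger.info("simulate: %d datasets, %d genes", len(compendium), comp_cfg.n_genes)

    # --- step 1: screening --------------------------------------------------
    screening_result = screen(
        compendium, config.queries, prior=config.prior,
        posterior_cutoff=config.posterior_cutoff,
    )
    sel = screening_result.selected
    pd.DataFrame(
        {
            "gene": screening_result.posteriors.index,
            "posterior": screening_result.posteriors.to_numpy(),
            "n_datasets": screening_result.n_datasets_used.to_numpy(),
            "selected": [g in set(sel) for g in screening_result.posteriors.index],
        }
    ).to_csv(out / "screening.tsv", sep="\t", index=False)
    counts["screened"] = len(sel)
    logger.info("screen: %d genes at posterior > %.2f", len(sel), config.posterior_cutoff)

    if config.run_robustness:
        alt = screen(compendium, config.alt_queries, prior=config.prior)
        ov = robustness_overlap(screening_result, alt)
        manifest.summaries["robustness"] = asdict(ov)
        logger.info("robustness: containment %.2f", ov.containment)

    # --- step 2: correlation filter ----------------------------------------
    records = corr_filter(aorta_ds, sel, config.queries, r_cutoff=config.r_cutoff)
    passed = [r.gene for r in records if r.passed_corr]
    pd.DataFrame([asdict(r) for r in records]).to_csv(
        out / "corr_filter.tsv", sep="\t", index=False
    )
    counts["corr_passed"] = len(passed)
    logger.info("filter: %d of %d pass |R| > %.2f", len(passed), len(sel), config.r_cutoff)

    # --- step 3: covariate-adjusted DE -------------------------------------
    if passed:
        de = de_covariate(aorta_ds, pheno, passed)
        usable = de[de["error"].isna()]
        rejected, thr = bh_select(usable["p_cusp"], q=config.q)
        de = de.assign(fdr_pass=[g in rejected for g in de.index])
        de.to_csv(out / "de.tsv", sep="\t")
        de_genes = [g for g in de.index if g in rejected]
    else:
        de = pd.DataFrame()
        de_genes, thr = [], 0.0
    counts["de_significant"] = len(de_genes)
    manifest.summaries["de_realized_threshold"] = thr
    logger.info("de: %d genes at FDR %.2f (threshold %.3g)", len(de_genes), config.q, thr)

    # --- negative control ---------------------------------------------------
    if config.run_control:
        # Control vessel: same co-expression structure, no cuspidity effect.
        ctrl_cfg = AortaConfig(
            gene_universe=comp_cfg.gene_universe,
            affected_genes=affected,
            effect_size=0.0,
            module_genes=module,
            seed=config.seed + 3,
        )
        ctrl_ds, ctrl_pheno, _ = gen_aorta(ctrl_cfg)
        ctrl = negative_control(
            ctrl_ds, ctrl_pheno, sel, config.queries, r_cutoff=config.r_cutoff, q=config.q
        )
        manifest.summaries["negative_control"] = asdict(ctrl)
        counts["control_rejected"] = ctrl.n_fdr_rejected
        logger.info("control: %d genes rejected (expect 0)", ctrl.n_fdr_rejected)

    # --- step 4: rat paired test + concordance -----------------------------
    if de_genes:
        rat_frame = paired_region_test(rat_ds, rat_pairs, de_genes)
        rat_frame.to_csv(out / "rat_test.tsv", sep="\t")
        human_records = [r for r in records if r.gene in set(de_genes)]
        for r in human_records:
            r.p_cusp = float(de.loc[r.gene, "p_cusp"])
            r.fc_signed = float(de.loc[r.gene, "fc_signed"])
            r.fdr_pass = True
        report_c = concordance(
            human_records,
            rat_frame.rename(columns={"rat_fc_signed": "rat_fc_signed"}),
            OrthologMap.identity(list(rat_frame.index)),
            q=config.q,
        )
        manifest.summaries["concordance"] = {
            "n_de": report_c.n_de,
            "n_on_platform": report_c.n_on_platform,
            "n_rat_sig": report_c.n_rat_sig,
            "n_concordant": report_c.n_concordant,
            "pct_rat_sig": report_c.pct_rat_sig,
            "pct_concordant": report_c.pct_concordant,
        }
        counts["rat_significant"] = report_c.n_rat_sig
        counts["concordant"] = report_c.n_concordant
        logger.info(
            "flowtest: %d/%d rat-significant, %d concordant",
            report_c.n_rat_sig, report_c.n_de, report_c.n_concordant,
        )
    else:
        counts["rat_significant"] = 0
        counts["concordant"] = 0

    # truth tables for audit
    comp_truth.to_csv(out / "truth_compendium.tsv", sep="\t", index=False)
    aorta_truth.to_csv(out / "truth_aorta.tsv", sep="\t", index=False)
    rat_truth.to_csv(out / "truth_rat.tsv", sep="\t", index=False)

    for f in sorted(out.glob("*.tsv")):
        manifest.checksums[f.name] = _checksum(f)
    manifest.save(out / "manifest.json")
    return manifest


def report(manifest: RunManifest, include_table1: bool = False) -> str:
    """Render a manifest as a human-readable funnel report (pure: same
    manifest → same text)."""
    lines = ["flow-signature pipeline report", "=" * 31]
    counts = manifest.stage_counts
    funnel = [
        ("gene universe", counts.get("universe")),
        ("planted module", counts.get("module")),
        ("screened (posterior)", counts.get("screened")),
        ("correlation-passed", counts.get("corr_passed")),
        ("DE-significant (FDR)", counts.get("de_significant")),
        ("rat-significant", counts.get("rat_significant")),
        ("direction-concordant", counts.get("concordant")),
    ]
    for label, v in funnel:
        if v is not None:
            lines.append(f"{label:>22}: {v}")
    if counts.get("de_significant") == 0:
        lines.append("no genes passed the differential-expression filter")
    conc = manifest.summaries.get("concordance")
    if conc:
        lines.append(
            f"concordance: {conc['n_concordant']}/{conc['n_rat_sig']} rat-significant genes "
            f"({conc['pct_concordant']}%) move with the human effect"
        )
    ctrl = manifest.summaries.get("negative_control")
    if ctrl is not None:
        state = "clean (no genes passed)" if ctrl["n_fdr_rejected"] == 0 else (
            f"{ctrl['n_fdr_rejected']} genes rejected"
        )
        lines.append(f"negative control: {state}")
    rob = manifest.summaries.get("robustness")
    if rob:
        lines.append(
            f"robustness: alternate queries select {rob['n_b']} genes, "
            f"containment {rob['containment']:.2f} in the primary list"
        )
    if include_table1:
        s = table1_summary(load_table1())
        lines += [
            "",
            "packaged cross-species results table",
            "-" * 36,
            f"  human BAV-vs-TAV DE genes : {s.n_total}",
            f"  on rat platform           : {s.n_on_platform}",
            f"  rat-significant (p<0.031) : {s.n_rat_sig} ({s.pct_rat_sig}%)",
            f"  direction-concordant      : {s.n_concordant} ({s.pct_concordant}%)",
            f"  flow-cited in literature  : {s.n_flow_cited} ({s.pct_flow_cited}%)",
            f"  strongest human signal    : {s.min_p_gene} (p = {s.min_p:.3g})",
        ]
    return "\n".join(lines) + "\n"
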