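"""End-to-end driver: QC -> expression filter -> eGWAS -> ASE -> networks.

The driver accepts either file paths through a :class:`PipelineConfig`
or in-memory objects (as produced by :func:`bloodeqtl.simulate_cohort`),
executes every stage with the configured thresholds, writes provenance-
stamped TSV outputs, and logs per-stage record counts in the style of a
results section: SNPs passing QC, probes analyzed, significant
associations, eQTL-SNPs with their local/distant split, ASE-SNPs,
ASE genes, and the eGWAS x ASE overlap.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import egwas as egwas_mod
from . import io as io_mod
from . import networks as net_mod
from .io import PipelineConfig
from .preprocess import ExpressionMatrix
from .qc import GenotypeMatrix, compute_genomic_kinship, filter_variants_and_samples

logger = logging.getLogger("bloodeqtl")

__all__ = ["run_pipeline", "run_pipeline_from_data"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis from files named in the config."""
    config.require("genotypes", "expression", "covariates")
    geno = io_mod.read_genotypes(config.genotypes, config.genotypes + ".map")
    expr = io_mod.read_expression(
        config.expression, config.expression + ".annotation"
    )
    covars = io_mod.read_tsv(config.covariates, index_col="sample")
    data = {"genotypes": geno, "expression": expr, "covariates": covars}
    if config.allele_counts:
        data["allele_counts"] = io_mod.read_allele_counts(config.allele_counts)
    if config.gene_intervals:
        data["gene_intervals"] = io_mod.read_gene_intervals(config.gene_intervals)
    return run_pipeline_from_data(data, config)


def run_pipeline_from_data(data: dict, config: PipelineConfig | None = None) -> dict:
    """Run the analysis on in-memory inputs.

    ``data`` must hold ``genotypes`` (GenotypeMatrix), ``expression``
    (ExpressionMatrix) and ``covariates`` (DataFrame); optionally
    ``allele_counts`` and ``gene_intervals`` (or an ``architecture``
    carrying the intervals) for the ASE branch.  Outputs are written
    under ``config.output_dir``; the returned bundle holds every
    intermediate table plus a ``counts`` summary.
    """
    config = config or PipelineConfig()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int | float] = {}

    geno_qc, qc_report, K = _stage("qc")(_run_qc)(data["genotypes"], config)
    counts["snps_pass_qc"] = geno_qc.n_snps
    counts["samples_pass_qc"] = geno_qc.n_samples
    io_mod.write_tsv(qc_report, outdir / "qc_report.tsv", config)
    io_mod.write_kinship(K, outdir / "kinship.tsv", config)

    expr = _stage("preprocess")(_select_expressed)(data["expression"], geno_qc)
    counts["probes_analyzed"] = expr.values.shape[1]

    egwas_out = _stage("egwas")(_run_egwas)(expr, geno_qc, data["covariates"], K, config)
    counts.update(egwas_out["counts"])
    io_mod.write_tsv(
        egwas_out["records"][egwas_out["records"]["is_significant"]],
        outdir / "associations.tsv", config,
    )
    io_mod.write_tsv(egwas_out["eqtl"], outdir / "eqtl_snps.tsv", config)
    io_mod.write_tsv(egwas_out["enrichment"], outdir / "enrichment.tsv", config)

    bundle = {
        "qc_report": qc_report, "kinship": K, "expression": expr,
        "records": egwas_out["records"], "thresholds": egwas_out["thresholds"],
        "eqtl": egwas_out["eqtl"], "enrichment": egwas_out["enrichment"],
    }

    if not egwas_out["eqtl"].empty:
        net_out = _stage("network")(_run_network)(egwas_out["eqtl"], expr, config, outdir)
        bundle.update(net_out)
        counts["network_components_ge3"] = net_out["component_summary"][
            "n_components_min_size"
        ]
        counts["master_regulators"] = len(net_out["masters"])

    counts_ase = {}
    if "allele_counts" in data:
        ase_out = _stage("ase")(_run_ase)(data, egwas_out, expr, config, outdir)
        bundle.update(ase_out)
        counts_ase = ase_out["ase_counts"]
    counts.update(counts_ase)
    bundle["counts"] = counts
    for key, value in counts.items():
        logger.info("%s: %s", key, value)
    return bundle


def _run_qc(geno: GenotypeMatrix, config: PipelineConfig):
    geno_qc, report = filter_variants_and_samples(
        geno, config.min_call_rate, config.min_maf, config.hwe_fdr
    )
    K = compute_genomic_kinship(geno_qc)
    return geno_qc, report, K


def _select_expressed(expr: ExpressionMatrix, geno_qc: GenotypeMatrix):
    """Drop negative-control probes and align samples to the QC'ed cohort."""
    ann = expr.probe_annotation
    if "probe_class" in ann.columns:
        keep = ann.index[ann["probe_class"] == "experimental"]
    else:
        keep = ann.index[ann["chromosome"].notna()]
    samples = [s for s in expr.values.index if s in set(geno_qc.dosages.index)]
    return ExpressionMatrix(
        values=expr.values.loc[samples, keep], probe_annotation=ann.loc[keep]
    )


def _run_egwas(expr, geno_qc, covars, K, config: PipelineConfig):
    covars = covars.loc[expr.values.index]
    records = egwas_mod.run_egwas(expr, geno_qc, covars, K)
    records, thresholds = egwas_mod.two_level_fdr(
        records, config.alpha_probe, config.alpha_global
    )
    sig = records[records["is_significant"]]
    eqtl = egwas_mod.prune_to_eqtl_snps(
        sig, geno_qc, expr, covars, K, thresholds, config.prune_window_bp
    )
    eqtl = egwas_mod.classify_local_distant(
        eqtl, expr.probe_annotation, config.local_window_bp
    )
    if not eqtl.empty:
        sds = expr.values.std(ddof=1)
        eqtl["effect_sd_ratio"] = [
            abs(b) / sds[p] if sds[p] > 0 else np.nan
            for b, p in zip(eqtl["beta_lead"], eqtl["probe_id"])
        ]
        summary = egwas_mod.snp_regulation_summary(eqtl)
        enrichment = egwas_mod.chromosome_enrichment(
            summary.index, geno_qc.dosages.columns,
            geno_qc.snp_map["chromosome"], class_of=summary,
        )
    else:
        summary = pd.Series(dtype=object)
        enrichment = pd.DataFrame()
    n_local = int((summary == "local").sum())
    n_distant = int((summary == "distant").sum())
    n_both = int((summary == "both").sum())
    counts = {
        "associations_tested": int(records["p_value"].notna().sum()),
        "significant_associations": int(records["is_significant"].sum()),
        "eqtl_associations": len(eqtl),
        "eqtl_snps": int(eqtl["lead_snp_id"].nunique()) if not eqtl.empty else 0,
        "local_eqtl_snps": n_local + n_both,
        "distant_eqtl_snps": n_distant + n_both,
        "both_eqtl_snps": n_both,
        "median_effect_sd_ratio": (
            float(eqtl["effect_sd_ratio"].median()) if not eqtl.empty else float("nan")
        ),
    }
    return {"records": records, "thresholds": thresholds, "eqtl": eqtl,
            "snp_summary": summary, "enrichment": enrichment, "counts": counts}


def _run_network(eqtl, expr, config: PipelineConfig, outdir: Path):
    network = net_mod.build_association_graph(eqtl, expr.probe_annotation)
    summary = net_mod.component_summary(network)
    masters = net_mod.find_master_regulators(network, config.master_min_targets)
    net_mod.export_network(network, outdir / "network.sif", fmt="sif")
    net_mod.export_network(network, outdir / "edges.tsv", fmt="tsv")
    io_mod.write_tsv(masters, outdir / "masters.tsv", config)
    return {"network": network, "component_summary": summary, "masters": masters}


def _run_ase(data, egwas_out, expr, config: PipelineConfig, outdir: Path):
    counts_table = data["allele_counts"]
    result = ase_mod.call_ase(
        counts_table,
        min_reads_per_sample=config.ase_min_reads,
        min_minor_allele_count=config.ase_min_mac,
        alpha=config.ase_alpha,
        het_fraction=config.ase_het_fraction,
    )
    calls = result["calls"]
    intervals = data.get("gene_intervals")
    if intervals is None and data.get("architecture") is not None:
        intervals = data["architecture"].gene_intervals
    ase_counts = {
        "ase_snps": int(calls["is_ase_snp"].sum()) if not calls.empty else 0,
        "ase_sites_tested": len(calls),
    }
    out = {"ase_calls": calls, "ase_registry": result["registry"],
           "ase_tested": result["tested"]}
    io_mod.write_tsv(calls, outdir / "ase_snps.tsv", config)
    if not calls.empty:
        io_mod.write_vcf_sites(calls, outdir / "ase_sites.vcf", config)
    if intervals is not None and not calls.empty:
        assignments, ase_genes, universe = ase_mod.map_sites_to_genes(
            calls, intervals, gene_read_counts=_gene_read_support(counts_table, intervals),
            min_gene_reads=config.ase_min_reads,
        )
        ase_counts["ase_genes"] = len(ase_genes)
        ase_counts["detectable_genes"] = len(universe)
        io_mod.write_tsv(ase_genes, outdir / "ase_genes.tsv", config)
        io_mod.write_tsv(
            pd.DataFrame({"gene": universe}), outdir / "universe.tsv", config
        )
        out.update({"ase_site_genes": assignments, "ase_genes": ase_genes,
                    "ase_universe": universe})
        eqtl = egwas_out["eqtl"]
        if not eqtl.empty:
            eqtl_genes = _eqtl_gene_table(eqtl, expr.probe_annotation)
            integration, int_counts = ase_mod.integrate_egwas_ase(
                eqtl_genes, ase_genes,
                gene_chromosome=_gene_chromosomes(intervals),
            )
            io_mod.write_tsv(integration, outdir / "egwas_ase_overlap.tsv", config)
            out["integration"] = integration
            ase_counts["overlap_genes"] = int_counts.get("overlap", 0)
            ase_counts["cis_validated_genes"] = int_counts.get("cis_validated", 0)
    out["ase_counts"] = ase_counts
    return out


def _gene_read_support(counts_table: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """Max single-sample read depth per gene over the sites it contains."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for _, row in intervals.iterrows():
        trees.setdefault(str(row["contig"]), IntervalTree()).addi(
            int(row["start"]), int(row["end"]) + 1, row["gene"]
        )
    support: dict[str, int] = {}
    totals = counts_table["refCount"] + counts_table["altCount"]
    for (contig, position), depth in (
        totals.groupby([counts_table["contig"].astype(str), counts_table["position"]])
        .max().items()
    ):
        tree = trees.get(contig)
        if tree is None:
            continue
        for iv in tree[int(position)]:
            support[iv.data] = max(support.get(iv.data, 0), int(depth))
    return pd.Series(support, dtype=float)


def _gene_chromosomes(intervals: pd.DataFrame) -> pd.Series:
    return intervals.drop_duplicates("gene").set_index("gene")["contig"].astype(str)


def _eqtl_gene_table(eqtl: pd.DataFrame, probe_annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse eQTL associations to genes with a per-gene class label."""
    tab = eqtl.copy()
    tab["gene"] = tab["probe_id"].map(probe_annotation["gene_symbol"])
    tab = tab.dropna(subset=["gene"])
    rows = []
    for gene, grp in tab.groupby("gene"):
        classes = set(grp["regulation_class"].dropna())
        if classes == {"local"}:
            cls = "local"
        elif classes == {"distant"}:
            cls = "distant"
        elif classes:
            cls = "both"
        else:
            continue
        distant_rows = grp[grp["regulation_class"] == "distant"]
        rows.append(
            {"gene": gene, "regulation_class": cls,
             "eqtl_chromosome": (
                 distant_rows["chromosome"].iloc[0] if len(distant_rows) else
                 grp["chromosome"].iloc[0]
             )}
        )
    return pd.DataFrame(rows, columns=["gene", "regulation_class", "eqtl_chromosome"])
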