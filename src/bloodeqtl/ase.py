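"""Allele-specific expression calling from per-sample allele counts.

Input is an ASEReadCounter-style table (sample, contig, position, ref,
alt, refCount, altCount, genotype).  The caller filters sample x site
entries below a read-depth floor, drops sites with insufficient cohort
minor-allele support or more than one alt allele, tests each
heterozygous entry with an exact two-sided binomial test against a 0.5
allele fraction, corrects per animal by Benjamini-Hochberg FDR, and
declares a site an ASE-SNP when significant imbalance is seen in more
than one-third of its heterozygous animals.  Sites are then mapped to
overlapping genes and intersected with eGWAS eQTL classes.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_sites",
    "binomial_ase_test",
    "per_animal_fdr",
    "aggregate_ase",
    "call_ase",
    "map_sites_to_genes",
    "integrate_egwas_ase",
]

SITE_KEY = ["contig", "position"]


def filter_sites(
    counts: pd.DataFrame,
    min_reads_per_sample: int = 10,
    min_minor_allele_count: int = 3,
    mac_scope: str = "cohort",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply read-depth, minor-allele-count and biallelic site filters.

    Entry-level: sample x site rows with fewer than
    ``min_reads_per_sample`` total reads are dropped.  Site-level (after
    the entry filter): sites whose cohort-wide minor-allele read count
    is not strictly greater than ``min_minor_allele_count`` are dropped
    (``mac_scope="sample"`` instead requires some single sample to carry
    that many minor-allele reads), as are sites observed with more than
    one alt (or ref) allele.  Returns the filtered table and a registry
    of exclusions with reasons.
    """
    registry_rows = []
    total = counts["refCount"] + counts["altCount"]
    shallow = total < min_reads_per_sample
    for _, row in counts.loc[shallow].iterrows():
        registry_rows.append(
            {"contig": row["contig"], "position": row["position"],
             "sample": row["sample"], "reason": "low_reads",
             "detail": f"{int(row['refCount'] + row['altCount'])} reads"}
        )
    kept = counts.loc[~shallow].copy()

    site_groups = kept.groupby(SITE_KEY, sort=False)
    drop_sites: set[tuple] = set()
    for site, grp in site_groups:
        if grp["ref"].nunique() > 1 or grp["alt"].nunique() > 1:
            drop_sites.add(site)
            registry_rows.append(
                {"contig": site[0], "position": site[1], "sample": pd.NA,
                 "reason": "not_biallelic",
                 "detail": f"ref={sorted(grp['ref'].unique())} alt={sorted(grp['alt'].unique())}"}
            )
            continue
        ref_total = int(grp["refCount"].sum())
        alt_total = int(grp["altCount"].sum())
        if mac_scope == "cohort":
            mac = min(ref_total, alt_total)
        elif mac_scope == "sample":
            mac = int(np.minimum(grp["refCount"], grp["altCount"]).max())
        else:
            raise ValueError(f"unknown mac_scope {mac_scope!r}")
        if not mac > min_minor_allele_count:
            drop_sites.add(site)
            registry_rows.append(
                {"contig": site[0], "position": site[1], "sample": pd.NA,
                 "reason": "low_mac", "detail": f"minor allele count {mac}"}
            )
    if drop_sites:
        key = pd.MultiIndex.from_frame(kept[SITE_KEY])
        kept = kept.loc[~key.isin(drop_sites)]
    registry = pd.DataFrame(
        registry_rows, columns=["contig", "position", "sample", "reason", "detail"]
    )
    return kept.reset_index(drop=True), registry


@lru_cache(maxsize=200_000)
def _binom_two_sided(k: int, n: int) -> float:
    return stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue


def binomial_ase_test(ref_count: int, alt_count: int) -> float:
    """Exact two-sided binomial test of allelic balance.

    Tests alt_count ~ Binomial(ref + alt, 0.5), two-sided in the
    "minlike" sense: the p-value sums the probabilities of all outcomes
    no more likely than the observed one.  Symmetric in its arguments.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    n = ref_count + alt_count
    if n < 1:
        raise ValueError("at least one read required")
    return _binom_two_sided(min(ref_count, alt_count), n)


def per_animal_fdr(
    pvalues: pd.Series, alpha: float = 5e-2
) -> tuple[pd.Series, pd.Series]:
    """BH step-up over one animal's tested sites; flag q <= alpha."""
    if len(pvalues) == 0:
        empty = pd.Series(dtype=float, index=pvalues.index)
        return empty, empty.astype(bool)
    _, q, _, _ = multipletests(pvalues.to_numpy(), method="fdr_bh")
    q = pd.Series(q, index=pvalues.index, name="q_value")
    return q, q <= alpha


def aggregate_ase(
    tested: pd.DataFrame,
    het_fraction: float = 1.0 / 3.0,
    strict: bool = True,
) -> pd.DataFrame:
    """Cross-animal aggregation of per-animal significance flags.

    ``tested`` needs columns contig, position, ref, alt, sample,
    p_value, q_value, significant — one row per heterozygous sample x
    site that survived filtering.  A site is an ASE-SNP when the
    fraction of significant heterozygous animals exceeds
    ``het_fraction`` (strictly by default).  Sites with no heterozygous
    animals are untestable and absent from the output.
    """
    rows = []
    for (contig, position), grp in tested.groupby(SITE_KEY, sort=False):
        n_het = len(grp)
        n_sig = int(grp["significant"].sum())
        frac = n_sig / n_het
        is_ase = frac > het_fraction if strict else frac >= het_fraction
        rows.append(
            {"contig": contig, "position": position,
             "ref": grp["ref"].iloc[0], "alt": grp["alt"].iloc[0],
             "n_het_animals": n_het, "n_significant_animals": n_sig,
             "significant_fraction": frac, "is_ase_snp": bool(is_ase)}
        )
    return pd.DataFrame(
        rows, columns=["contig", "position", "ref", "alt", "n_het_animals",
                       "n_significant_animals", "significant_fraction",
                       "is_ase_snp"]
    )


def call_ase(
    counts: pd.DataFrame,
    min_reads_per_sample: int = 10,
    min_minor_allele_count: int = 3,
    alpha: float = 5e-2,
    het_fraction: float = 1.0 / 3.0,
    strict: bool = True,
) -> dict:
    """Full ASE calling chain: filters, tests, per-animal FDR, aggregation.

    Returns a dict with the filtered table, per-entry test results
    (heterozygous entries only), the per-site calls, and the exclusion
    registry.
    """
    filtered, registry = filter_sites(
        counts, min_reads_per_sample, min_minor_allele_count
    )
    het = filtered[filtered["genotype"] == "het"].copy()
    het["p_value"] = [
        binomial_ase_test(int(r), int(a))
        for r, a in zip(het["refCount"], het["altCount"])
    ]
    qs, flags = [], []
    for _, grp in het.groupby("sample", sort=False):
        q, flag = per_animal_fdr(grp["p_value"], alpha=alpha)
        qs.append(q)
        flags.append(flag)
    if len(het):
        het["q_value"] = pd.concat(qs)
        het["significant"] = pd.concat(flags)
    else:
        het["q_value"] = pd.Series(dtype=float)
        het["significant"] = pd.Series(dtype=bool)
    calls = aggregate_ase(het, het_fraction=het_fraction, strict=strict)
    return {"filtered": filtered, "tested": het, "calls": calls,
            "registry": registry}


def map_sites_to_genes(
    sites: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    gene_read_counts: pd.Series | pd.DataFrame | None = None,
    min_gene_reads: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Map ASE sites to overlapping genes and build the detectable universe.

    ``gene_intervals`` has columns gene, contig, start, end (1-based
    inclusive); a site is assigned to every gene whose interval contains
    it, strand-agnostically.  ``gene_read_counts`` gives per-gene read
    support (Series of per-gene maxima, or genes x samples DataFrame);
    a gene counts as expressed with >= ``min_gene_reads`` reads in at
    least one sample (all genes are considered expressed when counts are
    omitted).  The detectable universe comprises expressed genes
    overlapping at least one tested heterozygous site.

    Returns (site-to-gene assignments, ASE-gene table, universe genes).
    ``sites`` must carry contig, position, is_ase_snp.
    """
    bad = gene_intervals["end"] < gene_intervals["start"]
    if bad.any():
        raise ValueError(
            f"malformed gene intervals (end < start): {gene_intervals.loc[bad, 'gene'].tolist()}"
        )
    trees: dict[str, IntervalTree] = {}
    for _, row in gene_intervals.iterrows():
        # IntervalTree is half-open; +1 makes the 1-based inclusive end queryable
        trees.setdefault(str(row["contig"]), IntervalTree()).addi(
            int(row["start"]), int(row["end"]) + 1, row["gene"]
        )
    if gene_read_counts is None:
        expressed = set(gene_intervals["gene"])
    else:
        if isinstance(gene_read_counts, pd.DataFrame):
            max_reads = gene_read_counts.max(axis=1)
        else:
            max_reads = gene_read_counts
        expressed = set(max_reads.index[max_reads >= min_gene_reads])

    assign_rows = []
    genes_with_site: set[str] = set()
    ase_genes: set[str] = set()
    for _, row in sites.iterrows():
        tree = trees.get(str(row["contig"]))
        hits = sorted(iv.data for iv in tree[int(row["position"])]) if tree else []
        for gene in hits:
            genes_with_site.add(gene)
            if row["is_ase_snp"]:
                ase_genes.add(gene)
        assign_rows.append(
            {"contig": row["contig"], "position": row["position"],
             "is_ase_snp": bool(row["is_ase_snp"]), "genes": hits}
        )
    universe = sorted(expressed & genes_with_site)
    ase_gene_rows = [
        {"gene": g, "in_universe": g in expressed} for g in sorted(ase_genes)
    ]
    return (
        pd.DataFrame(assign_rows, columns=["contig", "position", "is_ase_snp", "genes"]),
        pd.DataFrame(ase_gene_rows, columns=["gene", "in_universe"]),
        universe,
    )


def integrate_egwas_ase(
    eqtl_genes: pd.DataFrame,
    ase_genes: pd.DataFrame,
    gene_chromosome: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cross-classify genes by eGWAS association class and ASE status.

    ``eqtl_genes`` needs columns gene, regulation_class (local /
    distant / both) and optionally eqtl_chromosome; ``ase_genes`` needs
    a gene column.  Categories:

    * cis_validated — local (or both) eQTL and ASE;
    * cis_trans_candidate — distant eQTL and ASE (flag
      ``distant_other_chromosome`` when the eQTL-SNP sits on a different
      chromosome than the gene, requires ``gene_chromosome``);
    * egwas_only / ase_only — detected by a single approach.

    Returns the per-gene table and a category count dict (plus
    ``overlap``: genes found by both approaches).
    """
    eq = eqtl_genes.drop_duplicates(subset="gene").set_index("gene")
    ase_set = set(ase_genes["gene"])
    genes = sorted(set(eq.index) | ase_set)
    rows = []
    for gene in genes:
        has_eqtl = gene in eq.index
        cls = eq.loc[gene, "regulation_class"] if has_eqtl else None
        local = has_eqtl and cls in ("local", "both")
        distant = has_eqtl and cls in ("distant", "both")
        has_ase = gene in ase_set
        if has_ase and local:
            category = "cis_validated"
        elif has_ase and distant:
            category = "cis_trans_candidate"
        elif has_eqtl:
            category = "egwas_only"
        else:
            category = "ase_only"
        other_chrom = False
        if category == "cis_trans_candidate" and gene_chromosome is not None:
            eq_chrom = eq.loc[gene].get("eqtl_chromosome", None)
            gchrom = gene_chromosome.get(gene, None)
            other_chrom = (
                eq_chrom is not None and gchrom is not None
                and str(eq_chrom) != str(gchrom)
            )
        rows.append(
            {"gene": gene, "local_eqtl": local, "distant_eqtl": distant,
             "ase": has_ase, "category": category,
             "distant_other_chromosome": other_chrom}
        )
    table = pd.DataFrame(rows)
    counts = table["category"].value_counts().to_dict()
    counts["overlap"] = int((table["ase"] & (table["local_eqtl"] | table["distant_eqtl"])).sum())
    return table, counts
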