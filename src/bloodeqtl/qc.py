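"""Genotype quality control and genomic kinship estimation.

SNP-chip style QC for a dosage matrix: sample call rate, SNP call rate,
minor-allele frequency, and an exact Hardy-Weinberg test corrected by
Benjamini-Hochberg FDR across SNPs.  Kinship uses the per-SNP standardized
(Amin-style) estimator over autosomal markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "hwe_exact_test",
    "filter_variants_and_samples",
    "compute_genomic_kinship",
]

#: chromosome labels treated as non-autosomal (case-insensitive)
NON_AUTOSOMES = {"x", "y", "mt", "m", "xy", "chrx", "chry", "chrm", "chrmt"}


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with its SNP map.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample id, columns are SNP ids.  Entries are
        alt-allele counts in {0, 1, 2}; missing genotypes are NaN.
    snp_map
        DataFrame indexed by SNP id with columns ``chromosome``,
        ``position_bp`` (1-based), ``ref``, ``alt``.
    sample_sex
        Optional per-sample sex labels aligned to ``dosages.index``.
    """

    dosages: pd.DataFrame
    snp_map: pd.DataFrame
    sample_sex: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = self.dosages.columns.difference(self.snp_map.index)
        if len(missing):
            raise ValueError(f"SNPs absent from snp_map: {list(missing)[:5]}")
        vals = self.dosages.to_numpy(dtype=float)
        bad = np.isfinite(vals) & ~np.isin(vals, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or missing (NaN)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Return a copy with SNPs ordered by (chromosome, position)."""
        order = self.snp_map.sort_values(
            ["chromosome", "position_bp"], kind="mergesort"
        ).index
        return GenotypeMatrix(
            self.dosages.loc[:, order], self.snp_map.loc[order], self.sample_sex
        )

    def allele_frequencies(self) -> pd.Series:
        """Alt-allele frequency per SNP over non-missing samples."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def minor_allele_frequencies(self) -> pd.Series:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)


@dataclass
class KinshipMatrix:
    """Symmetric samples x samples genomic relationship estimate."""

    values: pd.DataFrame
    source_snp_count: int
    normalization: str = "per-snp standardized"

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("kinship matrix must be square and symmetric")

    @property
    def samples(self) -> pd.Index:
        return self.values.index


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value from genotype counts.

    Conditional on the observed allele counts, enumerates every possible
    heterozygote count, and sums the probabilities of all outcomes no more
    probable than the observed one (the standard exact HWE tail sum).

    Parameters are counts of heterozygotes and the two homozygote classes
    (order of the homozygote classes does not matter).
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele copies
    # P(het = h | allele counts) up to a constant, computed by recurrence to
    # stay in floating range; h ranges over values with h == n_rare (mod 2).
    h0 = n_rare % 2
    hs = np.arange(h0, min(n_rare, 2 * n - n_rare) + 1, 2)
    logp = np.zeros(len(hs))
    for i in range(1, len(hs)):
        h = hs[i]
        # ratio P(h)/P(h-2) = 4 * n_rare_hom(h-2) * n_common_hom(h-2) / (h*(h-1))
        rare_hom = (n_rare - (h - 2)) // 2
        common_hom = n - rare_hom - (h - 2)
        logp[i] = logp[i - 1] + np.log(4.0 * rare_hom * common_hom) - np.log(
            h * (h - 1.0)
        )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hs == n_het]
    if len(obs) != 1:  # pragma: no cover - guarded by count arithmetic
        raise ValueError("observed heterozygote count inconsistent with alleles")
    return float(min(1.0, prob[prob <= obs[0] * (1 + 1e-12)].sum()))


def _hwe_pvalues(dosages: pd.DataFrame) -> pd.Series:
    out = {}
    for snp in dosages.columns:
        g = dosages[snp].dropna().to_numpy()
        n_hom_ref = int((g == 0).sum())
        n_het = int((g == 1).sum())
        n_hom_alt = int((g == 2).sum())
        out[snp] = hwe_exact_test(n_het, n_hom_ref, n_hom_alt)
    return pd.Series(out, name="hwe_p")


def filter_variants_and_samples(
    geno: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    hwe_fdr: float = 0.01,
    hwe_test: str = "exact",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply sample and SNP QC filters in a fixed order.

    Order: (1) drop samples with call rate < ``min_call_rate``; (2) drop
    SNPs with call rate < ``min_call_rate``; (3) drop SNPs with MAF <=
    ``min_maf`` (the inclusion rule is strict, MAF > threshold); (4) drop
    SNPs whose exact HWE p-value has BH q-value < ``hwe_fdr``.

    Returns the filtered matrix and a report with one row per removed
    sample/SNP giving the stage, the offending value and the reason.
    SNPs are sorted by (chromosome, position) first so the report does
    not depend on input column order.
    """
    if geno.n_samples < 2:
        raise ValueError("QC requires at least 2 samples")
    geno = geno.sorted_by_position()
    report_rows: list[dict] = []

    dos = geno.dosages
    sample_cr = dos.notna().mean(axis=1)
    bad_samples = sample_cr.index[sample_cr < min_call_rate]
    for s in bad_samples:
        report_rows.append(
            {"stage": "sample_call_rate", "item": s, "value": sample_cr[s],
             "reason": f"call rate {sample_cr[s]:.3f} < {min_call_rate}"}
        )
    dos = dos.drop(index=bad_samples)

    snp_cr = dos.notna().mean(axis=0)
    bad_cr = snp_cr.index[snp_cr < min_call_rate]
    for s in bad_cr:
        report_rows.append(
            {"stage": "snp_call_rate", "item": s, "value": snp_cr[s],
             "reason": f"call rate {snp_cr[s]:.3f} < {min_call_rate}"}
        )
    dos = dos.drop(columns=bad_cr)

    p = dos.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(p, 1 - p)
    bad_maf = maf.index[~(maf > min_maf)]
    for s in bad_maf:
        report_rows.append(
            {"stage": "maf", "item": s, "value": maf[s],
             "reason": f"MAF {maf[s]:.4f} <= {min_maf}"}
        )
    dos = dos.drop(columns=bad_maf)

    if dos.shape[1] > 0:
        if hwe_test == "exact":
            hwe_p = _hwe_pvalues(dos)
        elif hwe_test == "chi2":
            hwe_p = _hwe_chi2_pvalues(dos)
        else:
            raise ValueError(f"unknown hwe_test {hwe_test!r}")
        _, hwe_q, _, _ = multipletests(hwe_p.to_numpy(), method="fdr_bh")
        hwe_q = pd.Series(hwe_q, index=hwe_p.index)
        bad_hwe = hwe_q.index[hwe_q < hwe_fdr]
        for s in bad_hwe:
            report_rows.append(
                {"stage": "hwe", "item": s, "value": hwe_q[s],
                 "reason": f"HWE q {hwe_q[s]:.2e} < {hwe_fdr}"}
            )
        dos = dos.drop(columns=bad_hwe)

    if dos.shape[1] == 0:
        counts = pd.Series([r["stage"] for r in report_rows]).value_counts()
        raise ValueError(f"all SNPs removed by QC; removals by stage: {counts.to_dict()}")

    report = pd.DataFrame(report_rows, columns=["stage", "item", "value", "reason"])
    sex = geno.sample_sex.loc[dos.index] if geno.sample_sex is not None else None
    return GenotypeMatrix(dos, geno.snp_map.loc[dos.columns], sex), report


def _hwe_chi2_pvalues(dosages: pd.DataFrame) -> pd.Series:
    """Chi-square (1 df) HWE p-values; fallback dialect for large counts."""
    from scipy import stats

    out = {}
    for snp in dosages.columns:
        g = dosages[snp].dropna().to_numpy()
        n = len(g)
        counts = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()], float)
        p = (counts[1] + 2 * counts[2]) / (2 * n)
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.nansum((counts - exp) ** 2 / exp)
        out[snp] = float(stats.chi2.sf(chi2, df=1))
    return pd.Series(out, name="hwe_p")


def compute_genomic_kinship(
    geno: GenotypeMatrix, autosomes_only: bool = True
) -> KinshipMatrix:
    """Per-SNP standardized genomic relationship matrix.

    K_ij = (1/M) sum_k (g_ik - 2 p_k)(g_jk - 2 p_k) / (2 p_k (1 - p_k))
    over SNPs with complete data for the pair (pairwise-complete averaging
    when genotypes are missing).  Monomorphic SNPs (p in {0,1}) are
    excluded from the sum.  Under this normalization unrelated pairs have
    expectation 0, self-relationship is ~1, and half-sib pairs ~0.25.
    """
    snp_map = geno.snp_map.loc[geno.dosages.columns]
    keep = geno.dosages.columns
    if autosomes_only:
        chrom = snp_map["chromosome"].astype(str).str.lower()
        keep = keep[~chrom.isin(NON_AUTOSOMES).to_numpy()]
    G = geno.dosages.loc[:, keep].to_numpy(dtype=float)
    p = np.nanmean(G, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    G = G[:, poly]
    p = p[poly]
    if G.shape[1] == 0:
        raise ValueError("no polymorphic autosomal SNPs available for kinship")
    Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
    obs = np.isfinite(Z)
    Z = np.where(obs, Z, 0.0)
    num = Z @ Z.T
    counts = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = num / counts
    K[counts == 0] = 0.0
    K = (K + K.T) / 2.0
    values = pd.DataFrame(K, index=geno.dosages.index, columns=geno.dosages.index)
    return KinshipMatrix(values=values, source_snp_count=int(G.shape[1]))
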