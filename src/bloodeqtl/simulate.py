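"""Synthetic half-sib cohorts with known expression-genetics ground truth.

Generates the three data layers the analysis pipeline consumes, together
with the architecture that produced them:

* genotypes — half-sib families (shared sires, per-progeny dams by
  default), first-order Markov linkage disequilibrium along each
  chromosome, gametes formed with distance-dependent recombination;
* expression — probe intensities driven by designated cis/trans eQTL
  effects, a polygenic background matched to the realized genomic
  kinship, and batch/sex nuisance effects, with per-probe residual SD
  standardized to 1 so effect sizes are in phenotype-SD units;
* allele-specific read counts — negative-binomial coverage per
  heterozygous sample x site, binomially split between alleles, balanced
  at null sites and imbalanced at designated true-ASE sites.

All randomness flows from the single seed in the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix
from .qc import GenotypeMatrix, compute_genomic_kinship

__all__ = [
    "SimulationConfig",
    "TrueArchitecture",
    "simulate_genotypes",
    "design_architecture",
    "simulate_expression",
    "simulate_allele_counts",
    "simulate_cohort",
]


@dataclass
class SimulationConfig:
    """Cohort shape, genetic architecture and noise levels.

    Defaults describe a paternal half-sib design of moderate size (10
    sires x 25 progeny), a SNP panel dense enough to exercise linkage-
    based pruning, and read coverage typical of whole-blood RNA-seq at
    testable depth.  Effect sizes are in units of the per-probe residual
    standard deviation, which the expression generator fixes at 1.
    """

    n_sires: int = 10
    progeny_per_sire: int = 25
    n_snps: int = 500
    n_probes: int = 50
    n_chromosomes: int = 5
    chrom_length_bp: int = 50_000_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_decay_rho: float = 0.3
    h2_polygenic: float = 0.3
    n_cis_effects: int = 5
    n_trans_effects: int = 2
    effect_size_sd_units: float = 1.0
    batch_levels: int = 3
    batch_effect_sd_units: float = 0.5
    sex_effect_sd_units: float = 0.2
    ase_coverage_mean: float = 50.0
    ase_overdispersion: float = 0.1
    ase_imbalance_fraction: float = 0.8
    n_negative_control_probes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.h2_polygenic < 1:
            raise ValueError("h2_polygenic must be in [0, 1)")
        if not 0 <= self.ld_decay_rho < 1:
            raise ValueError("ld_decay_rho must be in [0, 1)")
        if not 0 < self.ase_imbalance_fraction < 1:
            raise ValueError("ase_imbalance_fraction must be in (0, 1)")
        if self.ase_overdispersion < 0:
            raise ValueError("ase_overdispersion must be >= 0")
        for name in (
            "n_sires", "progeny_per_sire", "n_snps", "n_probes",
            "n_chromosomes", "chrom_length_bp", "batch_levels",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")

    @property
    def n_samples(self) -> int:
        return self.n_sires * self.progeny_per_sire


@dataclass
class TrueArchitecture:
    """Ground-truth regulatory architecture of a simulated cohort.

    cis pairs place the SNP within 1 Mb of the probe start on the same
    chromosome; trans pairs violate that rule.  ``true_ase_sites`` carry
    the expected alt-allele read fraction (!= 0.5) in heterozygotes.
    ``gene_intervals`` (gene, contig, start, end; 1-based inclusive)
    support site-to-gene mapping in the ASE caller.
    """

    cis_effects: list[tuple[str, str, float]]
    trans_effects: list[tuple[str, str, float]]
    true_ase_sites: list[tuple[str, str, float]]
    polygenic_h2: float
    probe_annotation: pd.DataFrame | None = None
    gene_intervals: pd.DataFrame | None = None

    def validate_against(self, geno: GenotypeMatrix, probes) -> None:
        probe_set = set(probes)
        snps = set(geno.dosages.columns)
        for snp, probe, _ in list(self.cis_effects) + list(self.trans_effects):
            if snp not in snps:
                raise ValueError(f"architecture references unknown SNP {snp!r}")
            if probe not in probe_set:
                raise ValueError(f"architecture references unknown probe {probe!r}")
        for _, _, frac in self.true_ase_sites:
            if not (0 < frac < 1) or frac == 0.5:
                raise ValueError("true-ASE alt fraction must be in (0,1) and != 0.5")

    def to_json(self, path) -> None:
        payload = {
            "cis_effects": [list(t) for t in self.cis_effects],
            "trans_effects": [list(t) for t in self.trans_effects],
            "true_ase_sites": [list(t) for t in self.true_ase_sites],
            "polygenic_h2": self.polygenic_h2,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _snp_positions(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    """SNP map with strictly increasing positions per chromosome."""
    base, extra = divmod(config.n_snps, config.n_chromosomes)
    rows = []
    snp_idx = 0
    for c in range(config.n_chromosomes):
        n_c = base + (1 if c < extra else 0)
        pos = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=n_c))
        while len(pos) < n_c:  # replace collisions (rare at genome scale)
            more = rng.integers(1, config.chrom_length_bp + 1, size=n_c - len(pos))
            pos = np.unique(np.concatenate([pos, more]))
        for p in pos:
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            rows.append(
                {"snp_id": f"snp{snp_idx:05d}", "chromosome": str(c + 1),
                 "position_bp": int(p), "ref": ref, "alt": alt}
            )
            snp_idx += 1
    return pd.DataFrame(rows).set_index("snp_id")


def _markov_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    freqs: np.ndarray,
    chrom: np.ndarray,
    rho: float,
) -> np.ndarray:
    """Population haplotypes with AR(1) Gaussian-copula LD within chromosomes.

    A latent AR(1) Gaussian process (lag correlation ``rho``, reset at
    chromosome boundaries) is thresholded at the allele-frequency
    quantile, giving adjacent-SNP allele correlation that decays
    geometrically with marker distance in index space.
    """
    m = len(freqs)
    z = np.empty((n_hap, m))
    innov = rng.standard_normal((n_hap, m))
    new_chrom = np.ones(m, dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    scale = np.sqrt(1 - rho**2)
    z[:, 0] = innov[:, 0]
    for k in range(1, m):
        if new_chrom[k]:
            z[:, k] = innov[:, k]
        else:
            z[:, k] = rho * z[:, k - 1] + scale * innov[:, k]
    thresh = stats.norm.ppf(freqs)
    return (z < thresh).astype(np.int8)


def _gamete(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    switch_prob: np.ndarray,
) -> np.ndarray:
    """Meiotic gamete from a diploid: per-interval recombination switches."""
    m = len(hap_a)
    switches = rng.random(m) < switch_prob
    phase = np.logical_xor.accumulate(switches)  # switch_prob[0]=0.5 randomizes start
    return np.where(phase, hap_b, hap_a)


def simulate_genotypes(
    config: SimulationConfig,
    dam_assignment: dict[int, int] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Half-sib family genotypes plus the pedigree that produced them.

    Each sire is a simulated diploid; each progeny receives one
    recombinant gamete from its sire and one from its dam.  By default
    every progeny has its own dam; ``dam_assignment`` (progeny index ->
    dam index, both 0-based within the cohort) lets tests create full
    sibs.  Recombination fractions between adjacent SNPs follow Haldane's
    map at 1 cM/Mb; chromosomes segregate independently.

    Returns the genotype matrix (progeny only) and a pedigree table with
    columns sample, sire, dam.
    """
    rng = np.random.default_rng(config.seed)
    snp_map = _snp_positions(rng, config)
    chrom = snp_map["chromosome"].to_numpy()
    pos = snp_map["position_bp"].to_numpy(dtype=float)
    freqs = rng.uniform(*config.maf_range, size=config.n_snps)

    # recombination fraction for the interval ending at each SNP;
    # 0.5 at chromosome starts => independent segregation across chromosomes
    d_morgan = np.zeros(config.n_snps)
    d_morgan[1:] = (pos[1:] - pos[:-1]) * 1e-8
    switch = 0.5 * (1 - np.exp(-2 * d_morgan))
    new_chrom = np.ones(config.n_snps, dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    switch[new_chrom] = 0.5

    n = config.n_samples
    sire_haps = _markov_haplotypes(
        rng, 2 * config.n_sires, freqs, chrom, config.ld_decay_rho
    ).reshape(config.n_sires, 2, -1)
    if dam_assignment is None:
        dam_assignment = {i: i for i in range(n)}
    n_dams = max(dam_assignment.values()) + 1
    dam_haps = _markov_haplotypes(
        rng, 2 * n_dams, freqs, chrom, config.ld_decay_rho
    ).reshape(n_dams, 2, -1)

    dosages = np.empty((n, config.n_snps), dtype=np.int8)
    ped_rows = []
    for i in range(n):
        sire = i // config.progeny_per_sire
        dam = dam_assignment[i]
        paternal = _gamete(rng, sire_haps[sire, 0], sire_haps[sire, 1], switch)
        maternal = _gamete(rng, dam_haps[dam, 0], dam_haps[dam, 1], switch)
        dosages[i] = paternal + maternal
        ped_rows.append(
            {"sample": f"pig{i:04d}", "sire": f"sire{sire:03d}", "dam": f"dam{dam:04d}"}
        )
    pedigree = pd.DataFrame(ped_rows)
    samples = pedigree["sample"]
    sex = pd.Series(
        rng.choice(["F", "M"], size=n), index=samples.to_numpy(), name="sex"
    )
    dos = pd.DataFrame(dosages, index=samples.to_numpy(), columns=snp_map.index)
    return GenotypeMatrix(dos.astype(float), snp_map, sex), pedigree


def design_architecture(
    geno: GenotypeMatrix, config: SimulationConfig
) -> TrueArchitecture:
    """Draw a random cis/trans architecture consistent with the genotypes.

    Probes are scattered across the genome; cis-effect probes are placed
    within 1 Mb of their causal SNP on the same chromosome, trans-effect
    SNPs are drawn from a different chromosome than their probe.  The
    cis-regulated genes double as true-ASE genes: the SNP of each cis
    pair is an imbalanced site inside its gene's interval.  The last
    ``n_negative_control_probes`` probes are unmapped negative controls.
    """
    rng = np.random.default_rng(config.seed + 1)
    snp_map = geno.snp_map
    n_exp = config.n_probes
    if config.n_cis_effects + config.n_trans_effects > n_exp:
        raise ValueError("more designated effects than probes")

    probe_ids = [f"probe{j:05d}" for j in range(n_exp)]
    chroms = rng.integers(1, config.n_chromosomes + 1, size=n_exp).astype(str)
    starts = rng.integers(1, config.chrom_length_bp - 30_000, size=n_exp)
    strands = rng.choice(["+", "-"], size=n_exp)

    effect_probes = rng.choice(
        n_exp, size=config.n_cis_effects + config.n_trans_effects, replace=False
    )
    cis_probes = effect_probes[: config.n_cis_effects]
    trans_probes = effect_probes[config.n_cis_effects:]

    snp_pool = list(snp_map.index)
    used_snps: set[str] = set()
    cis_effects, true_ase = [], []
    for j in cis_probes:
        snp = snp_pool[int(rng.integers(len(snp_pool)))]
        while snp in used_snps:
            snp = snp_pool[int(rng.integers(len(snp_pool)))]
        used_snps.add(snp)
        # place the probe near its causal SNP (same chromosome, <= 1 Mb)
        chroms[j] = snp_map.loc[snp, "chromosome"]
        offset = int(rng.integers(-900_000, 900_001))
        starts[j] = max(1, snp_map.loc[snp, "position_bp"] + offset)
        beta = config.effect_size_sd_units * (1 if rng.random() < 0.5 else -1)
        cis_effects.append((snp, probe_ids[j], float(beta)))
        true_ase.append((snp, f"gene{j:05d}", float(config.ase_imbalance_fraction)))

    trans_effects = []
    for j in trans_probes:
        other = snp_map.index[snp_map["chromosome"] != chroms[j]]
        other = [s for s in other if s not in used_snps]
        snp = other[int(rng.integers(len(other)))]
        used_snps.add(snp)
        beta = config.effect_size_sd_units * (1 if rng.random() < 0.5 else -1)
        trans_effects.append((snp, probe_ids[j], float(beta)))

    ann_rows = []
    gene_rows = []
    for j in range(n_exp):
        gene = f"gene{j:05d}"
        ann_rows.append(
            {"probe_id": probe_ids[j], "chromosome": chroms[j],
             "start_bp": int(starts[j]), "strand": strands[j],
             "gene_symbol": gene, "sense": True,
             "probe_class": "experimental"}
        )
        lo, hi = int(starts[j]), int(starts[j]) + 20_000
        gene_rows.append({"gene": gene, "contig": chroms[j], "start": lo, "end": hi})
    # widen cis-gene intervals to cover their imbalanced SNP
    gene_by_probe = {probe_ids[j]: j for j in range(n_exp)}
    for snp, probe, _ in cis_effects:
        j = gene_by_probe[probe]
        p = int(snp_map.loc[snp, "position_bp"])
        gene_rows[j]["start"] = min(gene_rows[j]["start"], p)
        gene_rows[j]["end"] = max(gene_rows[j]["end"], p)
    for k in range(config.n_negative_control_probes):
        ann_rows.append(
            {"probe_id": f"negctrl{k:03d}", "chromosome": pd.NA,
             "start_bp": pd.NA, "strand": pd.NA, "gene_symbol": pd.NA,
             "sense": pd.NA, "probe_class": "negative_control"}
        )
    annotation = pd.DataFrame(ann_rows).set_index("probe_id")
    gene_intervals = pd.DataFrame(gene_rows)
    return TrueArchitecture(
        cis_effects=cis_effects,
        trans_effects=trans_effects,
        true_ase_sites=true_ase,
        polygenic_h2=config.h2_polygenic,
        probe_annotation=annotation,
        gene_intervals=gene_intervals,
    )


def simulate_expression(
    geno: GenotypeMatrix,
    arch: TrueArchitecture,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Probe expression from the architecture plus structured noise.

    y = mu + batch + sex + sum(beta * g) + u + e, with the polygenic
    term u drawn from N(0, h2 * K) using the realized genomic kinship K
    (eigenvalues clipped at zero) and e ~ N(0, 1 - h2), so the residual
    variance around the fixed genetic effects is 1 and effect sizes are
    in residual-SD units.  Negative-control probes are pure noise around
    a low baseline intensity.  Returns the expression matrix and the
    covariate table (batch, sex).
    """
    if arch.probe_annotation is None:
        raise ValueError("architecture lacks probe annotation")
    probes = arch.probe_annotation.index
    exp_probes = arch.probe_annotation.index[
        arch.probe_annotation["probe_class"] == "experimental"
    ]
    arch.validate_against(geno, exp_probes)
    rng = np.random.default_rng(config.seed + 2)
    samples = geno.dosages.index
    n = len(samples)

    batch = pd.Series(
        rng.integers(config.batch_levels, size=n).astype(str), index=samples,
        name="batch",
    )
    sex = (
        geno.sample_sex
        if geno.sample_sex is not None
        else pd.Series(rng.choice(["F", "M"], size=n), index=samples, name="sex")
    )
    covars = pd.DataFrame({"batch": "b" + batch, "sex": sex})

    h2 = config.h2_polygenic
    if h2 > 0:
        K = compute_genomic_kinship(geno).values.to_numpy()
        w, U = np.linalg.eigh(K)
        L = U * np.sqrt(np.clip(w, 0, None))
    else:
        L = None

    beta_map: dict[str, list[tuple[str, float]]] = {}
    for snp, probe, beta in list(arch.cis_effects) + list(arch.trans_effects):
        beta_map.setdefault(probe, []).append((snp, beta))

    baseline = 8.0
    values = np.empty((n, len(probes)))
    batch_codes = batch.astype(int).to_numpy()
    sex_num = (sex.to_numpy() == "M").astype(float)
    for idx, probe in enumerate(probes):
        if arch.probe_annotation.loc[probe, "probe_class"] == "negative_control":
            values[:, idx] = 4.0 + rng.standard_normal(n)
            continue
        y = np.full(n, baseline)
        y += rng.normal(0, config.batch_effect_sd_units, config.batch_levels)[
            batch_codes
        ]
        y += rng.normal(0, config.sex_effect_sd_units) * sex_num
        for snp, beta in beta_map.get(probe, []):
            y += beta * geno.dosages[snp].to_numpy(dtype=float)
        if L is not None:
            y += np.sqrt(h2) * (L @ rng.standard_normal(n))
        y += np.sqrt(1 - h2) * rng.standard_normal(n)
        values[:, idx] = y
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=samples, columns=probes),
        probe_annotation=arch.probe_annotation,
    )
    return expr, covars


def _nb_total(rng: np.random.Generator, mean: float, disp: float, size: int) -> np.ndarray:
    """Negative-binomial coverage: var = mean + disp * mean^2 (Poisson at disp=0)."""
    if disp <= 0:
        return rng.poisson(mean, size=size)
    lam = rng.gamma(shape=1.0 / disp, scale=mean * disp, size=size)
    return rng.poisson(lam)


def simulate_allele_counts(
    arch: TrueArchitecture,
    geno: GenotypeMatrix,
    config: SimulationConfig,
    sites: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample allele read counts at SNP sites (ASEReadCounter layout).

    Coverage per sample x site is negative-binomial; in heterozygotes the
    alt count is Binomial(total, 0.5) at null sites and Binomial(total,
    alt_fraction) at designated true-ASE sites.  Homozygotes emit all
    reads on their single allele.  ``sites`` restricts output to a SNP
    subset (default: every SNP).
    """
    rng = np.random.default_rng(config.seed + 3)
    if sites is None:
        sites = list(geno.dosages.columns)
    true_frac = {snp: frac for snp, _, frac in arch.true_ase_sites}
    snp_map = geno.snp_map
    samples = geno.dosages.index
    rows = []
    for snp in sites:
        g = geno.dosages[snp].to_numpy(dtype=float)
        info = snp_map.loc[snp]
        totals = _nb_total(
            rng, config.ase_coverage_mean, config.ase_overdispersion, len(samples)
        )
        frac = true_frac.get(snp, 0.5)
        for i, sample in enumerate(samples):
            if not np.isfinite(g[i]):
                continue
            total = int(totals[i])
            if g[i] == 1:
                alt = int(rng.binomial(total, frac))
                call = "het"
            elif g[i] == 2:
                alt, call = total, "hom_alt"
            else:
                alt, call = 0, "hom_ref"
            rows.append(
                {"sample": sample, "contig": info["chromosome"],
                 "position": int(info["position_bp"]), "ref": info["ref"],
                 "alt": info["alt"], "refCount": total - alt, "altCount": alt,
                 "genotype": call}
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "contig", "position", "ref", "alt",
                 "refCount", "altCount", "genotype"],
    )


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: genotypes, architecture, expression, covariates,
    allele counts, pedigree — everything one end-to-end run needs."""
    geno, pedigree = simulate_genotypes(config)
    arch = design_architecture(geno, config)
    expr, covars = simulate_expression(geno, arch, config)
    counts = simulate_allele_counts(arch, geno, config)
    return {
        "genotypes": geno,
        "pedigree": pedigree,
        "architecture": arch,
        "expression": expr,
        "covariates": covars,
        "allele_counts": counts,
    }
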