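"""Readers and writers for the pipeline's tabular formats.

All TSV artifacts carry a provenance header of ``#key: value`` comment
lines (package version, seed, config hash) that readers skip
transparently.  Genotypes are accepted either as a dosage TSV or in
PLINK .ped/.map dialect; ASE sites can be exported as a minimal VCF.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import ExpressionMatrix
from .qc import GenotypeMatrix, KinshipMatrix

__all__ = [
    "PipelineConfig",
    "provenance_header",
    "read_tsv",
    "write_tsv",
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_kinship",
    "write_kinship",
    "read_allele_counts",
    "read_gene_intervals",
    "write_bed",
    "write_vcf_sites",
]


@dataclass
class PipelineConfig:
    """Declarative configuration for an end-to-end run.

    Thresholds default to the values the analysis is built around:
    call rate 0.95, MAF 0.05, HWE FDR 0.01, per-probe and global
    association FDR 0.05, 5-Mb pruning window, 1-Mb local window, ASE
    minimum 10 reads per entry, cohort minor-allele count > 3,
    per-animal FDR 0.05, more-than-one-third heterozygote aggregation,
    and 10 targets for a master regulator.
    """

    output_dir: str = "results"
    genotypes: str | None = None
    expression: str | None = None
    covariates: str | None = None
    allele_counts: str | None = None
    gene_intervals: str | None = None

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_fdr: float = 0.01
    alpha_probe: float = 0.05
    alpha_global: float = 0.05
    prune_window_bp: int = 5_000_000
    local_window_bp: int = 1_000_000
    ase_min_reads: int = 10
    ase_min_mac: int = 3
    ase_alpha: float = 0.05
    ase_het_fraction: float = 1.0 / 3.0
    master_min_targets: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def require(self, *fields: str) -> None:
        for f in fields:
            if getattr(self, f) is None:
                raise ValueError(f"config is missing required path {f!r}")


def provenance_header(config: PipelineConfig | None = None, **extra) -> str:
    lines = [f"#bloodeqtl_version: {__version__}"]
    if config is not None:
        lines.append(f"#seed: {config.seed}")
        lines.append(f"#config_hash: {config.config_hash()}")
    for k, v in extra.items():
        lines.append(f"#{k}: {v}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path, config: PipelineConfig | None = None,
              index: bool = False, **extra) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, **extra))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------- genotypes

def write_genotypes(geno: GenotypeMatrix, dosage_path, map_path,
                    config: PipelineConfig | None = None) -> None:
    dosages = geno.dosages.copy()
    dosages.index.name = "sample"
    write_tsv(dosages, dosage_path, config, index=True)
    snp_map = geno.snp_map.copy()
    snp_map.index.name = "snp_id"
    write_tsv(snp_map, map_path, config, index=True)  # sex travels with covariates


def _read_snp_map(map_path) -> pd.DataFrame:
    snp_map = read_tsv(map_path, index_col="snp_id")
    snp_map["chromosome"] = snp_map["chromosome"].astype(str)
    if snp_map.index.duplicated().any():
        dup = snp_map.index[snp_map.index.duplicated()][0]
        raise ValueError(f"duplicate SNP id {dup!r} in map")
    return snp_map


def read_genotypes(path, map_path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read genotypes as a dosage TSV or PLINK .ped/.map pair.

    The TSV dialect expects a ``sample`` index column and one column per
    SNP with 0/1/2 dosages (blank = missing).  The ped_map dialect reads
    white-space separated .ped (fam, id, sire, dam, sex, phenotype, then
    two alleles per SNP; 0 = missing) and counts the minor allele.
    """
    if dialect == "tsv":
        dosages = read_tsv(path, index_col="sample")
        if dosages.index.duplicated().any():
            dup = dosages.index[dosages.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        return GenotypeMatrix(dosages.astype(float), _read_snp_map(map_path))
    if dialect == "ped_map":
        return _read_ped_map(path, map_path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    map_df = pd.read_csv(
        map_path, sep=r"\s+", comment="#", header=None,
        names=["chromosome", "snp_id", "cm", "position_bp"],
    )
    snp_ids = map_df["snp_id"].tolist()
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError("duplicate SNP id in .map")
    samples, sexes, rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * len(snp_ids):
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(snp_ids)} fields, "
                    f"got {len(parts)}"
                )
            sample = parts[1]
            if sample in samples:
                raise ValueError(f"{ped_path}:{lineno}: duplicate sample id {sample!r}")
            samples.append(sample)
            sexes.append({"1": "M", "2": "F"}.get(parts[4], "U"))
            rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(samples), len(snp_ids), 2)
    dosages = np.full((len(samples), len(snp_ids)), np.nan)
    ref_alt = []
    for k in range(len(snp_ids)):
        col = alleles[:, k, :]
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(f"SNP {snp_ids[k]} has >2 alleles in .ped")
        if len(uniq) == 0:
            ref_alt.append(("N", "N"))
            continue
        order = np.argsort(-counts, kind="stable")  # major first; minor is counted
        major = uniq[order[0]]
        minor = uniq[order[1]] if len(uniq) == 2 else "N"
        ref_alt.append((major, minor))
        missing = (col == "0").any(axis=1)
        dosages[:, k] = np.where(missing, np.nan, (col == minor).sum(axis=1))
    snp_map = pd.DataFrame(
        {"chromosome": map_df["chromosome"].astype(str).to_numpy(),
         "position_bp": map_df["position_bp"].to_numpy(),
         "ref": [ra[0] for ra in ref_alt], "alt": [ra[1] for ra in ref_alt]},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    dos = pd.DataFrame(dosages, index=pd.Index(samples, name="sample"),
                       columns=snp_ids)
    sex = pd.Series(sexes, index=dos.index, name="sex")
    return GenotypeMatrix(dos, snp_map, sex)


# --------------------------------------------------------------- expression

def write_expression(expr: ExpressionMatrix, values_path, annotation_path,
                     config: PipelineConfig | None = None) -> None:
    values = expr.values.copy()
    values.index.name = "sample"
    write_tsv(values, values_path, config, index=True)
    ann = expr.probe_annotation.copy()
    ann.index.name = "probe_id"
    write_tsv(ann, annotation_path, config, index=True)


def read_expression(values_path, annotation_path) -> ExpressionMatrix:
    values = read_tsv(values_path, index_col="sample")
    ann = read_tsv(annotation_path, index_col="probe_id")
    ann["chromosome"] = ann["chromosome"].astype("string")
    return ExpressionMatrix(values=values, probe_annotation=ann)


# ------------------------------------------------------------------ kinship

def write_kinship(K: KinshipMatrix, path, config: PipelineConfig | None = None) -> None:
    values = K.values.copy()
    values.index.name = "sample"
    write_tsv(values, path, config, index=True,
              source_snp_count=K.source_snp_count,
              normalization=K.normalization)


def read_kinship(path) -> KinshipMatrix:
    n_snps = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#source_snp_count:"):
                n_snps = int(line.split(":", 1)[1])
            if not line.startswith("#"):
                break
    values = read_tsv(path, index_col="sample")
    values.columns = values.columns.astype(values.index.dtype)
    return KinshipMatrix(values=values, source_snp_count=n_snps)


# ------------------------------------------------------------- ASE and BED

ASE_COLUMNS = ["sample", "contig", "position", "ref", "alt",
               "refCount", "altCount", "genotype"]


def read_allele_counts(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(ASE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allele-count table lacks columns: {sorted(missing)}")
    df["contig"] = df["contig"].astype(str)
    return df[ASE_COLUMNS]


def read_gene_intervals(path) -> pd.DataFrame:
    """Gene intervals from a BED-like TSV.

    Accepts either a headered TSV with columns gene, contig, start, end
    (1-based inclusive) or a headerless 4-column BED (contig, start,
    end, gene; 0-based half-open, converted on read).
    """
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            first = fh.readline()
    if "gene" in first.split():
        df = read_tsv(path)
        df["contig"] = df["contig"].astype(str)
        return df[["gene", "contig", "start", "end"]]
    bed = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=["contig", "start", "end", "gene"])
    bed["contig"] = bed["contig"].astype(str)
    bed["start"] = bed["start"] + 1  # BED 0-based half-open -> 1-based inclusive
    return bed[["gene", "contig", "start", "end"]]


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write 1-based inclusive gene intervals as 0-based half-open BED."""
    out = intervals.copy()
    out["start"] = out["start"] - 1
    out[["contig", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_vcf_sites(sites: pd.DataFrame, path,
                    config: PipelineConfig | None = None) -> None:
    """Export ASE-SNP sites as a minimal sites-only VCF (no genotypes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=bloodeqtl {__version__}\n")
        fh.write('##INFO=<ID=ASE,Number=0,Type=Flag,Description="ASE-SNP">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = sites.sort_values(["contig", "position"], kind="mergesort")
        for _, row in ordered.iterrows():
            info = "ASE" if row.get("is_ase_snp", False) else "."
            fh.write(
                f"{row['contig']}\t{int(row['position'])}\t.\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t{info}\n"
            )
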