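"""Polygenic mixed-model expression GWAS.

For each probe, a polygenic null model y = X beta + u + e is fitted by
REML, with u ~ N(0, sigma2_g K) for a genomic kinship K and e ~
N(0, sigma2_e I).  The variance ratio h2 = sigma2_g / (sigma2_g +
sigma2_e) is profiled by 1-D optimization on the eigenbasis of K, whose
decomposition is computed once and shared across probes.  Each SNP is
then tested with the family-based score test: with V-metric residuals
g~, y~ (residualized on X), the statistic

    T = (g~' V^-1 y~)^2 / (g~' V^-1 g~)  ~  chi2(1)

and the SNP effect is b = (g~' V^-1 y~) / (g~' V^-1 g~).

Downstream: two-level Benjamini-Hochberg significance (per probe across
SNPs, and globally across all tests), conditional pruning of redundant
SNPs within a 5-Mb window to lead eQTL-SNPs, local/distant
classification at 1 Mb, effect/SD ratios, and per-chromosome enrichment
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .qc import KinshipMatrix

__all__ = [
    "KinshipEigen",
    "PolygenicNullModel",
    "build_design",
    "eigendecompose_kinship",
    "fit_polygenic_null",
    "score_test",
    "run_egwas",
    "two_level_fdr",
    "prune_to_eqtl_snps",
    "classify_local_distant",
    "snp_regulation_summary",
    "effect_sd_ratio",
    "chromosome_enrichment",
]

_H2_FLOOR = 1e-6
_VAR_FLOOR = 1e-12


@dataclass
class KinshipEigen:
    """Cached spectral decomposition of a kinship matrix (PSD-clipped)."""

    samples: pd.Index
    eigenvalues: np.ndarray  # clipped at zero, ascending
    eigenvectors: np.ndarray  # columns

    @property
    def n(self) -> int:
        return len(self.samples)

    def rotate(self, v: np.ndarray) -> np.ndarray:
        """Transform into the eigenbasis (U' v); v may be 1- or 2-D."""
        return self.eigenvectors.T @ v


def eigendecompose_kinship(K: KinshipMatrix | pd.DataFrame) -> KinshipEigen:
    values = K.values if isinstance(K, KinshipMatrix) else K
    w, U = np.linalg.eigh(values.to_numpy())
    return KinshipEigen(
        samples=values.index, eigenvalues=np.clip(w, 0.0, None), eigenvectors=U
    )


def build_design(covars: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect design matrix: intercept plus dummy-coded covariates.

    Categorical/object columns are dummy-coded dropping the first level;
    numeric columns enter as-is.
    """
    n = len(covars)
    cols = {"intercept": np.ones(n)}
    for name in covars.columns:
        col = covars[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        else:
            cols[name] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=covars.index)


@dataclass
class PolygenicNullModel:
    """REML fit of the polygenic null for one probe.

    Stores everything the score test reuses: the shared eigenbasis, the
    rotated design and residuals, and the diagonal weights of V^-1 (up
    to the total variance scale).
    """

    probe_id: str
    fixed_effects: pd.Series
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    eigen: KinshipEigen
    design_columns: pd.Index
    _Xr: np.ndarray = field(repr=False)  # rotated design
    _resid_r: np.ndarray = field(repr=False)  # rotated residuals y~ - X~ beta
    _weights: np.ndarray = field(repr=False)  # 1 / (h2*d + 1-h2)
    _XtWX_inv: np.ndarray = field(repr=False)

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_g + self.sigma2_e


def _reml_profile(h2: float, yr: np.ndarray, Xr: np.ndarray, d: np.ndarray):
    """Profiled REML pieces at a fixed variance ratio h2.

    Returns (negative restricted log-likelihood, beta, sigma2_total,
    weights, (X'WX)^-1).
    """
    n, p = Xr.shape
    delta = h2 * d + (1.0 - h2)
    w = 1.0 / delta
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    r = yr - Xr @ beta
    rss = float(np.sum(w * r * r))
    sigma2 = max(rss / (n - p), _VAR_FLOOR)
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular design in REML profile")
    nll = 0.5 * (
        (n - p) * np.log(sigma2) + np.sum(np.log(delta)) + logdet_xtwx + (n - p)
    )
    return nll, beta, sigma2, w, np.linalg.inv(XtWX)


def fit_polygenic_null(
    y: pd.Series,
    X: pd.DataFrame,
    K: KinshipMatrix | KinshipEigen,
    probe_id: str = "",
) -> PolygenicNullModel:
    """Fit the polygenic null model by REML profiled over h2.

    ``X`` must include the intercept (see :func:`build_design`).  The
    kinship may be passed pre-decomposed to share the eigenbasis across
    probes.  The optimizer searches h2 in [0, 1) with a bounded scalar
    minimizer; a flat likelihood (K = I) legitimately leaves h2
    unidentified while the total variance matches the OLS residual
    variance.
    """
    eigen = K if isinstance(K, KinshipEigen) else eigendecompose_kinship(K)
    yv = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(yv)):
        raise ValueError("non-finite values in probe expression")
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n < p + 2:
        raise ValueError("too few samples for the fixed-effect design")
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        # name one column involved in the collinearity for the error message
        _, R = np.linalg.qr(Xv)
        bad = X.columns[int(np.argmin(np.abs(np.diag(R))))]
        raise ValueError(f"singular design matrix (collinear column {bad!r})")

    yr = eigen.rotate(yv)
    Xr = eigen.rotate(Xv)
    d = eigen.eigenvalues

    def objective(h2: float) -> float:
        return _reml_profile(h2, yr, Xr, d)[0]

    res = optimize.minimize_scalar(
        objective, bounds=(0.0, 1.0 - _H2_FLOOR), method="bounded",
        options={"xatol": 1e-6},
    )
    h2_hat = float(res.x)
    # the bounded minimizer never evaluates the h2=0 boundary exactly
    if objective(0.0) < res.fun:
        h2_hat = 0.0
    nll, beta, sigma2, w, XtWX_inv = _reml_profile(h2_hat, yr, Xr, d)
    return PolygenicNullModel(
        probe_id=probe_id,
        fixed_effects=pd.Series(beta, index=X.columns),
        sigma2_g=h2_hat * sigma2,
        sigma2_e=(1 - h2_hat) * sigma2,
        h2=h2_hat,
        loglik=-nll,
        eigen=eigen,
        design_columns=X.columns,
        _Xr=Xr,
        _resid_r=yr - Xr @ beta,
        _weights=w,
        _XtWX_inv=XtWX_inv,
    )


def _score_batch(model: PolygenicNullModel, Gr: np.ndarray):
    """Vectorized score tests for rotated dosage columns Gr (n x m).

    Residualizing g on X in the V^-1 metric leaves the numerator
    g~' W r unchanged (r is already X-orthogonal in that metric), so only
    the denominator needs the projection correction.
    """
    w = model._weights
    r = model._resid_r
    num = Gr.T @ (w * r)
    XtWg = model._Xr.T @ (Gr * w[:, None])  # p x m
    den = np.einsum("ij,ij->j", Gr * w[:, None], Gr) - np.einsum(
        "pj,pq,qj->j", XtWg, model._XtWX_inv, XtWg
    )
    sigma2 = max(model.sigma2_total, _VAR_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / den
        T = num**2 / (sigma2 * den)
    bad = den <= 1e-10
    beta[bad] = np.nan
    T[bad] = np.nan
    p = np.where(np.isnan(T), np.nan, stats.chi2.sf(T, df=1))
    return beta, T, p


def score_test(
    model: PolygenicNullModel, g: pd.Series | np.ndarray
) -> tuple[float, float, float]:
    """Family-based score test of one SNP against a fitted null model.

    Returns (beta_snp, score_statistic, p_value); a monomorphic SNP (or
    one collinear with the covariates) yields NaNs rather than raising.
    Samples with missing dosage are dropped for this test, with the null
    model refitted on the complete subset.
    """
    gv = np.asarray(g, dtype=float)
    if len(gv) != model.eigen.n:
        raise ValueError("dosage vector length does not match the model")
    mask = np.isfinite(gv)
    if mask.all():
        if np.nanvar(gv) == 0:
            return (np.nan, np.nan, np.nan)
        beta, T, p = _score_batch(model, model.eigen.rotate(gv)[:, None])
        return float(beta[0]), float(T[0]), float(p[0])
    # missing dosages: pairwise-complete refit on the subset
    if gv[mask].var() == 0:
        return (np.nan, np.nan, np.nan)
    sub = _subset_refit(model, mask)
    beta, T, p = _score_batch(sub, sub.eigen.rotate(gv[mask])[:, None])
    return float(beta[0]), float(T[0]), float(p[0])


def _subset_refit(model: PolygenicNullModel, mask: np.ndarray) -> PolygenicNullModel:
    """Refit the null on a sample subset (fresh eigenbasis of K[S,S])."""
    U, d = model.eigen.eigenvectors, model.eigen.eigenvalues
    K_full = (U * d) @ U.T
    K_sub = pd.DataFrame(
        K_full[np.ix_(mask, mask)],
        index=model.eigen.samples[mask],
        columns=model.eigen.samples[mask],
    )
    X_full = pd.DataFrame(
        model.eigen.eigenvectors @ model._Xr, columns=model.design_columns,
        index=model.eigen.samples,
    )
    y_full = model.eigen.eigenvectors @ (model._resid_r + model._Xr @ model.fixed_effects.to_numpy())
    y_sub = pd.Series(y_full[mask], index=model.eigen.samples[mask])
    return fit_polygenic_null(
        y_sub, X_full.loc[mask], eigendecompose_kinship(K_sub), model.probe_id
    )


def run_egwas(
    expr,
    geno,
    covars: pd.DataFrame,
    K: KinshipMatrix | KinshipEigen,
    probes: list[str] | None = None,
    keep_models: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Score-test every probe against every SNP.

    Inputs must share the same sample ids; a mismatch raises with the
    offending set difference.  Returns one record per probe x SNP with
    beta, score statistic and p-value.  ``keep_models`` additionally
    returns the fitted null models keyed by probe for reuse in
    conditional pruning.
    """
    samples = expr.values.index
    for name, other in (
        ("genotypes", geno.dosages.index),
        ("covariates", covars.index),
        ("kinship", K.samples if isinstance(K, (KinshipMatrix, KinshipEigen)) else K.index),
    ):
        if set(other) != set(samples):
            diff = set(samples).symmetric_difference(other)
            raise ValueError(f"sample mismatch with {name}: {sorted(diff)[:10]}")
    geno_d = geno.dosages.loc[samples]
    covars = covars.loc[samples]
    if isinstance(K, KinshipMatrix):
        K = KinshipMatrix(K.values.loc[samples, samples], K.source_snp_count)
        eigen = eigendecompose_kinship(K)
    else:
        eigen = K
        if list(eigen.samples) != list(samples):
            raise ValueError(
                "pre-decomposed kinship must match the expression sample order"
            )

    X = build_design(covars)
    G = geno_d.to_numpy(dtype=float)
    complete = np.all(np.isfinite(G), axis=0)
    Gr = eigen.rotate(np.where(np.isfinite(G), G, 0.0))
    snp_ids = list(geno_d.columns)
    mono = np.nanvar(G, axis=0) == 0

    if probes is None:
        probes = list(expr.values.columns)
    frames = []
    models: dict[str, PolygenicNullModel] = {}
    for probe in probes:
        y = expr.values[probe]
        model = fit_polygenic_null(y, X, eigen, probe_id=probe)
        beta = np.full(len(snp_ids), np.nan)
        T = np.full(len(snp_ids), np.nan)
        p = np.full(len(snp_ids), np.nan)
        ok = complete & ~mono
        if ok.any():
            b, t, pv = _score_batch(model, Gr[:, ok])
            beta[ok], T[ok], p[ok] = b, t, pv
        for j in np.nonzero(~complete & ~mono)[0]:
            beta[j], T[j], p[j] = score_test(model, G[:, j])
        frames.append(
            pd.DataFrame(
                {"probe_id": probe, "snp_id": snp_ids, "beta_snp": beta,
                 "score_statistic": T, "p_value": p}
            )
        )
        if keep_models:
            models[probe] = model
    records = pd.concat(frames, ignore_index=True)
    return (records, models) if keep_models else records


def _bh_threshold(pvals: np.ndarray, alpha: float) -> float:
    """Largest p rejected by BH step-up at level alpha (-inf if none)."""
    p = np.sort(pvals[np.isfinite(pvals)])
    m = len(p)
    if m == 0:
        return -np.inf
    crit = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(p <= crit)[0]
    return float(p[passing[-1]]) if len(passing) else -np.inf


def two_level_fdr(
    records: pd.DataFrame,
    alpha_probe: float = 0.05,
    alpha_global: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Two-level BH significance over the full association table.

    Level 1: BH across SNPs within each probe gives a per-probe p
    threshold.  Level 2: BH across every test gives one global
    threshold.  An association is significant iff its p-value passes
    both (step-up semantics: p <= the largest rejected p of each pass).
    Adds columns q_probe, q_global, is_significant; returns thresholds.
    """
    out = records.copy()
    out["q_probe"] = np.nan
    valid = out["p_value"].notna()

    probe_thresholds: dict[str, float] = {}
    for probe, idx in out.groupby("probe_id").groups.items():
        pv = out.loc[idx, "p_value"].to_numpy()
        fin = np.isfinite(pv)
        if fin.any():
            _, q, _, _ = multipletests(pv[fin], method="fdr_bh")
            col = np.full(len(pv), np.nan)
            col[fin] = q
            out.loc[idx, "q_probe"] = col
        probe_thresholds[probe] = _bh_threshold(pv, alpha_probe)

    pv_all = out["p_value"].to_numpy()
    out["q_global"] = np.nan
    fin = np.isfinite(pv_all)
    if fin.any():
        _, q, _, _ = multipletests(pv_all[fin], method="fdr_bh")
        out.loc[fin, "q_global"] = q
    global_threshold = _bh_threshold(pv_all, alpha_global)

    thr = out["probe_id"].map(probe_thresholds).to_numpy(dtype=float)
    out["is_significant"] = (
        valid.to_numpy() & (pv_all <= thr) & (pv_all <= global_threshold)
    )
    return out, {"per_probe": probe_thresholds, "global": global_threshold}


def _conditional_p(
    expr, X: pd.DataFrame, eigen: KinshipEigen, probe: str,
    lead_g: pd.Series, other_g: pd.Series,
) -> float:
    """Score-test p of ``other_g`` with the lead SNP added as a covariate."""
    Xc = X.copy()
    Xc["__lead__"] = np.asarray(lead_g, dtype=float)
    if np.linalg.matrix_rank(Xc.to_numpy(dtype=float)) < Xc.shape[1]:
        return np.nan
    model = fit_polygenic_null(expr.values[probe], Xc, eigen, probe_id=probe)
    _, _, p = score_test(model, other_g)
    return p


def prune_to_eqtl_snps(
    sig_records: pd.DataFrame,
    geno,
    expr,
    covars: pd.DataFrame,
    K: KinshipMatrix | KinshipEigen,
    thresholds: dict,
    window_bp: int = 5_000_000,
    condition_on: str = "both",
) -> pd.DataFrame:
    """Collapse significant SNPs to lead eQTL-SNPs by conditional retest.

    Per probe, the most significant remaining SNP becomes a lead (ties
    broken by chromosome then position); every other significant SNP
    within ``window_bp`` of the lead on the same chromosome is retested
    with the lead dosage as an extra fixed covariate.  A SNP whose
    conditional p no longer passes the stored significance thresholds
    (``condition_on``: "both", "probe" or "global") is redundant and
    removed; survivors stay eligible to seed their own eQTL.  A
    conditional test that returns NaN (collinear with the lead) counts
    as redundant.

    Returns one row per retained eQTL-SNP: probe_id, lead_snp_id,
    chromosome, position_bp, p_lead, beta_lead, n_pruned, window_bp.
    """
    if sig_records.empty:
        return pd.DataFrame(
            columns=["probe_id", "lead_snp_id", "chromosome", "position_bp",
                     "p_lead", "beta_lead", "n_pruned", "window_bp"]
        )
    samples = expr.values.index
    if isinstance(K, KinshipMatrix):
        eigen = eigendecompose_kinship(
            KinshipMatrix(K.values.loc[samples, samples], K.source_snp_count)
        )
    else:
        eigen = K
    X = build_design(covars.loc[samples])
    snp_map = geno.snp_map

    def passes(p: float, probe: str) -> bool:
        if not np.isfinite(p):
            return False
        ok_probe = p <= thresholds["per_probe"].get(probe, -np.inf)
        ok_global = p <= thresholds["global"]
        if condition_on == "both":
            return ok_probe and ok_global
        if condition_on == "probe":
            return ok_probe
        if condition_on == "global":
            return ok_global
        raise ValueError(f"unknown condition_on {condition_on!r}")

    rows = []
    work = sig_records.merge(
        snp_map[["chromosome", "position_bp"]], left_on="snp_id", right_index=True
    )
    # stable chromosome ordering for tie-breaks: numeric where possible
    chrom_rank = {
        c: i for i, c in enumerate(
            sorted(snp_map["chromosome"].astype(str).unique(),
                   key=lambda c: (len(c), c))
        )
    }
    for probe, group in work.groupby("probe_id", sort=True):
        remaining = group.assign(
            _chrom_rank=group["chromosome"].astype(str).map(chrom_rank)
        ).sort_values(
            ["p_value", "_chrom_rank", "position_bp"], kind="mergesort"
        )
        while not remaining.empty:
            lead = remaining.iloc[0]
            lead_g = geno.dosages.loc[samples, lead["snp_id"]]
            in_window = (
                (remaining["chromosome"] == lead["chromosome"])
                & ((remaining["position_bp"] - lead["position_bp"]).abs() <= window_bp)
                & (remaining["snp_id"] != lead["snp_id"])
            )
            n_pruned = 0
            drop = [remaining.index[0]]
            for idx in remaining.index[in_window.to_numpy()]:
                other = remaining.loc[idx]
                p_cond = _conditional_p(
                    expr, X, eigen, probe, lead_g,
                    geno.dosages.loc[samples, other["snp_id"]],
                )
                if not passes(p_cond, probe):
                    drop.append(idx)
                    n_pruned += 1
            rows.append(
                {"probe_id": probe, "lead_snp_id": lead["snp_id"],
                 "chromosome": lead["chromosome"],
                 "position_bp": int(lead["position_bp"]),
                 "p_lead": lead["p_value"], "beta_lead": lead["beta_snp"],
                 "n_pruned": n_pruned, "window_bp": window_bp}
            )
            remaining = remaining.drop(index=drop)
    return pd.DataFrame(rows)


def classify_local_distant(
    eqtl: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    local_window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Label each eQTL as local or distant relative to its probe start.

    Local iff the SNP is on the probe's chromosome and within
    ``local_window_bp`` of the probe start (inclusive boundary);
    otherwise distant.  Probes without a genomic mapping get NA class
    and are excluded from positional summaries.  Adds columns
    regulation_class and distance_bp (NaN when on different chromosomes).
    """
    out = eqtl.copy()
    probe_chrom = out["probe_id"].map(probe_annotation["chromosome"])
    probe_start = pd.to_numeric(
        out["probe_id"].map(probe_annotation["start_bp"]), errors="coerce"
    )
    same = probe_chrom.astype("string") == out["chromosome"].astype("string")
    dist = (out["position_bp"] - probe_start).abs()
    out["distance_bp"] = dist.where(same)
    cls = np.where(
        probe_chrom.isna(), None,
        np.where(same & (dist <= local_window_bp), "local", "distant"),
    )
    out["regulation_class"] = cls
    return out


def snp_regulation_summary(classified: pd.DataFrame) -> pd.Series:
    """Per-SNP label over its probes: local, distant or both."""

    def label(classes: pd.Series) -> str:
        s = set(classes.dropna())
        if s == {"local"}:
            return "local"
        if s == {"distant"}:
            return "distant"
        return "both" if s else "unmapped"

    return classified.groupby("lead_snp_id")["regulation_class"].apply(label)


def effect_sd_ratio(beta_snp: float, probe_values: np.ndarray) -> float:
    """|SNP effect| / sample SD of the probe's expression (n-1 denominator)."""
    v = np.asarray(probe_values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 expression values")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.nan
    return abs(beta_snp) / sd


def chromosome_enrichment(
    feature_ids,
    background_ids,
    chromosome_of: pd.Series,
    class_of: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-chromosome enrichment of a feature set within a background.

    For each chromosome a 2x2 table (on/off chromosome x feature/other)
    is scored by one-sided Fisher exact tests for enrichment and for
    depletion.  When ``class_of`` labels features (e.g. local / distant
    / both), a chi-square test compares the on-chromosome class
    composition to the rest of the genome; chromosomes without features
    get NA there.
    """
    feature_ids = pd.Index(feature_ids).unique()
    background_ids = pd.Index(background_ids).unique()
    if not feature_ids.isin(background_ids).all():
        raise ValueError("feature set must be a subset of the background")
    chrom = chromosome_of.astype(str)
    feat_chrom = chrom.reindex(feature_ids)
    bg_chrom = chrom.reindex(background_ids)
    rows = []
    for c in sorted(bg_chrom.dropna().unique(), key=lambda c: (len(c), c)):
        a = int((feat_chrom == c).sum())  # feature on chromosome
        b = int((bg_chrom == c).sum()) - a  # non-feature on chromosome
        c_ = len(feature_ids) - a
        d = len(background_ids) - len(feature_ids) - b
        table = [[a, b], [c_, d]]
        _, p_enr = stats.fisher_exact(table, alternative="greater")
        _, p_dep = stats.fisher_exact(table, alternative="less")
        odds = (a * d) / (b * c_) if b * c_ > 0 else np.inf
        row = {
            "chromosome": c, "n_feature": a, "n_background": a + b,
            "odds_ratio": odds, "fisher_p_enrichment": p_enr,
            "fisher_p_depletion": p_dep, "chi2_p_composition": np.nan,
        }
        if class_of is not None:
            on = class_of.reindex(feature_ids)[feat_chrom == c].dropna()
            off = class_of.reindex(feature_ids)[feat_chrom != c].dropna()
            levels = sorted(set(on) | set(off))
            if len(on) and len(off) and len(levels) > 1:
                tab = np.array(
                    [[(on == l).sum() for l in levels],
                     [(off == l).sum() for l in levels]], dtype=float
                )
                keep = tab.sum(axis=0) > 0
                tab = tab[:, keep]
                if tab.shape[1] > 1:
                    row["chi2_p_composition"] = stats.chi2_contingency(tab)[1]
        rows.append(row)
    return pd.DataFrame(rows)
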