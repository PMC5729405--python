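"""Microarray-style expression preprocessing.

Single-channel intensity processing in three steps: normexp background
correction (normal + exponential convolution, method-of-moments fit per
array), log2 transform, quantile normalization across arrays, and a
negative-control based expression filter ("at least ``margin`` above the
per-array negative-control mean on at least ``min_arrays`` arrays").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RawIntensityMatrix",
    "ExpressionMatrix",
    "normexp_background",
    "quantile_normalize",
    "filter_expressed_probes",
    "preprocess_expression",
]

PROBE_CLASSES = ("experimental", "negative_control")


@dataclass
class RawIntensityMatrix:
    """Positive raw intensities (samples x probes) with probe classes."""

    values: pd.DataFrame
    probe_class: pd.Series  # per probe: experimental | negative_control

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("raw intensities must be strictly positive")
        unknown = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {unknown}")
        self.probe_class = self.probe_class.reindex(self.values.columns)

    @property
    def negative_controls(self) -> pd.Index:
        return self.probe_class.index[self.probe_class == "negative_control"]


@dataclass
class ExpressionMatrix:
    """Samples x probes log2 expression with probe annotation.

    ``probe_annotation`` is indexed by probe id with columns ``chromosome``,
    ``start_bp`` (1-based), ``strand``, ``gene_symbol`` (may be NA) and
    ``sense`` (True for sense-strand alignment).  Probes without a genomic
    mapping carry NA chromosome and are excluded from positional analyses.
    """

    values: pd.DataFrame
    probe_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        ann = self.probe_annotation
        mapped = ann["chromosome"].notna()
        if "start_bp" in ann and (ann.loc[mapped, "start_bp"] < 1).any():
            raise ValueError("probe start positions must be 1-based (>= 1)")

    @property
    def probes(self) -> pd.Index:
        return self.values.columns

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    def subset_probes(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, probes], self.probe_annotation.loc[probes]
        )


def _normexp_mom(x: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments fit of X = N(mu, sigma^2) + Exp(mean alpha).

    The exponential component carries all the skewness of the convolution:
    the third central moment of X equals 2 alpha^3, the variance is
    sigma^2 + alpha^2 and the mean mu + alpha.
    """
    m1 = x.mean()
    m2 = x.var(ddof=1)
    m3 = ((x - m1) ** 3).mean()
    alpha = (m3 / 2.0) ** (1.0 / 3.0) if m3 > 0 else np.sqrt(m2) * 0.1
    sigma2 = max(m2 - alpha**2, 1e-6 * m2)
    mu = m1 - alpha
    return mu, np.sqrt(sigma2), alpha


def _normexp_signal(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Posterior expected signal E[S | X = x] for the normexp model.

    a = x - mu - sigma^2/alpha; E[S|X] = a + sigma * phi(a/sigma)/Phi(a/sigma).
    Evaluated on the log scale for very negative a/sigma, where the naive
    ratio underflows but the true value decays smoothly toward zero.
    """
    a = x - mu - sigma**2 / alpha
    z = a / sigma
    ratio = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    out = a + sigma * ratio
    return np.maximum(out, 1e-10)


def normexp_background(raw: RawIntensityMatrix) -> RawIntensityMatrix:
    """Background-correct each array with the normexp convolution model.

    Fits (mu, sigma, alpha) per array by method of moments and replaces
    each intensity by the posterior mean of the signal component.  The
    transform is strictly positive and monotone nondecreasing in the raw
    intensity, so within-array ranks are preserved.  Arrays with zero
    variance are passed through unchanged with a warning.
    """
    corrected = raw.values.copy().astype(float)
    for sample in raw.values.index:
        x = raw.values.loc[sample].to_numpy(dtype=float)
        if np.ptp(x) == 0 or x.var(ddof=1) == 0:
            warnings.warn(
                f"array {sample!r} has zero variance; background correction skipped",
                stacklevel=2,
            )
            continue
        mu, sigma, alpha = _normexp_mom(x)
        corrected.loc[sample] = _normexp_signal(x, mu, sigma, alpha)
    return RawIntensityMatrix(values=corrected, probe_class=raw.probe_class)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every array (row) onto the mean empirical distribution.

    Each array's sorted values are replaced by the across-array mean of
    sorted values; ties within an array receive the mean of the reference
    values their rank span would have claimed, which keeps the operation
    deterministic and rank-preserving.
    """
    if values.shape[0] < 2:
        raise ValueError("quantile normalization needs >= 2 arrays")
    X = values.to_numpy(dtype=float)
    ref = np.sort(X, axis=1).mean(axis=0)  # reference distribution
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        order = np.argsort(X[i], kind="stable")
        row = np.empty_like(ref)
        row[order] = ref
        # average reference values over tie groups
        xs = X[i][order]
        start = 0
        for j in range(1, len(xs) + 1):
            if j == len(xs) or xs[j] != xs[start]:
                if j - start > 1:
                    row[order[start:j]] = ref[start:j].mean()
                start = j
        out[i] = row
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def filter_expressed_probes(
    raw: RawIntensityMatrix,
    min_arrays: int = 4,
    margin: float = 0.10,
    control_summary: str = "mean",
) -> tuple[pd.Index, pd.Series]:
    """Keep probes expressed above the negative-control background.

    A probe passes on an array when its intensity exceeds
    ``(1 + margin)`` times that array's negative-control summary (mean by
    default, median as a config alternative); it is kept when it passes
    on at least ``min_arrays`` arrays.  Returns the kept experimental
    probe ids and the per-probe pass count.
    """
    controls = raw.negative_controls
    if len(controls) == 0:
        raise ValueError("expression filter requires negative-control probes")
    ctrl = raw.values.loc[:, controls]
    if control_summary == "mean":
        level = ctrl.mean(axis=1)
    elif control_summary == "median":
        level = ctrl.median(axis=1)
    else:
        raise ValueError(f"unknown control summary {control_summary!r}")
    threshold = (1.0 + margin) * level
    experimental = raw.probe_class.index[raw.probe_class == "experimental"]
    passes = raw.values.loc[:, experimental].gt(threshold, axis=0)
    pass_counts = passes.sum(axis=0)
    kept = pass_counts.index[pass_counts >= min_arrays]
    return kept, pass_counts


def preprocess_expression(
    raw: RawIntensityMatrix,
    probe_annotation: pd.DataFrame,
    min_arrays: int = 4,
    margin: float = 0.10,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Full preprocessing chain: normexp -> filter -> log2 -> quantile.

    The expression filter operates on the background-corrected raw scale;
    the retained probes are then log2-transformed and quantile-normalized
    across arrays.  Returns the normalized matrix (experimental probes
    that passed the filter) and the per-probe pass counts.
    """
    corrected = normexp_background(raw)
    kept, pass_counts = filter_expressed_probes(corrected, min_arrays, margin)
    log2 = np.log2(corrected.values.loc[:, kept])
    norm = quantile_normalize(log2)
    ann = probe_annotation.reindex(kept)
    return ExpressionMatrix(values=norm, probe_annotation=ann), pass_counts
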