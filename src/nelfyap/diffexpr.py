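"""Minimal per-contrast differential-expression stage.

This is a deliberately small stand-in honouring the usual count-based DE
contract: median-of-ratios size factors, a log2 fold change of normalized
group means with a 0.5 pseudocount, and a Wald test of the log2 mean
difference using a method-of-moments negative-binomial variance (Poisson
fallback when the sample variance does not exceed the mean).  It performs no
shrinkage, outlier filtering or independent filtering; correctness is judged
by planted-effect recovery and null calibration, not by equality with any
particular DE package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CountMatrix

#: Contrast name -> (treated condition, control condition).
CONTRASTS = {
    "siNELFA": ("siNELFA", "siControl"),
    "siYAP": ("siYAP", "siControl"),
    "siNELFA_siYAP": ("siNELFA_siYAP", "siControl"),
}

_LN2_SQ = np.log(2.0) ** 2


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    The per-gene reference is the geometric mean across samples; genes with a
    zero count in any sample are excluded from the median.  Factors are
    rescaled to geometric mean 1.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("cannot normalize: no gene expressed in all samples")
    pos = counts[all_pos]
    log_ref = np.log(pos).mean(axis=1)
    ratios = np.log(pos) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def _group_matrix(m: CountMatrix, condition: str, factors: pd.Series) -> np.ndarray:
    samples = m.condition_samples(condition)
    if len(samples) < 2:
        raise ValueError(f"condition {condition!r} needs at least 2 replicates")
    norm = m.counts[samples].to_numpy(dtype=float) / factors[samples].to_numpy()
    return norm


def test_contrast(
    m: CountMatrix,
    treated: str,
    control: str,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene log2FC and Wald p-value for one treated-vs-control contrast.

    log2FC = log2((mean normalized treated + 0.5) / (mean normalized control
    + 0.5)).  The variance of each group mean uses a method-of-moments NB
    dispersion pooled across the two groups of the contrast and clamped at 0
    (the Poisson fallback); the Wald statistic on the log2 scale is referred
    to a t distribution with n_treated + n_control - 2 degrees of freedom.
    Genes whose counts are identical across both groups get log2FC 0, p 1 by
    convention.
    """
    if factors is None:
        factors = size_factors(m)
    t = _group_matrix(m, treated, factors)
    c = _group_matrix(m, control, factors)
    n_t, n_c = t.shape[1], c.shape[1]

    mean_t, mean_c = t.mean(axis=1), c.mean(axis=1)
    var_t, var_c = t.var(axis=1, ddof=1), c.var(axis=1, ddof=1)
    lfc = np.log2(mean_t + 0.5) - np.log2(mean_c + 0.5)

    # pooled MOM dispersion; alpha <= 0 means sample variance <= mean (Poisson)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_t = np.where(mean_t > 0, (var_t - mean_t) / np.square(mean_t), 0.0)
        a_c = np.where(mean_c > 0, (var_c - mean_c) / np.square(mean_c), 0.0)
    alpha = np.maximum((a_t + a_c) / 2.0, 0.0)
    v_t = (mean_t + alpha * mean_t**2) / n_t
    v_c = (mean_c + alpha * mean_c**2) / n_c
    se2 = v_t / (np.square(mean_t + 0.5) * _LN2_SQ) + v_c / (np.square(mean_c + 0.5) * _LN2_SQ)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se2 > 0, lfc / np.sqrt(se2), 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), df=n_t + n_c - 2)

    raw = m.counts[m.condition_samples(treated) + m.condition_samples(control)].to_numpy()
    flat = (raw == raw[:, [0]]).all(axis=1)
    lfc[flat] = 0.0
    p[flat] = 1.0
    base_mean = np.concatenate([t, c], axis=1).mean(axis=1)
    return pd.DataFrame(
        {"log2fc": lfc, "p": np.clip(p, 0.0, 1.0), "base_mean": base_mean},
        index=m.gene_ids,
    )


def contrast_table(m: CountMatrix) -> pd.DataFrame:
    """The full three-contrast table: log2fc_<c>, p_<c>, base_mean_<c>."""
    factors = size_factors(m)
    pieces = []
    for name, (treated, control) in CONTRASTS.items():
        part = test_contrast(m, treated, control, factors)
        part.columns = [f"{col}_{name}" for col in part.columns]
        pieces.append(part)
    return pd.concat(pieces, axis=1)


def significant_genes(table: pd.DataFrame, contrast: str, alpha: float = 0.05) -> set[str]:
    """Genes with nominal p < alpha in the contrast (strict inequality).

    No fold-change cutoff is applied at this step.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    col = f"p_{contrast}"
    if col not in table.columns:
        raise KeyError(f"unknown contrast: {contrast}")
    return set(table.index[table[col] < alpha])
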