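"""Count normalization, fold change and differential-expression calling.

Normalization follows the median-of-log-ratios scheme: per-sample size factors
s_j = exp(median_k ln(C_kj / geomean_k)) over reference genes (rows positive in
every sample, forced by the logarithm), and NC_kj = round(C_kj / s_j) with
round-half-to-even.  Fold change is the ratio of condition means of NC.  A gene
is called up when FC > 1.25 and BH-adjusted p < 0.05, down when FC < 0.8 and
BH-adjusted p < 0.05 (strict inequalities).

The significance test itself is a transparent negative-binomial Wald test with
pooled method-of-moments dispersion; it is pluggable via ``de_test(test=...)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SampleSheet

logger = logging.getLogger("methkey")

FC_UP = 1.25
FC_DOWN = 0.8
ALPHA = 0.05

#: dispersion floor for the method-of-moments estimate
MIN_DISPERSION = 1e-8


@dataclass
class SizeFactors:
    """Per-sample scaling factors s_j (> 0) and their logs eta_j."""

    s: pd.Series
    eta: pd.Series
    n_reference_genes: int


@dataclass
class DEResult:
    """Per-gene fold change, p-values and up/down/unchanged/untested status."""

    table: pd.DataFrame  # columns: FC, log2FC, pval, padj, status

    def genes_with_status(self, status: str) -> list[str]:
        t = self.table
        return list(t.index[t["status"] == status])


def size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-log-ratios size factors.

    Reference genes are those with positive counts in every sample; the
    geometric mean and the log ratios are undefined otherwise.
    """
    mat = counts.values.to_numpy(dtype=float)
    ref = (mat > 0).all(axis=1)
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ValueError(
            "no gene has positive counts in every sample; size factors need at "
            "least one all-positive reference gene (filter samples or genes first)"
        )
    refmat = mat[ref]
    log_geomean = np.log(refmat).mean(axis=1)  # per-gene ln geometric mean
    d = np.log(refmat) - log_geomean[:, None]  # d_kj = ln(C_kj / geomean_k)
    eta = np.median(d, axis=0)
    s = np.exp(eta)
    idx = counts.values.columns
    return SizeFactors(pd.Series(s, index=idx, name="s"),
                       pd.Series(eta, index=idx, name="eta"), n_ref)


def normalize(counts: CountMatrix, factors: SizeFactors) -> pd.DataFrame:
    """NC_kj = round(C_kj / s_j), round-half-to-even, as an integer frame."""
    if list(factors.s.index) != list(counts.values.columns):
        raise ValueError("size factors do not match the count matrix samples")
    scaled = counts.values.to_numpy(dtype=float) / factors.s.to_numpy()[None, :]
    nc = np.rint(scaled).astype(np.int64)
    return pd.DataFrame(nc, index=counts.values.index, columns=counts.values.columns)


def fold_change(norm: pd.DataFrame, sheet: SampleSheet) -> pd.Series:
    """Per-gene FC = mean(NC over cancer) / mean(NC over paracancer).

    A zero paracancer mean with a positive cancer mean yields +inf (logged);
    0/0 yields NaN.
    """
    t_cols = sheet.samples("cancer")
    p_cols = sheet.samples("paracancer")
    if not t_cols or not p_cols:
        raise ValueError("fold change requires samples of both conditions")
    mean_t = norm[t_cols].mean(axis=1)
    mean_p = norm[p_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_t / mean_p
    n_inf = int(np.isinf(fc).sum())
    if n_inf:
        logger.info("%d gene(s) with zero paracancer mean -> FC = +inf", n_inf)
    fc.name = "FC"
    return fc


def nb_wald_test(norm: pd.DataFrame, sheet: SampleSheet) -> pd.Series:
    """Two-sided negative-binomial Wald p-values on normalized counts.

    Per-gene dispersion is a pooled method-of-moments estimate
    alpha = (var - mean) / mean^2 averaged across the two groups and floored at
    ``MIN_DISPERSION``.  The Wald statistic compares log group means with
    delta-method standard errors; a zero group mean gets a 0.5 pseudo-mean for
    the test only.  Genes with zero counts everywhere return NaN (untested).
    """
    t_cols = sheet.samples("cancer")
    p_cols = sheet.samples("paracancer")
    if len(t_cols) < 2 or len(p_cols) < 2:
        raise ValueError("the Wald test needs >= 2 samples per condition")
    xt = norm[t_cols].to_numpy(dtype=float)
    xp = norm[p_cols].to_numpy(dtype=float)
    nt, npair = xt.shape[1], xp.shape[1]
    mt, mp_ = xt.mean(axis=1), xp.mean(axis=1)
    vt, vp = xt.var(axis=1, ddof=1), xp.var(axis=1, ddof=1)

    untested = (mt == 0) & (mp_ == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        at = (vt - mt) / mt**2
        ap = (vp - mp_) / mp_**2
    at = np.where(mt > 0, at, np.nan)
    ap = np.where(mp_ > 0, ap, np.nan)
    both = np.vstack([at, ap])
    all_nan = np.isnan(both).all(axis=0)
    both = np.where(np.isnan(both) & all_nan[None, :], 0.0, both)
    disp = np.nanmean(both, axis=0)
    disp[all_nan] = np.nan
    disp = np.where(np.isnan(disp), MIN_DISPERSION, np.maximum(disp, MIN_DISPERSION))

    mt_safe = np.where(mt > 0, mt, 0.5)
    mp_safe = np.where(mp_ > 0, mp_, 0.5)
    # Var(ln mean_S) ~= (mu + alpha mu^2) / (n_S mu^2)
    var_log = (1.0 / mt_safe + disp) / nt + (1.0 / mp_safe + disp) / npair
    z = (np.log(mt_safe) - np.log(mp_safe)) / np.sqrt(var_log)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.where(untested, np.nan, np.minimum(pval, 1.0))
    return pd.Series(pval, index=norm.index, name="pval")


def de_test(
    norm: pd.DataFrame,
    sheet: SampleSheet,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    alpha: float = ALPHA,
    test: Callable[[pd.DataFrame, SampleSheet], pd.Series] = nb_wald_test,
) -> DEResult:
    """Full differential-expression call: FC, p-values, BH adjustment, status.

    status is ``up`` iff FC > fc_up and padj < alpha, ``down`` iff FC < fc_down
    and padj < alpha, ``untested`` for genes with no counts anywhere, otherwise
    ``unchanged``.  BH adjustment runs over tested genes only.
    """
    fc = fold_change(norm, sheet)
    pval = test(norm, sheet)
    padj = pd.Series(np.nan, index=norm.index, name="padj")
    tested = pval.notna()
    if tested.any():
        padj.loc[tested] = multipletests(pval[tested].to_numpy(), method="fdr_bh")[1]

    with np.errstate(divide="ignore"):
        log2fc = np.log2(fc)
    status = pd.Series("unchanged", index=norm.index, name="status")
    status[~tested] = "untested"
    sig = padj < alpha  # NaN compares False
    status[(fc > fc_up) & sig] = "up"
    status[(fc < fc_down) & sig] = "down"
    table = pd.DataFrame(
        {"FC": fc, "log2FC": log2fc, "pval": pval, "padj": padj, "status": status}
    )
    logger.info(
        "DE: %d up, %d down, %d unchanged, %d untested",
        (status == "up").sum(), (status == "down").sum(),
        (status == "unchanged").sum(), (status == "untested").sum(),
    )
    return DEResult(table)
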