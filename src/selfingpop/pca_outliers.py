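"""PCA-based genome scan for excess differentiation.

Genotypes are centered and scaled by sqrt(p(1-p)), missing entries are
mean-imputed, and a truncated SVD yields K principal components capturing
population structure.  Each SNP is then regressed on the K per-sample score
vectors; the vector of K regression z-scores is summarized by a (robust)
Mahalanobis distance, recalibrated by the genomic inflation factor
lambda = median(stat) / median(chi^2_K) and converted to an upper-tail
chi^2_K p-value.  Because the empirical p-value distribution of such scans
is typically U-shaped, the primary output is the rank-based top-k set
(default k = 1000) rather than an FDR cut.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype import MISSING, GenotypeMatrix, ld_prune

__all__ = [
    "PCModel",
    "OutlierResult",
    "pca_fit",
    "outlier_stat",
    "outlier_region_pca",
    "parse_half_plane_rules",
]

log = logging.getLogger(__name__)


@dataclass
class PCModel:
    """Truncated-SVD population-structure model.

    ``scores`` columns are orthonormal left singular vectors (samples x K);
    per-site means/scales refer to the standardization used for the fit.
    """

    K: int
    scores: np.ndarray  # (n_samples, K), orthonormal columns
    singular_values: np.ndarray  # (K,)
    site_means: np.ndarray
    site_scales: np.ndarray
    fitted_sites: np.ndarray  # indices of sites used in the decomposition


@dataclass
class OutlierResult:
    """Per-site differentiation statistics.

    ``stat`` is the (robust) Mahalanobis distance of the K regression
    z-scores; NaN marks sites excluded as zero-variance.  ``rank`` is 1 for
    the most extreme site; ``top_k`` flags the rank-based outlier set.
    """

    stat: np.ndarray
    pvalue: np.ndarray
    rank: np.ndarray
    lambda_gc: float
    top_k: np.ndarray


def _standardize(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale haploid calls by sqrt(p(1-p)); mean-impute missing."""
    x = calls.astype(float)
    mask = calls == MISSING
    x[mask] = np.nan
    p = np.nanmean(x, axis=0)
    scale = np.sqrt(p * (1 - p))
    scale[scale == 0] = 1.0
    z = (x - p) / scale
    z[np.isnan(z)] = 0.0  # mean imputation after centering
    return z, p, scale


def pca_fit(
    g: GenotypeMatrix,
    K: int,
    clump_r2: float | None = 0.1,
    clump_window: int = 50,
    clump_step: int = 5,
) -> PCModel:
    """Fit a K-component PCA of the standardized genotype matrix.

    With ``clump_r2`` set, LD clumping (greedy window pruning at that r^2
    threshold) restricts the decomposition to quasi-independent SNPs; the
    outlier statistic is still computed for all sites afterwards.
    """
    if K >= min(g.n_samples, g.n_sites):
        raise ValueError("K must be smaller than both sample and site counts")
    if clump_r2 is not None:
        fitted = np.array(
            ld_prune(g, window_sites=clump_window, step_sites=clump_step, r2_max=clump_r2),
            dtype=np.int64,
        )
    else:
        fitted = np.arange(g.n_sites, dtype=np.int64)
    z, _, _ = _standardize(g.calls[:, fitted])
    # economy SVD of samples x sites matrix
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    zfull, means, scales = _standardize(g.calls)
    return PCModel(
        K=K,
        scores=u[:, :K],
        singular_values=s[:K],
        site_means=means,
        site_scales=scales,
        fitted_sites=fitted,
    )


def outlier_stat(
    g: GenotypeMatrix,
    model: PCModel,
    top_k: int = 1000,
    covariance: str = "robust",
) -> OutlierResult:
    """Differentiation statistic for every site given a fitted PC model.

    Each standardized SNP is regressed on the K orthonormal score vectors;
    the resulting z-scores are summarized by a Mahalanobis distance.  The
    default "robust" covariance is diagonal, estimated by per-component
    median and MAD across sites (components are near-uncorrelated after
    regression on orthonormal scores); "empirical" uses the full sample
    covariance.  Zero-variance sites are excluded (NaN).
    """
    z, _, _ = _standardize(g.calls)
    n, n_sites = z.shape
    K = model.K
    S = model.scores  # (n, K), orthonormal
    beta = S.T @ z  # (K, sites)
    obs_var = (g.calls != MISSING).any(axis=0)
    total_ss = (z**2).sum(axis=0)
    resid_ss = np.maximum(total_ss - (beta**2).sum(axis=0), 0.0)
    dof = max(n - K, 1)
    sigma2 = resid_ss / dof
    valid = obs_var & (total_ss > 0) & (sigma2 > 0)
    zscores = np.full((K, n_sites), np.nan)
    zscores[:, valid] = beta[:, valid] / np.sqrt(sigma2[valid])

    # the z-scores are centred at zero under the null by construction, and a
    # zero centre keeps the statistic invariant to per-site allele flips
    # (flipping negates a site's z-vector)
    zv = zscores[:, valid]
    if covariance == "robust":
        scale = np.median(np.abs(zv), axis=1) / 0.6745
        scale[scale == 0] = 1.0
        stat_valid = ((zv / scale[:, None]) ** 2).sum(axis=0)
    elif covariance == "empirical":
        second = (zv @ zv.T) / zv.shape[1]
        inv = np.linalg.pinv(np.atleast_2d(second))
        stat_valid = np.einsum("ks,kj,js->s", zv, inv, zv)
    else:
        raise ValueError(f"unknown covariance {covariance!r}")

    stat = np.full(n_sites, np.nan)
    stat[valid] = stat_valid
    lam = float(np.median(stat_valid) / stats.chi2.median(K))
    pval = np.full(n_sites, np.nan)
    pval[valid] = stats.chi2.sf(stat_valid / lam, df=K)
    pval[valid] = np.clip(pval[valid], np.finfo(float).tiny, 1.0)

    order = np.argsort(np.where(np.isnan(stat), -np.inf, stat))[::-1]
    rank = np.full(n_sites, n_sites + 1, dtype=np.int64)
    live = order[~np.isnan(stat[order])]
    rank[live] = np.arange(1, len(live) + 1)
    flag = rank <= top_k
    return OutlierResult(stat=stat, pvalue=pval, rank=rank, lambda_gc=lam, top_k=flag)


_RULE_RE = re.compile(r"PC(\d+)\s*(<=|>=|<|>)\s*(-?\d+(?:\.\d+)?)", re.IGNORECASE)


def parse_half_plane_rules(text: str) -> list[tuple[int, str, float]]:
    """Parse rules like "PC1 < 0 and PC2 > 0.07" into (component, op, value).

    Components are 1-based in the rule text.
    """
    clauses = re.split(r"\band\b", text, flags=re.IGNORECASE)
    out = []
    for clause in clauses:
        m = _RULE_RE.search(clause)
        if not m:
            raise ValueError(f"cannot parse rule clause {clause!r}")
        out.append((int(m.group(1)), m.group(2), float(m.group(3))))
    return out


def outlier_region_pca(
    g: GenotypeMatrix,
    outlier_sites: np.ndarray,
    group_rules: dict[str, str],
    K: int = 2,
) -> tuple[dict[str, str], np.ndarray]:
    """PCA restricted to outlier sites, with half-plane group labelling.

    No LD clumping is applied (the outlier set is already a focused region).
    ``group_rules`` maps a group name to a rule string such as
    "PC1 < 0 and PC2 > 0.07"; samples matching no rule are labelled
    "other".  Rules are applied in insertion order; first match wins.

    Returns (labels by sample id, sample scores).
    """
    outlier_sites = np.asarray(outlier_sites, dtype=np.int64)
    if len(outlier_sites) == 0:
        raise ValueError("outlier_sites must be non-empty")
    sub = g.take_sites(outlier_sites)
    z, _, _ = _standardize(sub.calls)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    K = min(K, len(s))
    scores = u[:, :K]
    parsed = {name: parse_half_plane_rules(r) for name, r in group_rules.items()}
    ops = {"<": np.less, ">": np.greater, "<=": np.less_equal, ">=": np.greater_equal}
    labels: dict[str, str] = {}
    for i, sample in enumerate(g.sample_ids):
        label = "other"
        for name, clauses in parsed.items():
            ok = True
            for comp, op, val in clauses:
                if comp > K:
                    raise ValueError(
                        f"rule references PC{comp} but only {K} components kept"
                    )
                if not ops[op](scores[i, comp - 1], val):
                    ok = False
                    break
            if ok:
                label = name
                break
        labels[sample] = label
    return labels, scores
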