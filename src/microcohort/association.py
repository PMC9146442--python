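"""Taxa-to-clinical association screens.

Spearman rank correlation with permutation p-values (exhaustive for tiny n,
Monte-Carlo otherwise), Benjamini-Hochberg FDR over the whole screen grid,
covariate-adjusted partial Spearman correlation, and canonical correlation
analysis between variable blocks with Bartlett's chi-square approximation
to Wilks' lambda for component significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_tables import AbundanceTable, ClinicalMetadata

__all__ = [
    "spearman",
    "permutation_pvalue",
    "bh_adjust",
    "partial_spearman",
    "AssociationMatrix",
    "association_grid",
    "CcaResult",
    "cca",
    "wilks_test",
]


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("spearman undefined for a constant vector")
    return x, y


def spearman(x, y) -> float:
    """Spearman rho: Pearson correlation of average ranks."""
    x, y = _check_pair(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _standardize_ranks(v: np.ndarray) -> np.ndarray:
    r = stats.rankdata(v)
    r = r - r.mean()
    return r / np.sqrt((r ** 2).sum())


def permutation_pvalue(
    x, y, b: int = 5000, seed: int | None = None, exhaustive_limit: int = 10_000
) -> float:
    """Two-sided permutation p-value for Spearman rho.

    Shuffles y while holding x fixed.  When n! <= ``exhaustive_limit`` the
    full permutation distribution is enumerated and p is the exact fraction
    with |rho_perm| >= |rho_obs| (the identity included); otherwise ``b``
    random shuffles give p = (1 + count) / (b + 1).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    x, y = _check_pair(x, y)
    n = x.size
    zx = _standardize_ranks(x)
    ry = stats.rankdata(y)
    zy = ry - ry.mean()
    zy = zy / np.sqrt((zy ** 2).sum())
    rho_obs = abs(float(zx @ zy))

    if factorial(n) <= exhaustive_limit:
        count = 0
        total = 0
        for perm in iter_permutations(range(n)):
            rho = abs(float(zx @ zy[list(perm)]))
            count += rho >= rho_obs - 1e-12
            total += 1
        return count / total

    rng = np.random.default_rng(seed)
    perm_matrix = np.tile(zy, (b, 1))
    perm_matrix = rng.permuted(perm_matrix, axis=1)
    rhos = np.abs(perm_matrix @ zx)
    count = int((rhos >= rho_obs - 1e-12).sum())
    return (1 + count) / (b + 1)


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a flat family of p-values.

    Returns (q_values, reject_mask); reject iff q <= fdr.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value family")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return q, q <= fdr


def partial_spearman(
    x, y, covariates=None, method: str = "analytic",
    b: int = 5000, seed: int | None = None,
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    All vectors are rank-transformed; the ranks of x and y are each
    least-squares projected onto the covariate ranks (plus intercept) and
    the Pearson correlation of the residuals is returned.  The p-value uses
    the t approximation with n - k - 2 degrees of freedom (k covariates);
    ``method='permutation'`` instead permutes the y residuals.
    """
    x, y = _check_pair(x, y)
    n = x.size
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        rho = spearman(x, y)
        k = 0
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
        k = c.shape[1]
        if n <= k + 2:
            raise ValueError("need n > #covariates + 2")
        c_ranks = np.column_stack([stats.rankdata(col) for col in c.T])
        design = np.column_stack([np.ones(n), c_ranks])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient covariates (constant or collinear column)")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        proj, *_ = np.linalg.lstsq(design, np.column_stack([rx, ry]), rcond=None)
        resid = np.column_stack([rx, ry]) - design @ proj
        denom = np.sqrt((resid[:, 0] ** 2).sum() * (resid[:, 1] ** 2).sum())
        if denom == 0:
            raise ValueError("degenerate residuals (x or y fully explained by covariates)")
        rho = float((resid[:, 0] * resid[:, 1]).sum() / denom)

    df = n - k - 2
    if method == "analytic":
        rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
        t = rho_c * np.sqrt(df / (1 - rho_c ** 2))
        p = float(2 * stats.t.sf(abs(t), df))
    elif method == "permutation":
        # permute y against x after removing covariate effects from both
        rng = np.random.default_rng(seed)
        if k == 0:
            p = permutation_pvalue(x, y, b=b, seed=seed)
        else:
            count = 0
            r0, r1 = resid[:, 0], resid[:, 1]
            z0 = r0 / np.sqrt((r0 ** 2).sum())
            z1 = r1 / np.sqrt((r1 ** 2).sum())
            for _ in range(b):
                count += abs(float(z0 @ rng.permutation(z1))) >= abs(rho) - 1e-12
            p = (1 + count) / (b + 1)
    else:
        raise ValueError("method must be 'analytic' or 'permutation'")
    return rho, min(p, 1.0)


@dataclass
class AssociationMatrix:
    """Taxa x variables screen: rho / permutation p / BH q grids plus a
    significance mask and per-cell complete-pair counts."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    significant: pd.DataFrame
    n_pairs: pd.DataFrame
    fdr: float
    b: int
    seed: int | None
    adjusted_for: list[str] = field(default_factory=list)

    def to_long(self) -> pd.DataFrame:
        records = []
        for taxon in self.rho.index:
            for var in self.rho.columns:
                records.append(
                    {
                        "taxon": taxon,
                        "variable": var,
                        "rho": self.rho.at[taxon, var],
                        "p": self.p.at[taxon, var],
                        "q": self.q.at[taxon, var],
                        "n_pairs": self.n_pairs.at[taxon, var],
                        "significant": bool(self.significant.at[taxon, var]),
                    }
                )
        return pd.DataFrame.from_records(records)


#: cells with fewer complete pairs than this are excluded from the screen
MIN_COMPLETE_PAIRS = 10


def association_grid(
    table: AbundanceTable,
    metadata: ClinicalMetadata,
    variables: list[str],
    b: int = 5000,
    fdr: float = 0.05,
    adjust_for: list[str] | None = None,
    seed: int | None = None,
) -> AssociationMatrix:
    """Screen every taxon against every clinical variable.

    Unadjusted cells get Spearman rho with a permutation p-value
    (``b`` shuffles of the clinical variable); with ``adjust_for`` the
    partial Spearman with the analytic t p-value is used.  Missing
    metadata is handled by pairwise-complete deletion; cells with fewer
    than 10 complete pairs are flagged NaN and excluded from the BH family,
    which spans the whole grid.
    """
    if table.mode != "relative":
        raise ValueError("association_grid expects a relative-abundance table")
    missing = [v for v in variables if v not in metadata.data.columns]
    if missing:
        raise ValueError(f"metadata lacks variables: {missing}")
    if adjust_for:
        missing = [v for v in adjust_for if v not in metadata.data.columns]
        if missing:
            raise ValueError(f"metadata lacks adjustment covariates: {missing}")
    meta = metadata.data.loc[table.sample_ids]

    taxa = table.taxon_ids
    shape = (len(taxa), len(variables))
    rho = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    n_pairs = np.zeros(shape, dtype=int)
    rng = np.random.default_rng(seed)

    for j, var in enumerate(variables):
        yv = meta[var].to_numpy(dtype=float)
        cov = (
            meta[list(adjust_for)].to_numpy(dtype=float) if adjust_for else None
        )
        for i, taxon in enumerate(taxa):
            xv = table.data[taxon].to_numpy(dtype=float)
            mask = np.isfinite(xv) & np.isfinite(yv)
            if cov is not None:
                mask &= np.isfinite(cov).all(axis=1)
            n_pairs[i, j] = int(mask.sum())
            if n_pairs[i, j] < MIN_COMPLETE_PAIRS:
                continue
            xs, ys = xv[mask], yv[mask]
            if len(np.unique(xs)) < 2 or len(np.unique(ys)) < 2:
                continue
            cell_seed = int(rng.integers(0, 2**31 - 1))
            if adjust_for:
                rho[i, j], p[i, j] = partial_spearman(xs, ys, cov[mask])
            else:
                rho[i, j] = spearman(xs, ys)
                p[i, j] = permutation_pvalue(xs, ys, b=b, seed=cell_seed)

    flat_p = p.ravel()
    tested = np.isfinite(flat_p)
    q = np.full(flat_p.shape, np.nan)
    sig = np.zeros(flat_p.shape, dtype=bool)
    if tested.any():
        q[tested], sig[tested] = bh_adjust(flat_p[tested], fdr=fdr)
    q = q.reshape(shape)
    sig = sig.reshape(shape)

    idx = pd.Index(taxa, name="taxon")
    cols = pd.Index(variables, name="variable")
    return AssociationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        q=pd.DataFrame(q, index=idx, columns=cols),
        significant=pd.DataFrame(sig, index=idx, columns=cols),
        n_pairs=pd.DataFrame(n_pairs, index=idx, columns=cols),
        fdr=fdr,
        b=b,
        seed=seed,
        adjusted_for=list(adjust_for or []),
    )


@dataclass
class CcaResult:
    correlations: np.ndarray   # r_1 >= r_2 >= ... >= 0
    x_weights: np.ndarray      # p x s
    y_weights: np.ndarray      # q x s
    wilks: pd.DataFrame        # per component: lambda, chi2, df, p, degenerate
    n: int


def cca(x_block, y_block) -> CcaResult:
    """Canonical correlation analysis between two variable blocks.

    Columns are standardized internally; canonical correlations and weights
    come from the SVD of the whitened cross-covariance
    Sxx^{-1/2} Sxy Syy^{-1/2}.  Component significance is assessed with
    :func:`wilks_test`.
    """
    x = np.asarray(x_block, dtype=float)
    y = np.asarray(y_block, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("blocks must be 2-D with matching sample counts")
    n, p = x.shape
    q = y.shape[1]
    if n <= p + q + 1:
        raise ValueError(f"need n > p + q + 1 (n={n}, p={p}, q={q})")
    for name, block in (("X", x), ("Y", y)):
        if (block.std(axis=0) == 0).any():
            raise ValueError(f"constant column in {name} block")

    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    ys = (y - y.mean(axis=0)) / y.std(axis=0, ddof=1)
    sxx = xs.T @ xs / (n - 1)
    syy = ys.T @ ys / (n - 1)
    sxy = xs.T @ ys / (n - 1)

    def inv_sqrt(m: np.ndarray) -> np.ndarray:
        vals, vecs = np.linalg.eigh(m)
        if (vals <= 1e-12).any():
            raise ValueError("singular within-block covariance (collinear columns)")
        return vecs @ np.diag(vals ** -0.5) @ vecs.T

    kx = inv_sqrt(sxx)
    ky = inv_sqrt(syy)
    u, svals, vt = np.linalg.svd(kx @ sxy @ ky)
    s = min(p, q)
    r = np.clip(svals[:s], 0.0, 1.0)
    x_w = kx @ u[:, :s]
    y_w = ky @ vt.T[:, :s]
    wilks = wilks_test(r, n, p, q)
    return CcaResult(correlations=r, x_weights=x_w, y_weights=y_w, wilks=wilks, n=n)


def wilks_test(canonical_correlations, n: int, p: int, q: int) -> pd.DataFrame:
    """Bartlett chi-square test of Wilks' lambda per canonical component.

    For component k, Lambda_k = prod_{i>=k} (1 - r_i^2) tests that the k-th
    and all later canonical correlations are zero;
    chi2 = -(n - 1 - (p + q + 1)/2) ln Lambda_k with (p-k+1)(q-k+1) df.
    A correlation of exactly 1 collapses Lambda to 0 and is flagged.
    """
    r = np.asarray(canonical_correlations, dtype=float)
    if ((r < 0) | (r > 1)).any():
        raise ValueError("canonical correlations must lie in [0, 1]")
    s = r.size
    factor = n - 1 - (p + q + 1) / 2.0
    rows = []
    for k in range(1, s + 1):
        tail = r[k - 1:]
        degenerate = bool((tail >= 1.0).any())
        lam = float(np.prod(1.0 - tail ** 2))
        df = (p - k + 1) * (q - k + 1)
        if degenerate or lam <= 0:
            chi2, pval = np.inf, 0.0
        else:
            chi2 = -factor * np.log(lam)
            pval = float(stats.chi2.sf(chi2, df))
        rows.append((k, lam, chi2, df, pval, degenerate))
    return pd.DataFrame(
        rows, columns=["component", "wilks_lambda", "chi2", "df", "p", "degenerate"]
    ).set_index("component")
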