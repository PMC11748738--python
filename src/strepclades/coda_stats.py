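"""Compositionally-aware statistics for read-count tables.

Read counts from shotgun metagenomics carry no information about absolute
abundance — only about ratios — so ordinary correlations on raw counts or
proportions are spurious.  All association measures here therefore operate
on the centred log-ratio (CLR) transform

    y_i = ln( (x_i + pc) / g(x + pc) ),   g = geometric mean over features,

which is invariant to per-sample rescaling of the counts.  On CLR values we
provide Pearson correlation (with t-distribution p-values and optional
Benjamini-Hochberg correction across all pairs), the proportionality
coefficient

    rho(i, j) = 1 - var(y_i - y_j) / (var(y_i) + var(y_j))
              = 2 cov(y_i, y_j) / (var(y_i) + var(y_j)),

a permutation-based FDR cutoff for |rho|, PCA of the CLR table with a
low-abundance filter, and a canonical-correlation screen of metadata
variables against a block of composition columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .table_io import SpeciesTable

logger = logging.getLogger(__name__)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return pd.DataFrame(np.asarray(matrix, dtype=float))


def clr_transform(counts, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform of a samples x features count matrix.

    A pseudocount (default 1 read) is added before closure so zero counts
    are representable.  Rows of the result sum to zero.
    """
    df = _as_frame(counts)
    if df.shape[1] == 0:
        raise ValueError("no features to transform")
    x = df.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("NaN in count matrix")
    if x.min() < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (x == 0).any():
        raise ValueError("pseudocount 0 requires strictly positive counts")
    if x.size and (x.sum(axis=1) == 0).all():
        raise ValueError("all samples are empty: nothing to transform")
    logx = np.log(x + pseudocount)
    y = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(y, index=df.index, columns=df.columns)


@dataclass
class CorrelationResult:
    feature_a: str
    feature_b: str
    method: str
    rho: float
    p: float | None = None
    q: float | None = None
    significant: bool | None = None


def clr_pearson(
    clr_matrix,
    pair: tuple[str, str] | None = None,
    *,
    alpha: float = 0.05,
) -> CorrelationResult | pd.DataFrame:
    """Pearson correlation on CLR columns with two-sided t-test p-values.

    With ``pair`` given, returns the single :class:`CorrelationResult`.
    Otherwise all feature pairs are tested and Benjamini-Hochberg-corrected
    q-values are attached.  Zero-variance columns yield NaN with a flag.
    """
    df = _as_frame(clr_matrix)
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 samples")

    def one(a: str, b: str) -> CorrelationResult:
        xa, xb = df[a].to_numpy(), df[b].to_numpy()
        if np.std(xa) == 0 or np.std(xb) == 0:
            logger.warning("zero-variance column in pair (%s, %s)", a, b)
            return CorrelationResult(a, b, "clr_pearson", np.nan, np.nan)
        r, p = stats.pearsonr(xa, xb)
        return CorrelationResult(a, b, "clr_pearson", float(r), float(p))

    if pair is not None:
        res = one(*pair)
        if not np.isnan(res.p):
            res.significant = res.p < alpha
        return res

    cols = list(df.columns)
    results = [one(cols[i], cols[j]) for i in range(len(cols))
               for j in range(i + 1, len(cols))]
    out = pd.DataFrame(
        {
            "feature_a": [r.feature_a for r in results],
            "feature_b": [r.feature_b for r in results],
            "method": "clr_pearson",
            "rho": [r.rho for r in results],
            "p": [r.p for r in results],
        }
    )
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out


def proportionality_rho(clr_matrix) -> pd.DataFrame:
    """Pairwise proportionality coefficient matrix on CLR columns.

    rho = 2 cov / (var + var); exactly 1 on the diagonal, symmetric, NaN for
    zero-variance pairs.
    """
    df = _as_frame(clr_matrix)
    if len(df) < 3:
        raise ValueError("need at least 3 samples")
    y = df.to_numpy(dtype=float)
    cov = np.cov(y, rowvar=False)
    var = np.diag(cov).copy()
    denom = var[:, None] + var[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = 2.0 * cov / denom
    rho[denom == 0] = np.nan
    np.fill_diagonal(rho, 1.0)
    bad = var == 0
    if bad.any():
        logger.warning("%d zero-variance features -> NaN rho", int(bad.sum()))
        rho[bad, :] = np.nan
        rho[:, bad] = np.nan
        np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def fdr_cutoff(
    clr_matrix,
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int | None = None,
    grid_step: float = 0.05,
) -> tuple[float | None, pd.DataFrame]:
    """Permutation FDR cutoff for the absolute proportionality coefficient.

    The null is built by independently permuting every feature column across
    samples.  For each cutoff c on a grid, FDR(c) is the mean permutation
    count of |rho_null| >= c divided by the observed count of |rho_obs| >= c
    (floored at 1).  Returns the smallest cutoff with FDR <= alpha that
    still retains at least one observed pair — a cutoff selecting nothing
    controls nothing — or ``None`` if no cutoff below 1 attains the target,
    plus the full per-cutoff table.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    df = _as_frame(clr_matrix)
    rng = np.random.default_rng(seed)

    def upper(rho: pd.DataFrame) -> np.ndarray:
        a = rho.to_numpy()
        return np.abs(a[np.triu_indices_from(a, k=1)])

    obs = upper(proportionality_rho(df))
    grid = np.round(np.arange(grid_step, 1.0, grid_step), 10)
    null_counts = np.zeros((n_perm, len(grid)))
    y = df.to_numpy()
    for b in range(n_perm):
        perm = np.column_stack(
            [rng.permutation(y[:, j]) for j in range(y.shape[1])]
        )
        nb = upper(proportionality_rho(pd.DataFrame(perm)))
        null_counts[b] = [(nb >= c).sum() for c in grid]
    obs_counts = np.array([(obs >= c).sum() for c in grid])
    fdr = null_counts.mean(axis=0) / np.maximum(obs_counts, 1)
    table = pd.DataFrame(
        {"cutoff": grid, "n_observed": obs_counts,
         "mean_null": null_counts.mean(axis=0), "fdr": fdr}
    )
    attained = table.loc[(table["fdr"] <= alpha) & (table["n_observed"] > 0),
                         "cutoff"]
    cutoff = float(attained.iloc[0]) if len(attained) else None
    if cutoff is None:
        logger.info("no cutoff below 1 attains FDR <= %.3g", alpha)
    return cutoff, table


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def clr_pca(
    table: SpeciesTable | pd.DataFrame,
    min_abundance_pct: float = 0.001,
    n_components: int | None = None,
    pseudocount: float = 1.0,
) -> PcaResult:
    """PCA of the CLR-transformed species table after a low-abundance filter.

    Features whose mean relative abundance across samples is below
    ``min_abundance_pct`` percent are removed (spurious low-abundance hits),
    then the CLR table is column-centred and decomposed by SVD.  Component
    signs follow a fixed convention: the largest-magnitude loading of each
    component is positive.
    """
    if isinstance(table, SpeciesTable):
        counts = table.species_view().counts.T  # samples x species
    else:
        counts = _as_frame(table)
    totals = counts.sum(axis=1).astype(float)
    rel = counts.div(totals.where(totals > 0), axis=0) * 100.0
    keep = rel.mean(axis=0) >= min_abundance_pct
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 features remain after the {min_abundance_pct}% filter"
        )
    filtered = counts.loc[:, keep]
    y = clr_transform(filtered, pseudocount=pseudocount).to_numpy()
    y = y - y.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    # sign convention: largest |loading| positive per component
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    var = s**2 / max(len(y) - 1, 1)
    evr = var / var.sum()
    comp = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=counts.index, columns=comp),
        loadings=pd.DataFrame(
            vt[:k].T, index=filtered.columns, columns=comp
        ),
        explained_variance_ratio=evr[:k],
    )


def _first_canonical_correlation(x: np.ndarray, yblock: np.ndarray) -> float:
    """Largest canonical correlation between two column blocks."""
    xc = x - x.mean(axis=0)
    yc = yblock - yblock.mean(axis=0)
    qx, rx = np.linalg.qr(xc)
    qy, ry = np.linalg.qr(yc)
    # drop rank-deficient directions
    keep_x = np.abs(np.diag(rx)) > 1e-10 * max(1.0, np.abs(np.diag(rx)).max())
    keep_y = np.abs(np.diag(ry)) > 1e-10 * max(1.0, np.abs(np.diag(ry)).max())
    if not keep_x.any() or not keep_y.any():
        return np.nan
    s = np.linalg.svd(qx[:, keep_x].T @ qy[:, keep_y], compute_uv=False)
    return float(min(s[0], 1.0))


def cancor_pairs(
    metadata: pd.DataFrame,
    block: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    min_cc: float = 0.4,
    max_p: float = 0.01,
) -> pd.DataFrame:
    """Screen metadata variables against a composition block by canonical
    correlation.

    Each variable (categoricals expanded to indicators, reference level
    dropped) is tested against the block; the p-value comes from seeded
    permutations of the variable's sample labels.  A variable is flagged
    significant only when the canonical correlation is at least ``min_cc``
    *and* the permutation p-value is at most ``max_p`` — association
    screening is deliberately conservative.
    """
    rng = np.random.default_rng(seed)
    results = []
    for var in metadata.columns:
        col = metadata[var]
        complete = col.notna() & block.notna().all(axis=1)
        n_complete = int(complete.sum())
        if n_complete < 5:
            raise ValueError(
                f"variable {var!r}: only {n_complete} complete cases (need >= 5)"
            )
        sub = col[complete]
        yb = block.loc[complete].to_numpy(dtype=float)
        if pd.api.types.is_numeric_dtype(sub):
            x = sub.to_numpy(dtype=float)[:, None]
        else:
            x = pd.get_dummies(sub, drop_first=True).to_numpy(dtype=float)
        if x.shape[1] == 0 or np.allclose(x.std(axis=0), 0):
            logger.warning("variable %r is constant; NA", var)
            results.append((var, np.nan, np.nan, False, n_complete))
            continue
        cc = _first_canonical_correlation(x, yb)
        n_ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(x))
            if _first_canonical_correlation(x[perm], yb) >= cc:
                n_ge += 1
        p = (1 + n_ge) / (1 + n_perm)
        results.append((var, cc, p, bool(cc >= min_cc and p <= max_p), n_complete))
    return pd.DataFrame(
        results, columns=["variable", "canonical_correlation", "p",
                          "significant", "n"]
    )
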