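"""Two-group differential-abundance testing with rank-based effect sizes.

Features (taxa or genes) are first prevalence-filtered, then compared
between two sample groups with the two-sided Wilcoxon rank-sum test.  The
effect size is the standardised statistic r = |Z| / sqrt(N) (with Z from the
tie-corrected normal approximation), p-values are Benjamini-Hochberg
corrected across features, and a feature is flagged *enriched* only when
q < 0.05 and r >= 0.4 — a double threshold that requires both statistical
and practical significance.  Gene tables are normalised to reads per
kilobase before testing so gene length does not masquerade as abundance.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Default double threshold for the enrichment flag.
DEFAULT_Q = 0.05
DEFAULT_EFFECT = 0.4

#: Use the exact rank-sum null (no ties) at or below this total sample size.
EXACT_N_MAX = 12


def prevalence_filter(
    matrix: pd.DataFrame, min_prevalence: float = 0.30
) -> tuple[pd.DataFrame, int]:
    """Drop features (columns) present (> 0) in fewer than ``min_prevalence``
    of samples.  Returns the filtered matrix and the number removed."""
    if not 0.0 < min_prevalence <= 1.0:
        raise ValueError(f"min_prevalence must be in (0, 1]: {min_prevalence}")
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(matrix)
    if (df.to_numpy() < 0).any():
        raise ValueError("matrix values must be >= 0")
    prevalence = (df > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "prevalence filter (%.0f%%): removed %d of %d features",
            100 * min_prevalence, removed, df.shape[1],
        )
    return df.loc[:, keep], removed


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected, continuity-corrected normal approximation.

    Returns (W, Z) where W is the Mann-Whitney U of the first group.
    """
    n1, n2 = len(x), len(y)
    both = np.concatenate([x, y])
    ranks = stats.rankdata(both)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(both, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u1), 0.0
    # continuity correction toward the mean
    cc = 0.5 * np.sign(u1 - mu) if u1 != mu else 0.0
    z = (u1 - mu - cc) / math.sqrt(sigma2)
    return float(u1), float(z)


def wilcoxon_enrichment(
    matrix: pd.DataFrame,
    groups: pd.Series,
    *,
    q_threshold: float = DEFAULT_Q,
    effect_threshold: float = DEFAULT_EFFECT,
) -> pd.DataFrame:
    """Per-feature two-group Wilcoxon rank-sum test with effect sizes.

    ``matrix`` is samples x features; ``groups`` a two-level factor over the
    same samples.  The exact null distribution is used for small samples
    (N <= 12, no ties); otherwise the tie-corrected normal approximation
    with continuity correction.  Constant features get p = 1, effect 0.
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(matrix)
    groups = pd.Series(groups).reindex(df.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"groups must have exactly two levels, got {levels}")
    g1, g2 = levels
    idx1, idx2 = groups == g1, groups == g2
    n1, n2 = int(idx1.sum()), int(idx2.sum())
    if min(n1, n2) < 2:
        raise ValueError("both groups need at least 2 samples")
    n = n1 + n2

    rows = []
    for feat in df.columns:
        x = df.loc[idx1, feat].to_numpy(dtype=float)
        y = df.loc[idx2, feat].to_numpy(dtype=float)
        if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
            rows.append((feat, x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1),
                         n1 * n2 / 2.0, 0.0, 0.0, 1.0, "none"))
            continue
        w, z = _ranksum_z(x, y)
        ties = len(np.unique(np.concatenate([x, y]))) < n
        if n <= EXACT_N_MAX and not ties:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact").pvalue)
        else:
            p = float(2.0 * stats.norm.sf(abs(z)))
        direction = g1 if z > 0 else (g2 if z < 0 else "none")
        rows.append((feat, x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1),
                     w, z, abs(z) / math.sqrt(n), min(p, 1.0), direction))

    out = pd.DataFrame(
        rows,
        columns=["feature", f"mean_{g1}", f"sd_{g1}", f"mean_{g2}", f"sd_{g2}",
                 "W", "Z", "effect_r", "p", "direction"],
    )
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched"] = (out["q"] < q_threshold) & (out["effect_r"] >= effect_threshold)
    return out


def rpk_normalize(
    gene_counts: pd.DataFrame, gene_lengths_bp: pd.Series
) -> pd.DataFrame:
    """Reads-per-kilobase normalisation: reads / (length / 1000).

    ``gene_counts`` is samples x genes; ``gene_lengths_bp`` maps each gene
    column to its length in base pairs (all > 0).
    """
    df = gene_counts if isinstance(gene_counts, pd.DataFrame) else pd.DataFrame(gene_counts)
    lengths = pd.Series(gene_lengths_bp).reindex(df.columns)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"missing gene lengths for: {missing[:5]}")
    if (lengths <= 0).any():
        bad = lengths[lengths <= 0].index.tolist()
        raise ValueError(f"non-positive gene lengths for: {bad[:5]}")
    return df / (lengths / 1000.0)
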