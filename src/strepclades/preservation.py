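"""Cumulative-percent-decay preservation QC for oral metagenomes.

Ancient dental calculus (and poorly stored modern samples) can be overgrown
by soil or skin taxa.  A simple, robust screen: rank a sample's taxa by
decreasing abundance and track, as the rank k grows, the percentage of the
top-k taxa that belong to a reference set of known oral taxa.  Well-preserved
samples keep that percentage high; contaminated samples decay quickly
because abundant non-oral taxa crowd the top ranks.

The pass/fail rule here is the simple-threshold variant: after a burn-in
rank (the first few ranks are noisy), the curve must stay at or above a
minimum percentage at every rank.  Thresholds are configurable per sample
group, since ancient, modern-human and non-human-primate samples have
different baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default simple-threshold parameters per sample group.
DEFAULT_BURN_IN_RANK = 10
DEFAULT_MIN_PERCENT = {"ancient": 50.0, "modern": 65.0}


@dataclass
class DecayCurve:
    sample_id: str
    taxa: list[str]          # ranked by decreasing abundance
    percent: np.ndarray      # cumulative % of top-k taxa in the oral set

    def __len__(self) -> int:
        return len(self.taxa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "rank": np.arange(1, len(self.taxa) + 1),
                "taxon": self.taxa,
                "percent_oral": self.percent,
            }
        )


def decay_curve(
    sample_abundances: pd.Series,
    oral_reference: set[str],
    sample_id: str = "",
) -> DecayCurve:
    """Cumulative oral-taxon percentage along the abundance ranking.

    Taxa with zero abundance are dropped; remaining taxa are ranked by
    decreasing abundance (ties broken lexicographically); at rank k the
    curve value is 100 * |top-k taxa in the reference| / k.
    """
    if not oral_reference:
        raise ValueError("oral reference set is empty")
    ab = pd.Series(sample_abundances).astype(float)
    ab = ab[ab > 0]
    if ab.empty:
        raise ValueError(f"sample {sample_id!r} has no non-zero taxa")
    ranked = ab.sort_index().sort_values(ascending=False, kind="mergesort")
    taxa = list(ranked.index)
    in_ref = np.array([t in oral_reference for t in taxa], dtype=float)
    percent = 100.0 * np.cumsum(in_ref) / np.arange(1, len(taxa) + 1)
    return DecayCurve(sample_id=sample_id, taxa=taxa, percent=percent)


def assess_preservation(
    curve: DecayCurve,
    burn_in_rank: int = DEFAULT_BURN_IN_RANK,
    min_percent: float = 50.0,
) -> bool:
    """Pass iff the curve stays at or above ``min_percent`` at every rank
    from ``burn_in_rank`` on."""
    if burn_in_rank < 1:
        raise ValueError("burn_in_rank must be >= 1")
    if burn_in_rank > len(curve):
        raise ValueError(
            f"burn_in_rank {burn_in_rank} beyond curve length {len(curve)}"
        )
    tail = curve.percent[burn_in_rank - 1:]
    return bool((tail >= min_percent).all())


def screen_cohort(
    abundances: pd.DataFrame,
    oral_reference: set[str],
    groups: pd.Series | None = None,
    burn_in_rank: int = DEFAULT_BURN_IN_RANK,
    min_percent: float | dict[str, float] | None = None,
) -> pd.DataFrame:
    """Run the decay-curve screen over a samples x taxa abundance table.

    ``min_percent`` may be a single threshold or a per-group mapping used
    together with ``groups`` (each sample's group selects its threshold).
    Returns a per-sample table with the pass flag and the curve minimum
    after burn-in.
    """
    if min_percent is None:
        min_percent = dict(DEFAULT_MIN_PERCENT)
    rows = []
    for sample in abundances.index:
        curve = decay_curve(abundances.loc[sample], oral_reference, sample)
        if isinstance(min_percent, dict):
            if groups is None:
                raise ValueError("per-group thresholds require `groups`")
            thr = min_percent[str(groups.loc[sample])]
        else:
            thr = float(min_percent)
        burn = min(burn_in_rank, len(curve))
        ok = assess_preservation(curve, burn, thr)
        rows.append(
            (sample, ok, float(curve.percent[burn - 1:].min()), thr, len(curve))
        )
    return pd.DataFrame(
        rows, columns=["sample", "passed", "min_percent_after_burnin",
                       "threshold", "n_taxa"],
    ).set_index("sample")
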