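"""Cohort-calibration summaries computed end-to-end on synthetic data.

Each function here regenerates the relevant default synthetic group(s) from
a seed, runs the real analysis stages on them, and returns the summary
quantity the generator is calibrated to: the Sanguinis-Anginosus CLR
correlations and the dominance split in the ancient cohort, multi-seed group
means of genus/clade/species shares, and the buccal industrialisation effect
size.  They are the single implementation used by the reproduction script
and the calibration tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coda_stats import clr_pearson, clr_transform, proportionality_rho
from .group_tests import wilcoxon_enrichment
from .profiles import clade_shares, cohort_summary, dominant_clade, species_shares
from .synthetic_data import default_config, focal_clade_map, generate_cohort


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """n child seeds (< 2**31) from one master seed, stable across runs."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def ancient_clade_correlations(seed: int) -> dict[str, float]:
    """CLR-Pearson and proportionality between Sanguinis and Anginosus clade
    counts across the default ancient-calculus cohort (n = 483)."""
    table, _ = generate_cohort(default_config(), seed=seed,
                               groups=["ancient_calculus"])
    profile = clade_shares(table, focal_clade_map())
    clr = clr_transform(profile.clade_counts, pseudocount=1)
    pearson = clr_pearson(clr, ("Sanguinis", "Anginosus"))
    prop = proportionality_rho(clr).loc["Sanguinis", "Anginosus"]
    return {
        "pearson_rho": float(pearson.rho),
        "pearson_p": float(pearson.p),
        "proportionality_rho": float(prop),
        "n": len(profile.sample_ids),
    }


def ancient_dominance_percent(seed: int) -> dict[str, float]:
    """Percentage of ancient-calculus samples whose dominant clade is
    Anginosus (plurality of layer-1 shares)."""
    table, _ = generate_cohort(default_config(), seed=seed,
                               groups=["ancient_calculus"])
    profile = clade_shares(table, focal_clade_map())
    summary = cohort_summary(dominant_clade(profile))
    return {
        "anginosus_percent": float(100.0 * summary.fractions["Anginosus"]),
        "n": summary.n,
    }


#: metric name -> (group, extractor); values returned as percent
GROUP_MEAN_METRICS = {
    "buccal_industrial_genus_share": ("buccal_industrial", "genus_share", None),
    "buccal_nonindustrial_genus_share": ("buccal_nonindustrial", "genus_share", None),
    "ancient_calculus_mitis_share": ("ancient_calculus", "clade_share", "Mitis"),
    "plaque_industrial_mitis_share": ("plaque_industrial", "clade_share", "Mitis"),
    "vervet_swab_genus_share": ("vervet_swab", "genus_share", None),
    "chimp_calculus_genus_share": ("chimp_calculus", "genus_share", None),
    "plaque_nonindustrial_sinensis_share": (
        "plaque_nonindustrial", "species_share", "Streptococcus sinensis"
    ),
}


def group_mean_percent(
    metric: str, master_seed: int, n_seeds: int = 20
) -> dict[str, float]:
    """Multi-seed mean (in percent) of one calibrated group-level share.

    ``metric`` is a key of :data:`GROUP_MEAN_METRICS`; the group is
    regenerated under ``n_seeds`` derived seeds and the per-sample shares
    pooled, reporting mean, SD and the standard error of the mean.
    """
    group, kind, arg = GROUP_MEAN_METRICS[metric]
    clades = focal_clade_map()
    values: list[float] = []
    for child in derive_seeds(master_seed, n_seeds):
        table, _ = generate_cohort(default_config(), seed=child, groups=[group])
        profile = clade_shares(table, clades)
        if kind == "genus_share":
            v = profile.genus_share
        elif kind == "clade_share":
            v = profile.clade_share_of_genus[arg]
        else:
            v = species_shares(table)[arg]
        values.extend(100.0 * v.dropna().to_numpy())
    arr = np.asarray(values)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)),
        "se": float(arr.std(ddof=1) / np.sqrt(len(arr))),
        "n": len(arr),
    }


def buccal_effect_size(seed: int) -> dict[str, float]:
    """Wilcoxon rank-sum effect size r = |Z|/sqrt(N) for genus-level
    *Streptococcus* share, industrial vs non-industrial buccal mucosa."""
    table, metadata = generate_cohort(
        default_config(), seed=seed,
        groups=["buccal_industrial", "buccal_nonindustrial"],
    )
    profile = clade_shares(table, focal_clade_map())
    feats = pd.DataFrame({"genus_share": profile.genus_share})
    res = wilcoxon_enrichment(feats, metadata["group"])
    return {
        "effect_r": float(res["effect_r"].iloc[0]),
        "p": float(res["p"].iloc[0]),
        "n": len(feats),
    }
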