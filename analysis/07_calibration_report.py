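#!/usr/bin/env python
"""Calibration report: the generator's summary statistics vs its targets.

Recomputes every calibrated quantity (dominance split, CLR correlations,
multi-seed group means, buccal effect size) through the analysis stages and
tabulates them next to the configured targets, writing
results/calibration_report.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from strepclades.calibration import (
    ancient_clade_correlations,
    ancient_dominance_percent,
    buccal_effect_size,
    group_mean_percent,
)
from strepclades.table_io import write_long_results

TARGETS = {
    "ancient CLR-Pearson Sanguinis~Anginosus": -0.68,
    "ancient proportionality Sanguinis~Anginosus": -0.67,
    "ancient Anginosus-dominant %": 14.7,
    "buccal industrial genus share %": 39.0,
    "buccal non-industrial genus share %": 16.0,
    "ancient calculus Mitis share %": 13.0,
    "industrial plaque Mitis share %": 43.0,
    "vervet swab genus share %": 59.0,
    "chimp calculus genus share %": 0.33,
    "non-industrial plaque S. sinensis share %": 11.0,
    "buccal industrialisation effect size r": 0.76,
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    corr = ancient_clade_correlations(args.seed)
    dom = ancient_dominance_percent(args.seed)
    eff = buccal_effect_size(args.seed)
    rows = [
        ("ancient CLR-Pearson Sanguinis~Anginosus", corr["pearson_rho"]),
        ("ancient proportionality Sanguinis~Anginosus",
         corr["proportionality_rho"]),
        ("ancient Anginosus-dominant %", dom["anginosus_percent"]),
        ("buccal industrialisation effect size r", eff["effect_r"]),
    ]
    for label, metric in [
        ("buccal industrial genus share %", "buccal_industrial_genus_share"),
        ("buccal non-industrial genus share %",
         "buccal_nonindustrial_genus_share"),
        ("ancient calculus Mitis share %", "ancient_calculus_mitis_share"),
        ("industrial plaque Mitis share %", "plaque_industrial_mitis_share"),
        ("vervet swab genus share %", "vervet_swab_genus_share"),
        ("chimp calculus genus share %", "chimp_calculus_genus_share"),
        ("non-industrial plaque S. sinensis share %",
         "plaque_nonindustrial_sinensis_share"),
    ]:
        rows.append((label, group_mean_percent(metric, args.seed)["mean"]))

    report = pd.DataFrame(rows, columns=["quantity", "measured"])
    report["target"] = report["quantity"].map(TARGETS)
    report["measured"] = report["measured"].round(4)
    write_long_results(report, args.out / "calibration_report.tsv",
                       sort_keys=["quantity"])
    print(report.to_string(index=False))


if __name__ == "__main__":
    main()
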