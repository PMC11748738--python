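"""End-to-end orchestration of the analysis stages.

``run_all`` executes, in fixed order: simulate (or ingest) -> preservation
QC -> ANI clade assignment -> clade profiles and dominance -> CoDA
correlations -> two-group enrichment -> cohort summary, writing one TSV per
stage plus a JSON run manifest.  Every stage is a pure function of (inputs,
config, seed): per-stage seeds are derived from the master seed through a
named, stable derivation, logging goes to standard error, and a rerun with
the same config and seed reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .table_io import (
    read_clade_map,
    read_metadata,
    read_mpa_table,
    write_clade_map,
    write_long_results,
    write_metadata,
    write_mpa_table,
    write_ani_matrix,
)
from .clade_assignment import assign_clades, cluster_species
from .coda_stats import clr_pearson, clr_transform, fdr_cutoff, proportionality_rho
from .group_tests import wilcoxon_enrichment
from .preservation import screen_cohort
from .profiles import (
    clade_shares,
    cohort_summary,
    dominant_clade,
    sample_ordering_key,
    species_shares,
)
from .synthetic_data import (
    default_config,
    focal_clade_map,
    generate_ani,
    generate_cohort,
    oral_reference_species,
)

logger = logging.getLogger(__name__)

DEFAULT_RUN_CONFIG = {
    "simulate": True,
    "seed": 0,
    "focal_genus": "Streptococcus",
    "stages": {
        "qc": True,
        "assign": True,
        "profile": True,
        "correlate": True,
        "enrich": True,
        "summary": True,
    },
    "qc": {"burn_in_rank": 10, "min_percent": {"ancient": 50.0, "modern": 65.0}},
    "correlate": {"pair": ["Sanguinis", "Anginosus"], "n_perm": 50},
    "enrich": {
        "metric": "genus_share",
        "groups": ["buccal_industrial", "buccal_nonindustrial"],
        "factor": "group",
    },
    "inputs": {"mpa": None, "metadata": None, "clade_map": None, "ani": None},
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derivation: crc32 of the stage name mixed into
    the master seed through a SeedSequence (always below 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path], counts: dict[str, int],
               elapsed: float) -> None:
        self.stages.append(
            {
                "stage": stage,
                "outputs": {k: str(v) for k, v in outputs.items()},
                "record_counts": counts,
                "elapsed_s": round(elapsed, 3),
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "version": self.version,
                    "stages": self.stages,
                },
                indent=2,
            )
            + "\n"
        )


def load_run_config(path: str | Path | None) -> dict:
    config = json.loads(json.dumps(DEFAULT_RUN_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def run_all(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "results",
    seed: int | None = None,
) -> RunManifest:
    """Run every enabled stage and write outputs plus a manifest.

    ``config`` may be a YAML path or an already-loaded dict; ``seed``
    overrides the config seed.  Any stage error aborts the run with a
    stage-tagged message and an ``incomplete`` marker in the manifest
    directory.
    """
    if not isinstance(config, dict):
        config = load_run_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    master = int(config["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_hash(config), master, __version__)
    incomplete = out / "INCOMPLETE"
    incomplete.write_text("run in progress\n")
    focal = config["focal_genus"]
    stages_on = config["stages"]

    try:
        # ------------------------------------------------ simulate / ingest
        t0 = time.time()
        if config.get("simulate", True):
            table, metadata = generate_cohort(
                default_config(), seed=stage_seed(master, "simulate")
            )
            clades = focal_clade_map()
        else:
            inputs = config["inputs"]
            table = read_mpa_table(inputs["mpa"])
            metadata = read_metadata(inputs["metadata"])
            clades = read_clade_map(inputs["clade_map"])
        write_mpa_table(table, out / "species_table.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        manifest.record(
            "simulate" if config.get("simulate", True) else "ingest",
            {"species_table": out / "species_table.tsv",
             "metadata": out / "metadata.tsv"},
            {"taxa": len(table.lineages), "samples": len(table.sample_ids)},
            time.time() - t0,
        )

        # ------------------------------------------------------------- qc
        if stages_on.get("qc", True):
            t0 = time.time()
            species = table.species_view()
            names = species.species_names()
            ab = species.counts.set_axis(
                [names[lin] for lin in species.counts.index], axis=0
            ).T
            qc_groups = metadata.reindex(ab.index)["group"].map(
                lambda g: "ancient" if g in ("ancient", "nhp") else "modern"
            )
            qc = screen_cohort(
                ab, oral_reference_species(), qc_groups,
                burn_in_rank=int(config["qc"]["burn_in_rank"]),
                min_percent=config["qc"]["min_percent"],
            )
            write_long_results(qc.reset_index(), out / "preservation_qc.tsv",
                               sort_keys=["sample"])
            keep = qc.index[qc["passed"]]
            table = table.subset_samples(list(keep))
            metadata = metadata.loc[keep]
            manifest.record(
                "qc", {"preservation_qc": out / "preservation_qc.tsv"},
                {"passed": int(qc["passed"].sum()), "failed": int((~qc["passed"]).sum())},
                time.time() - t0,
            )

        # --------------------------------------------------------- assign
        if stages_on.get("assign", True):
            t0 = time.time()
            planted = generate_ani(seed=stage_seed(master, "assign"))
            clusters = cluster_species(planted.ani)
            assigned = assign_clades(clusters, planted.references)
            write_ani_matrix(planted.ani, out / "ani_matrix.tsv")
            write_clade_map(assigned, out / "genome_clades.tsv")
            manifest.record(
                "assign",
                {"ani_matrix": out / "ani_matrix.tsv",
                 "genome_clades": out / "genome_clades.tsv"},
                {"genomes": planted.ani.n_genomes,
                 "clusters": len(clusters.cluster_ids)},
                time.time() - t0,
            )

        # -------------------------------------------------------- profile
        profile = clade_shares(table, clades, focal)
        if stages_on.get("profile", True):
            t0 = time.time()
            long = profile.to_long()
            dom = dominant_clade(profile)
            order = sample_ordering_key(profile)
            per_sample = pd.DataFrame(
                {"dominant_clade": dom, "order_key": order}
            ).reset_index(names="sample")
            write_long_results(long, out / "clade_profiles.tsv",
                               sort_keys=["sample", "layer", "clade"])
            write_long_results(per_sample, out / "dominance.tsv",
                               sort_keys=["sample"])
            sp = species_shares(table, focal)
            write_long_results(
                sp.reset_index(names="sample").melt(
                    id_vars="sample", var_name="species", value_name="share"
                ),
                out / "species_shares.tsv", sort_keys=["sample", "species"],
            )
            manifest.record(
                "profile",
                {"clade_profiles": out / "clade_profiles.tsv",
                 "dominance": out / "dominance.tsv",
                 "species_shares": out / "species_shares.tsv"},
                {"profile_rows": len(long), "samples": len(dom)},
                time.time() - t0,
            )

        # ------------------------------------------------------ correlate
        if stages_on.get("correlate", True):
            t0 = time.time()
            ancient = metadata.index[metadata["group"] == "ancient"]
            counts = profile.clade_counts.loc[
                profile.clade_counts.index.intersection(ancient)
            ]
            if len(counts) >= 3:
                clr = clr_transform(counts)
                pear = clr_pearson(clr)
                rho = proportionality_rho(clr)
                a, b = config["correlate"]["pair"]
                cutoff, fdr_table = fdr_cutoff(
                    clr, n_perm=int(config["correlate"]["n_perm"]),
                    seed=stage_seed(master, "correlate"),
                )
                pear["prop_rho"] = [
                    rho.loc[r.feature_a, r.feature_b] for r in pear.itertuples()
                ]
                pear["prop_fdr_cutoff"] = np.nan if cutoff is None else cutoff
                pear["prop_significant"] = (
                    False if cutoff is None else pear["prop_rho"].abs() >= cutoff
                )
                write_long_results(pear, out / "clade_correlations.tsv",
                                   sort_keys=["feature_a", "feature_b"])
                write_long_results(fdr_table, out / "prop_fdr_table.tsv",
                                   sort_keys=[])
                key = pear[
                    ((pear.feature_a == a) & (pear.feature_b == b))
                    | ((pear.feature_a == b) & (pear.feature_b == a))
                ]
                manifest.record(
                    "correlate",
                    {"clade_correlations": out / "clade_correlations.tsv",
                     "prop_fdr_table": out / "prop_fdr_table.tsv"},
                    {"pairs": len(pear),
                     "focal_pair_rho_x1000": int(round(1000 * key["rho"].iloc[0]))},
                    time.time() - t0,
                )

        # --------------------------------------------------------- enrich
        if stages_on.get("enrich", True):
            t0 = time.time()
            ecfg = config["enrich"]
            cohorts = metadata["cohort"] if "cohort" in metadata else metadata["group"]
            sel = cohorts.isin(ecfg["groups"])
            if sel.sum() >= 4 and metadata.loc[sel, ecfg["factor"]].nunique() == 2:
                feats = pd.DataFrame({"genus_share": profile.genus_share[sel]})
                res = wilcoxon_enrichment(feats, metadata.loc[sel, ecfg["factor"]])
                write_long_results(res, out / "enrichment.tsv", sort_keys=["feature"])
                manifest.record(
                    "enrich", {"enrichment": out / "enrichment.tsv"},
                    {"features": len(res)}, time.time() - t0,
                )

        # -------------------------------------------------------- summary
        if stages_on.get("summary", True):
            t0 = time.time()
            dom = dominant_clade(profile)
            rows = []
            key = metadata["cohort"] if "cohort" in metadata else metadata["group"]
            for cohort, sub in dom.groupby(key.reindex(dom.index)):
                summ = cohort_summary(sub).to_frame().reset_index()
                summ.insert(0, "cohort", cohort)
                rows.append(summ)
            summary = pd.concat(rows, ignore_index=True)
            write_long_results(summary, out / "dominance_summary.tsv",
                               sort_keys=["cohort", "clade"])
            manifest.record(
                "summary", {"dominance_summary": out / "dominance_summary.tsv"},
                {"rows": len(summary)}, time.time() - t0,
            )
    except Exception as exc:
        logger.error("pipeline aborted at stage boundary: %s", exc)
        raise
    else:
        incomplete.unlink(missing_ok=True)

    manifest.write(out / "run_manifest.json")
    return manifest
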