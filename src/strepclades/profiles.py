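"""Per-sample clade abundance layers, dominance calls and cohort summaries.

Three proportion layers are computed per sample, all on species-level read
assignments (genus-level reads not resolved to a species are excluded from
every denominator):

* layer 1, ``clade_share_of_genus`` — share of focal-genus reads per clade;
* layer 2, ``genus_share``          — share of all species-level reads that
  belong to the focal genus (equivalently, the focal genus's share of all
  genus assignments derived from species rows);
* layer 3, ``clade_share_of_species`` — share of all species-level reads per
  clade, so that summing layer 3 over clades recovers layer 2.

A sample's *dominant* clade is the plurality (argmax) clade of layer 1 —
dominance in the ecological sense of "most reads", with no numeric cutoff.
Ties are broken by a fixed clade precedence so calls are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table_io import CLADE_LABELS, CladeMap, SpeciesTable

logger = logging.getLogger(__name__)

#: Tie-break precedence for dominance calls (highest first).
DOMINANCE_PRECEDENCE = (
    "Sanguinis",
    "Mitis",
    "Anginosus",
    "Salivarius",
    "Mutans",
    "Bovis",
    "Pyogenic",
    "Downei",
    "Other",
    "Unknown",
)


@dataclass
class CladeProfile:
    """The three abundance layers for one cohort (samples x clades)."""

    clade_share_of_genus: pd.DataFrame
    genus_share: pd.Series
    clade_share_of_species: pd.DataFrame
    clade_counts: pd.DataFrame
    focal_genus: str

    @property
    def sample_ids(self) -> list[str]:
        return list(self.genus_share.index)

    def to_long(self) -> pd.DataFrame:
        """Long-format (sample, layer, clade, value) records."""
        rows = []
        for layer, df in (
            ("clade_share_of_genus", self.clade_share_of_genus),
            ("clade_share_of_species", self.clade_share_of_species),
        ):
            long = df.reset_index(names="sample").melt(
                id_vars="sample", var_name="clade", value_name="value"
            )
            long.insert(1, "layer", layer)
            rows.append(long)
        gs = self.genus_share.rename("value").rename_axis("sample").reset_index()
        gs.insert(1, "layer", "genus_share")
        gs.insert(2, "clade", self.focal_genus)
        rows.append(gs)
        return pd.concat(rows, ignore_index=True)


def clade_shares(
    table: SpeciesTable,
    clades: CladeMap,
    focal_genus: str = "Streptococcus",
) -> CladeProfile:
    """Compute all three abundance layers for every sample.

    Focal-genus species missing from the clade map are counted under
    "Unknown" with a warning.  Samples with zero species-level reads get NA
    in every layer (and will be called dominance "none").
    """
    species = table.species_view()
    genus = species.genus_of_species()
    names = species.species_names()

    focal_mask = (genus == focal_genus).to_numpy()
    if not focal_mask.any():
        logger.warning("no species of genus %s in table", focal_genus)

    clade_of_row = np.array(
        [
            clades.get(names[lin], "Unknown") if focal_mask[i] else ""
            for i, lin in enumerate(species.lineages)
        ],
        dtype=object,
    )
    uncovered = sorted(
        {names[lin] for i, lin in enumerate(species.lineages)
         if focal_mask[i] and names[lin] not in clades}
    )
    if uncovered:
        logger.warning(
            "%d %s species not in clade map, counted as Unknown: %s",
            len(uncovered), focal_genus, uncovered[:5],
        )

    counts = species.counts
    total_species = counts.sum(axis=0).astype(float)  # per sample
    focal_counts = counts.loc[focal_mask]
    clade_counts = (
        focal_counts.groupby(pd.Series(clade_of_row[focal_mask],
                                       index=focal_counts.index)).sum()
        .T.reindex(columns=list(CLADE_LABELS), fill_value=0)
        .astype(float)
    )
    clade_counts.index.name = "sample"

    focal_total = clade_counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        layer1 = clade_counts.div(focal_total.where(focal_total > 0), axis=0)
        genus_share = focal_total / total_species.where(total_species > 0)
        layer3 = clade_counts.div(total_species.where(total_species > 0), axis=0)

    empty = total_species == 0
    if empty.any():
        logger.warning(
            "%d samples have zero species-level reads; all layers NA",
            int(empty.sum()),
        )
    genus_share.name = "genus_share"
    return CladeProfile(
        clade_share_of_genus=layer1,
        genus_share=genus_share,
        clade_share_of_species=layer3,
        clade_counts=clade_counts,
        focal_genus=focal_genus,
    )


def species_shares(
    table: SpeciesTable,
    focal_genus: str = "Streptococcus",
) -> pd.DataFrame:
    """Per-sample share of focal-genus reads held by each focal species
    (samples x species).  Zero-genus samples are NA."""
    species = table.species_view()
    genus = species.genus_of_species()
    names = species.species_names()
    focal = species.counts.loc[(genus == focal_genus).to_numpy()]
    focal = focal.set_axis([names[lin] for lin in focal.index], axis=0)
    total = focal.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (focal / total.where(total > 0)).T


def log10p1(percent_matrix) -> np.ndarray | pd.DataFrame:
    """Heatmap transform: elementwise log10(x + 1) on *percent* values.

    0% maps to 0 and 99% maps to 2, compressing the dynamic range for
    display.  Negative input is an error.
    """
    values = np.asarray(percent_matrix, dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("percent values must be >= 0")
    out = np.log10(values + 1.0)
    if isinstance(percent_matrix, (pd.DataFrame, pd.Series)):
        return percent_matrix.__class__(
            out, index=percent_matrix.index,
            **({"columns": percent_matrix.columns}
               if isinstance(percent_matrix, pd.DataFrame) else {}),
        )
    return out


def dominant_clade(profile: CladeProfile) -> pd.Series:
    """Dominant (plurality) clade per sample; "none" where the sample has no
    focal-genus reads.  Ties go to the earlier clade in the precedence."""
    shares = profile.clade_share_of_genus[list(DOMINANCE_PRECEDENCE)]
    arr = shares.to_numpy(dtype=float)
    labels = []
    for row in arr:
        if np.isnan(row).all() or np.nansum(row) == 0:
            labels.append("none")
        else:
            labels.append(DOMINANCE_PRECEDENCE[int(np.nanargmax(row))])
    return pd.Series(labels, index=shares.index, name="dominant_clade")


@dataclass
class DominanceSummary:
    counts: pd.Series
    fractions: pd.Series
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": self.counts,
                "fraction": self.fractions,
                "percent": 100.0 * self.fractions,
            }
        ).rename_axis("clade")


def cohort_summary(labels: pd.Series) -> DominanceSummary:
    """Counts and fractions of samples dominated by each clade.

    Invariant to sample order; fractions sum to 1 over the labels present.
    """
    order = list(DOMINANCE_PRECEDENCE) + ["none"]
    counts = labels.value_counts().reindex(order, fill_value=0)
    n = int(counts.sum())
    fractions = counts / n if n else counts.astype(float)
    return DominanceSummary(counts=counts, fractions=fractions, n=n)


def sample_ordering_key(profile: CladeProfile) -> pd.Series:
    """Figure-reproduction ordering: decreasing Sanguinis share, then
    increasing Anginosus share."""
    l1 = profile.clade_share_of_genus
    key = l1[["Sanguinis", "Anginosus"]].copy()
    order = key.sort_values(
        ["Sanguinis", "Anginosus"], ascending=[False, True], kind="mergesort"
    ).index
    return pd.Series(np.arange(len(order)), index=order, name="order").reindex(
        l1.index
    )


def top_species(
    table: SpeciesTable,
    clades: CladeMap,
    clade: str,
    *,
    restrict_to_dominant: bool = True,
    focal_genus: str = "Streptococcus",
) -> tuple[pd.DataFrame, pd.Series]:
    """Most-abundant species of a clade per sample, plus a cohort tally.

    Per sample the species of ``clade`` with maximal reads is reported (ties
    resolved to the lexicographically first species and flagged).  The tally
    is the fraction of samples whose top species is each species; by default
    it is restricted to samples where ``clade`` is the dominant clade.
    """
    clade_species = sorted(s for s, c in clades.labels.items() if c == clade)
    if not clade_species:
        raise ValueError(f"clade {clade!r} has no species in the clade map")
    species = table.species_view()
    names = species.species_names()
    mask = np.array([names[lin] in set(clade_species) for lin in species.lineages])
    sub = species.counts.loc[mask]
    sub = sub.set_axis([names[lin] for lin in sub.index], axis=0).sort_index()

    rows = []
    for sample in sub.columns:
        col = sub[sample]
        if col.sum() == 0:
            rows.append((sample, None, 0, False))
            continue
        best = col.max()
        winners = col[col == best].index.tolist()
        rows.append((sample, winners[0], int(best), len(winners) > 1))
    per_sample = pd.DataFrame(
        rows, columns=["sample", "top_species", "reads", "tie"]
    ).set_index("sample")

    keep = per_sample["top_species"].notna()
    if restrict_to_dominant:
        profile = clade_shares(table, clades, focal_genus)
        dom = dominant_clade(profile)
        keep &= dom.reindex(per_sample.index) == clade
    tallied = per_sample.loc[keep, "top_species"]
    tally = (
        tallied.value_counts(normalize=True).sort_index()
        if len(tallied)
        else pd.Series(dtype=float)
    )
    return per_sample, tally
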