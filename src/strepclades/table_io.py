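"""Readers and writers for the tabular artifacts of the pipeline.

The central exchange format is the "mpa" taxonomy table produced by joining
Kraken-style per-sample reports: one row per taxon, the first column a
rank-prefixed, pipe-separated lineage string (``d__Bacteria|...|s__...``),
and one integer read-count column per sample.  GTDB-style rank prefixes are
assumed (``d__`` through ``s__``); a legacy ``k__`` kingdom prefix is
accepted as an alias for the domain rank.  GTDB polyphyly suffixes
("Streptococcus oralis_S") are kept verbatim as distinct species.

Also handled here: square pairwise-ANI matrices, per-sample metadata,
species-to-clade maps, and generic long-format result tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Rank prefixes in lineage order.  ``k__`` is normalised to ``d__`` on read.
RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

RANK_NAMES = {
    "d__": "domain",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}

#: The recognised clade labels: eight named phylogenetic clades plus the two
#: catch-all labels used for genomes that cannot be placed in a named clade.
CLADE_LABELS = (
    "Sanguinis",
    "Mitis",
    "Salivarius",
    "Anginosus",
    "Bovis",
    "Pyogenic",
    "Mutans",
    "Downei",
    "Other",
    "Unknown",
)

PROVENANCE_FLAGS = ("named_reference", "propagated", "other_rule", "unknown_rule")


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


def _terminal_rank(lineage: str) -> str:
    last = lineage.split("|")[-1]
    for prefix in RANK_PREFIXES:
        if last.startswith(prefix):
            return RANK_NAMES[prefix]
    raise TableFormatError(f"unrecognised rank prefix in lineage component {last!r}")


def _component(lineage: str, prefix: str) -> str | None:
    for part in lineage.split("|"):
        if part.startswith(prefix):
            return part[len(prefix):]
    return None


@dataclass
class SpeciesTable:
    """A taxa x samples read-count matrix with lineage annotations.

    ``counts`` is indexed by the full lineage string; ``rank`` gives the
    terminal rank of every row.  Counts are non-negative integers and are
    never modified by views — subsetting only filters rows.
    """

    counts: pd.DataFrame
    rank: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise TableFormatError(f"duplicate lineage string: {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise TableFormatError("negative read counts")
        self.counts.index.name = "lineage"
        if self.rank is None:
            self.rank = pd.Series(
                [_terminal_rank(lin) for lin in self.counts.index],
                index=self.counts.index,
                name="rank",
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lineages(self) -> list[str]:
        return list(self.counts.index)

    def at_rank(self, rank: str) -> "SpeciesTable":
        """Rows whose terminal rank is *rank* (counts untouched)."""
        mask = self.rank == rank
        return SpeciesTable(self.counts.loc[mask], self.rank[mask])

    def species_view(self) -> "SpeciesTable":
        return self.at_rank("species")

    def species_names(self) -> pd.Series:
        """Terminal species name per species-level row, indexed by lineage."""
        sp = self.counts.index[self.rank == "species"]
        return pd.Series({lin: _component(lin, "s__") for lin in sp}, name="species")

    def genus_of_species(self) -> pd.Series:
        """Genus of every species-level row, taken from the ``g__`` component
        of its own lineage (never parsed out of the species name)."""
        sp = self.counts.index[self.rank == "species"]
        out = {}
        for lin in sp:
            genus = _component(lin, "g__")
            if genus is None:
                raise TableFormatError(
                    f"species lineage lacks a genus component: {lin!r}"
                )
            out[lin] = genus
        return pd.Series(out, name="genus")

    def subset_samples(self, sample_ids: Sequence[str]) -> "SpeciesTable":
        missing = set(sample_ids) - set(self.counts.columns)
        if missing:
            raise KeyError(f"samples not in table: {sorted(missing)}")
        return SpeciesTable(self.counts[list(sample_ids)], self.rank)


def read_mpa_table(path: str | Path) -> SpeciesTable:
    """Read a joined mpa-format taxonomy table.

    The first column (``#Classification`` or unnamed) holds lineage strings;
    the remaining columns are per-sample integer read counts.  Duplicate
    lineages and non-numeric cells are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: no sample columns found")
    lineage_col = df.columns[0]
    lineages = df[lineage_col].str.strip()
    # normalise the k__ kingdom alias to the GTDB d__ domain prefix
    lineages = lineages.str.replace(r"(^|\|)k__", r"\1d__", regex=True)
    if lineages.duplicated().any():
        dup = lineages[lineages.duplicated()].iloc[0]
        raise TableFormatError(f"{path}: duplicate lineage string: {dup!r}")
    counts = df.drop(columns=[lineage_col])
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise TableFormatError(
            f"{path}: non-numeric count at row {lineages.iloc[bad[0]]!r}, "
            f"column {counts.columns[bad[1]]!r}: {counts.iloc[bad[0], bad[1]]!r}"
        )
    numeric.index = lineages
    numeric.index.name = "lineage"
    return SpeciesTable(numeric.round().astype(np.int64))


def write_mpa_table(table: SpeciesTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = "#Classification"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Per-sample metadata keyed by ``sample_id`` (first column)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise TableFormatError(f"{path}: duplicate sample_id {dup!r}")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def check_metadata_covers(table: SpeciesTable, metadata: pd.DataFrame) -> None:
    missing = set(table.sample_ids) - set(metadata.index)
    if missing:
        raise TableFormatError(
            f"samples absent from metadata: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )


# ---------------------------------------------------------------------------
# clade maps


@dataclass
class CladeMap:
    """Mapping from species name to clade label with per-entry provenance."""

    labels: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.labels.values() if c not in CLADE_LABELS}
        if bad:
            raise TableFormatError(f"unrecognised clade labels: {sorted(bad)}")
        for name in self.labels:
            self.provenance.setdefault(name, "named_reference")

    def __getitem__(self, species: str) -> str:
        return self.labels[species]

    def __contains__(self, species: str) -> bool:
        return species in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, species: str, default: str | None = None) -> str | None:
        return self.labels.get(species, default)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.labels)
        return pd.DataFrame(
            {
                "species": rows,
                "clade": [self.labels[s] for s in rows],
                "provenance": [self.provenance.get(s, "named_reference") for s in rows],
            }
        )


def read_clade_map(path: str | Path) -> CladeMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "species" not in cols or "clade" not in cols:
        raise TableFormatError(f"{path}: expected 'species' and 'clade' columns")
    labels = dict(zip(df[cols["species"]], df[cols["clade"]]))
    if len(labels) != len(df):
        raise TableFormatError(f"{path}: duplicate species entries")
    prov = (
        dict(zip(df[cols["species"]], df[cols["provenance"]]))
        if "provenance" in cols
        else {}
    )
    return CladeMap(labels, prov)


def write_clade_map(clades: CladeMap, path: str | Path) -> None:
    clades.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ANI matrices


def read_ani_matrix(
    path: str | Path,
    *,
    missing_floor: float = 70.0,
    asymmetry_tol: float = 0.5,
):
    """Read a square, labelled pairwise-ANI matrix (percent identities).

    The matrix is symmetrised (average of the two triangles), the diagonal is
    forced to 100, and missing pairs — which ANI callers omit below their
    reporting threshold — are imputed at ``missing_floor`` with a warning.
    Asymmetries beyond ``asymmetry_tol`` ANI points are an error.
    """
    from .clade_assignment import ANIMatrix  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    if df.shape[0] != df.shape[1]:
        raise TableFormatError(f"{path}: ANI matrix is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise TableFormatError(f"{path}: row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.warning(
            "%s: imputing %d missing ANI pairs at floor %.1f",
            path, n_missing, missing_floor,
        )
        values = np.where(np.isnan(values), missing_floor, values)
    delta = np.abs(values - values.T)
    bad = np.argwhere(np.triu(delta, 1) > asymmetry_tol)
    if len(bad):
        pairs = [
            f"({df.index[i]}, {df.index[j]}: {values[i, j]:.2f} vs {values[j, i]:.2f})"
            for i, j in bad[:10]
        ]
        raise TableFormatError(
            f"{path}: ANI asymmetry beyond {asymmetry_tol}: {', '.join(pairs)}"
        )
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 100.0)
    if values.min() < 0 or values.max() > 100:
        raise TableFormatError(f"{path}: ANI values outside [0, 100]")
    return ANIMatrix(genome_ids=list(df.index), ani=values)


def write_ani_matrix(ani, path: str | Path) -> None:
    df = pd.DataFrame(ani.ani, index=ani.genome_ids, columns=ani.genome_ids)
    df.index.name = "genome"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# long-format results


def write_long_results(
    records: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    *,
    sort_keys: Sequence[str] | None = None,
    float_format: str = "%.17g",
) -> None:
    """Write result records as a UTF-8 TSV with a deterministic row order.

    Rows are sorted by ``sort_keys`` (default: all non-numeric columns in
    order), so output files are identical regardless of insertion order.
    An empty collection yields a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records.reset_index(drop=True)
    else:
        df = pd.DataFrame(list(records))
    if len(df):
        if sort_keys is None:
            sort_keys = [
                c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])
            ]
        if sort_keys:
            df = df.sort_values(list(sort_keys), kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format=float_format, encoding="utf-8")


def read_long_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
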