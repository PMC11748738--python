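"""Synthetic oral-metagenome cohorts and planted ANI matrices.

The generator emits species-level read-count tables (mpa lineage strings),
sample metadata, and pairwise-ANI matrices with the statistical structure
the analysis stages assume, so the whole pipeline can be exercised and
calibrated without downloading any sequencing data.

Per sample the generative model is hierarchical:

1. a *dominance state* (only in groups configured with a minority mixture
   component — ancient calculus cohorts are a mixture of Sanguinis-dominant
   and Anginosus-dominant communities);
2. the focal-genus share of all species-level reads, drawn from a
   range-bounded logit-normal whose parameters are moment-matched to the
   configured group mean and SD;
3. the clade composition of the focal genus, a Dirichlet draw around a
   state-specific base profile;
4. species splits within each clade, Dirichlet draws around per-group base
   weights (so e.g. *S. sinensis* can dominate the Sanguinis clade in
   non-industrial plaque while being nearly absent from industrial plaque);
5. a background-genus composition, an optional soil-contaminant admixture
   for QC-failing samples, a log-normal sequencing depth, and finally one
   multinomial read-count draw over all species.

Every draw flows from one `numpy` Generator seeded per group from the
master seed, so identical seeds give bit-identical cohorts, and a group
generated alone is identical to the same group inside the full cohort.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, roots_hermitenorm

from .table_io import CLADE_LABELS, CladeMap, SpeciesTable
from .clade_assignment import ANIMatrix

# ---------------------------------------------------------------------------
# species inventory

#: Focal Streptococcus species per clade (GTDB-style names; the polyphyly
#: suffix in "oralis_S" is deliberate and kept verbatim everywhere).
FOCAL_SPECIES: dict[str, tuple[str, ...]] = {
    "Sanguinis": (
        "Streptococcus sinensis", "Streptococcus sanguinis",
        "Streptococcus cristatus", "Streptococcus gordonii",
        "Streptococcus oligofermentans",
    ),
    "Mitis": (
        "Streptococcus mitis", "Streptococcus oralis",
        "Streptococcus oralis_S", "Streptococcus pneumoniae",
        "Streptococcus infantis", "Streptococcus pseudopneumoniae",
        "Streptococcus australis",
    ),
    "Anginosus": (
        "Streptococcus constellatus", "Streptococcus anginosus",
        "Streptococcus intermedius",
    ),
    "Salivarius": (
        "Streptococcus salivarius", "Streptococcus vestibularis",
        "Streptococcus thermophilus",
    ),
    "Mutans": (
        "Streptococcus mutans", "Streptococcus sobrinus",
        "Streptococcus troglodytae",
    ),
    "Bovis": (
        "Streptococcus equinus", "Streptococcus gallolyticus",
        "Streptococcus macedonicus",
    ),
    "Pyogenic": (
        "Streptococcus pyogenes", "Streptococcus agalactiae",
        "Streptococcus dysgalactiae", "Streptococcus uberis",
        "Streptococcus canis",
    ),
    "Downei": ("Streptococcus downei", "Streptococcus dentirousetti"),
    "Other": ("Streptococcus sp000448245", "Streptococcus sp900766505"),
    "Unknown": ("Streptococcus sp902362275", "Streptococcus sp900541205"),
}

#: Background oral genera with fixed base weights (early colonisers,
#: biofilm structurers and common oral commensals; weights sum to 1).
BACKGROUND_GENERA: tuple[tuple[str, str, float], ...] = (
    # (genus, species, base weight before renormalisation)
    ("Actinomyces", "Actinomyces oris", 6.0),
    ("Actinomyces", "Actinomyces naeslundii", 3.0),
    ("Neisseria", "Neisseria flavescens", 5.0),
    ("Neisseria", "Neisseria subflava", 2.5),
    ("Veillonella", "Veillonella parvula", 5.0),
    ("Veillonella", "Veillonella atypica", 2.0),
    ("Haemophilus", "Haemophilus parainfluenzae", 4.0),
    ("Prevotella", "Prevotella melaninogenica", 4.0),
    ("Prevotella", "Prevotella intermedia", 2.0),
    ("Capnocytophaga", "Capnocytophaga gingivalis", 3.5),
    ("Capnocytophaga", "Capnocytophaga sputigena", 1.5),
    ("Corynebacterium", "Corynebacterium matruchotii", 4.0),
    ("Corynebacterium", "Corynebacterium durum", 1.5),
    ("Fusobacterium", "Fusobacterium nucleatum", 3.0),
    ("Fusobacterium", "Fusobacterium periodonticum", 1.5),
    ("Gemella", "Gemella haemolysans", 2.5),
    ("Granulicatella", "Granulicatella adiacens", 2.5),
    ("Eikenella", "Eikenella corrodens", 1.5),
    ("Rothia", "Rothia dentocariosa", 3.0),
    ("Rothia", "Rothia mucilaginosa", 2.0),
    ("Porphyromonas", "Porphyromonas gingivalis", 1.5),
    ("Tannerella", "Tannerella forsythia", 1.2),
    ("Treponema", "Treponema denticola", 1.2),
    ("Leptotrichia", "Leptotrichia buccalis", 1.5),
    ("Selenomonas", "Selenomonas sputigena", 1.0),
    ("Campylobacter", "Campylobacter gracilis", 1.2),
    ("Aggregatibacter", "Aggregatibacter aphrophilus", 1.2),
    ("Lautropia", "Lautropia mirabilis", 1.0),
    ("Ottowia", "Ottowia oryzae", 0.8),
    ("Olsenella", "Olsenella uli", 0.8),
    ("Lachnoanaerobaculum", "Lachnoanaerobaculum saburreum", 0.8),
    ("Oribacterium", "Oribacterium sinus", 0.8),
    ("Stomatobaculum", "Stomatobaculum longum", 0.7),
    ("Solobacterium", "Solobacterium moorei", 0.7),
    ("Atopobium", "Atopobium parvulum", 0.8),
    ("Megasphaera", "Megasphaera micronuciformis", 0.7),
    ("Dialister", "Dialister invisus", 0.7),
    ("Mogibacterium", "Mogibacterium diversum", 0.6),
    ("Parvimonas", "Parvimonas micra", 0.8),
    ("Peptostreptococcus", "Peptostreptococcus stomatis", 0.7),
    ("Filifactor", "Filifactor alocis", 0.6),
    ("Abiotrophia", "Abiotrophia defectiva", 0.7),
    ("Kingella", "Kingella oralis", 0.7),
    ("Cardiobacterium", "Cardiobacterium hominis", 0.6),
    ("Bergeyella", "Bergeyella zoohelcum", 0.5),
    ("Alloprevotella", "Alloprevotella tannerae", 0.7),
    ("Anaeroglobus", "Anaeroglobus geminatus", 0.5),
    ("Johnsonella", "Johnsonella ignava", 0.5),
    ("Catonella", "Catonella morbi", 0.5),
    ("Centipeda", "Centipeda periodontii", 0.4),
    ("Desulfobulbus", "Desulfobulbus oralis", 0.4),
    ("Scardovia", "Scardovia wiggsiae", 0.5),
    ("Bifidobacterium", "Bifidobacterium dentium", 0.6),
    ("Lactobacillus", "Lactobacillus gasseri", 0.5),
    ("Enterococcus", "Enterococcus faecalis", 0.4),
    ("Methanobrevibacter", "Methanobrevibacter oralis", 0.8),
    ("Ruminococcaceae_g", "Ruminococcaceae_g sp003478035", 0.4),
    ("Saccharibacteria_g", "Saccharibacteria_g sp000803625", 0.5),
    ("Absconditabacteria_g", "Absconditabacteria_g sp001871945", 0.4),
    ("Mycoplasma", "Mycoplasma salivarium", 0.4),
)

#: Soil/environmental contaminant taxa (never in the oral reference set).
CONTAMINANT_TAXA: tuple[tuple[str, str, float], ...] = (
    ("Bradyrhizobium", "Bradyrhizobium japonicum", 3.0),
    ("Streptomyces", "Streptomyces griseus", 2.5),
    ("Mycobacterium", "Mycobacterium vaccae", 2.0),
    ("Pseudomonas", "Pseudomonas fluorescens", 2.0),
    ("Bacillus", "Bacillus subtilis", 1.5),
    ("Nocardioides", "Nocardioides albus", 1.2),
    ("Rhodoplanes", "Rhodoplanes elegans", 1.0),
    ("Geobacter", "Geobacter metallireducens", 0.8),
    ("Acidobacterium", "Acidobacterium capsulatum", 1.0),
    ("Chthoniobacter", "Chthoniobacter flavus", 0.8),
    ("Gaiella", "Gaiella occulta", 0.7),
    ("Solirubrobacter", "Solirubrobacter soli", 0.7),
)

_LINEAGE_TEMPLATE = (
    "d__Bacteria|p__{phylum}|c__{cls}|o__{order}|f__{family}|g__{genus}|s__{species}"
)


def _lineage(genus: str, species: str) -> str:
    # Generic but well-formed higher taxonomy; only the g__ and s__
    # components matter downstream.
    return _LINEAGE_TEMPLATE.format(
        phylum="Bacillota" if genus == "Streptococcus" else "Bacteria_p",
        cls="Bacilli" if genus == "Streptococcus" else "Bacteria_c",
        order="Lactobacillales" if genus == "Streptococcus" else "Bacteria_o",
        family="Streptococcaceae" if genus == "Streptococcus" else f"{genus}aceae",
        genus=genus,
        species=species,
    )


def focal_clade_map() -> CladeMap:
    """The ground-truth species-to-clade map for the synthetic inventory."""
    labels = {
        sp: clade for clade, species in FOCAL_SPECIES.items() for sp in species
    }
    return CladeMap(labels, {sp: "named_reference" for sp in labels})


def oral_reference_species() -> set[str]:
    """All species of the synthetic inventory that are genuinely oral
    (everything except the planted soil contaminants)."""
    oral = {sp for species in FOCAL_SPECIES.values() for sp in species}
    oral |= {sp for _, sp, _ in BACKGROUND_GENERA}
    return oral


# ---------------------------------------------------------------------------
# bounded logit-normal, moment-matched

_GH_NODES, _GH_WEIGHTS = roots_hermitenorm(81)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _bln_moments(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    vals = lo + (hi - lo) * expit(mu + sigma * _GH_NODES)
    mean = float(_GH_WEIGHTS @ vals)
    var = float(_GH_WEIGHTS @ (vals - mean) ** 2)
    return mean, np.sqrt(var)


_BLN_CACHE: dict[tuple, tuple[float, float]] = {}


def bounded_logitnormal_params(
    mean: float, sd: float, lo: float = 0.0, hi: float = 1.0
) -> tuple[float, float]:
    """(mu, sigma) of the logit-normal on [lo, hi] matching a target mean/SD.

    Solved numerically by Gauss-Hermite quadrature; raises if the target
    moments are unattainable on the interval.
    """
    if not lo <= mean <= hi:
        raise ValueError(f"target mean {mean} outside [{lo}, {hi}]")
    if sd <= 0:
        raise ValueError("target sd must be > 0")
    key = (round(mean, 10), round(sd, 10), round(lo, 10), round(hi, 10))
    if key in _BLN_CACHE:
        return _BLN_CACHE[key]
    p0 = (mean - lo) / (hi - lo)
    x0 = np.array([np.log(p0 / (1 - p0)), max(sd / (hi - lo) / (p0 * (1 - p0)), 0.05)])

    def resid(theta):
        m, s = _bln_moments(theta[0], abs(theta[1]), lo, hi)
        return [(m - mean) / max(mean, 1e-6), (s - sd) / sd]

    sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14)
    mu, sigma = float(sol.x[0]), float(abs(sol.x[1]))
    m, s = _bln_moments(mu, sigma, lo, hi)
    if abs(m - mean) > 0.02 * max(mean, 1e-3) or abs(s - sd) > 0.05 * sd:
        raise ValueError(
            f"cannot match mean={mean}, sd={sd} on [{lo}, {hi}] "
            f"(achieved {m:.4g}, {s:.4g})"
        )
    _BLN_CACHE[key] = (mu, sigma)
    return mu, sigma


def _draw_bln(rng, mu: float, sigma: float, lo: float, hi: float, size=None):
    return lo + (hi - lo) * expit(rng.normal(mu, sigma, size=size))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ShareDist:
    """Range-bounded logit-normal target for a per-sample share."""

    mean: float
    sd: float
    lo: float = 0.0
    hi: float = 1.0

    def params(self) -> tuple[float, float]:
        return bounded_logitnormal_params(self.mean, self.sd, self.lo, self.hi)


@dataclass
class GroupConfig:
    name: str
    host: str
    sample_type: str
    group: str  # industrial | non_industrial | ancient | nhp
    n: int
    genus_share: ShareDist
    clade_base: dict[str, float]
    species_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    clade_conc: float = 18.0
    species_conc: float = 12.0
    # minority mixture component (e.g. Anginosus-dominant ancient samples)
    minor_weight: float = 0.0
    minor_clade_base: dict[str, float] | None = None
    minor_genus_share: ShareDist | None = None
    # QC-failure simulation
    contamination_rate: float = 0.0
    contamination_frac: tuple[float, float] = (0.6, 0.9)
    ancient: bool = False

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for base in (self.clade_base, self.minor_clade_base):
            if base is None:
                continue
            w = np.array(list(base.values()), dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-6):
                raise ValueError(
                    f"group {self.name}: clade weights must be a simplex, "
                    f"sum={w.sum():.6f}"
                )
            unknown = set(base) - set(CLADE_LABELS)
            if unknown:
                raise ValueError(f"group {self.name}: unknown clades {unknown}")
        if not 0.0 <= self.minor_weight <= 1.0:
            raise ValueError("minor_weight must be in [0, 1]")
        for clade, weights in self.species_weights.items():
            w = np.array(list(weights.values()), dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-6):
                raise ValueError(
                    f"group {self.name}, clade {clade}: species weights must "
                    f"be a simplex"
                )


@dataclass
class CohortConfig:
    groups: dict[str, GroupConfig]
    depth_median: float = 1e5
    depth_sigma: float = 0.5
    background_conc: float = 60.0

    def __post_init__(self) -> None:
        if self.depth_median <= 0 or self.depth_sigma <= 0:
            raise ValueError("depth parameters must be positive")


# per-group defaults; see docs/methods.md for the calibration rationale.

_UNIFORM_SP = {
    clade: {sp: 1.0 / len(spp) for sp in spp}
    for clade, spp in FOCAL_SPECIES.items()
}

_ANCIENT_MAJOR_BASE = {
    "Sanguinis": 0.52, "Mitis": 0.14, "Anginosus": 0.04, "Salivarius": 0.10,
    "Mutans": 0.04, "Bovis": 0.02, "Pyogenic": 0.03, "Downei": 0.01,
    "Other": 0.06, "Unknown": 0.04,
}
_ANCIENT_MINOR_BASE = {
    "Sanguinis": 0.03, "Mitis": 0.07, "Anginosus": 0.60, "Salivarius": 0.08,
    "Mutans": 0.03, "Bovis": 0.02, "Pyogenic": 0.04, "Downei": 0.01,
    "Other": 0.07, "Unknown": 0.05,
}

_ANCIENT_SPECIES = {
    "Sanguinis": {
        "Streptococcus sinensis": 0.55, "Streptococcus sanguinis": 0.20,
        "Streptococcus cristatus": 0.12, "Streptococcus gordonii": 0.09,
        "Streptococcus oligofermentans": 0.04,
    },
    "Anginosus": {
        "Streptococcus constellatus": 0.62, "Streptococcus anginosus": 0.24,
        "Streptococcus intermedius": 0.14,
    },
}

_PLAQUE_IND_BASE = {
    "Sanguinis": 0.14, "Mitis": 0.43, "Anginosus": 0.05, "Salivarius": 0.16,
    "Mutans": 0.05, "Bovis": 0.02, "Pyogenic": 0.03, "Downei": 0.01,
    "Other": 0.07, "Unknown": 0.04,
}
# S. sanguinis-led Sanguinis clade; S. sinensis nearly absent (0.43% of the
# genus => weight 0.0043 / 0.14)
_PLAQUE_IND_SPECIES = {
    "Sanguinis": {
        "Streptococcus sanguinis": 0.536, "Streptococcus sinensis": 0.031,
        "Streptococcus cristatus": 0.063, "Streptococcus gordonii": 0.320,
        "Streptococcus oligofermentans": 0.050,
    },
    "Mitis": {
        "Streptococcus mitis": 0.30, "Streptococcus oralis": 0.25,
        "Streptococcus oralis_S": 0.051, "Streptococcus pneumoniae": 0.10,
        "Streptococcus infantis": 0.15, "Streptococcus pseudopneumoniae": 0.069,
        "Streptococcus australis": 0.08,
    },
    "Anginosus": {
        "Streptococcus intermedius": 0.30, "Streptococcus anginosus": 0.45,
        "Streptococcus constellatus": 0.25,
    },
}

_PLAQUE_NONIND_BASE = {
    "Sanguinis": 0.24, "Mitis": 0.27, "Anginosus": 0.04, "Salivarius": 0.17,
    "Mutans": 0.08, "Bovis": 0.02, "Pyogenic": 0.04, "Downei": 0.01,
    "Other": 0.08, "Unknown": 0.05,
}
# S. sinensis-led (11% of the genus => weight 0.11 / 0.24)
_PLAQUE_NONIND_SPECIES = {
    "Sanguinis": {
        "Streptococcus sinensis": 0.458, "Streptococcus sanguinis": 0.113,
        "Streptococcus cristatus": 0.096, "Streptococcus gordonii": 0.283,
        "Streptococcus oligofermentans": 0.050,
    },
    "Mitis": {
        "Streptococcus mitis": 0.32, "Streptococcus oralis": 0.28,
        "Streptococcus oralis_S": 0.013, "Streptococcus pneumoniae": 0.10,
        "Streptococcus infantis": 0.16, "Streptococcus pseudopneumoniae": 0.047,
        "Streptococcus australis": 0.08,
    },
    "Anginosus": {
        "Streptococcus intermedius": 0.103, "Streptococcus anginosus": 0.52,
        "Streptococcus constellatus": 0.377,
    },
}

_MITIS_HEAVY_BASE = {
    "Sanguinis": 0.12, "Mitis": 0.60, "Anginosus": 0.04, "Salivarius": 0.12,
    "Mutans": 0.02, "Bovis": 0.01, "Pyogenic": 0.02, "Downei": 0.01,
    "Other": 0.04, "Unknown": 0.02,
}

_NHP_DISTINCT_BASE = {
    "Sanguinis": 0.04, "Mitis": 0.08, "Anginosus": 0.05, "Salivarius": 0.10,
    "Mutans": 0.06, "Bovis": 0.09, "Pyogenic": 0.12, "Downei": 0.04,
    "Other": 0.24, "Unknown": 0.18,
}


def default_config() -> CohortConfig:
    """The default synthetic cohort: the study conditions of the analysis.

    Group sizes, genus-share means and SDs, the ancient dominance mixture
    and the species splits are the calibration targets documented in
    docs/methods.md.
    """
    groups = {
        "ancient_calculus": GroupConfig(
            name="ancient_calculus", host="human", sample_type="ancient_calculus",
            group="ancient", n=483,
            genus_share=ShareDist(0.05, 0.03),
            clade_base=_ANCIENT_MAJOR_BASE,
            species_weights={**_UNIFORM_SP, **_ANCIENT_SPECIES},
            clade_conc=30.0,
            minor_weight=0.147,
            minor_clade_base=_ANCIENT_MINOR_BASE,
            minor_genus_share=ShareDist(0.02, 0.015),
            ancient=True,
        ),
        "modern_calculus": GroupConfig(
            name="modern_calculus", host="human", sample_type="modern_calculus",
            group="industrial", n=18,
            genus_share=ShareDist(0.05, 0.03),
            clade_base={
                "Sanguinis": 0.40, "Mitis": 0.19, "Anginosus": 0.05,
                "Salivarius": 0.13, "Mutans": 0.04, "Bovis": 0.02,
                "Pyogenic": 0.03, "Downei": 0.01, "Other": 0.08, "Unknown": 0.05,
            },
            species_weights={**_UNIFORM_SP, **_PLAQUE_IND_SPECIES},
        ),
        "plaque_industrial": GroupConfig(
            name="plaque_industrial", host="human", sample_type="plaque",
            group="industrial", n=152,
            genus_share=ShareDist(0.07, 0.06),
            clade_base=_PLAQUE_IND_BASE,
            species_weights={**_UNIFORM_SP, **_PLAQUE_IND_SPECIES},
        ),
        "plaque_nonindustrial": GroupConfig(
            name="plaque_nonindustrial", host="human", sample_type="plaque",
            group="non_industrial", n=68,
            genus_share=ShareDist(0.04, 0.03),
            clade_base=_PLAQUE_NONIND_BASE,
            species_weights={**_UNIFORM_SP, **_PLAQUE_NONIND_SPECIES},
        ),
        "buccal_industrial": GroupConfig(
            name="buccal_industrial", host="human", sample_type="buccal_mucosa",
            group="industrial", n=28,
            genus_share=ShareDist(0.39, 0.19, lo=0.25, hi=1.0),
            clade_base=_MITIS_HEAVY_BASE,
            species_weights={**_UNIFORM_SP, **_PLAQUE_IND_SPECIES},
        ),
        "buccal_nonindustrial": GroupConfig(
            name="buccal_nonindustrial", host="human", sample_type="buccal_mucosa",
            group="non_industrial", n=28,
            genus_share=ShareDist(0.16, 0.08, lo=0.0, hi=0.29),
            clade_base=_MITIS_HEAVY_BASE,
            species_weights={**_UNIFORM_SP, **_PLAQUE_NONIND_SPECIES},
        ),
        "saliva_industrial": GroupConfig(
            name="saliva_industrial", host="human", sample_type="saliva",
            group="industrial", n=134,
            genus_share=ShareDist(0.14, 0.03),
            clade_base=_MITIS_HEAVY_BASE,
            species_weights={**_UNIFORM_SP, **_PLAQUE_IND_SPECIES},
        ),
        "saliva_nonindustrial": GroupConfig(
            name="saliva_nonindustrial", host="human", sample_type="saliva",
            group="non_industrial", n=133,
            genus_share=ShareDist(0.19, 0.07),
            clade_base=_MITIS_HEAVY_BASE,
            species_weights={**_UNIFORM_SP, **_PLAQUE_NONIND_SPECIES},
        ),
        "chimp_calculus": GroupConfig(
            name="chimp_calculus", host="chimpanzee",
            sample_type="ancient_calculus", group="nhp", n=30,
            genus_share=ShareDist(0.0033, 0.0023),
            clade_base=_NHP_DISTINCT_BASE,
            species_weights=_UNIFORM_SP,
            ancient=True,
        ),
        "vervet_swab": GroupConfig(
            name="vervet_swab", host="vervet_monkey", sample_type="oral_swab",
            group="nhp", n=30,
            genus_share=ShareDist(0.59, 0.20),
            clade_base=_NHP_DISTINCT_BASE,
            species_weights=_UNIFORM_SP,
        ),
        "baboon_calculus": GroupConfig(
            name="baboon_calculus", host="baboon",
            sample_type="ancient_calculus", group="nhp", n=20,
            genus_share=ShareDist(0.04, 0.03),
            clade_base=_ANCIENT_MAJOR_BASE,
            species_weights={**_UNIFORM_SP, **_ANCIENT_SPECIES},
            ancient=True,
        ),
        "gorilla_calculus": GroupConfig(
            name="gorilla_calculus", host="gorilla",
            sample_type="ancient_calculus", group="nhp", n=15,
            genus_share=ShareDist(0.01, 0.008),
            clade_base=_NHP_DISTINCT_BASE,
            species_weights=_UNIFORM_SP,
            ancient=True,
        ),
    }
    return CohortConfig(groups=groups)


# ---------------------------------------------------------------------------
# cohort generation


def _group_rng(seed: int, name: str) -> np.random.Generator:
    # stable per-group stream: same seed => same group regardless of which
    # other groups are generated
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


_ALL_SPECIES: list[tuple[str, str]] = (
    [("Streptococcus", sp) for spp in FOCAL_SPECIES.values() for sp in spp]
    + [(g, sp) for g, sp, _ in BACKGROUND_GENERA]
    + [(g, sp) for g, sp, _ in CONTAMINANT_TAXA]
)
_N_FOCAL = sum(len(v) for v in FOCAL_SPECIES.values())
_BG_BASE = np.array([w for _, _, w in BACKGROUND_GENERA], dtype=float)
_BG_BASE /= _BG_BASE.sum()
_CONTAM_BASE = np.array([w for _, _, w in CONTAMINANT_TAXA], dtype=float)
_CONTAM_BASE /= _CONTAM_BASE.sum()

# flat focal index bookkeeping
_FOCAL_INDEX: dict[str, int] = {
    sp: i
    for i, sp in enumerate(sp for spp in FOCAL_SPECIES.values() for sp in spp)
}
_CLADE_SLICES: dict[str, list[int]] = {
    clade: [_FOCAL_INDEX[sp] for sp in spp]
    for clade, spp in FOCAL_SPECIES.items()
}


def _sample_probs(
    rng: np.random.Generator, cfg: GroupConfig, bg_conc: float, state: str
) -> tuple[np.ndarray, float]:
    """Species probability vector and the drawn genus share for one sample."""
    if state == "minor":
        base = cfg.minor_clade_base
        gs_dist = cfg.minor_genus_share or cfg.genus_share
    else:
        base = cfg.clade_base
        gs_dist = cfg.genus_share
    mu, sigma = gs_dist.params()
    gs = float(_draw_bln(rng, mu, sigma, gs_dist.lo, gs_dist.hi))

    clade_alpha = np.array(
        [cfg.clade_conc * base.get(c, 0.0) for c in CLADE_LABELS]
    )
    clade_alpha = np.maximum(clade_alpha, 1e-3)
    clade_p = rng.dirichlet(clade_alpha)

    focal = np.zeros(_N_FOCAL)
    for ci, clade in enumerate(CLADE_LABELS):
        weights = cfg.species_weights.get(clade, _UNIFORM_SP[clade])
        spp = FOCAL_SPECIES[clade]
        alpha = np.maximum(
            cfg.species_conc * np.array([weights.get(sp, 0.0) for sp in spp]),
            1e-3,
        )
        split = rng.dirichlet(alpha)
        for sp, w in zip(spp, split):
            focal[_FOCAL_INDEX[sp]] = clade_p[ci] * w

    bg = rng.dirichlet(bg_conc * _BG_BASE)
    p = np.concatenate([gs * focal, (1.0 - gs) * bg, np.zeros(len(_CONTAM_BASE))])
    return p, gs


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    groups: list[str] | None = None,
) -> tuple[SpeciesTable, pd.DataFrame]:
    """Generate a synthetic cohort (read-count table plus metadata).

    ``groups`` restricts generation to a subset of group names; each group's
    samples are identical whether generated alone or in the full cohort.
    Returns the mpa-style :class:`SpeciesTable` (species rows plus genus
    aggregate rows) and a metadata frame indexed by sample id, including the
    simulation truth columns ``sim_dominance_state`` and ``sim_contaminated``.
    """
    if config is None:
        config = default_config()
    wanted = list(config.groups) if groups is None else list(groups)
    unknown = set(wanted) - set(config.groups)
    if unknown:
        raise KeyError(f"unknown groups: {sorted(unknown)}")

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for name in wanted:
        cfg = config.groups[name]
        if cfg.n == 0:
            continue
        rng = _group_rng(seed, name)
        # stratified dominance mixture: the minority count is fixed at
        # round(w * n) and shuffled, so the cohort composition is the
        # configured mixture rather than a binomial draw around it
        n_minor = int(round(cfg.minor_weight * cfg.n)) if cfg.minor_weight else 0
        states = np.array(["major"] * (cfg.n - n_minor) + ["minor"] * n_minor)
        rng.shuffle(states)
        contaminated = rng.random(cfg.n) < cfg.contamination_rate
        for i in range(cfg.n):
            p, gs = _sample_probs(rng, cfg, config.background_conc, states[i])
            if contaminated[i]:
                frac = rng.uniform(*cfg.contamination_frac)
                contam = rng.dirichlet(40.0 * _CONTAM_BASE)
                p = (1.0 - frac) * p
                p[-len(_CONTAM_BASE):] = frac * contam
            depth = int(
                round(rng.lognormal(np.log(config.depth_median), config.depth_sigma))
            )
            depth = max(depth, 1000)
            counts = rng.multinomial(depth, p / p.sum())
            sample_id = f"{name}_{i:04d}"
            columns[sample_id] = counts
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "host": cfg.host,
                    "sample_type": cfg.sample_type,
                    "group": cfg.group,
                    "cohort": name,
                    "age_bp": (
                        float(np.round(rng.uniform(100, 3000)))
                        if cfg.ancient and cfg.host == "human"
                        else np.nan
                    ),
                    "sim_dominance_state": states[i],
                    "sim_contaminated": bool(contaminated[i]),
                }
            )

    if not columns:
        empty = pd.DataFrame(
            index=pd.Index(
                [_lineage(g, sp) for g, sp in _ALL_SPECIES], name="lineage"
            ),
            dtype=np.int64,
        )
        empty_meta = pd.DataFrame(
            columns=["host", "sample_type", "group", "cohort", "age_bp",
                     "sim_dominance_state", "sim_contaminated"]
        )
        empty_meta.index.name = "sample_id"
        return SpeciesTable(empty), empty_meta

    species_index = pd.Index(
        [_lineage(g, sp) for g, sp in _ALL_SPECIES], name="lineage"
    )
    counts = pd.DataFrame(columns, index=species_index, dtype=np.int64)

    # genus aggregate rows, as a joined Kraken-style mpa table would carry
    genus_lineages = {}
    for (g, _), lin in zip(_ALL_SPECIES, species_index):
        genus_lineages.setdefault(lin.rsplit("|", 1)[0], []).append(lin)
    genus_rows = pd.DataFrame(
        {
            glin: counts.loc[members].sum(axis=0)
            for glin, members in genus_lineages.items()
        }
    ).T
    genus_rows.index.name = "lineage"
    table = SpeciesTable(pd.concat([genus_rows, counts]))

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, metadata


# ---------------------------------------------------------------------------
# planted ANI matrices


@dataclass
class PlantedAni:
    ani: ANIMatrix
    planted_labels: CladeMap
    references: dict[str, str]       # one named genome per species cluster
    species_partition: dict[str, str]  # genome -> planted species id


def generate_ani(
    n_clades: int = 4,
    species_per_clade: int = 3,
    genomes_per_species: int = 3,
    n_unplaced: int = 2,
    seed: int = 0,
    *,
    within_species: tuple[float, float] = (96.5, 99.9),
    within_clade: tuple[float, float] = (85.0, 94.0),
    between_clades: tuple[float, float] = (75.0, 84.0),
    basal: tuple[float, float] = (70.0, 74.0),
) -> PlantedAni:
    """A block-structured ANI matrix with planted species and clade labels.

    Within-species pairs draw from ``within_species``, between-species pairs
    of the same clade from ``within_clade``, between-clade pairs from
    ``between_clades``, and the ``n_unplaced`` basal genomes relate to
    everything (including each other) through ``basal``.  The four ranges
    must be disjoint and decreasing, or block recovery is ill-posed.
    """
    if n_clades < 1 or species_per_clade < 1 or genomes_per_species < 1:
        raise ValueError("all counts must be >= 1 (n_unplaced may be 0)")
    if n_unplaced < 0:
        raise ValueError("n_unplaced must be >= 0")
    if n_clades > 8:
        raise ValueError("at most 8 named clades are available")
    ranges = [within_species, within_clade, between_clades, basal]
    for hi_range, lo_range in zip(ranges, ranges[1:]):
        if lo_range[1] >= hi_range[0]:
            raise ValueError(
                f"overlapping ANI ranges: {lo_range} must fall below {hi_range}"
            )

    rng = np.random.default_rng(seed)
    clade_names = [c for c in CLADE_LABELS if c not in ("Other", "Unknown")]
    genomes: list[str] = []
    clade_of: dict[str, str] = {}
    species_of: dict[str, str] = {}
    references: dict[str, str] = {}
    for ci in range(n_clades):
        clade = clade_names[ci]
        for si in range(species_per_clade):
            species_id = f"{clade}_sp{si + 1}"
            for gi in range(genomes_per_species):
                gid = f"{species_id}_g{gi + 1}"
                genomes.append(gid)
                clade_of[gid] = clade
                species_of[gid] = species_id
                if gi == 0:
                    references[gid] = clade
    for ui in range(n_unplaced):
        gid = f"basal_sp{ui + 1}_g1"
        genomes.append(gid)
        clade_of[gid] = "Unknown"
        species_of[gid] = f"basal_sp{ui + 1}"

    n = len(genomes)
    ani = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = genomes[i], genomes[j]
            if species_of[gi] == species_of[gj]:
                lo, hi = within_species
            elif "basal" in (gi.split("_")[0], gj.split("_")[0]):
                lo, hi = basal
            elif clade_of[gi] == clade_of[gj]:
                lo, hi = within_clade
            else:
                lo, hi = between_clades
            ani[i, j] = ani[j, i] = rng.uniform(lo, hi)
    labels = CladeMap(
        dict(clade_of),
        {
            g: ("unknown_rule" if clade_of[g] == "Unknown" else "named_reference")
            for g in genomes
        },
    )
    return PlantedAni(
        ani=ANIMatrix(genome_ids=genomes, ani=ani),
        planted_labels=labels,
        references=references,
        species_partition=species_of,
    )
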