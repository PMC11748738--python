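"""Abundance layers, dominance calls and per-clade top species."""

import numpy as np
import pandas as pd
import pytest

from strepclades import (
    CladeMap,
    SpeciesTable,
    clade_shares,
    cohort_summary,
    dominant_clade,
    generate_cohort,
    focal_clade_map,
    log10p1,
    species_shares,
    top_species,
)
from strepclades.profiles import sample_ordering_key
from strepclades.synthetic_data import default_config

from conftest import strep_lineage, other_lineage


class TestCladeShares:
    def test_forced_arithmetic_three_layers(self, tiny_table, tiny_clades):
        prof = clade_shares(tiny_table, tiny_clades)
        l1 = prof.clade_share_of_genus.loc["s1"]
        assert l1["Sanguinis"] == pytest.approx(0.3)
        assert l1["Mitis"] == pytest.approx(0.6)
        assert l1["Anginosus"] == pytest.approx(0.1)
        assert prof.genus_share["s1"] == pytest.approx(0.1)
        assert prof.clade_share_of_species.loc["s1", "Sanguinis"] == pytest.approx(0.03)

    def test_single_clade_sample_gets_share_one(self, tiny_table, tiny_clades):
        prof = clade_shares(tiny_table, tiny_clades)
        assert prof.clade_share_of_genus.loc["s2", "Sanguinis"] == pytest.approx(1.0)

    def test_layer_sum_invariants_on_random_cohort(self, rng):
        table, _ = generate_cohort(default_config(), seed=17,
                                   groups=["plaque_industrial"])
        sub = table.subset_samples(table.sample_ids[:20])
        prof = clade_shares(sub, focal_clade_map())
        l1_sums = prof.clade_share_of_genus.sum(axis=1)
        assert np.allclose(l1_sums.dropna(), 1.0, atol=1e-12)
        l3_sums = prof.clade_share_of_species.sum(axis=1)
        assert np.allclose(l3_sums, prof.genus_share, atol=1e-12)
        assert ((prof.genus_share.dropna() >= 0) & (prof.genus_share.dropna() <= 1)).all()

    def test_scaling_a_sample_leaves_layers_unchanged(self, tiny_table, tiny_clades):
        scaled = SpeciesTable(tiny_table.counts * 7)
        a = clade_shares(tiny_table, tiny_clades)
        b = clade_shares(scaled, tiny_clades)
        pd.testing.assert_frame_equal(a.clade_share_of_genus, b.clade_share_of_genus)
        pd.testing.assert_series_equal(a.genus_share, b.genus_share)

    def test_removing_non_focal_genus_keeps_layer1(self, tiny_table, tiny_clades):
        focal_only = SpeciesTable(
            tiny_table.counts.drop(index=other_lineage("Veillonella", "parvula"))
        )
        a = clade_shares(tiny_table, tiny_clades)
        b = clade_shares(focal_only, tiny_clades)
        pd.testing.assert_frame_equal(a.clade_share_of_genus, b.clade_share_of_genus)

    def test_uncovered_focal_species_counted_as_unknown(self, tiny_table):
        partial = CladeMap({"Streptococcus sanguinis": "Sanguinis",
                            "Streptococcus mitis": "Mitis"})
        prof = clade_shares(tiny_table, partial)
        assert prof.clade_share_of_genus.loc["s1", "Unknown"] == pytest.approx(0.1)

    def test_zero_species_sample_is_all_na(self, tiny_clades):
        counts = pd.DataFrame({"s1": [0]}, index=[strep_lineage("mitis")])
        prof = clade_shares(SpeciesTable(counts), tiny_clades)
        assert prof.clade_share_of_genus.loc["s1"].isna().all()
        assert dominant_clade(prof)["s1"] == "none"


class TestLog10p1:
    def test_closed_form_endpoints(self):
        assert log10p1(np.array([0.0]))[0] == 0.0
        assert log10p1(np.array([99.0]))[0] == pytest.approx(2.0)

    def test_inverse_recovers_percent_matrix(self, rng):
        x = rng.uniform(0, 100, size=(6, 4))
        y = log10p1(x)
        assert np.allclose(10.0**y - 1.0, x, atol=1e-10)

    def test_negative_input_is_error(self):
        with pytest.raises(ValueError):
            log10p1(np.array([-0.1]))


class TestDominance:
    def test_plurality_and_tie_precedence(self, tiny_clades):
        counts = pd.DataFrame(
            {
                "plur": [60, 30, 10],
                "tie": [50, 0, 50],
            },
            index=[
                strep_lineage("sanguinis"),
                strep_lineage("mitis"),
                strep_lineage("anginosus"),
            ],
        )
        dom = dominant_clade(clade_shares(SpeciesTable(counts), tiny_clades))
        assert dom["plur"] == "Sanguinis"
        assert dom["tie"] == "Sanguinis"  # Sanguinis precedes Anginosus

    def test_cohort_summary_reproduces_cohort_fraction(self):
        labels = pd.Series(
            ["Anginosus"] * 71 + ["Sanguinis"] * (483 - 71),
            index=[f"s{i}" for i in range(483)],
        )
        summary = cohort_summary(labels)
        assert summary.counts["Anginosus"] == 71
        assert 100 * summary.fractions["Anginosus"] == pytest.approx(14.7, abs=0.05)
        assert summary.fractions.sum() == pytest.approx(1.0)
        shuffled = cohort_summary(labels.sample(frac=1, random_state=0))
        assert (shuffled.counts == summary.counts).all()

    def test_ordering_key_sorts_sanguinis_down_anginosus_up(self, tiny_clades):
        counts = pd.DataFrame(
            {
                "hiS": [90, 0, 10],
                "loS": [10, 0, 90],
                "midS": [50, 0, 50],
            },
            index=[
                strep_lineage("sanguinis"),
                strep_lineage("mitis"),
                strep_lineage("anginosus"),
            ],
        )
        key = sample_ordering_key(clade_shares(SpeciesTable(counts), tiny_clades))
        assert list(key.sort_values().index) == ["hiS", "midS", "loS"]


class TestTopSpecies:
    def _table(self, a, b):
        counts = pd.DataFrame(
            {"s1": [a, b]},
            index=[strep_lineage("anginosus"), strep_lineage("constellatus")],
        )
        return SpeciesTable(counts)

    _clades = CladeMap(
        {
            "Streptococcus anginosus": "Anginosus",
            "Streptococcus constellatus": "Anginosus",
        }
    )

    def test_maximum_wins(self):
        per_sample, _ = top_species(
            self._table(5, 7), self._clades, "Anginosus",
            restrict_to_dominant=False,
        )
        assert per_sample.loc["s1", "top_species"] == "Streptococcus constellatus"
        assert not per_sample.loc["s1", "tie"]

    def test_tie_goes_to_lexicographic_first_with_flag(self):
        per_sample, _ = top_species(
            self._table(5, 5), self._clades, "Anginosus",
            restrict_to_dominant=False,
        )
        assert per_sample.loc["s1", "top_species"] == "Streptococcus anginosus"
        assert bool(per_sample.loc["s1", "tie"])

    def test_absent_clade_is_error(self):
        with pytest.raises(ValueError, match="no species"):
            top_species(self._table(1, 1), self._clades, "Bovis")

    def test_tally_mode_matches_largest_generator_mean(self):
        """Monte-Carlo: in a large non-industrial plaque cohort the modal top
        Sanguinis-clade species is the one with the largest configured mean
        (S. sinensis)."""
        cfg = default_config()
        cfg.groups["plaque_nonindustrial"].n = 500
        table, _ = generate_cohort(cfg, seed=23, groups=["plaque_nonindustrial"])
        _, tally = top_species(table, focal_clade_map(), "Sanguinis",
                               restrict_to_dominant=False)
        assert tally.idxmax() == "Streptococcus sinensis"


def test_species_shares_sum_to_one_over_focal(tiny_table, tiny_clades):
    shares = species_shares(tiny_table)
    sums = shares.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-12)
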