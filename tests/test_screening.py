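"""Non-local flagging rules and the occurrence-pattern analyses."""

import datetime
import math
import random

import numpy as np
import pytest
from scipy import stats

from ednascreen.abundance_filtering import SampleProfile
from ednascreen.io_formats import (
    LocalityChecklist,
    SampleMeta,
    ScreeningThresholds,
)
from ednascreen.nonlocal_screening import (
    build_occurrence_matrix,
    depth_and_richness_correlates,
    flag_nonlocal,
    ordering_concentration,
    rank_correlation,
    replicate_concordance,
)
from ednascreen.taxonomic_assignment import AssignmentResult

from helpers import spearman_oracle


def _assign(asv_id, name, rank="species", confidence="strict", tied=()):
    return AssignmentResult(
        asv_id=asv_id, assigned_rank=rank, assigned_name=name,
        best_identity_pct=100.0 if confidence == "strict" else 98.0,
        confidence_class=confidence,
        mismatches=0 if confidence == "strict" else 2,
        overlap_bp=145, tied_species=tuple(tied))


def _profile(sample_id, rra):
    return SampleProfile(sample_id=sample_id, total_reads=10_000,
                         rra=dict(rra), stage="filtered")


@pytest.fixture
def checklist():
    return LocalityChecklist({
        "Far species": (250.0, ""),
        "Near species": (150.0, ""),
        "Boundary species": (200.0, ""),
        "Distant one": (900.0, ""),
        "Distant two": (800.0, ""),
    })


class TestFlagNonlocal:
    def test_strict_distant_species_flagged(self, checklist, thresholds):
        out = flag_nonlocal({"A1": _assign("A1", "Far species")},
                            {"S1": _profile("S1", {"A1": 5.0})},
                            checklist, thresholds)
        assert len(out.flags) == 1
        assert out.flags[0].species == "Far species"
        assert out.flags[0].rra_pct == 5.0

    def test_near_and_boundary_species_not_flagged(self, checklist,
                                                   thresholds):
        assigns = {"A1": _assign("A1", "Near species"),
                   "A2": _assign("A2", "Boundary species")}
        out = flag_nonlocal(assigns,
                            {"S1": _profile("S1", {"A1": 5.0, "A2": 3.0})},
                            checklist, thresholds)
        assert out.flags == []

    def test_standard_confidence_reported_near_threshold(self, checklist,
                                                         thresholds):
        assigns = {"A1": _assign("A1", "Far species", confidence="standard")}
        out = flag_nonlocal(assigns, {"S1": _profile("S1", {"A1": 2.0})},
                            checklist, thresholds)
        assert out.flags == []
        assert len(out.near_threshold) == 1
        assert out.near_threshold[0].reason == "standard_confidence"

    def test_genus_tie_of_nonlocals_near_threshold(self, checklist,
                                                   thresholds):
        assigns = {"A1": _assign("A1", "Distant", rank="genus",
                                 tied=("Distant one", "Distant two"))}
        out = flag_nonlocal(assigns, {"S1": _profile("S1", {"A1": 2.0})},
                            checklist, thresholds)
        assert out.flags == []
        assert out.near_threshold[0].reason == "unresolved_nonlocal_tie"

    def test_species_absent_from_checklist_goes_to_unknown(self, checklist,
                                                           thresholds):
        assigns = {"A1": _assign("A1", "Unlisted species")}
        out = flag_nonlocal(assigns, {"S1": _profile("S1", {"A1": 2.0})},
                            checklist, thresholds)
        assert out.flags == []
        assert out.unknown_locality[0].species == "Unlisted species"

    def test_flag_set_invariant_to_input_order(self, checklist, thresholds):
        assigns = {"A1": _assign("A1", "Far species"),
                   "A2": _assign("A2", "Distant one")}
        profiles = {"S1": _profile("S1", {"A1": 5.0, "A2": 1.0}),
                    "S2": _profile("S2", {"A2": 2.0})}
        fwd = flag_nonlocal(assigns, profiles, checklist, thresholds)
        rev = flag_nonlocal(dict(reversed(list(assigns.items()))),
                            dict(reversed(list(profiles.items()))),
                            checklist, thresholds)
        assert fwd.flags == rev.flags

    def test_lowering_distance_threshold_only_adds_flags(self, checklist,
                                                         thresholds):
        assigns = {"A1": _assign("A1", "Far species"),
                   "A2": _assign("A2", "Near species")}
        profiles = {"S1": _profile("S1", {"A1": 5.0, "A2": 1.0})}
        base = flag_nonlocal(assigns, profiles, checklist, thresholds)
        lowered = flag_nonlocal(
            assigns, profiles, checklist,
            ScreeningThresholds(nonlocal_distance_km=100.0))
        base_keys = {(f.asv_id, f.sample_id) for f in base.flags}
        low_keys = {(f.asv_id, f.sample_id) for f in lowered.flags}
        assert base_keys <= low_keys


class TestOccurrenceMatrix:
    def _metas(self, dates, proc=None):
        proc = proc or range(1, len(dates) + 1)
        return {
            f"S{i}": SampleMeta(f"S{i}", "cat", d, p, "b")
            for i, (d, p) in enumerate(zip(dates, proc), start=1)
        }

    def test_columns_follow_collection_dates(self, checklist, thresholds):
        d = datetime.date
        metas = self._metas([d(2017, 6, 3), d(2017, 5, 20), d(2017, 7, 1)],
                            proc=[1, 2, 3])
        m = build_occurrence_matrix([], metas, "collection_date")
        assert list(m.columns) == ["S2", "S1", "S3"]

    def test_equal_dates_break_ties_lexicographically(self):
        d = datetime.date(2017, 6, 1)
        metas = self._metas([d, d, d])
        m = build_occurrence_matrix([], metas, "collection_date")
        assert list(m.columns) == ["S1", "S2", "S3"]

    def test_cells_reproduce_flag_abundances(self, checklist, thresholds):
        from ednascreen.nonlocal_screening import NonlocalFlag
        d = datetime.date
        metas = self._metas([d(2017, 6, 1), d(2017, 6, 2)])
        flags = [NonlocalFlag("A1", "Far species", "S1", 5.0),
                 NonlocalFlag("A2", "Far species", "S1", 2.0),
                 NonlocalFlag("A1", "Far species", "S2", 1.0)]
        m = build_occurrence_matrix(flags, metas, "collection_date")
        assert m.loc["Far species", "S1"] == pytest.approx(7.0)
        assert m.loc["Far species", "S2"] == pytest.approx(1.0)

    def test_missing_date_raises_with_sample_names(self):
        metas = {"S1": SampleMeta("S1", "cat", None, 1, "b")}
        with pytest.raises(ValueError, match="S1"):
            build_occurrence_matrix([], metas, "collection_date")


class TestRankCorrelation:
    def test_monotone_is_one(self):
        assert rank_correlation([1, 2, 3], [2, 4, 9]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert rank_correlation([1, 2, 3], [9, 4, 2]) == pytest.approx(-1.0)

    def test_constant_vector_is_missing(self):
        assert math.isnan(rank_correlation([1, 1, 1], [2, 4, 9]))

    def test_matches_average_rank_oracle_with_ties(self):
        rng = random.Random(17)
        for _ in range(50):
            n = rng.randint(3, 30)
            x = [rng.choice([0, 1, 2, 5, 5, 9]) for _ in range(n)]
            y = [rng.choice([0.0, 0.5, 0.5, 2.0, 7.0]) for _ in range(n)]
            expected = spearman_oracle(x, y)
            got = rank_correlation(x, y)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestDepthRichnessCorrelates:
    def _raw(self, sample_id, total, n_asvs):
        rra = {f"A{i}": 100.0 / n_asvs for i in range(n_asvs)}
        return SampleProfile(sample_id=sample_id, total_reads=total,
                             rra=rra, stage="raw")

    def test_depth_proportional_contamination_detected(self):
        from ednascreen.nonlocal_screening import NonlocalFlag
        rng = random.Random(5)
        profiles, flags = {}, []
        for i in range(40):
            total = 1000 * (i + 1)
            profiles[f"S{i:02d}"] = self._raw(f"S{i:02d}", total, 5)
            flags.append(NonlocalFlag("A9", "Far species", f"S{i:02d}",
                                      total / 1000 + rng.uniform(-0.1, 0.1)))
        rho_reads, _ = depth_and_richness_correlates(profiles, flags)
        assert rho_reads > 0.9

    def test_independent_contamination_is_uncorrelated(self):
        from ednascreen.nonlocal_screening import NonlocalFlag
        rng = random.Random(6)
        profiles, flags = {}, []
        for i in range(60):
            profiles[f"S{i:02d}"] = self._raw(f"S{i:02d}",
                                              rng.randint(1000, 50000), 5)
            if rng.random() < 0.5:
                flags.append(NonlocalFlag("A9", "Far species", f"S{i:02d}",
                                          rng.uniform(0.1, 20.0)))
        rho_reads, _ = depth_and_richness_correlates(profiles, flags)
        # permutation null band for n=60 at 95%: |rho| < ~0.25
        assert abs(rho_reads) < 0.25

    def test_no_flags_anywhere_gives_missing_value(self):
        profiles = {f"S{i}": self._raw(f"S{i}", 1000 * (i + 1), 4)
                    for i in range(5)}
        rho_reads, rho_asvs = depth_and_richness_correlates(profiles, [])
        assert math.isnan(rho_reads) and math.isnan(rho_asvs)


class TestOrderingConcentration:
    def test_consecutive_positions_small_statistic_and_p(self):
        stat, p = ordering_concentration([10, 11, 12], 94,
                                         n_permutations=2000, seed=1)
        assert stat == pytest.approx(4 / 3)
        assert p < 0.01

    def test_spread_positions_large_statistic_and_p(self):
        stat, p = ordering_concentration([1, 47, 94], 94,
                                         n_permutations=2000, seed=2)
        assert stat == pytest.approx(62.0)
        assert p > 0.5

    def test_single_occurrence_is_missing(self):
        stat, p = ordering_concentration([5], 94, seed=3)
        assert math.isnan(stat) and math.isnan(p)

    def test_null_p_values_are_uniform(self):
        """Under random placement the permutation p-values follow the
        uniform distribution (KS check over seeded replicates)."""
        rng = np.random.default_rng(42)
        pvals = []
        for i in range(150):
            positions = rng.choice(60, size=5, replace=False) + 1
            _, p = ordering_concentration(positions, 60,
                                          n_permutations=400, seed=1000 + i)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.005


class TestReplicateConcordance:
    def _merged(self, sample_id, rra):
        return SampleProfile(sample_id=sample_id, total_reads=1000,
                             rra=dict(rra), stage="merged")

    def test_identical_profiles_fully_concordant(self):
        a = self._merged("S1", {"X": 60.0, "Y": 40.0})
        b = self._merged("S2", {"X": 60.0, "Y": 40.0})
        assert replicate_concordance(a, b) == (1.0, 1.0, [])

    def test_rare_taxon_in_one_replicate_listed_discordant(self):
        a = self._merged("S1", {"X": 99.54, "Lymantria monacha": 0.46})
        b = self._merged("S2", {"X": 100.0})
        jac_all, jac_abundant, discordant = replicate_concordance(a, b)
        assert jac_all == pytest.approx(0.5)
        assert jac_abundant == 1.0  # abundant taxa agree
        assert discordant == [{"taxon": "Lymantria monacha",
                               "present_in": "S1", "rra_pct": 0.46}]

    def test_disjoint_profiles(self):
        a = self._merged("S1", {"X": 100.0})
        b = self._merged("S2", {"Y": 100.0})
        jac_all, jac_abundant, discordant = replicate_concordance(a, b)
        assert jac_all == 0.0 and jac_abundant == 0.0
        assert {d["taxon"] for d in discordant} == {"X", "Y"}
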