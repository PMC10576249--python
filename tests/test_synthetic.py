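"""The synthetic-data generator: determinism, calibration, and the
structure of the planted contamination."""

import numpy as np
import pytest

from ednascreen.io_formats import load_dataset
from ednascreen.provenance_tracing import homopolymer_discrepancies
from ednascreen.synthetic_data import (
    CHIMERA,
    CONTAMINANT,
    TRUE_DIET,
    ContaminationScenario,
    DivergenceParams,
    NoiseConfig,
    apply_sequencing_noise,
    generate_dataset,
    generate_reference_library,
    generate_sample_metadata,
    generate_true_communities,
    inject_contamination,
    local_and_foreign_species,
    species_amplicons,
)

from conftest import small_sim_config


def _p_dist(a, b):
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestReferenceLibrary:
    def test_fixed_seed_reproduces_library(self):
        div = DivergenceParams()
        lib1, cl1 = generate_reference_library(8, 4, 1, div, seed=5)
        lib2, cl2 = generate_reference_library(8, 4, 1, div, seed=5)
        assert lib1 == lib2
        assert list(cl1.items()) == list(cl2.items())

    def test_interspecies_divergence_floor_holds(self):
        div = DivergenceParams(min_between_species=0.02)
        lib, _ = generate_reference_library(10, 5, 2, div, seed=6)
        by_species = {}
        for rec in lib:
            by_species.setdefault(rec.species, rec.sequence)
        species = sorted(by_species)
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                amp_a = by_species[a][33:178]
                amp_b = by_species[b][33:178]
                assert _p_dist(amp_a, amp_b) >= 0.02

    def test_requested_congeneric_pair_count(self):
        lib, _ = generate_reference_library(8, 4, 1, DivergenceParams(),
                                            seed=7)
        genera = {}
        for rec in lib:
            genera.setdefault(rec.lineage["genus"], set()).add(rec.species)
        multi = [g for g, sp in genera.items() if len(sp) == 2]
        assert len(multi) == 1

    def test_checklist_distances_split_local_foreign(self):
        lib, checklist = generate_reference_library(6, 3, 0,
                                                    DivergenceParams(),
                                                    seed=8)
        local, foreign = local_and_foreign_species(checklist)
        assert len(local) == 6 and len(foreign) == 3
        assert all(checklist.distance_km(s) > 200 for s in foreign)

    def test_infeasible_divergence_raises(self):
        with pytest.raises(ValueError):
            generate_reference_library(
                4, 2, 0, DivergenceParams(min_between_species=0.6), seed=9)


class TestCommunities:
    def _setup(self, seed=21, n_samples=40, depth_mean=28000.0):
        cfg = small_sim_config()
        cfg.community.depth_mean = depth_mean
        cfg.community.depth_sd = 7000.0
        cfg.samples.category_counts = {"great_tit": n_samples}
        rng = np.random.default_rng(seed)
        lib, checklist = generate_reference_library(
            15, 6, 1, DivergenceParams(), rng)
        metas = generate_sample_metadata(cfg.samples, rng)
        local, foreign = local_and_foreign_species(checklist)
        amplicons = species_amplicons(lib, cfg.library)
        counts, truth = generate_true_communities(
            metas, local, amplicons, cfg.community, rng)
        return cfg, metas, local, foreign, amplicons, counts, truth

    def test_mean_depth_calibrated(self):
        _, metas, _, _, _, counts, _ = self._setup(n_samples=94)
        totals = [sum(c.get(m.sample_id, 0) for c in counts.values())
                  for m in metas if not m.is_negative_control]
        se = 7000 / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 28000) < 3 * se

    def test_no_foreign_species_in_truth_only_tables(self):
        _, _, _, foreign, amplicons, counts, truth = self._setup()
        foreign_seqs = {amplicons[s] for s in foreign}
        assert not (set(counts) & foreign_seqs)
        assert all(row["origin"] == TRUE_DIET for row in truth)

    def test_single_species_composition_is_all_of_sample(self):
        cfg, metas, local, _, amplicons, _, _ = self._setup()
        cfg.community.richness_mean = 0.0
        cfg.community.richness_min = 1
        rng = np.random.default_rng(3)
        counts, _ = generate_true_communities(
            metas, local[:1], amplicons, cfg.community, rng)
        assert len(counts) == 1  # one variant carries 100% everywhere


class TestContamination:
    def _base(self, seed=31):
        cfg, metas, local, foreign, amplicons, counts, truth = \
            TestCommunities()._setup(seed=seed)
        rng = np.random.default_rng(seed + 1)
        return cfg, metas, foreign, amplicons, counts, rng

    def test_lab_window_confines_occurrences(self):
        cfg, metas, foreign, amplicons, counts, rng = self._base()
        scenario = ContaminationScenario(
            mode="lab_point_source", contaminant_species=2,
            target_window=(0.25, 0.5), rra_level=(1.0, 5.0),
            per_sample_probability=1.0)
        truth = inject_contamination(counts, metas, foreign, amplicons,
                                     [scenario], rng)
        assert truth  # some samples were hit
        analysis = [m for m in metas if not m.is_negative_control]
        idx = [m.processing_index for m in analysis]
        lo = min(idx) + 0.25 * (max(idx) - min(idx))
        hi = min(idx) + 0.5 * (max(idx) - min(idx))
        meta_of = {m.sample_id: m for m in metas}
        for row in truth:
            assert lo <= meta_of[row["sample_id"]].processing_index <= hi

    def test_background_mostly_below_filter(self):
        cfg, metas, foreign, amplicons, counts, rng = self._base(seed=41)
        scenario = ContaminationScenario(
            mode="background_carryover", contaminant_species=4,
            rra_level=(0.05, 0.05), per_sample_probability=1.0)
        truth = inject_contamination(counts, metas, foreign, amplicons,
                                     [scenario], rng)
        below = 0
        for row in truth:
            seq, sid = None, row["sample_id"]
            seq = row["sequence"]
            total = sum(c.get(sid, 0) for c in counts.values())
            rra = 100.0 * counts[seq][sid] / total
            below += rra < 0.1
        assert len(truth) >= 20
        assert below / len(truth) >= 0.9

    def test_empty_window_raises(self):
        cfg, metas, foreign, amplicons, counts, rng = self._base(seed=51)
        # a zero-width window between two processing indices catches nobody
        scenario = ContaminationScenario(
            mode="lab_point_source", contaminant_species=1,
            target_window=(0.001, 0.002), rra_level=(1.0, 2.0),
            per_sample_probability=1.0)
        with pytest.raises(ValueError, match="zero samples"):
            inject_contamination(counts, metas, foreign, amplicons,
                                 [scenario], rng)

    def test_empty_scenario_list_is_identity(self):
        cfg, metas, foreign, amplicons, counts, rng = self._base(seed=61)
        before = {s: dict(c) for s, c in counts.items()}
        truth = inject_contamination(counts, metas, foreign, amplicons,
                                     [], rng)
        assert truth == [] and counts == before


class TestSequencingNoise:
    def test_zero_rates_change_nothing(self):
        counts = {"ACGT" * 40: {"S1": 1000}}
        before = {s: dict(c) for s, c in counts.items()}
        truth = apply_sequencing_noise(counts, np.random.default_rng(1),
                                       NoiseConfig(0.0, 0.0, 0.0))
        assert truth == [] and counts == before

    def test_certain_homopolymer_deletion_is_detectable(self):
        parent = "ACG" + "T" * 7 + "ACGTAC" * 20 + "GGA"
        counts = {parent: {"S1": 10_000}}
        apply_sequencing_noise(counts, np.random.default_rng(2),
                               NoiseConfig(0.0, 0.1, 0.0))
        # per-run probability is capped at 0.1; force by repetition
        rng = np.random.default_rng(3)
        for _ in range(200):
            if len(counts) > 1:
                break
            apply_sequencing_noise(counts, rng, NoiseConfig(0.0, 0.1, 0.0))
        variants = [s for s in counts if s != parent]
        assert variants
        events = homopolymer_discrepancies(parent, variants[0],
                                           min_overlap_bp=100)
        assert len(events) == 1
        assert {events[0].run_length_a, events[0].run_length_b} == {6, 7}

    def test_chimera_joins_prefix_and_suffix(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), 145))
        b = "".join(rng.choice(list("ACGT"), 145))
        counts = {a: {"S1": 5000}, b: {"S1": 5000}}
        truth = []
        for seed in range(50):
            truth = apply_sequencing_noise(
                counts, np.random.default_rng(seed),
                NoiseConfig(0.0, 0.0, 0.1))
            if truth:
                break
        assert truth and truth[0]["origin"] == CHIMERA
        chimera = truth[0]["sequence"]
        bp = next(i for i in range(146) if chimera[:i] + b[i:] == chimera
                  and chimera[:i] == a[:i])
        assert chimera == a[:bp] + b[bp:]


class TestGenerateDataset:
    def test_output_loads_cleanly(self, clean_sim):
        ds = load_dataset(clean_sim.paths["asv_table"],
                          clean_sim.paths["reference"],
                          clean_sim.paths["metadata"],
                          clean_sim.paths["checklist"],
                          clean_sim.paths["thresholds"])
        assert len(ds.asvs) == len(clean_sim.dataset.asvs)
        assert len(ds.metas) == len(clean_sim.dataset.metas)

    def test_same_seed_gives_identical_files(self, tmp_path):
        cfg = small_sim_config()
        sim1 = generate_dataset(cfg, tmp_path / "a", seed=99)
        sim2 = generate_dataset(small_sim_config(), tmp_path / "b", seed=99)
        for key in sim1.paths:
            assert sim1.paths[key].read_bytes() == \
                sim2.paths[key].read_bytes(), key

    def test_truth_covers_every_read_bearing_cell_once(self, clean_sim):
        truth = clean_sim.truth
        assert not truth.duplicated(["sample_id", "asv_id"]).any()
        cells = {(a.asv_id, s) for a in clean_sim.dataset.asvs
                 for s, n in a.counts.items() if n > 0}
        labelled = {(r.asv_id, r.sample_id)
                    for r in truth.itertuples()}
        assert cells == labelled

    def test_truth_row_counts_match_origins(self, tmp_path):
        cfg = small_sim_config(
            noise=NoiseConfig(sub_rate=0.002, homopolymer_del_prob=0.05,
                              chimera_rate=0.02))
        sim = generate_dataset(cfg, tmp_path, seed=13)
        origins = set(sim.truth["origin"])
        assert TRUE_DIET in origins and CONTAMINANT in origins
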