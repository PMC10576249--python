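"""Synthetic metabarcoding datasets with ground-truth contamination labels.

The generator emulates the statistical structure the screening pipeline
assumes so every stage is testable without downloads:

* a reference barcode library of full-length (658 bp) sequences for a
  local species pool and a non-local ("foreign") pool, with congeneric
  near-match pairs and optional within-species haplotypes; the 145 bp
  amplicon is a fixed window of each reference;
* per-sample true diets: log-normally distributed community composition
  sampled multinomially at sequencing depths around a mean of ~28,000
  reads per sample;
* contaminant injection structured in lab processing order
  (``lab_point_source``), in field collection time
  (``field_environmental``), or as low-level background carryover
  everywhere (``background_carryover``);
* sequencing noise: substitution error variants, homopolymer-run
  shortening and chimeric recombinants that split reads off their
  parents.

Every read-bearing cell of the generated table carries exactly one
origin label in the truth table (``true_diet``, ``contaminant``,
``chimera`` or ``error_variant``), which downstream recovery tests use
as ground truth. All randomness flows from one seeded generator; a
fixed seed reproduces the output byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    ASVRecord,
    Dataset,
    LocalityChecklist,
    ReferenceRecord,
    SampleMeta,
    ScreeningThresholds,
    write_asv_table,
    write_checklist,
    write_metadata,
    write_reference_fasta,
)

BASES = "ACGT"

TRUE_DIET = "true_diet"
CONTAMINANT = "contaminant"
CHIMERA = "chimera"
ERROR_VARIANT = "error_variant"

TRUTH_COLUMNS = ["sample_id", "asv_id", "origin", "mode", "parent"]


@dataclass
class DivergenceParams:
    """Within-species haplotype divergence range and the minimum
    between-species divergence, as p-distance proportions (0-1)."""

    within_species: tuple[float, float] = (0.0, 0.01)
    min_between_species: float = 0.02


@dataclass
class LibraryConfig:
    n_local_species: int = 60
    n_foreign_species: int = 25  # matches the 25 non-local species observed
    n_congeneric_pairs: int = 3
    ref_length: int = 658
    amplicon_start: int = 33
    amplicon_length: int = 145
    haplotype_fraction: float = 0.1  # local species given a 2nd reference
    divergence: DivergenceParams = field(default_factory=DivergenceParams)


@dataclass
class SampleConfig:
    """Sample layout mirroring a single ~94-sample nestling-season batch:
    four parid/flycatcher host categories plus environmental frass."""

    category_counts: dict = field(default_factory=lambda: {
        "crested_tit": 9, "willow_tit": 24, "blue_tit": 16,
        "great_tit": 24, "frass_sheet": 21,
    })
    n_negative_controls: int = 2
    n_replicate_pairs: int = 2
    season_start: datetime.date = datetime.date(2017, 5, 14)
    season_end: datetime.date = datetime.date(2017, 7, 17)
    batch: str = "batch1"

    @property
    def n_samples(self) -> int:
        return sum(self.category_counts.values())


@dataclass
class CommunityConfig:
    depth_mean: float = 28145.0
    depth_sd: float = 7200.0  # SE 743 on 94 samples
    depth_min: int = 500
    richness_mean: float = 10.0
    richness_min: int = 3
    lognormal_sigma: float = 1.2
    category_pool_fraction: float = 0.7


@dataclass
class ContaminationScenario:
    """One hypothesized contamination pathway.

    ``contaminant_species`` is either a list of species names from the
    non-local pool or an integer count resolved (seeded) against that
    pool. ``target_window`` is a (lo, hi) fraction of the processing
    order (lab mode) or of the collection-date span (field mode);
    ignored for background carryover. ``rra_level`` is the per-event
    relative-abundance draw range in percent for the point-source modes,
    and the *expected* abundance for background carryover.
    """

    mode: str  # lab_point_source | field_environmental | background_carryover
    contaminant_species: list | int = 3
    target_window: tuple[float, float] = (0.0, 1.0)
    rra_level: tuple[float, float] = (1.0, 10.0)
    per_sample_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("lab_point_source", "field_environmental",
                             "background_carryover"):
            raise ValueError(f"unknown contamination mode {self.mode!r}")
        lo, hi = self.target_window
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("target_window must satisfy 0 <= lo <= hi <= 1")
        if not (0.0 < self.rra_level[0] <= self.rra_level[1] <= 60.0):
            raise ValueError("rra_level must lie within (0, 60] percent")
        if not (0.0 <= self.per_sample_probability <= 1.0):
            raise ValueError("per_sample_probability must be in [0, 1]")


@dataclass
class NoiseConfig:
    sub_rate: float = 0.001  # per-base substitution error
    homopolymer_del_prob: float = 0.05  # per run of length >= 6
    chimera_rate: float = 0.01  # per parent variant
    variant_read_fraction: tuple[float, float] = (0.02, 0.1)

    def __post_init__(self) -> None:
        for name in ("sub_rate", "homopolymer_del_prob", "chimera_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.1):
                raise ValueError(f"{name} must be within [0, 0.1], got {v}")


@dataclass
class SimulationConfig:
    library: LibraryConfig = field(default_factory=LibraryConfig)
    samples: SampleConfig = field(default_factory=SampleConfig)
    community: CommunityConfig = field(default_factory=CommunityConfig)
    scenarios: list[ContaminationScenario] = field(default_factory=list)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    thresholds: ScreeningThresholds = field(
        default_factory=ScreeningThresholds)


def default_config() -> SimulationConfig:
    """The default simulated study: a ~94-sample season with one lab
    point-source event, a weaker field episode and ubiquitous trace
    carryover, calibrated so that per-sample non-local totals span
    roughly 0.1-55% and a majority of samples carry at least one
    non-local occurrence."""
    return SimulationConfig(scenarios=[
        ContaminationScenario(
            mode="lab_point_source", contaminant_species=8,
            target_window=(0.3, 0.7), rra_level=(0.5, 40.0),
            per_sample_probability=0.8),
        ContaminationScenario(
            mode="field_environmental", contaminant_species=4,
            target_window=(0.25, 0.75), rra_level=(0.2, 6.0),
            per_sample_probability=0.35),
        ContaminationScenario(
            mode="background_carryover", contaminant_species=4,
            rra_level=(0.05, 0.05), per_sample_probability=0.5),
    ])


# ---------------------------------------------------------------------------
# reference library


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _mutate(rng: np.random.Generator, sequence: str, n_sub: int,
            lo: int = 0, hi: Optional[int] = None) -> str:
    """Substitute ``n_sub`` distinct positions within [lo, hi)."""
    hi = len(sequence) if hi is None else hi
    positions = rng.choice(np.arange(lo, hi), size=n_sub, replace=False)
    out = list(sequence)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def _p_distance(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


def generate_reference_library(
    n_local_species: int,
    n_foreign_species: int,
    n_congeneric_pairs: int,
    divergence_params: DivergenceParams,
    seed: int | np.random.Generator,
    ref_length: int = 658,
    amplicon_start: int = 33,
    amplicon_length: int = 145,
    haplotype_fraction: float = 0.1,
) -> tuple[list[ReferenceRecord], LocalityChecklist]:
    """Seeded reference library plus matching locality checklist.

    Species barcodes are mutually separated by at least the configured
    between-species divergence over the amplicon window; congeneric
    pairs sit just above that floor. Local species receive checklist
    distances <= 200 km, foreign ones > 200 km.
    """
    if n_local_species < 1 or n_foreign_species < 1:
        raise ValueError("need at least one local and one foreign species")
    if 2 * n_congeneric_pairs > n_local_species:
        raise ValueError("more congeneric pairs than local species allow")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    amp_lo = amplicon_start
    amp_hi = amplicon_start + amplicon_length
    if amp_hi > ref_length:
        raise ValueError("amplicon window exceeds reference length")
    min_between = divergence_params.min_between_species
    pair_subs_amp = int(np.ceil(min_between * amplicon_length)) + 1
    if pair_subs_amp >= amplicon_length // 2:
        raise ValueError("between-species divergence constraint infeasible")

    n_total = n_local_species + n_foreign_species
    sequences: list[str] = []
    genera: list[str] = []
    species_names: list[str] = []
    next_genus = 0
    i = 0
    while i < n_total:
        in_pair = i < 2 * n_congeneric_pairs and i % 2 == 1
        if in_pair:
            # congener: perturb the previous species just past the floor
            base = sequences[i - 1]
            for _ in range(100):
                cand = _mutate(rng, base, pair_subs_amp, amp_lo, amp_hi)
                cand = _mutate(rng, cand,
                               int(np.ceil(min_between * ref_length)),
                               0, amp_lo)
                if _ok_divergence(cand, sequences, amp_lo, amp_hi,
                                  min_between):
                    break
            else:
                raise ValueError("could not satisfy divergence constraints")
            genus = genera[i - 1]
        else:
            for _ in range(100):
                cand = _random_sequence(rng, ref_length)
                if _ok_divergence(cand, sequences, amp_lo, amp_hi,
                                  min_between):
                    break
            else:
                raise ValueError("could not satisfy divergence constraints")
            genus = f"Genus{next_genus:03d}"
            next_genus += 1
        sequences.append(cand)
        genera.append(genus)
        species_names.append(f"{genus} species{i:03d}")
        i += 1

    records: list[ReferenceRecord] = []
    checklist_entries: dict[str, tuple[float, str]] = {}
    ref_counter = 0
    n_haplo = int(round(haplotype_fraction * n_local_species))
    within_lo, within_hi = divergence_params.within_species
    for i, (seq, genus, species) in enumerate(
            zip(sequences, genera, species_names)):
        is_local = i < n_local_species
        family = f"Family{i % 9:02d}"
        lineage = {"order": "Lepidoptera", "family": family,
                   "genus": genus, "species": species}
        records.append(ReferenceRecord(
            ref_id=f"REF{ref_counter:04d}", sequence=seq,
            lineage=lineage, species=species))
        ref_counter += 1
        if is_local and i >= 2 * n_congeneric_pairs and n_haplo > 0:
            # a within-species haplotype: 1-2 substitutions on 658 bp
            n_haplo -= 1
            max_sub = max(1, int(within_hi * ref_length))
            k = int(rng.integers(1, max_sub + 1))
            hap = _mutate(rng, seq, k)
            records.append(ReferenceRecord(
                ref_id=f"REF{ref_counter:04d}", sequence=hap,
                lineage=lineage, species=species))
            ref_counter += 1
        if is_local:
            dist = float(np.round(rng.uniform(0.0, 150.0), 1))
            note = "synthetic local species"
        else:
            dist = float(np.round(rng.uniform(250.0, 2500.0), 1))
            note = "synthetic non-local species"
        checklist_entries[species] = (dist, note)
    return records, LocalityChecklist(checklist_entries)


def _ok_divergence(candidate: str, accepted: Sequence[str],
                   amp_lo: int, amp_hi: int, min_between: float) -> bool:
    cand_amp = candidate[amp_lo:amp_hi]
    for other in accepted:
        if _p_distance(cand_amp, other[amp_lo:amp_hi]) < min_between:
            return False
        if _p_distance(candidate, other) < min_between:
            return False
    return True


def local_and_foreign_species(
        checklist: LocalityChecklist,
        nonlocal_distance_km: float = 200.0) -> tuple[list[str], list[str]]:
    local, foreign = [], []
    for species, (dist, _) in checklist.items():
        (local if dist <= nonlocal_distance_km else foreign).append(species)
    return local, foreign


def amplicon_of(record: ReferenceRecord, config: LibraryConfig) -> str:
    lo = config.amplicon_start
    return record.sequence[lo:lo + config.amplicon_length]


def species_amplicons(records: Sequence[ReferenceRecord],
                      config: LibraryConfig) -> dict[str, str]:
    """Species -> amplicon of its first reference record."""
    out: dict[str, str] = {}
    for rec in sorted(records, key=lambda r: r.ref_id):
        out.setdefault(rec.species, amplicon_of(rec, config))
    return out


# ---------------------------------------------------------------------------
# sample metadata


def generate_sample_metadata(config: SampleConfig,
                             rng: np.random.Generator) -> list[SampleMeta]:
    n = config.n_samples
    span = (config.season_end - config.season_start).days
    categories = [c for c in sorted(config.category_counts)
                  for _ in range(config.category_counts[c])]
    rng.shuffle(categories)
    offsets = np.sort(rng.integers(0, span + 1, size=n))
    processing = rng.permutation(n) + 1  # decoupled from collection order
    metas = []
    for i in range(n):
        metas.append(SampleMeta(
            sample_id=f"S{i + 1:03d}",
            category=categories[i],
            collection_date=config.season_start
            + datetime.timedelta(days=int(offsets[i])),
            processing_index=int(processing[i]),
            batch=config.batch,
        ))
    # technical replicate pairs within a category, sharing collection date
    by_category: dict[str, list[int]] = {}
    for idx, m in enumerate(metas):
        by_category.setdefault(m.category, []).append(idx)
    eligible = [c for c in sorted(by_category) if len(by_category[c]) >= 2]
    for k in range(config.n_replicate_pairs):
        if not eligible:
            break
        cat = eligible[k % len(eligible)]
        i1, i2 = by_category[cat][2 * (k // len(eligible)):][:2]
        group = f"rep{k + 1:02d}"
        metas[i1] = dataclasses.replace(metas[i1], replicate_group=group)
        metas[i2] = dataclasses.replace(
            metas[i2], replicate_group=group,
            collection_date=metas[i1].collection_date)
    for j in range(config.n_negative_controls):
        metas.append(SampleMeta(
            sample_id=f"NC{j + 1:02d}",
            category="negative_control",
            collection_date=None,
            processing_index=n + j + 1,
            batch=config.batch,
            is_negative_control=True,
        ))
    return metas


# ---------------------------------------------------------------------------
# true communities


def generate_true_communities(
    metas: Sequence[SampleMeta],
    local_species: Sequence[str],
    amplicons: Mapping[str, str],
    config: CommunityConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, dict[str, int]], list[dict]]:
    """Per-sample diet reads; only local species ever appear.

    Returns ``counts`` (sequence -> sample -> reads) and truth rows.
    Technical replicates share a composition and redraw only the reads.
    """
    local_species = sorted(local_species)
    categories = sorted({m.category for m in metas
                         if not m.is_negative_control})
    pool_size = max(config.richness_min + 1,
                    int(round(config.category_pool_fraction
                              * len(local_species))))
    pools = {
        c: sorted(rng.choice(local_species,
                             size=min(pool_size, len(local_species)),
                             replace=False))
        for c in categories
    }
    counts: dict[str, dict[str, int]] = {}
    truth: list[dict] = []
    compositions: dict[str, tuple[list[str], np.ndarray]] = {}

    for m in sorted((m for m in metas if not m.is_negative_control),
                    key=lambda m: m.sample_id):
        if m.replicate_group and m.replicate_group in compositions:
            chosen, probs = compositions[m.replicate_group]
        else:
            pool = pools[m.category]
            k = min(len(pool),
                    max(config.richness_min, int(rng.poisson(
                        config.richness_mean))))
            chosen = sorted(rng.choice(pool, size=k, replace=False))
            weights = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma,
                                    size=k)
            probs = weights / weights.sum()
            if m.replicate_group:
                compositions[m.replicate_group] = (chosen, probs)
        depth = max(config.depth_min,
                    int(round(rng.normal(config.depth_mean,
                                         config.depth_sd))))
        reads = rng.multinomial(depth, probs)
        for species, nreads in zip(chosen, reads):
            if nreads == 0:
                continue
            seq = amplicons[species]
            counts.setdefault(seq, {})[m.sample_id] = (
                counts.get(seq, {}).get(m.sample_id, 0) + int(nreads))
            truth.append({"sample_id": m.sample_id, "sequence": seq,
                          "origin": TRUE_DIET, "mode": "",
                          "parent": species})
    return counts, truth


# ---------------------------------------------------------------------------
# contamination


def _sample_total(counts: Mapping[str, Mapping[str, int]],
                  sample_id: str) -> int:
    return sum(c.get(sample_id, 0) for c in counts.values())


def inject_contamination(
    counts: dict[str, dict[str, int]],
    metas: Sequence[SampleMeta],
    foreign_species: Sequence[str],
    amplicons: Mapping[str, str],
    scenarios: Sequence[ContaminationScenario],
    rng: np.random.Generator,
) -> list[dict]:
    """Add contaminant reads per scenario; returns truth rows.

    Lab mode touches only samples inside the processing-index window,
    field mode only inside the collection-date window, background mode
    adds low Poisson reads everywhere. Read counts are chosen so the
    realized relative abundance approximates the scenario's level.
    """
    foreign_species = sorted(foreign_species)
    analysis = sorted((m for m in metas if not m.is_negative_control),
                      key=lambda m: m.sample_id)
    truth: list[dict] = []
    occupied: set[tuple[str, str]] = set()

    for scenario in scenarios:
        if isinstance(scenario.contaminant_species, int):
            k = min(scenario.contaminant_species, len(foreign_species))
            species_list = sorted(rng.choice(foreign_species, size=k,
                                             replace=False))
        else:
            species_list = sorted(scenario.contaminant_species)
        if not species_list:
            continue
        eligible = _eligible_samples(analysis, scenario)
        if not eligible:
            raise ValueError(
                f"scenario {scenario.mode} window {scenario.target_window} "
                "selects zero samples")
        if scenario.mode == "background_carryover":
            expected = scenario.rra_level[0]
            for m in eligible:
                total = _sample_total(counts, m.sample_id)
                for species in species_list:
                    if rng.random() >= scenario.per_sample_probability:
                        continue
                    reads = int(rng.poisson(expected / 100.0 * total))
                    seq = amplicons[species]
                    if reads == 0 or (m.sample_id, seq) in occupied:
                        continue
                    _add_reads(counts, seq, m.sample_id, reads)
                    occupied.add((m.sample_id, seq))
                    truth.append({"sample_id": m.sample_id, "sequence": seq,
                                  "origin": CONTAMINANT,
                                  "mode": scenario.mode, "parent": species})
        else:
            for m in eligible:
                if rng.random() >= scenario.per_sample_probability:
                    continue
                species = str(rng.choice(species_list))
                seq = amplicons[species]
                if (m.sample_id, seq) in occupied:
                    continue
                total = _sample_total(counts, m.sample_id)
                r = rng.uniform(*scenario.rra_level)
                reads = max(1, int(round(r / (100.0 - r) * total)))
                _add_reads(counts, seq, m.sample_id, reads)
                occupied.add((m.sample_id, seq))
                truth.append({"sample_id": m.sample_id, "sequence": seq,
                              "origin": CONTAMINANT,
                              "mode": scenario.mode, "parent": species})
    return truth


def _eligible_samples(metas: Sequence[SampleMeta],
                      scenario: ContaminationScenario) -> list[SampleMeta]:
    if scenario.mode == "background_carryover":
        return list(metas)
    lo_f, hi_f = scenario.target_window
    if scenario.mode == "lab_point_source":
        values = [m.processing_index for m in metas]
        key = lambda m: m.processing_index  # noqa: E731
    else:
        if any(m.collection_date is None for m in metas):
            raise ValueError("field scenario requires collection dates")
        values = [m.collection_date.toordinal() for m in metas]
        key = lambda m: m.collection_date.toordinal()  # noqa: E731
    vmin, vmax = min(values), max(values)
    lo = vmin + lo_f * (vmax - vmin)
    hi = vmin + hi_f * (vmax - vmin)
    return [m for m in metas if lo <= key(m) <= hi]


def _add_reads(counts: dict[str, dict[str, int]], seq: str,
               sample_id: str, reads: int) -> None:
    counts.setdefault(seq, {})
    counts[seq][sample_id] = counts[seq].get(sample_id, 0) + reads


# ---------------------------------------------------------------------------
# sequencing noise


def _find_runs(sequence: str, min_length: int) -> list[tuple[int, int, str]]:
    runs = []
    i = 0
    while i < len(sequence):
        j = i
        while j < len(sequence) and sequence[j] == sequence[i]:
            j += 1
        if j - i >= min_length:
            runs.append((i, j - i, sequence[i]))
        i = j
    return runs


def apply_sequencing_noise(
    counts: dict[str, dict[str, int]],
    rng: np.random.Generator,
    noise: NoiseConfig,
) -> list[dict]:
    """Split error-variant and chimeric reads off existing parents.

    Substitution variants appear with probability ``1-(1-sub_rate)^L``
    per parent; homopolymer variants shorten each run of length >= 6
    with probability ``homopolymer_del_prob``; chimeras join the prefix
    and suffix of two co-occurring parents at a uniform breakpoint.
    All rates zero leaves the dataset untouched.
    """
    truth: list[dict] = []
    parents = sorted(counts)
    frac_lo, frac_hi = noise.variant_read_fraction

    def _split_off(parent: str, variant: str, origin: str, mode: str,
                   parent_label: str,
                   only_samples: Optional[set[str]] = None) -> None:
        if variant in counts:
            return  # collision with an existing variant: keep origins unique
        created = False
        for sample_id in sorted(counts[parent]):
            if only_samples is not None and sample_id not in only_samples:
                continue
            reads = counts[parent][sample_id]
            if reads < 10:
                continue
            moved = max(1, int(round(rng.uniform(frac_lo, frac_hi) * reads)))
            counts[parent][sample_id] = reads - moved
            _add_reads(counts, variant, sample_id, moved)
            truth.append({"sample_id": sample_id, "sequence": variant,
                          "origin": origin, "mode": mode,
                          "parent": parent_label})
            created = True
        if not created and variant in counts and not counts[variant]:
            del counts[variant]

    for parent in parents:
        length = len(parent)
        if noise.sub_rate > 0 and rng.random() < 1 - (1 - noise.sub_rate) ** length:
            k = 1 + int(rng.poisson(0.5))
            variant = _mutate(rng, parent, min(k, length))
            _split_off(parent, variant, ERROR_VARIANT, "substitution", parent)
        if noise.homopolymer_del_prob > 0:
            for start, run_len, base in _find_runs(parent, 6):
                if rng.random() < noise.homopolymer_del_prob:
                    variant = parent[:start] + base * (run_len - 1) \
                        + parent[start + run_len:]
                    _split_off(parent, variant, ERROR_VARIANT,
                               "homopolymer", parent)

    if noise.chimera_rate > 0:
        n_chimeras = int(rng.binomial(len(parents), noise.chimera_rate))
        for _ in range(n_chimeras):
            pair = _co_occurring_pair(counts, parents, rng)
            if pair is None:
                break
            pa, pb, shared = pair
            bp = int(rng.integers(40, min(106, len(pa))))
            chimera = pa[:bp] + pb[bp:]
            if chimera in counts:
                continue
            for sample_id in sorted(shared):
                moved = 0
                for parent in (pa, pb):
                    reads = counts[parent][sample_id]
                    if reads < 10:
                        continue
                    take = max(1, int(round(0.02 * reads)))
                    counts[parent][sample_id] = reads - take
                    moved += take
                if moved:
                    _add_reads(counts, chimera, sample_id, moved)
                    truth.append({"sample_id": sample_id,
                                  "sequence": chimera, "origin": CHIMERA,
                                  "mode": "", "parent": f"{pa[:8]}+{pb[:8]}"})
    return truth


def _co_occurring_pair(counts, parents, rng):
    samples: dict[str, list[str]] = {}
    for p in parents:
        for s, n in counts[p].items():
            if n >= 10:
                samples.setdefault(s, []).append(p)
    rich = sorted(s for s, ps in samples.items() if len(ps) >= 2)
    if not rich:
        return None
    s = str(rng.choice(rich))
    pa, pb = rng.choice(samples[s], size=2, replace=False)
    shared = {
        sid for sid in counts[pa]
        if counts[pa].get(sid, 0) >= 10 and counts[pb].get(sid, 0) >= 10
    }
    return str(pa), str(pb), shared


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SimulatedDataset:
    dataset: Dataset
    truth: pd.DataFrame
    paths: dict[str, Path]
    config: SimulationConfig
    seed: int


def generate_dataset(config: SimulationConfig, out_dir: str | Path,
                     seed: int) -> SimulatedDataset:
    """One call producing a complete runnable input set on disk plus the
    ground-truth table; deterministic per seed."""
    rng = np.random.default_rng(seed)
    lib = config.library
    records, checklist = generate_reference_library(
        lib.n_local_species, lib.n_foreign_species, lib.n_congeneric_pairs,
        lib.divergence, rng, ref_length=lib.ref_length,
        amplicon_start=lib.amplicon_start,
        amplicon_length=lib.amplicon_length,
        haplotype_fraction=lib.haplotype_fraction)
    metas = generate_sample_metadata(config.samples, rng)
    local, foreign = local_and_foreign_species(
        checklist, config.thresholds.nonlocal_distance_km)
    amplicons = species_amplicons(records, lib)

    counts, truth_rows = generate_true_communities(
        metas, local, amplicons, config.community, rng)
    truth_rows += inject_contamination(
        counts, metas, foreign, amplicons, config.scenarios, rng)
    truth_rows += apply_sequencing_noise(counts, rng, config.noise)

    # trace carryover into negative controls: a few reads of the globally
    # dominant variant, mimicking the low-level counts real controls show
    controls = [m for m in metas if m.is_negative_control]
    if controls and counts:
        dominant = max(sorted(counts),
                       key=lambda s: sum(counts[s].values()))
        for m in controls:
            reads = int(rng.poisson(2))
            if reads:
                _add_reads(counts, dominant, m.sample_id, reads)
                truth_rows.append({
                    "sample_id": m.sample_id, "sequence": dominant,
                    "origin": CONTAMINANT, "mode": "background_carryover",
                    "parent": "control_carryover"})

    # assign variant ids in deterministic (sequence-sorted) order
    sequences = sorted(s for s in counts if any(v > 0
                                                for v in counts[s].values()))
    seq_to_id = {s: f"ASV{i + 1:04d}" for i, s in enumerate(sequences)}
    sample_ids = sorted(m.sample_id for m in metas)
    asvs = [
        ASVRecord(asv_id=seq_to_id[s], sequence=s,
                  counts={sid: counts[s].get(sid, 0) for sid in sample_ids})
        for s in sequences
    ]
    truth = pd.DataFrame([
        {"sample_id": row["sample_id"],
         "asv_id": seq_to_id[row["sequence"]],
         "origin": row["origin"], "mode": row["mode"],
         "parent": row["parent"]}
        for row in truth_rows if row["sequence"] in seq_to_id
    ], columns=TRUTH_COLUMNS)
    truth = truth.sort_values(TRUTH_COLUMNS).reset_index(drop=True)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "asv_table": out / "asv_table.tsv",
        "reference": out / "reference.fasta",
        "metadata": out / "metadata.tsv",
        "checklist": out / "checklist.tsv",
        "thresholds": out / "thresholds.yaml",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.yaml",
    }
    write_asv_table(asvs, sample_ids, paths["asv_table"])
    write_reference_fasta(records, paths["reference"])
    write_metadata(sorted(metas, key=lambda m: m.sample_id),
                   paths["metadata"])
    write_checklist(checklist, paths["checklist"])
    config.thresholds.to_yaml(paths["thresholds"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"].write_text(yaml.safe_dump(config_to_dict(config, seed),
                                              sort_keys=True))

    dataset = Dataset(asvs=asvs, references=records,
                      metas={m.sample_id: m for m in metas},
                      checklist=checklist, thresholds=config.thresholds)
    return SimulatedDataset(dataset=dataset, truth=truth, paths=paths,
                            config=config, seed=seed)


def config_to_dict(config: SimulationConfig, seed: Optional[int] = None) -> dict:
    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _clean(v)
                    for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, datetime.date):
            return obj.isoformat()
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    out = _clean(config)
    if seed is not None:
        out["seed"] = int(seed)
    return out
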