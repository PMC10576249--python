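"""Flagging non-local species observations and their occurrence patterns.

A variant observation is flagged when (i) its assignment is at species
rank, (ii) the match is of the strict confidence class (>99%, at most one
mismatch by default), and (iii) the species' nearest known occurrence is
strictly beyond the non-local distance (200 km by default). Observations
that match a non-local species at standard-but-not-strict confidence, and
rank-level assignments all of whose tied candidates are non-local, are
reported separately as near-threshold rather than flagged. Species absent
from the locality checklist are listed as "unknown locality", never
silently treated as local.

The module also provides the pattern analyses run over the flags: sample
occurrence matrices ordered by collection date or lab processing order, a
permutation test for positional concentration of a species' occurrences
within an ordering, Spearman correlations of non-local abundance with
sequencing depth and variant richness, and replicate concordance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance_filtering import SampleProfile
from .io_formats import LocalityChecklist, SampleMeta, ScreeningThresholds
from .taxonomic_assignment import AssignmentResult


@dataclass(frozen=True)
class NonlocalFlag:
    asv_id: str
    species: str
    sample_id: str
    rra_pct: float
    strict: bool = True


@dataclass(frozen=True)
class NearThresholdRecord:
    name: str  # species, or rank-level name for unresolved ties
    asv_id: str
    sample_id: str
    rra_pct: float
    reason: str  # standard_confidence | unresolved_nonlocal_tie


@dataclass(frozen=True)
class UnknownLocalityRecord:
    species: str
    asv_id: str
    sample_id: str
    rra_pct: float


@dataclass
class ScreenFlags:
    flags: list[NonlocalFlag]
    near_threshold: list[NearThresholdRecord]
    unknown_locality: list[UnknownLocalityRecord]


def flag_nonlocal(assignments: Mapping[str, AssignmentResult],
                  profiles_filtered: Mapping[str, SampleProfile],
                  checklist: LocalityChecklist,
                  thresholds: ScreeningThresholds) -> ScreenFlags:
    """One flag per (ASV, sample) occurrence of a strict species-rank match
    to a species beyond the non-local distance. The flag set is invariant
    to input ordering (results are canonically sorted)."""
    flags: list[NonlocalFlag] = []
    near: list[NearThresholdRecord] = []
    unknown: list[UnknownLocalityRecord] = []

    occurrences: dict[str, list[tuple[str, float]]] = {}
    for sample_id in sorted(profiles_filtered):
        profile = profiles_filtered[sample_id]
        for asv_id, rra in profile.rra.items():
            if rra > 0:
                occurrences.setdefault(asv_id, []).append((sample_id, rra))

    for asv_id in sorted(occurrences):
        a = assignments.get(asv_id)
        if a is None or a.is_no_match:
            continue
        if a.assigned_rank == "species":
            distance = checklist.distance_km(a.assigned_name)
            if distance is None:
                for sample_id, rra in occurrences[asv_id]:
                    unknown.append(UnknownLocalityRecord(
                        species=a.assigned_name, asv_id=asv_id,
                        sample_id=sample_id, rra_pct=rra))
            elif distance > thresholds.nonlocal_distance_km:
                if a.confidence_class == "strict":
                    for sample_id, rra in occurrences[asv_id]:
                        flags.append(NonlocalFlag(
                            asv_id=asv_id, species=a.assigned_name,
                            sample_id=sample_id, rra_pct=rra))
                else:
                    for sample_id, rra in occurrences[asv_id]:
                        near.append(NearThresholdRecord(
                            name=a.assigned_name, asv_id=asv_id,
                            sample_id=sample_id, rra_pct=rra,
                            reason="standard_confidence"))
        elif a.tied_species:
            known = [checklist.distance_km(sp) for sp in a.tied_species]
            if all(d is not None and d > thresholds.nonlocal_distance_km
                   for d in known):
                for sample_id, rra in occurrences[asv_id]:
                    near.append(NearThresholdRecord(
                        name=f"{a.assigned_name} [{a.assigned_rank}]",
                        asv_id=asv_id, sample_id=sample_id, rra_pct=rra,
                        reason="unresolved_nonlocal_tie"))

    flags.sort(key=lambda f: (f.species, f.sample_id, f.asv_id))
    near.sort(key=lambda f: (f.name, f.sample_id, f.asv_id))
    unknown.sort(key=lambda f: (f.species, f.sample_id, f.asv_id))
    return ScreenFlags(flags=flags, near_threshold=near,
                       unknown_locality=unknown)


# ---------------------------------------------------------------------------
# occurrence matrices


def sample_ordering(metas: Mapping[str, SampleMeta], ordering_key: str,
                    include_controls: bool = False) -> list[str]:
    """Sample ids ordered by collection date or lab processing order, with
    a deterministic lexicographic tie-break on sample id."""
    if ordering_key not in ("collection_date", "processing_index"):
        raise ValueError(f"unknown ordering key {ordering_key!r}")
    selected = [m for m in metas.values()
                if include_controls or not m.is_negative_control]
    if ordering_key == "collection_date":
        missing = sorted(m.sample_id for m in selected
                         if m.collection_date is None)
        if missing:
            raise ValueError(
                f"samples lack a collection date: {missing}")
        return [m.sample_id for m in
                sorted(selected,
                       key=lambda m: (m.collection_date, m.sample_id))]
    return [m.sample_id for m in
            sorted(selected, key=lambda m: (m.processing_index, m.sample_id))]


def build_occurrence_matrix(flags: Sequence[NonlocalFlag],
                            metas: Mapping[str, SampleMeta],
                            ordering_key: str) -> pd.DataFrame:
    """Species x sample matrix of flagged RRA (0 = absent), columns in the
    declared sample ordering. Multiple variants of one species within a
    sample are summed."""
    columns = sample_ordering(metas, ordering_key)
    species = sorted({f.species for f in flags})
    matrix = pd.DataFrame(0.0, index=species, columns=columns)
    matrix.index.name = f"species\\{ordering_key}"
    for f in flags:
        if f.sample_id in matrix.columns:
            matrix.loc[f.species, f.sample_id] += f.rra_pct
    return matrix


# ---------------------------------------------------------------------------
# correlations


def rank_correlation(x_values: Sequence[float],
                     y_values: Sequence[float]) -> float:
    """Spearman's rho with average ranks for ties; NaN for constant input."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        return math.nan
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def nonlocal_totals_per_sample(flags: Sequence[NonlocalFlag],
                               sample_ids: Sequence[str]) -> dict[str, float]:
    totals = {s: 0.0 for s in sample_ids}
    for f in flags:
        if f.sample_id in totals:
            totals[f.sample_id] += f.rra_pct
    return totals


def depth_and_richness_correlates(profiles_raw: Mapping[str, SampleProfile],
                                  flags: Sequence[NonlocalFlag],
                                  ) -> tuple[float, float]:
    """Spearman correlations of per-sample non-local total RRA against the
    sample's total reads and its number of distinct variants.

    Depth and richness are taken from the *raw* (pre-filter, no-match
    included) profiles; non-local totals come from the flags (post-filter
    abundances), with zero for samples carrying none.
    """
    samples = sorted(profiles_raw)
    if len(samples) < 3:
        return math.nan, math.nan
    totals = nonlocal_totals_per_sample(flags, samples)
    y = [totals[s] for s in samples]
    reads = [profiles_raw[s].total_reads for s in samples]
    richness = [len(profiles_raw[s].rra) for s in samples]
    return rank_correlation(reads, y), rank_correlation(richness, y)


# ---------------------------------------------------------------------------
# positional concentration within an ordering


def ordering_concentration(positions: Sequence[int], n_samples: int,
                           n_permutations: int = 10_000,
                           seed: Optional[int] = None,
                           ) -> tuple[float, float]:
    """Test whether occurrence positions cluster within a sample ordering.

    The statistic is the mean absolute pairwise difference of the
    occurrence positions (ranks in the ordering); the p-value is the
    fraction of uniform random position sets (drawn without replacement)
    whose statistic is at most the observed one. Small values of both
    indicate occurrences concentrated in a narrow stretch of the
    ordering, as a point-source contamination event would produce.
    This quantification is an addition of this package; the analyses it
    supports are traditionally read off occurrence figures by eye.
    """
    positions = sorted(set(int(p) for p in positions))
    k = len(positions)
    if k < 2:
        return math.nan, math.nan
    if k > n_samples:
        raise ValueError("more occurrence positions than samples")

    def _stat(pos: np.ndarray) -> float:
        diffs = np.abs(pos[:, None] - pos[None, :])
        n = pos.size
        return float(diffs.sum() / (n * (n - 1)))

    observed = _stat(np.asarray(positions))
    rng = np.random.default_rng(seed)
    # Vectorised null: each row of a random matrix argsorted gives a
    # uniform draw of k positions without replacement.
    draws = rng.random((n_permutations, n_samples)).argsort(axis=1)[:, :k]
    diffs = np.abs(draws[:, :, None] - draws[:, None, :])
    null = diffs.sum(axis=(1, 2)) / (k * (k - 1))
    count = int(np.sum(null <= observed + 1e-12))
    return observed, count / n_permutations


# ---------------------------------------------------------------------------
# replicates


def replicate_concordance(profile_a: SampleProfile,
                          profile_b: SampleProfile,
                          abundance_threshold: float = 1.0,
                          ) -> tuple[float, float, list[dict]]:
    """Agreement between technical replicates at the merged-taxon stage.

    Returns the Jaccard index over all present taxa, the Jaccard index
    restricted to taxa at or above ``abundance_threshold`` (% RRA) in
    either replicate, and the discordant taxa (present in exactly one
    replicate) with their abundances.
    """
    present_a = {k for k, v in profile_a.rra.items() if v > 0}
    present_b = {k for k, v in profile_b.rra.items() if v > 0}

    def _jaccard(sa: set, sb: set) -> float:
        union = sa | sb
        if not union:
            return 1.0
        return len(sa & sb) / len(union)

    abundant_a = {k for k in present_a
                  if profile_a.rra[k] >= abundance_threshold}
    abundant_b = {k for k in present_b
                  if profile_b.rra[k] >= abundance_threshold}
    discordant = []
    for taxon in sorted(present_a ^ present_b):
        in_a = taxon in present_a
        discordant.append({
            "taxon": taxon,
            "present_in": profile_a.sample_id if in_a else profile_b.sample_id,
            "rra_pct": profile_a.rra[taxon] if in_a else profile_b.rra[taxon],
        })
    return (_jaccard(present_a, present_b),
            _jaccard(abundant_a, abundant_b),
            discordant)
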