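"""Relative read abundances (RRA) and the low-abundance / no-match filter.

Per sample, each variant's reads are expressed as a percentage of the
sample total. The screening filter removes, in a single pass over the raw
RRA, every entry below ``rra_min_pct`` (strictly below: an entry at
exactly the threshold survives) together with every entry whose
assignment is "no match"; survivors are rescaled to sum to 100 again.
Abundances of variants sharing a taxonomic assignment can then be merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .io_formats import SampleMeta, ScreeningThresholds
from .taxonomic_assignment import AssignmentResult

RAW = "raw"
FILTERED = "filtered"
MERGED = "merged"


@dataclass
class SampleProfile:
    """Per-sample relative read abundances at one processing stage.

    At stages ``raw`` and ``filtered`` the values sum to 100 (unless the
    profile is empty); the ``merged`` stage is keyed by assigned taxon
    rather than variant id.
    """

    sample_id: str
    total_reads: int
    rra: dict[str, float] = field(default_factory=dict)
    stage: str = RAW

    @property
    def is_empty(self) -> bool:
        return not self.rra

    def nonzero_keys(self) -> list[str]:
        return sorted(k for k, v in self.rra.items() if v > 0)


def compute_rra(sample_id: str, counts: Mapping[str, int]) -> SampleProfile:
    """Raw relative read abundances: ``100 * count_i / total``.

    An all-zero sample yields an empty profile with a warning rather than
    an exception.
    """
    for asv, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {asv!r} in {sample_id!r}")
    total = int(sum(counts.values()))
    if total == 0:
        warnings.warn(f"sample {sample_id!r} has zero reads; empty profile",
                      stacklevel=2)
        return SampleProfile(sample_id=sample_id, total_reads=0, stage=RAW)
    rra = {asv: 100.0 * n / total for asv, n in counts.items() if n > 0}
    return SampleProfile(sample_id=sample_id, total_reads=total, rra=rra,
                         stage=RAW)


def filter_and_renormalize(profile: SampleProfile,
                           assignments: Mapping[str, AssignmentResult],
                           thresholds: ScreeningThresholds) -> SampleProfile:
    """Apply the abundance/no-match filter and rescale to 100%.

    Both criteria are evaluated against the raw RRA in one pass (no
    cascade): entries strictly below ``rra_min_pct`` or assigned
    "no match" are removed together, then the survivors are rescaled.
    """
    missing = sorted(set(profile.rra) - set(assignments))
    if missing:
        raise KeyError(f"profile {profile.sample_id!r} has ASVs without "
                       f"assignments: {missing}")
    kept = {
        asv: v for asv, v in profile.rra.items()
        if v >= thresholds.rra_min_pct and not assignments[asv].is_no_match
    }
    total = sum(kept.values())
    if not kept:
        if not profile.is_empty:
            warnings.warn(f"sample {profile.sample_id!r}: nothing survived "
                          "the abundance filter", stacklevel=2)
        return SampleProfile(sample_id=profile.sample_id,
                             total_reads=profile.total_reads, stage=FILTERED)
    rra = {asv: 100.0 * v / total for asv, v in kept.items()}
    return SampleProfile(sample_id=profile.sample_id,
                         total_reads=profile.total_reads, rra=rra,
                         stage=FILTERED)


def merged_key(assignment: AssignmentResult) -> str:
    """Taxon key for merging: the bare name at species rank, otherwise the
    name tagged with its rank so that e.g. a genus-level assignment never
    collapses onto a congeneric species-level one."""
    if assignment.assigned_rank == "species":
        return assignment.assigned_name
    return f"{assignment.assigned_name} [{assignment.assigned_rank}]"


def merge_by_identity(profile: SampleProfile,
                      assignments: Mapping[str, AssignmentResult],
                      ) -> SampleProfile:
    """Sum abundances of variants sharing the same (rank, name) assignment."""
    merged: dict[str, float] = {}
    for asv, v in profile.rra.items():
        key = merged_key(assignments[asv])
        merged[key] = merged.get(key, 0.0) + v
    return SampleProfile(sample_id=profile.sample_id,
                         total_reads=profile.total_reads, rra=merged,
                         stage=MERGED)


def summarize_by_category(metas: Mapping[str, SampleMeta],
                          nonlocal_totals: Mapping[str, float],
                          nonlocal_species: Mapping[str, set[str]],
                          ) -> list[dict]:
    """Per-category summary over non-control samples.

    ``nonlocal_totals`` maps sample id to the summed non-local RRA of that
    sample (samples carrying no flag count as 0); ``nonlocal_species``
    maps sample id to the set of distinct flagged species. The mean is
    unweighted over samples; the species count is the union over the
    category's samples. Categories with zero samples are omitted.
    """
    per_category: dict[str, list[str]] = {}
    for m in metas.values():
        if m.is_negative_control:
            continue
        per_category.setdefault(m.category, []).append(m.sample_id)
    rows = []
    for category in sorted(per_category):
        samples = per_category[category]
        totals = [nonlocal_totals.get(s, 0.0) for s in samples]
        species: set[str] = set()
        for s in samples:
            species |= nonlocal_species.get(s, set())
        rows.append({
            "category": category,
            "n_samples": len(samples),
            "n_nonlocal_species": len(species),
            "mean_nonlocal_rra_pct": sum(totals) / len(totals),
        })
    return rows
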