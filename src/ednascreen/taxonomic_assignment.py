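"""Rule-based taxonomic assignment of amplicon variants.

This module reproduces, as a deterministic rule engine over a local
reference library, the identification logic commonly applied with barcode
identification engines for short COI amplicons:

* candidate matches are found by end-gap-free (semi-global) placement of
  the shorter sequence within the longer, with identity computed over the
  aligned overlap and internal gaps each counting as one mismatch;
* matches spanning less than ``min_overlap_bp`` (default 140 bp of the
  145 bp amplicon, i.e. 96% coverage) are discarded;
* an assignment requires at least ``assign_min_identity_pct`` (default
  97%) identity; a *strict* confidence class additionally requires at
  most ``strict_max_mismatches`` (default 1, i.e. >99% on 145 bp);
* a unique best-matching species wins; when several species tie at the
  best identity, a species known to occur locally is favoured over
  non-local ones, and otherwise the lowest taxonomic rank shared by the
  tied species is assigned instead.

Identity is reported over the aligned overlap, not the query length;
coverage is handled separately. Ambiguous bases (N etc.) are accepted on
input but always count as mismatches, which is conservative toward
"No match".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib

from .io_formats import (
    ASVRecord,
    LocalityChecklist,
    ReferenceRecord,
    ScreeningThresholds,
)

NO_MATCH = "no_match"

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _sanitize(sequence: str, placeholder: str) -> str:
    """Uppercase and replace ambiguity codes so that a non-ACGT base can
    never align as a match (distinct placeholders per side make N-vs-N a
    mismatch too)."""
    s = sequence.upper()
    if all(c in "ACGT" for c in s):
        return s
    return "".join(c if c in "ACGT" else placeholder for c in s)


@dataclass(frozen=True)
class OverlapAlignment:
    """Best semi-global placement of the shorter of two sequences within
    the longer one."""

    overlap_bp: int
    mismatches: int
    identity_pct: float
    coverage_frac: float
    coverage_ok: bool
    mismatch_columns: tuple[int, ...]  # 0-based offsets in the aligned overlap


def overlap_align(query: str, reference: str,
                  min_overlap_bp: int = 140) -> OverlapAlignment:
    """Align ``query`` against ``reference`` end-gap-free.

    The shorter sequence is placed within the longer without end
    penalties; the alignment minimises mismatches + internal gaps.
    Identity is ``100 * (overlap - mismatches) / overlap`` and coverage is
    ``overlap / len(query)``. An overlap shorter than ``min_overlap_bp``
    is returned with ``coverage_ok=False``, never silently dropped.
    """
    if not query or not reference:
        raise ValueError("overlap_align requires non-empty sequences")
    q = _sanitize(query, "?")
    r = _sanitize(reference, "!")
    contained, container = (q, r) if len(q) <= len(r) else (r, q)
    result = edlib.align(contained, container, mode="HW", task="path")
    if len(q) == len(r):
        # equal lengths: the containment direction is ambiguous; keep the
        # better of the two so the result is symmetric in its arguments
        other = edlib.align(container, contained, mode="HW", task="path")
        if other["editDistance"] < result["editDistance"]:
            result = other
    mismatches = int(result["editDistance"])
    columns: list[int] = []
    overlap = 0
    for count, op in _CIGAR_RE.findall(result["cigar"]):
        count = int(count)
        if op != "=":
            columns.extend(range(overlap, overlap + count))
        overlap += count
    identity = 100.0 * (overlap - mismatches) / overlap
    coverage = overlap / len(query)
    return OverlapAlignment(
        overlap_bp=overlap,
        mismatches=mismatches,
        identity_pct=identity,
        coverage_frac=coverage,
        coverage_ok=overlap >= min_overlap_bp,
        mismatch_columns=tuple(columns),
    )


@dataclass(frozen=True)
class MatchHit:
    """Best hit of a query against one reference species."""

    ref_id: str
    species: str
    lineage: Mapping[str, str]
    identity_pct: float
    overlap_bp: int
    mismatches: int
    coverage_frac: float


@dataclass(frozen=True)
class AssignmentResult:
    asv_id: str
    assigned_rank: str  # species | genus | family | order | no_match
    assigned_name: str
    best_identity_pct: float
    confidence_class: str  # strict | standard | none
    mismatches: Optional[int] = None
    overlap_bp: Optional[int] = None
    tied_species: tuple[str, ...] = field(default_factory=tuple)
    local_preference_applied: bool = False

    @property
    def is_no_match(self) -> bool:
        return self.assigned_rank == NO_MATCH


def rank_matches(query_sequence: str,
                 reference_library: Sequence[ReferenceRecord],
                 thresholds: ScreeningThresholds) -> list[MatchHit]:
    """Per-species best hits, coverage-filtered and deterministically sorted.

    For each species the best record (max identity; ties broken by
    ``ref_id``) is retained; hits with overlap below ``min_overlap_bp``
    are removed. The result is sorted by identity descending, then
    species name ascending.
    """
    best: dict[str, MatchHit] = {}
    for rec in sorted(reference_library, key=lambda r: (r.species, r.ref_id)):
        aln = overlap_align(query_sequence, rec.sequence,
                            thresholds.min_overlap_bp)
        if not aln.coverage_ok:
            continue
        hit = MatchHit(
            ref_id=rec.ref_id,
            species=rec.species,
            lineage=dict(rec.lineage),
            identity_pct=aln.identity_pct,
            overlap_bp=aln.overlap_bp,
            mismatches=aln.mismatches,
            coverage_frac=aln.coverage_frac,
        )
        prev = best.get(rec.species)
        if prev is None or hit.identity_pct > prev.identity_pct + 1e-12:
            best[rec.species] = hit
    return sorted(best.values(), key=lambda h: (-h.identity_pct, h.species))


def _shared_rank(lineages: Sequence[Mapping[str, str]]) -> Optional[tuple[str, str]]:
    """Lowest rank (above species) at which all lineages agree."""
    for rank in ("genus", "family", "order"):
        names = {lin[rank] for lin in lineages}
        if len(names) == 1:
            return rank, names.pop()
    return None


def adjudicate(hits: Sequence[MatchHit],
               checklist: LocalityChecklist,
               thresholds: ScreeningThresholds,
               asv_id: str = "") -> AssignmentResult:
    """Turn a ranked hit list into one taxonomic assignment.

    Decision order: (i) no hit at or above the identity threshold ->
    no-match; (ii) a unique top species wins; (iii) a top-identity tie
    containing both local and non-local species resolves in favour of the
    local candidate(s); (iv) a tie with no local candidate is assigned
    the lowest rank shared by the tied species. The confidence class is
    *strict* when the winning hit has at most ``strict_max_mismatches``
    mismatches, otherwise *standard*.
    """
    if not hits or hits[0].identity_pct < thresholds.assign_min_identity_pct - 1e-12:
        best = hits[0].identity_pct if hits else math.nan
        return AssignmentResult(
            asv_id=asv_id, assigned_rank=NO_MATCH, assigned_name="No match",
            best_identity_pct=best, confidence_class="none",
        )
    top_identity = hits[0].identity_pct
    top = [h for h in hits if abs(h.identity_pct - top_identity) < 1e-9]

    def _result(rank: str, name: str, winner: MatchHit,
                tied: Sequence[MatchHit], local_pref: bool) -> AssignmentResult:
        confidence = ("strict"
                      if winner.mismatches <= thresholds.strict_max_mismatches
                      else "standard")
        return AssignmentResult(
            asv_id=asv_id,
            assigned_rank=rank,
            assigned_name=name,
            best_identity_pct=top_identity,
            confidence_class=confidence,
            mismatches=winner.mismatches,
            overlap_bp=winner.overlap_bp,
            tied_species=tuple(h.species for h in tied) if len(tied) > 1 else (),
            local_preference_applied=local_pref,
        )

    if len(top) == 1:
        return _result("species", top[0].species, top[0], top, False)

    local = [h for h in top
             if checklist.is_local(h.species, thresholds.nonlocal_distance_km)]
    if local and len(local) < len(top):
        if len(local) == 1:
            return _result("species", local[0].species, local[0], top, True)
        shared = _shared_rank([h.lineage for h in local])
        if shared is not None:
            return _result(shared[0], shared[1], local[0], top, True)
        # local candidates share no rank: fall through to the full tie
    shared = _shared_rank([h.lineage for h in top])
    if shared is None:
        # Degenerate: tied species share no rank at all; treated as
        # unidentifiable rather than picking arbitrarily.
        return AssignmentResult(
            asv_id=asv_id, assigned_rank=NO_MATCH, assigned_name="No match",
            best_identity_pct=top_identity, confidence_class="none",
            tied_species=tuple(h.species for h in top),
        )
    return _result(shared[0], shared[1], top[0], top, False)


def assign_asv(asv: ASVRecord,
               library: Sequence[ReferenceRecord],
               checklist: LocalityChecklist,
               thresholds: ScreeningThresholds,
               fallback_library: Optional[Sequence[ReferenceRecord]] = None,
               ) -> AssignmentResult:
    """Assign one ASV; an optional second library is consulted only when
    the primary yields no-match (mirroring a secondary database lookup)."""
    hits = rank_matches(asv.sequence, library, thresholds)
    result = adjudicate(hits, checklist, thresholds, asv_id=asv.asv_id)
    if result.is_no_match and fallback_library:
        fb_hits = rank_matches(asv.sequence, fallback_library, thresholds)
        fb = adjudicate(fb_hits, checklist, thresholds, asv_id=asv.asv_id)
        if not fb.is_no_match:
            return fb
    return result


def assign_all(asvs: Sequence[ASVRecord],
               library: Sequence[ReferenceRecord],
               checklist: LocalityChecklist,
               thresholds: ScreeningThresholds,
               fallback_library: Optional[Sequence[ReferenceRecord]] = None,
               ) -> dict[str, AssignmentResult]:
    return {
        a.asv_id: assign_asv(a, library, checklist, thresholds,
                             fallback_library)
        for a in sorted(asvs, key=lambda a: a.asv_id)
    }
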