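"""Tracing flagged sequences to candidate contamination sources.

Given the variants flagged as non-local, this module looks for their
origin: exact or near-exact matches against suspect sequence sets
(e.g. other datasets handled in the same laboratory), pairwise p-distance
matrices and neighbor-joining trees to find nearest similar sequences,
detection of homopolymer-length sequencing artefacts between variant
pairs, and a scan for unassigned ("no match") variants lying close to
flagged clusters.

All pairwise comparisons reuse the end-gap-free overlap aligner from the
assignment stage; distances are plain p-distances (mismatches over the
aligned overlap). With a single fixed 145 bp locus region, pairwise
alignment is sufficient and deterministic, and substitution-model
correction would be spurious precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import edlib

from .taxonomic_assignment import overlap_align, _sanitize, _CIGAR_RE


@dataclass(frozen=True)
class ProvenanceMatch:
    """Nearest source sequence for one flagged variant in one suspect set."""

    asv_id: str
    source_set: str
    best_source_id: str
    mismatches: int
    mismatch_positions: tuple[int, ...]  # 0-based offsets in the overlap
    exact: bool


@dataclass(frozen=True)
class HomopolymerEvent:
    """A length change of a single-base run between two sequences."""

    base: str
    run_length_a: int
    run_length_b: int
    offset: int  # 0-based start of the run in sequence a


def cross_match(flagged_sequences: Mapping[str, str],
                suspect_sets: Mapping[str, Mapping[str, str]],
                min_overlap_bp: int = 140) -> list[ProvenanceMatch]:
    """Nearest source sequence per (flagged variant, suspect set).

    ``exact`` means zero mismatches over the full length of the flagged
    sequence; exact matches short-circuit the scan of a set. Ties on
    mismatch count resolve to the lexicographically smallest source id.
    """
    matches: list[ProvenanceMatch] = []
    for asv_id in sorted(flagged_sequences):
        seq = flagged_sequences[asv_id]
        for set_name in sorted(suspect_sets):
            sources = suspect_sets[set_name]
            best: Optional[tuple[int, str, tuple[int, ...], bool]] = None
            for source_id in sorted(sources):
                aln = overlap_align(seq, sources[source_id], min_overlap_bp)
                exact = aln.mismatches == 0 and aln.overlap_bp >= len(seq)
                key = (aln.mismatches, source_id, aln.mismatch_columns, exact)
                if best is None or aln.mismatches < best[0]:
                    best = key
                if exact:
                    break
            if best is not None:
                matches.append(ProvenanceMatch(
                    asv_id=asv_id, source_set=set_name,
                    best_source_id=best[1], mismatches=best[0],
                    mismatch_positions=best[2], exact=best[3]))
    return matches


def p_distance_matrix(sequences: Sequence[str],
                      min_overlap_bp: int = 140) -> np.ndarray:
    """Symmetric matrix of pairwise p-distances (mismatches / overlap).

    Pairs whose aligned overlap falls below ``min_overlap_bp`` are marked
    missing (NaN).
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("p_distance_matrix needs at least 2 sequences")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = overlap_align(sequences[i], sequences[j], min_overlap_bp)
            d = (aln.mismatches / aln.overlap_bp if aln.coverage_ok
                 else np.nan)
            dm[i, j] = dm[j, i] = d
    return dm


# ---------------------------------------------------------------------------
# neighbor joining


def _newick_label(label: str) -> str:
    out = "".join("_" if c in " ():;," else c for c in label)
    return out or "_"


def nj_tree(distance_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Canonical neighbor-joining agglomeration, returned as a Newick
    string for an unrooted (trifurcating-root) tree.

    Negative branch lengths are clamped to zero with the deficit
    transferred to the sister edge, preserving the joined pair's mutual
    distance. Ties in the Q criterion break deterministically toward the
    pair whose smallest contained leaf labels sort first.
    """
    dm = np.asarray(distance_matrix, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels are inconsistent")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(dm).any():
        bad = sorted(
            (labels[i], labels[j])
            for i, j in zip(*np.where(np.isnan(dm))) if i < j)
        raise ValueError(f"missing distances for pairs: {bad}")

    fragments = [_newick_label(l) for l in labels]
    # canonical name of each active node = smallest leaf label within it
    names = [_newick_label(l) for l in labels]
    D = dm.copy()

    while len(fragments) > 3:
        m = len(fragments)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = [(tuple(sorted((names[i], names[j]))), i, j)
                      for i, j in zip(*np.where(Q <= qmin + 1e-12)) if i < j]
        _, i, j = min(candidates)
        dij = D[i, j]
        vi = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vi, vj = 0.0, dij
        elif vj < 0:
            vi, vj = dij, 0.0
        new_fragment = (f"({fragments[i]}:{vi:.10g},{fragments[j]}:{vj:.10g})")
        new_name = min(names[i], names[j])
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([
            np.hstack([D[np.ix_(keep, keep)], d_new[keep][:, None]]),
            np.hstack([d_new[keep], [0.0]]),
        ])
        fragments = [fragments[k] for k in keep] + [new_fragment]
        names = [names[k] for k in keep] + [new_name]

    # three-point closed form for the final star
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = max(0.0, (dab + dac - dbc) / 2)
    lb = max(0.0, (dab + dbc - dac) / 2)
    lc = max(0.0, (dac + dbc - dab) / 2)
    return (f"({fragments[0]}:{la:.10g},{fragments[1]}:{lb:.10g},"
            f"{fragments[2]}:{lc:.10g});")


# ---------------------------------------------------------------------------
# homopolymer artefacts


def _run_around(seq: str, pos: int, base: str) -> tuple[int, int]:
    """Maximal run of ``base`` in ``seq`` containing or adjacent to ``pos``;
    returns (start, length), length 0 if no such run."""
    n = len(seq)
    p = pos
    if p >= n or seq[p] != base:
        if p > 0 and seq[p - 1] == base:
            p -= 1
        elif p < n - 1 and seq[p + 1] == base:
            p += 1
        elif p >= n and n and seq[n - 1] == base:
            p = n - 1
        else:
            return pos, 0
    start = p
    while start > 0 and seq[start - 1] == base:
        start -= 1
    end = p
    while end < n - 1 and seq[end + 1] == base:
        end += 1
    return start, end - start + 1


def homopolymer_discrepancies(sequence_a: str, sequence_b: str,
                              min_overlap_bp: int = 140,
                              ) -> list[HomopolymerEvent]:
    """Detect single-base run-length changes between two sequences.

    An event is reported for each alignment indel whose gapped bases all
    equal one base and which sits inside a run of that base of length
    >= 2 in both sequences (the classic 7T -> 6T style miscall of
    semiconductor sequencing). Substitutions are never reported. Offsets
    refer to ``sequence_a``.
    """
    a = sequence_a.upper()
    b = sequence_b.upper()
    qa, qb = _sanitize(a, "?"), _sanitize(b, "!")
    a_is_contained = len(a) <= len(b)
    contained, container = (qa, qb) if a_is_contained else (qb, qa)
    result = edlib.align(contained, container, mode="HW", task="path")
    if result["editDistance"] < 0:
        warnings.warn("sequences could not be aligned", stacklevel=2)
        return []
    overlap = sum(int(c) for c, _ in _CIGAR_RE.findall(result["cigar"]))
    if overlap < min_overlap_bp and overlap < min(len(a), len(b)):
        warnings.warn("aligned overlap below the minimum; no events reported",
                      stacklevel=2)
        return []
    window_start = result["locations"][0][0]

    cont_seq = a if a_is_contained else b
    hold_seq = b if a_is_contained else a

    events: list[HomopolymerEvent] = []
    pos_contained = 0
    pos_container = window_start
    for count, op in _CIGAR_RE.findall(result["cigar"]):
        count = int(count)
        if op in ("=", "X", "M"):
            pos_contained += count
            pos_container += count
            continue
        # edlib cigar: I consumes the query (contained), D the target
        if op == "I":
            gap_bases = cont_seq[pos_contained:pos_contained + count]
            with_extra, extra_pos = cont_seq, pos_contained
            other, other_pos = hold_seq, pos_container
            extra_is_a = a_is_contained
            pos_contained += count
        else:  # "D"
            gap_bases = hold_seq[pos_container:pos_container + count]
            with_extra, extra_pos = hold_seq, pos_container
            other, other_pos = cont_seq, pos_contained
            extra_is_a = not a_is_contained
            pos_container += count
        if len(set(gap_bases)) != 1:
            continue
        base = gap_bases[0]
        start_e, run_e = _run_around(with_extra, extra_pos, base)
        start_o, run_o = _run_around(other, other_pos, base)
        if run_e < 2 or run_o < 2 or run_e == run_o:
            continue
        if extra_is_a:
            events.append(HomopolymerEvent(base=base, run_length_a=run_e,
                                           run_length_b=run_o,
                                           offset=start_e))
        else:
            events.append(HomopolymerEvent(base=base, run_length_a=run_o,
                                           run_length_b=run_e,
                                           offset=start_o))
    return events


# ---------------------------------------------------------------------------
# no-match neighbours of flagged clusters


def near_threshold_neighbors(no_match_sequences: Mapping[str, str],
                             flagged_clusters: Mapping[str, Mapping[str, str]],
                             max_mismatches: int = 4,
                             min_overlap_bp: int = 140,
                             ) -> dict[str, list[dict]]:
    """Unassigned sequences within ``max_mismatches`` of a flagged cluster.

    ``flagged_clusters`` maps a flagged species to its member variant
    sequences. The default radius of 4 mismatches sits just beyond the
    97% assignment threshold on a 145 bp amplicon.
    """
    out: dict[str, list[dict]] = {}
    for species in sorted(flagged_clusters):
        members = flagged_clusters[species]
        hits = []
        for nm_id in sorted(no_match_sequences):
            best = None
            for member_id in sorted(members):
                aln = overlap_align(no_match_sequences[nm_id],
                                    members[member_id], min_overlap_bp)
                if not aln.coverage_ok:
                    continue
                if best is None or aln.mismatches < best[0]:
                    best = (aln.mismatches, member_id)
            if best is not None and best[0] <= max_mismatches:
                hits.append({"no_match_id": nm_id,
                             "nearest_member": best[1],
                             "mismatches": best[0]})
        if hits:
            out[species] = hits
    return out
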