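"""End-to-end screening run: load -> assign -> filter -> flag -> patterns
-> provenance -> report, driven by one config and fully reproducible."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import abundance_filtering as af
from . import nonlocal_screening as ns
from . import provenance_tracing as pt
from .io_formats import (
    Dataset,
    ScreenReport,
    ScreeningThresholds,
    load_dataset,
    read_reference_fasta,
    write_report,
    ASSIGNMENT_COLUMNS,
    CATEGORY_COLUMNS,
    CONCENTRATION_COLUMNS,
    CORRELATION_COLUMNS,
    FLAG_COLUMNS,
    HOMOPOLYMER_COLUMNS,
    NEAR_THRESHOLD_COLUMNS,
    PROVENANCE_COLUMNS,
    UNKNOWN_LOCALITY_COLUMNS,
)
from .taxonomic_assignment import assign_all


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    """Inputs and analysis switches of one screening run."""

    asv_table: str
    reference_fasta: str
    metadata: str
    checklist: str
    thresholds: Optional[str] = None  # YAML path; defaults when omitted
    fallback_reference_fasta: Optional[str] = None
    suspect_sets: dict = field(default_factory=dict)  # name -> FASTA path
    n_permutations: int = 10_000
    seed: Optional[int] = None
    replicate_abundance_threshold: float = 1.0
    control_max_subtraction: bool = False
    out_dir: str = "screen_out"

    def __post_init__(self) -> None:
        if self.n_permutations > 0 and self.seed is None:
            raise ValueError(
                "seed is mandatory when stochastic analyses are enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in ("asv_table", "reference_fasta", "metadata",
                               "checklist") if k not in data]
        if missing:
            raise ValueError(f"config lacks required paths: {missing}")
        base = Path(path).parent
        for key in ("asv_table", "reference_fasta", "metadata", "checklist",
                    "thresholds", "fallback_reference_fasta"):
            if data.get(key):
                data[key] = str((base / data[key]).resolve()
                                if not Path(data[key]).is_absolute()
                                else data[key])
        if data.get("suspect_sets"):
            data["suspect_sets"] = {
                name: str((base / p).resolve()
                          if not Path(p).is_absolute() else p)
                for name, p in data["suspect_sets"].items()
            }
        return cls(**data)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_screen(config: RunConfig,
               write: bool = True) -> ScreenReport:
    """Execute the full screen and (optionally) write all report files
    plus a run manifest. Output is invariant to input row order and
    byte-identical across reruns of the same config."""
    for key in ("asv_table", "reference_fasta", "metadata", "checklist"):
        path = getattr(config, key)
        if not Path(path).exists():
            raise PipelineError(f"startup: missing {key} file {path!r}")

    try:
        dataset = load_dataset(config.asv_table, config.reference_fasta,
                               config.metadata, config.checklist,
                               config.thresholds)
    except Exception as exc:
        raise PipelineError(f"load: {exc}") from exc
    thresholds = dataset.thresholds

    fallback = (read_reference_fasta(config.fallback_reference_fasta)
                if config.fallback_reference_fasta else None)

    report, counts_log = _screen_dataset(
        dataset, thresholds, fallback=fallback,
        suspect_sets={name: _read_suspect_fasta(path)
                      for name, path in sorted(config.suspect_sets.items())},
        n_permutations=config.n_permutations, seed=config.seed,
    )

    if write:
        out = Path(config.out_dir)
        written = write_report(report, out)
        manifest = {
            "config": dataclasses.asdict(config),
            "config_hash": hashlib.sha256(
                yaml.safe_dump(dataclasses.asdict(config),
                               sort_keys=True).encode()).hexdigest(),
            "seed": config.seed,
            "input_checksums": {
                key: _sha256(getattr(config, key))
                for key in ("asv_table", "reference_fasta", "metadata",
                            "checklist")
            },
            "stage_counts": counts_log,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        written.append(out / "manifest.json")
    return report


def _read_suspect_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def _screen_dataset(dataset: Dataset,
                    thresholds: ScreeningThresholds,
                    fallback=None,
                    suspect_sets: Optional[Mapping[str, Mapping[str, str]]] = None,
                    n_permutations: int = 10_000,
                    seed: Optional[int] = None,
                    ) -> tuple[ScreenReport, dict]:
    suspect_sets = suspect_sets or {}
    counts = dataset.counts_frame()
    metas = dataset.metas

    # 1. drop low-read samples when a minimum is configured
    analysis_samples = [
        s for s in dataset.sample_ids
        if not metas[s].is_negative_control
        and (thresholds.min_total_reads is None
             or counts[s].sum() >= thresholds.min_total_reads)
    ]
    control_samples = [s for s in dataset.sample_ids
                       if metas[s].is_negative_control]

    # 2. taxonomic assignment
    assignments = assign_all(dataset.asvs, dataset.references,
                             dataset.checklist, thresholds,
                             fallback_library=fallback)

    # 3. abundance profiles
    profiles_raw: dict[str, af.SampleProfile] = {}
    profiles_filtered: dict[str, af.SampleProfile] = {}
    profiles_merged: dict[str, af.SampleProfile] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in analysis_samples:
            raw = af.compute_rra(s, counts[s].to_dict())
            profiles_raw[s] = raw
            filt = af.filter_and_renormalize(raw, assignments, thresholds)
            profiles_filtered[s] = filt
            profiles_merged[s] = af.merge_by_identity(filt, assignments)

    # 4. non-local flags
    screen_flags = ns.flag_nonlocal(assignments, profiles_filtered,
                                    dataset.checklist, thresholds)
    flags = screen_flags.flags

    # 5. occurrence matrices
    analysis_metas = {s: metas[s] for s in analysis_samples}
    occurrence_date = ns.build_occurrence_matrix(
        flags, analysis_metas, "collection_date")
    occurrence_proc = ns.build_occurrence_matrix(
        flags, analysis_metas, "processing_index")

    # 6. correlations and ordering concentration
    rho_reads, rho_asvs = ns.depth_and_richness_correlates(
        profiles_raw, flags)
    correlations = pd.DataFrame([
        {"statistic": "spearman_rho_total_reads", "value": rho_reads,
         "n": len(analysis_samples)},
        {"statistic": "spearman_rho_n_asvs", "value": rho_asvs,
         "n": len(analysis_samples)},
    ], columns=CORRELATION_COLUMNS)

    concentration_rows = []
    for ordering, matrix in (("collection_date", occurrence_date),
                             ("processing_index", occurrence_proc)):
        order = list(matrix.columns)
        pos_of = {s: i + 1 for i, s in enumerate(order)}
        for rank, species in enumerate(sorted(matrix.index)):
            row = matrix.loc[species]
            positions = [pos_of[s] for s in order if row[s] > 0]
            if len(positions) < 2:
                continue
            sub_seed = None if seed is None else (
                (seed * 1000003 + rank * 2 + (ordering == "processing_index"))
                % (2 ** 31))
            stat, p = ns.ordering_concentration(
                positions, len(order), n_permutations, seed=sub_seed)
            concentration_rows.append({
                "species": species, "ordering": ordering,
                "n_occurrences": len(positions), "statistic": stat,
                "p_value": p})
    concentration = pd.DataFrame(concentration_rows,
                                 columns=CONCENTRATION_COLUMNS)

    # 7. per-category summary
    totals = ns.nonlocal_totals_per_sample(flags, analysis_samples)
    species_per_sample: dict[str, set[str]] = {}
    for f in flags:
        species_per_sample.setdefault(f.sample_id, set()).add(f.species)
    category_rows = af.summarize_by_category(analysis_metas, totals,
                                             species_per_sample)
    category_summary = pd.DataFrame(category_rows, columns=CATEGORY_COLUMNS)

    # 8. provenance
    sequences = {a.asv_id: a.sequence for a in dataset.asvs}
    flagged_ids = sorted({f.asv_id for f in flags})
    flagged_seqs = {i: sequences[i] for i in flagged_ids}
    provenance_rows = []
    if suspect_sets and flagged_seqs:
        for m in pt.cross_match(flagged_seqs, suspect_sets,
                                thresholds.min_overlap_bp):
            provenance_rows.append({
                "asv_id": m.asv_id, "source_set": m.source_set,
                "best_source_id": m.best_source_id,
                "mismatches": m.mismatches,
                "mismatch_positions": ",".join(map(str, m.mismatch_positions)),
                "exact": m.exact})
    provenance = pd.DataFrame(provenance_rows, columns=PROVENANCE_COLUMNS)

    trees: dict[str, str] = {}
    if len(flagged_ids) >= 3:
        seqs = [flagged_seqs[i] for i in flagged_ids]
        dm = pt.p_distance_matrix(seqs, thresholds.min_overlap_bp)
        try:
            trees["flagged_nj"] = pt.nj_tree(dm, flagged_ids)
        except ValueError:
            pass  # incomplete matrix (overlap failures): skip the tree

    homopolymer_rows = []
    by_species: dict[str, list[str]] = {}
    for asv_id, a in assignments.items():
        if a.assigned_rank == "species" and asv_id in sequences:
            by_species.setdefault(a.assigned_name, []).append(asv_id)
    for species in sorted(by_species):
        ids = sorted(by_species[species])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    events = pt.homopolymer_discrepancies(
                        sequences[ids[i]], sequences[ids[j]],
                        thresholds.min_overlap_bp)
                for e in events:
                    homopolymer_rows.append({
                        "species": species, "asv_a": ids[i], "asv_b": ids[j],
                        "base": e.base, "run_length_a": e.run_length_a,
                        "run_length_b": e.run_length_b, "offset": e.offset})
    homopolymer = pd.DataFrame(homopolymer_rows, columns=HOMOPOLYMER_COLUMNS)

    # 9. assemble tables
    ident = {a: assignments[a] for a in assignments}
    flags_frame = pd.DataFrame([
        {"species": f.species, "sample_id": f.sample_id, "asv_id": f.asv_id,
         "rra_pct": f.rra_pct,
         "identity_pct": ident[f.asv_id].best_identity_pct,
         "mismatches": ident[f.asv_id].mismatches}
        for f in flags], columns=FLAG_COLUMNS)
    near_frame = pd.DataFrame([
        {"species_or_name": r.name, "sample_id": r.sample_id,
         "asv_id": r.asv_id, "rra_pct": r.rra_pct, "reason": r.reason}
        for r in screen_flags.near_threshold],
        columns=NEAR_THRESHOLD_COLUMNS)
    unknown_frame = pd.DataFrame([
        {"species": r.species, "sample_id": r.sample_id, "asv_id": r.asv_id,
         "rra_pct": r.rra_pct}
        for r in screen_flags.unknown_locality],
        columns=UNKNOWN_LOCALITY_COLUMNS)
    assignment_frame = pd.DataFrame([
        {"asv_id": a.asv_id, "rank": a.assigned_rank,
         "name": a.assigned_name, "identity": a.best_identity_pct,
         "mismatches": a.mismatches, "overlap": a.overlap_bp,
         "confidence_class": a.confidence_class,
         "tied_species": ",".join(a.tied_species),
         "local_preference_applied": a.local_preference_applied}
        for a in (assignments[k] for k in sorted(assignments))],
        columns=ASSIGNMENT_COLUMNS)

    affected = sorted({f.sample_id for f in flags})
    control_max = int(counts[control_samples].max().max()) \
        if control_samples else 0
    summary = {
        "n_asvs": len(dataset.asvs),
        "n_samples_analysed": len(analysis_samples),
        "n_samples_excluded_low_reads": len(
            [s for s in dataset.sample_ids
             if not metas[s].is_negative_control]) - len(analysis_samples),
        "n_negative_controls": len(control_samples),
        "max_control_asv_reads": control_max,
        "n_assigned_species": int(
            (assignment_frame["rank"] == "species").sum()),
        "n_no_match": int((assignment_frame["rank"] == "no_match").sum()),
        "n_flags": len(flags),
        "n_flagged_asvs": len(flagged_ids),
        "n_flagged_species": len({f.species for f in flags}),
        "n_affected_samples": len(affected),
        "nonlocal_total_rra_min": min(
            (totals[s] for s in affected), default=0.0),
        "nonlocal_total_rra_max": max(
            (totals[s] for s in affected), default=0.0),
        "spearman_rho_total_reads": rho_reads,
        "spearman_rho_n_asvs": rho_asvs,
    }
    counts_log = {
        "asvs": len(dataset.asvs),
        "samples": len(analysis_samples),
        "assignments": len(assignments),
        "flags": len(flags),
        "near_threshold": len(screen_flags.near_threshold),
        "unknown_locality": len(screen_flags.unknown_locality),
        "provenance_matches": len(provenance_rows),
        "homopolymer_events": len(homopolymer_rows),
    }

    report = ScreenReport(
        flags=flags_frame,
        near_threshold=near_frame,
        unknown_locality=unknown_frame,
        assignments=assignment_frame,
        occurrence_by_date=occurrence_date,
        occurrence_by_processing=occurrence_proc,
        correlations=correlations,
        concentration=concentration,
        category_summary=category_summary,
        provenance=provenance,
        homopolymer=homopolymer,
        trees=trees,
        summary=summary,
    )
    return report, counts_log


def screen_dataset(dataset: Dataset,
                   n_permutations: int = 1000,
                   seed: int = 0,
                   suspect_sets: Optional[Mapping[str, Mapping[str, str]]] = None,
                   ) -> ScreenReport:
    """Library-level entry point: screen an in-memory dataset."""
    report, _ = _screen_dataset(dataset, dataset.thresholds,
                                suspect_sets=suspect_sets,
                                n_permutations=n_permutations, seed=seed)
    return report
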