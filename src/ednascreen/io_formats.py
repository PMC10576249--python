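"""Domain types and file readers/writers.

Everything downstream of this module consumes the types defined here:
amplicon sequence variants (ASVs) with per-sample read counts, reference
barcodes with taxonomic lineages, sample metadata, the species locality
checklist, and the screening thresholds.

File dialects
-------------
* Reference library: FASTA, header ``ref_id;order;family;genus;Genus species``.
* ASV table: tab-separated, columns ``asv_id``, ``sequence``, then one column
  per sample id holding integer read counts.
* Metadata / checklist / report tables: tab-separated with a named header row.
* Thresholds / configs: flat YAML.
* Trees: Newick.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS = ("order", "family", "genus", "species")


class ValidationError(ValueError):
    """A structurally invalid dataset (bad cross-references, duplicates...)."""


class ParseError(ValueError):
    """A malformed input file (bad FASTA header, unparsable field...)."""


@dataclass(frozen=True)
class ASVRecord:
    """One denoised amplicon variant: sequence plus per-sample read counts."""

    asv_id: str
    sequence: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"ASV {self.asv_id!r} has an empty sequence")
        for sample, n in self.counts.items():
            if n < 0:
                raise ValidationError(
                    f"ASV {self.asv_id!r} has a negative count for sample {sample!r}"
                )

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class ReferenceRecord:
    """A library barcode with its taxonomic lineage.

    ``lineage`` maps the ordered ranks order -> family -> genus -> species;
    ``species`` is the binomial name (genus + epithet).
    """

    ref_id: str
    sequence: str
    lineage: Mapping[str, str]
    species: str

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineage]
        if missing:
            raise ValidationError(
                f"reference {self.ref_id!r} lineage lacks ranks: {missing}"
            )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    category: str
    collection_date: Optional[datetime.date]
    processing_index: int
    batch: str
    replicate_group: Optional[str] = None
    is_negative_control: bool = False


class LocalityChecklist:
    """Species -> nearest-known-occurrence distance (km), with free-text note.

    Species names are expected pre-normalized (genus + epithet, single
    spaces); synonym reconciliation is the caller's responsibility.
    """

    def __init__(self, entries: Mapping[str, tuple[float, str]]):
        self._entries: dict[str, tuple[float, str]] = {}
        for species, (dist, note) in entries.items():
            name = normalize_species(species)
            if dist < 0:
                raise ValidationError(
                    f"checklist distance for {name!r} is negative ({dist})"
                )
            self._entries[name] = (float(dist), str(note))

    def distance_km(self, species: str) -> Optional[float]:
        entry = self._entries.get(normalize_species(species))
        return None if entry is None else entry[0]

    def is_local(self, species: str, nonlocal_distance_km: float) -> bool:
        """True only for species *known* to occur within the distance bound."""
        d = self.distance_km(species)
        return d is not None and d <= nonlocal_distance_km

    def __contains__(self, species: str) -> bool:
        return normalize_species(species) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self) -> Iterable[tuple[str, tuple[float, str]]]:
        return sorted(self._entries.items())


def normalize_species(name: str) -> str:
    return " ".join(str(name).split())


@dataclass
class ScreeningThresholds:
    """All decision thresholds of the screen, with the defaults used
    throughout: a match must span >=140 bp (96% of the 145 bp amplicon),
    assignments require >=97% identity, the strict class tolerates at most
    1 mismatch (>99%), ASVs below 0.1% relative abundance are filtered, and
    species are non-local beyond 200 km."""

    min_overlap_bp: int = 140
    min_coverage_frac: float = 0.96
    assign_min_identity_pct: float = 97.0
    strict_max_mismatches: int = 1
    rra_min_pct: float = 0.1
    nonlocal_distance_km: float = 200.0
    min_total_reads: Optional[int] = None

    def __post_init__(self) -> None:
        positive = {
            "min_overlap_bp": self.min_overlap_bp,
            "min_coverage_frac": self.min_coverage_frac,
            "assign_min_identity_pct": self.assign_min_identity_pct,
            "rra_min_pct": self.rra_min_pct,
            "nonlocal_distance_km": self.nonlocal_distance_km,
        }
        for k, v in positive.items():
            if v <= 0:
                raise ValidationError(f"threshold {k} must be positive, got {v}")
        if self.strict_max_mismatches < 0:
            raise ValidationError("strict_max_mismatches must be >= 0")
        if self.min_total_reads is not None and self.min_total_reads <= 0:
            raise ValidationError("min_total_reads must be positive when set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreeningThresholds":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown threshold keys in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


@dataclass
class Dataset:
    """A fully cross-validated input set."""

    asvs: list[ASVRecord]
    references: list[ReferenceRecord]
    metas: dict[str, SampleMeta]
    checklist: LocalityChecklist
    thresholds: ScreeningThresholds

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.metas)

    def counts_frame(self) -> pd.DataFrame:
        """Rectangular read-count table (rows ASVs, columns all samples,
        missing cells 0)."""
        frame = pd.DataFrame(
            0, index=[a.asv_id for a in self.asvs], columns=self.sample_ids,
            dtype=int,
        )
        for a in self.asvs:
            for sample, n in a.counts.items():
                frame.loc[a.asv_id, sample] = int(n)
        return frame


# ---------------------------------------------------------------------------
# readers


def read_reference_fasta(path: str | Path) -> list[ReferenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        parts = [p.strip() for p in header.split(";")]
        if len(parts) != 5:
            raise ParseError(
                f"reference record {parts[0]!r}: header must be "
                f"'ref_id;order;family;genus;Genus species', got {header!r}"
            )
        ref_id, order, family, genus, species = parts
        records.append(
            ReferenceRecord(
                ref_id=ref_id,
                sequence=str(rec.seq).upper(),
                lineage={
                    "order": order,
                    "family": family,
                    "genus": genus,
                    "species": normalize_species(species),
                },
                species=normalize_species(species),
            )
        )
    return records


def read_asv_table(path: str | Path) -> list[ASVRecord]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["asv_id", "sequence"]:
        raise ParseError(
            f"ASV table {path}: first two columns must be asv_id, sequence"
        )
    sample_cols = list(table.columns[2:])
    dup = table["asv_id"][table["asv_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate asv_id in {path}: {sorted(set(dup))}")
    asvs = []
    for _, row in table.iterrows():
        counts = {s: int(row[s]) for s in sample_cols}
        asvs.append(ASVRecord(asv_id=row["asv_id"],
                              sequence=str(row["sequence"]).upper(),
                              counts=counts))
    return asvs


def read_metadata(path: str | Path) -> dict[str, SampleMeta]:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "category", "collection_date", "processing_index",
                "batch", "replicate_group", "is_negative_control"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"metadata {path} lacks columns: {sorted(missing)}")
    metas: dict[str, SampleMeta] = {}
    for _, row in table.iterrows():
        sid = row["sample_id"]
        if sid in metas:
            raise ValidationError(f"duplicate sample_id in metadata: {sid!r}")
        date = None
        if row["collection_date"]:
            try:
                date = datetime.date.fromisoformat(row["collection_date"])
            except ValueError as exc:
                raise ParseError(
                    f"sample {sid!r}: collection_date must be ISO-8601, "
                    f"got {row['collection_date']!r}"
                ) from exc
        metas[sid] = SampleMeta(
            sample_id=sid,
            category=row["category"],
            collection_date=date,
            processing_index=int(row["processing_index"]),
            batch=row["batch"],
            replicate_group=row["replicate_group"] or None,
            is_negative_control=_parse_bool(row["is_negative_control"], sid),
        )
    _check_processing_unique(metas)
    return metas


def _parse_bool(value: str, sample_id: str) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise ParseError(f"sample {sample_id!r}: bad boolean {value!r}")


def _check_processing_unique(metas: Mapping[str, SampleMeta]) -> None:
    seen: dict[tuple[str, int], str] = {}
    for m in metas.values():
        key = (m.batch, m.processing_index)
        if key in seen:
            raise ValidationError(
                f"processing_index {m.processing_index} duplicated within "
                f"batch {m.batch!r} (samples {seen[key]!r}, {m.sample_id!r})"
            )
        seen[key] = m.sample_id


def read_checklist(path: str | Path) -> LocalityChecklist:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"species", "distance_km"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"checklist {path} lacks columns: {sorted(missing)}")
    entries = {}
    for _, row in table.iterrows():
        note = row["note"] if "note" in table.columns else ""
        entries[row["species"]] = (float(row["distance_km"]), note)
    return LocalityChecklist(entries)


def load_dataset(
    asv_table_path: str | Path,
    reference_fasta_path: str | Path,
    metadata_path: str | Path,
    checklist_path: str | Path,
    thresholds: ScreeningThresholds | str | Path | None = None,
) -> Dataset:
    """Load and cross-validate a complete input set.

    Raises :class:`ValidationError` when a counts-table sample lacks
    metadata or an ``asv_id`` is duplicated; :class:`ParseError` for
    malformed records. Missing count cells are treated as 0 (the table
    format is rectangular by construction).
    """
    if thresholds is None:
        thresholds = ScreeningThresholds()
    elif not isinstance(thresholds, ScreeningThresholds):
        thresholds = ScreeningThresholds.from_yaml(thresholds)
    asvs = read_asv_table(asv_table_path)
    references = read_reference_fasta(reference_fasta_path)
    metas = read_metadata(metadata_path)
    checklist = read_checklist(checklist_path)

    sample_ids = set(metas)
    orphans = sorted({s for a in asvs for s in a.counts} - sample_ids)
    if orphans:
        raise ValidationError(
            f"samples present in the ASV table but absent from metadata: {orphans}"
        )
    return Dataset(asvs=asvs, references=references, metas=metas,
                   checklist=checklist, thresholds=thresholds)


# ---------------------------------------------------------------------------
# writers


def write_reference_fasta(records: Iterable[ReferenceRecord],
                          path: str | Path) -> None:
    seqs = []
    for r in records:
        header = ";".join([r.ref_id] + [r.lineage[rank] for rank in RANKS])
        seqs.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def write_asv_table(asvs: Iterable[ASVRecord], sample_ids: Iterable[str],
                    path: str | Path) -> None:
    sample_ids = list(sample_ids)
    rows = []
    for a in asvs:
        row = {"asv_id": a.asv_id, "sequence": a.sequence}
        for s in sample_ids:
            row[s] = int(a.counts.get(s, 0))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["asv_id", "sequence"] + sample_ids)
    frame.to_csv(path, sep="\t", index=False)


def write_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        rows.append({
            "sample_id": m.sample_id,
            "category": m.category,
            "collection_date": m.collection_date.isoformat()
            if m.collection_date else "",
            "processing_index": m.processing_index,
            "batch": m.batch,
            "replicate_group": m.replicate_group or "",
            "is_negative_control": "true" if m.is_negative_control else "false",
        })
    cols = ["sample_id", "category", "collection_date", "processing_index",
            "batch", "replicate_group", "is_negative_control"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_checklist(checklist: LocalityChecklist, path: str | Path) -> None:
    rows = [{"species": sp, "distance_km": dist, "note": note}
            for sp, (dist, note) in checklist.items()]
    pd.DataFrame(rows, columns=["species", "distance_km", "note"]).to_csv(
        path, sep="\t", index=False, float_format="%.1f")


# ---------------------------------------------------------------------------
# screen report


FLAG_COLUMNS = ["species", "sample_id", "asv_id", "rra_pct", "identity_pct",
                "mismatches"]
NEAR_THRESHOLD_COLUMNS = ["species_or_name", "sample_id", "asv_id", "rra_pct",
                          "reason"]
UNKNOWN_LOCALITY_COLUMNS = ["species", "sample_id", "asv_id", "rra_pct"]
ASSIGNMENT_COLUMNS = ["asv_id", "rank", "name", "identity", "mismatches",
                      "overlap", "confidence_class", "tied_species",
                      "local_preference_applied"]
PROVENANCE_COLUMNS = ["asv_id", "source_set", "best_source_id", "mismatches",
                      "mismatch_positions", "exact"]
HOMOPOLYMER_COLUMNS = ["species", "asv_a", "asv_b", "base", "run_length_a",
                       "run_length_b", "offset"]
CORRELATION_COLUMNS = ["statistic", "value", "n"]
CONCENTRATION_COLUMNS = ["species", "ordering", "n_occurrences", "statistic",
                         "p_value"]
CATEGORY_COLUMNS = ["category", "n_samples", "n_nonlocal_species",
                    "mean_nonlocal_rra_pct"]


@dataclass
class ScreenReport:
    """All outputs of one screening run, as plain tables ready to write."""

    flags: pd.DataFrame
    near_threshold: pd.DataFrame
    unknown_locality: pd.DataFrame
    assignments: pd.DataFrame
    occurrence_by_date: pd.DataFrame
    occurrence_by_processing: pd.DataFrame
    correlations: pd.DataFrame
    concentration: pd.DataFrame
    category_summary: pd.DataFrame
    provenance: pd.DataFrame
    homopolymer: pd.DataFrame
    trees: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "ScreenReport":
        return cls(
            flags=pd.DataFrame(columns=FLAG_COLUMNS),
            near_threshold=pd.DataFrame(columns=NEAR_THRESHOLD_COLUMNS),
            unknown_locality=pd.DataFrame(columns=UNKNOWN_LOCALITY_COLUMNS),
            assignments=pd.DataFrame(columns=ASSIGNMENT_COLUMNS),
            occurrence_by_date=pd.DataFrame(),
            occurrence_by_processing=pd.DataFrame(),
            correlations=pd.DataFrame(columns=CORRELATION_COLUMNS),
            concentration=pd.DataFrame(columns=CONCENTRATION_COLUMNS),
            category_summary=pd.DataFrame(columns=CATEGORY_COLUMNS),
            provenance=pd.DataFrame(columns=PROVENANCE_COLUMNS),
            homopolymer=pd.DataFrame(columns=HOMOPOLYMER_COLUMNS),
        )


def _write_table(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.6f",
                 lineterminator="\n")


def write_report(report: ScreenReport, out_dir: str | Path) -> list[Path]:
    """Write every report table; output is byte-stable for identical input
    (fixed column order, fixed float formatting, sorted JSON keys)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    tables = {
        "flags.tsv": report.flags,
        "near_threshold.tsv": report.near_threshold,
        "unknown_locality.tsv": report.unknown_locality,
        "assignments.tsv": report.assignments,
        "correlations.tsv": report.correlations,
        "ordering_concentration.tsv": report.concentration,
        "category_summary.tsv": report.category_summary,
        "provenance.tsv": report.provenance,
        "homopolymer_events.tsv": report.homopolymer,
    }
    for name, frame in tables.items():
        path = out / name
        _write_table(frame, path)
        written.append(path)
    for name, frame in (("occurrence_by_date.tsv", report.occurrence_by_date),
                        ("occurrence_by_processing.tsv",
                         report.occurrence_by_processing)):
        path = out / name
        _write_table(frame, path, index=True)
        written.append(path)
    for name, newick in sorted(report.trees.items()):
        path = out / f"{name}.nwk"
        path.write_text(newick + "\n")
        written.append(path)
    path = out / "summary.json"
    path.write_text(json.dumps(report.summary, indent=2, sort_keys=True,
                               default=str) + "\n")
    written.append(path)
    return written
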