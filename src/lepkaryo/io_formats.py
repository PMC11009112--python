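"""Readers and writers for the external formats the pipeline touches.

Dialect contracts:

* orthologue tables -- BUSCO ``full_table.tsv`` dialect ('#' comments;
  columns id, status, sequence, start, end; 1-based inclusive coordinates)
  or a plain ``simple_tsv`` with the same five columns and a header.
  Coordinates are converted to 0-based half-open on read and back on write.
* trees -- newick with branch lengths (dendropy underneath).
* chromosome indices -- samtools ``.fai`` or two-column TSV.
* annotation tracks -- BED3/BED4, 0-based half-open.

All writers emit '#'-prefixed metadata lines that readers skip.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import dendropy

logger = logging.getLogger(__name__)

STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True)
class OrthologRecord:
    ortholog_id: str
    status: str
    chromosome: Optional[str] = None
    start_bp: Optional[int] = None  # 0-based half-open internally
    end_bp: Optional[int] = None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status in ("Complete", "Duplicated"):
            if self.chromosome is None or self.start_bp is None or self.end_bp is None:
                raise ValueError(
                    f"{self.ortholog_id}: status {self.status} requires location fields")
        if self.start_bp is not None and self.end_bp is not None:
            if self.start_bp < 0 or self.end_bp <= self.start_bp:
                raise ValueError(
                    f"{self.ortholog_id}: invalid interval [{self.start_bp}, {self.end_bp})")


@dataclass
class GenomeTable:
    """One species' orthologue locations plus chromosome lengths."""

    species_id: str
    records: List[OrthologRecord] = field(default_factory=list)
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    def complete_records(self) -> List[OrthologRecord]:
        return [r for r in self.records if r.status == "Complete"]

    def complete_by_chromosome(self) -> Dict[str, List[OrthologRecord]]:
        out: Dict[str, List[OrthologRecord]] = {}
        for r in self.complete_records():
            out.setdefault(r.chromosome, []).append(r)
        for recs in out.values():
            recs.sort(key=lambda r: (r.start_bp, r.ortholog_id))
        return out

    def validate(self) -> None:
        seen_complete = set()
        for r in self.records:
            if r.status == "Complete":
                if r.ortholog_id in seen_complete:
                    raise ValueError(
                        f"{self.species_id}: {r.ortholog_id} Complete more than once")
                seen_complete.add(r.ortholog_id)
            if r.chromosome is not None and r.chromosome not in self.chrom_lengths:
                raise ValueError(
                    f"{self.species_id}: chromosome {r.chromosome} missing from index")

    def drop_unlocalized(self, chrom_index: Dict[str, int]) -> int:
        """Drop records on sequences absent from ``chrom_index`` (unlocalized
        scaffolds); returns the number dropped."""
        kept, dropped = [], 0
        for r in self.records:
            if r.chromosome is not None and r.chromosome not in chrom_index:
                dropped += 1
            else:
                kept.append(r)
        self.records = kept
        self.chrom_lengths = dict(chrom_index)
        if dropped:
            logger.info("%s: dropped %d records on unlocalized scaffolds",
                        self.species_id, dropped)
        return dropped


@dataclass(frozen=True)
class IntervalTrack:
    chromosome: str
    intervals: Tuple[Tuple[int, int], ...]  # 0-based half-open
    label: str = "."


def _split_fields(line: str) -> List[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_ortholog_table(path, dialect: str = "busco_full_table",
                        species_id: Optional[str] = None) -> GenomeTable:
    """Read a per-species orthologue location table.

    ``busco_full_table``: BUSCO's full_table.tsv (1-based inclusive
    coordinates, '#'-comment lines). ``simple_tsv``: same columns with
    a '#'-prefixed header, also 1-based inclusive.
    Duplicated rows for one id are all retained (flagged via status).
    """
    if dialect not in ("busco_full_table", "simple_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    species = species_id or path.stem
    records: List[OrthologRecord] = []
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_fields(line)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns")
            oid, status = fields[0], fields[1]
            if status not in STATUSES:
                raise ParseError(f"{path}:{lineno}: unknown status {status!r}")
            n_rows += 1
            if status in ("Fragmented", "Missing"):
                records.append(OrthologRecord(oid, status))
                continue
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: located row needs 5 columns")
            chrom = fields[2]
            try:
                start1 = int(float(fields[3]))
                end1 = int(float(fields[4]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end {end1} < start {start1}")
            # 1-based inclusive -> 0-based half-open
            records.append(OrthologRecord(oid, status, chrom, start1 - 1, end1))
    if len(records) != n_rows:
        raise ParseError(f"{path}: parsed {len(records)} of {n_rows} rows")
    chrom_lengths: Dict[str, int] = {}
    for r in records:
        if r.chromosome is not None:
            chrom_lengths[r.chromosome] = max(
                chrom_lengths.get(r.chromosome, 0), r.end_bp)
    table = GenomeTable(species, records, chrom_lengths)
    table.validate()
    return table


def write_ortholog_table(table: GenomeTable, path, metadata: Optional[Dict] = None) -> None:
    """Write a GenomeTable in the busco_full_table dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(f"# lepkaryo orthologue table; species={table.species_id}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("# Busco id\tStatus\tSequence\tGene Start\tGene End\n")
        for r in table.records:
            if r.status in ("Fragmented", "Missing"):
                fh.write(f"{r.ortholog_id}\t{r.status}\n")
            else:
                fh.write(f"{r.ortholog_id}\t{r.status}\t{r.chromosome}\t"
                         f"{r.start_bp + 1}\t{r.end_bp}\n")


def read_tree(path) -> dendropy.Tree:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"{path}: duplicate tip label") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError(f"{path}: duplicate tip labels")
    if len(labels) == 1:
        warnings.warn(f"{path}: single-tip tree (degenerate)")
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
        elif edge.length < 0:
            raise ValueError(f"{path}: negative branch length")
    if n_missing:
        warnings.warn(f"{path}: {n_missing} branch lengths missing, set to 0")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def read_chrom_index(path, dialect: str = "fai") -> Dict[str, int]:
    """Read chromosome lengths from a .fai or two-column TSV (extra
    columns ignored)."""
    if dialect not in ("fai", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: Dict[str, int] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_fields(line)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer length") from exc
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive length")
            out[fields[0]] = length
    if not out:
        warnings.warn(f"{path}: empty chromosome index")
    return out


def read_bed(path) -> List[IntervalTrack]:
    """Read BED3/BED4 into per-(chromosome, label) tracks; intervals kept
    as given (no merging)."""
    path = Path(path)
    grouped: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_fields(line)
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval {start}..{end}")
            label = fields[3] if len(fields) > 3 else "."
            grouped.setdefault((chrom, label), []).append((start, end))
    return [IntervalTrack(chrom, tuple(ivals), label)
            for (chrom, label), ivals in grouped.items()]


def write_bed(tracks: Iterable[IntervalTrack], path) -> None:
    with open(path, "w") as fh:
        for track in tracks:
            for start, end in track.intervals:
                fh.write(f"{track.chromosome}\t{start}\t{end}\t{track.label}\n")


EVENT_COLUMNS = ["event_id", "kind", "elements", "species_or_node",
                 "chromosome", "breakpoint_bp", "support"]


def write_event_table(events, path, metadata: Optional[Dict] = None) -> None:
    """TSV twin of the supplementary rearrangement-event tables."""
    with open(path, "w") as fh:
        fh.write("# lepkaryo event table\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for i, ev in enumerate(events):
            fh.write("\t".join([
                str(i),
                ev.kind,
                ",".join(sorted(ev.elements)),
                ev.placement,
                ev.chromosome or "NA",
                "NA" if ev.breakpoint_bp is None else str(ev.breakpoint_bp),
                ",".join(sorted(ev.supporting_species)),
            ]) + "\n")


def read_event_table(path):
    """Inverse of :func:`write_event_table`."""
    from .events import RearrangementEvent  # local import to avoid cycle
    events = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                if fields != EVENT_COLUMNS:
                    raise ParseError(f"{path}:{lineno}: bad header")
                header = fields
                continue
            row = dict(zip(header, fields))
            events.append(RearrangementEvent(
                kind=row["kind"],
                elements=frozenset(row["elements"].split(",")),
                placement=row["species_or_node"],
                supporting_species=frozenset(
                    s for s in row["support"].split(",") if s),
                chromosome=None if row["chromosome"] == "NA" else row["chromosome"],
                breakpoint_bp=None if row["breakpoint_bp"] == "NA"
                else int(row["breakpoint_bp"]),
            ))
    return events
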