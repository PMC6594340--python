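"""Per-sample alignment parsing, read QC and top-hit assignment.

Metagenomic reads are aligned (externally, e.g. with DIAMOND blastx) against
the BGC protein catalog; this module consumes the standard 12-column tabular
output, keeps hits passing the E-value cutoff (default 1e-05), selects one
deterministic top hit per read, and joins the catalog plus precomputed gene
classifications to emit validated read -> (cluster, gene) assignments.  Only
assignments to biosynthesis genes count toward cluster abundance downstream.

The QC step mirrors a fixed-length trimming protocol: every read is cut to
its first ``keep_bp`` bases (default 70) and reads shorter than that are
dropped, so all surviving reads have identical length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from bgcquant._util import open_text, strip_pfam_version
from bgcquant.catalog import BIOSYNTHESIS, BGCCatalog
from bgcquant.errors import InputError, ParseError

logger = logging.getLogger(__name__)

DEFAULT_ALIGN_EVALUE = 1e-05
DEFAULT_KEEP_BP = 70

#: standard BLAST/DIAMOND outfmt-6 column order
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class AlignmentHit:
    """One read-vs-protein alignment from BLAST tabular output."""

    read_id: str
    protein_id: str
    percent_identity: float
    e_value: float
    bit_score: float
    #: remaining tabular columns, retained opaquely
    extra: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReadAssignment:
    sample_id: str
    read_id: str
    protein_id: str
    gene_id: str
    cluster_id: str
    biosynthesis: bool


@dataclass
class QCSummary:
    reads_kept: int = 0
    reads_dropped: int = 0
    #: most common input read length; a whole sample is suspect when this
    #: falls below the trim length (sample-level QC is a pipeline decision,
    #: separate from the per-read drop rule)
    modal_read_length: int | None = None

    @property
    def reads_total(self) -> int:
        return self.reads_kept + self.reads_dropped

    def sample_passes(self, keep_bp: int = DEFAULT_KEEP_BP) -> bool:
        return self.modal_read_length is not None and self.modal_read_length >= keep_bp


@dataclass
class ParseReport:
    """Bookkeeping for a BLAST-tab parse: nothing is silently skipped."""

    lines_total: int = 0
    hits_kept: int = 0
    hits_filtered: int = 0
    malformed_lines: int = 0


@dataclass
class AssignmentReport:
    assignments: int = 0
    unknown_protein_reads: int = 0


def qc_trim_reads(
    fastq_in: str | Path, fastq_out: str | Path, keep_bp: int = DEFAULT_KEEP_BP
) -> QCSummary:
    """Trim every read to its first ``keep_bp`` bases; drop shorter reads.

    Emits plain (uncompressed) FASTQ.  Raises ParseError with the 1-based
    record index on a structurally malformed input record.
    """
    if keep_bp < 1:
        raise ValueError(f"keep_bp must be >= 1, got {keep_bp}")
    summary = QCSummary()
    length_counts: dict[int, int] = {}
    with open_text(fastq_in) as fin, open(fastq_out, "w") as fout:
        record_index = 0
        while True:
            header = fin.readline()
            if not header:
                break
            record_index += 1
            seq = fin.readline().rstrip("\n")
            plus = fin.readline()
            qual = fin.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ParseError(
                    f"malformed FASTQ record #{record_index} in {fastq_in}",
                )
            if len(seq) != len(qual):
                raise ParseError(
                    f"FASTQ record #{record_index}: sequence/quality length mismatch"
                )
            length_counts[len(seq)] = length_counts.get(len(seq), 0) + 1
            if len(seq) < keep_bp:
                summary.reads_dropped += 1
                continue
            fout.write(header)
            fout.write(seq[:keep_bp] + "\n")
            fout.write("+\n")
            fout.write(qual[:keep_bp] + "\n")
            summary.reads_kept += 1
    if length_counts:
        # deterministic: highest count, longest length on ties
        summary.modal_read_length = max(
            length_counts, key=lambda L: (length_counts[L], L)
        )
    return summary


def parse_blast_tab(
    path: str | Path,
    e_threshold: float = DEFAULT_ALIGN_EVALUE,
    report: ParseReport | None = None,
) -> Iterator[AlignmentHit]:
    """Stream hits from 12-column BLAST/DIAMOND tabular output.

    Hits with E-value above ``e_threshold`` are discarded (counted in the
    report).  Lines with the wrong column count are counted as malformed and
    reported; a 12-column line with a non-numeric E-value or bit score is a
    hard error naming the line number.
    """
    if report is None:
        report = ParseReport()
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            report.lines_total += 1
            fields = line.split("\t")
            if len(fields) < 12:
                report.malformed_lines += 1
                logger.warning("%s:%d: malformed line (%d columns)", path, lineno, len(fields))
                continue
            try:
                e_value = float(fields[10])
                bit_score = float(fields[11])
                pident = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-numeric field in {path}: {exc}", lineno) from exc
            if e_value < 0:
                raise ParseError(f"negative E-value in {path}", lineno)
            if e_value > e_threshold:
                report.hits_filtered += 1
                continue
            report.hits_kept += 1
            yield AlignmentHit(
                read_id=fields[0],
                protein_id=fields[1],
                percent_identity=pident,
                e_value=e_value,
                bit_score=bit_score,
                extra=tuple(fields[3:10]) + tuple(fields[12:]),
            )


def select_top_hit(hits_for_read: Iterable[AlignmentHit]) -> AlignmentHit:
    """The single best hit for one read.

    Maximal bit score; ties broken by minimal E-value, then lexicographically
    smallest protein_id, so the choice is independent of input order.
    """
    hits = list(hits_for_read)
    if not hits:
        raise ValueError("select_top_hit: empty hit collection")
    read_ids = {h.read_id for h in hits}
    if len(read_ids) > 1:
        raise ValueError(f"select_top_hit: hits span multiple reads {sorted(read_ids)}")
    return min(hits, key=lambda h: (-h.bit_score, h.e_value, h.protein_id))


def assign_reads(
    hits: Iterable[AlignmentHit],
    catalog: BGCCatalog,
    gene_flags: Mapping[str, str],
    sample_id: str,
    on_unknown_protein: str = "drop",
    report: AssignmentReport | None = None,
) -> list[ReadAssignment]:
    """One validated assignment per read, via top-hit selection.

    ``gene_flags`` is the tri-state classification from
    :func:`bgcquant.catalog.classify_catalog_genes`; assignments to
    nonbiosynthesis or unclassified genes carry ``biosynthesis=False``.
    Hits to proteins absent from the catalog are dropped with a count
    (default) or raise, per ``on_unknown_protein`` ("drop" | "error").
    Output is sorted by read_id, so identical inputs yield identical tables
    regardless of input line order.
    """
    if on_unknown_protein not in ("drop", "error"):
        raise ValueError(f"on_unknown_protein must be 'drop' or 'error'")
    if report is None:
        report = AssignmentReport()
    by_read: dict[str, list[AlignmentHit]] = {}
    unknown_reads: set[str] = set()
    for hit in hits:
        if hit.protein_id not in catalog.entries:
            if on_unknown_protein == "error":
                raise InputError(
                    f"hit references protein {hit.protein_id!r} absent from catalog"
                )
            unknown_reads.add(hit.read_id)
            continue
        by_read.setdefault(hit.read_id, []).append(hit)

    report.unknown_protein_reads += len(unknown_reads - set(by_read))
    assignments: list[ReadAssignment] = []
    for read_id in sorted(by_read):
        top = select_top_hit(by_read[read_id])
        entry = catalog.entries[top.protein_id]
        flag = gene_flags.get(entry.gene_id)
        if flag is None:
            raise InputError(
                f"gene {entry.gene_id!r} has no classification; "
                "run domain classification over the full catalog first"
            )
        assignments.append(
            ReadAssignment(
                sample_id=sample_id,
                read_id=read_id,
                protein_id=top.protein_id,
                gene_id=entry.gene_id,
                cluster_id=entry.cluster_id,
                biosynthesis=(flag == BIOSYNTHESIS),
            )
        )
    report.assignments += len(assignments)
    return assignments


def parse_domtblout(path: str | Path) -> dict[str, set[tuple[str, float]]]:
    """Parse HMMER3 ``--domtblout`` output into gene -> domain hits.

    Expects hmmscan orientation: the query (column 4) is the gene/protein,
    the target accession (column 2) is the Pfam model.  Uses the per-domain
    independent E-value (column 13); Pfam version suffixes are stripped; per
    (gene, accession) pair only the best (smallest) E-value is kept.
    Truncated data lines are a hard error naming the line number.
    """
    best: dict[str, dict[str, float]] = {}
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ParseError(f"truncated domtblout line in {path}", lineno)
            accession = strip_pfam_version(fields[1])
            gene_id = fields[3]
            try:
                i_evalue = float(fields[12])
            except ValueError as exc:
                raise ParseError(f"non-numeric i-Evalue in {path}", lineno) from exc
            gene_hits = best.setdefault(gene_id, {})
            if accession not in gene_hits or i_evalue < gene_hits[accession]:
                gene_hits[accession] = i_evalue
    return {g: {(a, e) for a, e in hits.items()} for g, hits in best.items()}


ASSIGNMENT_COLUMNS = (
    "sample_id",
    "read_id",
    "protein_id",
    "gene_id",
    "cluster_id",
    "biosynthesis",
)


def write_assignments(assignments: Iterable[ReadAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for a in assignments:
            fh.write(
                f"{a.sample_id}\t{a.read_id}\t{a.protein_id}\t{a.gene_id}\t"
                f"{a.cluster_id}\t{int(a.biosynthesis)}\n"
            )


def read_assignments(path: str | Path) -> list[ReadAssignment]:
    out: list[ReadAssignment] = []
    with open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ASSIGNMENT_COLUMNS:
            raise ParseError(f"unexpected assignment header in {path}", 1)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ParseError(f"expected 6 columns in {path}", lineno)
            out.append(
                ReadAssignment(
                    sample_id=fields[0],
                    read_id=fields[1],
                    protein_id=fields[2],
                    gene_id=fields[3],
                    cluster_id=fields[4],
                    biosynthesis=fields[5] in ("1", "True", "true"),
                )
            )
    return out
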