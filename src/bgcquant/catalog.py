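"""BGC protein catalog and Pfam-based biosynthesis-gene classification.

A BGC (biosynthetic gene cluster) catalog is a set of protein sequences, each
belonging to one gene, one cluster and one source genome.  Because FASTA
headers from cluster atlases are not standardized, the mapping
protein -> gene -> cluster -> genome travels as a required sidecar TSV next to
the FASTA.  Genes are classified as biosynthesis / nonbiosynthesis /
unclassified from their Pfam domain content: a gene counts as a biosynthesis
gene only if it carries at least one biosynthesis-associated domain below the
E-value cutoff and no nonbiosynthesis-associated domain (the nonbiosynthesis
list exists to remove contamination, so its hits veto).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from bgcquant._util import open_text, strip_pfam_version
from bgcquant.errors import CatalogError, InputError

logger = logging.getLogger(__name__)

#: tri-state gene classification values
BIOSYNTHESIS = "biosynthesis"
NONBIOSYNTHESIS = "nonbiosynthesis"
UNCLASSIFIED = "unclassified"

MAPPING_COLUMNS = ("protein_id", "gene_id", "cluster_id", "genome_id")


@dataclass(frozen=True)
class ProteinEntry:
    """One catalog protein; under the 1-protein-per-gene convention the
    gene_id is usually identical to the protein_id."""

    protein_id: str
    gene_id: str
    cluster_id: str
    genome_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise CatalogError(
                f"protein {self.protein_id!r} has non-positive length {self.length}"
            )


@dataclass
class BGCCatalog:
    """Indexed protein catalog.

    ``clusters`` maps cluster_id -> set of gene_ids, ``genomes`` maps
    genome_id -> set of cluster_ids.  ``annotations`` optionally maps
    cluster_id -> (best-hit organism name, known-SM name) for report joining.
    """

    entries: dict[str, ProteinEntry] = field(default_factory=dict)
    clusters: dict[str, set[str]] = field(default_factory=dict)
    genomes: dict[str, set[str]] = field(default_factory=dict)
    annotations: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def n_proteins(self) -> int:
        return len(self.entries)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def add(self, entry: ProteinEntry) -> None:
        if entry.protein_id in self.entries:
            raise CatalogError(f"duplicate protein_id {entry.protein_id!r} in catalog")
        self.entries[entry.protein_id] = entry
        self.clusters.setdefault(entry.cluster_id, set()).add(entry.gene_id)
        self.genomes.setdefault(entry.genome_id, set()).add(entry.cluster_id)

    def gene_of_protein(self, protein_id: str) -> str:
        return self.entries[protein_id].gene_id

    def cluster_of_protein(self, protein_id: str) -> str:
        return self.entries[protein_id].cluster_id

    def genome_of_cluster(self, cluster_id: str) -> str:
        """First genome carrying the cluster (clusters map to one genome in
        practice; deterministic min() if the mapping ever disagrees)."""
        genomes = sorted(
            e.genome_id for e in self.entries.values() if e.cluster_id == cluster_id
        )
        if not genomes:
            raise KeyError(cluster_id)
        return genomes[0]

    def genes_of_cluster(self, cluster_id: str) -> set[str]:
        return self.clusters[cluster_id]

    def validate(self) -> None:
        """Check index consistency; raises CatalogError on violation."""
        for cid, genes in self.clusters.items():
            if not genes:
                raise CatalogError(f"cluster {cid!r} has no genes")
        gene_cluster: dict[str, str] = {}
        for entry in self.entries.values():
            prev = gene_cluster.setdefault(entry.gene_id, entry.cluster_id)
            if prev != entry.cluster_id:
                raise CatalogError(
                    f"gene {entry.gene_id!r} mapped to clusters {prev!r} and "
                    f"{entry.cluster_id!r}"
                )


@dataclass(frozen=True)
class PfamDomainLists:
    """Pfam accessions defining biosynthesis vs nonbiosynthesis domains.

    Accessions are matched version-insensitively (PF00501.28 == PF00501);
    both sets are stored with version suffixes stripped.
    """

    biosynthesis: frozenset[str]
    nonbiosynthesis: frozenset[str]

    def __post_init__(self) -> None:
        if not self.biosynthesis or not self.nonbiosynthesis:
            raise InputError("both Pfam domain lists must be non-empty")

    @classmethod
    def from_iterables(
        cls, biosynthesis: Iterable[str], nonbiosynthesis: Iterable[str]
    ) -> "PfamDomainLists":
        return cls(
            biosynthesis=frozenset(strip_pfam_version(a) for a in biosynthesis),
            nonbiosynthesis=frozenset(strip_pfam_version(a) for a in nonbiosynthesis),
        )


def load_pfam_lists(
    biosynthesis_path: str | Path, nonbiosynthesis_path: str | Path
) -> PfamDomainLists:
    """Read two one-accession-per-line text files (``#`` comments allowed)."""

    def read_list(path: str | Path) -> list[str]:
        accs = []
        with open_text(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    accs.append(line)
        return accs

    return PfamDomainLists.from_iterables(
        read_list(biosynthesis_path), read_list(nonbiosynthesis_path)
    )


def load_catalog(
    fasta_path: str | Path,
    mapping_path: str | Path,
    annotations_path: str | Path | None = None,
) -> BGCCatalog:
    """Load and index a BGC protein catalog.

    Parameters
    ----------
    fasta_path
        Protein FASTA; record ids are protein_ids.
    mapping_path
        TSV with header ``protein_id  gene_id  cluster_id  genome_id``.
    annotations_path
        Optional TSV with header ``cluster_id  organism  sm`` used to join
        best-hit organism and known secondary-metabolite names into reports.

    Raises
    ------
    CatalogError
        On duplicate protein ids, mapping rows without a FASTA record, FASTA
        records without a mapping row, or empty inputs.
    """
    fasta_records: dict[str, tuple[int, str]] = {}
    with open_text(fasta_path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in fasta_records:
                raise CatalogError(f"duplicate protein_id {record.id!r} in FASTA")
            seq = str(record.seq)
            fasta_records[record.id] = (len(seq), seq)
    if not fasta_records:
        raise CatalogError(f"empty FASTA file: {fasta_path}")

    catalog = BGCCatalog()
    seen_proteins: set[str] = set()
    with open_text(mapping_path) as fh:
        header = fh.readline()
        if not header:
            raise CatalogError(f"empty mapping file: {mapping_path}")
        cols = tuple(header.rstrip("\n").split("\t"))
        if cols != MAPPING_COLUMNS:
            raise CatalogError(
                f"mapping header must be {MAPPING_COLUMNS}, got {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CatalogError(
                    f"mapping line {lineno}: expected 4 columns, got {len(fields)}"
                )
            protein_id, gene_id, cluster_id, genome_id = fields
            if protein_id in seen_proteins:
                raise CatalogError(
                    f"protein {protein_id!r} listed more than once in mapping"
                )
            seen_proteins.add(protein_id)
            if protein_id not in fasta_records:
                raise CatalogError(
                    f"mapping line {lineno}: protein {protein_id!r} has no FASTA record"
                )
            length, seq = fasta_records[protein_id]
            catalog.add(
                ProteinEntry(protein_id, gene_id, cluster_id, genome_id, length, seq)
            )
    if not catalog.entries:
        raise CatalogError(f"mapping file has no data rows: {mapping_path}")

    unmapped = set(fasta_records) - seen_proteins
    if unmapped:
        names = ", ".join(repr(p) for p in sorted(unmapped)[:5])
        raise CatalogError(
            f"{len(unmapped)} FASTA protein(s) absent from mapping (e.g. {names})"
        )

    if annotations_path is not None:
        with open_text(annotations_path) as fh:
            header = fh.readline()
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                catalog.annotations[fields[0]] = (fields[1], fields[2])

    catalog.validate()
    return catalog


def write_catalog(catalog: BGCCatalog, mapping_path: str | Path) -> None:
    """Write the catalog's mapping table back to TSV (entry order)."""
    with open(mapping_path, "w") as fh:
        fh.write("\t".join(MAPPING_COLUMNS) + "\n")
        for entry in catalog.entries.values():
            fh.write(
                f"{entry.protein_id}\t{entry.gene_id}\t{entry.cluster_id}\t"
                f"{entry.genome_id}\n"
            )


def classify_gene(
    gene_domain_hits: Iterable[tuple[str, float]],
    lists: PfamDomainLists,
    e_threshold: float = 0.01,
) -> str:
    """Classify one gene from its Pfam domain hits.

    Hits with E-value above ``e_threshold`` are ignored.  A gene is
    ``biosynthesis`` iff at least one surviving hit is in the biosynthesis
    list and none is in the nonbiosynthesis list; ``nonbiosynthesis`` iff at
    least one surviving nonbiosynthesis hit exists (veto); ``unclassified``
    otherwise.  Accessions in neither list are logged and contribute nothing.
    """
    if e_threshold <= 0:
        raise ValueError(f"e_threshold must be > 0, got {e_threshold}")
    has_bio = False
    has_nonbio = False
    for accession, e_value in gene_domain_hits:
        if e_value > e_threshold:
            continue
        acc = strip_pfam_version(accession)
        if acc in lists.nonbiosynthesis:
            has_nonbio = True
        elif acc in lists.biosynthesis:
            has_bio = True
        else:
            logger.debug("Pfam accession %s in neither domain list; ignored", acc)
    if has_nonbio:
        return NONBIOSYNTHESIS
    if has_bio:
        return BIOSYNTHESIS
    return UNCLASSIFIED


def classify_catalog_genes(
    domain_hits: Mapping[str, set[tuple[str, float]]],
    catalog: BGCCatalog,
    lists: PfamDomainLists,
    e_threshold: float = 0.01,
) -> dict[str, str]:
    """Classify every gene in the catalog; genes with no domain hits at all
    are unclassified and never count toward abundance."""
    flags: dict[str, str] = {}
    for entry in catalog.entries.values():
        hits = domain_hits.get(entry.gene_id, set())
        flags[entry.gene_id] = classify_gene(hits, lists, e_threshold)
    return flags
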