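"""Per-sample BGC abundance: counting, detection filtering, normalization.

The abundance score of a cluster in a sample is the number of reads whose
top hit lands on one of the cluster's *biosynthesis* genes (F_BGC).  Clusters
are retained when (a) at least a minimum fraction of their biosynthesis genes
are detected anywhere in the cohort and (b) strictly more than ``min_samples``
samples carry at least ``min_reads`` such reads.  Retained counts are
normalized to reads-per-million of the sample's total read count,

    N = F * 1e6 / total,

and a retained cluster absent from a sample (zero count) is imputed with a
small pseudo-abundance (default 0.01) so that rank statistics downstream see
a complete matrix; the imputation mask is carried alongside the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from bgcquant.catalog import BIOSYNTHESIS, BGCCatalog
from bgcquant.errors import InputError, StageError
from bgcquant.hits import ReadAssignment

DEFAULT_MIN_GENE_FRACTION = 0.5
DEFAULT_MIN_SAMPLES = 10
DEFAULT_MIN_READS = 10
DEFAULT_IMPUTE_VALUE = 0.01


@dataclass
class RawCountMatrix:
    """samples x clusters biosynthesis-read counts plus per-sample totals.

    ``counts``: DataFrame, rows = sample_ids, columns = cluster_ids.
    ``totals``: Series indexed by sample_id (total reads per sample, i.e. the
    pre-alignment library size after QC).
    ``gene_detection``: Series indexed by cluster_id, fraction of the
    cluster's biosynthesis genes with >= 1 assigned read anywhere in the
    cohort.
    """

    counts: pd.DataFrame
    totals: pd.Series
    gene_detection: pd.Series

    def __post_init__(self) -> None:
        if (self.totals <= 0).any():
            bad = self.totals.index[self.totals <= 0].tolist()
            raise InputError(f"non-positive total read count for sample(s) {bad}")
        if (self.counts.values < 0).any():
            raise InputError("negative counts in RawCountMatrix")
        exceeded = self.counts.gt(self.totals, axis=0)
        if exceeded.values.any():
            raise InputError("cluster count exceeds sample total read count")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class AbundanceMatrix:
    """Normalized samples x clusters abundances with an imputation mask."""

    values: pd.DataFrame
    imputed: pd.DataFrame
    impute_value: float = DEFAULT_IMPUTE_VALUE

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.values.columns)


def count_bgc_reads(
    assignments: Iterable[ReadAssignment],
    totals: Mapping[str, int],
    catalog: BGCCatalog,
    gene_flags: Mapping[str, str],
) -> RawCountMatrix:
    """Aggregate biosynthesis-gene read assignments into a count matrix.

    Assignments with ``biosynthesis=False`` are ignored.  The matrix covers
    every sample in ``totals`` and every catalog cluster (zero rows/columns
    kept so downstream filters see true absences).  A sample appearing in the
    assignments but missing from ``totals`` is a hard error.
    """
    bio_genes_per_cluster: dict[str, set[str]] = {
        cid: {g for g in genes if gene_flags.get(g) == BIOSYNTHESIS}
        for cid, genes in catalog.clusters.items()
    }
    sample_ids = sorted(totals)
    cluster_ids = sorted(catalog.clusters)
    counts = pd.DataFrame(
        0, index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.Index(cluster_ids, name="cluster_id"), dtype=np.int64,
    )
    detected_genes: dict[str, set[str]] = {cid: set() for cid in cluster_ids}
    bio = [(a.sample_id, a.cluster_id, a.gene_id) for a in assignments if a.biosynthesis]
    if bio:
        df = pd.DataFrame(bio, columns=["sample_id", "cluster_id", "gene_id"])
        missing = set(df["sample_id"].unique()) - set(totals)
        if missing:
            raise InputError(
                f"sample(s) {sorted(missing)} present in assignments but missing from totals"
            )
        cell = df.groupby(["sample_id", "cluster_id"]).size()
        counts = counts.add(cell.unstack(fill_value=0), fill_value=0).astype(np.int64)
        counts = counts.reindex(index=sample_ids, columns=cluster_ids, fill_value=0)
        for cid, genes in df.groupby("cluster_id")["gene_id"]:
            detected_genes[cid].update(genes.unique())

    detection = {}
    for cid in cluster_ids:
        bio = bio_genes_per_cluster[cid]
        detection[cid] = len(detected_genes[cid] & bio) / len(bio) if bio else 0.0
    gene_detection = pd.Series(detection, name="gene_detection").reindex(cluster_ids)
    totals_s = pd.Series({s: int(totals[s]) for s in sample_ids}, name="total_reads")
    return RawCountMatrix(counts=counts, totals=totals_s, gene_detection=gene_detection)


def filter_bgcs(
    m: RawCountMatrix,
    min_gene_fraction: float = DEFAULT_MIN_GENE_FRACTION,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_reads: int = DEFAULT_MIN_READS,
    strict_sample_inequality: bool = True,
) -> set[str]:
    """Retention filter over clusters.

    A cluster is retained iff its cohort-wide biosynthesis-gene detection is
    >= ``min_gene_fraction`` AND the number of samples with at least
    ``min_reads`` reads is > ``min_samples`` (strict by default; set
    ``strict_sample_inequality=False`` for >=).  An empty retained set is a
    valid outcome.
    """
    support = (m.counts >= min_reads).sum(axis=0)
    if strict_sample_inequality:
        enough_samples = support > min_samples
    else:
        enough_samples = support >= min_samples
    enough_genes = m.gene_detection >= min_gene_fraction
    keep = enough_genes & enough_samples.reindex(m.gene_detection.index)
    return set(keep.index[keep])


def normalize(
    m: RawCountMatrix,
    retained: set[str],
    impute_value: float = DEFAULT_IMPUTE_VALUE,
) -> AbundanceMatrix:
    """Reads-per-million normalization of the retained clusters.

    value = count * 1e6 / total where count > 0; cells with zero count get
    ``impute_value`` and are flagged in the mask.  Non-retained clusters are
    absent from the output entirely.
    """
    if (m.totals <= 0).any():
        raise StageError("cannot normalize: zero total read count")
    cols = sorted(retained & set(m.counts.columns))
    counts = m.counts[cols]
    values = counts.astype(float).mul(1e6).div(m.totals, axis=0)
    imputed = counts == 0
    values = values.mask(imputed, impute_value)
    return AbundanceMatrix(values=values, imputed=imputed, impute_value=impute_value)


def load_totals(path: str | Path) -> dict[str, int]:
    """Read a totals TSV with columns sample_id, total_reads."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "total_reads"}.issubset(df.columns):
        raise InputError(f"totals file {path} needs columns sample_id, total_reads")
    return dict(zip(df["sample_id"], df["total_reads"].astype(int)))


def write_abundance(abund: AbundanceMatrix, values_path: str | Path,
                    mask_path: str | Path | None = None) -> None:
    abund.values.to_csv(values_path, sep="\t")
    if mask_path is not None:
        abund.imputed.astype(int).to_csv(mask_path, sep="\t")


def read_abundance(values_path: str | Path,
                   mask_path: str | Path | None = None,
                   impute_value: float = DEFAULT_IMPUTE_VALUE) -> AbundanceMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if mask_path is not None:
        imputed = pd.read_csv(mask_path, sep="\t", index_col=0).astype(bool)
        imputed.index = imputed.index.astype(str)
        imputed.columns = imputed.columns.astype(str)
    else:
        imputed = values == impute_value
    return AbundanceMatrix(values=values, imputed=imputed, impute_value=impute_value)
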