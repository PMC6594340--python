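"""End-to-end orchestration: QC -> assign -> quantify -> associate -> report.

A single :class:`PipelineConfig` holds every input path and threshold; the
defaults are the standard protocol values (alignment E-value 1e-05, domain
E-value 0.01, cluster retention at >=50% biosynthesis-gene detection in >10
samples with >=10 reads, impute 0.01, 70 bp trimming).  ``run_pipeline``
writes a self-contained output directory: the abundance matrix and
imputation mask, association tables, the per-sample mean-abundance
statistic, a run log, and the fully resolved configuration, so a rerun with
the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from bgcquant import associate as assoc
from bgcquant import catalog as cat
from bgcquant import hits as hp
from bgcquant import quantify as qt
from bgcquant.errors import BgcquantError, InputError, StageError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs
    catalog_fasta: str = ""
    catalog_mapping: str = ""
    annotations: str | None = None
    pfam_biosynthesis: str = ""
    pfam_nonbiosynthesis: str = ""
    domtblout: str = ""
    hits_dir: str = ""
    reads_dir: str | None = None
    totals: str = ""
    metadata: str = ""
    tax_profile: str | None = None
    #: cluster whose abundance is correlated against phyla; "top" picks the
    #: best BMI-associated cluster
    taxa_feature_cluster: str | None = None
    # thresholds (protocol defaults)
    align_evalue: float = 1e-05
    domain_evalue: float = 0.01
    min_gene_fraction: float = 0.5
    min_samples: int = 10
    min_reads: int = 10
    strict_sample_inequality: bool = True
    impute_value: float = 0.01
    keep_bp: int = 70
    #: "human" for the broad catalog, "known_sm" for a known-metabolite
    #: catalog (adds the SM column to the association table)
    catalog_mode: str = "human"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def required_paths(self) -> dict[str, str]:
        req = {
            "catalog_fasta": self.catalog_fasta,
            "catalog_mapping": self.catalog_mapping,
            "pfam_biosynthesis": self.pfam_biosynthesis,
            "pfam_nonbiosynthesis": self.pfam_nonbiosynthesis,
            "domtblout": self.domtblout,
            "hits_dir": self.hits_dir,
            "totals": self.totals,
            "metadata": self.metadata,
        }
        if self.annotations:
            req["annotations"] = self.annotations
        if self.tax_profile:
            req["tax_profile"] = self.tax_profile
        return req


@dataclass
class PipelineResult:
    outdir: Path
    retained: set[str]
    abundance: qt.AbundanceMatrix
    bmi_table: pd.DataFrame
    mean_abundance: pd.Series
    mean_rho: float
    mean_p: float
    taxa_table: pd.DataFrame | None = None
    counts: qt.RawCountMatrix | None = None


def _check_inputs(config: PipelineConfig) -> None:
    for name, path in config.required_paths().items():
        if not path:
            raise InputError(f"config field {name!r} is required")
        if not Path(path).exists():
            raise InputError(f"{name}: no such file or directory: {path}")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage and write the output directory.  Any stage failure is
    re-raised as StageError naming the stage."""
    _check_inputs(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        line = f"[{stage}] {message}"
        logger.info(line)
        log_lines.append(line)

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                log(name, "start")

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, InputError):
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                if exc is None:
                    log(name, "done")
                return False

        return _Ctx()

    with stage("catalog"):
        catalog = cat.load_catalog(
            config.catalog_fasta, config.catalog_mapping, config.annotations
        )
        lists = cat.load_pfam_lists(
            config.pfam_biosynthesis, config.pfam_nonbiosynthesis
        )
        domain_hits = hp.parse_domtblout(config.domtblout)
        gene_flags = cat.classify_catalog_genes(
            domain_hits, catalog, lists, e_threshold=config.domain_evalue
        )
        n_bio = sum(1 for f in gene_flags.values() if f == cat.BIOSYNTHESIS)
        log("catalog", f"{catalog.n_proteins} proteins, {catalog.n_clusters} clusters, "
                       f"{n_bio} biosynthesis genes")

    with stage("assign"):
        hit_files = sorted(Path(config.hits_dir).glob("*.tsv"))
        if not hit_files:
            raise InputError(f"no *.tsv hit files in {config.hits_dir}")
        assignments: list[hp.ReadAssignment] = []
        parse_report = hp.ParseReport()
        assign_report = hp.AssignmentReport()
        for hit_file in hit_files:
            hits = hp.parse_blast_tab(hit_file, config.align_evalue, parse_report)
            assignments.extend(
                hp.assign_reads(hits, catalog, gene_flags, hit_file.stem,
                                report=assign_report)
            )
        log("assign", f"{assign_report.assignments} read assignments from "
                      f"{len(hit_files)} samples "
                      f"({parse_report.hits_filtered} hits over E-value threshold, "
                      f"{parse_report.malformed_lines} malformed lines, "
                      f"{assign_report.unknown_protein_reads} reads on unknown proteins)")
        hp.write_assignments(assignments, outdir / "assignments.tsv")

    with stage("quantify"):
        totals = qt.load_totals(config.totals)
        matrix = qt.count_bgc_reads(assignments, totals, catalog, gene_flags)
        retained = qt.filter_bgcs(
            matrix,
            min_gene_fraction=config.min_gene_fraction,
            min_samples=config.min_samples,
            min_reads=config.min_reads,
            strict_sample_inequality=config.strict_sample_inequality,
        )
        log("quantify", f"{len(retained)}/{matrix.counts.shape[1]} clusters retained")
        abundance = qt.normalize(matrix, retained, config.impute_value)
        matrix.counts.to_csv(outdir / "counts.tsv", sep="\t")
        qt.write_abundance(abundance, outdir / "abundance.tsv", outdir / "imputed_mask.tsv")
        (outdir / "retained_clusters.txt").write_text(
            "".join(c + "\n" for c in sorted(retained))
        )

    with stage("associate"):
        meta = assoc.load_metadata(config.metadata)
        cluster_genomes = {
            cid: catalog.genome_of_cluster(cid) for cid in sorted(retained)
        }
        bmi_table = assoc.associate_bmi(
            abundance, meta,
            annotations=catalog.annotations or None,
            cluster_genomes=cluster_genomes,
        )
        if config.catalog_mode != "known_sm" and "sm" in bmi_table.columns:
            bmi_table = bmi_table.drop(columns=["sm"])
        assoc.write_association_table(bmi_table, outdir / "associations_bmi.tsv")
        means, mean_rho, mean_p = assoc.mean_abundance_stat(abundance, meta)
        means.rename("mean_abundance").rename_axis("sample_id").reset_index().to_csv(
            outdir / "mean_abundance.tsv", sep="\t", index=False
        )
        log("associate", f"mean abundance vs BMI: rho={mean_rho:.4f} p={mean_p:.3g}")

        taxa_table = None
        if config.tax_profile:
            tax = assoc.load_metaphlan_profile(config.tax_profile)
            feature_cluster = config.taxa_feature_cluster
            if feature_cluster in (None, "top"):
                testable = bmi_table[bmi_table["note"] == ""]
                if testable.empty:
                    raise StageError("no testable cluster for taxa association")
                feature_cluster = str(testable.iloc[0]["cluster_id"])
            if feature_cluster not in abundance.values.columns:
                raise InputError(
                    f"taxa feature cluster {feature_cluster!r} not in abundance matrix"
                )
            taxa_table = assoc.associate_taxa(abundance.values[feature_cluster], tax)
            assoc.write_association_table(taxa_table, outdir / "associations_taxa.tsv")
            log("associate", f"taxa association computed for cluster {feature_cluster}")

    with stage("report"):
        summary = {
            "n_samples": int(matrix.counts.shape[0]),
            "n_clusters_total": int(matrix.counts.shape[1]),
            "n_clusters_retained": len(retained),
            "mean_abundance_rho": mean_rho,
            "mean_abundance_p": mean_p,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        config.to_yaml(outdir / "resolved_config.yaml")
        (outdir / "run.log").write_text("".join(l + "\n" for l in log_lines))

    return PipelineResult(
        outdir=outdir, retained=retained, abundance=abundance,
        bmi_table=bmi_table, mean_abundance=means, mean_rho=mean_rho,
        mean_p=mean_p, taxa_table=taxa_table, counts=matrix,
    )
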