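"""Seeded synthetic cohorts with known planted structure.

The generator emulates the inputs of a fecal-metagenome BGC survey: a
protein catalog with per-cluster biosynthesis-gene composition, Pfam domain
lists, HMMER domain tables, per-sample read-vs-protein alignment tables,
library sizes, BMI metadata from a lean/obese mixture, and phylum-level
taxonomic profiles.  Selected clusters carry a *planted* monotone
association with BMI realized through a Gaussian copula: the latent
abundance of a planted cluster is

    z = r * z_BMI + sqrt(1 - r^2) * noise,

where z_BMI are normal scores of the BMI ranks and r = 2 sin(pi * rho_s / 6)
converts the target Spearman rho_s into the copula's Pearson parameter, so
the population rank correlation of the latent abundance with BMI equals
rho_s exactly.  Latents are discretized to counts through the negative
binomial quantile function (metagenomic counts are overdispersed) and
sparsified by an independent per-cell dropout.  The alignment tables contain
exactly the reads needed to reproduce the intended count matrix when pushed
through QC, top-hit assignment and counting, so generator/pipeline agreement
can be asserted cell-for-cell.
"""

from __future__ import annotations

import hashlib
import json
import math
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from bgcquant import catalog as cat
from bgcquant import hits as hp
from bgcquant import quantify as qt
from bgcquant.errors import InputError

#: Pfam accessions used for synthetic biosynthesis domains (condensation,
#: AMP-binding, ketoacyl synthases) and housekeeping/transport domains.
SYNTH_BIO_PFAMS = ("PF00668", "PF00501", "PF00109", "PF02801", "PF00550")
SYNTH_NONBIO_PFAMS = ("PF00005", "PF00072", "PF07690", "PF00486")

DEFAULT_PHYLA = (
    "Acidobacteria", "Actinobacteria", "Bacteroidetes",
    "Candidatus Saccharibacteria", "Chlorobi", "Deinococcus-Thermus",
    "Firmicutes", "Fusobacteria", "Proteobacteria", "Spirochaetes",
    "Synergistetes", "Tenericutes", "Verrucomicrobia",
)


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-size gut cohort: 150 samples, 100 clusters of
    3-8 genes (75% biosynthesis genes each), 5 clusters planted at a
    population Spearman rho of 0.4 with BMI, 20% per-cell dropout, and BMI
    drawn from a lean/obese normal mixture weighted 123:169.
    """

    n_samples: int = 150
    n_clusters: int = 100
    genes_per_cluster: tuple[int, int] = (3, 8)
    biosynthesis_fraction: float = 0.75
    n_planted: int = 5
    planted_rho: float = 0.4
    planted_effects: dict[str, float] | None = None
    sparsity: float = 0.2
    mean_count_range: tuple[float, float] = (20.0, 80.0)
    nb_dispersion: float = 2.0
    total_reads_range: tuple[int, int] = (800_000, 1_200_000)
    bmi_lean: tuple[float, float] = (23.5, 2.0)
    bmi_obese: tuple[float, float] = (33.0, 4.0)
    obese_weight: float = 169 / 292
    n_phyla: int = 13
    phylum_effects: dict[str, float] | None = None
    known_sm: bool = False
    write_fastq: bool = False
    read_length: int = 75
    seed: int = 7

    def cluster_ids(self) -> list[str]:
        return [str(160_000_000 + i) for i in range(self.n_clusters)]

    def resolved_planted(self) -> dict[str, float]:
        if self.planted_effects is not None:
            return dict(self.planted_effects)
        ids = self.cluster_ids()
        return {ids[i]: self.planted_rho for i in range(min(self.n_planted, len(ids)))}

    def resolved_phylum_effects(self) -> dict[str, float]:
        if self.phylum_effects is not None:
            return dict(self.phylum_effects)
        phyla = self.phylum_names()
        effects = {}
        if "Actinobacteria" in phyla:
            effects["Actinobacteria"] = 0.35
        if "Bacteroidetes" in phyla:
            effects["Bacteroidetes"] = -0.3
        return effects

    def phylum_names(self) -> list[str]:
        if self.n_phyla <= len(DEFAULT_PHYLA):
            return list(DEFAULT_PHYLA[: self.n_phyla])
        extra = [f"Phylum_{i}" for i in range(self.n_phyla - len(DEFAULT_PHYLA))]
        return list(DEFAULT_PHYLA) + extra

    def validate(self) -> None:
        if self.n_samples < 3 or self.n_clusters < 1:
            raise InputError("need n_samples >= 3 and n_clusters >= 1")
        if not (0 <= self.sparsity <= 1):
            raise InputError("sparsity must lie in [0, 1]")
        if not (0 <= self.biosynthesis_fraction <= 1):
            raise InputError("biosynthesis_fraction must lie in [0, 1]")
        planted = self.resolved_planted()
        if any(abs(r) >= 1 for r in planted.values()):
            raise InputError("planted |rho| must be < 1")
        if self.sparsity >= 1 and any(r != 0 for r in planted.values()):
            raise InputError(
                "infeasible spec: sparsity 1.0 erases every planted association"
            )
        known = set(self.cluster_ids())
        unknown = set(planted) - known
        if unknown:
            raise InputError(f"planted effects reference unknown clusters {sorted(unknown)}")
        if any(abs(r) >= 1 for r in self.resolved_phylum_effects().values()):
            raise InputError("phylum |rho| must be < 1")


@dataclass
class CohortTables:
    """In-memory realization of a cohort: the generator's ground truth."""

    spec: SyntheticCohortSpec
    mapping: pd.DataFrame              # protein_id, gene_id, cluster_id, genome_id
    gene_flags_truth: dict[str, str]   # gene -> tri-state classification
    counts: pd.DataFrame               # intended samples x clusters matrix
    totals: pd.Series
    bmi: pd.Series
    latents: pd.DataFrame              # samples x clusters copula latents
    tax: pd.DataFrame                  # samples x phyla percentages
    designated_cluster: str | None


def spearman_to_pearson(rho_s: float) -> float:
    """Copula parameter giving population Spearman ``rho_s`` for a bivariate
    normal: r = 2 sin(pi * rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Blom-style normal scores of the value ranks (ties impossible for
    continuous draws)."""
    n = values.size
    ranks = stats.rankdata(values)
    return stats.norm.ppf(ranks / (n + 1.0))


def generate_tables(spec: SyntheticCohortSpec) -> CohortTables:
    """Draw the cohort in memory (no files).  Deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    cluster_ids = spec.cluster_ids()
    planted = spec.resolved_planted()

    # --- catalog structure -------------------------------------------------
    lo, hi = spec.genes_per_cluster
    n_genes = rng.integers(lo, hi + 1, size=spec.n_clusters)
    rows = []
    gene_flags: dict[str, str] = {}
    for j, cid in enumerate(cluster_ids):
        genome_id = str(641_000_000 + j)
        g = int(n_genes[j])
        n_bio = max(1, round(spec.biosynthesis_fraction * g)) if spec.biosynthesis_fraction > 0 else 0
        n_bio = min(n_bio, g)
        for k in range(g):
            gene_id = f"{cid}.g{k:02d}"
            rows.append((gene_id, gene_id, cid, genome_id))
            if k < n_bio:
                gene_flags[gene_id] = cat.BIOSYNTHESIS
            elif (k - n_bio) % 3 == 2:
                gene_flags[gene_id] = cat.UNCLASSIFIED
            else:
                gene_flags[gene_id] = cat.NONBIOSYNTHESIS
    mapping = pd.DataFrame(
        rows, columns=["protein_id", "gene_id", "cluster_id", "genome_id"]
    )

    # --- BMI mixture and its normal scores ---------------------------------
    obese = rng.random(n) < spec.obese_weight
    bmi = np.where(
        obese,
        rng.normal(spec.bmi_obese[0], spec.bmi_obese[1], size=n),
        rng.normal(spec.bmi_lean[0], spec.bmi_lean[1], size=n),
    )
    bmi = np.clip(bmi, 15.0, 60.0)
    z_bmi = _normal_scores(bmi)

    # --- latent abundances via the Gaussian copula -------------------------
    latents = np.empty((n, spec.n_clusters))
    for j, cid in enumerate(cluster_ids):
        r = spearman_to_pearson(planted.get(cid, 0.0))
        eps = rng.standard_normal(n)
        latents[:, j] = r * z_bmi + math.sqrt(1.0 - r * r) * eps

    # --- discretize via a zero-inflated negative-binomial quantile link ----
    # absence (probability `sparsity`) is the zero point mass at the bottom
    # of the distribution, so the link stays monotone in the latent and the
    # planted population Spearman carries through to the observable counts
    # (independent per-cell masking would attenuate it badly)
    mu = np.exp(rng.uniform(
        math.log(spec.mean_count_range[0]), math.log(spec.mean_count_range[1]),
        size=spec.n_clusters,
    ))
    k_disp = spec.nb_dispersion
    u = stats.norm.cdf(latents)
    # lower clip stays positive: discrete ppf at exactly 0 would return -1
    u = np.clip(
        (u - spec.sparsity) / max(1.0 - spec.sparsity, 1e-12), 1e-12, 1.0 - 1e-12
    )
    counts = np.empty_like(latents, dtype=np.int64)
    for j in range(spec.n_clusters):
        p_nb = k_disp / (k_disp + mu[j])
        counts[:, j] = stats.nbinom.ppf(u[:, j], k_disp, p_nb).astype(np.int64)
    # clusters without a single biosynthesis gene can never accrue counted
    # reads; their intended counts are zero by construction
    has_bio = np.array([
        any(gene_flags.get(f"{cid}.g{k:02d}") == cat.BIOSYNTHESIS
            for k in range(int(n_genes[j])))
        for j, cid in enumerate(cluster_ids)
    ])
    counts[:, ~has_bio] = 0

    counts_df = pd.DataFrame(
        counts, index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.Index(cluster_ids, name="cluster_id"),
    )
    latents_df = pd.DataFrame(latents, index=counts_df.index, columns=counts_df.columns)

    # --- library sizes ------------------------------------------------------
    totals = rng.integers(
        spec.total_reads_range[0], spec.total_reads_range[1] + 1, size=n
    )
    totals = np.maximum(totals, counts.sum(axis=1) + 1000)
    totals_s = pd.Series(totals, index=counts_df.index, name="total_reads")

    # --- taxonomic profiles -------------------------------------------------
    phyla = spec.phylum_names()
    phylum_effects = spec.resolved_phylum_effects()
    designated = next(iter(planted), cluster_ids[0]) if cluster_ids else None
    # plant phylum effects against the *observable* abundance of the
    # designated cluster (normal scores of its counts, ties averaged), so the
    # realized rank correlation matches the target despite discretization
    # and dropout
    if designated is not None:
        ref_counts = counts_df[designated].values
        z_ref = stats.norm.ppf(stats.rankdata(ref_counts) / (n + 1.0))
    else:
        z_ref = np.zeros(n)
    z_ref = (z_ref - z_ref.mean()) / (z_ref.std() or 1.0)
    base_level = rng.normal(0.0, 1.5, size=len(phyla))
    tax = np.empty((n, len(phyla)))
    for q, ph in enumerate(phyla):
        r = spearman_to_pearson(phylum_effects.get(ph, 0.0))
        eps = rng.standard_normal(n)
        z_ph = r * z_ref + math.sqrt(1.0 - r * r) * eps
        tax[:, q] = np.exp(base_level[q] + z_ph)
    tax = tax / tax.sum(axis=1, keepdims=True) * 100.0
    tax_df = pd.DataFrame(tax, index=counts_df.index, columns=pd.Index(phyla, name="phylum"))

    bmi_s = pd.Series(bmi, index=counts_df.index, name="bmi")
    return CohortTables(
        spec=spec, mapping=mapping, gene_flags_truth=gene_flags,
        counts=counts_df, totals=totals_s, bmi=bmi_s, latents=latents_df,
        tax=tax_df, designated_cluster=designated,
    )


# ---------------------------------------------------------------------------
# file bundle
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: synthetic secondary-metabolite names for known-SM flavored catalogs
_SM_NAMES = (
    "Menaquinone", "Yersiniabactin", "Toxoflavin", "Pimaricin", "Enterochelin",
    "Gramicidin", "L-Rhamnose", "Lipopolysaccharide", "GDP-mannose", "L-Citrulline",
)


def generate_cohort(spec: SyntheticCohortSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the full input bundle for one cohort and return its paths.

    Layout: ``catalog.faa`` + ``catalog_mapping.tsv`` + ``annotations.tsv``,
    ``pfam_biosynthesis.txt`` / ``pfam_nonbiosynthesis.txt``,
    ``domains.domtblout``, ``hits/<sample>.tsv`` (BLAST outfmt-6),
    optionally ``reads/<sample>.fastq``, ``totals.tsv``, ``metadata.tsv``,
    ``tax_profile.tsv``, ``intended_counts.tsv`` and ``ground_truth.json``.
    """
    tables = generate_tables(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "hits").mkdir(exist_ok=True)
    if spec.write_fastq:
        (outdir / "reads").mkdir(exist_ok=True)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB6C]))

    # catalog FASTA + mapping + annotations
    fasta_path = outdir / "catalog.faa"
    with open(fasta_path, "w") as fh:
        for row in tables.mapping.itertuples(index=False):
            seq = "".join(rng.choice(list(_AA), size=60))
            fh.write(f">{row.protein_id}\n{seq}\n")
    mapping_path = outdir / "catalog_mapping.tsv"
    tables.mapping.to_csv(mapping_path, sep="\t", index=False)
    annotations_path = outdir / "annotations.tsv"
    with open(annotations_path, "w") as fh:
        fh.write("cluster_id\torganism\tsm\n")
        for j, cid in enumerate(spec.cluster_ids()):
            sm = _SM_NAMES[j % len(_SM_NAMES)] if spec.known_sm else ""
            fh.write(f"{cid}\tOrganism sp. {j:03d}\t{sm}\n")

    # Pfam lists
    pfam_bio = outdir / "pfam_biosynthesis.txt"
    pfam_nonbio = outdir / "pfam_nonbiosynthesis.txt"
    pfam_bio.write_text("".join(a + "\n" for a in SYNTH_BIO_PFAMS))
    pfam_nonbio.write_text("".join(a + "\n" for a in SYNTH_NONBIO_PFAMS))

    # domtblout consistent with the truth flags
    dom_path = outdir / "domains.domtblout"
    with open(dom_path, "w") as fh:
        fh.write("#                                                               --- full sequence --- -------------- this domain -------------\n")
        fh.write("# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target\n")
        for gene_id, flag in tables.gene_flags_truth.items():
            if flag == cat.UNCLASSIFIED:
                continue
            pool = SYNTH_BIO_PFAMS if flag == cat.BIOSYNTHESIS else SYNTH_NONBIO_PFAMS
            acc = pool[int(rng.integers(len(pool)))]
            ev = 10.0 ** float(rng.uniform(-40, -5))
            fh.write(
                f"Domain_{acc}         {acc}.12      200 {gene_id:<20} -            60 "
                f"{ev:9.1e}  150.0   0.1   1   1  {ev:9.1e} {ev:9.1e}  149.0   0.1     1   190     2    58     1    60 0.95 synthetic domain\n"
            )

    # per-sample alignment tables (and optional FASTQ)
    gene_lists: dict[str, list[str]] = {}
    nonbio_pool: list[str] = []
    for row in tables.mapping.itertuples(index=False):
        flag = tables.gene_flags_truth[row.gene_id]
        if flag == cat.BIOSYNTHESIS:
            gene_lists.setdefault(row.cluster_id, []).append(row.gene_id)
        elif flag == cat.NONBIOSYNTHESIS:
            nonbio_pool.append(row.gene_id)

    read_len = spec.read_length
    hit_paths: dict[str, Path] = {}
    for sample_id in tables.counts.index:
        hit_path = outdir / "hits" / f"{sample_id}.tsv"
        hit_paths[sample_id] = hit_path
        fastq_lines: list[str] = []
        counter = 0
        with open(hit_path, "w") as fh:
            row = tables.counts.loc[sample_id]
            for cid in tables.counts.columns:
                k = int(row[cid])
                if k == 0:
                    continue
                genes = gene_lists[cid]
                for t in range(k):
                    gene = genes[t % len(genes)]
                    read_id = f"{sample_id}:r{counter:06d}"
                    counter += 1
                    fh.write(_blast_line(read_id, gene, bit=88.2, evalue=3e-21))
                    # occasional suboptimal secondary hit: top-hit selection
                    # must ignore it
                    if t % 7 == 3 and nonbio_pool:
                        decoy = nonbio_pool[counter % len(nonbio_pool)]
                        fh.write(_blast_line(read_id, decoy, bit=41.0, evalue=2e-8))
                    if spec.write_fastq:
                        fastq_lines.append(_fastq_record(read_id, read_len))
            # a few reads whose top hit is a nonbiosynthesis gene: excluded
            # from abundance but present in the assignment table
            for d in range(3 if nonbio_pool else 0):
                read_id = f"{sample_id}:x{d:03d}"
                decoy = nonbio_pool[(counter + d) % len(nonbio_pool)]
                fh.write(_blast_line(read_id, decoy, bit=75.0, evalue=5e-15))
                if spec.write_fastq:
                    fastq_lines.append(_fastq_record(read_id, read_len))
            # one sub-threshold line the E-value filter must remove
            if gene_lists:
                any_gene = next(iter(gene_lists.values()))[0]
                fh.write(_blast_line(f"{sample_id}:weak", any_gene, bit=22.0, evalue=1e-3))
        if spec.write_fastq:
            (outdir / "reads" / f"{sample_id}.fastq").write_text("".join(fastq_lines))

    # tabular sidecars
    totals_path = outdir / "totals.tsv"
    tables.totals.rename_axis("sample_id").reset_index().to_csv(
        totals_path, sep="\t", index=False
    )
    metadata_path = outdir / "metadata.tsv"
    meta = pd.DataFrame({
        "sample_id": tables.bmi.index,
        "bmi": np.round(tables.bmi.values, 2),
        "group": np.where(tables.bmi.values >= 30, "obese", "lean"),
    })
    meta.to_csv(metadata_path, sep="\t", index=False)

    tax_path = outdir / "tax_profile.tsv"
    with open(tax_path, "w") as fh:
        fh.write("clade_name\t" + "\t".join(tables.tax.index) + "\n")
        fh.write("k__Bacteria\t" + "\t".join(["100.0"] * len(tables.tax.index)) + "\n")
        for ph in tables.tax.columns:
            vals = "\t".join(f"{v:.6f}" for v in tables.tax[ph].values)
            fh.write(f"k__Bacteria|p__{ph}\t{vals}\n")

    counts_path = outdir / "intended_counts.tsv"
    tables.counts.to_csv(counts_path, sep="\t")

    truth_path = outdir / "ground_truth.json"
    truth = {
        "seed": spec.seed,
        "planted_effects": tables.spec.resolved_planted(),
        "phylum_effects": tables.spec.resolved_phylum_effects(),
        "designated_cluster": tables.designated_cluster,
        "n_samples": spec.n_samples,
        "n_clusters": spec.n_clusters,
        "sparsity": spec.sparsity,
        "gene_flags": tables.gene_flags_truth,
    }
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))

    return {
        "fasta": fasta_path, "mapping": mapping_path, "annotations": annotations_path,
        "pfam_biosynthesis": pfam_bio, "pfam_nonbiosynthesis": pfam_nonbio,
        "domtblout": dom_path, "hits_dir": outdir / "hits",
        "reads_dir": (outdir / "reads") if spec.write_fastq else None,
        "totals": totals_path, "metadata": metadata_path, "tax_profile": tax_path,
        "intended_counts": counts_path, "ground_truth": truth_path,
    }


def _blast_line(read_id: str, protein_id: str, bit: float, evalue: float) -> str:
    return (
        f"{read_id}\t{protein_id}\t96.2\t23\t1\t0\t1\t70\t1\t23\t"
        f"{evalue:.2e}\t{bit:.1f}\n"
    )


def _fastq_record(read_id: str, read_len: int) -> str:
    seq = ("ACGT" * (read_len // 4 + 1))[:read_len]
    return f"@{read_id}\n{seq}\n+\n{'I' * read_len}\n"


def recover_matrix(paths: dict[str, Path], keep_bp: int = 70,
                   scratch: Path | None = None) -> "qt.RawCountMatrix":
    """Run QC -> parse -> assign -> count over a generated bundle and return
    the recovered RawCountMatrix (all catalog clusters, sorted samples)."""
    catalog = cat.load_catalog(paths["fasta"], paths["mapping"])
    lists = cat.load_pfam_lists(paths["pfam_biosynthesis"], paths["pfam_nonbiosynthesis"])
    domain_hits = hp.parse_domtblout(paths["domtblout"])
    flags = cat.classify_catalog_genes(domain_hits, catalog, lists)
    totals = qt.load_totals(paths["totals"])

    assignments: list[hp.ReadAssignment] = []
    for hit_file in sorted(Path(paths["hits_dir"]).glob("*.tsv")):
        sample_id = hit_file.stem
        if paths.get("reads_dir"):
            fastq = Path(paths["reads_dir"]) / f"{sample_id}.fastq"
            if fastq.exists():
                if scratch is None:
                    scratch = Path(tempfile.mkdtemp(prefix="bgcquant-qc-"))
                scratch.mkdir(parents=True, exist_ok=True)
                hp.qc_trim_reads(fastq, scratch / f"{sample_id}.qc.fastq", keep_bp=keep_bp)
        hits = hp.parse_blast_tab(hit_file)
        assignments.extend(hp.assign_reads(hits, catalog, flags, sample_id))
    return qt.count_bgc_reads(assignments, totals, catalog, flags)


def recover_counts(paths: dict[str, Path], keep_bp: int = 70,
                   scratch: Path | None = None) -> pd.DataFrame:
    """Count-matrix convenience wrapper around :func:`recover_matrix`."""
    return recover_matrix(paths, keep_bp=keep_bp, scratch=scratch).counts


def roundtrip_check(
    spec: SyntheticCohortSpec, workdir: str | Path | None = None
) -> tuple[bool, pd.DataFrame]:
    """Generate a bundle, push it through the pipeline's counting stages and
    compare with the intended matrix.  Returns (ok, diff) where diff lists
    the mismatched cells (sample, cluster, expected, observed)."""
    if workdir is None:
        workdir = Path(tempfile.mkdtemp(prefix="bgcquant-roundtrip-"))
    workdir = Path(workdir)
    paths = generate_cohort(spec, workdir)
    intended = pd.read_csv(paths["intended_counts"], sep="\t", index_col=0)
    intended.index = intended.index.astype(str)
    intended.columns = intended.columns.astype(str)
    recovered = recover_counts(paths, scratch=workdir / "scratch_qc")
    recovered = recovered.reindex(index=intended.index, columns=intended.columns)
    mismatch = recovered != intended
    diff_cells = []
    for s, c in zip(*np.where(mismatch.values)):
        diff_cells.append((
            intended.index[s], intended.columns[c],
            int(intended.iat[s, c]), int(recovered.iat[s, c]),
        ))
    diff = pd.DataFrame(diff_cells, columns=["sample_id", "cluster_id", "expected", "observed"])
    return diff.empty, diff


def bundle_digest(outdir: str | Path) -> str:
    """SHA-256 over every file in a bundle (sorted relative paths), for
    seed-determinism checks."""
    outdir = Path(outdir)
    h = hashlib.sha256()
    for path in sorted(p for p in outdir.rglob("*") if p.is_file()):
        h.update(str(path.relative_to(outdir)).encode())
        h.update(path.read_bytes())
    return h.hexdigest()
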