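"""Shared fixtures: tiny on-disk catalogs and a small synthetic cohort."""

from __future__ import annotations

from pathlib import Path

import pytest

from bgcquant.simulate import SyntheticCohortSpec, generate_cohort


def write_catalog_files(
    tmp_path: Path,
    rows: list[tuple[str, str, str, str]],
    fasta_ids: list[str] | None = None,
    seq: str = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
) -> tuple[Path, Path]:
    """Write a FASTA + mapping TSV for the given (protein, gene, cluster,
    genome) rows; FASTA record ids default to the mapping's protein ids."""
    if fasta_ids is None:
        fasta_ids = [r[0] for r in rows]
    fasta = tmp_path / "catalog.faa"
    fasta.write_text("".join(f">{pid}\n{seq}\n" for pid in fasta_ids))
    mapping = tmp_path / "mapping.tsv"
    lines = ["protein_id\tgene_id\tcluster_id\tgenome_id"]
    lines += ["\t".join(r) for r in rows]
    mapping.write_text("\n".join(lines) + "\n")
    return fasta, mapping


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> tuple[SyntheticCohortSpec, dict[str, Path]]:
    """A 30-sample, 12-cluster cohort with two clusters planted at rho 0.6."""
    spec = SyntheticCohortSpec(
        n_samples=30,
        n_clusters=12,
        n_planted=2,
        planted_rho=0.6,
        mean_count_range=(15.0, 40.0),
        total_reads_range=(40_000, 60_000),
        sparsity=0.15,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("bundle")
    paths = generate_cohort(spec, outdir)
    return spec, paths
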