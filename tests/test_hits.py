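"""Read QC, alignment parsing, top-hit selection and assignment."""

from __future__ import annotations

import random

import pytest

from bgcquant.catalog import PfamDomainLists, classify_catalog_genes, load_catalog
from bgcquant.errors import InputError, ParseError
from bgcquant.hits import (
    AlignmentHit,
    AssignmentReport,
    ParseReport,
    assign_reads,
    parse_blast_tab,
    parse_domtblout,
    qc_trim_reads,
    select_top_hit,
    write_assignments,
)

from conftest import write_catalog_files


def fastq_record(name: str, length: int) -> str:
    return f"@{name}\n{'A' * length}\n+\n{'I' * length}\n"


def blast_line(read: str, protein: str, evalue: str = "1e-10", bits: str = "80.0") -> str:
    return f"{read}\t{protein}\t95.0\t23\t1\t0\t1\t70\t1\t23\t{evalue}\t{bits}\n"


class TestQcTrim:
    @pytest.mark.parametrize(
        "lengths, kept, dropped",
        [
            ([100], 1, 0),
            ([69], 0, 1),
            ([70, 71, 10], 2, 1),
        ],
    )
    def test_keep_and_drop_counts(self, tmp_path, lengths, kept, dropped):
        src = tmp_path / "in.fastq"
        src.write_text("".join(fastq_record(f"r{i}", n) for i, n in enumerate(lengths)))
        out = tmp_path / "out.fastq"
        summary = qc_trim_reads(src, out, keep_bp=70)
        assert (summary.reads_kept, summary.reads_dropped) == (kept, dropped)
        assert summary.reads_total == len(lengths)
        emitted = [l for l in out.read_text().splitlines()[1::4]]
        assert all(len(seq) == 70 for seq in emitted)
        assert len(emitted) == kept

    def test_modal_length_and_sample_level_check(self, tmp_path):
        src = tmp_path / "in.fastq"
        src.write_text("".join(fastq_record(f"r{i}", n) for i, n in enumerate([50, 50, 50, 90])))
        summary = qc_trim_reads(src, tmp_path / "out.fastq", keep_bp=70)
        assert summary.modal_read_length == 50
        assert not summary.sample_passes(70)
        assert summary.sample_passes(50)

    def test_malformed_record_reports_index(self, tmp_path):
        src = tmp_path / "bad.fastq"
        src.write_text(fastq_record("ok", 80) + "not-a-header\nACGT\n+\nIIII\n")
        with pytest.raises(ParseError, match="#2"):
            qc_trim_reads(src, tmp_path / "out.fastq")

    def test_quality_length_mismatch_rejected(self, tmp_path):
        src = tmp_path / "bad.fastq"
        src.write_text("@r\nACGT\n+\nIII\n")
        with pytest.raises(ParseError, match="mismatch"):
            qc_trim_reads(src, tmp_path / "out.fastq")


class TestParseBlastTab:
    def test_threshold_filtering(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(blast_line("r1", "p1", "1e-10") + blast_line("r2", "p1", "1e-3"))
        report = ParseReport()
        hits = list(parse_blast_tab(path, e_threshold=1e-5, report=report))
        assert [h.read_id for h in hits] == ["r1"]
        assert report.hits_filtered == 1

    def test_malformed_lines_counted_not_skipped_silently(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            blast_line("r1", "p1")
            + "garbage line\n"
            + blast_line("r2", "p1")
            + blast_line("r3", "p1")
        )
        report = ParseReport()
        hits = list(parse_blast_tab(path, report=report))
        assert len(hits) == 3
        assert report.malformed_lines == 1

    def test_non_numeric_evalue_is_hard_error_with_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(blast_line("r1", "p1") + blast_line("r2", "p1", evalue="oops"))
        with pytest.raises(ParseError, match="line 2"):
            list(parse_blast_tab(path))

    def test_gzip_input(self, tmp_path):
        import gzip

        path = tmp_path / "hits.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(blast_line("r1", "p1"))
        assert len(list(parse_blast_tab(path))) == 1


class TestSelectTopHit:
    def make(self, protein, bits, evalue=1e-10, read="r1"):
        return AlignmentHit(read, protein, 90.0, evalue, bits)

    def test_single_hit_identity(self):
        h = self.make("pA", 50.0)
        assert select_top_hit([h]) is h

    def test_strict_maximum_bit_score(self):
        hits = [self.make("pA", 50.0), self.make("pB", 60.0)]
        assert select_top_hit(hits).protein_id == "pB"

    def test_tie_break_by_evalue_then_protein_id(self):
        hits = [self.make("pB", 60.0), self.make("pA", 60.0)]
        assert select_top_hit(hits).protein_id == "pA"
        hits = [self.make("pB", 60.0, 1e-20), self.make("pA", 60.0, 1e-10)]
        assert select_top_hit(hits).protein_id == "pB"

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            select_top_hit([])

    def test_mixed_reads_rejected(self):
        with pytest.raises(ValueError):
            select_top_hit([self.make("pA", 10, read="r1"), self.make("pB", 10, read="r2")])

    def test_agrees_with_exhaustive_argmax_oracle(self):
        rng = random.Random(42)
        for _ in range(200):
            hits = [
                self.make(
                    f"p{rng.randrange(8)}",
                    bits=rng.choice([40.0, 50.0, 60.0]),
                    evalue=rng.choice([1e-20, 1e-10, 1e-6]),
                )
                for _ in range(rng.randint(1, 20))
            ]
            best_bits = max(h.bit_score for h in hits)
            pool = [h for h in hits if h.bit_score == best_bits]
            best_e = min(h.e_value for h in pool)
            pool = [h for h in pool if h.e_value == best_e]
            expected = min(pool, key=lambda h: h.protein_id)
            assert select_top_hit(hits) == expected


class TestParseDomtblout:
    HEADER = "# comment line\n"

    def row(self, target_acc, query, i_evalue, nfields_ok=True):
        fields = [
            "Domain", target_acc, "200", query, "-", "60", "1e-30", "150.0", "0.1",
            "1", "1", "1e-29", str(i_evalue), "149.0", "0.1", "1", "190", "2",
            "58", "1", "60", "0.95", "desc",
        ]
        return " ".join(fields) + "\n"

    def test_single_row(self, tmp_path):
        path = tmp_path / "dom.txt"
        path.write_text(self.HEADER + self.row("PF00501.28", "gene1", "2e-30"))
        assert parse_domtblout(path) == {"gene1": {("PF00501", 2e-30)}}

    def test_comment_only_file_empty_mapping(self, tmp_path):
        path = tmp_path / "dom.txt"
        path.write_text(self.HEADER * 3)
        assert parse_domtblout(path) == {}

    def test_dedup_keeps_best_evalue_per_domain(self, tmp_path):
        path = tmp_path / "dom.txt"
        path.write_text(
            self.row("PF00501.28", "gene1", "2e-30")
            + self.row("PF00501.28", "gene1", "5e-10")
            + self.row("PF00668.20", "gene1", "1e-8")
        )
        result = parse_domtblout(path)
        assert result == {"gene1": {("PF00501", 2e-30), ("PF00668", 1e-8)}}

    def test_truncated_line_is_hard_error(self, tmp_path):
        path = tmp_path / "dom.txt"
        path.write_text("Domain PF00501.28 200 gene1\n")
        with pytest.raises(ParseError, match="line 1"):
            parse_domtblout(path)


@pytest.fixture()
def tiny_catalog(tmp_path):
    rows = [
        ("bioA", "bioA", "c1", "g1"),
        ("bioB", "bioB", "c1", "g1"),
        ("nonbioC", "nonbioC", "c1", "g1"),
        ("bioD", "bioD", "c2", "g2"),
    ]
    fasta, mapping = write_catalog_files(tmp_path, rows)
    catalog = load_catalog(fasta, mapping)
    lists = PfamDomainLists.from_iterables(["PF00501"], ["PF00005"])
    domain_hits = {
        "bioA": {("PF00501", 1e-20)},
        "bioB": {("PF00501", 1e-12)},
        "nonbioC": {("PF00005", 1e-15)},
        "bioD": {("PF00501", 1e-9)},
    }
    flags = classify_catalog_genes(domain_hits, catalog, lists)
    return catalog, flags


class TestAssignReads:
    def test_biosynthesis_read_assigned(self, tiny_catalog):
        catalog, flags = tiny_catalog
        hits = [AlignmentHit("r1", "bioA", 95.0, 1e-10, 80.0)]
        [a] = assign_reads(hits, catalog, flags, "s1")
        assert a.biosynthesis and a.cluster_id == "c1" and a.sample_id == "s1"

    def test_top_hit_wins_no_reassignment(self, tiny_catalog):
        # top hit is a nonbiosynthesis gene; the biosynthesis runner-up must
        # not steal the read
        catalog, flags = tiny_catalog
        hits = [
            AlignmentHit("r1", "nonbioC", 95.0, 1e-10, 90.0),
            AlignmentHit("r1", "bioA", 95.0, 1e-10, 70.0),
        ]
        [a] = assign_reads(hits, catalog, flags, "s1")
        assert a.protein_id == "nonbioC" and not a.biosynthesis

    def test_count_preservation_many_reads_one_protein(self, tiny_catalog):
        catalog, flags = tiny_catalog
        hits = [AlignmentHit(f"r{i}", "bioD", 95.0, 1e-10, 80.0) for i in range(10)]
        assignments = assign_reads(hits, catalog, flags, "s1")
        assert len(assignments) == 10
        assert {a.gene_id for a in assignments} == {"bioD"}

    def test_one_assignment_per_surviving_read(self, tiny_catalog):
        catalog, flags = tiny_catalog
        hits = [
            AlignmentHit("r1", "bioA", 95.0, 1e-10, 80.0),
            AlignmentHit("r1", "bioB", 95.0, 1e-10, 60.0),
            AlignmentHit("r2", "bioD", 95.0, 1e-10, 80.0),
        ]
        assignments = assign_reads(hits, catalog, flags, "s1")
        assert len(assignments) == len({h.read_id for h in hits})

    def test_unknown_protein_dropped_with_count_or_error(self, tiny_catalog):
        catalog, flags = tiny_catalog
        hits = [AlignmentHit("r1", "ghost", 95.0, 1e-10, 80.0)]
        report = AssignmentReport()
        assert assign_reads(hits, catalog, flags, "s1", report=report) == []
        assert report.unknown_protein_reads == 1
        with pytest.raises(InputError, match="ghost"):
            assign_reads(hits, catalog, flags, "s1", on_unknown_protein="error")

    def test_assignment_table_independent_of_input_order(self, tiny_catalog, tmp_path):
        catalog, flags = tiny_catalog
        rng = random.Random(3)
        hits = [
            AlignmentHit(f"r{i}", p, 95.0, e, b)
            for i in range(20)
            for p, e, b in [("bioA", 1e-10, 80.0), ("bioB", 1e-12, 80.0)]
        ]
        shuffled = hits[:]
        rng.shuffle(shuffled)
        out1, out2 = tmp_path / "a1.tsv", tmp_path / "a2.tsv"
        write_assignments(assign_reads(hits, catalog, flags, "s1"), out1)
        write_assignments(assign_reads(shuffled, catalog, flags, "s1"), out2)
        assert out1.read_bytes() == out2.read_bytes()
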