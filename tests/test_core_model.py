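import tempfile
from pathlib import Path

import pytest
from hypothesis import given, settings, strategies as st

from utiliseq import core_model as cm


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def test_read_fasta_minimal(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">c1\nACGT\n")
    recs = cm.read_fasta(p)
    assert len(recs) == 1 and recs[0].contig_id == "c1" and len(recs[0]) == 4


def test_read_fasta_uppercases_and_keeps_order(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">c1\nacgt\n>c2\nNNNN\n")
    recs = cm.read_fasta(p)
    assert [r.contig_id for r in recs] == ["c1", "c2"]
    assert recs[0].sequence == "ACGT"
    assert recs[1].sequence == "NNNN"


def test_read_fasta_maps_u_to_t(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">c1\nACGU\n")
    assert cm.read_fasta(p)[0].sequence == "ACGT"


def test_read_fasta_duplicate_id_is_error(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">c1\nACGT\n>c1\nACGT\n")
    with pytest.raises(cm.PipelineError, match="duplicate"):
        cm.read_fasta(p)


def test_read_fasta_illegal_character_names_offender(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">c1\nACXT\n")
    with pytest.raises(cm.PipelineError, match="X"):
        cm.read_fasta(p)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.text(alphabet="ACGTN", min_size=1, max_size=80),
                min_size=1, max_size=5))
def test_fasta_round_trip_property(seqs):
    recs = [cm.GenomeSequence(f"c{i}", s) for i, s in enumerate(seqs)]
    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "rt.fa"
        cm.write_fasta(recs, path)
        assert cm.read_fasta(path) == recs


def test_fasta_round_trip(tmp_path):
    recs = [cm.GenomeSequence("c1", "ACGTN" * 20),
            cm.GenomeSequence("c2", "GATTACA" * 30)]
    p = tmp_path / "rt.fa"
    cm.write_fasta(recs, p)
    assert cm.read_fasta(p) == recs


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("start,end", [(1, 1), (10, 309), (7, 7), (100, 250)])
def test_slice_conversion_round_trips(start, end):
    assert cm.from_slice(*cm.to_slice(start, end)) == (start, end)
    lo, hi = cm.to_slice(start, end)
    assert hi - lo == end - start + 1  # slice length equals interval length


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def test_read_gff3_maps_fields(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("c1\tpredA\tgene\t10\t309\t.\t+\t.\tID=g1\n")
    (g,) = cm.read_gff3(p)
    assert (g.gene_id, g.contig_id, g.start, g.end, g.strand) == \
        ("g1", "c1", 10, 309, "+")
    assert g.predictors == frozenset({"predA"})


def test_read_gff3_minus_strand_preserved(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("c1\tB\tgene\t5\t304\t.\t-\t.\tID=g2\n")
    assert cm.read_gff3(p)[0].strand == "-"


def test_read_gff3_sub_minimum_gene_parses(tmp_path):
    # 59 aa = 177 nt: the reader keeps it; filtering happens downstream
    p = tmp_path / "g.gff3"
    p.write_text("c1\tA\tgene\t1\t177\t.\t+\t.\tID=tiny\n")
    (g,) = cm.read_gff3(p)
    assert g.length == 177 and g.length < cm.PipelineConfig().min_gene_nt


def test_read_gff3_rejects_bad_coordinates_and_strand(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("c1\tA\tgene\t20\t10\t.\t+\t.\tID=g1\n")
    with pytest.raises(cm.PipelineError, match="start > end"):
        cm.read_gff3(p)
    p.write_text("c1\tA\tgene\t10\t20\t.\t.\t.\tID=g1\n")
    with pytest.raises(cm.PipelineError, match="strand"):
        cm.read_gff3(p)


def test_gff3_round_trip(tmp_path):
    genes = [
        cm.GeneModel("g1", "c1", 10, 309, "+", frozenset({"A", "B"}),
                     ("SP1", 1e-30), "conserved"),
        cm.GeneModel("g2", "c1", 700, 1000, "-", frozenset({"B"})),
    ]
    p = tmp_path / "rt.gff3"
    cm.write_gff3(genes, p)
    back = cm.read_gff3(p)
    assert [g.coords for g in back] == [g.coords for g in genes]
    assert back[0].best_homolog == ("SP1", 1e-30)
    assert back[0].accuracy_class == "conserved"
    assert back[0].predictors == frozenset({"A", "B"})


# ---------------------------------------------------------------------------
# similarity hits
# ---------------------------------------------------------------------------

def _hit_line(q, s, length, evalue):
    return f"{q}\t{s}\t90.0\t{length}\t5\t0\t1\t{length}\t1\t{length}\t{evalue}\t200"


def test_read_hits_aggregates_hsps(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(_hit_line("q1", "s1", 100, "1e-30") + "\n"
                 + _hit_line("q1", "s1", 50, "1e-10") + "\n")
    (h,) = cm.read_hits(p)
    assert h.hsp_total_length == 150
    assert h.evalue == 1e-30


def test_read_hits_drops_self_hits(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(_hit_line("q1", "q1", 100, "0.0") + "\n")
    assert cm.read_hits(p) == []


def test_read_hits_empty_file(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text("")
    assert cm.read_hits(p) == []


def test_read_hits_negative_evalue_is_error(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(_hit_line("q1", "s1", 100, "-1e-5") + "\n")
    with pytest.raises(cm.PipelineError, match="negative"):
        cm.read_hits(p)


def test_read_hits_attaches_lengths(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(_hit_line("q1", "s1", 80, "1e-30") + "\n")
    (h,) = cm.read_hits(p, {"q1": 100, "s1": 120})
    assert (h.query_length, h.subject_length) == (100, 120)
    assert h.coverage() == pytest.approx(0.8)


# ---------------------------------------------------------------------------
# BED and pathways
# ---------------------------------------------------------------------------

def test_bed_round_trip_converts_coordinates(tmp_path):
    p = tmp_path / "r.bed"
    p.write_text("c1\t99\t200\n")  # 0-based half-open
    assert cm.read_bed(p) == [("c1", 100, 200)]  # 1-based inclusive
    cm.write_bed([("c1", 100, 200)], p)
    assert p.read_text() == "c1\t99\t200\n"


def test_read_bed_malformed_is_error(tmp_path):
    p = tmp_path / "r.bed"
    p.write_text("c1\t99\n")
    with pytest.raises(cm.PipelineError):
        cm.read_bed(p)


def test_pathways_round_trip(tmp_path):
    pw = {"pw1": {"g1", "g2"}, "pw2": {"g3"}}
    p = tmp_path / "p.tsv"
    cm.write_pathways(pw, p)
    assert cm.read_pathways(p) == pw
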