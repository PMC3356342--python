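import numpy as np
import pytest

from _oracles import exhaustive_map
from utiliseq import synthetic_data as synth, tag_mapper as tm
from utiliseq.core_model import (
    GeneModel,
    GenomeSequence,
    PipelineError,
    revcomp,
)


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return [GenomeSequence("c1", seq)]


@pytest.fixture(scope="module")
def toy_index(toy_genome):
    return tm.build_index(toy_genome)


# ---------------------------------------------------------------------------
# index
# ---------------------------------------------------------------------------

def test_index_unique_25mer_single_position(toy_genome, toy_index):
    seq = toy_genome[0].sequence
    kmer = seq[1000:1025]
    occ = toy_index.occurrences(kmer)
    assert ("c1", 1001, "+") in occ


def test_index_reports_both_strands():
    # palindromic 26-mer region: its 25-mers occur on both strands somewhere
    core = "ACGTACGTACGTA"
    pal = core + revcomp(core)  # reverse-complement palindrome, 26 bp
    genome = [GenomeSequence("c1", "TT" + pal + "GG" + "C" * 30)]
    index = tm.build_index(genome)
    kmer = pal[:25]
    occ = index.occurrences(kmer)
    strands = {s for _, _, s in occ}
    assert strands == {"+", "-"}


def test_index_matches_naive_scan(toy_genome, toy_index):
    seq = toy_genome[0].sequence
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = int(rng.integers(0, len(seq) - 25))
        kmer = seq[p:p + 25]
        naive = [("c1", i + 1, "+") for i in range(len(seq) - 24)
                 if seq[i:i + 25] == kmer]
        rc = revcomp(kmer)
        naive += [("c1", i + 1, "-") for i in range(len(seq) - 24)
                  if seq[i:i + 25] == rc]
        assert sorted(toy_index.occurrences(kmer)) == sorted(naive)


def test_short_contig_skipped_with_warning(caplog):
    import logging
    with caplog.at_level(logging.WARNING):
        index = tm.build_index([GenomeSequence("stub", "ACGT")])
    assert index.contig_ids == []
    assert "shorter than k" in caplog.text


# ---------------------------------------------------------------------------
# map_tag
# ---------------------------------------------------------------------------

def test_error_free_read_maps_exactly(toy_genome, toy_index, config):
    seq = toy_genome[0].sequence
    read = seq[2000:2050]
    res = tm.map_tag("r", read, toy_index, config)
    assert isinstance(res, tm.Alignment)
    assert (res.start, res.strand, res.mismatches_5prime) == (2001, "+", 0)
    assert res.three_prime_match


def test_minus_strand_read_maps_to_plus_coordinates(toy_genome, toy_index, config):
    seq = toy_genome[0].sequence
    read = revcomp(seq[3000:3050])
    res = tm.map_tag("r", read, toy_index, config)
    assert isinstance(res, tm.Alignment)
    assert (res.start, res.strand) == (3001, "-")


def test_two_mismatches_in_5prime_half_accepted(toy_genome, toy_index, config):
    seq = toy_genome[0].sequence
    read = list(seq[4000:4050])
    for pos in (3, 17):
        read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
    res = tm.map_tag("r", "".join(read), toy_index, config)
    assert isinstance(res, tm.Alignment) and res.mismatches_5prime == 2


def test_three_mismatches_in_5prime_half_unmapped(toy_genome, toy_index, config):
    seq = toy_genome[0].sequence
    read = list(seq[4000:4050])
    for pos in (3, 11, 21):
        read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
    res = tm.map_tag("r", "".join(read), toy_index, config)
    assert isinstance(res, tm.Rejection) and res.reason == "unmapped"


def test_3prime_mismatches_recorded_not_required(toy_genome, toy_index, config):
    seq = toy_genome[0].sequence
    read = list(seq[5000:5050])
    read[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[40]]
    res = tm.map_tag("r", "".join(read), toy_index, config)
    assert isinstance(res, tm.Alignment)
    assert res.mismatches_5prime == 0 and not res.three_prime_match


def test_repeated_locus_is_multi_mapped(config):
    rng = np.random.default_rng(1)
    unit = "".join(rng.choice(list("ACGT"), size=60))
    filler = "".join(rng.choice(list("ACGT"), size=200))
    genome = [GenomeSequence("c1", unit + filler + unit)]
    index = tm.build_index(genome)
    res = tm.map_tag("r", unit[:50], index, config)
    assert isinstance(res, tm.Rejection) and res.reason == "multi_mapped"


def test_wrong_read_length_is_error(toy_index, config):
    with pytest.raises(PipelineError, match="length"):
        tm.map_tag("r", "ACGT", toy_index, config)


def test_map_tag_equals_exhaustive_scan(toy_genome, toy_index, config):
    seq = toy_genome[0].sequence
    rng = np.random.default_rng(31)
    for i in range(500):
        if rng.random() < 0.6:
            p = int(rng.integers(0, len(seq) - 50 + 1))
            read = seq[p:p + 50]
            if rng.random() < 0.5:
                read = revcomp(read)
            chars = list(read)
            for j in rng.choice(50, size=int(rng.integers(0, 4)), replace=False):
                chars[j] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(chars)
        else:
            read = "".join(rng.choice(list("ACGT"), size=50))
        res = tm.map_tag(f"r{i}", read, toy_index, config)
        cands = exhaustive_map(seq, read)
        if len(cands) == 1:
            ((p, s, mm),) = cands
            assert isinstance(res, tm.Alignment)
            assert (res.start, res.strand, res.mismatches_5prime) == (p + 1, s, mm)
        elif not cands:
            assert isinstance(res, tm.Rejection) and res.reason == "unmapped"
        else:
            assert isinstance(res, tm.Rejection) and res.reason == "multi_mapped"


def test_mapping_recovers_simulated_origins(small_truth, config):
    index = tm.build_index(small_truth.genome)
    reads, table = synth.simulate_tags(small_truth, "log", seed=3,
                                       error_fraction=0.0, rrna_fraction=0.0)
    truth_by_id = {r.read_id: r for r in table.itertuples()}
    recovered = unique = 0
    for rid, seq in reads:
        if len(index.occurrences(seq[:25] if truth_by_id[rid].strand == "+"
                                 else revcomp(seq)[25:])) != 1:
            continue  # origin 5'-half not unique genome-wide
        unique += 1
        res = tm.map_tag(rid, seq, index, config)
        t = truth_by_id[rid]
        if isinstance(res, tm.Alignment) and \
                (res.contig_id, res.start, res.strand) == \
                (t.contig_id, t.start, t.strand):
            recovered += 1
    assert unique > 1000
    assert recovered / unique >= 0.999


# ---------------------------------------------------------------------------
# rRNA filtering
# ---------------------------------------------------------------------------

def _aln(start, strand="+", contig="c1"):
    return tm.Alignment("r", contig, start, strand, 0, True)


def test_filter_rrna_boundaries():
    intervals = [("c1", 100, 200)]
    inside = _aln(150)
    at_end = _aln(200)
    past = _aln(201)
    kept, n = tm.filter_rrna([inside, at_end, past], intervals)
    assert n == 2
    assert [a.start for a in kept] == [201]


def test_filter_rrna_fraction_on_simulated_sample(small_truth, config):
    index = tm.build_index(small_truth.genome)
    reads, _ = synth.simulate_tags(small_truth, "log", seed=8,
                                   error_fraction=0.0, rrna_fraction=0.02)
    alignments, _ = tm.map_reads(reads, index, config)
    kept, n_rrna = tm.filter_rrna(alignments, small_truth.rrna_intervals)
    frac = n_rrna / len(alignments)
    assert frac == pytest.approx(0.02, abs=0.003)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def test_coverage_and_counts_assignment():
    genes = [GeneModel("plus", "c1", 100, 399, "+"),
             GeneModel("minus", "c1", 700, 999, "-")]
    alns = [_aln(150, "+"),   # sense for plus gene
            _aln(150, "-"),   # antisense for plus gene
            _aln(750, "-"),   # sense for minus gene
            _aln(500, "+")]   # intergenic
    counts, depth, unassigned = tm.coverage_and_counts(
        alns, genes, {"c1": 2000})
    assert counts.loc["plus", "sense"] == 1
    assert counts.loc["plus", "antisense"] == 1
    assert counts.loc["minus", "sense"] == 1
    assert unassigned == 1
    assert counts.to_numpy().sum() + unassigned == len(alns)
    # intergenic tag still contributes depth on its strand
    assert depth["c1"]["+"][499:549].min() == 1
    assert depth["c1"]["-"][149:199].min() == 1


def test_same_strand_gene_takes_precedence():
    genes = [GeneModel("fwd", "c1", 100, 399, "+"),
             GeneModel("rev", "c1", 100, 399, "-")]
    counts, _, unassigned = tm.coverage_and_counts(
        [_aln(200, "+")], genes, {"c1": 1000})
    assert counts.loc["fwd", "sense"] == 1
    assert counts.loc["rev", "antisense"] == 0
    assert unassigned == 0
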