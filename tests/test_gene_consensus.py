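import numpy as np
import pytest

from utiliseq import gene_consensus as gc
from utiliseq import synthetic_data as synth
from utiliseq.core_model import (
    GeneModel,
    PipelineConfig,
    SimilarityHit,
    genome_dict,
)


def _gene(gid, start, end, strand="+", predictors=("A",), contig="c1"):
    return GeneModel(gid, contig, start, end, strand,
                     predictors=frozenset(predictors))


@pytest.fixture()
def flat_genome():
    return {"c1": "ACGT" * 2500}  # 10 kb, no Ns


# ---------------------------------------------------------------------------
# candidate filtering
# ---------------------------------------------------------------------------

def test_filter_length_boundary(flat_genome, config):
    keep = _gene("ok", 1, 180)      # 60 aa
    drop = _gene("tiny", 1, 177)    # 59 aa
    out = gc.filter_candidates([keep, drop], flat_genome, config)
    assert [g.gene_id for g in out] == ["ok"]


def test_filter_n_run_boundary(config):
    genome = {"c1": "A" * 100 + "N" * 9 + "A" * 191,
              "c2": "A" * 100 + "N" * 10 + "A" * 190}
    nine = _gene("nine", 50, 250, contig="c1")
    ten = GeneModel("ten", "c2", 50, 250, "+")
    out = gc.filter_candidates([nine, ten], genome, config)
    assert [g.gene_id for g in out] == ["nine"]


def test_filter_gene_outside_contig_is_error(flat_genome, config):
    with pytest.raises(Exception, match="outside"):
        gc.filter_candidates([_gene("g", 9900, 10_200)], flat_genome, config)


# ---------------------------------------------------------------------------
# accuracy classification
# ---------------------------------------------------------------------------

def _hits(gid, evalue):
    return {gid: [SimilarityHit(gid, "SPX", evalue, 100, 100, 100)]}


def test_classify_conserved(config):
    g = _gene("g", 1, 300, predictors=("A", "B"))
    assert gc.classify_accuracy(g, _hits("g", 1e-12), config) == "conserved"
    assert g.best_homolog == ("SPX", 1e-12)


def test_classify_slightly_conserved_band(config):
    g = _gene("g", 1, 300, predictors=("A", "B"))
    assert gc.classify_accuracy(g, _hits("g", 1e-7), config) == "slightly_conserved"


def test_classify_no_hit_depends_on_predictor_agreement(config):
    both = _gene("g", 1, 300, predictors=("A", "B"))
    single = _gene("h", 1, 300, predictors=("A",))
    assert gc.classify_accuracy(both, {}, config) == "hypothetical"
    assert gc.classify_accuracy(single, {}, config) == "predicted"


def test_classify_hit_above_nonortholog_cut_does_not_count(config):
    g = _gene("g", 1, 300, predictors=("A",))
    assert gc.classify_accuracy(g, _hits("g", 1e-4), config) == "predicted"
    assert g.best_homolog is None


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def test_merge_identical_models_become_common(config):
    a = [_gene("g1", 100, 399, predictors=("A",))]
    b = [_gene("g1", 100, 399, predictors=("B",))]
    res = gc.merge_predictions(a, b, config)
    assert len(res.common) == 1 and not res.only_a and not res.only_b
    assert res.common[0].predictors == frozenset({"A", "B"})


def test_merge_nonoverlapping_single_predictor_kept_as_predicted(config):
    res = gc.merge_predictions([_gene("g1", 100, 399)], [], config)
    assert [g.gene_id for g in res.only_a] == ["g1"]
    assert res.only_a[0].accuracy_class == "predicted"


def test_merge_overlap_resolved_by_accuracy_class(config):
    a = [_gene("ga", 100, 399, predictors=("A",))]
    b = [_gene("gb", 250, 549, predictors=("B",))]
    hits = [SimilarityHit("gb", "SPX", 1e-30, 100, 100, 100)]
    res = gc.merge_predictions(a, b, config, hits)
    assert [g.gene_id for g in res.only_b] == ["gb"]  # conserved beats predicted
    assert [g.gene_id for g in res.dropped_overlaps] == ["ga"]


def test_merge_overlap_tie_prefers_longer_then_a(config):
    a = [_gene("ga", 100, 399, predictors=("A",))]
    b = [_gene("gb", 200, 599, predictors=("B",))]
    res = gc.merge_predictions(a, b, config)
    assert [g.gene_id for g in res.only_b] == ["gb"]  # longer wins
    a = [_gene("ga", 100, 399, predictors=("A",))]
    b = [_gene("gb", 200, 499, predictors=("B",))]
    res = gc.merge_predictions(a, b, config)
    assert [g.gene_id for g in res.only_a] == ["ga"]  # equal: predictor A wins


def test_merge_opposite_strand_overlap_not_resolved(config):
    a = [_gene("ga", 100, 399, "+")]
    b = [_gene("gb", 250, 549, "-")]
    res = gc.merge_predictions(a, b, config)
    assert len(res.only_a) == 1 and len(res.only_b) == 1


def test_merge_symmetric_up_to_labels(small_truth, config):
    genome = genome_dict(small_truth.genome)
    a, b, _ = synth.corrupt_predictions(small_truth, seed=13)
    fa = gc.filter_candidates(a, genome, config)
    fb = gc.filter_candidates(b, genome, config)
    r1 = gc.merge_predictions(fa, fb, config)
    a2, b2, _ = synth.corrupt_predictions(small_truth, seed=13)
    fa2 = gc.filter_candidates(a2, genome, config)
    fb2 = gc.filter_candidates(b2, genome, config)
    r2 = gc.merge_predictions(fb2, fa2, config)
    assert sorted(g.coords for g in r1.common) == sorted(g.coords for g in r2.common)


def test_merge_common_count_matches_generator_bookkeeping(small_truth, config):
    genome = genome_dict(small_truth.genome)
    a, b, book = synth.corrupt_predictions(small_truth, seed=21)
    fa = gc.filter_candidates(a, genome, config)
    fb = gc.filter_candidates(b, genome, config)
    res = gc.merge_predictions(fa, fb, config)
    assert len(res.common) == book["common_count"]


def test_no_retained_gene_violates_filters(small_run, config):
    from utiliseq.core_model import read_fasta, read_gff3
    out, _ = small_run
    genome = genome_dict(read_fasta(out / "genome.fasta"))
    merged = read_gff3(out / "genes_merged.gff3")
    assert merged
    for g in merged:
        assert g.length >= config.min_gene_nt
        assert "N" * config.max_internal_gap_nt not in \
            genome[g.contig_id][g.start - 1:g.end]


# ---------------------------------------------------------------------------
# frame-shift artifact detection
# ---------------------------------------------------------------------------

def _homolog_pair(gap):
    a = _gene("fa", 1000, 1299)
    b = _gene("fb", 1300 + gap, 1599 + gap)
    for g, ev in ((a, 1e-40), (b, 1e-38)):
        g.best_homolog = ("SP1", ev)
    return a, b


def test_interrupted_gap_boundary(config):
    a, b = _homolog_pair(gap=599)
    rep = gc.detect_frameshift_artifacts([a, b], [], config)
    assert [(x.gene_id, y.gene_id) for x, y in rep.interrupted_pairs] == [("fa", "fb")]
    a, b = _homolog_pair(gap=600)
    rep = gc.detect_frameshift_artifacts([a, b], [], config)
    assert rep.interrupted_pairs == []


def test_mutual_ortholog_hit_suppresses_interrupted_call(config):
    a, b = _homolog_pair(gap=100)
    mutual = [SimilarityHit("fa", "fb", 1e-20, 90, 100, 100)]
    rep = gc.detect_frameshift_artifacts([a, b], mutual, config)
    assert rep.interrupted_pairs == []
    weak = [SimilarityHit("fa", "fb", 1e-3, 90, 100, 100)]
    rep = gc.detect_frameshift_artifacts([a, b], weak, config)
    assert len(rep.interrupted_pairs) == 1


def test_overlapping_pair_detected(config):
    a = _gene("fa", 1000, 1299)
    b = _gene("fb", 1200, 1499)
    a.best_homolog = ("SP1", 1e-40)
    b.best_homolog = ("SP1", 1e-38)
    rep = gc.detect_frameshift_artifacts([a, b], [], config)
    assert len(rep.overlapping_pairs) == 1 and not rep.interrupted_pairs


def test_frameshift_recall_on_planted_splits(config):
    truth = synth.make_genome(1, 60_000, 100, seed=17, frameshift_rate=0.1,
                              homolog_fraction=1.0)
    genome = genome_dict(truth.genome)
    a, b, _ = synth.corrupt_predictions(truth, seed=17)
    hits = synth.simulate_hits(truth, list({m.gene_id: m for m in a + b}.values()),
                               seed=17)
    fa = gc.filter_candidates(a, genome, config)
    fb = gc.filter_candidates(b, genome, config)
    res = gc.merge_predictions(fa, fb, config, hits)
    rep = gc.detect_frameshift_artifacts(res.merged, hits, config)
    found = {g.gene_id.split(".")[0]
             for pair in rep.interrupted_pairs for g in pair}
    recall = len(found & truth.frameshift_genes) / len(truth.frameshift_genes)
    assert recall >= 0.95


def test_artifact_rate_percent():
    assert gc.artifact_rate_percent(296, 4706) == 6.3
    assert gc.artifact_rate_percent(52, 4706) == 1.1


# ---------------------------------------------------------------------------
# codon usage
# ---------------------------------------------------------------------------

def test_codon_usage_single_orf():
    genome = {"c1": "ATGTTTTAA"}
    usage = gc.codon_usage([_gene("g", 1, 9)], genome)
    assert usage.loc["ATG", "count"] == 1
    assert usage.loc["TTT", "count"] == 1
    assert usage.loc["TAA", "count"] == 1
    assert usage["count"].sum() == 3


def test_codon_usage_per_aa_frequencies_sum_to_one(small_truth):
    genome = genome_dict(small_truth.genome)
    genes = [g for g in small_truth.true_genes if g.length % 3 == 0]
    usage = gc.codon_usage(genes, genome)
    sums = usage.groupby("amino_acid")["rel_freq"].sum()
    for aa, s in sums.items():
        assert s == pytest.approx(1.0, abs=1e-12)


def test_codon_usage_skips_out_of_frame_gene_with_warning():
    genome = {"c1": "ATGTTTTAAA"}
    with pytest.warns(UserWarning, match="multiple of 3"):
        usage = gc.codon_usage([_gene("g", 1, 10)], genome)
    assert usage["count"].sum() == 0


def test_codon_usage_recovers_generator_bias():
    truth = synth.make_genome(2, 300_000, 1200, seed=23, frameshift_rate=0.0)
    genome = genome_dict(truth.genome)
    usage = gc.codon_usage(truth.true_genes, genome)
    probs = truth.codon_probs
    aa_of = usage["amino_acid"]
    # expected per-aa conditional frequency from the generator weights
    for codon, p in probs.items():
        aa = aa_of[codon]
        if aa in ("*", "M", "W"):
            continue  # start/stop codons are forced, single-codon aa trivial
        syn = [c for c in probs if aa_of[c] == aa]
        expected = p / sum(probs[c] for c in syn)
        assert usage.loc[codon, "rel_freq"] == pytest.approx(expected, abs=0.02)


def test_codon_bias_direction_tt_ending(small_truth):
    # A/T-ending codons are preferred by the generator: TTT over TTC (Phe),
    # TAT over TAC (Tyr) — the tabulator must see that direction.
    genome = genome_dict(small_truth.genome)
    genes = [g for g in small_truth.true_genes if g.length % 3 == 0]
    usage = gc.codon_usage(genes, genome)
    assert usage.loc["TTT", "rel_freq"] > usage.loc["TTC", "rel_freq"]
    assert usage.loc["TAT", "rel_freq"] > usage.loc["TAC", "rel_freq"]
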