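import pytest

from circsponge import detect
from circsponge.io import FormatError, SampleMeta, reverse_complement


def _bsj_read(genome, model, run, k, read_length=60):
    """Back-splice read over exon run (first, last), k donor-side bases."""
    first_exon = model.exons[run[0]]
    last_exon = model.exons[run[1]]
    seq = genome[model.chrom]
    if model.strand == "+":
        return seq[last_exon[1] - k:last_exon[1]] + seq[first_exon[0]:first_exon[0] + read_length - k]
    return (
        reverse_complement(seq[first_exon[0]:first_exon[0] + k])
        + reverse_complement(seq[last_exon[1] - (read_length - k):last_exon[1]])
    )


class TestSplitAlign:
    def test_recovers_multi_exon_junction(self, toy_gene):
        genome, model = toy_gene["genome"], toy_gene["model"]
        reads = {"s1": [("r1", _bsj_read(genome, model, (1, 3), 20))]}
        junctions = detect.split_align_backsplice(reads, genome, [model])
        by_key = {j.key: j for j in junctions}
        assert ("chrT", 600, 1700, "+") in by_key
        assert by_key[("chrT", 600, 1700, "+")].counts == {"s1": 1}
        # off-by-a-few shifted splits may also satisfy the raw definition, but
        # only the boundary-exact junction survives exonic annotation
        calls = detect.annotate_exonic(junctions, [model])
        assert [c.junction.key for c in calls] == [("chrT", 600, 1700, "+")]

    def test_minus_strand_junction(self, toy_gene_minus):
        genome, model = toy_gene_minus["genome"], toy_gene_minus["model"]
        reads = {"s1": [("r1", _bsj_read(genome, model, (0, 2), 25))]}
        junctions = detect.split_align_backsplice(reads, genome, [model])
        calls = detect.annotate_exonic(junctions, [model])
        assert [c.junction.key for c in calls] == [("chrT", 200, 1300, "-")]

    def test_linear_read_yields_no_junction(self, toy_gene):
        genome, model = toy_gene["genome"], toy_gene["model"]
        reads = {"s1": [("r1", genome["chrT"][1000:1060])]}
        assert detect.split_align_backsplice(reads, genome, [model]) == []

    def test_identical_reads_count_once_per_sample(self, toy_gene):
        genome, model = toy_gene["genome"], toy_gene["model"]
        r = _bsj_read(genome, model, (1, 3), 20)
        reads = {"s1": [("a", r), ("b", r)], "s2": [("c", r)]}
        junctions = detect.split_align_backsplice(reads, genome, [model])
        by_key = {j.key: j for j in junctions}
        assert by_key[("chrT", 600, 1700, "+")].counts == {"s1": 1, "s2": 1}

    def test_empty_reads_give_empty_result(self, toy_gene):
        out = detect.split_align_backsplice({}, toy_gene["genome"], [toy_gene["model"]])
        assert out == []

    def test_anchor_below_minimum_rejected(self, toy_gene):
        with pytest.raises(ValueError):
            detect.split_align_backsplice({}, toy_gene["genome"], [toy_gene["model"]], anchor_min=5)


class TestIngestJunctions:
    def test_parses_counts(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t100\t500\t.\t+\ts1:3\ts2:0\n")
        (j,) = detect.ingest_junctions(p)
        assert j.key == ("chr1", 100, 500, "+")
        assert j.counts == {"s1": 3, "s2": 0}

    def test_donor_before_acceptor_names_row(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t500\t100\t.\t+\ts1:3\n")
        with pytest.raises(FormatError, match="j.bed:1"):
            detect.ingest_junctions(p)

    def test_write_read_round_trip(self, tmp_path):
        js = [
            detect.BackspliceJunction("chr1", 10, 99, "+", {"s1": 2}),
            detect.BackspliceJunction("chr2", 5, 50, "-", {"s1": 0, "s2": 7}),
        ]
        p = tmp_path / "j.bed"
        detect.write_junctions(p, js)
        back = detect.ingest_junctions(p)
        assert [(j.key, dict(j.counts)) for j in back] == [(j.key, dict(j.counts)) for j in js]


class TestAnnotateExonic:
    def test_multi_exon_run(self, toy_gene):
        model = toy_gene["model"]
        j = detect.BackspliceJunction("chrT", 600, 1700, "+", {"s1": 3})
        (call,) = detect.annotate_exonic([j], [model])
        assert call.exon_run == (1, 3)
        assert call.spliced_length == 200 + 300 + 200

    def test_single_exon_circle(self, toy_gene):
        model = toy_gene["model"]
        j = detect.BackspliceJunction("chrT", 1000, 1300, "+", {"s1": 2})
        (call,) = detect.annotate_exonic([j], [model])
        assert call.exon_run == (2, 2)
        assert call.spliced_length == 300

    def test_intronic_junction_dropped(self, toy_gene):
        j = detect.BackspliceJunction("chrT", 450, 1400, "+", {"s1": 5})
        assert detect.annotate_exonic([j], [toy_gene["model"]]) == []

    def test_boundary_tolerance_snaps(self, toy_gene):
        j = detect.BackspliceJunction("chrT", 601, 1699, "+", {"s1": 1})
        assert detect.annotate_exonic([j], [toy_gene["model"]], boundary_tol=0) == []
        (call,) = detect.annotate_exonic([j], [toy_gene["model"]], boundary_tol=2)
        assert (call.junction.acceptor_pos, call.junction.donor_pos) == (600, 1700)


class TestHighConfidenceFilter:
    @pytest.mark.parametrize(
        "counts,kept",
        [
            ({"s1": 2, "s2": 2, "s3": 0}, True),
            ({"s1": 5}, False),           # only one sample
            ({"s1": 1, "s2": 1}, False),  # each below 2 reads
        ],
    )
    def test_rule(self, counts, kept, toy_gene):
        j = detect.BackspliceJunction("chrT", 600, 1700, "+", counts)
        (call,) = detect.annotate_exonic([j], [toy_gene["model"]])
        result = detect.filter_high_confidence([call])
        assert (len(result) == 1) is kept

    def test_subset_and_idempotent(self, pipeline_result):
        calls = pipeline_result.calls
        once = detect.filter_high_confidence(calls)
        assert set(id(c) for c in once) <= set(id(c) for c in calls)
        assert detect.filter_high_confidence(once) == once


class TestSRPBM:
    def _call(self, counts):
        j = detect.BackspliceJunction("chrT", 600, 1700, "+", counts)
        return detect.CircRNACall("c", j, "G", "T", (1, 3), 700, dict(counts))

    def test_hand_computed_value(self):
        call = self._call({"s1": 2})
        meta = [SampleMeta("s1", "resistant", "MCF", 10**8, 100)]
        detect.compute_srpbm([call], meta)
        assert call.srpbm["s1"] == pytest.approx(0.2)

    def test_zero_count_is_zero(self):
        call = self._call({})
        meta = [SampleMeta("s1", "resistant", "MCF", 10**8, 100)]
        detect.compute_srpbm([call], meta)
        assert call.srpbm["s1"] == 0.0

    def test_depth_invariance(self):
        c1 = self._call({"s1": 2})
        c2 = self._call({"s1": 20})
        detect.compute_srpbm([c1], [SampleMeta("s1", "resistant", "MCF", 10**6, 100)])
        detect.compute_srpbm([c2], [SampleMeta("s1", "resistant", "MCF", 10**7, 100)])
        assert c1.srpbm["s1"] == pytest.approx(c2.srpbm["s1"])


class TestCircSequence:
    def test_length_equals_exon_sum(self, toy_gene):
        model = toy_gene["model"]
        j = detect.BackspliceJunction("chrT", 1000, 1300, "+", {"s1": 1})
        (call,) = detect.annotate_exonic([j], [model])
        seq = detect.circ_sequence(call, toy_gene["genome"], [model])
        assert len(seq) == call.spliced_length == 300

    def test_minus_strand_is_reverse_complement(self, toy_gene, toy_gene_minus):
        plus, minus = toy_gene["model"], toy_gene_minus["model"]
        genome = toy_gene["genome"]
        jp = detect.BackspliceJunction("chrT", 600, 1700, "+", {"s1": 1})
        jm = detect.BackspliceJunction("chrT", 600, 1700, "-", {"s1": 1})
        (cp,) = detect.annotate_exonic([jp], [plus])
        (cm,) = detect.annotate_exonic([jm], [minus])
        sp = detect.circ_sequence(cp, genome, [plus])
        sm = detect.circ_sequence(cm, genome, [minus])
        assert sm == reverse_complement(sp)

    def test_exon_beyond_chromosome_raises(self):
        from circsponge.io import ExonModel
        model = ExonModel("G", "T", "chrT", "+", ((0, 50),))
        call = detect.CircRNACall(
            "c", detect.BackspliceJunction("chrT", 0, 50, "+", {}), "G", "T", (0, 0), 50, {}
        )
        with pytest.raises(IndexError):
            detect.circ_sequence(call, {"chrT": "ACGT" * 10}, [model])


def test_truth_recovery_on_synthetic_fixture(pipeline_result):
    """Detected exonic high-confidence calls equal the planted set exactly."""
    detected = {c.junction.key: c for c in pipeline_result.calls}
    planted = {t.junction_key: t for t in pipeline_result.truth.circ_truth}
    assert set(detected) == set(planted)
    for key, truth in planted.items():
        call = detected[key]
        assert call.spliced_length == truth.spliced_length
        for sample, count in truth.counts.items():
            assert call.counts.get(sample, 0) == count
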