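import json

import numpy as np
import pytest

from grnkit.annotation import GeneModel, promoter_window
from grnkit.expression import ExpressionRecord, Perturbation
from grnkit.genomic_io import GenomicInterval, Loop, Peak, Track, overlap_length
from grnkit.motif_scan import TFBSHit
from grnkit.network_builder import (
    Edge,
    Network,
    annotate_promoter_marks,
    build_direct_network,
    cooccupancy,
    expand_indirect,
    export_network,
    infer_sign,
    networks_equal,
    read_edge_table,
)
from grnkit.target_detection import PeakAssignment


def _peak(chrom, start, end, intensity=1.0):
    return Peak(GenomicInterval(chrom, start, end), intensity)


def _assignment(gene, mode="promoter", distance=0):
    loop = None
    if mode == "loop":
        loop = Loop(GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 900, 1000))
    return PeakAssignment(gene, _peak("chr1", 0, 100, 5.0), mode, distance, loop=loop)


def _hit(start=0, accessible=True):
    return TFBSHit(GenomicInterval("chr1", start, start + 10, "+"),
                   "m", "tf1", 8.0, "+", accessible=accessible)


class TestInferSign:
    @pytest.mark.parametrize(
        "log2fc, direction, expected",
        [
            (-2.3, "loss", "activate"),   # target falls when factor is lost
            (2.0, "loss", "repress"),
            (2.0, "gain", "activate"),
            (-2.0, "gain", "repress"),
            (0.0, "loss", "unknown"),
        ],
    )
    def test_sign_table(self, log2fc, direction, expected):
        assert infer_sign(log2fc, Perturbation("f", direction)) == expected

    def test_flipping_direction_flips_every_known_sign(self):
        rng = np.random.default_rng(1)
        for fc in rng.normal(0, 2, size=50):
            loss = infer_sign(float(fc), Perturbation("f", "loss"))
            gain = infer_sign(float(fc), Perturbation("f", "gain"))
            if loss == "unknown":
                assert gain == "unknown"
            else:
                assert {loss, gain} == {"activate", "repress"}


class TestBuildDirectNetwork:
    def test_evidence_union_per_gene(self):
        assignments = [_assignment("gA"), _assignment("gA", "loop")]
        net = build_direct_network("center", {"gA"}, assignments)
        (edge,) = net.edges
        assert edge.evidence == frozenset({"promoter_peak", "loop_distal_peak"})
        assert edge.tier == "direct"

    def test_loop_only_target_carries_loop_evidence(self):
        net = build_direct_network("center", {"gA"}, [_assignment("gA", "loop")])
        assert net.edges[0].evidence == frozenset({"loop_distal_peak"})

    def test_empty_target_set_leaves_center_alone(self):
        net = build_direct_network("center", set(), [])
        assert list(net.nodes) == ["center"]
        assert net.edges == []

    def test_target_without_evidence_is_internal_error(self):
        with pytest.raises(ValueError, match="binding evidence"):
            build_direct_network("center", {"gA"}, [])

    def test_signs_from_expression_and_tf_typing(self):
        expr = {"gA": ExpressionRecord("gA", -2.0, 0.01)}
        net = build_direct_network(
            "center", {"gA"}, [_assignment("gA")], expr,
            Perturbation("center", "loss"), tf_registry={"gA"})
        assert net.edges[0].sign == "activate"
        assert net.nodes["gA"].role == "tf"


class TestExpandIndirect:
    def _base_network(self):
        expr = {"tf1": ExpressionRecord("tf1", -2.0, 0.01)}
        return build_direct_network(
            "center", {"tf1"}, [_assignment("tf1")], expr,
            Perturbation("center", "loss"), tf_registry={"tf1"})

    def test_accessible_site_plus_deg_yields_indirect_edge(self):
        net = self._base_network()
        degs = {"gX": ExpressionRecord("gX", -1.5, 0.01)}
        expand_indirect(net, {"tf1": {"gX": [_hit()]}}, degs,
                        Perturbation("center", "loss"), {"tf1"}, depth=1)
        assert net.has_edge("tf1", "gX", "indirect")
        (edge,) = [e for e in net.edges if e.tier == "indirect"]
        assert edge.evidence == frozenset({"predicted_tfbs"})
        # center activates tf1 (down under loss), tf1 loses activity, gX down
        # => tf1 activates gX
        assert edge.sign == "activate"

    def test_curated_peak_evidence_tagged_as_curated_binding(self):
        net = self._base_network()
        degs = {"gX": ExpressionRecord("gX", -1.5, 0.01)}
        expand_indirect(net, {"tf1": {"gX": [_assignment("gX")]}}, degs,
                        Perturbation("center", "loss"), {"tf1"}, depth=1)
        (edge,) = [e for e in net.edges if e.tier == "indirect"]
        assert edge.evidence == frozenset({"curated_binding"})

    def test_non_deg_gene_excluded(self):
        net = self._base_network()
        expand_indirect(net, {"tf1": {"gX": [_hit()]}}, set(), depth=1)
        assert not net.has_edge("tf1", "gX", "indirect")

    def test_depth_zero_changes_nothing(self):
        net = self._base_network()
        before = len(net.edges)
        expand_indirect(net, {"tf1": {"gX": [_hit()]}}, {"gX"}, depth=0)
        assert len(net.edges) == before

    def test_depth_guard(self):
        net = self._base_network()
        with pytest.raises(ValueError, match="depth"):
            expand_indirect(net, {}, set(), depth=4)

    def test_no_self_edges_and_direct_wins(self):
        net = self._base_network()
        evidence = {"tf1": {"tf1": [_hit()]}}
        expand_indirect(net, evidence, {"tf1"}, depth=1)
        assert not net.has_edge("tf1", "tf1", "indirect")
        # a gene already a direct target of tf1 keeps only the direct edge
        net2 = self._base_network()
        net2.add_edge(Edge("tf1", "gY", "direct", frozenset({"promoter_peak"})))
        expand_indirect(net2, {"tf1": {"gY": [_hit()]}}, {"gY"}, depth=1)
        assert not net2.has_edge("tf1", "gY", "indirect")

    def test_depth_two_chains_through_second_tf(self):
        net = self._base_network()
        degs = {"tf2": ExpressionRecord("tf2", -1.0, 0.01),
                "gZ": ExpressionRecord("gZ", 2.0, 0.01)}
        evidence = {"tf1": {"tf2": [_hit()]}, "tf2": {"gZ": [_hit()]}}
        expand_indirect(net, evidence, degs, Perturbation("center", "loss"),
                        tf_registry={"tf1", "tf2"}, depth=2)
        assert net.has_edge("tf1", "tf2", "indirect")
        assert net.has_edge("tf2", "gZ", "indirect")

    def test_accessibility_filtering_only_removes_edges(self):
        """The filtered evidence set yields a subset of the unfiltered edges."""
        all_hits = {"tf1": {"gX": [_hit()], "gY": [_hit(accessible=False)]}}
        filtered = {"tf1": {"gX": [_hit()]}}
        degs = {"gX": ExpressionRecord("gX", -1.0, 0.01),
                "gY": ExpressionRecord("gY", -1.0, 0.01)}
        net_all = expand_indirect(self._base_network(), all_hits, degs, depth=1)
        net_filtered = expand_indirect(self._base_network(), filtered, degs, depth=1)
        keys = lambda n: {e.key for e in n.edges}
        assert keys(net_filtered) <= keys(net_all)


class TestAnnotatePromoterMarks:
    def _network_and_genes(self):
        net = build_direct_network("center", {"gA", "gB", "gC"},
                                   [_assignment(g) for g in ("gA", "gB", "gC")])
        genes = [GeneModel("gA", "chr1", 10_000, "+"),
                 GeneModel("gB", "chr1", 50_000, "+"),
                 GeneModel("gC", "chr1", 90_000, "+")]
        return net, genes

    def test_single_bivalent_and_empty_annotations(self):
        net, genes = self._network_and_genes()
        tracks = [
            Track("H3K4me3", [GenomicInterval("chr1", 9_000, 11_000),
                              GenomicInterval("chr1", 49_000, 51_000)], "active_mark"),
            Track("H3K27me3", [GenomicInterval("chr1", 49_500, 50_500)], "repressive_mark"),
        ]
        annotate_promoter_marks(net, genes, tracks, 2_000, 2_000)
        assert net.nodes["gA"].marks == {"H3K4me3"}
        assert net.nodes["gB"].marks == {"H3K4me3", "H3K27me3"}  # bivalent
        assert net.nodes["gC"].marks == set()

    def test_edges_untouched(self):
        net, genes = self._network_and_genes()
        before = [e.key for e in net.edges]
        annotate_promoter_marks(net, genes, [], 2_000, 2_000)
        assert [e.key for e in net.edges] == before


class TestCooccupancy:
    def _peaks(self, positions, chrom="chr1", width=100):
        return [_peak(chrom, p, p + width) for p in positions]

    def test_identical_sets_maximal_overlap(self):
        peaks = self._peaks([1000, 5000, 9000])
        result = cooccupancy(peaks, list(peaks), {"chr1": 20_000},
                             n_permutations=99, seed=0)
        assert result.observed == 3
        assert result.jaccard == 1.0

    def test_disjoint_chromosomes(self):
        a = self._peaks([1000], chrom="chr1")
        b = self._peaks([1000], chrom="chr2")
        result = cooccupancy(a, b, {"chr1": 20_000, "chr2": 20_000},
                             n_permutations=99, seed=0)
        assert result.observed == 0
        assert result.jaccard == 0.0

    def test_empirical_p_bounds(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            a = self._peaks(sorted(rng.integers(0, 90_000, size=10)))
            b = self._peaks(sorted(rng.integers(0, 90_000, size=10)))
            result = cooccupancy(a, b, {"chr1": 100_000}, n_permutations=49,
                                 seed=trial)
            assert 1 / 50 <= result.p_value <= 1.0

    def test_seeded_runs_are_identical_and_order_invariant(self):
        rng = np.random.default_rng(3)
        a = self._peaks(sorted(rng.integers(0, 90_000, size=15)))
        b = self._peaks(sorted(rng.integers(0, 90_000, size=15)))
        sizes = {"chr1": 100_000}
        r1 = cooccupancy(a, b, sizes, n_permutations=200, seed=42)
        r2 = cooccupancy(list(a), b, sizes, n_permutations=200, seed=42)
        r3 = cooccupancy(list(reversed(a)), b, sizes, n_permutations=200, seed=42)
        assert (r1.observed, r1.p_value, r1.expected) == (r2.observed, r2.p_value, r2.expected)
        assert r3.observed == r1.observed

    def test_peak_beyond_chromosome_end_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            cooccupancy(self._peaks([1000]), self._peaks([500]), {"chr1": 900})


class TestExport:
    def _network(self):
        expr = {"gA": ExpressionRecord("gA", -2.0, 0.01),
                "tf1": ExpressionRecord("tf1", -3.0, 0.001)}
        net = build_direct_network(
            "center", {"gA", "tf1"},
            [_assignment("gA"), _assignment("tf1", "loop")], expr,
            Perturbation("center", "loss"), tf_registry={"tf1"})
        expand_indirect(net, {"tf1": {"gX": [_hit()]}},
                        {"gX": ExpressionRecord("gX", 1.5, 0.01)},
                        Perturbation("center", "loss"), {"tf1"}, depth=1)
        net.nodes["gA"].marks = {"H3K4me3"}
        return net

    def test_edge_table_round_trip(self, tmp_path):
        net = self._network()
        path = tmp_path / "net.tsv"
        export_network(net, path, "edge_table_tsv")
        assert networks_equal(read_edge_table(path), net)

    def test_empty_network_round_trip(self, tmp_path):
        net = Network("center")
        path = tmp_path / "empty.tsv"
        export_network(net, path, "edge_table_tsv")
        assert networks_equal(read_edge_table(path), net)

    def test_sif_triples(self, tmp_path):
        path = tmp_path / "net.sif"
        export_network(self._network(), path, "sif")
        lines = path.read_text().splitlines()
        assert "center\tdirect\tgA" in lines
        assert "tf1\tindirect\tgX" in lines

    def test_graph_json_carries_annotations(self, tmp_path):
        path = tmp_path / "net.json"
        export_network(self._network(), path, "graph_json", metadata={"seed": 1})
        doc = json.loads(path.read_text())
        assert doc["center"] == "center"
        assert doc["metadata"]["seed"] == 1
        nodes = {n["gene_id"]: n for n in doc["nodes"]}
        assert nodes["tf1"]["role"] == "tf"
        assert nodes["gA"]["marks"] == ["H3K4me3"]

    def test_max_nodes_cap_keeps_center_and_drops_dangling_edges(self, tmp_path):
        net = self._network()
        path = tmp_path / "capped.tsv"
        export_network(net, path, "edge_table_tsv", max_nodes=3)
        capped = read_edge_table(path)
        assert len(capped.nodes) <= 3
        assert "center" in capped.nodes
        for e in capped.edges:
            assert e.regulator in capped.nodes and e.target in capped.nodes
        # the strongest responders survive
        assert "tf1" in capped.nodes

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(self._network(), tmp_path / "x", "graphml")


def test_every_promoter_edge_support_reverifies():
    """Validation pass: each promoter_peak edge carries at least one
    assignment whose peak overlaps the target's promoter window."""
    genes = [GeneModel("gA", "chr1", 10_000, "+"), GeneModel("gB", "chr1", 50_000, "-")]
    peaks = [_peak("chr1", 9_500, 10_500, 4.0), _peak("chr1", 49_800, 50_100, 2.0)]
    from grnkit.target_detection import assign_peaks_promoter
    assignments = assign_peaks_promoter(peaks, genes, 2_000, 2_000)
    net = build_direct_network("center", {"gA", "gB"}, assignments)
    by_id = {g.gene_id: g for g in genes}
    for edge in net.edges:
        if "promoter_peak" in edge.evidence:
            window = promoter_window(by_id[edge.target], 2_000, 2_000)
            assert any(
                isinstance(s, PeakAssignment)
                and overlap_length(s.peak.region, window) > 0
                for s in edge.support
            )
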