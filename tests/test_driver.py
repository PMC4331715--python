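"""Iterative extraction loop and whole-dataset pipeline."""

import numpy as np
import pytest

from conftest import make_locus
from ispasm.driver import (
    AssemblyConfig,
    assemble_all,
    assemble_locus,
    calls_to_records,
)
from ispasm.evaluate import score_predictions
from ispasm.mscg import build_mscg
from ispasm.pairing import filter_informative, group_fragments
from ispasm.segmentation import SegmentVectorRead
from ispasm.simulate import SimConfig, simulate_dataset


def paired(sample, rid, b, b2):
    return [
        SegmentVectorRead(sample, rid, 1, tuple(b)),
        SegmentVectorRead(sample, rid, 2, tuple(b2)),
    ]


def run_locus(locus, reads, config=None):
    cfg = config or AssemblyConfig()
    graph = build_mscg(locus, reads, filter_junctions=True)
    frags, _ = group_fragments(reads)
    patterns = filter_informative(frags, alpha=cfg.alpha_real, M=locus.M)
    return assemble_locus(locus, graph, patterns, cfg, fragments=frags)


class TestAssembleLocus:
    def test_single_clean_isoform_yields_one_call(self):
        locus = make_locus([(0, 200), (400, 600), (800, 1000)])
        reads = []
        for i in range(30):
            reads.extend(paired(0, f"p{i}", (1, 2), (2, 3)))
        calls, stats = run_locus(locus, reads)
        assert len(calls) == 1
        assert calls[0].exons == ((0, 200), (400, 600), (800, 1000))
        assert stats["stop"] in {"duplicate", "objective"}

    def test_two_isoforms_sharing_no_junctions(self):
        # two structures over disjoint junction sets in one locus,
        # each well covered: both come out within two iterations
        locus = make_locus(
            [(0, 150), (300, 450), (600, 750), (760, 910), (1060, 1210),
             (1360, 1510)]
        )
        reads = []
        for i in range(25):
            reads.extend(paired(0, f"a{i}", (1, 2), (2, 3)))
            reads.extend(paired(0, f"b{i}", (4, 5), (5, 6)))
        calls, _ = run_locus(locus, reads)
        chains = sorted(c.exons for c in calls)
        assert chains == [
            ((0, 150), (300, 450), (600, 750)),
            ((760, 910), (1060, 1210), (1360, 1510)),
        ]
        assert all(c.iteration <= 2 for c in calls)

    def test_exon_skip_isoforms_both_recovered(self):
        locus = make_locus([(0, 200), (400, 600), (800, 1000)])
        reads = []
        for i in range(40):
            reads.extend(paired(0, f"full{i}", (1, 2), (2, 3)))
        for i in range(15):
            reads.extend(paired(0, f"skip{i}", (1, 3), (1, 3)))
        calls, _ = run_locus(locus, reads)
        chains = {c.exons for c in calls}
        assert chains == {
            ((0, 200), (400, 600), (800, 1000)),
            ((0, 200), (800, 1000)),
        }

    def test_low_density_single_segment_not_emitted(self):
        locus = make_locus([(0, 300)])
        reads = [SegmentVectorRead(0, "i0", 0, (1,))]
        calls, stats = run_locus(locus, reads)
        assert calls == []
        assert stats["stop"] == "single_exon_floor"

    def test_dense_single_exon_gene_is_emitted(self):
        locus = make_locus([(0, 300)])
        reads = [SegmentVectorRead(0, f"i{k}", 0, (1,)) for k in range(800)]
        calls, _ = run_locus(locus, reads)
        assert [c.exons for c in calls] == [((0, 300),)]

    def test_iteration_budget_respected(self):
        locus = make_locus([(0, 200), (400, 600), (800, 1000)])
        reads = []
        for i in range(10):
            reads.extend(paired(0, f"p{i}", (1, 2), (2, 3)))
        cfg = AssemblyConfig(max_iter=1)
        calls, stats = run_locus(locus, reads, cfg)
        assert len(calls) == 1
        assert stats["stop"] == "max_iter"

    def test_unwitnessed_double_deviation_is_vetoed(self):
        # molecules support skipping exon 2 or exon 4, never both: the
        # chimeric double-skip path must not be emitted
        locus = make_locus([(i * 400, i * 400 + 200) for i in range(5)])
        reads = []
        for i in range(40):
            reads.extend(paired(0, f"f{i}", (1, 2), (2, 3)))
            reads.extend(paired(0, f"g{i}", (3, 4), (4, 5)))
        for i in range(12):
            reads.extend(paired(0, f"s2_{i}", (1, 3), (3, 4)))
            reads.extend(paired(0, f"s4_{i}", (2, 3), (3, 5)))
        calls, _ = run_locus(locus, reads)
        chains = {c.exons for c in calls}
        skip_both = ((0, 200), (800, 1000), (1600, 1800))
        assert skip_both not in chains
        full = tuple((i * 400, i * 400 + 200) for i in range(5))
        assert full in chains


class TestAssembleAll:
    def test_empty_input(self):
        calls, summary = assemble_all([[]], AssemblyConfig())
        assert calls == [] and summary["loci"] == 0

    def test_clean_two_locus_dataset_recovered_exactly(self):
        cfg_sim = SimConfig(n_samples=2, reads_per_sample=400,
                            error_rate=0.0, seed=11)
        sim = simulate_dataset([1, 2], cfg_sim)
        calls, summary = assemble_all(sim.alignments, AssemblyConfig(seed=0))
        rep = score_predictions(calls_to_records(calls), sim.transcripts)
        assert rep.sensitivity == 1.0 and rep.precision == 1.0
        assert summary["loci"] == 2

    def test_sample_relabelling_does_not_change_calls(self):
        cfg_sim = SimConfig(n_samples=2, reads_per_sample=300,
                            error_rate=0.0, seed=13)
        sim = simulate_dataset([2], cfg_sim)
        calls1, _ = assemble_all(sim.alignments, AssemblyConfig(seed=0))
        swapped = [sim.alignments[1], sim.alignments[0]]
        # sample ids inside alignments refer to their list position
        relabel = [
            [a.__class__(k, a.read_id, a.mate, a.chrom, a.blocks)
             for a in alns]
            for k, alns in enumerate(swapped)
        ]
        calls2, _ = assemble_all(relabel, AssemblyConfig(seed=0))
        assert [c.exons for c in calls1] == [c.exons for c in calls2]

    def test_summary_counters_present(self):
        sim = simulate_dataset(
            [1], SimConfig(n_samples=1, reads_per_sample=100, seed=1)
        )
        _, summary = assemble_all(sim.alignments, AssemblyConfig())
        for key in ("loci", "calls", "ilp_solves", "vetoed_paths",
                    "dropped_alignments", "pseudo_reads"):
            assert key in summary


class TestConfig:
    def test_from_file_round_trip(self, tmp_path):
        text = """
        # assembler settings
        alpha_real = 0.5
        fdr: 10
        max_iter = 7
        depth_normalize = true
        """
        path = tmp_path / "ispasm.conf"
        path.write_text("\n".join(l.strip() for l in text.splitlines()))
        cfg = AssemblyConfig.from_file(str(path))
        assert cfg.alpha_real == 0.5
        assert cfg.fdr == 10.0
        assert cfg.max_iter == 7
        assert cfg.depth_normalize is True
        assert cfg.gamma == AssemblyConfig().gamma

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.conf"
        path.write_text("no_such_option = 1\n")
        with pytest.raises(ValueError, match="no_such_option"):
            AssemblyConfig.from_file(str(path))
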