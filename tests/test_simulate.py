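"""Simulator contracts: determinism, distance law, lineage, scenarios, reads."""

import numpy as np
import pytest
from scipy import stats as sps

from cd5switch.reads import ReadPair, merge_pairs, median_quality
from cd5switch.simulate import (
    ConfigurationError,
    SimulationConfig,
    assign_cd5_states,
    emit_reads,
    sample_single_cells,
    simulate_clone,
)
from cd5switch.stats import hamming


def test_single_cell_clone_is_central_identity():
    truth = simulate_clone(SimulationConfig(seed=1, clone_cells=1, background_clones=0))
    assert len(truth.cells) == 1
    cell = truth.cells[0]
    assert cell.bcr_sequence == truth.central_sequence
    assert cell.distance_from_central == 0
    assert cell.lineage_parent is None


def test_simulation_is_deterministic(small_config):
    t1 = simulate_clone(small_config)
    t2 = simulate_clone(small_config)
    assert t1.central_sequence == t2.central_sequence
    assert t1.cells_table().equals(t2.cells_table())
    assert t1.background_sequences == t2.background_sequences


def test_distance_field_matches_hamming_to_central(truth_c):
    for cell in truth_c.cells:
        assert hamming(cell.bcr_sequence, truth_c.central_sequence) == cell.distance_from_central


def test_variant_distance_mean_matches_configured_law():
    """Mean variant Hamming distance tracks the configured geometric mean 1.5."""
    means = []
    for seed in range(5):
        truth = simulate_clone(SimulationConfig(seed=seed, clone_cells=500))
        d = [c.distance_from_central for c in truth.cells if c.distance_from_central > 0]
        means.append(np.mean(d))
    assert abs(np.mean(means) - 1.5) < 0.3


def test_lineage_is_tree_rooted_at_central_ancestor(truth_c):
    ids = {c.cell_id for c in truth_c.cells}
    roots = [c for c in truth_c.cells if c.lineage_parent is None]
    assert len(roots) == 1 and roots[0].bcr_sequence == truth_c.central_sequence
    # every parent exists and following parents always terminates at the root
    for cell in truth_c.cells:
        seen = set()
        cur = cell
        while cur.lineage_parent is not None:
            assert cur.lineage_parent in ids and cur.cell_id not in seen
            seen.add(cur.cell_id)
            cur = next(c for c in truth_c.cells if c.cell_id == cur.lineage_parent)
        assert cur is truth_c.cells[0]


def test_mutations_nest_along_lineage(truth_c):
    """A child's distance to its parent plus the parent's distance to the
    central sequence equals the child's distance (substitutions accumulate)."""
    by_id = {c.cell_id: c for c in truth_c.cells}
    for cell in truth_c.cells:
        if cell.lineage_parent is None:
            continue
        parent = by_id[cell.lineage_parent]
        d_edge = hamming(cell.bcr_sequence, parent.bcr_sequence)
        assert parent.distance_from_central + d_edge == cell.distance_from_central


def test_scenario_c_zero_rate_all_high(small_config):
    truth = simulate_clone(small_config)
    assign_cd5_states(truth, "C", 0.0, seed=1)
    assert all(c.cd5_state == "high" for c in truth.cells)


def test_scenario_c_switch_count_binomial():
    cfg = SimulationConfig(seed=2, clone_cells=100, background_clones=0)
    counts = []
    for seed in range(40):
        truth = simulate_clone(cfg)
        assign_cd5_states(truth, "C", 0.2, seed=seed)
        counts.append(sum(c.cd5_state == "low" for c in truth.cells))
    # mean within 4 sd of binomial(100, 0.2) expectation over 40 replicates
    assert abs(np.mean(counts) - 20) < 4 * 4.0 / np.sqrt(40)
    assert all(0 <= c <= 100 for c in counts)


def test_scenario_a_founder_at_root_switches_everything(small_config):
    truth = simulate_clone(small_config)
    assign_cd5_states(truth, "A", 1, seed=1, founder_cells=[truth.cells[0].cell_id])
    assert all(c.cd5_state == "low" for c in truth.cells)


def test_scenario_a_low_set_is_complete_subtree(truth_c, small_config):
    truth = simulate_clone(small_config)
    assign_cd5_states(truth, "A", 1, seed=3)
    children = truth.children_map()
    low_ids = {c.cell_id for c in truth.cells if c.cd5_state == "low"}
    assert low_ids, "one founder event must switch at least one cell"
    # the low set is closed under descent and has a unique top element
    tops = [cid for cid in low_ids
            if next(c for c in truth.cells if c.cell_id == cid).lineage_parent not in low_ids]
    assert len(tops) == 1
    for cid in low_ids:
        for kid in children[cid]:
            assert kid in low_ids


def test_scenario_b_mirrors_a(small_config):
    truth_a = simulate_clone(small_config)
    truth_b = simulate_clone(small_config)
    assign_cd5_states(truth_a, "A", 1, seed=5)
    assign_cd5_states(truth_b, "B", 1, seed=5)
    flip = {"high": "low", "low": "high"}
    assert [c.cd5_state for c in truth_b.cells] == [flip[c.cd5_state] for c in truth_a.cells]


def test_unknown_scenario_rejected(small_config):
    truth = simulate_clone(small_config)
    with pytest.raises(ConfigurationError):
        assign_cd5_states(truth, "D", 0.1, seed=0)


def test_scenario_c_labels_independent_of_lineage():
    """Child and parent CD5 labels are uncorrelated under common switching
    (chi-square association test non-significant in nearly all seeds)."""
    cfg = SimulationConfig(seed=0, clone_cells=400, background_clones=0)
    truth0 = simulate_clone(cfg)
    n_sig = 0
    n_seeds = 100
    for seed in range(n_seeds):
        truth = simulate_clone(cfg)
        assign_cd5_states(truth, "C", 0.3, seed=seed)
        state = {c.cell_id: c.cd5_state for c in truth.cells}
        table = np.zeros((2, 2))
        for c in truth.cells:
            if c.lineage_parent is None:
                continue
            i = int(state[c.cell_id] == "low")
            j = int(state[c.lineage_parent] == "low")
            table[i, j] += 1
        _, p, _, _ = sps.chi2_contingency(table)
        n_sig += p < 0.01
    assert n_sig <= 0.05 * n_seeds


def test_read_conservation_and_determinism(small_config, tmp_path):
    truth = simulate_clone(small_config)
    assign_cd5_states(truth, "C", 0.15, seed=7)
    rec1, ab1 = emit_reads(truth, out_prefix=tmp_path / "a" / "run")
    rec2, ab2 = emit_reads(truth, out_prefix=tmp_path / "b" / "run")
    expected = len(truth.cells) * small_config.reads_per_cell + sum(
        n for _s, n in truth.background_sequences
    )
    assert len(rec1) == expected == int(ab1["n_read_pairs"].sum())
    assert (tmp_path / "a" / "run_R1.fastq").read_bytes() == (tmp_path / "b" / "run_R1.fastq").read_bytes()
    assert (tmp_path / "a" / "run_R2.fastq").read_bytes() == (tmp_path / "b" / "run_R2.fastq").read_bytes()


def test_error_free_reads_merge_back_to_cell_sequences():
    cfg = SimulationConfig(seed=4, clone_cells=50, background_clones=0, error_rate=0.0,
                           reads_per_cell=2)
    truth = simulate_clone(cfg)
    assign_cd5_states(truth, "C", 0.1, seed=4)
    records, _ = emit_reads(truth)
    truth_seqs = {cfg.primer_fwd + c.bcr_sequence + cfg.primer_rev for c in truth.cells}
    for rid, f, fq, r, rq in records:
        merged = merge_pairs(ReadPair(rid, f, fq, r, rq))
        assert merged in truth_seqs


def test_read_geometry_asymmetric_mates_merge_to_expected_length():
    # 200 + 180 - 70 = 310 = 20 + 270 + 20 amplicon
    cfg = SimulationConfig(seed=1, clone_cells=5, background_clones=0, error_rate=0.0,
                           sequence_length=270, read_length=200, read_length_rev=180,
                           overlap_length=70, reads_per_cell=1)
    truth = simulate_clone(cfg)
    assign_cd5_states(truth, "C", 0.0, seed=1)
    records, _ = emit_reads(truth)
    for rid, f, fq, r, rq in records:
        assert (len(f), len(r)) == (200, 180)
        assert len(merge_pairs(ReadPair(rid, f, fq, r, rq))) == 310


def test_inconsistent_read_geometry_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(read_length=150, overlap_length=100)


def test_low_quality_fraction_spikes_median_filter_failures():
    cfg = SimulationConfig(seed=9, clone_cells=100, background_clones=0,
                           reads_per_cell=10, low_quality_fraction=0.1)
    truth = simulate_clone(cfg)
    assign_cd5_states(truth, "C", 0.1, seed=9)
    records, _ = emit_reads(truth)
    n_fail = sum(
        1 for _rid, _f, fq, _r, rq in records
        if median_quality(fq) <= 32 or median_quality(rq) <= 32
    )
    assert sps.binom.ppf(0.0005, 1000, 0.1) <= n_fail <= sps.binom.ppf(0.9995, 1000, 0.1)


def test_plate_sampling_contracts(truth_c):
    all_failed = sample_single_cells(truth_c, "high", n_wells=10, dropout_rate=1.0,
                                     doublet_rate=0.0, seed=1)
    assert (all_failed["status"] == "failed").all()

    clean = sample_single_cells(truth_c, "high", n_wells=96, dropout_rate=0.0,
                                doublet_rate=0.0, seed=1)
    assert (clean["status"] == "single").all() and len(clean) == 96

    low_seqs = {c.bcr_sequence for c in truth_c.cells if c.cd5_state == "low"}
    gated = sample_single_cells(truth_c, "low", n_wells=50, dropout_rate=0.0,
                                doublet_rate=0.0, seed=2)
    assert set(gated["sequence"]) <= low_seqs

    with pytest.raises(ConfigurationError):
        sample_single_cells(truth_c, "nope", n_wells=5)
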