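"""End-to-end orchestration: simulate -> process -> network -> match -> stats -> tree.

One :class:`RunConfig` (one seed) drives every stage; per-stage artifacts
are written under the output directory and a consolidated ``report.json`` /
``report.tsv`` collects the headline quantities: per-sample largest-cluster
fractions, per-gate single-cell clonal fractions, the hypergeometric
overlap table, the co-clustering permutation p-value, the subclonal
frequency regression, and tip-state counts — plus a switching-regime
verdict combining the two tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import lineage as _lineage
from . import matching as _matching
from . import network as _network
from . import reads as _reads
from . import simulate as _simulate
from . import stats as _stats

log = logging.getLogger("cd5switch")

GATES = ("high", "low")


@dataclass
class RunConfig:
    simulation: _simulate.SimulationConfig = field(
        default_factory=_simulate.SimulationConfig
    )
    seed: int = 0
    # read-processing thresholds
    min_median_q: int = _reads.MIN_MEDIAN_QUALITY
    min_overlap: int = _reads.MIN_OVERLAP
    min_ig_score: float = _reads.IG_SIMILARITY_MIN_SCORE
    min_length: int = _reads.MIN_LENGTH
    max_primer_mismatch: int = 0
    # single-cell plates
    n_wells: int = 96
    dropout_rate: float = 0.3
    doublet_rate: float = 0.02
    max_mismatch: int = _matching.DEFAULT_MAX_MISMATCH
    # switching statistics
    n_boot: int = 1000
    subsample_size: int | None = None
    # stage toggles
    do_process: bool = True
    do_network: bool = True
    do_match: bool = True
    do_stats: bool = True
    do_tree: bool = True
    figures: bool = False

    def __post_init__(self) -> None:
        # the run seed fans out to every stage through the simulation config
        if self.simulation.seed != self.seed:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["simulation"] = json.loads(self.simulation.to_json())
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = _simulate.SimulationConfig.from_dict(d["simulation"])
        return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _flatten(d: dict, prefix: str = "") -> list[tuple[str, object]]:
    rows = []
    for key in sorted(d):
        val = d[key]
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            rows.extend(_flatten(val, name + "."))
        elif isinstance(val, (list, tuple)):
            rows.append((name, json.dumps(val)))
        else:
            rows.append((name, val))
    return rows


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order and write a consolidated report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.json").write_text(config.to_json() + "\n")
    report: dict = {"seed": config.seed, "scenario": config.simulation.scenario}

    # --- simulate -----------------------------------------------------------
    try:
        truth = _simulate.simulate_clone(config.simulation)
        _simulate.assign_cd5_states(truth)
        truth.to_dir(outdir / "truth")
        n_low = sum(c.cd5_state == "low" for c in truth.cells)
        report["simulation"] = {
            "clone_cells": len(truth.cells),
            "n_unique_clone_sequences": len({c.bcr_sequence for c in truth.cells}),
            "n_low_cells": n_low,
            "n_high_cells": len(truth.cells) - n_low,
            "background_clones": len(truth.background_sequences),
        }
        log.info("simulate: %d cells (%d low)", len(truth.cells), n_low)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("simulate", exc)

    processed_all: list[_reads.ProcessedSequence] = []
    if config.do_process:
        try:
            proc_report = {}
            for gate in GATES:
                cells = truth.gate_cells(gate)
                pairs_rec, _ab = _simulate.emit_reads(
                    truth,
                    cells=cells,
                    include_background=(gate == "high"),
                    seed=config.seed + (0 if gate == "high" else 1),
                    out_prefix=outdir / "reads" / gate,
                )
                pairs = [_reads.ReadPair(*rec) for rec in pairs_rec]
                processed, frep = _reads.process_sample(
                    pairs,
                    config.simulation.primer_fwd,
                    config.simulation.primer_rev,
                    sample_id=gate,
                    min_median_q=config.min_median_q,
                    min_overlap=config.min_overlap,
                    min_score=config.min_ig_score,
                    min_length=config.min_length,
                    max_primer_mismatch=config.max_primer_mismatch,
                )
                _reads.write_processed_fasta(processed, outdir / f"processed_{gate}.fa")
                (outdir / f"filter_report_{gate}.json").write_text(
                    json.dumps(frep.to_dict(), indent=2) + "\n"
                )
                proc_report[gate] = {
                    "reads_in": len(pairs),
                    "reads_retained": frep.stages[-1]["n_retained"],
                    "unique_sequences": len(processed),
                }
                processed_all.extend(processed)
                log.info(
                    "process[%s]: %d pairs -> %d reads, %d unique",
                    gate, len(pairs), frep.stages[-1]["n_retained"], len(processed),
                )
            report["processing"] = proc_report
        except Exception as exc:
            raise StageError("process", exc)

    clone = None
    net = None
    if config.do_network and processed_all:
        try:
            vertices = _network.collapse_unique(processed_all)
            net = _network.build_network(vertices)
            net.cluster_summary().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            net.to_graphml(outdir / "network.graphml")
            clone = _network.largest_cluster_stats(net)
            per_sample = {}
            for gate in GATES:
                gate_proc = [p for p in processed_all if p.sample_id == gate]
                gv = _network.collapse_unique(gate_proc)
                gn = _network.build_network(gv)
                gc = _network.largest_cluster_stats(gn)
                per_sample[gate] = {
                    "largest_cluster_read_fraction": gc.fraction_of_repertoire,
                    "largest_cluster_vertex_fraction": gc.fraction_of_vertices,
                    "n_vertices": len(gv),
                }
            report["network"] = {
                "n_vertices": len(vertices),
                "n_edges": len(net.edges),
                "n_clusters": len(net.clusters),
                "largest_cluster_read_fraction": clone.fraction_of_repertoire,
                "largest_cluster_vertex_fraction": clone.fraction_of_vertices,
                "central_is_true_ancestor": clone.central_sequence == truth.central_sequence,
                "per_sample": per_sample,
            }
            log.info(
                "network: %d vertices, %d edges, largest cluster %.1f%% of reads",
                len(vertices), len(net.edges), 100 * clone.fraction_of_repertoire,
            )
        except Exception as exc:
            raise StageError("network", exc)

    if config.do_match and clone is not None:
        try:
            match_report = {}
            for gate in GATES:
                plate = _simulate.sample_single_cells(
                    truth,
                    gate,
                    n_wells=config.n_wells,
                    dropout_rate=config.dropout_rate,
                    doublet_rate=config.doublet_rate,
                    seed=config.seed,
                )
                annotated = _matching.annotate_plate(plate, clone, config.max_mismatch)
                annotated.to_csv(outdir / f"plate_{gate}.tsv", sep="\t", index=False)
                frac, counts = _matching.clonal_fraction(annotated)
                match_report[gate] = {"clonal_fraction": frac, **counts}
                log.info("match[%s]: clonal fraction %s", gate, frac)
            report["single_cell"] = match_report
        except Exception as exc:
            raise StageError("match", exc)

    high_set: set[str] = set()
    low_set: set[str] = set()
    if clone is not None:
        high_set = clone.sample_member_sequences("high")
        low_set = clone.sample_member_sequences("low")

    if config.do_stats and clone is not None:
        try:
            overlap = _stats.hypergeometric_overlap_test(
                high_set, low_set, clone.central_sequence
            )
            overlap.table.to_csv(outdir / "overlap_test.tsv", sep="\t", index=False)
            cocluster = _stats.cocluster_bootstrap_test(
                high_set,
                low_set,
                n_boot=config.n_boot,
                subsample_size=config.subsample_size,
                seed=config.seed,
            )
            pd.DataFrame({"null_ratio": cocluster.null_ratios}).to_csv(
                outdir / "cocluster_null.tsv", sep="\t", index=False
            )
            hf = _stats.clone_frequencies(clone.members, "high")
            lf = _stats.clone_frequencies(clone.members, "low")
            try:
                reg = _stats.subclonal_correlation(hf, lf)
                reg_report = {
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r_squared": reg.r_squared,
                    "n_shared_variants": reg.n_shared,
                }
            except ValueError as exc:
                reg_report = {"error": str(exc)}
            overlap_sig = overlap.pooled_log10_p < -10
            cocluster_sig = cocluster.p_value < 0.05
            if overlap_sig and not cocluster_sig:
                verdict = "common-switching consistent"
            elif cocluster_sig and not overlap_sig:
                verdict = "rare-switching consistent"
            else:
                verdict = "indeterminate"
            report["switch_stats"] = {
                "overlap_pooled_p": overlap.pooled_p,
                "overlap_pooled_log10_p": overlap.pooled_log10_p,
                "overlap_classes": len(overlap.table),
                "cocluster_ratio": cocluster.ratio,
                "cocluster_p": cocluster.p_value,
                "n_boot": cocluster.n_boot,
                "subclonal_regression": reg_report,
                "verdict": verdict,
            }
            log.info(
                "stats: overlap log10 p %.2f, cocluster p %.3f -> %s",
                overlap.pooled_log10_p, cocluster.p_value, verdict,
            )
        except Exception as exc:
            raise StageError("stats", exc)

    if config.do_tree and clone is not None:
        try:
            tree = _lineage.build_lineage_tree(
                sorted(clone.member_sequences), clone.central_sequence
            )
            states, counts = _lineage.classify_tips(tree, high_set, low_set)
            newick = _lineage.export_newick(tree, states=states)
            (outdir / "lineage.nwk").write_text(newick + "\n")
            pd.DataFrame(
                sorted(states.items()), columns=["sequence", "tip_state"]
            ).to_csv(outdir / "tip_states.tsv", sep="\t", index=False)
            report["lineage"] = {
                "n_tips": len(tree.sequences),
                "parsimony_score": _lineage.parsimony_score(tree),
                "tip_states": dict(sorted(counts.items())),
                "low_only_confined_to_one_subtree": _lineage.states_confined_to_subtree(
                    tree, states, "low_only"
                ),
            }
            log.info("tree: %d tips, parsimony %d", len(tree.sequences), tree.total_weight)
        except Exception as exc:
            raise StageError("tree", exc)

    if config.figures and "switch_stats" in report:
        _write_figures(outdir, report)

    report_json = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_json + "\n")
    pd.DataFrame(_flatten(report), columns=["key", "value"]).to_csv(
        outdir / "report.tsv", sep="\t", index=False
    )
    return report


def _write_figures(outdir: Path, report: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    null = pd.read_csv(outdir / "cocluster_null.tsv", sep="\t")["null_ratio"]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(null, bins=40, color="steelblue", alpha=0.8)
    ax.axvline(report["switch_stats"]["cocluster_ratio"], color="crimson", lw=2)
    ax.set_xlabel("within/between distance ratio (null)")
    ax.set_ylabel("permutation replicates")
    ax.set_title(f"co-clustering p = {report['switch_stats']['cocluster_p']:.3g}")
    fig.tight_layout()
    fig.savefig(figdir / "cocluster_null.png", dpi=120)
    plt.close(fig)
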