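"""Synthetic BCR repertoire simulator with known CD5 state-switching regime.

Emulates the data a clonality analysis consumes: one dominant leukemic clone
whose members radiate star-like (by point substitution only) from a single
central ancestor sequence, a polyclonal random background, CD5 high/low
labels assigned under one of three switching scenarios, paired sequencing
reads with substitution errors, and single-cell plate sampling with dropout
and doublets.

Scenarios
---------
``A``  unidirectional high -> low: every cell is CD5-high except the full
       descendant subtree(s) of the founder cell(s) that switched.
``B``  mirror image (low -> high).
``C``  common bidirectional switching: each cell is low independently with
       probability ``switch_rate`` regardless of lineage.

Variant cells are organised into subclones (groups of cells sharing one
variant sequence). Each new subclone attaches to the central ancestor with
probability ``root_attachment`` (star-likeness) or to a uniformly chosen
existing subclone, and differs from its parent by exactly one fresh
substitution, so mutations nest along lineages, every variant is reachable
from the central sequence through single-substitution steps (the clone is
one connected component of the Hamming-1 network), and the variant
distance from the central sequence equals its subclone depth, with mean
``1/root_attachment``. By default ``root_attachment`` is derived from the
configured mean of ``distance_distribution``. Subclone cell counts follow
the abundance distribution; multi-cell subclones are what allows the same
variant sequence to be observed in both CD5 gates under common switching.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io

BASES = "ACGT"
#: lineage/sequence, state assignment, read emission, plate sampling
_STAGE_CLONE, _STAGE_STATES, _STAGE_READS, _STAGE_PLATE = 0, 1, 2, 3

DEFAULT_PRIMER_FWD = "ACGGTCTGACCTAGGAACCT"
DEFAULT_PRIMER_REV = "TGGTCACCGTCTCCTCAGGT"


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters or geometry."""


def _stage_rng(seed: int, stage: int, salt: int = 0) -> np.random.Generator:
    """Deterministic per-stage RNG sub-stream derived from the run seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage, salt)))


@dataclass
class SimulationConfig:
    """Parameters of one synthetic repertoire.

    ``central_fraction`` is the fraction of clone cells (hence, with constant
    reads per cell, of clone reads) carrying the unmutated central sequence.
    ``distance_distribution`` is ``("geometric", mean)``: the target mean
    Hamming distance of variant cells from the central sequence, realised
    by star-biased lineage growth with one substitution per lineage edge
    (``root_attachment`` defaults to ``1/mean``; setting it explicitly
    overrides the derivation). ``abundance_distribution`` is the geometric
    law of variant subclone cell counts. ``switch_rate`` is a probability
    for scenario C and an integer founder count for scenarios A/B.
    """

    seed: int = 0
    sequence_length: int = 300
    clone_cells: int = 1000
    background_clones: int = 50
    central_fraction: float = 0.85
    distance_distribution: tuple[str, float] = ("geometric", 1.5)
    abundance_distribution: tuple[str, float] = ("geometric", 3.0)
    root_attachment: float | None = None  # default: 1 / distance mean
    scenario: str = "C"
    switch_rate: float = 0.15
    reads_per_cell: int = 10
    error_rate: float = 0.001
    low_quality_fraction: float = 0.0
    primer_fwd: str = DEFAULT_PRIMER_FWD
    primer_rev: str = DEFAULT_PRIMER_REV
    read_length: int = 220
    read_length_rev: int | None = None  # defaults to read_length
    overlap_length: int = 100

    def __post_init__(self) -> None:
        for name in ("central_fraction", "error_rate", "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.central_fraction <= 1.0:
            raise ConfigurationError("central_fraction must be in (0, 1]")
        if self.clone_cells < 1:
            raise ConfigurationError("clone_cells must be >= 1")
        if self.sequence_length <= 2 * max(len(self.primer_fwd), len(self.primer_rev)):
            raise ConfigurationError("sequence_length must exceed twice the primer length")
        if self.root_attachment is not None and not 0.0 < self.root_attachment <= 1.0:
            raise ConfigurationError("root_attachment must be in (0, 1]")
        name, param = self.distance_distribution
        if name != "geometric" or param < 1.0:
            raise ConfigurationError(
                "distance_distribution must be ('geometric', mean) with mean >= 1"
            )
        aname, aparam = self.abundance_distribution
        if aname != "geometric" or aparam < 1.0:
            raise ConfigurationError(
                "abundance_distribution must be ('geometric', mean) with mean >= 1"
            )
        amplicon = len(self.primer_fwd) + self.sequence_length + len(self.primer_rev)
        rl_rev = self.read_length_rev if self.read_length_rev is not None else self.read_length
        if self.read_length > amplicon or rl_rev > amplicon:
            raise ConfigurationError("read length exceeds amplicon length")
        if self.read_length + rl_rev - amplicon != self.overlap_length:
            raise ConfigurationError(
                f"read geometry inconsistent: read lengths minus amplicon give an overlap of "
                f"{self.read_length + rl_rev - amplicon} but overlap_length = {self.overlap_length}"
            )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["distance_distribution"] = list(self.distance_distribution)
        d["abundance_distribution"] = list(self.abundance_distribution)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("distance_distribution", "abundance_distribution"):
            if key in d:
                d[key] = (d[key][0], float(d[key][1]))
        return cls(**d)


@dataclass
class SimulatedCell:
    cell_id: str
    bcr_sequence: str
    distance_from_central: int
    cd5_state: str | None = None  # "high" | "low" | None before assignment
    lineage_parent: str | None = None


@dataclass
class SimulationTruth:
    """Ground truth emitted by the simulator, fully reproducible from config."""

    central_sequence: str
    cells: list[SimulatedCell]
    background_sequences: list[tuple[str, int]]  # (sequence, read abundance)
    scenario: str | None
    seed: int
    config: SimulationConfig = field(repr=False)

    def cells_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "sequence": [c.bcr_sequence for c in self.cells],
                "distance": [c.distance_from_central for c in self.cells],
                "cd5_state": [c.cd5_state or "unassigned" for c in self.cells],
                "parent": [c.lineage_parent or "" for c in self.cells],
            }
        )

    def gate_cells(self, gate: str) -> list[SimulatedCell]:
        return [c for c in self.cells if c.cd5_state == gate]

    def children_map(self) -> dict[str, list[str]]:
        kids: dict[str, list[str]] = {c.cell_id: [] for c in self.cells}
        for c in self.cells:
            if c.lineage_parent is not None:
                kids[c.lineage_parent].append(c.cell_id)
        return kids

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells_table().to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
        pd.DataFrame(
            self.background_sequences, columns=["sequence", "abundance"]
        ).to_csv(outdir / "truth_background.tsv", sep="\t", index=False)
        (outdir / "config.json").write_text(self.config.to_json() + "\n")


def load_v_reference() -> list[tuple[str, str]]:
    """Packaged synthetic V-like reference segments (id, sequence)."""
    ref = resources.files("cd5switch").joinpath("data/vref_synthetic.fa")
    with resources.as_file(ref) as path:
        return _io.read_fasta(path)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray, central: str) -> str:
    """Substitute each position to a base different from the central base."""
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in BASES if b != central[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_clone(config: SimulationConfig) -> SimulationTruth:
    """Generate the clonal lineage, variant sequences and background.

    The central ancestor sequence is a packaged V-like segment extended by a
    random junction region to ``sequence_length``, so clone sequences retain
    V-gene similarity while background sequences are uniform random.
    CD5 states are left unassigned (see :func:`assign_cd5_states`).
    """
    rng = _stage_rng(config.seed, _STAGE_CLONE)
    L = config.sequence_length

    v_id, v_seq = load_v_reference()[0]
    if len(v_seq) >= L:
        central = v_seq[:L]
    else:
        central = v_seq + _random_seq(rng, L - len(v_seq))

    n_central = max(1, round(config.central_fraction * config.clone_cells))
    n_variant = config.clone_cells - n_central

    width = max(4, len(str(config.clone_cells)))
    cells: list[SimulatedCell] = [
        SimulatedCell(f"cell{0:0{width}d}", central, 0, None, None)
    ]
    for i in range(1, n_central):
        cells.append(SimulatedCell(f"cell{i:0{width}d}", central, 0, None, cells[0].cell_id))

    if n_variant > 0:
        # variant subclones on a star-biased lineage, one substitution per
        # edge: variant distance = subclone depth, mean 1/rho, and the clone
        # stays connected under the Hamming-1 edge rule
        mu = config.distance_distribution[1]
        rho = config.root_attachment if config.root_attachment is not None else 1.0 / mu
        size_mean = config.abundance_distribution[1]

        sub_parent: list[int] = []  # -1 = central ancestor
        sub_seq: list[str] = []
        sub_mut: list[frozenset[int]] = []
        sub_cells: list[int] = []
        seen = {central}
        assigned = 0
        while assigned < n_variant:
            i = len(sub_parent)
            parent = -1 if (i == 0 or rng.random() < rho) else int(rng.integers(0, i))
            base_seq = central if parent < 0 else sub_seq[parent]
            base_mut = frozenset() if parent < 0 else sub_mut[parent]
            free = [k for k in range(L) if k not in base_mut]
            delta = min(1, len(free))
            # distinct subclones carry distinct sequences (no homoplasy in a
            # substitution-only star model); retry the position/base draw
            for _attempt in range(50):
                new_pos = rng.choice(np.array(free), size=delta, replace=False)
                seq = _mutate(rng, base_seq, new_pos, central)
                if seq not in seen:
                    break
            seen.add(seq)
            m = min(int(rng.geometric(min(1.0, 1.0 / size_mean))), n_variant - assigned)
            sub_parent.append(parent)
            sub_seq.append(seq)
            sub_mut.append(base_mut | {int(k) for k in new_pos})
            sub_cells.append(m)
            assigned += m

        sub_lead: list[str] = []
        idx = n_central
        for s in range(len(sub_parent)):
            d = len(sub_mut[s])
            lead_parent = cells[0].cell_id if sub_parent[s] < 0 else sub_lead[sub_parent[s]]
            lead_id = f"cell{idx:0{width}d}"
            sub_lead.append(lead_id)
            cells.append(SimulatedCell(lead_id, sub_seq[s], d, None, lead_parent))
            idx += 1
            for _ in range(sub_cells[s] - 1):
                cells.append(
                    SimulatedCell(f"cell{idx:0{width}d}", sub_seq[s], d, None, lead_id)
                )
                idx += 1

    mean_ab = config.abundance_distribution[1]
    background = [
        (_random_seq(rng, L), int(rng.geometric(min(1.0, 1.0 / mean_ab))))
        for _ in range(config.background_clones)
    ]

    return SimulationTruth(
        central_sequence=central,
        cells=cells,
        background_sequences=background,
        scenario=None,
        seed=config.seed,
        config=config,
    )


def _subtree(children: dict[str, list[str]], root_id: str) -> set[str]:
    out, stack = set(), [root_id]
    while stack:
        node = stack.pop()
        if node in out:
            continue
        out.add(node)
        stack.extend(children[node])
    return out


def default_founders(truth: SimulationTruth, k: int) -> list[str]:
    """Pick ``k`` founder cells for rare-switch scenarios A/B.

    Founders are the variant cells whose descendant sub-lineages carry the
    most distinct sequences (ties: most cells; nested subtrees excluded),
    modelling early switch events whose progeny expanded and diversified
    into a detectable sorted population.
    """
    children = truth.children_map()
    variants = [c for c in truth.cells if c.distance_from_central > 0]
    if not variants:
        raise ConfigurationError("no variant cells to found a switch lineage")
    seq_of = {c.cell_id: c.bcr_sequence for c in truth.cells}

    def key(cid: str):
        sub = _subtree(children, cid)
        return (-len({seq_of[s] for s in sub}), -len(sub), cid)

    sized = sorted(((0, c.cell_id) for c in variants), key=lambda t: key(t[1]))
    chosen: list[str] = []
    covered: set[str] = set()
    for _, cid in sized:
        if cid in covered:
            continue
        chosen.append(cid)
        covered |= _subtree(children, cid)
        if len(chosen) == k:
            break
    return chosen


def assign_cd5_states(
    truth: SimulationTruth,
    scenario: str | None = None,
    switch_rate: float | None = None,
    seed: int | None = None,
    founder_cells: list[str] | None = None,
) -> SimulationTruth:
    """Fill ``cd5_state`` on every cell according to the switching scenario.

    Scenario A/B: ``switch_rate`` is the integer number of founder switch
    events; the full descendant subtree of each founder takes the switched
    state. Scenario C: each cell switches independently with probability
    ``switch_rate``. Mutates ``truth`` in place and returns it.
    """
    cfg = truth.config
    scenario = scenario if scenario is not None else cfg.scenario
    switch_rate = switch_rate if switch_rate is not None else cfg.switch_rate
    seed = seed if seed is not None else cfg.seed
    if scenario not in ("A", "B", "C"):
        raise ConfigurationError(f"unknown scenario {scenario!r}; expected A, B or C")
    rng = _stage_rng(seed, _STAGE_STATES)

    if scenario == "C":
        if not 0.0 <= switch_rate <= 1.0:
            raise ConfigurationError("scenario C switch_rate must be a probability")
        low = rng.random(len(truth.cells)) < switch_rate
        for cell, is_low in zip(truth.cells, low):
            cell.cd5_state = "low" if is_low else "high"
    else:
        k = int(switch_rate)
        if founder_cells is None:
            founder_cells = default_founders(truth, k) if k > 0 else []
        children = truth.children_map()
        switched: set[str] = set()
        for fid in founder_cells:
            switched |= _subtree(children, fid)
        base, flipped = ("high", "low") if scenario == "A" else ("low", "high")
        for cell in truth.cells:
            cell.cd5_state = flipped if cell.cell_id in switched else base
    truth.scenario = scenario
    return truth


def _median_lower(values: list[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _good_quality(rng: np.random.Generator, n: int) -> list[int]:
    q = list(rng.integers(30, 41, size=n))
    while _median_lower(q) < 33:
        q = [min(40, v + 3) for v in q]
    return [int(v) for v in q]


def _bad_quality(rng: np.random.Generator, n: int) -> list[int]:
    return [int(v) for v in rng.integers(20, 33, size=n)]


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for pos in hits:
        alternatives = [b for b in BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def emit_reads(
    truth: SimulationTruth,
    config: SimulationConfig | None = None,
    cells: list[SimulatedCell] | None = None,
    include_background: bool = True,
    seed: int | None = None,
    out_prefix: str | Path | None = None,
) -> tuple[list[tuple[str, str, str, str, str]], pd.DataFrame]:
    """Emit paired reads for the given cells (default: all clone cells).

    Each template is ``primer_fwd + bcr_sequence + primer_rev``; the forward
    read is its 5' prefix and the reverse read the reverse complement of its
    3' suffix, sharing an identical overlap of ``overlap_length`` bp before
    substitution errors are applied. Returns the read records
    ``(read_id, fwd_seq, fwd_qual, rev_seq, rev_qual)`` and an abundance
    table; optionally writes ``<prefix>_R1.fastq``/``_R2.fastq`` and
    ``<prefix>_abundance.tsv``.
    """
    config = config or truth.config
    if any(c.cd5_state is None for c in truth.cells):
        raise ConfigurationError("cd5_state not assigned; run assign_cd5_states first")
    seed = seed if seed is not None else config.seed
    rng = _stage_rng(seed, _STAGE_READS)
    cells = truth.cells if cells is None else cells
    rl = config.read_length
    rl_rev = config.read_length_rev if config.read_length_rev is not None else rl

    templates: list[tuple[str, str, int, str, int]] = []  # id, seq, n_reads, state, dist
    for c in cells:
        templates.append((c.cell_id, c.bcr_sequence, config.reads_per_cell, c.cd5_state, c.distance_from_central))
    if include_background:
        for i, (seq, ab) in enumerate(truth.background_sequences):
            templates.append((f"bg{i:04d}", seq, ab, "background", -1))

    records = []
    for tid, seq, n_reads, _state, _d in templates:
        amplicon = config.primer_fwd + seq + config.primer_rev
        for r in range(n_reads):
            fwd = _apply_errors(rng, amplicon[:rl], config.error_rate)
            rev = _apply_errors(rng, revcomp(amplicon[-rl_rev:]), config.error_rate)
            bad = rng.random() < config.low_quality_fraction
            make_q = _bad_quality if bad else _good_quality
            records.append(
                (
                    f"{tid}:{r}",
                    fwd,
                    _io.encode_phred(make_q(rng, rl)),
                    rev,
                    _io.encode_phred(make_q(rng, rl_rev)),
                )
            )

    abundance = pd.DataFrame(
        [(tid, seq, n, state, d) for tid, seq, n, state, d in templates],
        columns=["template_id", "sequence", "n_read_pairs", "cd5_state", "distance"],
    )

    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        _io.write_fastq(((rid, f, fq) for rid, f, fq, _, _ in records), f"{out_prefix}_R1.fastq")
        _io.write_fastq(((rid, r, rq) for rid, _, _, r, rq in records), f"{out_prefix}_R2.fastq")
        abundance.to_csv(f"{out_prefix}_abundance.tsv", sep="\t", index=False)
    return records, abundance


def sample_single_cells(
    truth: SimulationTruth,
    gate: str,
    n_wells: int = 96,
    dropout_rate: float = 0.3,
    doublet_rate: float = 0.02,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate sorting single cells from a CD5 gate into a plate.

    Each well fails with probability ``dropout_rate``, receives two cells
    with distinct sequences with probability ``doublet_rate`` (a
    multiple-signal well) and otherwise one cell drawn uniformly from the
    gated population. Returns a table (well_id, status, sequence, sequence2).
    """
    if gate not in ("high", "low"):
        raise ConfigurationError(f"gate must be 'high' or 'low', got {gate!r}")
    pool = truth.gate_cells(gate)
    if not pool:
        raise ConfigurationError(f"no cells in the {gate} gate")
    seed = seed if seed is not None else truth.config.seed
    rng = _stage_rng(seed, _STAGE_PLATE, salt=0 if gate == "high" else 1)
    unique_seqs = {c.bcr_sequence for c in pool}

    rows = []
    for w in range(n_wells):
        u = rng.random()
        well_id = f"{gate}_well{w:03d}"
        if u < dropout_rate:
            rows.append((well_id, "failed", "", ""))
        elif u < dropout_rate + doublet_rate and len(unique_seqs) >= 2:
            a = pool[rng.integers(0, len(pool))]
            b = pool[rng.integers(0, len(pool))]
            tries = 0
            while b.bcr_sequence == a.bcr_sequence and tries < 100:
                b = pool[rng.integers(0, len(pool))]
                tries += 1
            rows.append((well_id, "multiple", a.bcr_sequence, b.bcr_sequence))
        else:
            c = pool[rng.integers(0, len(pool))]
            rows.append((well_id, "single", c.bcr_sequence, ""))
    return pd.DataFrame(rows, columns=["well_id", "status", "sequence", "sequence2"])
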