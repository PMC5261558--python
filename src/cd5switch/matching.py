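"""Single-cell clonotype matching against the bulk leukemic clone.

A single-cell BCR sequence is called clonal either because it is identical
to some member of the bulk clonal cluster, or because it lies within a small
number of substitutions (default 3) of the clone's dominant (central)
sequence. Both criteria are reported separately; the headline clonal
fraction uses their union. Only single-signal wells enter the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network import CloneCluster
from .stats import hamming

DEFAULT_MAX_MISMATCH = 3


@dataclass
class MatchCall:
    call: str  # clonal_identical | clonal_near | non_clonal
    distance_to_dominant: int | None  # None when lengths differ
    in_cluster: bool


def match_cell(
    seq: str, clone: CloneCluster, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> MatchCall:
    """Classify one single-cell sequence against the bulk clone.

    ``clonal_identical``: equals any cluster member. ``clonal_near``: equal
    length and within ``max_mismatch`` substitutions of the dominant
    sequence. Unequal-length sequences are never rescued by alignment.
    """
    in_cluster = seq in clone.member_sequences
    if len(seq) == len(clone.central_sequence):
        dist = hamming(seq, clone.central_sequence)
    else:
        dist = None
    if in_cluster:
        call = "clonal_identical"
    elif dist is not None and dist <= max_mismatch:
        call = "clonal_near"
    else:
        call = "non_clonal"
    return MatchCall(call=call, distance_to_dominant=dist, in_cluster=in_cluster)


def annotate_plate(
    plate: pd.DataFrame, clone: CloneCluster, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> pd.DataFrame:
    """Add match calls to a plate table (columns: well_id, status, sequence).

    Non-single wells get match_call ``n/a``.
    """
    calls, dists = [], []
    for _, row in plate.iterrows():
        if row["status"] != "single" or not row["sequence"]:
            calls.append("n/a")
            dists.append(pd.NA)
        else:
            m = match_cell(str(row["sequence"]), clone, max_mismatch)
            calls.append(m.call)
            dists.append(m.distance_to_dominant if m.distance_to_dominant is not None else pd.NA)
    out = plate.copy()
    out["match_call"] = calls
    out["distance_to_dominant"] = dists
    return out


def clonal_fraction(wells: pd.DataFrame) -> tuple[float | None, dict[str, int]]:
    """Clonal fraction over single-signal wells, with the full count table.

    fraction = (clonal_identical + clonal_near) / single wells; ``None``
    when there are no usable wells.
    """
    counts = {
        "n_wells": len(wells),
        "failed": int((wells["status"] == "failed").sum()),
        "multiple": int((wells["status"] == "multiple").sum()),
        "single": int((wells["status"] == "single").sum()),
        "clonal_identical": int((wells["match_call"] == "clonal_identical").sum()),
        "clonal_near": int((wells["match_call"] == "clonal_near").sum()),
        "non_clonal": int((wells["match_call"] == "non_clonal").sum()),
    }
    if counts["single"] == 0:
        return None, counts
    frac = (counts["clonal_identical"] + counts["clonal_near"]) / counts["single"]
    return frac, counts
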