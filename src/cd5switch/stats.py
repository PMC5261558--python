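"""Statistics for the CD5 state-switching question.

Two complementary tests ask whether the CD5-high and CD5-low fractions of a
leukemic clone are a random mixture of the same diversifying population
(common/continuous switching) or distinct sub-lineages (a rare switch):

* a per-distance-class hypergeometric overlap test — given the clone's
  central sequence of length ``l``, a variant at Hamming distance ``d`` is
  one of ``C(l, d) * 3**d`` possible mutants; the probability of the two
  gates sharing at least the observed number of distance-``d`` variants by
  chance is an exact hypergeometric tail over that universe, pooled across
  distance classes with Fisher's method;
* a within/between mean pairwise-distance ratio whose null distribution is
  built by permuting gate labels over the pooled unique sequences — a ratio
  well below 1 means the gates form distinct sequence clusters.

A least-squares regression of per-variant subclonal frequencies between the
gates quantifies how similar the two population structures are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps


def mutation_combinations(l: int, d: int) -> int:
    """Number of distinct sequences at Hamming distance d from a fixed l-mer.

    Choose the d mutated positions, then one of three alternative bases at
    each: ``C(l, d) * 3**d``. Exact integer arithmetic.
    """
    if l < 0 or d < 0 or d > l:
        raise ValueError(f"require 0 <= d <= l, got l={l}, d={d}")
    return math.comb(l, d) * 3**d


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), as an exact rational.

    Computed by explicit tail summation with big-integer binomials, so it is
    exact for universes far beyond floating-point range.
    """
    if N < 0 or K < 0 or n < 0 or k < 0:
        raise ValueError(f"negative hypergeometric parameter: N={N}, K={K}, n={n}, k={k}")
    if K > N or n > N:
        raise ValueError(f"K and n must not exceed N (N={N}, K={K}, n={n})")
    lo = max(k, 0, K + n - N)
    hi = min(K, n)
    if lo > hi:
        return Fraction(0)
    total = math.comb(N, n)
    acc = 0
    for i in range(lo, hi + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(acc, total)


def _log(frac: Fraction) -> float:
    """Natural log of a positive rational, safe for huge numerators."""
    if frac <= 0:
        return float("-inf")
    return math.log(frac.numerator) - math.log(frac.denominator)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def _encode(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def distance_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise Hamming distance matrix over equal-length sequences."""
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("all sequences must have equal length")
    enc = _encode(seqs)
    return (enc[:, None, :] != enc[None, :, :]).sum(axis=2).astype(np.int64)


@dataclass
class OverlapTest:
    table: pd.DataFrame  # d, universe, n_high, n_low, n_shared, p_value, log10_p
    pooled_p: float
    pooled_log10_p: float
    method: str = "fisher"


def hypergeometric_overlap_test(
    high: set[str], low: set[str], central: str
) -> OverlapTest:
    """Test whether the gates share more variants than expected by chance.

    For each Hamming distance class ``d >= 1`` present in either gate, the
    universe is all ``C(l, d)*3**d`` possible mutants of the central
    sequence; the per-class p-value is the exact upper hypergeometric tail
    of the observed overlap. Classes with no overlap contribute p = 1. The
    pooled p-value combines the per-class tails with Fisher's method.
    The central sequence itself is excluded from both variant sets (the
    single shared ancestor is the given).
    """
    l = len(central)
    if any(len(s) != l for s in high | low):
        raise ValueError("all sequences must match the central sequence length")
    high_v = {s for s in high if s != central}
    low_v = {s for s in low if s != central}

    by_d_high: dict[int, set[str]] = {}
    by_d_low: dict[int, set[str]] = {}
    for s in high_v:
        by_d_high.setdefault(hamming(s, central), set()).add(s)
    for s in low_v:
        by_d_low.setdefault(hamming(s, central), set()).add(s)

    rows = []
    log_ps: list[float] = []
    for d in sorted(set(by_d_high) | set(by_d_low)):
        N = mutation_combinations(l, d)
        K = len(by_d_high.get(d, ()))
        n = len(by_d_low.get(d, ()))
        k = len(by_d_high.get(d, set()) & by_d_low.get(d, set()))
        p = hypergeom_sf_exact(k, N, K, n) if k > 0 else Fraction(1)
        log_p = _log(p)
        rows.append(
            {
                "d": d,
                "universe": N,
                "n_high": K,
                "n_low": n,
                "n_shared": k,
                "p_value": float(p),
                "log10_p": log_p / math.log(10),
            }
        )
        log_ps.append(log_p)

    table = pd.DataFrame(
        rows, columns=["d", "universe", "n_high", "n_low", "n_shared", "p_value", "log10_p"]
    )
    if log_ps:
        x2 = -2.0 * sum(log_ps)
        pooled_p = float(sps.chi2.sf(x2, 2 * len(log_ps)))
        # chi2.sf underflows around 1e-300; keep a log-scale summary too
        pooled_log10 = (
            math.log10(pooled_p)
            if pooled_p > 0
            else float(sps.chi2.logsf(x2, 2 * len(log_ps))) / math.log(10)
        )
    else:
        pooled_p, pooled_log10 = 1.0, 0.0
    return OverlapTest(table=table, pooled_p=pooled_p, pooled_log10_p=pooled_log10)


def pairwise_distance_means(
    high: set[str], low: set[str]
) -> tuple[float, float, float]:
    """Mean within-gate and between-gate pairwise Hamming distances and ratio.

    Within-distances pool all unordered pairs inside the high gate and
    inside the low gate; between-distances run over all high x low pairs of
    distinct sequences (a sequence observed in both gates is one sequence,
    not a zero-distance pair, so identical gates give ratio exactly 1).
    Unique sequences, unweighted by abundance.
    """
    hi, lo = sorted(high), sorted(low)
    if len(hi) < 2:
        raise ValueError("high set needs >= 2 unique sequences for within-distances")
    if len(lo) < 2:
        raise ValueError("low set needs >= 2 unique sequences for within-distances")
    seqs = hi + lo
    D = distance_matrix(seqs)
    nh = len(hi)
    iu_h = np.triu_indices(nh, k=1)
    iu_l = np.triu_indices(len(lo), k=1)
    within = np.concatenate([D[:nh, :nh][iu_h], D[nh:, nh:][iu_l]])
    between_block = D[:nh, nh:]
    distinct = np.array([[a != b for b in lo] for a in hi])
    if not distinct.any():
        raise ValueError("high and low sets share every sequence pairing; no between-pairs")
    between = between_block[distinct]
    mean_within = float(within.mean())
    mean_between = float(between.mean())
    if mean_between == 0:
        raise ValueError("mean between-group distance is zero")
    return mean_within, mean_between, mean_within / mean_between


@dataclass
class CoClusterTest:
    mean_within: float
    mean_between: float
    ratio: float
    n_boot: int
    null_ratios: np.ndarray = field(repr=False)
    p_value: float = float("nan")
    subsample_size: int = 0
    seed: int = 0


def _masked_ratio(D: np.ndarray, E: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> float:
    """Within/between ratio over index groups, skipping equal-string pairs."""
    iu1 = np.triu_indices(len(g1), k=1)
    iu2 = np.triu_indices(len(g2), k=1)
    w1 = D[np.ix_(g1, g1)][iu1][~E[np.ix_(g1, g1)][iu1]]
    w2 = D[np.ix_(g2, g2)][iu2][~E[np.ix_(g2, g2)][iu2]]
    eb = E[np.ix_(g1, g2)]
    between = D[np.ix_(g1, g2)][~eb]
    if between.size == 0 or between.mean() == 0:
        return 1.0
    within = np.concatenate([w1, w2])
    mw = within.mean() if within.size else 0.0
    return float(mw / between.mean())


def cocluster_bootstrap_test(
    high: set[str],
    low: set[str],
    n_boot: int = 1000,
    subsample_size: int | None = None,
    seed: int = 0,
) -> CoClusterTest:
    """Label-permutation test of whether the gates form distinct clusters.

    The observed statistic is the within/between mean-distance ratio. Null
    replicates pool both gates, permute the gate labels preserving group
    sizes, subsample each pseudo-group to ``min(subsample_size, group
    size)`` (default cap 200, so groups at desk scale are kept whole and
    the procedure is a plain label-permutation test) and recompute the
    ratio. One-sided: a small ratio indicates distinct clustering;
    ``p = (1 + #{null <= observed}) / (n_boot + 1)``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    mean_within, mean_between, ratio = pairwise_distance_means(high, low)
    hi, lo = sorted(high), sorted(low)
    seqs = hi + lo
    D = distance_matrix(seqs)
    arr = np.array(seqs)
    E = arr[:, None] == arr[None, :]  # equal-string pairs never count
    nh, nl = len(hi), len(lo)
    cap = max(2, subsample_size) if subsample_size is not None else 200
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    idx = np.arange(nh + nl)
    for b in range(n_boot):
        perm = rng.permutation(idx)
        g1, g2 = perm[:nh], perm[nh:]
        if len(g1) > cap:
            g1 = rng.choice(g1, size=cap, replace=False)
        if len(g2) > cap:
            g2 = rng.choice(g2, size=cap, replace=False)
        null[b] = _masked_ratio(D, E, g1, g2)
    p = (1 + int(np.sum(null <= ratio))) / (n_boot + 1)
    return CoClusterTest(
        mean_within=mean_within,
        mean_between=mean_between,
        ratio=ratio,
        n_boot=n_boot,
        null_ratios=null,
        p_value=p,
        subsample_size=cap,
        seed=seed,
    )


@dataclass
class SubclonalCorrelation:
    slope: float
    intercept: float
    r_squared: float
    n_shared: int
    only_high: list[str] = field(default_factory=list)
    only_low: list[str] = field(default_factory=list)


def subclonal_correlation(
    high_freqs: dict[str, float], low_freqs: dict[str, float]
) -> SubclonalCorrelation:
    """Least-squares regression of low-gate on high-gate variant frequencies.

    Only variants observed in both gates enter the fit; variants private to
    one gate are reported separately, never imputed as zero.
    """
    shared = sorted(set(high_freqs) & set(low_freqs))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared variants for a regression, got {len(shared)}")
    x = np.array([high_freqs[s] for s in shared])
    y = np.array([low_freqs[s] for s in shared])
    fit = sps.linregress(x, y)
    return SubclonalCorrelation(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_shared=len(shared),
        only_high=sorted(set(high_freqs) - set(low_freqs)),
        only_low=sorted(set(low_freqs) - set(high_freqs)),
    )


def clone_frequencies(members: list, sample_id: str) -> dict[str, float]:
    """Per-variant read frequencies within one sample's clone reads.

    ``members`` are UniqueSequence-like objects with ``sequence`` and
    ``sample_counts``; frequencies are normalised to the sample's total
    clone reads.
    """
    counts = {
        m.sequence: m.sample_counts.get(sample_id, 0)
        for m in members
        if m.sample_counts.get(sample_id, 0) > 0
    }
    total = sum(counts.values())
    if total == 0:
        return {}
    return {seq: n / total for seq, n in counts.items()}
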