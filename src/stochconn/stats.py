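"""Group-level statistics on fitted connectivity: connection-wise
permutation tests with z-scores, change maps, ranked directed changes,
excitation/inhibition balance and rank-sum comparisons of scalar
summaries."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortDataset

__all__ = [
    "PermutationTestResult",
    "ChangeMaps",
    "BalanceReport",
    "RankSumResult",
    "permutation_diff_test",
    "connectionwise_changes",
    "rank_changes",
    "balance_analysis",
    "ranksum_compare",
]

#: entries whose reference-group mean is below this fraction of the median
#: magnitude are masked in the relative change map
RELATIVE_FLOOR_FRACTION = 1e-3


@dataclass
class PermutationTestResult:
    observed_diff: float
    z_score: float
    p_left: float
    p_two_sided: float
    n_permutations: int
    seed: int | None
    degenerate: bool = False


@dataclass
class ChangeMaps:
    """Connection-wise group-difference maps (case minus reference)."""

    channel_ids: list[str]
    delta: np.ndarray  # mean_case - mean_reference, (N, N)
    zmap: np.ndarray
    p_two_sided: np.ndarray
    weighted: np.ndarray  # delta * z
    relative: np.ndarray  # (delta / |mean_reference|) * z, NaN-masked
    reference_mean: np.ndarray
    input_change: np.ndarray  # per-node row means of `weighted`
    output_change: np.ndarray  # per-node column means of `weighted`
    input_change_relative: np.ndarray
    output_change_relative: np.ndarray
    n_permutations: int
    seed: int | None


@dataclass
class BalanceReport:
    """Per-node excitation/inhibition sums and their absolute correlations.

    I+/I- are row sums of positive/negative entries (incoming weight onto a
    node); O+/O- are the corresponding column sums (outgoing weight)."""

    i_pos: np.ndarray
    i_neg: np.ndarray
    o_pos: np.ndarray
    o_neg: np.ndarray
    correlations: dict[str, float]  # absolute Pearson r; NaN when degenerate


@dataclass
class RankSumResult:
    statistic: float  # rank sum of the first sample (midranks)
    p_value: float
    exact: bool


def _nanmean_quiet(M: np.ndarray, axis: int) -> np.ndarray:
    """nanmean that returns NaN (without warning) on all-NaN slices."""
    mask = np.isfinite(M)
    counts = mask.sum(axis=axis)
    sums = np.where(mask, M, 0.0).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def permutation_diff_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> PermutationTestResult:
    """Difference-of-means permutation test.

    The pooled values are randomly re-partitioned into groups of the
    original sizes; the z-score is the observed difference divided by the
    null standard deviation, `p_left` is the null mass at or below the
    observed value, and `p_two_sided` the null mass with absolute
    difference at least as large.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return PermutationTestResult(observed, 0.0, 1.0, 1.0, n_perm, seed, True)
    rng = np.random.default_rng(seed)
    n, m = a.size, b.size
    total = pooled.sum()
    # vectorized permutations: random order via argsort of uniforms
    order = np.argsort(rng.random((n_perm, n + m)), axis=1)
    sum_a = pooled[order[:, :n]].sum(axis=1)
    null = sum_a / n - (total - sum_a) / m
    sd = float(null.std(ddof=1))
    if sd == 0:
        return PermutationTestResult(observed, 0.0, 1.0, 1.0, n_perm, seed, True)
    z = observed / sd
    # tolerance so partitions tying the observed value exactly (e.g. the
    # identity re-partition) are counted despite summation-order rounding
    tol = 1e-12 * max(abs(observed), np.max(np.abs(pooled)), 1.0)
    p_left = float(np.mean(null <= observed + tol))
    p_two = float(np.mean(np.abs(null) >= abs(observed) - tol))
    return PermutationTestResult(observed, z, p_left, p_two, n_perm, seed, False)


def connectionwise_changes(
    cohort: CohortDataset,
    n_perm: int = 10_000,
    seed: int | None = 0,
    chunk: int = 500,
) -> ChangeMaps:
    """Run the difference-of-means permutation test on every ordered
    channel pair and assemble the change maps.

    All N^2 tests share one set of group re-partitions (each test's
    marginal null is unchanged); permutations are processed in chunks to
    bound memory at full sensor counts.
    """
    ref_label, case_label = cohort.groups
    W_ref = cohort.connectivity_stack(ref_label)
    W_case = cohort.connectivity_stack(case_label)
    n_ref, n_case = len(W_ref), len(W_case)
    if n_ref == 0 or n_case == 0:
        raise ValueError("both groups must contain fitted subjects")
    N = W_ref.shape[1]
    flat = np.concatenate([W_case, W_ref]).reshape(n_case + n_ref, -1)
    mean_case = flat[:n_case].mean(axis=0)
    mean_ref = flat[n_case:].mean(axis=0)
    delta = mean_case - mean_ref
    total = flat.sum(axis=0)

    rng = np.random.default_rng(seed)
    S = n_case + n_ref
    sum_sq = np.zeros_like(delta)
    sum_null = np.zeros_like(delta)
    count_two = np.zeros_like(delta)
    tol = 1e-12 * max(float(np.max(np.abs(flat))), 1.0)
    abs_delta = np.abs(delta) - tol
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        order = np.argsort(rng.random((size, S)), axis=1)
        sum_a = flat[order[:, :n_case]].sum(axis=1)  # (size, N^2)
        null = sum_a / n_case - (total - sum_a) / n_ref
        sum_null += null.sum(axis=0)
        sum_sq += (null**2).sum(axis=0)
        count_two += (np.abs(null) >= abs_delta).sum(axis=0)
        done += size
    mean_null = sum_null / n_perm
    var_null = (sum_sq - n_perm * mean_null**2) / (n_perm - 1)
    sd = np.sqrt(np.clip(var_null, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zflat = np.where(sd > 0, delta / sd, 0.0)
    p_two = count_two / n_perm
    p_two[sd == 0] = 1.0

    zmap = zflat.reshape(N, N)
    delta_m = delta.reshape(N, N)
    ref_m = mean_ref.reshape(N, N)
    weighted = delta_m * zmap
    floor = RELATIVE_FLOOR_FRACTION * np.median(np.abs(ref_m))
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.where(
            np.abs(ref_m) >= floor, delta_m / np.abs(ref_m) * zmap, np.nan
        )
    return ChangeMaps(
        channel_ids=cohort.channel_ids,
        delta=delta_m,
        zmap=zmap,
        p_two_sided=p_two.reshape(N, N),
        weighted=weighted,
        relative=relative,
        reference_mean=ref_m,
        input_change=weighted.mean(axis=1),
        output_change=weighted.mean(axis=0),
        input_change_relative=_nanmean_quiet(relative, axis=1),
        output_change_relative=_nanmean_quiet(relative, axis=0),
        n_permutations=n_perm,
        seed=seed,
    )


def rank_changes(maps: ChangeMaps, k: int, kind: str = "weighted") -> pd.DataFrame:
    """Top-k directed connection changes, sorted by decreasing |value|.

    `kind` selects the z-weighted absolute ('weighted') or relative
    ('relative') map.  Self-loops are excluded (arrows connect distinct
    sensors); ties are broken by (row, column) index order.  Returns a
    DataFrame with columns source, target, value — `source` is the channel
    exerting the coupling (column index j), `target` the one receiving it
    (row index i).
    """
    if kind not in ("weighted", "relative"):
        raise ValueError("kind must be 'weighted' or 'relative'")
    M = maps.weighted if kind == "weighted" else maps.relative
    N = M.shape[0]
    if k < 0 or k > N * N - N:
        raise ValueError(f"k must be in [0, {N * N - N}]")
    rows = []
    for i in range(N):
        for j in range(N):
            if i == j or not np.isfinite(M[i, j]):
                continue
            rows.append((-abs(M[i, j]), i, j, M[i, j]))
    rows.sort()
    ids = maps.channel_ids
    top = rows[:k]
    return pd.DataFrame(
        [(ids[j], ids[i], v) for _, i, j, v in top],
        columns=["source", "target", "value"],
    )


def _abs_corr(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        return float("nan")
    return float(abs(np.corrcoef(u, v)[0, 1]))


def balance_analysis(W: np.ndarray) -> BalanceReport:
    """Per-node excitatory/inhibitory input and output sums and the six
    absolute correlations among them."""
    W = np.asarray(W, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    pos = np.clip(W, 0.0, None)
    neg = np.clip(W, None, 0.0)
    i_pos, i_neg = pos.sum(axis=1), neg.sum(axis=1)
    o_pos, o_neg = pos.sum(axis=0), neg.sum(axis=0)
    corr = {
        "I+/I-": _abs_corr(i_pos, i_neg),
        "O+/O-": _abs_corr(o_pos, o_neg),
        "I+/O+": _abs_corr(i_pos, o_pos),
        "I+/O-": _abs_corr(i_pos, o_neg),
        "I-/O+": _abs_corr(i_neg, o_pos),
        "I-/O-": _abs_corr(i_neg, o_neg),
    }
    return BalanceReport(i_pos=i_pos, i_neg=i_neg, o_pos=o_pos, o_neg=o_neg, correlations=corr)


def ranksum_compare(values_a: np.ndarray, values_b: np.ndarray) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with midrank ties.

    Uses exhaustive enumeration of all group re-partitions when
    n + m <= 12, otherwise the normal approximation with tie-corrected
    variance and continuity correction.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[:n].sum())
    if n + m <= 12:
        total = ranks.sum()
        mean_w = n * total / (n + m)
        dev_obs = abs(w_obs - mean_w)
        count = 0
        n_part = 0
        for combo in itertools.combinations(range(n + m), n):
            w = ranks[list(combo)].sum()
            if abs(w - mean_w) >= dev_obs - 1e-12:
                count += 1
            n_part += 1
        return RankSumResult(statistic=w_obs, p_value=count / n_part, exact=True)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(statistic=w_obs, p_value=float(res.pvalue), exact=False)
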