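"""Microarray differential expression: quantile normalization, median
polish summarization, signal-to-noise statistic and permutation p-values.

The statistic for a probe is

    SNR = (mean_treated - mean_control) / (sd_treated + sd_control)

with sample standard deviations, and nominal p-values taken from the
left/right tails of an empirical null built by permuting sample
labels (optionally pooling the null across probes). A probe is
called differentially expressed when its two-sided p-value is at most
0.01 and its absolute linear fold change is at least 1.2.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force all columns to share the same (mean) sorted distribution."""
    arr = df.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ranks = np.empty_like(order)
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = np.arange(arr.shape[0])
    means = np.sort(arr, axis=0).mean(axis=1)
    out = means[ranks]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def median_polish(
    matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Additive decomposition overall + row + column + residual.

    Alternating row/column median sweeps, as used to summarize the
    rows of a multi-row probe into one value per sample
    (overall + column effect).
    """
    resid = np.asarray(matrix, dtype=float).copy()
    nr, nc = resid.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(row)
        overall += cmed_of_row
        row -= cmed_of_row
        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(col)
        overall += rmed_of_col
        col -= rmed_of_col
        if np.abs(rmed).sum() + np.abs(cmed).sum() < tol:
            break
    return overall, row, col, resid


def normalize(raw: pd.DataFrame, log2_input: bool = False) -> pd.DataFrame:
    """log2-transform, quantile normalize, and median-polish summarize.

    ``raw`` is probes x samples with positive intensities (or already
    log2 with ``log2_input=True``); rows sharing an index value are
    treated as one multi-row probe and summarized into a single row.
    """
    arr = raw.to_numpy(dtype=float)
    if not log2_input:
        if (arr <= 0).any():
            raise ValueError("raw intensities must be positive for log2 transform")
        logged = pd.DataFrame(np.log2(arr), index=raw.index, columns=raw.columns)
    else:
        logged = raw.astype(float)
    normed = quantile_normalize(logged)
    if normed.index.is_unique:
        return normed
    rows = []
    index = []
    for probe in normed.index.unique():
        block = normed.loc[[probe]].to_numpy()
        if block.shape[0] == 1:
            rows.append(block[0])
        else:
            overall, _, col, _ = median_polish(block)
            rows.append(overall + col)
        index.append(probe)
    return pd.DataFrame(rows, index=index, columns=normed.columns)


# ---------------------------------------------------------------------------
# Signal-to-noise statistic and permutation p-values
# ---------------------------------------------------------------------------


def snr_statistic(
    treated: Sequence[float],
    control: Sequence[float],
    eps: float = 0.01,
    floor_frac: float = 0.0,
) -> float:
    """(mean_t - mean_c) / (sd_t + sd_c), with an sd floor.

    Each group sd is floored at max(eps, floor_frac * |group mean|)
    so replicate-identical groups do not divide by zero; with both
    floors disabled and zero sds this raises.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("need >= 2 replicates per group")
    sd_t, sd_c = t.std(ddof=1), c.std(ddof=1)
    floor_t = max(eps, floor_frac * abs(t.mean()))
    floor_c = max(eps, floor_frac * abs(c.mean()))
    sd_t, sd_c = max(sd_t, floor_t), max(sd_c, floor_c)
    if sd_t + sd_c == 0:
        raise ValueError("zero variance in both groups and sd floor disabled")
    return float((t.mean() - c.mean()) / (sd_t + sd_c))


def _snr_rows(arr: np.ndarray, treated_idx: np.ndarray, control_idx: np.ndarray, eps: float) -> np.ndarray:
    t = arr[:, treated_idx]
    c = arr[:, control_idx]
    sd_t = np.maximum(t.std(axis=1, ddof=1), eps)
    sd_c = np.maximum(c.std(axis=1, ddof=1), eps)
    return (t.mean(axis=1) - c.mean(axis=1)) / (sd_t + sd_c)


def permutation_pvalues(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    pool_probes: bool = True,
    exhaustive: bool = False,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Left/right/two-sided permutation p-values for the SNR statistic.

    The null is built by relabeling samples ``n_perm`` times (or by
    exhaustively enumerating all distinct treated-group choices with
    ``exhaustive=True``); with ``pool_probes`` the null pools SNR
    values across probes. Random mode uses the +1 pseudocount
    estimator p = (1 + #{null >= obs}) / (1 + N); exhaustive mode
    reports exact enumeration frequencies (the identity labeling is
    part of the enumeration, so p > 0). Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = list(groups)
    labels = np.asarray(groups)
    treated_idx = np.flatnonzero(labels == "treated")
    control_idx = np.flatnonzero(labels == "control")
    arr = matrix.to_numpy(dtype=float)
    obs = _snr_rows(arr, treated_idx, control_idx, eps)

    n_samples = arr.shape[1]
    if exhaustive:
        combos = list(combinations(range(n_samples), len(treated_idx)))
        null_cols = []
        for combo in combos:
            t_idx = np.array(combo)
            c_idx = np.array([i for i in range(n_samples) if i not in combo])
            null_cols.append(_snr_rows(arr, t_idx, c_idx, eps))
        null = np.stack(null_cols, axis=1)  # probes x relabelings
        if pool_probes:
            flat = null.ravel()
            p_right = np.array([(flat >= o).mean() for o in obs])
            p_left = np.array([(flat <= o).mean() for o in obs])
        else:
            p_right = (null >= obs[:, None]).mean(axis=1)
            p_left = (null <= obs[:, None]).mean(axis=1)
    else:
        rng = np.random.default_rng(seed)
        ge = np.zeros(len(obs))
        le = np.zeros(len(obs))
        n_null = 0
        for _ in range(n_perm):
            perm = rng.permutation(n_samples)
            t_idx = perm[: len(treated_idx)]
            c_idx = perm[len(treated_idx) :]
            null_snr = _snr_rows(arr, t_idx, c_idx, eps)
            if pool_probes:
                srt = np.sort(null_snr)
                ge += len(srt) - np.searchsorted(srt, obs, side="left")
                le += np.searchsorted(srt, obs, side="right")
                n_null += len(srt)
            else:
                ge += null_snr >= obs
                le += null_snr <= obs
                n_null += 1
        p_right = (1 + ge) / (1 + n_null)
        p_left = (1 + le) / (1 + n_null)

    p_two = np.minimum(1.0, 2 * np.minimum(p_left, p_right))
    return pd.DataFrame(
        {"snr": obs, "p_left": p_left, "p_right": p_right, "p_two": p_two},
        index=matrix.index,
    )


def signed_fold_change(matrix: pd.DataFrame, groups: Sequence[str]) -> pd.Series:
    """Linear fold change from mean log2 difference, sign-folded.

    2^d for upregulated probes, -2^(-d) for downregulated, so that
    |FC| >= threshold reads the same in both directions.
    """
    labels = np.asarray(list(groups))
    arr = matrix.to_numpy(dtype=float)
    d = arr[:, labels == "treated"].mean(axis=1) - arr[:, labels == "control"].mean(axis=1)
    fc = np.where(d >= 0, 2.0**d, -(2.0 ** (-d)))
    return pd.Series(fc, index=matrix.index, name="fold_change")


def de_table(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    p_threshold: float = 0.01,
    fc_threshold: float = 1.2,
    pool_probes: bool = True,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Per-probe DE statistics with the p and fold-change gate applied."""
    stats = permutation_pvalues(
        matrix, groups, n_perm=n_perm, seed=seed, pool_probes=pool_probes, exhaustive=exhaustive
    )
    stats["fold_change"] = signed_fold_change(matrix, groups)
    stats["significant"] = (stats["p_two"] <= p_threshold) & (
        stats["fold_change"].abs() >= fc_threshold
    )
    return stats


def gate_and_intersect(
    stats: pd.DataFrame, target_gene_lists: Mapping[str, Iterable[str]] | None = None
) -> tuple[set[str], dict[str, set[str]]]:
    """Significant probe set and its intersection with target gene lists."""
    significant = set(stats.index[stats["significant"]])
    intersections = {}
    if target_gene_lists:
        for name, genes in target_gene_lists.items():
            intersections[name] = significant & set(genes)
    return significant, intersections
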