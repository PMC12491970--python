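"""Compositional ordination: CLR transform, PCA, and PERMANOVA.

Beta diversity is analyzed in Aitchison geometry: each sample is mapped by
the centered log-ratio (CLR) transform, y_i = ln(x_i + pc) - mean_j ln(x_j +
pc), after which Euclidean distance, PCA and the PERMANOVA pseudo-F are
meaningful for compositions.  PERMANOVA supports both Monte-Carlo label
permutation and exact enumeration of all distinct label assignments (small
cohorts), plus pairwise multilevel comparisons with Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "clr_transform",
    "default_pseudocount",
    "pca",
    "permanova",
    "pairwise_permanova",
]


@dataclass
class OrdinationResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # features x components
    variance_explained: np.ndarray  # fraction per retained component
    loading_scale: float = 1.0    # display multiplier applied to loadings


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_perm: float
    n_permutations: int
    method: str  # "monte_carlo" or "exhaustive"


def default_pseudocount(values: pd.DataFrame, unit: str) -> float:
    """Zero-replacement default: 1 for counts, half the minimum positive
    value for relative abundances."""
    if unit == "count":
        return 1.0
    arr = values.to_numpy(dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("table has no positive values")
    return float(positive.min() / 2.0)


def clr_transform(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of a samples x features table.

    Each row becomes ln(x + pc) minus its mean, so rows sum to zero.  A zero
    pseudocount is only valid on strictly positive tables.
    """
    arr = values.to_numpy(dtype=float) + pseudocount
    if (arr <= 0).any():
        raise ValueError("CLR requires strictly positive values; increase the pseudocount")
    logs = np.log(arr)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=values.index, columns=values.columns)


def pca(clr_matrix: pd.DataFrame, n_components: int | None = None, loading_scale: float = 1.0) -> OrdinationResult:
    """PCA of a (CLR-transformed) matrix by SVD of the column-centered data.

    ``variance_explained`` is eigenvalue fractions over the full rank, so it
    sums to 1 when all components are retained.  Sign convention: the
    largest-magnitude loading of each component is positive.  ``loading_scale``
    is a cosmetic display multiplier recorded in the result.
    """
    X = clr_matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2
    total = eig.sum()
    var_frac = eig / total if total > 0 else np.zeros_like(eig)
    # deterministic sign: flip so each component's extreme loading is positive
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    comps = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * s[:n_components], index=clr_matrix.index, columns=comps
    )
    loadings = pd.DataFrame(
        Vt[:n_components].T * loading_scale, index=clr_matrix.columns, columns=comps
    )
    return OrdinationResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_frac[:n_components],
        loading_scale=loading_scale,
    )


def _group_sums_of_squares(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from a squared-distance matrix and group codes."""
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        ix = np.flatnonzero(codes == g)
        if len(ix):
            ss_within += d2[np.ix_(ix, ix)].sum() / (2.0 * len(ix))
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """PERMANOVA pseudo-F and R2 for one labeling."""
    n = len(codes)
    ss_total, ss_within = _group_sums_of_squares(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    denom = ss_within / (n - n_groups)
    if denom == 0:
        return np.inf, r2
    return (ss_between / (n_groups - 1)) / denom, r2


def _distinct_labelings(codes: np.ndarray):
    """Yield every distinct assignment of the multiset of group codes."""
    n = len(codes)
    counts = np.bincount(codes)

    # choose positions for each group code in turn
    def assign(free: frozenset[int], g: int, current: dict[int, int]):
        if g == len(counts):
            arr = np.empty(n, dtype=int)
            for pos, code in current.items():
                arr[pos] = code
            yield arr
            return
        k = counts[g]
        for chosen in combinations(sorted(free), k):
            nxt = dict(current)
            for pos in chosen:
                nxt[pos] = g
            yield from assign(free - set(chosen), g + 1, nxt)

    yield from assign(frozenset(range(n)), 0, {})


def permanova(
    clr_matrix: pd.DataFrame,
    groups,
    n_permutations: int = 9_999,
    seed: int | None = 0,
    method: str = "monte_carlo",
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean (Aitchison) distances.

    ``pseudo_F = (SS_between/(g-1)) / (SS_within/(n-g))`` computed from
    pairwise squared distances.  ``monte_carlo`` draws ``n_permutations``
    uniform label permutations with the given seed and reports
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)``; ``exhaustive``
    enumerates every distinct label assignment (feasible for small n) and
    reports the exact tail fraction including the observed labeling.
    """
    groups = np.asarray(groups)
    if len(groups) != len(clr_matrix.index):
        raise ValueError("groups length must match number of samples")
    labels, codes = np.unique(groups, return_inverse=True)
    n_groups = len(labels)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = labels[sizes < 2]
        raise ValueError(f"groups need >= 2 samples: {list(small)}")

    d2 = squareform(pdist(clr_matrix.to_numpy(dtype=float), metric="euclidean") ** 2)
    f_obs, r2 = _pseudo_f(d2, codes, n_groups)

    if method == "exhaustive":
        n_assign = 0
        n_extreme = 0
        for labeling in _distinct_labelings(codes):
            f_perm, _ = _pseudo_f(d2, labeling, n_groups)
            n_assign += 1
            if f_perm >= f_obs - 1e-12 * max(1.0, abs(f_obs)) or (
                np.isinf(f_perm) and np.isinf(f_obs)
            ):
                n_extreme += 1
        return PermanovaResult(
            pseudo_F=float(f_obs),
            R2=float(r2),
            p_perm=n_extreme / n_assign,
            n_permutations=n_assign,
            method="exhaustive",
        )
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_perm, _ = _pseudo_f(d2, perm, n_groups)
        if f_perm >= f_obs - 1e-12 * max(1.0, abs(f_obs)) or (
            np.isinf(f_perm) and np.isinf(f_obs)
        ):
            n_extreme += 1
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p_perm=(1 + n_extreme) / (1 + n_permutations),
        n_permutations=n_permutations,
        method="monte_carlo",
    )


def pairwise_permanova(
    clr_matrix: pd.DataFrame,
    groups,
    n_permutations: int = 9_999,
    seed: int | None = 0,
    method: str = "monte_carlo",
) -> pd.DataFrame:
    """Multilevel pairwise PERMANOVA with BH adjustment across group pairs."""
    groups = pd.Series(np.asarray(groups), index=clr_matrix.index)
    labels = pd.unique(groups)
    rows = []
    for i, (a, b) in enumerate(combinations(labels, 2)):
        mask = groups.isin([a, b])
        res = permanova(
            clr_matrix.loc[mask],
            groups[mask].to_numpy(),
            n_permutations=n_permutations,
            seed=None if seed is None else seed + i,
            method=method,
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_F": res.pseudo_F,
                "R2": res.R2,
                "p_raw": res.p_perm,
                "n_permutations": res.n_permutations,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out
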