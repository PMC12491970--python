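"""Alpha diversity: Shannon index with Kruskal-Wallis + Dunn post-hoc tests.

Shannon entropy is computed in nats by default (the convention of the vegan
ecology stack); group differences are tested with the Kruskal-Wallis omnibus
followed by Dunn's pairwise z tests on the pooled mid-ranks with tie
correction, Benjamini-Hochberg adjusted across pairs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["shannon", "shannon_per_sample", "kruskal_dunn"]


def shannon(sample_abundances, base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i of one abundance vector.

    Zeros are excluded from the sum; ``base`` defaults to e (nats).
    """
    x = np.asarray(sample_abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("sample has no positive abundance")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannon_per_sample(values: pd.DataFrame, base: float | None = None) -> pd.Series:
    """Shannon index for every row of a samples x features table."""
    return pd.Series(
        [shannon(row, base=base) for _, row in values.iterrows()],
        index=values.index,
        name="shannon",
    )


def kruskal_dunn(values, groups, p_adjust: str = "fdr_bh") -> dict:
    """Kruskal-Wallis omnibus plus Dunn's pairwise post-hoc tests.

    Ranks are mid-ranks over the pooled data; the Dunn z for groups A, B is
    ``(meanrank_A - meanrank_B) / sqrt((N(N+1)/12 - T/(12(N-1)))(1/nA + 1/nB))``
    with the tie term ``T = sum(t^3 - t)`` over tied value groups.  Pairwise
    p-values are two-sided normal and adjusted across pairs (BH by default,
    ``"bonferroni"`` optional).

    Returns a dict with ``kruskal_H``, ``kruskal_p`` and a ``pairwise``
    DataFrame (group_a, group_b, z, p_raw, p_adj).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lbl in labels:
        if (groups == lbl).sum() == 0:
            raise ValueError(f"empty group {lbl!r}")

    n_total = len(values)
    if np.ptp(values) == 0:
        kw_h, kw_p = 0.0, 1.0
    else:
        kw_h, kw_p = stats.kruskal(*[values[groups == lbl] for lbl in labels])

    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(labels, 2):
        ra, rb = ranks[groups == a], ranks[groups == b]
        denom = np.sqrt(var_unit * (1.0 / len(ra) + 1.0 / len(rb)))
        z = 0.0 if denom == 0 else float((ra.mean() - rb.mean()) / denom)
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p_raw"], method=p_adjust)[1]
    return {"kruskal_H": float(kw_h), "kruskal_p": float(kw_p), "pairwise": pairwise}
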