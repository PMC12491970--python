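"""Two-group negative-binomial Wald differential abundance on species counts.

A deliberately simplified DESeq2-style pipeline: a pseudocount of 1 is added
to raw counts, samples are normalized by median-of-ratios size factors,
per-feature dispersion is estimated by a pooled within-group method of
moments, and the group contrast is tested with a Wald z on the log2 fold
change using the delta-method standard error of the NB log-mean.  P-values
are Benjamini-Hochberg adjusted; significance is called at adjusted p < 0.05.

The full DESeq2 machinery (Cox-Reid dispersion fitting, dispersion-trend and
LFC shrinkage, independent filtering, outlier replacement) is intentionally
not reproduced; results on identical input will differ from DESeq2's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profile_io import SampleMeta, TaxonTable

__all__ = ["DaaRecord", "size_factors", "nb_wald_test", "rank_top", "records_frame", "CONTRASTS"]

#: contrast name -> (metadata column, contrast level(s), reference level(s))
CONTRASTS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    "Q3Q4_vs_Q1Q2": ("age_quartile", ("Q3", "Q4"), ("Q1", "Q2")),
    "HSIL_vs_healthy": ("status", ("HSIL",), ("healthy",)),
    "LS_vs_healthy": ("status", ("LS",), ("healthy",)),
}

DISPERSION_FLOOR = 1e-8
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class DaaRecord:
    feature_id: str
    base_mean: float
    log2fc: float
    se_log2fc: float
    wald_z: float
    p_raw: float
    p_adj: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.p_adj < 0.05)


def size_factors(count_table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    ``s_j = median_i(c_ij / geometric_mean_i)`` over features whose geometric
    mean is positive (features with any zero are excluded from the median, as
    in the reference normalization).  Operates on the matrix as given; the
    caller is responsible for any pseudocount.
    """
    arr = count_table.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    usable = np.isfinite(log_arr).all(axis=0)
    if not usable.any():
        raise ValueError("no feature with all-positive counts; size factors undefined")
    gm = np.exp(log_arr[:, usable].mean(axis=0))
    s_raw = np.median(arr[:, usable] / gm[np.newaxis, :], axis=1)
    s = s_raw / np.exp(np.log(s_raw).mean())  # geometric mean 1
    return pd.Series(s, index=count_table.index, name="size_factor")


def _resolve_groups(meta: SampleMeta, contrast) -> tuple[pd.Index, pd.Index, str]:
    """Sample ids of the contrast and reference groups for a named contrast
    or a user-supplied (column, contrast_levels, reference_levels) triple."""
    if isinstance(contrast, str):
        if contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {contrast!r}; define a custom triple")
        column, test_levels, ref_levels = CONTRASTS[contrast]
        name = contrast
    else:
        column, test_levels, ref_levels = contrast
        test_levels = tuple(np.atleast_1d(test_levels))
        ref_levels = tuple(np.atleast_1d(ref_levels))
        name = f"{'_'.join(test_levels)}_vs_{'_'.join(ref_levels)}"
    if column not in meta.table.columns:
        raise ValueError(f"metadata has no column {column!r}")
    col = meta.table[column]
    test_ids = col.index[col.isin(test_levels)]
    ref_ids = col.index[col.isin(ref_levels)]
    if len(test_ids) < 2 or len(ref_ids) < 2:
        raise ValueError(
            f"contrast {name}: both groups need >= 2 samples "
            f"(got {len(test_ids)} vs {len(ref_ids)})"
        )
    return test_ids, ref_ids, name


def _pooled_dispersion(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion pooled within groups.

    For each group, alpha_g = (var - mean) / mean^2 on normalized counts;
    groups are combined with (n_g - 1)/(n - 2) weights so the group-mean
    difference does not inflate the dispersion estimate.
    """
    n_a, n_b = norm_a.shape[0], norm_b.shape[0]
    w_a = (n_a - 1) / (n_a + n_b - 2)
    alphas = []
    for grp in (norm_a, norm_b):
        m = grp.mean(axis=0)
        v = grp.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        alphas.append(np.where(np.isfinite(a), a, 0.0))
    alpha = w_a * alphas[0] + (1 - w_a) * alphas[1]
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(
    count_table: TaxonTable | pd.DataFrame,
    meta: SampleMeta,
    contrast,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    relabund_library_size: int = 100_000,
) -> tuple[list[DaaRecord], list[str]]:
    """NB Wald differential abundance for one two-group contrast.

    Returns the per-feature records (BH-adjusted) and the list of features
    skipped because they are all-zero in both groups.  Relative-abundance
    tables are converted to pseudo-counts at ``relabund_library_size`` with a
    warning, since the test is defined on counts.
    """
    if isinstance(count_table, TaxonTable):
        values = count_table.values
        if count_table.unit == "relabund":
            import warnings

            warnings.warn(
                "relative abundances converted to pseudo-counts "
                f"(library size {relabund_library_size})",
                stacklevel=2,
            )
            values = (values * relabund_library_size).round()
    else:
        values = count_table
    test_ids, ref_ids, _ = _resolve_groups(meta, contrast)
    test_ids = [s for s in test_ids if s in values.index]
    ref_ids = [s for s in ref_ids if s in values.index]
    both = values.loc[list(test_ids) + list(ref_ids)]

    skipped = [f for f in both.columns if (both[f] == 0).all()]
    kept = [f for f in both.columns if f not in skipped]
    pseudo = both[kept] + pseudocount
    sf = size_factors(pseudo)
    norm = pseudo.div(sf, axis=0)
    norm_t = norm.loc[test_ids].to_numpy(dtype=float)
    norm_r = norm.loc[ref_ids].to_numpy(dtype=float)
    n_t, n_r = norm_t.shape[0], norm_r.shape[0]

    mu_t = norm_t.mean(axis=0)
    mu_r = norm_r.mean(axis=0)
    alpha = _pooled_dispersion(norm_t, norm_r)

    log2fc = np.log2(mu_t / mu_r)
    # delta-method variance of ln(mu_hat): Var(mu_hat)/mu^2 = (1/mu + alpha)/n
    var_ln = (1.0 / mu_t + alpha) / n_t + (1.0 / mu_r + alpha) / n_r
    se = np.sqrt(var_ln) / np.log(2.0)
    with np.errstate(invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = multipletests(p_raw, method="fdr_bh")[1] if len(kept) else np.array([])

    base_mean = norm.mean(axis=0).to_numpy()
    records = [
        DaaRecord(
            feature_id=f,
            base_mean=float(base_mean[i]),
            log2fc=float(log2fc[i]),
            se_log2fc=float(se[i]),
            wald_z=float(z[i]),
            p_raw=float(p_raw[i]),
            p_adj=float(p_adj[i]),
        )
        for i, f in enumerate(kept)
    ]
    return records, skipped


def rank_top(daa_records: list[DaaRecord], direction: str, k: int = 10) -> list[DaaRecord]:
    """Top-k significant records by |log2fc| in one direction of change."""
    if direction not in ("increased", "decreased"):
        raise ValueError("direction must be 'increased' or 'decreased'")
    sign = 1 if direction == "increased" else -1
    hits = [r for r in daa_records if r.significant and sign * r.log2fc > 0]
    hits.sort(key=lambda r: abs(r.log2fc), reverse=True)
    return hits[:k]


def records_frame(records: list[DaaRecord]) -> pd.DataFrame:
    """DAA records as a DataFrame indexed by feature id."""
    return pd.DataFrame(
        {
            "base_mean": [r.base_mean for r in records],
            "log2fc": [r.log2fc for r in records],
            "se_log2fc": [r.se_log2fc for r in records],
            "wald_z": [r.wald_z for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
            "significant": [r.significant for r in records],
        },
        index=pd.Index([r.feature_id for r in records], name="feature_id"),
    )
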