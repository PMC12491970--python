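"""Profile and metadata tables: containers, TSV readers/writers, and filters.

Two table kinds are handled, mirroring the standard shotgun-metagenomic
post-profiling outputs:

* taxonomic tables — samples x species abundances, either a MetaPhlAn-style
  merged relative-abundance table (pipe-delimited clade strings, 0-100 scale)
  or a plain numeric matrix of counts;
* functional tables — samples x enzyme (EC number) abundances, HUMAnN-style.

The filters implement the cohort's pre-processing rules: exclusion of samples
with at most 20,000 reads, removal of species whose cumulative share of the
cohort-wide total falls below 0.05%, and selection of enzymes present in at
least 10% of samples with redundant features removed.  Age quartiles are
assigned by a rank split with ties always placed in the younger quartile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TaxonTable",
    "EnzymeTable",
    "SampleMeta",
    "read_taxon_table",
    "read_enzyme_table",
    "read_sample_meta",
    "write_table",
    "filter_low_read_samples",
    "filter_low_abundance_species",
    "filter_enzymes",
    "assign_age_quartiles",
]

VALID_STATUS = frozenset({"healthy", "LS", "HSIL"})
QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")

#: read-count exclusion threshold; samples with read_count <= this are dropped
DEFAULT_READ_THRESHOLD = 20_000
#: minimum per-species share of the cohort-wide grand total (0.05%)
DEFAULT_CUM_SHARE = 0.0005
#: minimum fraction of samples in which an enzyme must be detected
DEFAULT_ENZYME_PREVALENCE = 0.10


class ProfileParseError(ValueError):
    """Raised when an input profile table violates its format contract."""


@dataclass
class TaxonTable:
    """Samples x species abundance matrix.

    ``values`` is a DataFrame indexed by sample id with one column per species
    (``"Genus species"`` strings).  ``unit`` records whether cells are raw
    counts or relative-abundance fractions (rows summing to at most 1).
    """

    values: pd.DataFrame
    unit: str = "count"

    def __post_init__(self) -> None:
        if self.unit not in ("count", "relabund"):
            raise ValueError(f"unknown unit {self.unit!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("taxon table contains missing cells")
        if (arr < 0).any():
            raise ValueError("taxon table contains negative values")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate species: {sorted(set(dups))}")
        if self.unit == "relabund":
            sums = arr.sum(axis=1)
            if (sums > 1 + 1e-9).any():
                bad = self.values.index[sums > 1 + 1e-9][0]
                raise ValueError(f"relabund row sum exceeds 1 for sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genus_of(self) -> dict[str, str]:
        """Genus of each species, parsed as the first token of the name."""
        return {sp: sp.split(" ", 1)[0] for sp in self.values.columns}

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized fractions (rows with zero total stay all-zero)."""
        totals = self.values.sum(axis=1)
        safe = totals.replace(0.0, 1.0)
        return self.values.div(safe, axis=0)

    def subset_samples(self, sample_ids) -> "TaxonTable":
        return replace(self, values=self.values.loc[list(sample_ids)])


@dataclass
class EnzymeTable:
    """Samples x EC-feature abundance matrix for functional capacity."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("enzyme table contains missing cells")
        if (arr < 0).any():
            raise ValueError("enzyme table contains negative values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "EnzymeTable":
        return EnzymeTable(self.values.loc[list(sample_ids)])


@dataclass
class SampleMeta:
    """Per-sample covariates: age, cohort, health status, read count.

    ``table`` is indexed by sample id; ``age_quartile`` and ``signature`` are
    filled in by :func:`assign_age_quartiles` and the signature classifier.
    """

    table: pd.DataFrame

    REQUIRED = ("age", "cohort", "status", "read_count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        bad = set(self.table["status"]) - VALID_STATUS
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")
        if (self.table["age"] <= 0).any():
            raise ValueError("ages must be positive")
        if (self.table["read_count"] < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, sample_ids) -> "SampleMeta":
        return SampleMeta(self.table.loc[list(sample_ids)].copy())


def _parse_species_clade(clade: str, lineno: int) -> str:
    """`k__...|g__Genus|s__Genus_species` -> `Genus species`."""
    last = clade.split("|")[-1]
    if not last.startswith("s__"):
        raise ProfileParseError(
            f"line {lineno}: clade string does not terminate at species level: {clade!r}"
        )
    name = last[3:]
    if not name or "_" not in name:
        raise ProfileParseError(f"line {lineno}: unparseable species token {last!r}")
    genus, epithet = name.split("_", 1)
    if not genus or not epithet:
        raise ProfileParseError(f"line {lineno}: unparseable species token {last!r}")
    return f"{genus} {epithet.replace('_', ' ')}"


def read_taxon_table(path, dialect: str = "metaphlan_merged") -> TaxonTable:
    """Read a taxonomic profile TSV.

    ``metaphlan_merged``: first column holds pipe-delimited clade strings; only
    rows terminating at species level (``s__``) are retained, values are
    rescaled from the 0-100 percentage convention to fractions, and the unit is
    recorded as ``relabund``.  ``plain_matrix``: first column holds
    ``Genus species`` names, values are taken as counts.
    """
    if dialect not in ("metaphlan_merged", "plain_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    raw.index = raw.index.astype(str)
    if dialect == "plain_matrix":
        table = raw.T
        table.index.name = "sample_id"
        return TaxonTable(values=table.astype(float), unit="count")

    species_rows: dict[str, np.ndarray] = {}
    for lineno, (clade, row) in enumerate(raw.iterrows(), start=2):
        last = clade.split("|")[-1]
        if not last.startswith("s__"):
            continue  # kingdom/.../genus summaries and t__ strain rows
        name = _parse_species_clade(clade, lineno)
        if name in species_rows:
            raise ProfileParseError(f"line {lineno}: duplicate species row {name!r}")
        species_rows[name] = row.to_numpy(dtype=float)
    values = pd.DataFrame(species_rows, index=raw.columns.astype(str)) / 100.0
    values.index.name = "sample_id"
    return TaxonTable(values=values, unit="relabund")


def read_enzyme_table(path) -> EnzymeTable:
    """Read a HUMAnN-style EC table (features in rows, samples in columns)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    table = raw.T.astype(float)
    table.index.name = "sample_id"
    table.index = table.index.astype(str)
    return EnzymeTable(values=table)


def read_sample_meta(path) -> SampleMeta:
    """Read the metadata TSV (`sample_id age cohort status read_count`)."""
    raw = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    raw = raw.set_index("sample_id")
    return SampleMeta(raw)


def write_table(frame: pd.DataFrame, path, index_label: str = "sample_id") -> None:
    """Write any result table as TSV with full float precision."""
    frame.to_csv(path, sep="\t", index_label=index_label, float_format="%.12g")


def filter_low_read_samples(
    meta: SampleMeta, threshold_reads: int = DEFAULT_READ_THRESHOLD
) -> tuple[SampleMeta, pd.DataFrame]:
    """Drop samples sequenced at or below ``threshold_reads`` reads.

    The boundary is inclusive (a sample at exactly the threshold is removed).
    Returns the retained metadata and an exclusion report with columns
    ``reason`` and ``value``.
    """
    counts = meta.table["read_count"]
    removed = counts.index[counts <= threshold_reads]
    report = pd.DataFrame(
        {
            "reason": ["low_read_count"] * len(removed),
            "value": counts.loc[removed].to_numpy(),
        },
        index=removed,
    )
    kept = meta.table.drop(index=removed)
    return SampleMeta(kept), report


def filter_low_abundance_species(
    table: TaxonTable, cum_threshold: float = DEFAULT_CUM_SHARE
) -> TaxonTable:
    """Remove species whose cohort-wide cumulative share is below threshold.

    A species is retained iff its total abundance across all samples, divided
    by the grand total of the table, is >= ``cum_threshold`` (boundary
    inclusive).  Rows are deliberately not renormalized afterwards.
    """
    totals = table.values.sum(axis=0)
    grand = float(totals.sum())
    if grand <= 0:
        raise ValueError("cannot filter an all-zero taxon table")
    keep = totals[totals / grand >= cum_threshold].index
    return replace(table, values=table.values[list(keep)])


def filter_enzymes(
    table: EnzymeTable, min_prevalence: float = DEFAULT_ENZYME_PREVALENCE
) -> EnzymeTable:
    """Keep enzymes detected in >= ``min_prevalence`` of samples; drop redundancy.

    Duplicate EC identifiers are collapsed by summation first.  Then features
    whose value vector exactly duplicates another's are reduced to a single
    representative: duplicates are resolved in lexicographic feature order, the
    first kept.
    """
    values = table.values
    if values.columns.duplicated().any():
        values = values.T.groupby(level=0, sort=False).sum().T
    n = len(values.index)
    prevalence = (values > 0).sum(axis=0) / max(n, 1)
    values = values.loc[:, prevalence >= min_prevalence]

    seen: dict[tuple, str] = {}
    drop: list[str] = []
    for feat in sorted(values.columns):
        key = tuple(values[feat].to_numpy())
        if key in seen:
            drop.append(feat)
        else:
            seen[key] = feat
    return EnzymeTable(values.drop(columns=drop))


def assign_age_quartiles(meta: SampleMeta) -> SampleMeta:
    """Label samples Q1-Q4 by age rank, ties resolved to the younger quartile.

    Samples are stably sorted by age and quartiles are filled in order, each
    taking an even share of the samples still unassigned (earlier quartiles
    take the remainder).  When the boundary would split a tied age value, the
    whole tie group joins the earlier (younger) quartile and the remaining
    quartiles rebalance over what is left — so a boundary never splits an age
    value and e.g. ages (30,30,30,40,50,60,70,80) give Q1 = all three 30s and
    Q2 = (40, 50).
    """
    n = len(meta.table)
    if n < 4:
        raise ValueError(f"need at least 4 samples for quartiles, got {n}")
    order = meta.table["age"].sort_values(kind="stable")
    ids = list(order.index)
    ages = order.to_numpy()
    labels: dict[str, str] = {}
    pos = 0
    for k in range(4):
        remaining = n - pos
        size = -(-remaining // (4 - k))  # ceil: earlier quartiles take remainder
        end = n if k == 3 else min(pos + size, n)
        while end < n and end > pos and ages[end] == ages[end - 1]:
            end += 1  # tie group joins the younger quartile wholesale
        for i in range(pos, end):
            labels[ids[i]] = QUARTILE_LABELS[k]
        pos = end
    out = meta.table.copy()
    out["age_quartile"] = pd.Series(labels).reindex(out.index)
    return SampleMeta(out)
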