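"""Ecological-signature classification of vulvar microbiome samples.

Each sample is labeled skin-, vagina-, or multispecies-mixture-dominant by
the fraction of its profiled abundance carried by a skin genus panel
(Cutibacterium, Staphylococcus) versus a vaginal genus panel (Gardnerella,
Lactobacillus, Prevotella, Atopobium, Finegoldia, Ureaplasma): a dominant
signature requires at least 50% of the sample's retained abundance on the
corresponding panel; everything else is a mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .profile_io import TaxonTable

__all__ = ["GenusPanels", "SignatureCall", "DEFAULT_PANELS", "compute_fractions", "classify", "classify_cohort"]


@dataclass(frozen=True)
class GenusPanels:
    """Disjoint genus panels defining the skin and vaginal niches."""

    skin_genera: frozenset[str]
    vagina_genera: frozenset[str]

    def __post_init__(self) -> None:
        if not self.skin_genera or not self.vagina_genera:
            raise ValueError("genus panels must be non-empty")
        overlap = self.skin_genera & self.vagina_genera
        if overlap:
            raise ValueError(f"panels must be disjoint; shared: {sorted(overlap)}")


DEFAULT_PANELS = GenusPanels(
    skin_genera=frozenset({"Cutibacterium", "Staphylococcus"}),
    vagina_genera=frozenset(
        {"Gardnerella", "Lactobacillus", "Prevotella", "Atopobium", "Finegoldia", "Ureaplasma"}
    ),
)


@dataclass(frozen=True)
class SignatureCall:
    sample_id: str
    skin_fraction: float
    vagina_fraction: float
    label: str


def compute_fractions(
    table: TaxonTable, panels: GenusPanels, sample_id: str
) -> tuple[float, float]:
    """Fractions of a sample's total abundance on the skin and vaginal panels.

    The denominator is the total abundance of all retained species in the
    sample, so the result is invariant to rescaling the sample.
    """
    row = table.values.loc[sample_id]
    total = float(row.sum())
    if total <= 0:
        raise ValueError(f"sample {sample_id!r} has zero total abundance")
    genus_of = table.genus_of
    skin = sum(v for sp, v in row.items() if genus_of[sp] in panels.skin_genera)
    vagina = sum(v for sp, v in row.items() if genus_of[sp] in panels.vagina_genera)
    return skin / total, vagina / total


def classify(skin_fraction: float, vagina_fraction: float) -> str:
    """Dominance rule: >=50% on a panel wins; an exact double tie is a mixture."""
    if skin_fraction >= 0.5 and vagina_fraction >= 0.5:
        return "mixture"
    if skin_fraction >= 0.5:
        return "skin"
    if vagina_fraction >= 0.5:
        return "vagina"
    return "mixture"


def classify_cohort(
    table: TaxonTable, panels: GenusPanels = DEFAULT_PANELS
) -> tuple[list[SignatureCall], pd.DataFrame]:
    """Classify every sample; also return per-label counts and percentages."""
    genus_of = table.genus_of
    skin_cols = [sp for sp in table.feature_ids if genus_of[sp] in panels.skin_genera]
    vag_cols = [sp for sp in table.feature_ids if genus_of[sp] in panels.vagina_genera]
    totals = table.values.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    skin_frac = table.values[skin_cols].sum(axis=1) / totals
    vag_frac = table.values[vag_cols].sum(axis=1) / totals
    calls = [
        SignatureCall(sid, float(s), float(v), classify(float(s), float(v)))
        for sid, s, v in zip(table.sample_ids, skin_frac, vag_frac)
    ]
    counts = pd.Series([c.label for c in calls]).value_counts()
    summary = pd.DataFrame(
        {
            "count": [int(counts.get(lbl, 0)) for lbl in ("skin", "vagina", "mixture")],
        },
        index=pd.Index(["skin", "vagina", "mixture"], name="label"),
    )
    summary["percent"] = 100.0 * summary["count"] / summary["count"].sum()
    return calls, summary


def calls_frame(calls: list[SignatureCall]) -> pd.DataFrame:
    """Per-sample calls as a DataFrame indexed by sample id."""
    return pd.DataFrame(
        {
            "skin_fraction": [c.skin_fraction for c in calls],
            "vagina_fraction": [c.vagina_fraction for c in calls],
            "label": [c.label for c in calls],
        },
        index=pd.Index([c.sample_id for c in calls], name="sample_id"),
    )
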