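"""Seeded synthetic vulvar-microbiome cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any sequencing data:

* three community archetypes — skin-dominant, vagina-dominant, and a
  multispecies mixture — each defined by a base composition over a species
  panel in which the named skin genera (Cutibacterium, Staphylococcus) or
  vaginal genera (Gardnerella, Lactobacillus, Prevotella, Atopobium,
  Finegoldia, Ureaplasma) carry >=50% of the mass for the dominant types and
  <50% of each for the mixture;
* per-sample overdispersed counts via a Dirichlet-multinomial: the realized
  composition is Dirichlet around the (effect-perturbed) archetype base, and
  counts are multinomial at a drawn sequencing depth;
* covariate effects planted multiplicatively on the expected composition:
  an age-associated decline of Lactobacillus species and disease-associated
  depletion of named species, expressed as log2 fold changes;
* enzyme tables derived linearly from taxon relative abundances through a
  sparse species-by-EC matrix with multiplicative lognormal noise.

All sampling is driven by a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile_io import EnzymeTable, SampleMeta, TaxonTable

__all__ = [
    "ArchetypeSpec",
    "EffectSpec",
    "CohortTruth",
    "default_species_panel",
    "default_effects",
    "default_ec_map",
    "simulate_cohort",
    "simulate_enzyme_table",
    "simulate_two_group_counts",
]

SKIN_GENERA = frozenset({"Cutibacterium", "Staphylococcus"})
VAGINA_GENERA = frozenset(
    {"Gardnerella", "Lactobacillus", "Prevotella", "Atopobium", "Finegoldia", "Ureaplasma"}
)

#: archetype mixing proportions observed in the motivating cohort (skin,
#: vagina, mixture) — a default parameter of the generator, not a claim
DEFAULT_ARCHETYPE_WEIGHTS = (0.24, 0.22, 0.54)
#: Dirichlet precision; 50 gives visible inter-sample variability
DEFAULT_CONCENTRATION = 50.0
DEFAULT_DEPTH_RANGE = (50_000, 500_000)
DEFAULT_AGE_RANGE = (22, 82)
#: healthy / LS / HSIL prevalences mirroring a 58/6/3 cohort
DEFAULT_STATUS_PREVALENCE = {"healthy": 58 / 67, "LS": 6 / 67, "HSIL": 3 / 67}


@dataclass(frozen=True)
class ArchetypeSpec:
    """One community archetype: a base composition plus Dirichlet precision."""

    name: str
    base_composition: dict[str, float]
    concentration: float = DEFAULT_CONCENTRATION

    def __post_init__(self) -> None:
        total = sum(self.base_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base composition of {self.name!r} sums to {total}, not 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """A planted covariate effect on a set of target species.

    ``covariate`` is ``"age"`` (effect per decade above the cohort minimum)
    or a disease status (``"LS"``/``"HSIL"``, effect per affected sample).
    """

    target_species: tuple[str, ...]
    covariate: str
    log2_effect_per_unit: float

    def __post_init__(self) -> None:
        if self.covariate not in ("age", "LS", "HSIL"):
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if not np.isfinite(self.log2_effect_per_unit):
            raise ValueError("effect must be finite")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, serializable to JSON."""

    archetype: dict[str, str]
    effects: list[EffectSpec]
    seed: int
    parameters: dict = field(default_factory=dict)

    def true_log2fc(self, contrast: str) -> dict[str, float]:
        """Planted log2 fold change per species for a named contrast.

        ``Q3Q4_vs_Q1Q2`` maps an age effect per decade onto the expected
        three-decade gap between the older and younger halves of a uniform
        22-82 age distribution; disease contrasts use the per-status effect.
        """
        out: dict[str, float] = {}
        for eff in self.effects:
            if contrast == "Q3Q4_vs_Q1Q2" and eff.covariate == "age":
                scale = 3.0  # decades between means of the two age halves
            elif contrast == f"{eff.covariate}_vs_healthy":
                scale = 1.0
            else:
                continue
            for sp in eff.target_species:
                out[sp] = out.get(sp, 0.0) + eff.log2_effect_per_unit * scale
        return out

    def to_json(self) -> str:
        payload = {
            "archetype": self.archetype,
            "effects": [dataclasses.asdict(e) for e in self.effects],
            "seed": self.seed,
            "parameters": self.parameters,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def default_species_panel() -> dict[str, ArchetypeSpec]:
    """The default 22-species panel and its three archetype compositions.

    Includes the species most prevalent on the vulva (S. epidermidis,
    F. magna, P. harei, P. timonensis, C. acnes), the vaginal marker species
    (G. vaginalis, Lactobacillus spp.), and the disease-associated species
    (S. hominis, M. luteus, C. amycolatum, C. simulans, M. osloensis).
    """
    skin = {
        "Cutibacterium acnes": 0.26,
        "Cutibacterium granulosum": 0.05,
        "Staphylococcus epidermidis": 0.20,
        "Staphylococcus hominis": 0.09,
        "Staphylococcus aureus": 0.04,
    }
    vagina = {
        "Gardnerella vaginalis": 0.17,
        "Finegoldia magna": 0.14,
        "Lactobacillus iners": 0.12,
        "Lactobacillus crispatus": 0.06,
        "Lactobacillus gasseri": 0.04,
        "Lactobacillus jensenii": 0.02,
        "Prevotella timonensis": 0.05,
        "Prevotella bivia": 0.02,
        "Atopobium vaginae": 0.02,
        "Ureaplasma parvum": 0.01,
    }
    other = {
        "Peptoniphilus harei": 0.07,
        "Micrococcus luteus": 0.03,
        "Corynebacterium amycolatum": 0.03,
        "Corynebacterium simulans": 0.02,
        "Moraxella osloensis": 0.02,
        "Anaerococcus obesiensis": 0.02,
        "Escherichia coli": 0.01,
    }
    def mix(w_skin: float, w_vag: float, w_other: float) -> dict[str, float]:
        comp = {}
        for pool, weight in ((skin, w_skin), (vagina, w_vag), (other, w_other)):
            total = sum(pool.values())
            for sp, v in pool.items():
                comp[sp] = weight * v / total
        # exact closure against float drift
        s = sum(comp.values())
        return {sp: v / s for sp, v in comp.items()}

    return {
        "skin": ArchetypeSpec("skin", mix(0.66, 0.14, 0.20)),
        "vagina": ArchetypeSpec("vagina", mix(0.12, 0.66, 0.22)),
        "mixture": ArchetypeSpec("mixture", mix(0.30, 0.35, 0.35)),
    }


def default_effects() -> list[EffectSpec]:
    """Default planted effects: Lactobacillus decline with age and
    disease-associated depletion of four marker species."""
    lacto = (
        "Lactobacillus iners",
        "Lactobacillus crispatus",
        "Lactobacillus gasseri",
    )
    depleted = (
        "Staphylococcus hominis",
        "Micrococcus luteus",
        "Moraxella osloensis",
        "Corynebacterium simulans",
    )
    return [
        EffectSpec(lacto, "age", -0.5),
        EffectSpec(depleted, "LS", -2.0),
        EffectSpec(depleted, "HSIL", -2.0),
    ]


def _panel_species(archetypes: dict[str, ArchetypeSpec]) -> list[str]:
    first = next(iter(archetypes.values()))
    species = list(first.base_composition)
    for spec in archetypes.values():
        if set(spec.base_composition) != set(species):
            raise ValueError("archetypes must share one species panel")
    return species


def simulate_cohort(
    n_samples: int,
    archetype_weights=DEFAULT_ARCHETYPE_WEIGHTS,
    effects: list[EffectSpec] | None = None,
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE,
    seed: int = 0,
    archetypes: dict[str, ArchetypeSpec] | None = None,
    status_prevalence: dict[str, float] | None = None,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
    low_depth_fraction: float = 0.0,
    concentration: float | None = None,
) -> tuple[TaxonTable, SampleMeta, CohortTruth]:
    """Draw a synthetic cohort of taxon counts, metadata and ground truth.

    Per sample: an archetype is drawn from ``archetype_weights``; age is
    uniform on ``age_range``; status follows ``status_prevalence``; the
    archetype base composition is perturbed multiplicatively by
    ``2**(log2_effect * covariate)`` on each effect's target species and
    renormalized; the realized composition is Dirichlet with the archetype's
    precision; counts are multinomial at a depth drawn uniformly from
    ``depth_range``.  ``low_depth_fraction`` of samples instead receive a
    depth below 20,000 so the read-count filter can be exercised.
    ``concentration`` overrides every archetype's Dirichlet precision.
    """
    weights = np.asarray(archetype_weights, dtype=float)
    if weights.ndim != 1 or len(weights) != 3 or (weights < 0).any() or abs(weights.sum() - 1) > 1e-9:
        raise ValueError("archetype_weights must be 3 non-negative values summing to 1")
    if depth_range[0] <= 0 or depth_range[1] < depth_range[0]:
        raise ValueError("invalid depth range")
    archetypes = archetypes or default_species_panel()
    if concentration is not None:
        archetypes = {
            k: ArchetypeSpec(a.name, a.base_composition, concentration)
            for k, a in archetypes.items()
        }
    effects = list(effects) if effects is not None else []
    prevalence = status_prevalence or DEFAULT_STATUS_PREVALENCE

    rng = np.random.default_rng(seed)
    species = _panel_species(archetypes)
    names = list(archetypes)
    sp_index = {sp: i for i, sp in enumerate(species)}

    draws = rng.choice(len(names), size=n_samples, p=weights)
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n_samples)
    statuses = rng.choice(
        list(prevalence), size=n_samples, p=np.asarray(list(prevalence.values()))
    )
    cohorts = rng.choice(["TNO", "CHDR"], size=n_samples, p=[49 / 67, 18 / 67])
    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n_samples)
    if low_depth_fraction > 0:
        low = rng.random(n_samples) < low_depth_fraction
        depths[low] = rng.integers(1_000, 20_001, size=int(low.sum()))

    counts = np.zeros((n_samples, len(species)), dtype=np.int64)
    archetype_of: dict[str, str] = {}
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    for i in range(n_samples):
        spec = archetypes[names[draws[i]]]
        expected = np.array([spec.base_composition[sp] for sp in species])
        for eff in effects:
            if eff.covariate == "age":
                units = (ages[i] - age_range[0]) / 10.0
            else:
                units = 1.0 if statuses[i] == eff.covariate else 0.0
            if units:
                factor = 2.0 ** (eff.log2_effect_per_unit * units)
                for sp in eff.target_species:
                    expected[sp_index[sp]] *= factor
        expected /= expected.sum()
        realized = rng.dirichlet(spec.concentration * expected)
        counts[i] = rng.multinomial(depths[i], realized)
        archetype_of[sample_ids[i]] = names[draws[i]]

    taxa = TaxonTable(
        values=pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=species),
        unit="count",
    )
    meta = SampleMeta(
        pd.DataFrame(
            {
                "age": ages,
                "cohort": cohorts,
                "status": statuses,
                "read_count": depths,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = CohortTruth(
        archetype=archetype_of,
        effects=effects,
        seed=seed,
        parameters={
            "n_samples": n_samples,
            "archetype_weights": list(map(float, weights)),
            "depth_range": list(depth_range),
            "age_range": list(age_range),
            "low_depth_fraction": low_depth_fraction,
        },
    )
    return taxa, meta, truth


def default_ec_map(species: list[str], ecs_per_species: int = 8, n_ecs: int = 150, seed: int = 17) -> pd.DataFrame:
    """A sparse species-by-EC weight matrix, deterministic in ``seed``.

    A handful of real EC numbers relevant to the vulvar niche (aspartate and
    L-histidine pathway enzymes) head the feature list; the remainder are
    synthetic placeholder identifiers.
    """
    named = [
        "EC 6.3.1.1",   # aspartate--ammonia ligase
        "EC 5.1.1.13",  # aspartate racemase
        "EC 4.2.1.19",  # imidazoleglycerol-phosphate dehydratase (His pathway)
        "EC 1.1.1.23",  # histidinol dehydrogenase (His pathway)
        "EC 4.3.1.3",   # histidine ammonia-lyase (His pathway)
    ]
    ec_ids = named + [f"EC 9.9.{i // 10}.{i % 10}" for i in range(n_ecs - len(named))]
    rng = np.random.default_rng(seed)
    mat = np.zeros((len(species), n_ecs))
    for i in range(len(species)):
        cols = rng.choice(n_ecs, size=min(ecs_per_species, n_ecs), replace=False)
        mat[i, cols] = rng.gamma(2.0, 1.0, size=len(cols))
    return pd.DataFrame(mat, index=species, columns=ec_ids)


def simulate_enzyme_table(
    taxon_counts: TaxonTable,
    taxon_to_ec_map: pd.DataFrame,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> EnzymeTable:
    """Enzyme abundances as a noisy linear map of taxon relative abundances.

    ``enzyme = (relative abundance @ species-by-EC matrix) * lognormal noise``,
    with the noise i.i.d. per cell and ``noise_sd`` the standard deviation of
    its natural logarithm.  Deterministic under a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if list(taxon_counts.feature_ids) != list(taxon_to_ec_map.index):
        raise ValueError("species panel of the taxon table and EC map disagree")
    rel = taxon_counts.relative_abundance().to_numpy()
    base = rel @ taxon_to_ec_map.to_numpy()
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        base = base * np.exp(rng.normal(0.0, noise_sd, size=base.shape))
    return EnzymeTable(
        pd.DataFrame(
            base,
            index=pd.Index(taxon_counts.sample_ids, name="sample_id"),
            columns=list(taxon_to_ec_map.columns),
        )
    )


def simulate_two_group_counts(
    n_features: int,
    n_per_group: int,
    planted: dict[int, float] | None = None,
    dispersion: float = 0.1,
    mean_log_mu: float = 4.0,
    sd_log_mu: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[int, float]]:
    """Generic two-group negative-binomial count simulator with planted truth.

    Feature baseline means are lognormal; features listed in ``planted`` have
    their group-B mean multiplied by ``2**log2fc``.  Counts are gamma-Poisson
    with the given dispersion (variance mu + dispersion*mu^2).  Returns the
    samples x features count table, the group labels ("A"/"B"), and the
    planted map.  Used for differential-abundance power and null studies.
    """
    planted = dict(planted or {})
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(mean_log_mu, sd_log_mu, size=n_features))
    mu_b = mu.copy()
    for idx, lfc in planted.items():
        mu_b[idx] *= 2.0**lfc

    def draw(mu_vec: np.ndarray, n: int) -> np.ndarray:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, scale=mu_vec / shape, size=(n, n_features))
        return rng.poisson(lam)

    counts = np.vstack([draw(mu, n_per_group), draw(mu_b, n_per_group)])
    samples = [f"A{i:03d}" for i in range(n_per_group)] + [
        f"B{i:03d}" for i in range(n_per_group)
    ]
    table = pd.DataFrame(
        counts,
        index=pd.Index(samples, name="sample_id"),
        columns=[f"sp{j:03d}" for j in range(n_features)],
    )
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=table.index)
    return table, groups, planted
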