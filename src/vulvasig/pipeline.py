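"""End-to-end pipeline: filter -> classify -> diversity -> ordination -> DAA.

A single :class:`PipelineConfig` drives the fixed stage order; every excluded
sample or feature is logged with its reason, all stochastic steps consume the
config seed, and a reproducibility manifest (config hash, input checksums,
per-stage sample/feature counts) is written next to the TSV reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import daa_function, daa_taxa, diversity, ordination, profile_io, signature

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline", "load_config"]

logger = logging.getLogger("vulvasig")

#: report files every full run produces
REPORT_FILES = (
    "exclusions.tsv",
    "signature_calls.tsv",
    "signature_summary.tsv",
    "shannon.tsv",
    "diversity_tests.tsv",
    "pca_scores.tsv",
    "pca_loadings.tsv",
    "pca_variance.tsv",
    "permanova.tsv",
    "daa_taxa.tsv",
    "daa_function.tsv",
)


@dataclass
class PipelineConfig:
    taxon_table: str
    metadata: str
    seed: int
    enzyme_table: str | None = None
    taxon_dialect: str = "plain_matrix"
    read_min: int = profile_io.DEFAULT_READ_THRESHOLD
    species_cum_share: float = profile_io.DEFAULT_CUM_SHARE
    enzyme_prevalence: float = profile_io.DEFAULT_ENZYME_PREVALENCE
    skin_genera: list[str] = field(
        default_factory=lambda: sorted(signature.DEFAULT_PANELS.skin_genera)
    )
    vagina_genera: list[str] = field(
        default_factory=lambda: sorted(signature.DEFAULT_PANELS.vagina_genera)
    )
    taxon_contrasts: list[str] = field(
        default_factory=lambda: ["Q3Q4_vs_Q1Q2", "HSIL_vs_healthy", "LS_vs_healthy"]
    )
    # HSIL deliberately absent by default: tiny groups make the functional
    # contrast uninformative, so only age and LS are configured out of the box
    function_contrasts: list[str] = field(
        default_factory=lambda: ["Q3Q4_vs_Q1Q2", "LS_vs_healthy"]
    )
    permutations: int = 9_999
    alpha: float = 0.05
    outdir: str = "results/pipeline"

    def panels(self) -> signature.GenusPanels:
        return signature.GenusPanels(
            frozenset(self.skin_genera), frozenset(self.vagina_genera)
        )


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_checksums: dict[str, str]
    stage_counts: list[dict]
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON pipeline config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """All constraint violations, as `field: problem` strings (empty = valid)."""
    errors: list[str] = []
    if config.seed is None:
        errors.append("seed: a seed is mandatory")
    if not 0 < config.alpha < 1:
        errors.append(f"alpha: must be in (0, 1), got {config.alpha}")
    if config.read_min < 0:
        errors.append("read_min: must be non-negative")
    if not 0 <= config.species_cum_share <= 1:
        errors.append("species_cum_share: must be a fraction in [0, 1]")
    if not 0 <= config.enzyme_prevalence <= 1:
        errors.append("enzyme_prevalence: must be a fraction in [0, 1]")
    if config.permutations < 1:
        errors.append("permutations: must be >= 1")
    if config.taxon_dialect not in ("metaphlan_merged", "plain_matrix"):
        errors.append(f"taxon_dialect: unknown dialect {config.taxon_dialect!r}")
    if set(config.skin_genera) & set(config.vagina_genera):
        errors.append("skin_genera/vagina_genera: panels must be disjoint")
    if not config.skin_genera or not config.vagina_genera:
        errors.append("skin_genera/vagina_genera: panels must be non-empty")
    for c in config.taxon_contrasts + config.function_contrasts:
        if isinstance(c, str) and c not in daa_taxa.CONTRASTS:
            errors.append(f"contrasts: unknown contrast {c!r}")
    return errors


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in fixed order and write the TSV reports.

    Stage order: read-count sample filter -> species abundance filter ->
    signature classification -> age quartiles -> alpha diversity (per
    signature, age half, and status) -> CLR-PCA + PERMANOVA -> NB-Wald DAA on
    species -> enzyme filter -> moderated-t DAA on enzymes.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    checksums = {"taxon_table": _sha256(config.taxon_table), "metadata": _sha256(config.metadata)}
    if config.enzyme_table:
        checksums["enzyme_table"] = _sha256(config.enzyme_table)
    stage_counts: list[dict] = []

    def record(stage: str, kind: str, n_in: int, n_kept: int) -> None:
        stage_counts.append(
            {"stage": stage, "kind": kind, "in": n_in, "kept": n_kept, "excluded": n_in - n_kept}
        )
        logger.info("%s: %d/%d %s kept", stage, n_kept, n_in, kind)

    taxa = profile_io.read_taxon_table(config.taxon_table, dialect=config.taxon_dialect)
    meta = profile_io.read_sample_meta(config.metadata)

    # -- sample filter on read counts
    n_in = len(meta.sample_ids)
    meta, excl = profile_io.filter_low_read_samples(meta, config.read_min)
    record("filter_low_read_samples", "samples", n_in, len(meta.sample_ids))
    kept_ids = [s for s in taxa.sample_ids if s in set(meta.sample_ids)]
    taxa = taxa.subset_samples(kept_ids)
    excl.to_csv(outdir / "exclusions.tsv", sep="\t", index_label="sample_id")

    # -- species filter on cohort-wide cumulative share
    n_sp = len(taxa.feature_ids)
    taxa = profile_io.filter_low_abundance_species(taxa, config.species_cum_share)
    record("filter_low_abundance_species", "species", n_sp, len(taxa.feature_ids))

    # -- ecological signatures
    calls, summary = signature.classify_cohort(taxa, config.panels())
    calls_df = signature.calls_frame(calls)
    profile_io.write_table(calls_df, outdir / "signature_calls.tsv")
    summary.to_csv(outdir / "signature_summary.tsv", sep="\t")
    record("classify_signatures", "samples", len(calls), len(calls))

    # -- age quartiles and derived grouping columns
    meta = profile_io.assign_age_quartiles(meta)
    table = meta.table.copy()
    table["signature"] = calls_df["label"].reindex(table.index)
    table["age_half"] = table["age_quartile"].map(
        {"Q1": "Q1_Q2", "Q2": "Q1_Q2", "Q3": "Q3_Q4", "Q4": "Q3_Q4"}
    )
    meta = profile_io.SampleMeta(table)

    # -- alpha diversity with Dunn post-hoc per grouping
    h = diversity.shannon_per_sample(taxa.values)
    profile_io.write_table(h.to_frame(), outdir / "shannon.tsv")
    div_rows = []
    for grouping in ("signature", "age_quartile", "status"):
        labels = table[grouping]
        if labels.nunique() < 2:
            continue
        res = diversity.kruskal_dunn(h.to_numpy(), labels.to_numpy())
        pw = res["pairwise"].copy()
        pw.insert(0, "grouping", grouping)
        pw["kruskal_H"] = res["kruskal_H"]
        pw["kruskal_p"] = res["kruskal_p"]
        div_rows.append(pw)
    pd.concat(div_rows, ignore_index=True).to_csv(
        outdir / "diversity_tests.tsv", sep="\t", index=False
    )

    # -- CLR-PCA and PERMANOVA on the signature grouping
    pc = ordination.default_pseudocount(taxa.values, taxa.unit)
    clr = ordination.clr_transform(taxa.values, pseudocount=pc)
    ord_res = ordination.pca(clr)
    profile_io.write_table(ord_res.scores, outdir / "pca_scores.tsv")
    profile_io.write_table(ord_res.loadings, outdir / "pca_loadings.tsv", index_label="feature_id")
    pd.DataFrame(
        {"variance_explained": ord_res.variance_explained},
        index=pd.Index([f"PC{k+1}" for k in range(len(ord_res.variance_explained))], name="component"),
    ).to_csv(outdir / "pca_variance.tsv", sep="\t")
    perm_rows = []
    for grouping in ("signature", "age_quartile", "status"):
        labels = table[grouping]
        sizes = labels.value_counts()
        usable = labels.isin(sizes.index[sizes >= 2])
        if labels[usable].nunique() < 2:
            continue
        res = ordination.permanova(
            clr.loc[usable], labels[usable].to_numpy(),
            n_permutations=config.permutations, seed=config.seed,
        )
        pw = ordination.pairwise_permanova(
            clr.loc[usable], labels[usable].to_numpy(),
            n_permutations=config.permutations, seed=config.seed,
        )
        pw.insert(0, "grouping", grouping)
        pw["omnibus_F"] = res.pseudo_F
        pw["omnibus_R2"] = res.R2
        pw["omnibus_p"] = res.p_perm
        perm_rows.append(pw)
    pd.concat(perm_rows, ignore_index=True).to_csv(
        outdir / "permanova.tsv", sep="\t", index=False
    )

    # -- species differential abundance per contrast
    daa_frames = []
    for contrast in config.taxon_contrasts:
        try:
            records, skipped = daa_taxa.nb_wald_test(taxa, meta, contrast)
        except ValueError as exc:
            logger.warning("daa_taxa %s skipped: %s", contrast, exc)
            continue
        frame = daa_taxa.records_frame(records).reset_index()
        frame.insert(0, "contrast", contrast)
        daa_frames.append(frame)
        if skipped:
            logger.info("daa_taxa %s: %d all-zero features skipped", contrast, len(skipped))
    pd.concat(daa_frames, ignore_index=True).to_csv(outdir / "daa_taxa.tsv", sep="\t", index=False)
    record("daa_taxa", "contrasts", len(config.taxon_contrasts), len(daa_frames))

    # -- enzyme differential abundance per contrast
    fn_frames = []
    if config.enzyme_table:
        enz = profile_io.read_enzyme_table(config.enzyme_table)
        enz = enz.subset_samples([s for s in enz.sample_ids if s in set(meta.sample_ids)])
        n_ec = len(enz.feature_ids)
        enz = profile_io.filter_enzymes(enz, config.enzyme_prevalence)
        record("filter_enzymes", "enzymes", n_ec, len(enz.feature_ids))
        logged = daa_function.log_transform(enz)
        for contrast in config.function_contrasts:
            try:
                results = daa_function.moderated_t_test(logged, meta, contrast)
            except ValueError as exc:
                logger.warning("daa_function %s skipped: %s", contrast, exc)
                continue
            frame = daa_function.modt_frame(results).reset_index()
            frame.insert(0, "contrast", contrast)
            fn_frames.append(frame)
    if fn_frames:
        pd.concat(fn_frames, ignore_index=True).to_csv(
            outdir / "daa_function.tsv", sep="\t", index=False
        )
    else:
        pd.DataFrame(
            columns=["contrast", "feature_id", "mean_diff", "s2", "s2_post",
                     "t_mod", "df_total", "p_raw", "p_adj", "significant"]
        ).to_csv(outdir / "daa_function.tsv", sep="\t", index=False)

    manifest = RunManifest(
        version=_package_version(),
        config_hash=_config_hash(config),
        input_checksums=checksums,
        stage_counts=stage_counts,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("vulvasig")
    except PackageNotFoundError:
        return "unknown"
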