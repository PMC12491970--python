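"""Generate the default synthetic vulvar cohort used by the later steps.

Writes taxon counts, an enzyme table, metadata and the generator ground
truth to results/cohort/.  The cohort carries the default planted effects:
a Lactobacillus decline with age and depletion of four marker species in
disease, plus a small fraction of under-sequenced samples so the read-count
filter has something to do.
"""

from pathlib import Path

from vulvasig import synthetic_cohort as sc

OUT = Path("results/cohort")
SEED = 20_250_919
N_SAMPLES = 400

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    taxa, meta, truth = sc.simulate_cohort(
        N_SAMPLES, seed=SEED, effects=sc.default_effects(), low_depth_fraction=0.03
    )
    enzymes = sc.simulate_enzyme_table(
        taxa, sc.default_ec_map(taxa.feature_ids), seed=SEED + 1
    )
    taxa.values.T.to_csv(OUT / "taxon_counts.tsv", sep="\t", index_label="species")
    enzymes.values.T.to_csv(OUT / "enzyme_table.tsv", sep="\t", index_label="feature_id")
    meta.table.to_csv(OUT / "metadata.tsv", sep="\t", index_label="sample_id")
    (OUT / "truth.json").write_text(truth.to_json())
    n_low = int((meta.table["read_count"] <= 20_000).sum())
    print(
        f"simulated {N_SAMPLES} samples x {len(taxa.feature_ids)} species "
        f"({n_low} below the 20k read threshold); wrote {OUT}/"
    )
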