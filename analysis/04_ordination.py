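"""Beta diversity in Aitchison geometry: CLR-PCA and PERMANOVA.

Ordinates the filtered cohort, reports variance explained by the leading
components, and tests signature / age-quartile / status groupings with
one-way and pairwise PERMANOVA.  Tables land in results/ordination/.
"""

from pathlib import Path

import pandas as pd

from vulvasig import ordination, profile_io

COHORT = Path("results/cohort")
SIG = Path("results/signature")
OUT = Path("results/ordination")
SEED = 20_250_919

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    taxa = profile_io.read_taxon_table(COHORT / "taxon_counts.tsv", dialect="plain_matrix")
    meta = profile_io.read_sample_meta(COHORT / "metadata.tsv")
    meta, _ = profile_io.filter_low_read_samples(meta)
    meta = profile_io.assign_age_quartiles(meta)
    taxa = profile_io.filter_low_abundance_species(taxa.subset_samples(meta.sample_ids))
    calls = pd.read_csv(SIG / "signature_calls.tsv", sep="\t", index_col=0)
    table = meta.table.join(calls["label"].rename("signature"))

    clr = ordination.clr_transform(
        taxa.values, pseudocount=ordination.default_pseudocount(taxa.values, taxa.unit)
    )
    res = ordination.pca(clr)
    profile_io.write_table(res.scores, OUT / "pca_scores.tsv")
    profile_io.write_table(res.loadings, OUT / "pca_loadings.tsv", index_label="feature_id")
    ve = res.variance_explained
    print(f"PC1 {100*ve[0]:.1f}% | PC2 {100*ve[1]:.1f}% of CLR variance")

    frames = []
    for grouping in ("signature", "age_quartile", "status"):
        omnibus = ordination.permanova(
            clr, table[grouping].to_numpy(), n_permutations=999, seed=SEED
        )
        pw = ordination.pairwise_permanova(
            clr, table[grouping].to_numpy(), n_permutations=999, seed=SEED
        )
        pw.insert(0, "grouping", grouping)
        frames.append(pw)
        print(
            f"{grouping}: PERMANOVA F={omnibus.pseudo_F:.2f} "
            f"R2={omnibus.R2:.3f} p={omnibus.p_perm:.4f}"
        )
    pd.concat(frames, ignore_index=True).to_csv(OUT / "permanova.tsv", sep="\t", index=False)
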