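"""Alpha diversity of the cohort: Shannon index with Dunn post-hoc tests.

Compares diversity across ecological signatures, age quartiles and health
status; writes per-sample indices and all pairwise tests to
results/diversity/.
"""

from pathlib import Path

import pandas as pd

from vulvasig import diversity, profile_io

COHORT = Path("results/cohort")
SIG = Path("results/signature")
OUT = Path("results/diversity")

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    taxa = profile_io.read_taxon_table(COHORT / "taxon_counts.tsv", dialect="plain_matrix")
    meta = profile_io.read_sample_meta(COHORT / "metadata.tsv")
    meta, _ = profile_io.filter_low_read_samples(meta)
    meta = profile_io.assign_age_quartiles(meta)
    taxa = profile_io.filter_low_abundance_species(taxa.subset_samples(meta.sample_ids))

    calls = pd.read_csv(SIG / "signature_calls.tsv", sep="\t", index_col=0)
    table = meta.table.join(calls["label"].rename("signature"))

    h = diversity.shannon_per_sample(taxa.values)
    profile_io.write_table(h.to_frame(), OUT / "shannon.tsv")

    frames = []
    for grouping in ("signature", "age_quartile", "status"):
        res = diversity.kruskal_dunn(h.to_numpy(), table[grouping].to_numpy())
        pw = res["pairwise"].copy()
        pw.insert(0, "grouping", grouping)
        frames.append(pw)
        print(f"{grouping}: Kruskal-Wallis H={res['kruskal_H']:.2f} p={res['kruskal_p']:.2e}")
    pd.concat(frames, ignore_index=True).to_csv(OUT / "dunn_pairwise.tsv", sep="\t", index=False)

    means = h.groupby(table["signature"]).mean()
    print("mean Shannon by signature:")
    print(means.to_string(float_format="%.3f"))
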