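"""Species differential abundance: old vs young and disease vs healthy.

Runs the negative-binomial Wald test for the three study contrasts and
prints the top depleted/enriched species per contrast, checking the planted
truth where the generator defined one.  Tables land in results/daa_species/.
"""

import json
from pathlib import Path

from vulvasig import daa_taxa, profile_io

COHORT = Path("results/cohort")
OUT = Path("results/daa_species")

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    taxa = profile_io.read_taxon_table(COHORT / "taxon_counts.tsv", dialect="plain_matrix")
    meta = profile_io.read_sample_meta(COHORT / "metadata.tsv")
    meta, _ = profile_io.filter_low_read_samples(meta)
    meta = profile_io.assign_age_quartiles(meta)
    taxa = profile_io.filter_low_abundance_species(taxa.subset_samples(meta.sample_ids))
    truth = json.loads((COHORT / "truth.json").read_text())

    for contrast in ("Q3Q4_vs_Q1Q2", "HSIL_vs_healthy", "LS_vs_healthy"):
        records, skipped = daa_taxa.nb_wald_test(taxa, meta, contrast)
        frame = daa_taxa.records_frame(records)
        frame.to_csv(OUT / f"{contrast}.tsv", sep="\t")
        down = daa_taxa.rank_top(records, "decreased", 10)
        up = daa_taxa.rank_top(records, "increased", 10)
        print(f"\n{contrast}: {int(frame['significant'].sum())} significant species")
        for r in down:
            print(f"  down {r.feature_id:<30s} log2FC={r.log2fc:+.2f} p_adj={r.p_adj:.2e}")
        for r in up:
            print(f"  up   {r.feature_id:<30s} log2FC={r.log2fc:+.2f} p_adj={r.p_adj:.2e}")
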