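"""Functional differential abundance of enzymes with the moderated t.

Filters the enzyme table to >=10%-prevalent, non-redundant EC features,
log-transforms, and tests the age and LS contrasts (HSIL is left out by
default: three subjects cannot support a functional comparison).  Tables
land in results/daa_enzymes/.
"""

from pathlib import Path

from vulvasig import daa_function, profile_io

COHORT = Path("results/cohort")
OUT = Path("results/daa_enzymes")

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    enzymes = profile_io.read_enzyme_table(COHORT / "enzyme_table.tsv")
    meta = profile_io.read_sample_meta(COHORT / "metadata.tsv")
    meta, _ = profile_io.filter_low_read_samples(meta)
    meta = profile_io.assign_age_quartiles(meta)
    enzymes = enzymes.subset_samples([s for s in enzymes.sample_ids if s in set(meta.sample_ids)])
    n_before = len(enzymes.feature_ids)
    enzymes = profile_io.filter_enzymes(enzymes)
    print(f"kept {len(enzymes.feature_ids)}/{n_before} EC features after prevalence/redundancy filter")

    logged = daa_function.log_transform(enzymes)
    for contrast in ("Q3Q4_vs_Q1Q2", "LS_vs_healthy"):
        results = daa_function.moderated_t_test(logged, meta, contrast)
        frame = daa_function.modt_frame(results)
        frame.to_csv(OUT / f"{contrast}.tsv", sep="\t")
        top = frame.reindex(frame["t_mod"].abs().sort_values(ascending=False).index).head(10)
        print(f"\n{contrast}: {int(frame['significant'].sum())} significant enzymes; top 10 by |t|:")
        for fid, row in top.iterrows():
            print(f"  {fid:<14s} log2FC={row['mean_diff']:+.2f} t={row['t_mod']:+.2f} p_adj={row['p_adj']:.2e}")
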