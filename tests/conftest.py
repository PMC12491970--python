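import numpy as np
import pandas as pd
import pytest

from vulvasig import synthetic_cohort
from vulvasig.profile_io import SampleMeta

METAPHLAN_FIXTURE = "\n".join(
    [
        "clade_name\tS1\tS2",
        "k__Bacteria\t100.0\t100.0",
        "k__Bacteria|p__Firmicutes\t60.0\t80.0",
        "k__Bacteria|p__Firmicutes|g__Staphylococcus\t40.0\t10.0",
        "k__Bacteria|p__Firmicutes|g__Staphylococcus|s__Staphylococcus_epidermidis\t12.5\t5.0",
        "k__Bacteria|p__Firmicutes|g__Staphylococcus|s__Staphylococcus_epidermidis|t__SGB7865\t12.5\t5.0",
        "k__Bacteria|p__Firmicutes|g__Finegoldia|s__Finegoldia_magna\t30.0\t20.0",
        "k__Bacteria|p__Actinobacteria|g__Cutibacterium|s__Cutibacterium_acnes\t27.5\t15.0",
        "k__Bacteria|p__Actinobacteria|g__Gardnerella|s__Gardnerella_vaginalis\t10.0\t45.0",
        "k__Bacteria|p__Firmicutes|g__Lactobacillus|s__Lactobacillus_iners\t20.0\t15.0",
    ]
)


@pytest.fixture
def metaphlan_file(tmp_path):
    path = tmp_path / "merged_abundance.tsv"
    path.write_text(METAPHLAN_FIXTURE + "\n")
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample simulated cohort with the default planted effects."""
    return synthetic_cohort.simulate_cohort(
        60, seed=123, effects=synthetic_cohort.default_effects()
    )


def two_group_meta(groups: pd.Series) -> SampleMeta:
    """Metadata where group 'B' is LS and group 'A' healthy."""
    return SampleMeta(
        pd.DataFrame(
            {
                "age": 40,
                "cohort": "TNO",
                "status": np.where(np.asarray(groups) == "B", "LS", "healthy"),
                "read_count": 100_000,
            },
            index=groups.index,
        )
    )
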