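import numpy as np
import pandas as pd
import pytest

from cellprs.containers import DosageMatrix
from cellprs.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced cohort used by most unit tests: fast but non-trivial."""
    return SimConfig(
        n_blocks=6,
        variants_per_block=12,
        n_haplotypes=120,
        n_subjects_per_group=25,
        genes_per_block=4,
        set_size=8,
        pairwise_overlap_target=0.25,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


def make_dosage_matrix(dosages, info=None, chrom="1", spacing=1000) -> DosageMatrix:
    """Hand-rolled DosageMatrix from a (subjects x variants) array."""
    dosages = np.asarray(dosages, dtype=float)
    n_sub, n_var = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * n_var,
            "pos": [1 + j * spacing for j in range(n_var)],
            "ref": ["A"] * n_var,
            "alt": ["G"] * n_var,
            "info": info if info is not None else [1.0] * n_var,
        }
    )
    subjects = [f"S{i + 1:03d}" for i in range(n_sub)]
    return DosageMatrix(subjects=subjects, variants=variants, dosages=dosages)
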