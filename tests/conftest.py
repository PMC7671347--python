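import numpy as np
import pandas as pd
import pytest

from polyploid_diel.simulate import (
    SimDesign,
    draw_library_sizes,
    make_gene_truth,
    simulate_diel_counts,
)

STUDY_HOURS = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0])


@pytest.fixture(scope="session")
def study_hours():
    return STUDY_HOURS


def make_meta(channel: str, hours=STUDY_HOURS, n_reps: int = 3) -> pd.DataFrame:
    """Sample-metadata table for one expression channel."""
    return pd.DataFrame(
        [
            {
                "sample_id": f"{channel}_t{int(t):02d}_r{r}",
                "cytotype": channel,
                "clock_hour": float(t),
                "replicate": r,
            }
            for t in hours
            for r in range(1, n_reps + 1)
        ]
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A 400-gene arrhythmic bundle with planted HEB categories."""
    design = SimDesign(n_genes=400, seed=0)
    truth = make_gene_truth(
        design, frac_rhythmic=0.0, dispersion=0.05,
        base_range=(500.0, 2000.0), bias_fold=2.0,
    )
    libs = draw_library_sizes(design)
    counts, meta = simulate_diel_counts(design, truth, libs)
    return design, truth, libs, counts, meta
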