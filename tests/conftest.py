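import numpy as np
import pandas as pd
import pytest

from epiterroir import simulate as sim


@pytest.fixture(scope="session")
def msap_small():
    """Small simulated MSAP dataset with a planted gradient (3 regions)."""
    ds, truth = sim.simulate_msap_dataset(
        n_regions=3, vineyards_per_region=3, plants_per_vineyard=4,
        n_msl=80, n_nml=30, seed=11,
    )
    return ds, truth


@pytest.fixture(scope="session")
def msgbs_recovery():
    """msGBS counts with 50 planted 4-fold DMMs over a toy annotated genome."""
    genes, mapping, ann_truth = sim.simulate_annotation(seed=5, n_genes=150)
    cm, truth = sim.simulate_msgbs_dataset(
        n_regions=2, samples_per_region=20, n_loci=1000, n_dmm=50,
        fold_change=4.0, dispersion=0.2, seed=5, annotation=(genes, ann_truth),
    )
    return cm, truth, genes, mapping, ann_truth


def binary_frame(rows, samples=None, loci=None):
    """Binary profile DataFrame from a list of 0/1/None rows."""
    arr = np.array(rows, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    loci = loci or [f"L{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=samples, columns=loci)
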