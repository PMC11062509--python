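import numpy as np
import pandas as pd
import pytest

from sgpipe import simdata
from sgpipe.types import GenotypeMatrix


@pytest.fixture(scope="session")
def noise_free_scene():
    """Small noise-free season: 30 plots, 12 flights, all stages resolvable."""
    return simdata.simulate_scene(
        n_acc=30, n_snp=60, n_flights=12, soil_fraction=0.0, noise_sd=0.0, seed=0
    )


@pytest.fixture(scope="session")
def small_geno():
    return simdata.simulate_genotypes(60, 40, seed=1)


def toy_genotypes(dosages, pos=None, chrom=None, ref=None, alt=None, labels=None):
    """Build a GenotypeMatrix from a raw dosage array for hand-sized tests."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    acc = np.array([f"a{i}" for i in range(n)])
    if labels is None:
        labels = pd.DataFrame(
            {"flowering_class": "MF", "era": "pre-1950", "region": "I", "group": "CL"},
            index=pd.Index(acc, name="accession"),
        )
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    chrom = np.array(["1A"] * m) if chrom is None else np.asarray(chrom)
    return GenotypeMatrix(
        dosages=dosages,
        chrom=chrom,
        pos_bp=pos,
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        accessions=acc,
        labels=labels,
        ref=ref,
        alt=alt,
    )
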