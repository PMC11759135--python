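import numpy as np
import pandas as pd
import pytest

from caprigen import (
    GenotypeMatrix,
    PhenotypeTable,
    SimConfig,
    blend,
    simulate_genotypes,
    simulate_phenotypes,
    vanraden_g,
)


def genotypes_from_dosages(dosages, missing=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage array (missing = -1)."""
    dosages = np.asarray(dosages, dtype=np.int16)
    if missing is None:
        missing = dosages < 0
    n, m = dosages.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        dosages=dosages,
        missing=np.asarray(missing, dtype=bool),
    )


def phenotypes_from_values(y, milk=None, year=None, trait_names=None) -> PhenotypeTable:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1:
        y = y.T
    n, t = y.shape
    trait_names = trait_names or [f"trait{k}" for k in range(t)]
    data = pd.DataFrame(y, columns=trait_names,
                        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
    data["milk_status"] = milk if milk is not None else "producing"
    data["birth_year"] = year if year is not None else "year1"
    return PhenotypeTable(data, trait_names)


@pytest.fixture(scope="session")
def small_population():
    """One shared simulated population: 200 goats x 800 markers, 3 traits."""
    cfg = SimConfig(n_individuals=200, n_markers=800, n_causal=200, seed=11)
    genos = simulate_genotypes(cfg)
    phenos = simulate_phenotypes(genos, cfg)
    G = blend(vanraden_g(genos), 0.95)
    return cfg, genos, phenos, G
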