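import numpy as np
import pandas as pd
import pytest

import migprs as M


@pytest.fixture(scope="session")
def small_panel():
    panel = M.make_variant_panel(n_variants=120, n_blocks=12, seed=11)
    return M.simulate_summary_stats(panel, 375_000, seed=12)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """Pedigree + genotypes + battery for ~40 families."""
    ped = M.generate_pedigrees(40, seed=21)
    geno = M.simulate_genotypes(ped, small_panel, seed=22)
    battery = M.simulate_phenotypes(geno, small_panel, seed=23)
    return ped, geno, battery


def make_battery(n=1, **true_fields):
    """A battery frame of all-False rows with the named fields set True."""
    df = pd.DataFrame(False, index=range(n), columns=M.BATTERY_COLUMNS)
    for f in true_fields:
        if f not in M.BATTERY_COLUMNS:
            raise KeyError(f)
        df[f] = True
    return df


def random_genotypes(rng, n, m, missing_rate=0.0, chrom=None, pos=None):
    """Toy GenotypeMatrix + positional panel for oracle tests."""
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    missing = rng.random((n, m)) < missing_rate
    dosage[missing] = 0
    vids = np.array([f"v{j}" for j in range(m)], dtype=object)
    ids = np.array([f"i{i}" for i in range(n)], dtype=object)
    geno = M.GenotypeMatrix(dosage, missing, ids, vids)
    panel = pd.DataFrame(
        {
            "variant_id": vids,
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
        }
    )
    return geno, panel
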