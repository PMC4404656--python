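import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ncoscan import pedio
from ncoscan.simulate import SimParams, simulate_pedigrees

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sim():
    """12 pedigrees, 2 x 10 Mb, inflated NCO rate; clean genotypes."""
    params = SimParams(
        n_pedigrees=12,
        chrom_lengths={"chr01": 10_000_000, "chr02": 10_000_000},
        nco_rate=5e-5,
        mean_tract_bp=300,
        gc_bias=0.68,
    )
    peds, gm, truth = simulate_pedigrees(params, 20260901)
    return params, peds, gm, truth


@pytest.fixture(scope="session")
def analyzed_small(small_sim):
    from ncoscan.pipeline import analyze

    params, peds, gm, truth = small_sim
    return params, peds, gm, truth, analyze(peds, gm)


def make_individuals(rows):
    return pd.DataFrame(
        rows, columns=["family", "id", "father", "mother", "sex", "role"]
    )


@pytest.fixture()
def twelve_member_family():
    """2 gen1 parents, 4 children, 2 analyzed with partner + 2 grandchildren."""
    rows = [
        ("F1", "P1", "0", "0", "M", "gen1"),
        ("F1", "P2", "0", "0", "F", "gen1"),
        ("F1", "C1", "P1", "P2", "M", "gen2"),
        ("F1", "C2", "P1", "P2", "F", "gen2"),
        ("F1", "C3", "P1", "P2", "M", "gen2"),
        ("F1", "C4", "P1", "P2", "F", "gen2"),
        ("F1", "C1P", "0", "0", "F", "gen2_partner"),
        ("F1", "C2P", "0", "0", "M", "gen2_partner"),
        ("F1", "G1", "C1", "C1P", "M", "gen3"),
        ("F1", "G2", "C1", "C1P", "F", "gen3"),
        ("F1", "G3", "C2P", "C2", "M", "gen3"),
        ("F1", "G4", "C2P", "C2", "F", "gen3"),
    ]
    return make_individuals(rows)


def write_ped(df, path):
    peds = pedio.build_pedigree_set(df)
    pedio.write_pedigree(peds, path)
    return peds


def genotype_matrix_from_arrays(chrom, positions, dosages_by_sample):
    """Build a GenotypeMatrix from {sample: dosage array}; A/G markers."""
    n = len(positions)
    markers = pedio.make_marker_table(
        [chrom] * n, positions, [f"m{i}" for i in range(n)],
        ["A"] * n, ["G"] * n,
    )
    samples = list(dosages_by_sample)
    dosage = np.vstack([dosages_by_sample[s] for s in samples]).T.astype(np.int8)
    return pedio.GenotypeMatrix(markers, dosage, samples)
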