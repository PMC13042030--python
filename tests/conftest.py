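import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gwarch.architecture import HitTable, ModelGrid, TraitParams, simulate_hits
from gwarch.demography import toy_demography
from gwarch.inference import InferenceConfig
from gwarch.sfs import SelectionGrid, build_sfs_table
from gwarch.spline_fs import SplineFS, TOY_KNOT_LOG10S, TOY_SUPPORT

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_table():
    """Shared SFS table for the toy demography (built once per session)."""
    return build_sfs_table(
        toy_demography(),
        SelectionGrid.toy(),
        replicates=1_000_000,
        seed=7,
        n_bins=40,
    )


@pytest.fixture(scope="session")
def fs_ref():
    return SplineFS.toy_reference()


@pytest.fixture(scope="session")
def fs_strong():
    return SplineFS.toy_strong()


@pytest.fixture(scope="session")
def toy_cfg():
    """Inference settings sized for the toy grid."""
    return InferenceConfig(
        knot_log10s=TOY_KNOT_LOG10S,
        support=TOY_SUPPORT,
        n_s=20,
        n_starts=2,
        nm_maxiter=100,
        outer_maxiter=18,
        inner_maxiter=12,
    )


@pytest.fixture(scope="session")
def ref_params():
    return TraitParams(h2=0.5, L=1e8, N=3e5, trait="ref-trait")


@pytest.fixture(scope="session")
def ref_grid(fs_ref, toy_table):
    return ModelGrid(fs_ref, toy_table, n_s=20)


@pytest.fixture(scope="session")
def ref_sim(ref_params, fs_ref, toy_table, ref_grid):
    """One canonical simulated hit table under the reference condition."""
    return simulate_hits(ref_params, fs_ref, toy_table, seed=5, grid=ref_grid)


def hit_table_from_arrays(maf, z, n, trait="t", blocks=None, seed=0):
    maf = np.asarray(maf, dtype=float)
    z = np.asarray(z, dtype=float)
    if blocks is None:
        blocks = np.random.default_rng(seed).integers(0, 50, size=len(maf))
    df = pd.DataFrame(
        {
            "trait": trait,
            "variant": [f"v{i:05d}" for i in range(len(maf))],
            "maf": maf,
            "z": z,
            "block": blocks,
        }
    )
    return HitTable(df, {trait: {"n": float(n)}})
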