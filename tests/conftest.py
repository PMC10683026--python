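"""Shared fixtures: expensive synthetic ground-truth datasets are built
once per session and reused by the module and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from coevocv.msa import sequence_weights
from coevocv.potts import apply_apc, coupling_matrix, fit_potts
from coevocv.synthetic import (
    TwoStateSpec,
    gibbs_sample_msa,
    planted_potts_model,
    sample_two_state_trajectory,
)
from coevocv.units import RT_STANDARD_KJ_PER_MOL

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_msa_recovery():
    """Gibbs-sampled MSA (L=20, q=21, 10 planted pairs, 2000 sequences)
    plus the fitted APC coupling map."""
    L = 20
    rng = np.random.default_rng(42)
    perm = rng.permutation(L)
    pairs = sorted(tuple(sorted((int(perm[2 * k]), int(perm[2 * k + 1])))) for k in range(10))
    model = planted_potts_model(L, pairs, strength=1.0, seed=1)
    msa = gibbs_sample_msa(model, 2000, burn_in=100, seed=2)
    weights = sequence_weights(msa)
    fitted = fit_potts(msa, weights, init="zeros", learning_rate=0.05, iterations=300)
    coevo = apply_apc(coupling_matrix(fitted))
    return {"pairs": set(pairs), "msa": msa, "weights": weights, "model": fitted, "coevo": coevo}


@pytest.fixture(scope="session")
def two_state_ln2():
    """10^5-frame Metropolis trajectory with exact 2/3 : 1/3 populations."""
    spec = TwoStateSpec(delta_u_kj_mol=RT_STANDARD_KJ_PER_MOL * np.log(2.0))
    return sample_two_state_trajectory(spec, 100_000, seed=3)
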