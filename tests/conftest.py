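import numpy as np
import pytest

from panelscrutiny import (
    CorrelationTriple,
    LongitudinalCorrelationMatrix,
    MoslaParams,
    simulate_from_corr,
)

#: the study's generating conditions used throughout the suite
STUDY_PARAMS = MoslaParams(phi_n=0.4, phi_c=0.4, phi_nc=0.1, psi=0.3, rho=0.5, theta=0.3)


def random_psd_triple(rng: np.random.Generator) -> CorrelationTriple:
    """A random valid (r_x1y1, r_x1y2, r_y1y2) triple: correlations of a
    random full-rank 3-variable Gram matrix."""
    a = rng.standard_normal((4, 3))
    w = a.T @ a
    d = np.sqrt(np.diag(w))
    r = w / np.outer(d, d)
    return CorrelationTriple(r[0, 1], r[0, 2], r[1, 2])


def triple_target(triple: CorrelationTriple) -> LongitudinalCorrelationMatrix:
    """Wrap a correlation triple as a labeled matrix over (X@1, Y@1, Y@2)."""
    return LongitudinalCorrelationMatrix(
        (("X", 1), ("Y", 1), ("Y", 2)), triple.matrix()
    )


def exact_data_from_triple(triple: CorrelationTriple, n: int = 561, seed: int = 0):
    """Standardized data whose empirical correlations equal the triple."""
    return simulate_from_corr(triple_target(triple), n=n, seed=seed, exact=True)


def three_construct_target(waves: int = 3) -> LongitudinalCorrelationMatrix:
    """A deterministic PSD correlation matrix over MPEE/MNEE/CU x 3 waves.

    Built from a trait-plus-shared-state process extended to three
    constructs (trait correlations of mixed sign), so it carries realistic
    cross-construct, cross-wave structure with unit diagonal.
    """
    trait_corr = np.array([[1.0, -0.2, -0.3], [-0.2, 1.0, 0.4], [-0.3, 0.4, 1.0]])
    phi, psi, rho, theta = 0.4, 0.3, 0.5, 0.3
    constructs = ("MPEE", "MNEE", "CU")
    labels = [(c, w) for c in constructs for w in range(1, waves + 1)]
    p = len(labels)
    values = np.empty((p, p))
    for i, (ci, wi) in enumerate(labels):
        for j, (cj, wj) in enumerate(labels):
            lag = abs(wi - wj)
            ii, jj = constructs.index(ci), constructs.index(cj)
            values[i, j] = phi * trait_corr[ii, jj] + psi * rho**lag
            if i == j:
                values[i, j] += theta
    return LongitudinalCorrelationMatrix(tuple(labels), values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def study_params():
    return STUDY_PARAMS
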