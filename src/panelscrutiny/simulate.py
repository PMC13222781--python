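"""Synthetic panel-data generators.

Three generating processes are provided:

* ``simulate_from_corr`` — multivariate-normal panel data matching a target
  correlation matrix, either in population (sampled) or exactly: the
  *empirical* correlation matrix of the returned sample equals the target
  to machine precision.  Standardized regression effects are functions of
  correlations alone, so analyses of exact-mode data coincide with the
  closed forms computed from the target matrix.
* ``simulate_mosla`` — data from the model of spurious longitudinal
  associations (MoSLA): stable trait factors per construct plus a shared,
  autocorrelated occasion-state factor and iid measurement noise, with no
  direct effects among the observed scores.
* ``simulate_common_cause`` — a minimal three-variable demonstration in
  which a common cause loads on X1, Y1, Y2 and Y1 feeds Y2, but there is
  no direct X1 -> Y2 path; cross-lagged regressions on such data still
  return nonzero coefficients.

All generators take one integer seed; independent sub-streams are derived
from it deterministically so that, e.g., adding waves does not perturb
earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import Label, LongitudinalCorrelationMatrix, PanelDataset
from .exceptions import ParameterError, SchemaError, SpecificationError


# --------------------------------------------------------------------------
# MoSLA process
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MoslaParams:
    """Parameters of the MoSLA generating process.

    Attributes
    ----------
    phi_n, phi_c : float
        Trait variances of the two constructs (> 0).
    phi_nc : float
        Trait covariance; |phi_nc| <= sqrt(phi_n * phi_c).
    psi : float
        Stationary variance of the shared occasion-state factor (>= 0).
    rho : float
        State autocorrelation, |rho| < 1.  Stationarity is enforced by
        construction: state disturbances have variance psi * (1 - rho**2).
    theta : float
        Measurement-residual variance, one value shared by all indicators
        (>= 0 for generation; an ML fit keeps it strictly positive).

    With ``phi + psi + theta = 1`` for each construct the implied observed
    variances are 1 and the process generates standardized scores in
    population.
    """

    phi_n: float
    phi_c: float
    phi_nc: float
    psi: float
    rho: float
    theta: float

    def __post_init__(self):
        if not (self.phi_n > 0 and self.phi_c > 0):
            raise ParameterError("trait variances must be positive")
        if self.psi < 0:
            raise ParameterError("state variance psi must be >= 0")
        if self.theta < 0:
            raise ParameterError("residual variance theta must be >= 0")
        if not abs(self.rho) < 1:
            raise ParameterError("state autocorrelation must satisfy |rho| < 1")
        if abs(self.phi_nc) > math.sqrt(self.phi_n * self.phi_c) + 1e-12:
            raise ParameterError("|phi_nc| may not exceed sqrt(phi_n * phi_c)")

    @property
    def is_standardized(self) -> bool:
        """True when both implied total variances equal 1."""
        return (
            abs(self.phi_n + self.psi + self.theta - 1) < 1e-12
            and abs(self.phi_c + self.psi + self.theta - 1) < 1e-12
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "phi_n": self.phi_n,
            "phi_c": self.phi_c,
            "phi_nc": self.phi_nc,
            "psi": self.psi,
            "rho": self.rho,
            "theta": self.theta,
        }


#: study-scale defaults: standardized generation (phi + psi + theta = 1),
#: moderate trait overlap and state autocorrelation
DEFAULT_MOSLA_PARAMS = MoslaParams(
    phi_n=0.4, phi_c=0.4, phi_nc=0.1, psi=0.3, rho=0.5, theta=0.3
)

#: the original study's sample size and design
STUDY_N = 561
STUDY_WAVES = 3


def mosla_labels(waves: int, constructs: tuple[str, str] = ("N", "C")) -> tuple[Label, ...]:
    """Construct-major variable ordering: N@1..N@W, C@1..C@W."""
    a, b = constructs
    return tuple([(a, w) for w in range(1, waves + 1)] + [(b, w) for w in range(1, waves + 1)])


def implied_cov_mosla(
    params: MoslaParams,
    waves: int,
    constructs: tuple[str, str] = ("N", "C"),
) -> tuple[tuple[Label, ...], np.ndarray]:
    """Closed-form implied covariance of the MoSLA.

    cov(N_t, N_u) = phi_n + psi * rho**|t-u| + [t == u] * theta,
    cov(C_t, C_u) = phi_c + psi * rho**|t-u| + [t == u] * theta,
    cov(N_t, C_u) = phi_nc + psi * rho**|t-u|.

    Returns the labels (construct-major ordering) and the (2W x 2W)
    covariance matrix.  An independent RAM-matrix derivation of the same
    quantity lives in :mod:`panelscrutiny.mosla`.
    """
    if waves < 2:
        raise ParameterError("waves must be >= 2")
    labels = mosla_labels(waves, constructs)
    t = np.arange(waves)
    lag = np.abs(t[:, None] - t[None, :])
    state = params.psi * params.rho ** lag
    eye = np.eye(waves)
    nn = params.phi_n + state + params.theta * eye
    cc = params.phi_c + state + params.theta * eye
    nc = params.phi_nc + state
    cov = np.block([[nn, nc], [nc.T, cc]])
    return labels, cov


def simulate_mosla(
    params: MoslaParams,
    n: int = STUDY_N,
    waves: int = STUDY_WAVES,
    seed: int | None = None,
    constructs: tuple[str, str] = ("N", "C"),
) -> PanelDataset:
    """Draw an n-subject panel from the MoSLA process.

    Traits come from a bivariate normal with covariance (phi_n, phi_c,
    phi_nc); the shared state starts at Normal(0, psi) and evolves as an
    AR(1) with disturbance variance psi * (1 - rho**2); residuals are iid
    Normal(0, theta).  Observed score = trait + state + residual.
    """
    if n < 10:
        raise ParameterError("n must be >= 10")
    if waves < 2:
        raise ParameterError("waves must be >= 2")
    rng_traits, rng_states, rng_resid = np.random.default_rng(seed).spawn(3)

    trait_cov = np.array([[params.phi_n, params.phi_nc], [params.phi_nc, params.phi_c]])
    chol = np.linalg.cholesky(trait_cov + 1e-15 * np.eye(2))
    traits = rng_traits.standard_normal((n, 2)) @ chol.T

    states = np.empty((n, waves))
    states[:, 0] = rng_states.normal(0.0, math.sqrt(params.psi), size=n) if params.psi > 0 else 0.0
    dist_sd = math.sqrt(params.psi * (1 - params.rho**2))
    for t in range(1, waves):
        innov = rng_states.normal(0.0, dist_sd, size=n) if dist_sd > 0 else 0.0
        states[:, t] = params.rho * states[:, t - 1] + innov

    resid_sd = math.sqrt(params.theta)
    scores = np.empty((n, 2 * waves))
    for t in range(waves):  # wave-by-wave residual draws keep early waves stable
        res = rng_resid.normal(0.0, resid_sd, size=(n, 2))
        scores[:, t] = traits[:, 0] + states[:, t] + res[:, 0]
        scores[:, waves + t] = traits[:, 1] + states[:, t] + res[:, 1]

    return PanelDataset(mosla_labels(waves, constructs), scores)


# --------------------------------------------------------------------------
# Correlation-matrix-driven simulation
# --------------------------------------------------------------------------

def _psd_sqrtm(a: np.ndarray, clip: float = 0.0) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition (negatives clipped)."""
    vals, vecs = np.linalg.eigh((a + a.T) / 2.0)
    vals = np.clip(vals, clip, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def simulate_from_corr(
    target: LongitudinalCorrelationMatrix,
    n: int = STUDY_N,
    seed: int | None = None,
    exact: bool = True,
) -> PanelDataset:
    """Generate standardized panel data whose correlation structure matches
    ``target``.

    exact=False draws from a multivariate normal with population
    correlation equal to the target.  exact=True makes the *empirical*
    correlation matrix equal the target to ~1e-10: iid normal deviates are
    column-centered, empirically whitened with the inverse symmetric square
    root of their sample covariance, then colored with the symmetric square
    root of the target.  Symmetric (not triangular) factors avoid any order
    dependence among variables.  In both modes the returned columns have
    mean 0 and SD 1 under the population divisor.
    """
    p = target.p
    rng = np.random.default_rng(seed)
    if exact:
        if n <= p:
            raise ParameterError(f"exact mode needs n > p (got n={n}, p={p})")
        z = rng.standard_normal((n, p))
        z -= z.mean(axis=0)
        cov = z.T @ z / n
        vals, vecs = np.linalg.eigh(cov)
        if vals.min() <= 1e-12:
            raise np.linalg.LinAlgError("degenerate deviate matrix; re-seed")
        whitener = (vecs / np.sqrt(vals)) @ vecs.T
        scores = z @ whitener @ _psd_sqrtm(target.values)
        # exact-mode columns are z-scores by construction; scrub rounding
        scores -= scores.mean(axis=0)
        return PanelDataset(target.labels, scores, standardized=True)
    scores = rng.multivariate_normal(
        np.zeros(p), target.values, size=n, method="eigh"
    )
    data = PanelDataset(target.labels, scores)
    return data.standardize()


# --------------------------------------------------------------------------
# Common-cause demonstration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CommonCauseSpec:
    """Standardized common-cause model for X1, Y1, Y2.

    A latent common cause CC (standard normal) loads on all three observed
    variables and Y1 has a direct path to Y2; there is *no* X1 -> Y2 path.
    Unique variances are implied so each observed variable has unit
    variance in population.
    """

    load_cc_x1: float
    load_cc_y1: float
    load_cc_y2: float
    auto_y1_y2: float

    def __post_init__(self):
        for name, var in self.unique_variances().items():
            if var < -1e-12:
                raise SpecificationError(
                    f"implied unique variance of {name} is negative ({var:.4f})"
                )
        for pair, r in zip(("x1,y1", "x1,y2", "y1,y2"), self.implied_corr()):
            if abs(r) > 1 + 1e-12:
                raise SpecificationError(f"implied |r_{pair}| = {abs(r):.4f} > 1")

    def implied_corr(self) -> tuple[float, float, float]:
        """Path-tracing correlations (r_x1y1, r_x1y2, r_y1y2)."""
        r_x1y1 = self.load_cc_x1 * self.load_cc_y1
        r_x1y2 = self.load_cc_x1 * (self.load_cc_y2 + self.auto_y1_y2 * self.load_cc_y1)
        r_y1y2 = self.load_cc_y1 * self.load_cc_y2 + self.auto_y1_y2
        return r_x1y1, r_x1y2, r_y1y2

    def unique_variances(self) -> dict[str, float]:
        explained_y2 = (
            self.load_cc_y2**2
            + self.auto_y1_y2**2
            + 2 * self.load_cc_y2 * self.auto_y1_y2 * self.load_cc_y1
        )
        return {
            "X1": 1 - self.load_cc_x1**2,
            "Y1": 1 - self.load_cc_y1**2,
            "Y2": 1 - explained_y2,
        }


def implied_corr_common_cause(spec: CommonCauseSpec) -> tuple[float, float, float]:
    """Correlations (r_x1y1, r_x1y2, r_y1y2) implied by the common-cause
    model, by the path-tracing rules for standardized variables."""
    return spec.implied_corr()


def simulate_common_cause(
    spec: CommonCauseSpec,
    n: int,
    seed: int | None = None,
) -> PanelDataset:
    """Draw (X1, Y1, Y2) from the common-cause process.

    The returned dataset has variables X@1, Y@1, Y@2 (the exposure is only
    measured at wave 1, so the variable grid is deliberately incomplete).
    """
    if n < 10:
        raise ParameterError("n must be >= 10")
    rng_cc, rng_unique = np.random.default_rng(seed).spawn(2)
    uv = spec.unique_variances()
    cc = rng_cc.standard_normal(n)
    e = rng_unique.standard_normal((n, 3)) * np.sqrt(
        np.clip([uv["X1"], uv["Y1"], uv["Y2"]], 0.0, None)
    )
    x1 = spec.load_cc_x1 * cc + e[:, 0]
    y1 = spec.load_cc_y1 * cc + e[:, 1]
    y2 = spec.load_cc_y2 * cc + spec.auto_y1_y2 * y1 + e[:, 2]
    return PanelDataset((("X", 1), ("Y", 1), ("Y", 2)), np.column_stack([x1, y1, y2]))
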