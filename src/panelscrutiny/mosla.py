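"""Maximum-likelihood engine for the model of spurious longitudinal
associations (MoSLA).

The MoSLA explains longitudinal scores on two constructs (N and C, each
observed at waves 1..W) through

* stable trait factors gN and gC with free variances phi_n, phi_c and a
  free covariance phi_nc,
* a single occasion-state factor ST_t per wave, shared by both constructs,
  following a stationary AR(1) with autocorrelation rho and stationary
  variance psi (disturbance variance psi * (1 - rho**2)), and
* iid measurement residuals with one shared variance theta.

All loadings are fixed at 1 and there are no direct effects among the
observed scores, so any cross-lagged regression effect found in data
generated this way is spurious.  With six free parameters and W = 3 the
model leaves 21 - 6 = 15 degrees of freedom.

The implied covariance is assembled from RAM path matrices,
Sigma = F (I - A)^-1 S (I - A)^-T F^T, and the ML discrepancy

    F_ML = ln|Sigma| + tr(S_obs Sigma^-1) - ln|S_obs| - p

is minimized over transformed parameters (log variances, atanh-transformed
correlations) with an analytic gradient, quasi-Newton iterations and a
damped-Newton polish.  chi2 = (n - 1) * F_min by default (Wishart
convention; a multiplier of n is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import Label, LongitudinalCorrelationMatrix, PanelDataset
from .exceptions import ConvergenceError, ParameterError, SchemaError
from .simulate import MoslaParams, implied_cov_mosla, mosla_labels

PARAM_NAMES = ("phi_n", "phi_c", "phi_nc", "psi", "rho", "theta")

_LOG_LO, _LOG_HI = -30.0, 10.0
_ATANH_LIM = 12.0


# --------------------------------------------------------------------------
# Model specification (RAM matrices)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MoslaSpec:
    """Structural specification of the MoSLA for a given number of waves.

    Variables are ordered observed-first, construct-major
    (N@1..N@W, C@1..C@W), followed by latents (gN, gC, ST_1..ST_W).
    """

    waves: int
    constructs: tuple[str, str] = ("N", "C")

    def __post_init__(self):
        if self.waves < 2:
            raise ParameterError("the MoSLA needs at least two waves")

    @property
    def observed(self) -> tuple[Label, ...]:
        return mosla_labels(self.waves, self.constructs)

    @property
    def latents(self) -> tuple[str, ...]:
        a, b = self.constructs
        return (f"g{a}", f"g{b}") + tuple(f"ST_{t}" for t in range(1, self.waves + 1))

    @property
    def p(self) -> int:
        return 2 * self.waves

    @property
    def n_moments(self) -> int:
        return self.p * (self.p + 1) // 2

    @property
    def n_free(self) -> int:
        return len(PARAM_NAMES)

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free

    def ram_matrices(self, params: MoslaParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """RAM matrices (A, S, F) over the combined observed+latent vector.

        A holds directed paths (all loadings fixed at 1; ST_{t-1} -> ST_t
        is rho); S holds exogenous (co)variances: trait covariance block,
        the ST_1 stationary variance psi, AR disturbance variances
        psi * (1 - rho**2), and residual variances theta.
        """
        w, p = self.waves, self.p
        m = p + 2 + w  # total variables
        i_gn, i_gc = p, p + 1
        i_st = [p + 2 + t for t in range(w)]

        a = np.zeros((m, m))
        for t in range(w):
            a[t, i_gn] = 1.0  # N_t <- gN
            a[t, i_st[t]] = 1.0  # N_t <- ST_t
            a[w + t, i_gc] = 1.0  # C_t <- gC
            a[w + t, i_st[t]] = 1.0  # C_t <- ST_t
        for t in range(1, w):
            a[i_st[t], i_st[t - 1]] = params.rho

        s = np.zeros((m, m))
        s[:p, :p] = params.theta * np.eye(p)
        s[i_gn, i_gn] = params.phi_n
        s[i_gc, i_gc] = params.phi_c
        s[i_gn, i_gc] = s[i_gc, i_gn] = params.phi_nc
        s[i_st[0], i_st[0]] = params.psi
        for t in range(1, w):
            s[i_st[t], i_st[t]] = params.psi * (1 - params.rho**2)

        f = np.zeros((p, m))
        f[:, :p] = np.eye(p)
        return a, s, f


def build_spec(waves: int, constructs: tuple[str, str] = ("N", "C")) -> MoslaSpec:
    """Construct the MoSLA specification; waves=3 yields df = 15."""
    return MoslaSpec(waves=waves, constructs=constructs)


def implied_cov(spec: MoslaSpec, params: MoslaParams) -> np.ndarray:
    """Model-implied covariance via the RAM formula
    Sigma = F (I - A)^-1 S (I - A)^-T F^T."""
    a, s, f = spec.ram_matrices(params)
    inv = np.linalg.inv(np.eye(a.shape[0]) - a)
    return f @ inv @ s @ inv.T @ f.T


# --------------------------------------------------------------------------
# Transformed parameter space
# --------------------------------------------------------------------------

def _x_to_params(x: np.ndarray) -> MoslaParams:
    phi_n, phi_c = math.exp(x[0]), math.exp(x[1])
    r_t = math.tanh(x[2])
    return MoslaParams(
        phi_n=phi_n,
        phi_c=phi_c,
        phi_nc=r_t * math.sqrt(phi_n * phi_c),
        psi=math.exp(x[3]),
        rho=math.tanh(x[4]),
        theta=math.exp(x[5]),
    )


def _params_to_x(params: MoslaParams) -> np.ndarray:
    r_t = params.phi_nc / math.sqrt(params.phi_n * params.phi_c)
    r_t = min(max(r_t, -0.999), 0.999)
    rho = min(max(params.rho, -0.999), 0.999)
    return np.array(
        [
            math.log(params.phi_n),
            math.log(params.phi_c),
            math.atanh(r_t),
            math.log(max(params.psi, 1e-12)),
            math.atanh(rho),
            math.log(params.theta),
        ]
    )


def _transform_jacobian(x: np.ndarray) -> np.ndarray:
    """d(natural params)/dx, rows ordered as PARAM_NAMES."""
    p = _x_to_params(x)
    r_t = math.tanh(x[2])
    j = np.zeros((6, 6))
    j[0, 0] = p.phi_n
    j[1, 1] = p.phi_c
    j[2, 0] = 0.5 * p.phi_nc
    j[2, 1] = 0.5 * p.phi_nc
    j[2, 2] = math.sqrt(p.phi_n * p.phi_c) * (1 - r_t**2)
    j[3, 3] = p.psi
    j[4, 4] = 1 - p.rho**2
    j[5, 5] = p.theta
    return j


class _Objective:
    """ML discrepancy and its analytic gradient in transformed coordinates."""

    def __init__(self, spec: MoslaSpec, s_obs: np.ndarray):
        self.spec = spec
        self.s = s_obs
        sign, self.logdet_s = np.linalg.slogdet(s_obs)
        if sign <= 0:
            raise SchemaError("sample covariance must be positive definite")
        self.p = spec.p
        w = spec.waves
        t = np.arange(w)
        self.lag = np.abs(t[:, None] - t[None, :])
        ones = np.ones((w, w))
        zero = np.zeros((w, w))
        self.e_nn = np.block([[ones, zero], [zero, zero]])
        self.e_cc = np.block([[zero, zero], [zero, ones]])
        self.e_x = np.block([[zero, ones], [ones, zero]])

    def sigma(self, x: np.ndarray) -> np.ndarray:
        return implied_cov_mosla(_x_to_params(x), self.spec.waves)[1]

    def value(self, x: np.ndarray) -> float:
        sigma = self.sigma(x)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        inv = np.linalg.inv(sigma)
        return float(logdet + np.trace(self.s @ inv) - self.logdet_s - self.p)

    def _dsigma(self, x: np.ndarray) -> list[np.ndarray]:
        params = _x_to_params(x)
        w = self.spec.waves
        r_t = math.tanh(x[2])
        rho_pow = params.rho ** self.lag
        r_full = np.tile(rho_pow, (2, 2))
        dr = np.where(self.lag > 0, self.lag * params.rho ** np.maximum(self.lag - 1, 0), 0.0)
        dr_full = np.tile(dr, (2, 2))
        return [
            params.phi_n * self.e_nn + 0.5 * params.phi_nc * self.e_x,
            params.phi_c * self.e_cc + 0.5 * params.phi_nc * self.e_x,
            math.sqrt(params.phi_n * params.phi_c) * (1 - r_t**2) * self.e_x,
            params.psi * r_full,
            params.psi * (1 - params.rho**2) * dr_full,
            params.theta * np.eye(2 * w),
        ]

    def gradient(self, x: np.ndarray) -> np.ndarray:
        sigma = self.sigma(x)
        try:
            inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return np.zeros(6)
        m = inv - inv @ self.s @ inv
        return np.array([float(np.sum(m * d)) for d in self._dsigma(x)])

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        return self.value(x), self.gradient(x)


def _numeric_hessian(grad_fn, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    h = np.zeros((len(x), len(x)))
    for k in range(len(x)):
        dx = np.zeros_like(x)
        dx[k] = step
        h[:, k] = (grad_fn(x + dx) - grad_fn(x - dx)) / (2 * step)
    return (h + h.T) / 2


# --------------------------------------------------------------------------
# Fit statistics
# --------------------------------------------------------------------------

def chi2_pvalue(chi2: float, df: int) -> float:
    """Upper-tail probability of the central chi-square distribution."""
    if chi2 < 0 or df < 1:
        raise ParameterError("need chi2 >= 0 and df >= 1")
    return float(stats.chi2.sf(chi2, df))


def rmsea(chi2: float, df: int, n: int) -> float:
    """Point RMSEA = sqrt(max(chi2 - df, 0) / (df * (n - 1)))."""
    return math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))


def _ncx2_cdf(x: float, df: int, nc: float) -> float:
    if nc <= 0:
        return float(stats.chi2.cdf(x, df))
    return float(stats.ncx2.cdf(x, df, nc))


def _solve_noncentrality(chi2: float, df: int, prob: float) -> float:
    """The noncentrality lambda with P(X2(df, lambda) <= chi2) = prob,
    or 0 when no nonnegative solution exists (cdf decreases in lambda)."""
    if _ncx2_cdf(chi2, df, 0.0) <= prob:
        return 0.0
    hi = 10.0 * df * max(chi2, 1.0)
    if _ncx2_cdf(chi2, df, hi) > prob:
        raise ConvergenceError(
            "noncentrality bracket exhausted",
            {"chi2": chi2, "df": df, "prob": prob, "hi": hi},
        )
    return float(
        optimize.brentq(lambda nc: _ncx2_cdf(chi2, df, nc) - prob, 0.0, hi, xtol=1e-10)
    )


def rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Confidence interval for RMSEA by inverting the noncentral
    chi-square distribution of the test statistic."""
    if chi2 < 0:
        raise ParameterError("chi2 must be >= 0")
    alpha = 1.0 - level
    lam_lo = _solve_noncentrality(chi2, df, 1.0 - alpha / 2.0)
    lam_hi = _solve_noncentrality(chi2, df, alpha / 2.0)
    scale = df * (n - 1)
    return math.sqrt(lam_lo / scale), math.sqrt(lam_hi / scale)


@dataclass(frozen=True)
class FitIndices:
    """Standard SEM fit summary (independence baseline for CFI/TLI)."""

    chi2: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci_low: float
    rmsea_ci_high: float
    baseline_chi2: float
    baseline_df: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compute_fit_indices(
    chi2: float,
    df: int,
    n: int,
    baseline_chi2: float,
    baseline_df: int,
    level: float = 0.90,
) -> FitIndices:
    """Assemble CFI, TLI, RMSEA (+ CI) from model and baseline chi-squares.

    Undefined indices (degenerate baseline) are reported as NaN rather
    than fabricated.
    """
    excess = max(chi2 - df, 0.0)
    cfi_denom = max(baseline_chi2 - baseline_df, excess, 0.0)
    cfi = 1.0 - excess / cfi_denom if cfi_denom > 0 else 1.0
    tli_denom = baseline_chi2 / baseline_df - 1.0 if baseline_df > 0 else 0.0
    if tli_denom > 0 and df > 0:
        tli = (baseline_chi2 / baseline_df - chi2 / df) / tli_denom
    else:
        tli = float("nan")
    lo, hi = rmsea_ci(chi2, df, n, level)
    return FitIndices(
        chi2=chi2,
        df=df,
        p_value=chi2_pvalue(chi2, df),
        cfi=cfi,
        tli=tli,
        rmsea=rmsea(chi2, df, n),
        rmsea_ci_low=lo,
        rmsea_ci_high=hi,
        baseline_chi2=baseline_chi2,
        baseline_df=baseline_df,
    )


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

class MoslaModel:
    """MoSLA fitted to a sample covariance matrix by maximum likelihood.

    Parameters
    ----------
    cov : ndarray, shape (2W, 2W)
        Sample covariance (or correlation) matrix in construct-major order
        (N@1..N@W, C@1..C@W); must be positive definite.
    n : int
        Sample size behind ``cov``.
    spec : MoslaSpec, optional
        Defaults to ``build_spec(waves)`` inferred from the matrix size.
    """

    def __init__(self, cov: np.ndarray, n: int, spec: MoslaSpec | None = None):
        cov = np.asarray(cov, dtype=float)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise SchemaError("cov must be square")
        if cov.shape[0] % 2:
            raise SchemaError("two constructs require an even number of variables")
        waves = cov.shape[0] // 2
        self.spec = spec if spec is not None else build_spec(waves)
        if self.spec.p != cov.shape[0]:
            raise SchemaError("spec size does not match the covariance matrix")
        if n <= self.spec.p:
            raise SchemaError("n must exceed the number of observed variables")
        if np.max(np.abs(cov - cov.T)) > 1e-10:
            raise SchemaError("cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise SchemaError("cov must be positive definite")
        self.s = (cov + cov.T) / 2.0
        self.n = int(n)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_data(
        cls,
        data: PanelDataset,
        constructs: tuple[str, str] | None = None,
        ddof: int = 1,
    ) -> "MoslaModel":
        """Build from subject-level panel data (covariance divisor n-1 by
        default, pairing with the (n-1) chi-square multiplier)."""
        if constructs is None:
            constructs = tuple(data.constructs)
        if len(constructs) != 2:
            raise SchemaError("the MoSLA analyzes exactly two constructs")
        waves = data.waves
        order = [data.index(c, w) for c in constructs for w in range(1, waves + 1)]
        sub = data.scores[:, order]
        cov = np.cov(sub, rowvar=False, ddof=ddof)
        return cls(cov, data.n, build_spec(waves, tuple(constructs)))

    @classmethod
    def from_corr(
        cls, corr: LongitudinalCorrelationMatrix, n: int,
        constructs: tuple[str, str] | None = None,
    ) -> "MoslaModel":
        if constructs is None:
            constructs = tuple(corr.constructs)
        waves = corr.waves
        order = [corr.index(c, w) for c in constructs for w in range(1, waves + 1)]
        values = corr.values[np.ix_(order, order)]
        return cls(values, n, build_spec(waves, tuple(constructs)))

    # -- starting values ---------------------------------------------------
    def _moment_start(self) -> np.ndarray:
        s, w = self.s, self.spec.waves
        cross = s[:w, w:]
        lag = np.abs(np.subtract.outer(np.arange(w), np.arange(w)))
        c = [float(cross[lag == l].mean()) for l in range(w)]
        if w >= 3 and abs(c[0] - c[1]) > 1e-8:
            rho0 = (c[1] - c[2]) / (c[0] - c[1])
        else:
            rho0 = 0.3
        rho0 = float(np.clip(rho0, -0.9, 0.9))
        psi0 = (c[0] - c[1]) / (1 - rho0) if abs(1 - rho0) > 1e-8 else 0.1
        psi0 = float(np.clip(psi0, 1e-3, None))
        phi_nc0 = c[0] - psi0

        def trait_var(block: np.ndarray) -> float:
            off = [block[lag == l].mean() - psi0 * rho0**l for l in range(1, w)]
            return float(np.clip(np.mean(off), 1e-3, None))

        phi_n0 = trait_var(s[:w, :w])
        phi_c0 = trait_var(s[w:, w:])
        total = float(np.diag(s).mean())
        theta0 = float(np.clip(total - 0.5 * (phi_n0 + phi_c0) - psi0, 1e-3, None))
        lim = 0.99 * math.sqrt(phi_n0 * phi_c0)
        phi_nc0 = float(np.clip(phi_nc0, -lim, lim))
        start = MoslaParams(phi_n0, phi_c0, phi_nc0, psi0, rho0, theta0)
        return _params_to_x(start)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        chi2_multiplier: str = "nm1",
        n_restarts: int = 5,
        seed: int = 0,
        tol_grad: float = 1e-8,
    ) -> "MoslaResults":
        """Minimize the ML discrepancy; converged when the projected
        gradient max-norm falls below ``tol_grad``.  Failing starts fall
        back to ``n_restarts`` perturbed restarts; if none converges a
        :class:`ConvergenceError` with best-so-far diagnostics is raised.
        """
        if chi2_multiplier not in ("nm1", "n"):
            raise ParameterError("chi2_multiplier must be 'nm1' or 'n'")
        obj = _Objective(self.spec, self.s)
        bounds = [
            (_LOG_LO, _LOG_HI), (_LOG_LO, _LOG_HI), (-_ATANH_LIM, _ATANH_LIM),
            (_LOG_LO, _LOG_HI), (-_ATANH_LIM, _ATANH_LIM), (_LOG_LO, _LOG_HI),
        ]
        rng = np.random.default_rng(seed)
        try:
            x0 = self._moment_start()
        except (ParameterError, ValueError):
            x0 = _params_to_x(MoslaParams(0.3, 0.3, 0.05, 0.2, 0.3, 0.4))
        starts = [x0]
        for _ in range(n_restarts):
            starts.append(np.clip(x0 + rng.normal(scale=0.5, size=6), -8, 8))

        best = None  # (f, x, gnorm)
        for start in starts:
            res = optimize.minimize(
                obj.value_and_grad, start, jac=True, method="L-BFGS-B",
                bounds=bounds, options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
            )
            x, f = self._polish(obj, res.x, bounds)
            gnorm = self._projected_gnorm(obj, x, bounds)
            if best is None or f < best[0] - 1e-14 or (abs(f - best[0]) < 1e-12 and gnorm < best[2]):
                best = (f, x, gnorm)
        f_min, x_opt, gnorm = best
        converged = gnorm < tol_grad
        if not converged:
            raise ConvergenceError(
                "MoSLA optimization did not reach the gradient tolerance",
                {"F_min": f_min, "grad_norm": gnorm, "x": x_opt.tolist()},
            )
        mult = (self.n - 1) if chi2_multiplier == "nm1" else self.n
        params = _x_to_params(x_opt)
        se, cov_params = self._standard_errors(obj, x_opt, mult)
        f_min = max(f_min, 0.0)
        chi2 = mult * f_min
        return MoslaResults(
            model=self,
            params=params,
            se=se,
            cov_params=cov_params,
            x_opt=x_opt,
            f_min=f_min,
            chi2=chi2,
            df=self.spec.df,
            p_value=chi2_pvalue(chi2, self.spec.df),
            chi2_multiplier=chi2_multiplier,
            converged=converged,
            grad_norm=gnorm,
        )

    @staticmethod
    def _projected_gnorm(obj: _Objective, x: np.ndarray, bounds) -> float:
        g = obj.gradient(x)
        for k, (lo, hi) in enumerate(bounds):
            if x[k] <= lo + 1e-12 and g[k] > 0:
                g[k] = 0.0
            if x[k] >= hi - 1e-12 and g[k] < 0:
                g[k] = 0.0
        return float(np.max(np.abs(g)))

    @staticmethod
    def _polish(obj: _Objective, x: np.ndarray, bounds, max_iter: int = 40):
        """Damped-Newton refinement to drive the gradient to ~1e-12."""
        x = x.copy()
        f = obj.value(x)
        for _ in range(max_iter):
            g = obj.gradient(x)
            if np.max(np.abs(g)) < 1e-12:
                break
            h = _numeric_hessian(obj.gradient, x)
            lam = 1e-10
            for _ in range(12):
                try:
                    step = np.linalg.solve(h + lam * np.eye(6), -g)
                except np.linalg.LinAlgError:
                    lam *= 10
                    continue
                cand = np.clip(x + step, [b[0] for b in bounds], [b[1] for b in bounds])
                f_cand = obj.value(cand)
                if f_cand <= f + 1e-14:
                    x, f = cand, f_cand
                    break
                lam *= 10
            else:
                break
        return x, f

    def _standard_errors(self, obj: _Objective, x_opt: np.ndarray, mult: int):
        h = (mult / 2.0) * _numeric_hessian(obj.gradient, x_opt)
        # pinv tolerates boundary solutions (psi -> 0) with flat directions
        cov_x = np.linalg.pinv(h, rcond=1e-12)
        j = _transform_jacobian(x_opt)
        cov_nat = j @ cov_x @ j.T
        diag = np.clip(np.diag(cov_nat), 0.0, None)
        se = dict(zip(PARAM_NAMES, np.sqrt(diag)))
        return se, pd.DataFrame(cov_nat, index=PARAM_NAMES, columns=PARAM_NAMES)


def fit_ml(spec: MoslaSpec, s: np.ndarray, n: int, **kwargs) -> "MoslaResults":
    """Functional entry point: fit the MoSLA to a sample covariance."""
    return MoslaModel(s, n, spec=spec).fit(**kwargs)


@dataclass
class MoslaResults:
    """ML solution of the MoSLA with fit statistics.

    Carries point estimates (``params``), delta-method standard errors on
    the natural scale (``se``), the minimized discrepancy and chi-square
    test, and methods for fit indices, the standardized solution and a
    text summary.
    """

    model: MoslaModel
    params: MoslaParams
    se: dict[str, float]
    cov_params: pd.DataFrame = field(repr=False)
    x_opt: np.ndarray = field(repr=False)
    f_min: float
    chi2: float
    df: int
    p_value: float
    chi2_multiplier: str
    converged: bool
    grad_norm: float

    @property
    def n(self) -> int:
        return self.model.n

    @property
    def s(self) -> np.ndarray:
        return self.model.s

    @property
    def implied_cov(self) -> np.ndarray:
        return implied_cov(self.model.spec, self.params)

    def baseline(self) -> tuple[float, int]:
        """Independence baseline (free variances, zero covariances): its
        ML chi-square has the closed form mult * (sum log s_ii - log|S|)."""
        mult = (self.n - 1) if self.chi2_multiplier == "nm1" else self.n
        s = self.s
        f_b = float(np.sum(np.log(np.diag(s))) - np.linalg.slogdet(s)[1])
        p = s.shape[0]
        return mult * max(f_b, 0.0), p * (p - 1) // 2

    def fit_indices(self, level: float = 0.90) -> FitIndices:
        base_chi2, base_df = self.baseline()
        return compute_fit_indices(self.chi2, self.df, self.n, base_chi2, base_df, level)

    def standardized_solution(self) -> pd.DataFrame:
        """Standardized estimates: each path scaled by the ratio of implied
        SDs of source and target; variances as shares of implied totals."""
        p = self.params
        spec = self.model.spec
        a, b = spec.constructs
        sd_n = math.sqrt(p.phi_n + p.psi + p.theta)
        sd_c = math.sqrt(p.phi_c + p.psi + p.theta)
        if sd_n == 0 or sd_c == 0:
            raise ParameterError("zero implied variance; standardization undefined")
        sd_st = math.sqrt(p.psi) if p.psi > 0 else 0.0
        rows = []
        for t in range(1, spec.waves + 1):
            rows.append((f"g{a}", "=~", f"{a}@{t}", 1.0, math.sqrt(p.phi_n) / sd_n))
            rows.append((f"g{b}", "=~", f"{b}@{t}", 1.0, math.sqrt(p.phi_c) / sd_c))
            rows.append((f"ST_{t}", "=~", f"{a}@{t}", 1.0, sd_st / sd_n))
            rows.append((f"ST_{t}", "=~", f"{b}@{t}", 1.0, sd_st / sd_c))
        for t in range(2, spec.waves + 1):
            rows.append((f"ST_{t-1}", "~>", f"ST_{t}", p.rho, p.rho))
        rows.append(
            (f"g{a}", "~~", f"g{b}", p.phi_nc, p.phi_nc / math.sqrt(p.phi_n * p.phi_c))
        )
        for construct, var in ((a, sd_n**2), (b, sd_c**2)):
            trait = p.phi_n if construct == a else p.phi_c
            rows.append((construct, "var%trait", construct, trait, trait / var))
            rows.append((construct, "var%state", construct, p.psi, p.psi / var))
            rows.append((construct, "var%residual", construct, p.theta, p.theta / var))
        return pd.DataFrame(rows, columns=["lhs", "op", "rhs", "estimate", "standardized"])

    def summary(self) -> str:
        ind = self.fit_indices()
        lines = [
            "Model of Spurious Longitudinal Associations (ML)",
            "=" * 56,
            f"waves: {self.model.spec.waves}   n: {self.n}   "
            f"free parameters: {self.model.spec.n_free}",
            f"discrepancy F_min: {self.f_min:.6g}   multiplier: {self.chi2_multiplier}",
            f"chi2 = {self.chi2:.3f}, df = {self.df}, p = {self.p_value:.3f}",
            f"CFI = {ind.cfi:.3f}, TLI = {ind.tli:.3f}, "
            f"RMSEA = {ind.rmsea:.3f} [90% CI: {ind.rmsea_ci_low:.3f}; {ind.rmsea_ci_high:.3f}]",
            "-" * 56,
            f"{'parameter':<10}{'estimate':>12}{'se':>12}{'z':>10}",
        ]
        for name in PARAM_NAMES:
            est = getattr(self.params, name)
            se = self.se[name]
            z = est / se if se > 0 else float("nan")
            lines.append(f"{name:<10}{est:>12.4f}{se:>12.4f}{z:>10.2f}")
        return "\n".join(lines)
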