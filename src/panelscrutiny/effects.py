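"""Difference-score effect variants for scrutinizing cross-lagged findings.

For standardized variables X1, Y1, Y2 the effect of X1 on the change score
Y2 - Y1 is estimated three ways:

* ``adjust-initial`` (a1): regression Y2 - Y1 = a0 + a1*X1 + a2*Y1 + e.
  a1 is identical to the traditional cross-lagged effect of X1 on Y2.
* ``adjust-subsequent`` (b1): Y2 - Y1 = b0 + b1*X1 + b2*Y2 + e, a
  time-reversed scrutiny of the same association.
* ``unadjusted`` (c1): Y2 - Y1 = c0 + c1*X1 + e.

Because all variables are standardized, each coefficient is a function of
the three correlations (r_x1y1, r_x1y2, r_y1y2) alone:

    a1 = (r_x1y2 - r_x1y1 * r_y1y2) / (1 - r_x1y1**2)
    b1 = (r_x1y2 * r_y1y2 - r_x1y1) / (1 - r_x1y2**2)
    c1 = r_x1y2 - r_x1y1

so the same effects can be computed either from a correlation matrix
(closed form) or from raw data (OLS); on exact-mode simulated data the two
routes agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import Label, PanelDataset
from .exceptions import DegenerateInputError, ParameterError, SchemaError

VARIANTS = ("adjust-initial", "adjust-subsequent", "unadjusted")
#: coefficient names conventional for the three regressions
VARIANT_COEF = {"adjust-initial": "a1", "adjust-subsequent": "b1", "unadjusted": "c1"}


@dataclass(frozen=True)
class CorrelationTriple:
    """The three correlations that fully determine the standardized
    difference-score effects: r(X1,Y1), r(X1,Y2), r(Y1,Y2)."""

    r_x1y1: float
    r_x1y2: float
    r_y1y2: float

    def __post_init__(self):
        r = np.array([self.r_x1y1, self.r_x1y2, self.r_y1y2])
        if np.any(np.abs(r) > 1):
            raise ParameterError("correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(self.matrix()).min() < -1e-10:
            raise ParameterError("the implied 3x3 correlation matrix is not PSD")

    def matrix(self) -> np.ndarray:
        """The implied 3x3 correlation matrix, ordered (X1, Y1, Y2)."""
        return np.array(
            [
                [1.0, self.r_x1y1, self.r_x1y2],
                [self.r_x1y1, 1.0, self.r_y1y2],
                [self.r_x1y2, self.r_y1y2, 1.0],
            ]
        )


class EffectTriple(NamedTuple):
    a1: float
    b1: float
    c1: float


def closed_form_effects(r: CorrelationTriple) -> EffectTriple:
    """Closed-form standardized difference-score effects from correlations.

    Raises :class:`DegenerateInputError` when |r_x1y1| = 1 (a1 undefined)
    or |r_x1y2| = 1 (b1 undefined).
    """
    if abs(r.r_x1y1) >= 1 or abs(r.r_x1y2) >= 1:
        raise DegenerateInputError("|r| = 1 makes an adjusted effect undefined")
    a1 = (r.r_x1y2 - r.r_x1y1 * r.r_y1y2) / (1 - r.r_x1y1**2)
    b1 = (r.r_x1y2 * r.r_y1y2 - r.r_x1y1) / (1 - r.r_x1y2**2)
    c1 = r.r_x1y2 - r.r_x1y1
    return EffectTriple(a1, b1, c1)


@dataclass(frozen=True)
class EffectEstimate:
    """One fitted difference-score effect with its OLS uncertainty.

    ``coefficient`` is the standardized effect of the exposure on the
    change score; ``adjust_coefficient`` is the coefficient of the
    adjustment covariate (a2/b2), or None for the unadjusted variant.
    """

    coefficient: float
    se: float
    variant: str
    exposure: Label
    outcome: str
    timeframe: tuple[int, int]
    n: int
    intercept: float
    adjust_coefficient: float | None
    residual_sd: float

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown variant {self.variant!r}")
        if not self.se > 0:
            raise ParameterError("standard error must be positive")

    @property
    def variance(self) -> float:
        return self.se**2

    @property
    def z(self) -> float:
        return self.coefficient / self.se

    @property
    def p_value(self) -> float:
        return 2 * stats.norm.sf(abs(self.z))

    @property
    def significant(self) -> bool:
        """Two-sided z-test at alpha = 0.05."""
        return abs(self.z) > stats.norm.ppf(0.975)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        half = stats.norm.ppf(0.5 + level / 2) * self.se
        return self.coefficient - half, self.coefficient + half


class DifferenceScoreModel:
    """OLS model of a change score on a standardized exposure.

    Parameters
    ----------
    data : PanelDataset
        Standardized panel data (columns mean 0, SD 1).
    exposure : (construct, wave)
        The X1 variable.
    outcome_pair : ((construct, wave), (construct, wave))
        The (Y1, Y2) variables forming the change score Y2 - Y1.
    variant : {"adjust-initial", "adjust-subsequent", "unadjusted"}
        Which adjustment covariate (Y1, Y2, none) enters the regression.
    """

    def __init__(
        self,
        data: PanelDataset,
        exposure: Label,
        outcome_pair: tuple[Label, Label],
        variant: str = "adjust-initial",
    ):
        if variant not in VARIANTS:
            raise ParameterError(f"variant must be one of {VARIANTS}")
        if not data.standardized:
            raise SchemaError("difference-score models require standardized data")
        y1, y2 = outcome_pair
        if len({tuple(exposure), tuple(y1), tuple(y2)}) != 3:
            raise SchemaError("exposure, Y1 and Y2 must be three distinct variables")
        self.data = data
        self.exposure = tuple(exposure)
        self.outcome_pair = (tuple(y1), tuple(y2))
        self.variant = variant

    def fit(self) -> EffectEstimate:
        data = self.data
        y1, y2 = self.outcome_pair
        x = data.column(*self.exposure)
        diff = data.column(*y2) - data.column(*y1)
        if self.variant == "adjust-initial":
            covar = data.column(*y1)
        elif self.variant == "adjust-subsequent":
            covar = data.column(*y2)
        else:
            covar = None
        cols = [x] if covar is None else [x, covar]
        design = sm.add_constant(np.column_stack(cols), has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise np.linalg.LinAlgError("collinear design matrix")
        res = sm.OLS(diff, design).fit()
        return EffectEstimate(
            coefficient=float(res.params[1]),
            se=float(res.bse[1]),
            variant=self.variant,
            exposure=self.exposure,
            outcome=y1[0],
            timeframe=(y1[1], y2[1]),
            n=data.n,
            intercept=float(res.params[0]),
            adjust_coefficient=float(res.params[2]) if covar is not None else None,
            residual_sd=float(np.sqrt(res.mse_resid)),
        )


def fit_difference_model(
    data: PanelDataset,
    exposure: Label,
    outcome_pair: tuple[Label, Label],
    variant: str = "adjust-initial",
) -> EffectEstimate:
    """Functional convenience wrapper around :class:`DifferenceScoreModel`."""
    return DifferenceScoreModel(data, exposure, outcome_pair, variant).fit()


def panel_effects(
    data: PanelDataset,
    exposure_construct: str,
    outcome_construct: str,
) -> list[EffectEstimate]:
    """The six effects of one exposure -> outcome panel.

    Ordering follows the study's effect numbering 1-6: adjust-initial for
    timeframes (1,2) and (2,3), then adjust-subsequent for both, then
    unadjusted for both.  Requires both constructs at waves 1-3.
    """
    if exposure_construct == outcome_construct:
        raise SchemaError("exposure and outcome constructs must differ")
    for construct in (exposure_construct, outcome_construct):
        for wave in (1, 2, 3):
            if (construct, wave) not in data.variables:
                raise SchemaError(f"panel needs {construct}@{wave}")
    out = []
    for variant in VARIANTS:
        for t in (1, 2):
            out.append(
                fit_difference_model(
                    data,
                    exposure=(exposure_construct, t),
                    outcome_pair=((outcome_construct, t), (outcome_construct, t + 1)),
                    variant=variant,
                )
            )
    return out
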