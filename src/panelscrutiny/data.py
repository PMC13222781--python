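"""Containers for longitudinal two-construct panel data.

Two in-memory types are used throughout the package:

``LongitudinalCorrelationMatrix``
    A labeled, symmetric, positive-semidefinite correlation matrix over
    construct-by-wave variables (e.g. ``MNEE@1 ... CU@3``).

``PanelDataset``
    Subject-level scores, one row per subject and one column per
    construct-wave variable, optionally standardized.

Variable labels are ``(construct, wave)`` pairs, serialized to text as
``CONSTRUCT@WAVE``.  Standardization and empirical correlation use the
population divisor (n) so that exact-mode simulated data reproduces its
target matrix without n/(n-1) drift; Pearson correlations themselves are
invariant to the divisor choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SchemaError

Label = tuple[str, int]

#: numerical tolerances for the container invariants
_SYM_TOL = 1e-12
_PSD_TOL = 1e-10
_STD_TOL = 1e-10


def format_label(label: Label) -> str:
    construct, wave = label
    return f"{construct}@{wave}"


def parse_label(text: str) -> Label:
    try:
        construct, wave = text.rsplit("@", 1)
        return construct, int(wave)
    except ValueError as exc:
        raise SchemaError(f"label {text!r} is not of the form CONSTRUCT@WAVE") from exc


def _check_labels(labels: list[Label]) -> None:
    if len(set(labels)) != len(labels):
        raise SchemaError("variable labels must be unique")
    for construct, wave in labels:
        if wave < 1:
            raise SchemaError(f"wave indices are 1-based; got {construct}@{wave}")


@dataclass(frozen=True)
class LongitudinalCorrelationMatrix:
    """Labeled correlation matrix over construct-by-wave variables.

    Parameters
    ----------
    labels : list of (construct, wave)
        Ordered variable labels; waves are 1-based integers.
    values : ndarray, shape (p, p)
        Pearson correlations; symmetric, unit diagonal, PSD.
    """

    labels: tuple[Label, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        labels = tuple((str(c), int(w)) for c, w in self.labels)
        object.__setattr__(self, "labels", labels)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        _check_labels(list(labels))
        p = len(labels)
        if values.shape != (p, p):
            raise SchemaError(f"matrix shape {values.shape} != ({p}, {p})")
        if not np.all(np.isfinite(values)):
            raise SchemaError("correlation matrix contains non-finite values")
        if np.max(np.abs(values - values.T)) > _SYM_TOL:
            raise SchemaError("correlation matrix is not symmetric (tol 1e-12)")
        if np.max(np.abs(np.diag(values) - 1.0)) > _SYM_TOL:
            raise SchemaError("correlation matrix diagonal must be 1")
        if np.max(np.abs(values)) > 1.0 + _SYM_TOL:
            raise SchemaError("correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(values).min() < -_PSD_TOL:
            raise SchemaError("correlation matrix is not positive semidefinite")

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def constructs(self) -> list[str]:
        seen: list[str] = []
        for construct, _ in self.labels:
            if construct not in seen:
                seen.append(construct)
        return seen

    @property
    def waves(self) -> int:
        return max(w for _, w in self.labels)

    def index(self, construct: str, wave: int) -> int:
        try:
            return self.labels.index((construct, wave))
        except ValueError as exc:
            raise SchemaError(f"no variable {construct}@{wave}") from exc

    def corr(self, a: Label, b: Label) -> float:
        return float(self.values[self.index(*a), self.index(*b)])

    def to_dataframe(self) -> pd.DataFrame:
        names = [format_label(l) for l in self.labels]
        return pd.DataFrame(self.values, index=names, columns=names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LongitudinalCorrelationMatrix":
        labels = tuple(parse_label(str(c)) for c in df.columns)
        if list(df.index) != list(df.columns):
            raise SchemaError("row and column labels must match")
        return cls(labels, df.to_numpy(dtype=float))

    def write_csv(self, path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep)

    @classmethod
    def read_csv(cls, path, sep: str = ",") -> "LongitudinalCorrelationMatrix":
        return cls.from_dataframe(pd.read_csv(path, sep=sep, index_col=0))


@dataclass(frozen=True)
class PanelDataset:
    """Subject-level panel scores with construct/wave labels.

    ``standardized`` asserts that every column has mean 0 and SD 1 under
    the population (divisor n) convention, checked to 1e-10.
    """

    variables: tuple[Label, ...]
    scores: np.ndarray = field(repr=False)
    standardized: bool = False

    def __post_init__(self):
        variables = tuple((str(c), int(w)) for c, w in self.variables)
        object.__setattr__(self, "variables", variables)
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        _check_labels(list(variables))
        if scores.ndim != 2 or scores.shape[1] != len(variables):
            raise SchemaError(
                f"scores shape {scores.shape} does not match {len(variables)} variables"
            )
        if not np.all(np.isfinite(scores)):
            raise SchemaError("missing or non-finite values are not accepted")
        if self.standardized:
            means = scores.mean(axis=0)
            sds = scores.std(axis=0)  # population divisor
            if np.max(np.abs(means)) > _STD_TOL or np.max(np.abs(sds - 1)) > _STD_TOL:
                raise SchemaError("standardized flag set but columns are not z-scores")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def p(self) -> int:
        return self.scores.shape[1]

    @property
    def constructs(self) -> list[str]:
        seen: list[str] = []
        for construct, _ in self.variables:
            if construct not in seen:
                seen.append(construct)
        return seen

    @property
    def waves(self) -> int:
        return max(w for _, w in self.variables)

    @property
    def is_complete_grid(self) -> bool:
        """True when every construct is observed at every wave 1..waves."""
        want = {(c, w) for c in self.constructs for w in range(1, self.waves + 1)}
        return set(self.variables) == want

    def index(self, construct: str, wave: int) -> int:
        try:
            return self.variables.index((construct, wave))
        except ValueError as exc:
            raise SchemaError(f"no variable {construct}@{wave}") from exc

    def column(self, construct: str, wave: int) -> np.ndarray:
        return self.scores[:, self.index(construct, wave)]

    def standardize(self) -> "PanelDataset":
        """Return a copy with each column centered and scaled to unit SD
        (population divisor)."""
        centered = self.scores - self.scores.mean(axis=0)
        sds = centered.std(axis=0)
        if np.any(sds == 0):
            raise SchemaError("cannot standardize a constant column")
        return PanelDataset(self.variables, centered / sds, standardized=True)

    def correlation_matrix(self) -> LongitudinalCorrelationMatrix:
        r = np.corrcoef(self.scores, rowvar=False)
        # clean tiny asymmetries from floating point before validation
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
        return LongitudinalCorrelationMatrix(self.variables, r)

    def covariance(self, ddof: int = 1) -> np.ndarray:
        """Sample covariance of the scores (default divisor n-1, the
        Wishart convention paired with the (n-1) chi-square multiplier)."""
        return np.cov(self.scores, rowvar=False, ddof=ddof)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=[format_label(v) for v in self.variables])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, standardized: bool = False) -> "PanelDataset":
        variables = tuple(parse_label(str(c)) for c in df.columns)
        return cls(variables, df.to_numpy(dtype=float), standardized=standardized)

    def write_csv(self, path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)

    @classmethod
    def read_csv(cls, path, sep: str = ",") -> "PanelDataset":
        return cls.from_dataframe(pd.read_csv(path, sep=sep))
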