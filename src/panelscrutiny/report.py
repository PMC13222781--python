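"""End-to-end scrutiny pipeline: panels of difference-score effects,
meta-analytic pooling, and the MoSLA fit, driven by a declarative config.

The default configuration mirrors the study design: three waves, N = 561,
constructs MPEE (maternal positive emotional expressiveness), MNEE
(negative expressiveness) and CU (children's callous-unemotional traits),
four panels A-D — (MPEE->CU), (CU->MPEE), (MNEE->CU), (CU->MNEE) — each
with six difference-score effects (Table-1 ordering) plus one pooled
effect, and one MoSLA fit on the MNEE/CU pair.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data import LongitudinalCorrelationMatrix, PanelDataset
from .effects import EffectEstimate, VARIANT_COEF, panel_effects
from .exceptions import ConfigError, SchemaError
from .meta import PooledEffect, pool_random_effects
from .mosla import MoslaModel, MoslaResults
from .simulate import (
    DEFAULT_MOSLA_PARAMS,
    MoslaParams,
    STUDY_N,
    STUDY_WAVES,
    simulate_from_corr,
    simulate_mosla,
)

logger = logging.getLogger("panelscrutiny")

DEFAULT_PANELS = (
    ("A", "MPEE", "CU"),
    ("B", "CU", "MPEE"),
    ("C", "MNEE", "CU"),
    ("D", "CU", "MNEE"),
)
DEFAULT_MOSLA_PAIR = ("MNEE", "CU")


@dataclass(frozen=True)
class PanelSpec:
    """One exposure -> outcome panel (id A-D in default mode)."""

    panel_id: str
    exposure: str
    outcome: str

    def __post_init__(self):
        if self.exposure == self.outcome:
            raise ConfigError(
                f"panel {self.panel_id}: exposure and outcome must differ"
            )


@dataclass
class ScrutinyConfig:
    """Declarative description of one scrutiny run.

    Exactly one data source must be given: a panel-data file, a
    correlation-matrix file with ``n``, or a simulation recipe.
    """

    panels: list[PanelSpec] = field(
        default_factory=lambda: [PanelSpec(*p) for p in DEFAULT_PANELS]
    )
    data_path: str | None = None
    corr_path: str | None = None
    n: int | None = None
    simulate: dict | None = None
    seed: int = 1
    tau2_method: str = "reml"
    chi2_multiplier: str = "nm1"
    mosla_pair: tuple[str, str] | None = DEFAULT_MOSLA_PAIR
    fit_all_pairs: bool = False

    def __post_init__(self):
        sources = [
            self.data_path is not None,
            self.corr_path is not None,
            self.simulate is not None,
        ]
        if sum(sources) != 1:
            raise ConfigError(
                "exactly one of data_path, corr_path or simulate must be set"
            )
        if self.corr_path is not None and self.n is None:
            raise ConfigError("a correlation matrix input needs a sample size n")

    @classmethod
    def from_dict(cls, raw: dict) -> "ScrutinyConfig":
        raw = dict(raw)
        panels = raw.pop("panels", None)
        cfg_panels = (
            [PanelSpec(p["id"], p["exposure"], p["outcome"]) for p in panels]
            if panels is not None
            else [PanelSpec(*p) for p in DEFAULT_PANELS]
        )
        pair = raw.pop("mosla_pair", DEFAULT_MOSLA_PAIR)
        if pair is not None:
            pair = tuple(pair)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(panels=cfg_panels, mosla_pair=pair, **raw)

    @classmethod
    def from_yaml(cls, path) -> "ScrutinyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panels"] = [dataclasses.asdict(p) for p in self.panels]
        d["mosla_pair"] = list(self.mosla_pair) if self.mosla_pair else None
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# --------------------------------------------------------------------------
# Report container
# --------------------------------------------------------------------------

@dataclass
class PanelResult:
    spec: PanelSpec
    effects: list[EffectEstimate]
    pooled: PooledEffect

    def __post_init__(self):
        if len(self.effects) != 6:
            raise SchemaError("a panel carries exactly six effect estimates")


@dataclass
class ScrutinyReport:
    """Full output of one run: per-panel effects 1-7 and MoSLA fit(s)."""

    panels: list[PanelResult]
    mosla: dict[str, MoslaResults]
    provenance: dict

    def effect_table(self) -> pd.DataFrame:
        """Long table, one row per panel x effect (1-6) plus the pooled
        row (effect 7) per panel."""
        rows = []
        for panel in self.panels:
            for num, eff in enumerate(panel.effects, start=1):
                lo, hi = eff.ci()
                rows.append(
                    {
                        "panel": panel.spec.panel_id,
                        "effect": num,
                        "variant": eff.variant,
                        "coefficient_name": VARIANT_COEF[eff.variant],
                        "timeframe": f"{eff.timeframe[0]}->{eff.timeframe[1]}",
                        "exposure": f"{eff.exposure[0]}@{eff.exposure[1]}",
                        "outcome": eff.outcome,
                        "estimate": eff.coefficient,
                        "se": eff.se,
                        "ci_low": lo,
                        "ci_high": hi,
                        "p": eff.p_value,
                        "significant": bool(eff.significant),
                    }
                )
            pooled = panel.pooled
            rows.append(
                {
                    "panel": panel.spec.panel_id,
                    "effect": 7,
                    "variant": f"pooled-{pooled.method}",
                    "coefficient_name": "rma",
                    "timeframe": "1->3",
                    "exposure": panel.spec.exposure,
                    "outcome": panel.spec.outcome,
                    "estimate": pooled.estimate,
                    "se": pooled.se,
                    "ci_low": pooled.ci_low,
                    "ci_high": pooled.ci_high,
                    "p": pooled.p_value,
                    "significant": bool(pooled.significant),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def eff_dict(eff: EffectEstimate) -> dict:
            return {
                "coefficient": eff.coefficient,
                "se": eff.se,
                "variant": eff.variant,
                "exposure": list(eff.exposure),
                "outcome": eff.outcome,
                "timeframe": list(eff.timeframe),
                "n": eff.n,
                "intercept": eff.intercept,
                "adjust_coefficient": eff.adjust_coefficient,
                "residual_sd": eff.residual_sd,
            }

        def pooled_dict(p: PooledEffect) -> dict:
            return {
                "estimate": p.estimate, "se": p.se, "ci_low": p.ci_low,
                "ci_high": p.ci_high, "tau2": p.tau2, "q": p.q, "i2": p.i2,
                "k": p.k, "method": p.method,
            }

        def mosla_dict(res: MoslaResults) -> dict:
            ind = res.fit_indices()
            return {
                "params": res.params.as_dict(),
                "se": dict(res.se),
                "f_min": res.f_min,
                "chi2": res.chi2,
                "df": res.df,
                "p_value": res.p_value,
                "chi2_multiplier": res.chi2_multiplier,
                "n": res.n,
                "fit_indices": ind.as_dict(),
                "sample_cov": [[float(v) for v in row] for row in res.s],
            }

        return {
            "provenance": self.provenance,
            "panels": [
                {
                    "id": panel.spec.panel_id,
                    "exposure": panel.spec.exposure,
                    "outcome": panel.spec.outcome,
                    "effects": [eff_dict(e) for e in panel.effects],
                    "pooled": pooled_dict(panel.pooled),
                }
                for panel in self.panels
            ],
            "mosla": {key: mosla_dict(res) for key, res in self.mosla.items()},
        }


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def _load_or_simulate(config: ScrutinyConfig) -> PanelDataset:
    if config.data_path is not None:
        logger.info("loading panel data from %s", config.data_path)
        return PanelDataset.read_csv(config.data_path)
    if config.corr_path is not None:
        logger.info("exact-mode simulation from %s (n=%d)", config.corr_path, config.n)
        target = LongitudinalCorrelationMatrix.read_csv(config.corr_path)
        return simulate_from_corr(target, n=config.n, seed=config.seed, exact=True)
    recipe = dict(config.simulate or {})
    model = recipe.pop("model", "mosla")
    n = int(recipe.pop("n", STUDY_N))
    waves = int(recipe.pop("waves", STUDY_WAVES))
    if model == "mosla":
        constructs = tuple(recipe.pop("constructs", ("MNEE", "CU")))
        params = MoslaParams(**recipe) if recipe else DEFAULT_MOSLA_PARAMS
        logger.info("simulating MoSLA data (n=%d, waves=%d)", n, waves)
        return simulate_mosla(params, n=n, waves=waves, seed=config.seed,
                              constructs=constructs)
    raise ConfigError(f"unknown simulation model {model!r}")


def run_scrutiny(config: ScrutinyConfig) -> ScrutinyReport:
    """Execute the full pipeline described by ``config``.

    Deterministic for a fixed config and seed.  Every panel yields six
    effect estimates in the study's effect order plus one random-effects
    pooled effect; the MoSLA is fitted on the configured construct pair(s)
    using the sample covariance of the (unstandardized) scores.
    """
    t0 = time.perf_counter()
    data = _load_or_simulate(config)
    zdata = data if data.standardized else data.standardize()

    panels = []
    for spec in config.panels:
        effects = panel_effects(zdata, spec.exposure, spec.outcome)
        pooled = pool_random_effects(effects, method=config.tau2_method)
        logger.info(
            "panel %s (%s->%s): pooled %.4f [%.4f; %.4f]",
            spec.panel_id, spec.exposure, spec.outcome,
            pooled.estimate, pooled.ci_low, pooled.ci_high,
        )
        panels.append(PanelResult(spec, effects, pooled))

    mosla_fits: dict[str, MoslaResults] = {}
    if config.fit_all_pairs:
        pairs = {tuple(sorted((p.exposure, p.outcome))) for p in config.panels}
    elif config.mosla_pair is not None:
        pairs = {tuple(config.mosla_pair)}
    else:
        pairs = set()
    for pair in sorted(pairs):
        model = MoslaModel.from_data(data, constructs=tuple(pair))
        res = model.fit(chi2_multiplier=config.chi2_multiplier, seed=config.seed)
        ind = res.fit_indices()
        logger.info(
            "MoSLA %s: chi2=%.2f df=%d p=%.3f CFI=%.3f RMSEA=%.3f",
            "-".join(pair), res.chi2, res.df, res.p_value, ind.cfi, ind.rmsea,
        )
        mosla_fits["-".join(pair)] = res

    provenance = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": config.canonical_dict(),
        "package_version": __version__,
        "n": data.n,
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return ScrutinyReport(panels=panels, mosla=mosla_fits, provenance=provenance)


def write_report(
    report: ScrutinyReport,
    out_dir,
    plots: bool = False,
) -> list[Path]:
    """Write the report: ``report.json`` (complete, machine-readable),
    ``effects.csv`` (one row per panel x effect 1-7), and optionally one
    forest plot per panel.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    json_path = out / "report.json"
    payload = report.to_dict()
    # timing is environment noise; keep the JSON reproducible for a fixed
    # config+seed
    payload["provenance"] = {
        k: v for k, v in payload["provenance"].items() if k != "elapsed_s"
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    written.append(json_path)

    csv_path = out / "effects.csv"
    report.effect_table().to_csv(csv_path, index=False)
    written.append(csv_path)

    if plots:
        from .plotting import forest_plot

        for panel in report.panels:
            fig = forest_plot(panel)
            path = out / f"forest_{panel.spec.panel_id}.png"
            fig.savefig(path, dpi=150, bbox_inches="tight")
            written.append(path)
    return written


def read_report(path) -> dict:
    """Read back the machine-readable report written by write_report."""
    with open(Path(path)) as fh:
        return json.load(fh)
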