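"""End-to-end orchestration: simulate/read -> adjust -> pairs -> quantile
process with bootstrap -> heritability curve -> trend tests, with tabular
outputs (per-quantile slopes, h^2 curve, trend tests, a summary table in the
traditional-vs-quantile layout, and a machine-readable run summary)."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import adjustment, heritability, pairs as pairs_mod, pedigree_io, quantreg
from .synthetic import SyntheticConfig, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_table1"]

KIND_BUILDERS = {
    "op": pairs_mod.build_op_pairs,
    "midparent": pairs_mod.build_midparent_pairs,
    "fs": pairs_mod.build_fullsib_pairs,
}
KIND_METHODS = {"op": "OP", "midparent": "MIDPARENT", "fs": "FS"}


@dataclass
class RunConfig:
    pedigree_path: str | None = None
    exam_path: str | None = None
    synthetic: SyntheticConfig | None = None
    kinds: tuple[str, ...] = ("op", "midparent", "fs")
    transform: str = "identity"
    grid_min: float = 0.05
    grid_max: float = 0.95
    grid_step: float = 0.01
    n_boot: int = 1000
    seed: int = 0
    resample_unit: str = "pair"
    min_age: float = 16.0
    medication_scope: str = "exam"
    flat_sib_weights: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.kinds:
            raise ValueError("at least one pair kind must be requested")
        unknown = set(self.kinds) - set(KIND_BUILDERS)
        if unknown:
            raise ValueError(f"unknown pair kind(s): {sorted(unknown)}")
        if self.synthetic is None and (self.pedigree_path is None or self.exam_path is None):
            raise ValueError("either input paths or a synthetic config is required")

    def grid(self) -> quantreg.QuantileGrid:
        return quantreg.QuantileGrid.from_range(self.grid_min, self.grid_max, self.grid_step)


def _load(config: RunConfig) -> pedigree_io.CohortData:
    if config.synthetic is not None:
        ped, exams = generate_cohort(config.synthetic)
        ped = ped.assign(female=(ped["sex"] == "F").astype(int))
        exams = exams.assign(on_lipid_meds=exams["on_lipid_meds"].astype(bool))
        return pedigree_io.CohortData(individuals=ped, exams=exams)
    return pedigree_io.read_tables(config.pedigree_path, config.exam_path)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the result bundle and optionally writes it."""
    stage = "load"
    try:
        data = _load(config)
        stage = "eligibility"
        data = pedigree_io.apply_eligibility(
            data, min_age=config.min_age, medication_scope=config.medication_scope
        )
        stage = "adjustment"
        adjusted, models = adjustment.adjust_cohorts(
            data.exams, data.individuals, transform=config.transform
        )
        stage = "spouse-correlation"
        try:
            spouse = pairs_mod.build_spouse_pairs(adjusted, data.individuals)
            r_spouse = pairs_mod.weighted_correlation(spouse)
            n_spouse = len(spouse)
        except ValueError:
            log.warning("no usable spouse pairs; r_spouse set to 0")
            r_spouse, n_spouse = 0.0, 0

        grid = config.grid()
        seed_rng = np.random.default_rng(config.seed)
        slope_rows, h2_rows, trend_obj, kind_results = [], [], {}, {}
        for kind in config.kinds:
            stage = f"fit-{kind}"
            builder = KIND_BUILDERS[kind]
            kwargs = {"flat_weights": config.flat_sib_weights} if kind == "fs" else {}
            pset = builder(adjusted, data.individuals, **kwargs)
            ols = quantreg.fit_weighted_ols(pset)
            kind_seed = int(seed_rng.integers(2**31))
            fit = quantreg.bootstrap_process(
                pset,
                grid,
                n_boot=config.n_boot,
                seed=kind_seed,
                resample_unit=config.resample_unit,
            )
            method = KIND_METHODS[kind]
            curve = heritability.h2_curve(fit, r_spouse, method)
            trends = {
                d: heritability.trend_test(fit, d) for d in (1, 2, 3) if len(grid) > d
            }
            try:
                diff = heritability.difference_test(fit, 0.90, 0.10)
            except ValueError:
                diff = None  # 0.10/0.90 not on the requested grid

            ses = fit.slope_se
            for i, tau in enumerate(grid.taus):
                slope_rows.append(
                    (kind, float(tau), fit.intercepts[i], fit.slopes[i], ses[i])
                )
                h2_rows.append(
                    (kind, float(tau), fit.slopes[i], ses[i], curve.h2[i], curve.se[i])
                )
            trend_obj[kind] = {
                "trends": {str(d): asdict(t) for d, t in trends.items()},
                "difference_90_10": asdict(diff) if diff is not None else None,
            }
            kind_results[kind] = {
                "pairset": pset,
                "ols": ols,
                "fit": fit,
                "curve": curve,
                "trends": trends,
                "difference": diff,
                "seed": kind_seed,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    slopes = pd.DataFrame(
        slope_rows, columns=["kind", "tau", "intercept", "slope", "slope_se"]
    )
    h2_curve_df = pd.DataFrame(
        h2_rows, columns=["kind", "tau", "slope", "slope_se", "h2", "h2_se"]
    )
    table1 = render_table1(kind_results, config.transform)
    summary = {
        "transform": config.transform,
        "kinds": list(config.kinds),
        "grid": {"min": config.grid_min, "max": config.grid_max, "step": config.grid_step},
        "n_boot": config.n_boot,
        "seed": config.seed,
        "resample_unit": config.resample_unit,
        "min_age": config.min_age,
        "medication_scope": config.medication_scope,
        "flat_sib_weights": config.flat_sib_weights,
        "r_spouse": r_spouse,
        "n_spouse_pairs": n_spouse,
        "n_individuals": int(data.n_individuals),
        "n_exams": int(data.n_exams),
        "adjustment": {
            c: {"n_obs": m.n_obs, "dropped": list(m.dropped)} for c, m in models.items()
        },
        "kind_seeds": {k: v["seed"] for k, v in kind_results.items()},
        "pair_counts": {k: len(v["pairset"]) for k, v in kind_results.items()},
        "pair_dfs": {k: v["pairset"].df for k, v in kind_results.items()},
        "synthetic": asdict(config.synthetic) if config.synthetic is not None else None,
        "inputs": {"pedigree": config.pedigree_path, "exams": config.exam_path},
    }
    bundle = {
        "slopes": slopes,
        "h2_curve": h2_curve_df,
        "trend_tests": trend_obj,
        "table1": table1,
        "run_summary": summary,
        "kind_results": kind_results,
        "r_spouse": r_spouse,
    }
    if config.out_dir is not None:
        pedigree_io.write_results(
            {
                "slopes": slopes,
                "h2_curve": h2_curve_df,
                "trend_tests": trend_obj,
                "table1": table1,
                "run_summary": summary,
            },
            config.out_dir,
        )
    return bundle


def render_table1(kind_results: dict, transform: str) -> pd.DataFrame:
    """Traditional-vs-quantile summary: one row per pair kind."""
    rows = []
    nan = float("nan")
    for kind, res in kind_results.items():
        ols, trends, diff = res["ols"], res["trends"], res["difference"]
        lin = trends.get(1)
        rows.append(
            {
                "kind": kind,
                "transform": transform,
                "correlation": ols.correlation,
                "trad_slope": ols.slope,
                "trad_se": ols.slope_se,
                "trad_p": ols.p_value,
                "slope_per_percentile": lin.per_percentile_slope if lin else nan,
                "slope_per_percentile_se": lin.per_percentile_se if lin else nan,
                "linear_p": lin.p_value if lin else nan,
                "quadratic_p": trends[2].p_value if 2 in trends else nan,
                "cubic_p": trends[3].p_value if 3 in trends else nan,
                "diff_90_10": diff.difference if diff else nan,
                "diff_90_10_se": diff.se if diff else nan,
                "diff_90_10_p": diff.p_value if diff else nan,
            }
        )
    return pd.DataFrame(rows)
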