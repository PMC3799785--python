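"""End-to-end reproduction of the headline quantities of the analysis.

Two tiers:

* *model-based* quantities need no data: the three optimal-fineness values
  of the rigid-body drag model (fixed-Re drag-bracket minimiser, the
  constant-volume/constant-speed drag minimiser, and the constant-volume
  maximiser of the iteratively solved U_max), plus the qualitative laminar
  checks (monotone U_max(f), ~4-iteration convergence);
* *data-based* quantities need a species table (and optionally a tree):
  the all-subsets pGLS/OLS model table, model-averaged coefficients, raw
  and PIC correlations, the mass/fin-adjusted speeds, the mechanistic
  R^2 of the laminar drag model and its permutation P, and the BCF
  quadratic optimum.

``reproduce`` computes whichever tier its inputs allow and returns a plain
dict suitable for JSON serialisation.
"""

from __future__ import annotations

import numpy as np

from . import compstats, dragmodel, morphometrics
from .dragmodel import (
    LAMINAR,
    TRANSITIONAL,
    BodyOfRevolution,
    FluidEnvironment,
    PropulsionParams,
)
from .morphometrics import BCF, MPF

__all__ = [
    "fixed_re_transitional_optimum",
    "model_targets",
    "predicted_umax_curve",
    "mechanistic_umax",
    "reproduce",
]

#: Parameterisation of the published constant-volume sweeps.
TRANSITIONAL_VOLUME = 0.001  # m^3
TRANSITIONAL_SPEED = 1.5  # m/s
LAMINAR_VOLUME = 1.5e-5  # m^3
LAMINAR_SPEED = 0.6  # m/s


def fixed_re_transitional_optimum(step: float = 0.01) -> float:
    """Fineness minimising the transitional drag bracket at fixed Re.

    With the friction coefficient held constant, only the fineness
    polynomial matters; the minimiser is located on a fine grid over
    [1, 20] and refined by quadratic interpolation.
    """
    grid = np.arange(1.0, 20.0 + 0.5 * step, step)
    values = dragmodel.form_factor(grid, TRANSITIONAL)
    i = int(np.argmin(values))
    return dragmodel._refine_quadratic(grid, values, i)


def model_targets(fluid: FluidEnvironment | None = None) -> dict:
    """The three optimal-fineness quantities of the drag model.

    * ``fixed_re_f_opt`` — minimiser of the transitional fineness bracket
      at constant Re (grid 0.01, quadratic-refined);
    * ``constant_volume_cd_f_opt`` — C_D-minimising fineness among equal
      bodies (V = 0.001 m^3) at equal speed (1.5 m/s), f = 1..20 by 0.1;
    * ``umax_f_opt`` — U_max-maximising fineness under the full power
      balance (eta = 0.34, 16.5 W/kg, muscle fraction 0.019, M = rho V).

    The latter two are reported at the sweep's 0.1 grid resolution.
    """
    fluid = fluid or FluidEnvironment()
    prop = PropulsionParams()
    cd_sweep = dragmodel.sweep_fineness(
        TRANSITIONAL_VOLUME, fluid, prop, TRANSITIONAL,
        mode="min_cd_at_speed", speed=TRANSITIONAL_SPEED,
    )
    umax_sweep = dragmodel.sweep_fineness(
        TRANSITIONAL_VOLUME, fluid, prop, TRANSITIONAL, mode="max_umax"
    )
    grid_n = cd_sweep.fineness.size
    return {
        "fixed_re_f_opt": {"value": float(fixed_re_transitional_optimum()), "n": 1901},
        "constant_volume_cd_f_opt": {"value": float(cd_sweep.f_opt), "n": int(grid_n)},
        "umax_f_opt": {"value": float(umax_sweep.f_opt), "n": int(umax_sweep.fineness.size)},
    }


def predicted_umax_curve(
    volume: float,
    regime: str,
    fluid: FluidEnvironment | None = None,
    propulsion: PropulsionParams | None = None,
    **sweep_kwargs,
) -> dragmodel.FinenessSweep:
    """Convenience wrapper: U_max(f) sweep for one constant-volume body."""
    return dragmodel.sweep_fineness(
        volume, fluid, propulsion, regime, mode="max_umax", **sweep_kwargs
    )


def mechanistic_umax(
    records,
    gait: str = MPF,
    regime: str = LAMINAR,
    fluid: FluidEnvironment | None = None,
    propulsion: PropulsionParams | None = None,
) -> np.ndarray:
    """Drag-model U_max prediction per species at the group-mean volume.

    All species share the mean body volume (mean mass over water density),
    so only their fineness differentiates the predictions — the modelled
    curve evaluated at each species' fineness.
    """
    fluid = fluid or FluidEnvironment()
    propulsion = propulsion or PropulsionParams()
    recs = [r for r in records if r.gait == gait]
    if not recs:
        raise ValueError(f"no records of gait {gait!r}")
    mean_volume = float(np.mean([r.mass for r in recs])) / fluid.density
    out = np.empty(len(recs))
    for i, r in enumerate(recs):
        f = morphometrics.derive(r, viscosity=fluid.kinematic_viscosity).fineness
        body = BodyOfRevolution(mean_volume, max(f, 1.0))
        out[i] = dragmodel.solve_umax(body, fluid, propulsion, regime).speed
    return out


def reproduce(
    records=None,
    tree=None,
    *,
    seed: int = 0,
    n_boot: int = 0,
    n_perm: int = 4999,
    fluid: FluidEnvironment | None = None,
) -> dict:
    """Compute the reproduction report; data-based parts only with data."""
    fluid = fluid or FluidEnvironment()
    report: dict = {"seed": seed, "model_based": model_targets(fluid)}

    lam_sweep = predicted_umax_curve(LAMINAR_VOLUME, LAMINAR, fluid)
    mask = lam_sweep.fineness <= 10.0
    du = np.diff(lam_sweep.umax[mask])
    report["model_based"]["laminar_umax_monotone"] = bool(np.all(du > 0))
    report["model_based"]["laminar_umax_concave"] = bool(np.all(np.diff(du) < 0))

    if records is None:
        return report

    records = list(records)
    for gait in (MPF, BCF):
        recs = [r for r in records if r.gait == gait]
        if len(recs) < 6:
            continue
        section: dict = {"n_species": len(recs)}
        design = compstats.build_design(recs, gait, viscosity=fluid.kinematic_viscosity)
        modelset = compstats.enumerate_and_retain(design, tree)
        if n_boot > 0:
            avg = compstats.bootstrap_cis(
                recs, gait, tree, n_boot=n_boot, seed=seed,
                viscosity=fluid.kinematic_viscosity,
            )
        else:
            avg = compstats.model_average(modelset)
        best = modelset.best
        section["best_model"] = {
            "predictors": list(best.predictors),
            "aicc": best.aicc,
            "beta": {k: float(v) for k, v in best.beta.items()},
            "lambda": best.lambda_,
            "adj_r2": best.adj_r2,
        }
        section["n_retained"] = int(modelset.retained.sum())
        section["averaged_beta"] = avg.coef
        if avg.intervals:
            section["intervals"] = {
                p: {str(k): list(v) for k, v in iv.items()} for p, iv in avg.intervals.items()
            }
        full = [f for f in modelset.fits if set(f.predictors) == set(compstats.PREDICTORS)]
        section["full_model_r2"] = full[0].r2 if full else None
        ar_logm = [f for f in modelset.fits if set(f.predictors) == {"AR", "logM"}]
        section["ar_logm_r2"] = ar_logm[0].r2 if ar_logm else None

        if tree is not None:
            pic = compstats.pic_correlations(recs, tree, viscosity=fluid.kinematic_viscosity)
            section["raw_corr_ar_logu"] = float(pic.raw.loc["AR", "logU"])
            section["pic_corr_ar_logu"] = float(pic.pic.loc["AR", "logU"])
        else:
            table = morphometrics.derive_table(recs, viscosity=fluid.kinematic_viscosity)
            section["raw_corr_ar_logu"] = float(
                np.corrcoef(table["fin_ar"], table["logU"])[0, 1]
            )

        if gait == MPF:
            adjusted = compstats.adjusted_umax(recs, gait).to_numpy()
            modeled = mechanistic_umax(recs, gait, LAMINAR, fluid)
            section["mechanistic_r2"] = compstats.mechanistic_r2(adjusted, modeled)
            perm = compstats.permutation_test(adjusted, modeled, n_perm=n_perm, seed=seed)
            section["permutation_p"] = perm.p_value
        else:
            if "f" in avg.coef and "f2" in avg.coef and avg.coef["f2"] < 0:
                vertex = compstats.quadratic_vertex(avg, design.meta)
                section["quadratic_f_opt"] = vertex.f_vertex
                section["effect_at_fmin"] = vertex.effect_at_fmin
                section["effect_at_fmax"] = vertex.effect_at_fmax
        report[gait] = section
    return report
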