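"""Flux estimation by glucose-input minimisation.

Per-strain extracellular yields (mmol/L at the sampling point) and dry
biomass (g/L) constrain the excretion drains and the biomass flux of the
network to ±`margin` boxes (default 2.5%).  The intracellular flux
distribution is then the solution of

    min  v_glucose   s.t.  S·v = 0,  lb ≤ v ≤ ub,

i.e. the most parsimonious sugar input that explains the measured
products at steady state.  Fructose is treated as glucose: the measured
consumed hexose (glucose + fructose) bounds the single glucose-uptake
reaction.  Because the glucose minimum need not pin every internal flux,
a deterministic second stage minimises the L1 norm of the flux vector at
the fixed optimal glucose input; whether it changed anything is recorded
in ``tie_break_applied``.  Reported fluxes are normalised to the
predicted sugar uptake (glucose input = 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, eye, hstack, vstack

from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "MeasurementSet",
    "FluxSolution",
    "MEASUREMENT_COLUMNS",
    "HEXOSE_MOLAR_MASS",
    "build_constraints",
    "estimate_fluxes",
    "sugar_uptake_divergence",
    "read_measurements",
    "write_measurements",
]

#: g/mol of glucose and fructose (isomers)
HEXOSE_MOLAR_MASS = 180.156

#: measurement CSV column → excretion reaction id in the packaged model
MEASUREMENT_COLUMNS = {
    "ethanol": "Eth_t",
    "glycerol": "Glyc_t",
    "acetate": "Ac_t",
    "succinate": "Succ_t",
    "pyruvate": "Pyr_t",
    "akg": "Akg_t",
    "co2": "CO2_t",
}

STEADY_STATE_TOL = 1e-6
_FEAS_TOL = 1e-9


@dataclass
class MeasurementSet:
    """Extracellular phenotype of one strain at the sampling point."""

    strain_id: str
    metabolite_yields: dict[str, float]  # excretion reaction id → mmol/L
    dry_mass: float                      # g/L
    glucose_residual: float = 0.0        # g/L
    fructose_residual: float = 0.0       # g/L
    hexose_consumed: float = 0.0         # mmol/L, glucose + fructose consumed
    margin: float = 0.025

    def __post_init__(self) -> None:
        if not (0.0 <= self.margin < 1.0):
            raise ValueError(f"margin must be in [0, 1), got {self.margin}")
        for rid, y in self.metabolite_yields.items():
            if not np.isfinite(y) or y < 0:
                raise ValueError(f"{self.strain_id}: invalid yield {y!r} for {rid}")


@dataclass
class FluxSolution:
    """Estimated flux distribution for one strain."""

    strain_id: str
    fluxes: dict[str, float]        # normalised: per 100 units glucose input
    raw_fluxes: dict[str, float]    # measurement units (mmol/L, biomass g/L)
    objective_value: float          # glucose input, mmol/L
    status: str                     # optimal | infeasible | unbounded
    tie_break_applied: bool = False
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def build_constraints(
    model: MetabolicModel,
    meas: MeasurementSet,
    succinate_bounds: tuple[float, float] | None = None,
    *,
    succinate_rxn: str = "Succ_t",
    biomass_margin: float | None = None,
) -> MetabolicModel:
    """Box the measured drains, the biomass flux and the sugar uptake.

    Each measured excretion flux y is bounded to [y·(1−margin),
    y·(1+margin)]; the biomass flux likewise from dry mass (same margin
    unless ``biomass_margin`` is given); the glucose-uptake reaction is
    bounded by total consumed hexose.  A non-positive dry mass or hexose
    value means "not measured" and leaves the reaction unconstrained.  ``succinate_bounds``, when given,
    replace the measurement-derived succinate bounds (fixed range used
    when succinate determinations suffer block effects).
    """
    m = meas.margin
    bounds: dict[str, tuple[float, float]] = {}
    for rid, y in meas.metabolite_yields.items():
        if rid not in model.exchange_ids:
            raise ValueError(f"measurement for unknown exchange reaction {rid!r}")
        bounds[rid] = _clamped(y * (1 - m), y * (1 + m), rid)
    if meas.dry_mass > 0:
        bm = meas.margin if biomass_margin is None else biomass_margin
        bounds[model.biomass_id] = _clamped(
            meas.dry_mass * (1 - bm), meas.dry_mass * (1 + bm), model.biomass_id
        )
    if meas.hexose_consumed > 0:
        h = meas.hexose_consumed
        bounds[model.glucose_uptake_id] = _clamped(
            h * (1 - m), h * (1 + m), model.glucose_uptake_id
        )
    if succinate_bounds is not None:
        lo, hi = succinate_bounds
        bounds[succinate_rxn] = _clamped(lo, hi, succinate_rxn)
    return model.copy_with_bounds(bounds)


def _clamped(lo: float, hi: float, rid: str) -> tuple[float, float]:
    if hi < lo:
        raise ValueError(f"{rid}: empty bound interval [{lo}, {hi}]")
    if lo < 0:
        warnings.warn(f"{rid}: negative lower bound {lo:.4g} clamped to 0",
                      stacklevel=3)
        lo = 0.0
    return (lo, hi)


def _linprog_bounds(model: MetabolicModel, cap: float = 1e6):
    out = []
    for rxn in model.reactions:
        lb, ub = rxn.bounds()
        out.append((max(lb, -cap), min(ub, cap)))
    return out


def estimate_fluxes(model: MetabolicModel, strain_id: str = "") -> FluxSolution:
    """Solve the two-stage glucose-minimisation LP on a constrained model."""
    S = csr_matrix(stoichiometric_matrix(model))
    n = len(model.reactions)
    c = np.zeros(n)
    j_glc = model.reaction_index(model.glucose_uptake_id)
    c[j_glc] = 1.0
    bounds = _linprog_bounds(model)

    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    if res.status == 2:
        return FluxSolution(strain_id, {}, {}, np.nan, "infeasible",
                            message=res.message)
    if res.status == 3:
        return FluxSolution(strain_id, {}, {}, np.nan, "unbounded",
                            message=res.message)
    if res.status != 0:
        return FluxSolution(strain_id, {}, {}, np.nan, "infeasible",
                            message=res.message)
    v1 = res.x
    obj = float(res.fun)

    # second stage: minimise Σ|v_i| at the fixed optimal glucose input
    v2 = _l1_tie_break(S, bounds, j_glc, obj, n)
    v = v2 if v2 is not None else v1
    tie_break = v2 is not None and bool(np.max(np.abs(v2 - v1)) > 1e-6)

    resid = np.abs(S @ v).max()
    if resid > STEADY_STATE_TOL:
        warnings.warn(
            f"{strain_id or 'solution'}: steady-state residual {resid:.2e}",
            stacklevel=2,
        )
    raw = dict(zip(model.reaction_ids, v))
    if obj <= _FEAS_TOL:
        # zero sugar uptake (e.g. all drains at 0): steady state holds but
        # fluxes cannot be expressed per 100 units of glucose input
        return FluxSolution(strain_id, {}, raw, obj, "optimal",
                            tie_break_applied=tie_break,
                            message="zero sugar uptake; normalised fluxes undefined")
    norm = {rid: 100.0 * x / obj for rid, x in raw.items()}
    return FluxSolution(strain_id, norm, raw, obj, "optimal",
                        tie_break_applied=tie_break)


def _l1_tie_break(S, bounds, j_glc: int, obj: float, n: int):
    """min Σt, t ≥ ±v, S·v = 0, v_glc pinned to the stage-1 optimum."""
    I = eye(n, format="csr")
    Z = csr_matrix((S.shape[0], n))
    A_eq = hstack([S, Z], format="csr")
    A_ub = vstack([hstack([I, -I]), hstack([-I, -I])], format="csr")
    b_ub = np.zeros(2 * n)
    pin = max(_FEAS_TOL, 1e-9 * max(1.0, abs(obj)))
    bnds = list(bounds) + [(0, None)] * n
    lo, hi = bnds[j_glc]
    bnds[j_glc] = (max(lo, obj - pin), min(hi, obj + pin))
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    res = linprog(c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                  b_eq=np.zeros(S.shape[0]), bounds=bnds, method="highs")
    if res.status != 0:
        return None
    return res.x[:n]


def sugar_uptake_divergence(solution: FluxSolution, meas: MeasurementSet) -> float:
    """Relative gap between modelled and measured consumed hexose."""
    if not solution.optimal:
        raise ValueError("divergence requires an optimal solution")
    if meas.hexose_consumed <= 0:
        raise ValueError("measured hexose consumption is zero")
    return abs(solution.objective_value - meas.hexose_consumed) / meas.hexose_consumed


# -- measurement table I/O -------------------------------------------

def read_measurements(
    path,
    *,
    initial_glucose: float = 100.0,
    initial_fructose: float = 100.0,
    margin: float = 0.025,
    average: bool = True,
) -> list[MeasurementSet]:
    """Read the per-strain measurement CSV.

    Columns: strain, replicate, ethanol, glycerol, acetate, succinate,
    pyruvate, akg, co2 (mmol/L), drymass, glucose_res, fructose_res
    (g/L).  Replicates are averaged per strain unless ``average`` is
    False (then strain ids become ``strain/replicate``).  Consumed
    hexose is computed from the initial sugar content of the medium
    (g/L) minus residuals.
    """
    df = pd.read_csv(path)
    needed = {"strain", "drymass", "glucose_res", "fructose_res",
              *MEASUREMENT_COLUMNS}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"measurement file missing columns: {sorted(missing)}")
    if average:
        df = df.groupby("strain", sort=False, as_index=False).mean(numeric_only=True)
        ids = df["strain"].astype(str)
    else:
        ids = df["strain"].astype(str) + "/" + df.get(
            "replicate", pd.Series(range(len(df)))).astype(str)
    out = []
    for sid, row in zip(ids, df.itertuples(index=False)):
        consumed_g = max(initial_glucose - row.glucose_res, 0.0)
        consumed_f = max(initial_fructose - row.fructose_res, 0.0)
        hexose = 1000.0 * (consumed_g + consumed_f) / HEXOSE_MOLAR_MASS
        yields = {rid: float(getattr(row, col))
                  for col, rid in MEASUREMENT_COLUMNS.items()}
        out.append(MeasurementSet(
            strain_id=sid, metabolite_yields=yields,
            dry_mass=float(row.drymass),
            glucose_residual=float(row.glucose_res),
            fructose_residual=float(row.fructose_res),
            hexose_consumed=hexose, margin=margin,
        ))
    return out


def write_measurements(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False)
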