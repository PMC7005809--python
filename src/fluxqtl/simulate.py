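"""Synthetic segregant crosses and fermentation measurements.

The generator emulates the study design that the pipeline targets: a
population of haploid F2-segregants (default 125) phenotyped in
duplicate for extracellular metabolite yields during the exponential
phase of an anaerobic wine fermentation, genotyped on a multi-chromosome
marker map.  Ground truth is known, so every pipeline stage can be
validated offline.

Meiosis is a two-state Markov chain per chromosome with Haldane
recombination fractions between adjacent markers (no interference, no
segregation distortion).  Planted QTL act multiplicatively on the
expected yields of target excretion fluxes (a fraction of the base
yield per A allele), matching how allelic effects on fluxes are usually
reported (ratios).  Because the stoichiometric network couples yields
(carbon, redox and ATP balances), raw scaled targets need not be
attainable; each segregant's expected yields are therefore projected
onto the feasible steady-state yield set by a weighted-L1 linear
program before lognormal measurement noise (given CV) is applied.
Measurement noise is multiplicative lognormal, appropriate for strictly
positive concentrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, eye, hstack

from .fba import HEXOSE_MOLAR_MASS, MEASUREMENT_COLUMNS, _l1_tie_break
from .model import MetabolicModel, stoichiometric_matrix
from .scan import MarkerMap, SegregantCross, haldane

__all__ = [
    "PlantedEffect",
    "SimulationScenario",
    "default_scenario",
    "simulate_cross",
    "simulate_measurements",
    "project_to_feasible",
]


@dataclass(frozen=True)
class PlantedEffect:
    """One additive allelic effect: +`effect`·base on `target` per A allele."""

    chrom: str
    cm: float
    target: str          # excretion reaction id or the biomass reaction
    effect: float        # fraction of the base yield


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic experiment."""

    n_segregants: int = 125
    #: (length in cM, number of evenly spaced markers) per chromosome
    chromosomes: list[tuple[float, int]] = field(
        default_factory=lambda: [(100.0, 41)] * 4)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    base_yields: dict[str, float] = field(default_factory=lambda: {
        # mmol/L at the exponential-phase sampling point
        "Eth_t": 225.0, "Glyc_t": 8.0, "Ac_t": 2.2, "Succ_t": 1.2,
        "Pyr_t": 0.6, "Akg_t": 0.35, "CO2_t": 228.0,
    })
    base_dry_mass: float = 0.8        # g/L (redox-consistent with the yields)
    noise_cv: float = 0.02            # replicate-to-replicate CV
    replicates: int = 2
    seed: int = 0
    initial_glucose: float = 100.0    # g/L in the medium
    initial_fructose: float = 100.0   # g/L
    glucose_preference: float = 0.55  # glucose share of consumed hexose
    bp_per_cm: float = 3000.0         # physical/genetic scale of the map

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        chrom_names = {str(i + 1) for i in range(len(self.chromosomes))}
        for eff in self.planted_effects:
            if str(eff.chrom) not in chrom_names:
                raise ValueError(f"planted effect on undeclared chromosome {eff.chrom}")


def default_scenario(seed: int = 0) -> SimulationScenario:
    """Study-scale defaults: 125 segregants, 4 chromosomes, duplicate
    phenotyping, three planted loci on distinct chromosomes."""
    return SimulationScenario(
        seed=seed,
        planted_effects=[
            # glycerol locus (with the biomass co-response that balances NADH)
            PlantedEffect("1", 30.0, "Glyc_t", 0.08),
            PlantedEffect("1", 30.0, "BIOMASS", 0.04),
            # glycolysis/ethanol locus: ethanol and CO2 move together
            PlantedEffect("2", 50.0, "Eth_t", 0.04),
            PlantedEffect("2", 50.0, "CO2_t", 0.04),
            # acetate locus
            PlantedEffect("3", 70.0, "Ac_t", 0.25),
        ],
    )


# -- cross simulation ------------------------------------------------

def simulate_cross(scenario: SimulationScenario,
                   rng: np.random.Generator | None = None) -> SegregantCross:
    """Haploid gametes as a Markov chain along each chromosome."""
    rng = rng or np.random.default_rng(scenario.seed)
    n = scenario.n_segregants
    tables, geno_cols = [], {}
    for ci, (length_cm, n_markers) in enumerate(scenario.chromosomes):
        if n_markers < 1:
            raise ValueError(f"chromosome {ci + 1}: needs at least one marker")
        chrom = str(ci + 1)
        cms = np.linspace(0.0, length_cm, n_markers)
        bps = np.round(cms * scenario.bp_per_cm).astype(int) + 1
        names = [f"c{chrom}_m{j + 1}" for j in range(n_markers)]
        tables.append(pd.DataFrame(
            {"marker": names, "chrom": chrom, "cm": cms, "bp": bps}))
        g = np.empty((n, n_markers))
        g[:, 0] = rng.random(n) < 0.5
        rs = haldane(np.diff(cms))
        for j in range(1, n_markers):
            flip = rng.random(n) < rs[j - 1]
            g[:, j] = np.where(flip, 1.0 - g[:, j - 1], g[:, j - 1])
        for j, name in enumerate(names):
            geno_cols[name] = g[:, j]
    inds = [f"seg{i + 1:03d}" for i in range(n)]
    markers = MarkerMap(pd.concat(tables, ignore_index=True))
    genotypes = pd.DataFrame(geno_cols, index=inds)
    phenotypes = pd.DataFrame(index=pd.Index(inds))
    return SegregantCross(markers, genotypes, phenotypes)


# -- feasible-yield projection ---------------------------------------

def project_to_feasible(
    model: MetabolicModel,
    targets: dict[str, float],
    weights: dict[str, float] | None = None,
) -> tuple[dict[str, float], float, np.ndarray]:
    """Nearest steady-state-attainable yields to a target yield vector.

    Stage 1 minimises the weighted L1 distance between the target
    exchange fluxes and attainable ones (weights default to 1/target so
    relative deviations are comparable); stage 2 pins the realised
    exchange fluxes and minimises glucose input, so the returned uptake
    is the parsimonious one the estimator should reconstruct.  Returns
    (realised yields, glucose uptake, full flux vector).
    """
    S = csr_matrix(stoichiometric_matrix(model))
    n = len(model.reactions)
    ks = list(targets)
    k = len(ks)
    idx = np.array([model.reaction_index(r) for r in ks])
    w = np.array([
        (weights or {}).get(r, 1.0 / max(abs(targets[r]), 1e-3)) for r in ks])
    # rows: v_idx + sp - sm = target
    sel = csr_matrix((np.ones(k), (np.arange(k), idx)), shape=(k, n))
    A_eq = csr_matrix(np.vstack([
        np.hstack([S.toarray(), np.zeros((S.shape[0], 2 * k))]),
        np.hstack([sel.toarray(), np.eye(k), -np.eye(k)]),
    ]))
    b_eq = np.concatenate([np.zeros(S.shape[0]),
                           np.array([targets[r] for r in ks])])
    bounds = []
    for rxn in model.reactions:
        lb, ub = rxn.bounds()
        bounds.append((max(lb, -1e6), min(ub, 1e6)))
    bounds += [(0, None)] * (2 * k)
    c = np.concatenate([np.zeros(n), w, w])
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        raise ValueError(f"no feasible yields near target: {res.message}")
    realised = {r: float(res.x[j]) for r, j in zip(ks, idx)}

    # stage 2: parsimonious glucose input for the realised yields
    c2 = np.zeros(n)
    c2[model.reaction_index(model.glucose_uptake_id)] = 1.0
    bounds2 = list(bounds[:n])
    for r, j in zip(ks, idx):
        bounds2[j] = (realised[r] - 1e-9, realised[r] + 1e-9)
    res2 = linprog(c2, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds2,
                   method="highs")
    if res2.status != 0:
        raise ValueError(f"glucose minimisation failed on realised yields: "
                         f"{res2.message}")
    # canonical flux state: the same L1 tie-break the estimator applies,
    # so non-identifiable internal routes take their minimal representative
    j_glc = model.reaction_index(model.glucose_uptake_id)
    v = _l1_tie_break(S, bounds2, j_glc, float(res2.fun), n)
    if v is None:
        v = res2.x
    return realised, float(res2.fun), v


# -- measurement simulation ------------------------------------------

def _allele_at(cross: SegregantCross, chrom: str, cm: float) -> np.ndarray:
    sub = cross.markers.chrom_table(chrom)
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chrom}")
    j = int((sub["cm"] - cm).abs().to_numpy().argmin())
    marker = sub["marker"].iloc[j]
    return cross.genotypes[marker].to_numpy(dtype=float)


def simulate_measurements(
    scenario: SimulationScenario,
    cross: SegregantCross,
    model: MetabolicModel,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-segregant × replicate measurement table plus ground truth.

    Expected yields are the (projected) base yields scaled by
    1 + Σ allele·effect per target; dry mass follows biomass effects the
    same way.  Residual sugars are derived from the parsimonious
    glucose uptake of each segregant's feasible flux state, split
    between glucose and fructose by the configured preference.
    """
    rng = rng or np.random.default_rng(scenario.seed + 1)
    base_targets = dict(scenario.base_yields)
    base_targets[model.biomass_id] = scenario.base_dry_mass
    base, base_glc, _ = project_to_feasible(model, base_targets)

    effects_by_target: dict[str, list[PlantedEffect]] = {}
    for eff in scenario.planted_effects:
        effects_by_target.setdefault(eff.target, []).append(eff)
    unknown = [t for t in effects_by_target if t not in base]
    if unknown:
        raise ValueError(f"planted effects on unconstrained reactions: {unknown}")

    col_of = {rid: col for col, rid in MEASUREMENT_COLUMNS.items()}
    sigma = np.sqrt(np.log1p(scenario.noise_cv ** 2))
    rows = []
    truth_yields = {}
    for ind in cross.individuals:
        i = cross.individuals.index(ind)
        factors = {}
        for target, effs in effects_by_target.items():
            f = 1.0
            for eff in effs:
                allele = _allele_at(cross, str(eff.chrom), eff.cm)[i]
                f += eff.effect * allele
            factors[target] = f
        target_yields = {r: base[r] * factors.get(r, 1.0) for r in base}
        if factors:
            yields, glc, _ = project_to_feasible(model, target_yields)
        else:
            yields, glc = dict(base), base_glc
        truth_yields[ind] = {**yields, "glucose_uptake": glc}
        for rep in range(1, scenario.replicates + 1):
            noise = {r: float(np.exp(rng.normal(-sigma ** 2 / 2, sigma)))
                     for r in yields}
            g_noise = float(np.exp(rng.normal(-sigma ** 2 / 2, sigma)))
            consumed_g_total = glc * g_noise * HEXOSE_MOLAR_MASS / 1000.0  # g/L
            cons_glc = consumed_g_total * scenario.glucose_preference
            cons_fru = consumed_g_total - cons_glc
            row = {"strain": ind, "replicate": rep}
            for rid, y in yields.items():
                if rid == model.biomass_id:
                    row["drymass"] = y * noise[rid]
                else:
                    row[col_of[rid]] = y * noise[rid]
            row["glucose_res"] = max(scenario.initial_glucose - cons_glc, 0.0)
            row["fructose_res"] = max(scenario.initial_fructose - cons_fru, 0.0)
            rows.append(row)

    cols = ["strain", "replicate", *MEASUREMENT_COLUMNS,
            "drymass", "glucose_res", "fructose_res"]
    table = pd.DataFrame(rows)[cols]
    truth = {
        "seed": scenario.seed,
        "planted_effects": [asdict(e) for e in scenario.planted_effects],
        "base_yields": base,
        "base_glucose_uptake": base_glc,
        "per_segregant_yields": truth_yields,
    }
    return table, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))
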