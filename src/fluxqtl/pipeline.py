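"""End-to-end orchestration: flux estimation then QTL mapping.

The pipeline mirrors the two-step design of flux-QTL studies: first a
genome scan on the measured extracellular yields (plus the G/F ratio,
the ratio of residual glucose to residual fructose, when both residuals
are present), then a scan on the estimated intracellular fluxes of the
pathway-representative reactions.  Defaults are pinned to the standard
settings: ±2.5% measurement margin, pseudomarkers every 2.5 cM, 1000
permutations at α = 0.05, 1-LOD support intervals, 10 cM fQTL grouping.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fba, scan as qscan, structure
from .model import MetabolicModel, load_default_model, load_model

logger = logging.getLogger("fluxqtl")

__all__ = ["PipelineConfig", "run_flux_stage", "run_qtl_stage", "run_all"]


@dataclass
class PipelineConfig:
    measurements: str = "measurements.csv"
    cross: str = "cross.csv"
    model: str | None = None            # None = packaged CCM network
    selection_config: str | None = None  # None = packaged default
    out_dir: str = "results"
    margin: float = 0.025
    succinate_bounds: tuple[float, float] | None = None
    biomass_margin: float | None = None
    initial_glucose: float = 100.0
    initial_fructose: float = 100.0
    average_replicates: bool = True
    step_cm: float = 2.5
    error_rate: float = 1e-4
    n_perm: int = 1000
    alpha: float = 0.05
    drop: float = 1.0
    grouping_cm: float = 10.0
    min_shared_individuals: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.margin < 1):
            raise ValueError("margin must be in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("step_cm", "grouping_cm", "drop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("succinate_bounds") is not None:
            raw["succinate_bounds"] = tuple(raw["succinate_bounds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if d["succinate_bounds"] is not None:
            d["succinate_bounds"] = list(d["succinate_bounds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def load_model(self) -> MetabolicModel:
        return load_model(self.model) if self.model else load_default_model()


def run_flux_stage(
    config: PipelineConfig,
    model: MetabolicModel | None = None,
) -> tuple[structure.FluxMatrix, pd.DataFrame]:
    """Estimate fluxes for every strain in the measurement table.

    Returns the normalised flux matrix over strains with optimal
    solutions plus a per-strain diagnostic table; strains with
    infeasible constraint sets are excluded and logged, not fatal.
    """
    model = model or config.load_model()
    measurements = fba.read_measurements(
        config.measurements,
        initial_glucose=config.initial_glucose,
        initial_fructose=config.initial_fructose,
        margin=config.margin,
        average=config.average_replicates,
    )
    solutions, diags = [], []
    for meas in measurements:
        try:
            constrained = fba.build_constraints(
                model, meas, config.succinate_bounds,
                biomass_margin=config.biomass_margin)
            sol = fba.estimate_fluxes(constrained, meas.strain_id)
        except ValueError as exc:
            logger.warning("strain %s: %s", meas.strain_id, exc)
            diags.append({"strain": meas.strain_id, "status": "error",
                          "divergence": np.nan, "message": str(exc)})
            continue
        if sol.optimal and sol.fluxes:
            div = fba.sugar_uptake_divergence(sol, meas)
            diags.append({"strain": meas.strain_id, "status": sol.status,
                          "divergence": div, "message": sol.message})
        else:
            logger.warning("strain %s: %s solution excluded (%s)",
                           meas.strain_id, sol.status, sol.message)
            diags.append({"strain": meas.strain_id, "status": sol.status,
                          "divergence": np.nan, "message": sol.message})
        solutions.append(sol)
    matrix = structure.FluxMatrix.from_solutions(solutions, model)
    logger.info("flux stage: %d/%d strains optimal, mean uptake divergence %.3g",
                len(matrix.strains), len(measurements),
                float(np.nanmean([d["divergence"] for d in diags])))
    return matrix, pd.DataFrame(diags)


def _scan_one_trait(
    probs: qscan.GenotypeProbabilities,
    phenotype: pd.Series,
    trait: str,
    marker_map: qscan.MarkerMap,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> tuple[list[qscan.QTLInterval], dict[str, qscan.ScanResult]]:
    scans = {}
    for model_name, fn in (("hk", qscan.scan_hk), ("np", qscan.scan_np)):
        res = fn(probs, phenotype, trait)
        res.threshold = qscan.permutation_threshold(
            probs, phenotype, model=model_name, n_perm=config.n_perm,
            alpha=config.alpha, seed=rng)
        scans[model_name] = res
    intervals = qscan.merge_models(scans["hk"], scans["np"], marker_map,
                                   drop=config.drop,
                                   grouping_cm=config.grouping_cm)
    return intervals, scans


def run_qtl_stage(
    config: PipelineConfig,
    cross: qscan.SegregantCross,
    phenotypes: pd.DataFrame,
    probs: qscan.GenotypeProbabilities | None = None,
) -> tuple[pd.DataFrame, list[qscan.FQTLGroup], dict]:
    """Scan every phenotype column, merge models, group loci.

    Returns the QTL report table (one row per trait × interval, columns
    as in the standard QTL tables), the grouped loci, and the raw scans.
    """
    shared = [i for i in cross.individuals if i in phenotypes.index]
    if len(shared) < config.min_shared_individuals:
        raise ValueError(
            f"only {len(shared)} individuals shared between cross and "
            f"phenotypes (need {config.min_shared_individuals})")
    if probs is None:
        sub = qscan.SegregantCross(
            cross.markers, cross.genotypes.loc[shared],
            phenotypes.loc[shared])
        probs = qscan.genotype_probabilities(
            sub, step_cm=config.step_cm, error_rate=config.error_rate)
    rng = np.random.default_rng(config.seed)
    all_intervals: list[qscan.QTLInterval] = []
    all_scans: dict[str, dict[str, qscan.ScanResult]] = {}
    for trait in phenotypes.columns:
        y = phenotypes[trait].reindex(probs.individuals)
        if y.notna().sum() < 3 or np.nanvar(y.to_numpy(dtype=float)) == 0:
            logger.warning("trait %s skipped: too few values or zero variance",
                           trait)
            continue
        intervals, scans = _scan_one_trait(
            probs, y, trait, cross.markers, config, rng)
        all_intervals.extend(intervals)
        all_scans[trait] = scans
        for iv in intervals:
            logger.info("QTL %s for %s: LOD %.2f (%s)", iv.name, trait,
                        iv.peak_lod, iv.model)
    groups = qscan.group_fqtls(all_intervals, config.grouping_cm)
    rows = []
    for grp in groups:
        for iv in grp.members:
            rows.append({
                "trait": iv.trait, "qtl_name": grp.name,
                "chromosome": iv.chromosome,
                "start_bp": iv.start_bp, "end_bp": iv.end_bp,
                "peak_cm": iv.peak_cm, "lod": iv.peak_lod,
                "model": iv.model, "group_max_lod": grp.max_lod,
            })
    report = pd.DataFrame(rows, columns=[
        "trait", "qtl_name", "chromosome", "start_bp", "end_bp",
        "peak_cm", "lod", "model", "group_max_lod"])
    return report, groups, all_scans


def _yield_phenotypes(config: PipelineConfig) -> pd.DataFrame:
    """Measured-yield traits (averaged over replicates) incl. G/F ratio."""
    df = pd.read_csv(config.measurements)
    avg = df.groupby("strain", sort=False).mean(numeric_only=True)
    cols = [c for c in fba.MEASUREMENT_COLUMNS if c in avg.columns]
    out = avg[cols + ["drymass"]].copy()
    if {"glucose_res", "fructose_res"}.issubset(avg.columns):
        with np.errstate(divide="ignore"):
            out["gf_ratio"] = avg["glucose_res"] / avg["fructose_res"]
    return out


def run_all(config: PipelineConfig) -> Path:
    """Run both stages and write all tables to the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config_snapshot.yaml")
        model = config.load_model()
        flux_matrix, diagnostics = run_flux_stage(config, model)
        flux_matrix.to_csv(out / "flux_matrix.csv")
        diagnostics.to_csv(out / "flux_diagnostics.csv", index=False)

        cross = qscan.read_cross(config.cross)
        selection = (structure.load_selection_config(config.selection_config)
                     if config.selection_config else None)
        reps = structure.select_representatives(model, selection)

        yield_phenos = _yield_phenotypes(config)
        yield_report, yield_groups, _ = run_qtl_stage(config, cross, yield_phenos)
        yield_report.to_csv(out / "qtl_yields.csv", index=False)

        flux_phenos = flux_matrix.data[reps]
        flux_report, flux_groups, _ = run_qtl_stage(config, cross, flux_phenos)
        flux_report.to_csv(out / "qtl_fluxes.csv", index=False)

        grp_rows = [{
            "qtl_name": g.name, "chromosome": g.chromosome,
            "start_bp": g.start_bp, "end_bp": g.end_bp,
            "max_lod": g.max_lod, "traits": ";".join(g.traits), "stage": stage}
            for stage, groups in (("yields", yield_groups), ("fluxes", flux_groups))
            for g in groups]
        pd.DataFrame(grp_rows, columns=[
            "qtl_name", "chromosome", "start_bp", "end_bp", "max_lod",
            "traits", "stage"]).to_csv(out / "fqtl_groups.csv", index=False)
        logger.info("pipeline complete: %d yield QTL rows, %d flux QTL rows",
                    len(yield_report), len(flux_report))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
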