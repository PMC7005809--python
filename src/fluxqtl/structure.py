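"""Structure of the steady-state flux space and population summaries.

Two reactions are fully coupled when their fluxes are proportional in
every steady state; the correlation coefficient φ between reactions i
and j is the cosine of the angle between rows i and j of an orthonormal
null-space basis K of the stoichiometric matrix.  |φ| = 1 marks full
coupling, φ = 0 no steady-state relationship.  Reactions whose kernel
row is zero can carry no steady-state flux at all (blocked).

The population summaries (coefficient of variation per reaction,
flux-around-mean distributions) operate on a strains × reactions matrix
of normalised fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fba import FluxSolution
from .model import MetabolicModel, null_space_kernel

__all__ = [
    "FluxMatrix",
    "CorrelationStructure",
    "reaction_correlation",
    "coefficient_of_variation",
    "select_representatives",
    "load_selection_config",
    "load_default_selection_config",
    "distribution_summary",
]

_BLOCKED_TOL = 1e-9
_COUPLED_TOL = 1e-9


@dataclass
class FluxMatrix:
    """Normalised fluxes, strains × reactions."""

    data: pd.DataFrame  # index = strain ids, columns = reaction ids

    @property
    def strains(self) -> list[str]:
        return list(self.data.index)

    @property
    def reactions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @classmethod
    def from_solutions(cls, solutions: list[FluxSolution],
                       model: MetabolicModel) -> "FluxMatrix":
        """Stack optimal solutions; non-optimal strains are omitted."""
        rows, idx = [], []
        for sol in solutions:
            if sol.optimal and sol.fluxes:
                rows.append([sol.fluxes[r] for r in model.reaction_ids])
                idx.append(sol.strain_id)
        return cls(pd.DataFrame(rows, index=idx, columns=model.reaction_ids))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="strain")

    @classmethod
    def read_csv(cls, path: str | Path) -> "FluxMatrix":
        return cls(pd.read_csv(path, index_col="strain"))


@dataclass
class CorrelationStructure:
    phi: pd.DataFrame                       # reactions × reactions
    coupled_groups: list[list[str]]         # partition of unblocked reactions
    blocked: list[str] = field(default_factory=list)


def reaction_correlation(model: MetabolicModel,
                         kernel: np.ndarray | None = None) -> CorrelationStructure:
    """Correlation φ between steady-state reaction fluxes.

    φ[i, j] = (K_i · K_j) / (‖K_i‖ ‖K_j‖) over rows of an orthonormal
    null-space basis; the result is independent of the basis chosen.
    Blocked reactions (zero row) get φ = 0 off-diagonal.
    """
    K = null_space_kernel(model) if kernel is None else kernel
    if K.shape[1] == 0:
        raise ValueError("null space is empty: no steady-state flux possible")
    norms = np.linalg.norm(K, axis=1)
    blocked_mask = norms <= _BLOCKED_TOL * max(1.0, norms.max())
    safe = np.where(blocked_mask, 1.0, norms)
    U = K / safe[:, None]
    phi = U @ U.T
    phi[blocked_mask, :] = 0.0
    phi[:, blocked_mask] = 0.0
    np.fill_diagonal(phi, 1.0)
    phi = np.clip(phi, -1.0, 1.0)
    rids = model.reaction_ids
    phi_df = pd.DataFrame(phi, index=rids, columns=rids)

    # fully-coupled groups: connected components of |phi| = 1 (within tol)
    unblocked = [i for i in range(len(rids)) if not blocked_mask[i]]
    adj = np.abs(phi) >= 1.0 - _COUPLED_TOL
    seen: set[int] = set()
    groups: list[list[str]] = []
    for i in unblocked:
        if i in seen:
            continue
        stack, comp = [i], []
        seen.add(i)
        while stack:
            a = stack.pop()
            comp.append(a)
            for b in unblocked:
                if b not in seen and adj[a, b]:
                    seen.add(b)
                    stack.append(b)
        groups.append(sorted(rids[a] for a in comp))
    groups.sort(key=lambda g: g[0])
    return CorrelationStructure(
        phi=phi_df, coupled_groups=groups,
        blocked=[rids[i] for i in range(len(rids)) if blocked_mask[i]],
    )


def coefficient_of_variation(fluxes: FluxMatrix,
                             group: list[str] | None = None) -> pd.Series:
    """Per-reaction CV = sample SD / |mean| within a strain group.

    Uses the n−1 (sample) standard deviation.  Reactions with mean 0
    are undefined and reported as NaN.
    """
    if group is None:
        sub = fluxes.data
    else:
        unknown = [s for s in group if s not in fluxes.data.index]
        if unknown:
            raise ValueError(f"unknown strains in group: {unknown}")
        sub = fluxes.data.loc[group]
    if len(sub) == 0:
        raise ValueError("empty strain group")
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    cv = sd / mean.abs()
    cv[mean == 0] = np.nan
    return cv


def load_selection_config(path: str | Path) -> list[dict]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg["selection"]


def load_default_selection_config() -> list[dict]:
    ref = resources.files("fluxqtl.data") / "representative_fluxes.yaml"
    with resources.as_file(ref) as p:
        return load_selection_config(p)


def select_representatives(model: MetabolicModel,
                           selection_config: list[dict] | None = None) -> list[str]:
    """Resolve the per-pathway representative-flux rules.

    Each config entry names a pathway and a rule: ``first``/``last``
    (position in model reaction order within that pathway), ``explicit``
    (listed ids, parallel routes all kept) or ``all``.  The packaged
    default configuration selects the 20 representatives of the main
    CCM pathways.
    """
    if selection_config is None:
        selection_config = load_default_selection_config()
    by_pathway: dict[str, list[str]] = {}
    for rxn in model.reactions:
        by_pathway.setdefault(rxn.pathway, []).append(rxn.id)
    out: list[str] = []
    for entry in selection_config:
        pathway = entry.get("pathway", "")
        rule = entry["rule"]
        if rule == "explicit":
            ids = entry["ids"]
            missing = [i for i in ids if i not in model.reaction_ids]
            if missing:
                raise ValueError(f"selection {pathway!r}: unknown reactions {missing}")
            chosen = list(ids)
        else:
            members = by_pathway.get(pathway)
            if not members:
                raise ValueError(f"selection rule for unknown pathway {pathway!r}")
            if rule == "first":
                chosen = [members[0]]
            elif rule == "last":
                chosen = [members[-1]]
            elif rule == "all":
                chosen = list(members)
            else:
                raise ValueError(f"unknown selection rule {rule!r}")
        for rid in chosen:
            if rid not in out:
                out.append(rid)
    return out


def distribution_summary(fluxes: FluxMatrix, reaction: str
                         ) -> tuple[float, float, pd.Series]:
    """Mean, sample SD, and per-strain flux normalised to mean = 1."""
    if reaction not in fluxes.data.columns:
        raise KeyError(reaction)
    col = fluxes.data[reaction]
    if len(col) < 2:
        raise ValueError("need at least two strains")
    mean = float(col.mean())
    sd = float(col.std(ddof=1))
    if mean == 0.0:
        normalised = pd.Series(np.nan, index=col.index)
    else:
        normalised = col / mean
    return mean, sd, normalised
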