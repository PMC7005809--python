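"""Compartmented stoichiometric model of yeast central carbon metabolism.

The network is a reduced constraint-based model of anaerobic (wine
fermentation) central carbon metabolism with three compartments: cytosol
``[c]``, mitochondria ``[m]`` and the extracellular space.  Excreted
metabolites are represented as pure drain reactions ("``etoh[c] →``", a
single −1 stoichiometric entry) rather than as explicit extracellular
species, and transport across the mitochondrial membrane is written as
ordinary reactions suffixed ``_tm``.

Reactions are stored with signed stoichiometries (consumed negative,
produced positive).  The model exposes its stoichiometric matrix ``S``
(metabolites × reactions) and an orthonormal basis of the steady-state
flux space ``{v : S·v = 0}`` used for flux-coupling analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelParseError",
    "parse_equation",
    "format_equation",
    "load_model",
    "write_model",
    "load_default_model",
    "stoichiometric_matrix",
    "null_space_kernel",
]

COMPARTMENTS = {"c": "cytosol", "m": "mitochondria", "e": "extracellular"}

_FORWARD_ARROWS = ("→", "->", "=>")
_REVERSIBLE_ARROWS = ("⇌", "<=>", "<->", "<==>")


class ModelParseError(ValueError):
    """Raised when a model file or reaction equation cannot be parsed."""


@dataclass(frozen=True)
class Metabolite:
    """One chemical species in one compartment.

    ``id`` is the full bracketed token (e.g. ``g6p[c]``) and is unique
    within a model; ``base`` is the bare chemical token.
    """

    id: str
    base: str
    compartment: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS.values():
            raise ValueError(f"unknown compartment {self.compartment!r} for {self.id}")


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (consumed < 0, produced > 0).

    Zero coefficients are kept explicitly so that printed equations such
    as biomass terms with coefficient 0 survive a round trip.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float | None = None
    upper_bound: float | None = None
    pathway: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound is None:
            self.lower_bound = -np.inf if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = np.inf
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"reaction {self.id}: lower bound exceeds upper bound")
        if not self.reversible and self.lower_bound < 0:
            raise ValueError(f"reaction {self.id}: irreversible but lower bound < 0")

    def bounds(self) -> tuple[float, float]:
        return (float(self.lower_bound), float(self.upper_bound))


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str = "BIOMASS"
    glucose_uptake_id: str = "Glc_t"
    exchange_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.validate()

    # -- bookkeeping -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def validate(self) -> None:
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelParseError(
                        f"reaction {rxn.id}: undeclared metabolite {met_id!r}"
                    )
        used = {m for r in self.reactions for m in r.stoichiometry}
        orphans = [m for m in self._met_index if m not in used]
        if orphans:
            raise ValueError(f"metabolites in no reaction: {orphans}")
        for rid in (self.biomass_id, self.glucose_uptake_id, *self.exchange_ids):
            if rid not in self._rxn_index:
                raise ValueError(f"designated reaction {rid!r} not in model")

    def copy_with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Return a copy whose listed reactions carry replaced bounds."""
        new_rxns = []
        for rxn in self.reactions:
            lb, ub = bounds.get(rxn.id, rxn.bounds())
            new_rxns.append(
                Reaction(rxn.id, dict(rxn.stoichiometry), rxn.reversible or lb < 0,
                         lb, ub, rxn.pathway)
            )
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=new_rxns,
            biomass_id=self.biomass_id,
            glucose_uptake_id=self.glucose_uptake_id,
            exchange_ids=list(self.exchange_ids),
        )


# -- equation grammar ------------------------------------------------

_TERM_RE = re.compile(
    r"^\s*(?:(?P<coef>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(?P<met>\S+)\s*$"
)
_MET_RE = re.compile(r"^(?P<base>[A-Za-z0-9_]+)(?:\[(?P<comp>[a-z])\])?$")


def _parse_side(side: str, sign: float, stoich: dict[str, float], ctx: str) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = _TERM_RE.match(term)
        if m is None:
            raise ModelParseError(f"{ctx}: cannot parse term {term!r}")
        coef = float(m.group("coef")) if m.group("coef") is not None else 1.0
        tok = m.group("met")
        if _MET_RE.match(tok) is None:
            raise ModelParseError(f"{ctx}: malformed metabolite token {tok!r}")
        stoich[tok] = stoich.get(tok, 0.0) + sign * coef
        if stoich[tok] == 0.0:
            stoich[tok] = 0.0  # normalise −0.0


def parse_equation(text: str, ctx: str = "equation") -> tuple[dict[str, float], bool]:
    """Parse a reaction equation in the bracketed-compartment grammar.

    ``"pep[c] + adp[c] → pyr[c] + atp[c]"`` gives signed coefficients
    (substrates negative); ``⇌`` marks the reaction reversible.  Pure
    drains ("``etoh[c] →``") and pure sources ("``→ glc[c]``") have one
    side empty.  Explicit zero coefficients ("``0 pyr[c]``") are kept.
    """
    arrow = None
    reversible = False
    for a in _REVERSIBLE_ARROWS:
        if a in text:
            arrow, reversible = a, True
            break
    if arrow is None:
        for a in _FORWARD_ARROWS:
            if a in text:
                arrow = a
                break
    if arrow is None:
        raise ModelParseError(f"{ctx}: no reaction arrow in {text!r}")
    lhs, rhs = text.split(arrow, 1)
    stoich: dict[str, float] = {}
    _parse_side(lhs, -1.0, stoich, ctx)
    _parse_side(rhs, +1.0, stoich, ctx)
    if not stoich:
        raise ModelParseError(f"{ctx}: equation has no metabolites")
    return stoich, reversible


def _fmt_coef(c: float) -> str:
    return f"{c:.12g}"


def format_equation(rxn: Reaction) -> str:
    """Inverse of :func:`parse_equation` (term order follows the map)."""
    # zero-coefficient terms are conventionally printed on the substrate side
    lhs = []
    rhs = []
    for m, c in rxn.stoichiometry.items():
        if c < 0:
            lhs.append(f"{_fmt_coef(-c)} {m}" if c != -1.0 else m)
        elif c > 0:
            rhs.append(f"{_fmt_coef(c)} {m}" if c != 1.0 else m)
        else:
            lhs.append(f"0 {m}")
    arrow = "⇌" if rxn.reversible else "→"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# -- file I/O --------------------------------------------------------

def _metabolite_from_token(tok: str, names: dict[str, str]) -> Metabolite:
    m = _MET_RE.match(tok)
    comp_code = m.group("comp")
    if comp_code is None:
        comp = "extracellular"
    elif comp_code in COMPARTMENTS:
        comp = COMPARTMENTS[comp_code]
    else:
        raise ModelParseError(f"unknown compartment code [{comp_code}] in {tok!r}")
    return Metabolite(id=tok, base=m.group("base"), compartment=comp,
                      name=names.get(tok, ""))


def _metabolites_sidecar(path: Path) -> Path:
    return path.with_suffix(".metabolites.tsv")


def load_model(path: str | Path, *, biomass_id: str = "BIOMASS",
               glucose_uptake_id: str = "Glc_t") -> MetabolicModel:
    """Load a model from a reaction table (TSV).

    Columns: ``id``, ``equation`` (bracketed-compartment grammar),
    ``reversible`` (0/1), optional ``lb``/``ub`` (blank = open) and
    ``pathway``.  If a sidecar ``<stem>.metabolites.tsv`` with columns
    ``id``, ``name``, ``compartment`` exists, its declarations are
    authoritative and any equation metabolite missing from it is an
    error; otherwise metabolites are inferred from the equations.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"id", "equation", "reversible"}
    if not required.issubset(df.columns):
        raise ModelParseError(f"{path}: missing columns {required - set(df.columns)}")

    declared: dict[str, str] | None = None
    sidecar = _metabolites_sidecar(path)
    if sidecar.exists():
        mdf = pd.read_csv(sidecar, sep="\t", comment="#", dtype=str).fillna("")
        declared = dict(zip(mdf["id"], mdf.get("name", "")))

    reactions: list[Reaction] = []
    seen: set[str] = set()
    tokens: dict[str, None] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        rid = row.id.strip()
        if not rid:
            raise ModelParseError(f"{path}:{lineno}: empty reaction id")
        if rid in seen:
            raise ModelParseError(f"{path}:{lineno}: duplicate reaction id {rid!r}")
        seen.add(rid)
        ctx = f"{path}:{lineno} ({rid})"
        stoich, rev_eq = parse_equation(row.equation, ctx)
        rev_col = str(row.reversible).strip().lower() in {"1", "true", "yes"}
        reversible = rev_eq or rev_col
        lb = float(row.lb) if getattr(row, "lb", "") not in ("", None) else None
        ub = float(row.ub) if getattr(row, "ub", "") not in ("", None) else None
        if declared is not None:
            for tok in stoich:
                if tok not in declared:
                    raise ModelParseError(f"{ctx}: undeclared metabolite {tok!r}")
        for tok in stoich:
            tokens.setdefault(tok, None)
        reactions.append(Reaction(rid, stoich, reversible, lb, ub,
                                  getattr(row, "pathway", "")))

    names = declared or {}
    if declared is not None:
        ordered = list(declared)  # declaration order
    else:
        ordered = list(tokens)  # first-appearance order
    metabolites = [_metabolite_from_token(tok, names) for tok in ordered]
    # excretion drains: "_t" reactions whose only entries are consumed species
    exchange_ids = [r.id for r in reactions
                    if r.id.endswith("_t") and r.id != glucose_uptake_id
                    and all(c <= 0 for c in r.stoichiometry.values())]
    return MetabolicModel(metabolites, reactions, biomass_id=biomass_id,
                          glucose_uptake_id=glucose_uptake_id,
                          exchange_ids=exchange_ids)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the reaction table and metabolite sidecar (inverse of load)."""
    path = Path(path)
    rows = []
    for rxn in model.reactions:
        lb, ub = rxn.bounds()
        rows.append({
            "id": rxn.id,
            "equation": format_equation(rxn),
            "reversible": int(rxn.reversible),
            "lb": "" if np.isneginf(lb) or (not rxn.reversible and lb == 0.0) else lb,
            "ub": "" if np.isposinf(ub) else ub,
            "pathway": rxn.pathway,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    mrows = [{"id": m.id, "name": m.name,
              "compartment": m.compartment} for m in model.metabolites]
    pd.DataFrame(mrows).to_csv(_metabolites_sidecar(path), sep="\t", index=False)


def load_default_model() -> MetabolicModel:
    """Load the packaged 68-reaction / 61-metabolite CCM network."""
    ref = resources.files("fluxqtl.data") / "yeast_ccm_synthetic.tsv"
    with resources.as_file(ref) as p:
        return load_model(p)


# -- linear algebra --------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense S (metabolites × reactions), column order = reaction order."""
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            S[model.metabolite_index(met_id), j] = coef
    return S


def null_space_kernel(model: MetabolicModel, rcond: float = 1e-10) -> np.ndarray:
    """Orthonormal basis K (reactions × dim null(S)) of the steady-state space.

    Computed by SVD with singular values below ``rcond·max(σ)`` treated
    as zero; an empty kernel (fully determined network) gives a
    (reactions × 0) array.
    """
    S = stoichiometric_matrix(model)
    K = linalg.null_space(S, rcond=rcond)
    return K
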