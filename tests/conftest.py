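import numpy as np
import pandas as pd
import pytest

from fluxqtl.model import MetabolicModel, Metabolite, Reaction, load_default_model
from fluxqtl.scan import MarkerMap, SegregantCross


def _met(tok: str) -> Metabolite:
    base, comp = (tok[:-3], tok[-2]) if tok.endswith("]") else (tok, None)
    comp_name = {"c": "cytosol", "m": "mitochondria", None: "extracellular"}[comp]
    return Metabolite(id=tok, base=base, compartment=comp_name)


def make_model(reactions: dict[str, dict[str, float]],
               reversible: set[str] = frozenset(),
               biomass_id: str | None = None,
               glucose_uptake_id: str = "",
               exchange_ids: list[str] | None = None) -> MetabolicModel:
    """Small helper to assemble toy networks inline in tests."""
    mets = sorted({m for st in reactions.values() for m in st})
    rxns = [Reaction(rid, dict(st), rid in reversible)
            for rid, st in reactions.items()]
    return MetabolicModel(
        metabolites=[_met(t) for t in mets],
        reactions=rxns,
        biomass_id=biomass_id or next(iter(reactions)),
        glucose_uptake_id=glucose_uptake_id or next(iter(reactions)),
        exchange_ids=exchange_ids or [],
    )


@pytest.fixture(scope="session")
def ccm_model():
    return load_default_model()


@pytest.fixture
def branched_toy():
    """Uptake A, split to drains B and C: min input = sum of drain lows."""
    return make_model(
        {
            "A_in": {"A[c]": 1.0},
            "A_B": {"A[c]": -1.0, "B[c]": 1.0},
            "B_out": {"B[c]": -1.0},
            "A_C": {"A[c]": -1.0, "C[c]": 1.0},
            "C_out": {"C[c]": -1.0},
        },
        glucose_uptake_id="A_in",
        biomass_id="A_B",
        exchange_ids=["B_out", "C_out"],
    )


@pytest.fixture
def tiny_cross():
    """One chromosome, 5 markers over 40 cM, 8 segregants."""
    mk = MarkerMap(pd.DataFrame({
        "marker": [f"m{i}" for i in range(1, 6)],
        "chrom": "1",
        "cm": [0.0, 10.0, 20.0, 30.0, 40.0],
        "bp": [1, 30001, 60001, 90001, 120001],
    }))
    rng = np.random.default_rng(42)
    geno = pd.DataFrame(
        rng.integers(0, 2, size=(8, 5)).astype(float),
        index=[f"i{k}" for k in range(8)],
        columns=mk.table["marker"],
    )
    pheno = pd.DataFrame({"y": rng.normal(size=8)}, index=geno.index)
    return SegregantCross(mk, geno, pheno)
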