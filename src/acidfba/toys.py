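"""Small enzyme-constrained toy models with analytically known optima.

The generated networks are a linear chain ``S_ext -> S -> P -> biomass`` with
K parallel enzyme-catalyzed S -> P routes.  Route k carries a turnover number
kcat_k and a biomass yield y_k, and the enzymes follow GECKO conventions
(pseudo-metabolite ``prot_<id>``, draw reaction ``draw_prot_<id>`` costing
MW_k/1000 g of pool per mmol enzyme, and a pool exchange bounded by the
available enzyme mass).  The reduced problem over the K route fluxes is the
tiny linear program

    max  sum_k y_k v_k
    s.t. sum_k v_k <= uptake                 (substrate supply)
         sum_k (MW_k / 1000 / kcat_k) v_k <= pool bound
         v_k >= 0

whose optimum is recovered exactly by exhaustive vertex enumeration
(:func:`enumerate_lp`), providing an independent ground truth for every LP
the package solves elsewhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from cobra import Metabolite, Model, Reaction

from .amino_acids import AA_CODES, ProteinRecord, protein_mw
from .model_build import GeckoConventions, classify_ec_model

__all__ = [
    "EnzymeSpec",
    "CarbonSource",
    "ToySpec",
    "TOYEC1",
    "OracleResult",
    "enumerate_lp",
    "make_toy_ecgem",
    "toy_oracle",
    "min_pool_oracle",
    "random_toy_spec",
    "make_random_ecgem",
]


@dataclass(frozen=True)
class EnzymeSpec:
    """One catalytic route: sequence, turnover number (h^-1), biomass yield."""

    enzyme_id: str
    sequence: str
    kcat: float
    yield_coeff: float

    def __post_init__(self):
        if self.kcat <= 0:
            raise ValueError("kcat must be positive")
        if self.yield_coeff <= 0:
            raise ValueError("pathway yield must be positive")

    @property
    def mw(self) -> float:
        return protein_mw(self.sequence)

    @property
    def pool_cost(self) -> float:
        """Gram of pool consumed per unit route flux: MW/1000/kcat."""
        return self.mw / 1000.0 / self.kcat


@dataclass(frozen=True)
class CarbonSource:
    """An extracellular carbon source; ``substrate_yield`` mol S per mol taken up."""

    name: str
    substrate_yield: float = 1.0
    transportable: bool = True


@dataclass(frozen=True)
class ToySpec:
    """Specification of a toy enzyme-constrained model."""

    enzymes: tuple[EnzymeSpec, ...]
    uptake: float = 10.0
    pool_bound: float = 0.01
    carbon_sources: tuple[CarbonSource, ...] = ()
    with_nutrient_classes: bool = False
    seed: int | None = None

    def __post_init__(self):
        if not self.enzymes:
            raise ValueError("need at least one enzyme")
        if self.uptake < 0 or self.pool_bound < 0:
            raise ValueError("uptake and pool bound must be non-negative")
        object.__setattr__(self, "enzymes", tuple(self.enzymes))
        object.__setattr__(self, "carbon_sources", tuple(self.carbon_sources))

    def with_(self, **changes) -> "ToySpec":
        return replace(self, **changes)


#: Reference two-route toy: an Ala-only enzyme (high cost, high yield) versus a
#: Gly-only enzyme (low cost, half yield) competing for 10 units of substrate
#: and 0.01 g gDW^-1 of enzyme mass.
TOYEC1 = ToySpec(
    enzymes=(
        EnzymeSpec("E1", "AAAA", kcat=100.0, yield_coeff=1.0),
        EnzymeSpec("E2", "GGGG", kcat=1000.0, yield_coeff=0.5),
    ),
    uptake=10.0,
    pool_bound=0.01,
)


def make_toy_ecgem(spec: ToySpec, *, conventions: GeckoConventions | None = None):
    """Build a GECKO-style cobra model from ``spec``.

    Returns ``(EcModel, [ProteinRecord, ...])`` — the classified model and the
    protein sequences needed to build its composition matrix.
    """
    conv = conventions or GeckoConventions()
    model = Model("toy_ecgem")
    model.solver = "glpk"

    s_c = Metabolite("S_c", name="substrate", compartment="c", formula="C6H12O6")
    p_c = Metabolite("P_c", name="precursor", compartment="c", formula="C3H4O3")
    pool = Metabolite(conv.pool_metabolite, name="protein pool", compartment="c")

    reactions = []
    sources = spec.carbon_sources or (CarbonSource("C1"),)
    for i, src in enumerate(sources):
        ext = Metabolite(f"{src.name}_e", compartment="e", formula="C6H12O6")
        ex = Reaction(f"EX_{src.name}_e",
                      lower_bound=-spec.uptake if i == 0 else 0.0,
                      upper_bound=1000.0)
        ex.add_metabolites({ext: -1.0})
        reactions.append(ex)
        if src.transportable:
            t = Reaction(f"T_{src.name}", lower_bound=0.0, upper_bound=1000.0)
            t.add_metabolites({ext: -1.0, s_c: src.substrate_yield})
            reactions.append(t)

    biomass = Reaction("biomass", lower_bound=0.0, upper_bound=1000.0)
    biomass_stoich = {p_c: -1.0}

    if spec.with_nutrient_classes:
        # Trace N/P/S requirements so every elemental class is growth-essential.
        for sym, formula, coeff in (("N", "H4N", 0.01), ("Pho", "HO4P", 0.005),
                                    ("Sul", "O4S", 0.002)):
            ext = Metabolite(f"{sym}_e", compartment="e", formula=formula)
            internal = Metabolite(f"{sym}_c", compartment="c", formula=formula)
            ex = Reaction(f"EX_{sym}_e", lower_bound=-1000.0, upper_bound=1000.0)
            ex.add_metabolites({ext: -1.0})
            t = Reaction(f"T_{sym}", lower_bound=0.0, upper_bound=1000.0)
            t.add_metabolites({ext: -1.0, internal: 1.0})
            reactions.extend([ex, t])
            biomass_stoich[internal] = -coeff

    pool_ex = Reaction(conv.pool_reaction, lower_bound=0.0,
                       upper_bound=spec.pool_bound)
    pool_ex.add_metabolites({pool: 1.0})
    reactions.append(pool_ex)

    proteins = []
    for enz in spec.enzymes:
        met = Metabolite(conv.enzyme_prefix + enz.enzyme_id, compartment="c")
        draw = Reaction(conv.draw_prefix + enz.enzyme_id,
                        lower_bound=0.0, upper_bound=1000.0)
        draw.add_metabolites({pool: -enz.mw / 1000.0, met: 1.0})
        route = Reaction(f"R_{enz.enzyme_id}", lower_bound=0.0, upper_bound=1000.0)
        route.add_metabolites({s_c: -1.0, met: -1.0 / enz.kcat,
                               p_c: enz.yield_coeff})
        reactions.extend([draw, route])
        proteins.append(ProteinRecord(enz.enzyme_id, enz.sequence))

    biomass.add_metabolites(biomass_stoich)
    reactions.append(biomass)
    model.add_reactions(reactions)
    model.objective = "biomass"
    ec = classify_ec_model(model, conventions=conv, biomass_reaction="biomass")
    return ec, proteins


@dataclass(frozen=True)
class OracleResult:
    """Exact solution of a small LP by vertex enumeration."""

    objective: float
    solution: np.ndarray
    degenerate: bool = False
    status: str = "optimal"


def enumerate_lp(c: np.ndarray, a_ub: np.ndarray, b_ub: np.ndarray,
                 a_eq: np.ndarray | None = None, b_eq: np.ndarray | None = None,
                 *, sense: str = "max", tol: float = 1e-9) -> OracleResult:
    """Solve ``opt c.v  s.t.  a_ub v <= b_ub, a_eq v = b_eq, v >= 0`` exactly.

    Exhaustively enumerates basic feasible points (intersections of n active
    constraints drawn from the inequality rows, equality rows, and the
    non-negativity bounds) and returns the best vertex.  Only intended for
    n <= ~8 variables; used as the independent ground truth in tests.
    Unboundedness is not detected — supply bounded feasible regions.
    """
    c = np.asarray(c, dtype=float)
    n = c.size
    if n > 8:
        raise ValueError("vertex enumeration is limited to <= 8 variables")
    a_ub = np.atleast_2d(np.asarray(a_ub, dtype=float))
    b_ub = np.atleast_1d(np.asarray(b_ub, dtype=float))
    rows = [(a_ub[i], b_ub[i], False) for i in range(a_ub.shape[0])]
    if a_eq is not None:
        a_eq = np.atleast_2d(np.asarray(a_eq, dtype=float))
        b_eq = np.atleast_1d(np.asarray(b_eq, dtype=float))
        rows += [(a_eq[i], b_eq[i], True) for i in range(a_eq.shape[0])]
    for j in range(n):
        axis = np.zeros(n)
        axis[j] = -1.0  # -v_j <= 0, i.e. v_j >= 0
        rows.append((axis, 0.0, False))

    eq_rows = frozenset(i for i, (_, _, is_eq) in enumerate(rows) if is_eq)
    if len(eq_rows) > n:
        raise ValueError("more equality constraints than variables")
    sign = 1.0 if sense == "max" else -1.0
    best: OracleResult | None = None
    best_points: list[np.ndarray] = []
    for combo in itertools.combinations(range(len(rows)), n):
        if not eq_rows.issubset(combo):
            continue
        a_active = np.array([rows[i][0] for i in combo])
        b_active = np.array([rows[i][1] for i in combo])
        if abs(np.linalg.det(a_active)) < 1e-12:
            continue
        v = np.linalg.solve(a_active, b_active)
        feasible = (v >= -tol).all() and all(
            abs(a @ v - b) <= tol if eq else a @ v <= b + tol
            for a, b, eq in rows)
        if not feasible:
            continue
        z = float(c @ v)
        if best is None or sign * z > sign * best.objective + tol * max(1.0, abs(z)):
            best = OracleResult(z, np.clip(v, 0.0, None))
            best_points = [v]
        elif abs(z - best.objective) <= tol * max(1.0, abs(z)):
            if all(np.max(np.abs(v - p)) > 1e-7 for p in best_points):
                best_points.append(v)
                best = replace(best, degenerate=True)
    if best is None:
        return OracleResult(float("nan"), np.full(n, np.nan), status="infeasible")
    return best


def toy_oracle(spec: ToySpec) -> OracleResult:
    """Exact optimal growth of ``spec`` via vertex enumeration of the route LP."""
    if len(spec.enzymes) > 8:
        raise ValueError("oracle enumeration supports at most 8 enzymes")
    yields = np.array([e.yield_coeff for e in spec.enzymes])
    costs = np.array([e.pool_cost for e in spec.enzymes])
    substrate_yield = (spec.carbon_sources[0].substrate_yield
                       if spec.carbon_sources else 1.0)
    a_ub = np.vstack([np.ones_like(yields) / substrate_yield, costs])
    b_ub = np.array([spec.uptake, spec.pool_bound])
    return enumerate_lp(yields, a_ub, b_ub, sense="max")


def min_pool_oracle(spec: ToySpec, mu: float) -> OracleResult:
    """Exact minimal pool usage sustaining growth ``mu`` on a toy model."""
    yields = np.array([e.yield_coeff for e in spec.enzymes])
    costs = np.array([e.pool_cost for e in spec.enzymes])
    res = enumerate_lp(costs, np.ones((1, yields.size)),
                       np.array([spec.uptake]),
                       a_eq=yields[None, :], b_eq=np.array([mu]),
                       sense="min")
    return res


_RANDOM_AA = np.array(list(AA_CODES))


def random_toy_spec(n_enzymes: int, seed: int, *, uptake: float = 10.0) -> ToySpec:
    """Random :class:`ToySpec`: log-uniform kcats in [10, 1e4] h^-1, uniform
    random sequences of length 50-500, log-uniform yields and pool bound."""
    if not 1 <= n_enzymes <= 8:
        raise ValueError("n_enzymes must be in [1, 8]")
    rng = np.random.default_rng(seed)
    enzymes = []
    for k in range(n_enzymes):
        kcat = 10.0 ** rng.uniform(1.0, 4.0)
        length = int(rng.integers(50, 501))
        seq = "".join(rng.choice(_RANDOM_AA, size=length))
        yld = 10.0 ** rng.uniform(-0.7, 0.3)
        enzymes.append(EnzymeSpec(f"E{k + 1}", seq, kcat=kcat, yield_coeff=yld))
    pool_bound = 10.0 ** rng.uniform(-3.0, -1.0)
    return ToySpec(tuple(enzymes), uptake=uptake, pool_bound=pool_bound, seed=seed)


def make_random_ecgem(n_enzymes: int, seed: int, **kwargs):
    """Reproducible random toy ecGEM; returns ``(EcModel, proteins, ToySpec)``."""
    spec = random_toy_spec(n_enzymes, seed, **kwargs)
    ec, proteins = make_toy_ecgem(spec)
    return ec, proteins, spec
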