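"""Species-specific amino-acid distributions as hard or soft constraints.

A species distribution is a normalized 20-vector of relative amino-acid mass
fractions p_l (for non-yeast species, derived from the biomass coefficients
of their genome-scale models).  Two analyses are supported:

* **hard constraints** — couple every drain to the distribution,
  ``a_l = p_l * T`` with ``T = sum_m a_m`` a free auxiliary total, and
  maximize growth.  Infeasibility is a legitimate, reportable outcome (a
  sufficiently alien distribution cannot express the required proteome).
* **soft fit** — pin growth at a fraction of a reference optimum and minimize
  the Euclidean distance ``sum_l (a_l - p_l T)^2``, a convex quadratic
  program solved with OSQP over the model's stoichiometric polytope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import osqp
import pandas as pd
import scipy.sparse as sp
from cobra.util.array import create_stoichiometric_matrix

from .amino_acids import AA_CODES, AA_NAMES, RESIDUE_MASSES
from .model_build import AcidFBAModel
from .simulate import (AminoAcidProfile, FluxSolution, maximize_growth,
                       relative_deviation)

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesDistribution",
    "QPFit",
    "load_distribution",
    "constrain_profile",
    "constrained_max_growth",
    "min_euclidean_fit",
    "profile_difference",
    "growth_fraction_scan",
]

NORMALIZATION_TOL = 1e-6


@dataclass(frozen=True)
class SpeciesDistribution:
    """A species label and its normalized 20-vector of mass fractions."""

    species: str
    fractions: np.ndarray

    def __post_init__(self):
        fractions = np.asarray(self.fractions, dtype=float)
        if fractions.shape != (len(AA_CODES),):
            raise ValueError("distribution must be a 20-vector in canonical order")
        if (fractions < 0).any():
            raise ValueError("distribution has negative entries")
        total = fractions.sum()
        if total <= 0:
            raise ValueError("distribution sums to zero")
        if abs(total - 1.0) > NORMALIZATION_TOL:
            logger.warning("distribution %r sums to %.6g; renormalizing",
                           self.species, total)
        object.__setattr__(self, "fractions", fractions / total)

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=list(AA_CODES),
                         name=self.species)


def load_distribution(source, *, species: str | None = None
                      ) -> SpeciesDistribution:
    """Load a 20-row (code, value) TSV as a normalized mass distribution.

    The header of the value column declares the units: a name containing
    ``mmol`` or ``coeff`` marks biomass coefficients (mmol gDW^-1), which are
    converted to mass fractions by residue-mass weighting before
    normalization; anything else is treated as (possibly unnormalized) mass
    fractions.  Every amino acid must be present and non-negative.
    """
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        frame = pd.read_csv(source, sep="\t")
        if species is None:
            species = Path(str(source)).stem
    if frame.shape[1] < 2:
        raise ValueError("expected two columns: amino-acid code and value")
    code_col, value_col = frame.columns[:2]
    frame[code_col] = frame[code_col].astype(str).str.strip().str.upper()
    values = frame.set_index(code_col)[value_col]
    missing = [c for c in AA_CODES if c not in values.index]
    if missing:
        names = ", ".join(AA_NAMES[c] for c in missing)
        raise ValueError(f"amino acid(s) absent from table: {names}")
    vec = values.reindex(list(AA_CODES)).to_numpy(dtype=float)
    if np.isnan(vec).any() or (vec < 0).any():
        raise ValueError("distribution values must be non-negative numbers")
    unit_hint = str(value_col).lower()
    if "mmol" in unit_hint or "coeff" in unit_hint:
        vec = vec * np.array([RESIDUE_MASSES[c] for c in AA_CODES])
    return SpeciesDistribution(species or "species", vec)


def constrain_profile(acid: AcidFBAModel, dist: SpeciesDistribution
                      ) -> AcidFBAModel:
    """Return a copy of ``acid`` whose drains are coupled to ``dist``.

    Adds an auxiliary total variable T >= 0 and, for every amino acid l, the
    proportionality constraint ``a_l - p_l T = 0``.  Growth maximization on
    the result defines the reference state; infeasibility means the model
    cannot express any proteome with that amino-acid distribution.
    """
    acid = acid.copy()
    model = acid.model
    total = model.problem.Variable("aa_profile_total", lb=0.0)
    constraints = []
    for l, code in enumerate(AA_CODES):
        drain = model.reactions.get_by_id(acid.drain_reactions[code])
        expr = drain.flux_expression - float(dist.fractions[l]) * total
        constraints.append(model.problem.Constraint(
            expr, lb=0.0, ub=0.0, name=f"aa_couple_{code}"))
    model.add_cons_vars([total] + constraints)
    return acid


def constrained_max_growth(acid: AcidFBAModel, dist: SpeciesDistribution
                           ) -> FluxSolution:
    """Maximal growth with the drain profile hard-coupled to ``dist``."""
    return maximize_growth(constrain_profile(acid, dist))


@dataclass
class QPFit:
    """Result of a minimal-Euclidean-distance profile fit."""

    profile: AminoAcidProfile
    distance: float            # sqrt of the QP objective, g gDW^-1
    growth: float
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _qp_arrays(acid: AcidFBAModel, fractions: np.ndarray, mu: float):
    """Assemble OSQP matrices for min sum_l (a_l - p_l T)^2 at growth mu.

    Variables are the n reaction fluxes plus T appended last.  Constraints:
    steady state S v = 0, flux bounds, biomass pinned to mu, and
    T - sum_l a_l = 0.
    """
    model = acid.model
    n = len(model.reactions)
    stoich = sp.csc_matrix(create_stoichiometric_matrix(model, "lil"))
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    drain_idx = np.array([rxn_index[acid.drain_reactions[c]] for c in AA_CODES])
    bio_idx = rxn_index[acid.biomass_reaction]

    # selector rows: row l picks a_l - p_l T
    sel = sp.lil_matrix((len(AA_CODES), n + 1))
    for l, j in enumerate(drain_idx):
        sel[l, j] = 1.0
        sel[l, n] = -float(fractions[l])
    sel = sel.tocsc()
    quad = 2.0 * (sel.T @ sel)
    lin = np.zeros(n + 1)

    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    lb[bio_idx] = ub[bio_idx] = mu

    total_row = sp.lil_matrix((1, n + 1))
    for j in drain_idx:
        total_row[0, j] = -1.0
    total_row[0, n] = 1.0

    a_mat = sp.vstack([
        sp.hstack([stoich, sp.csc_matrix((stoich.shape[0], 1))]),
        sp.hstack([sp.identity(n, format="csc"),
                   sp.csc_matrix((n, 1))]),
        total_row.tocsc(),
        sp.csc_matrix(([1.0], ([0], [n])), shape=(1, n + 1)),
    ]).tocsc()
    lower = np.concatenate([np.zeros(stoich.shape[0]), lb, [0.0], [0.0]])
    upper = np.concatenate([np.zeros(stoich.shape[0]), ub, [0.0], [np.inf]])
    return quad.tocsc(), lin, a_mat, lower, upper, drain_idx


def min_euclidean_fit(acid: AcidFBAModel, dist: SpeciesDistribution,
                      growth_fraction: float, reference_growth: float, *,
                      eps: float = 1e-8) -> QPFit:
    """Profile minimally distant from ``dist`` at a pinned growth rate.

    Growth is fixed at ``growth_fraction * reference_growth`` and the convex
    quadratic ``sum_l (a_l - p_l T)^2`` minimized over the flux polytope,
    with the auxiliary total ``T = sum_l a_l`` kept free.  The reported
    distance is the square root of the optimal objective (g gDW^-1); it is
    zero precisely when the hard-coupled model can grow that fast.
    """
    mu = growth_fraction * reference_growth
    quad, lin, a_mat, lower, upper, drain_idx = _qp_arrays(
        acid, dist.fractions, mu)
    solver = osqp.OSQP()
    solver.setup(P=quad, q=lin, A=a_mat, l=lower, u=upper, verbose=False,
                 polish=True, eps_abs=eps, eps_rel=eps, max_iter=400_000)
    result = solver.solve(raise_error=False)
    status = str(result.info.status)
    if "solved" not in status:
        label = "infeasible" if "infeasible" in status else status
        return QPFit(AminoAcidProfile(np.zeros(len(AA_CODES))),
                     float("nan"), mu, label)
    v = np.asarray(result.x)
    mass = np.clip(v[drain_idx], 0.0, None)
    objective = max(float(result.info.obj_val) / 2.0, 0.0)
    return QPFit(AminoAcidProfile(mass), float(np.sqrt(objective)), mu,
                 "optimal")


def profile_difference(profile: AminoAcidProfile | np.ndarray,
                       dist: SpeciesDistribution) -> pd.Series:
    """Per-amino-acid |q_l - p_l| / p_l between a fitted profile and ``dist``.

    NaN marks amino acids the species distribution lacks entirely (p_l = 0
    with q_l > 0); these are excluded from medians.
    """
    q = np.asarray(getattr(profile, "fraction", profile), dtype=float)
    values = relative_deviation(dist.fractions, q)
    return pd.Series(values, index=list(AA_CODES), name="abs_rel_difference")


def growth_fraction_scan(acid: AcidFBAModel, dist: SpeciesDistribution,
                         fractions=None, *,
                         reference_growth: float | None = None,
                         reference_dist: SpeciesDistribution | None = None,
                         step: float = 0.05) -> pd.DataFrame:
    """Minimal-distance fits over a grid of relative growth rates.

    The reference growth defaults to the hard-constrained optimum under
    ``reference_dist`` (or ``dist`` itself) — the reference optimal growth
    state.  The default grid runs from 0.1 in ``step`` increments up to the
    ratio of the unconstrained optimum to the reference growth.  Returns a
    long-format table (growth_fraction, amino_acid, fitted fraction,
    abs_rel_difference, distance, feasible).
    """
    if reference_growth is None:
        ref = constrained_max_growth(acid, reference_dist or dist)
        if not ref.ok or not np.isfinite(ref.objective) or ref.objective <= 0:
            raise RuntimeError(
                "reference distribution infeasible; supply reference_growth")
        reference_growth = ref.objective
    if fractions is None:
        upper = maximize_growth(acid).objective / reference_growth
        fractions = np.arange(0.1, upper + step / 2, step)
    fractions = np.asarray(list(fractions), dtype=float)
    if (np.diff(fractions) <= 0).any():
        raise ValueError("growth fractions must be strictly increasing")
    records = []
    for frac in fractions:
        fit = min_euclidean_fit(acid, dist, float(frac), reference_growth)
        if not fit.ok:
            records.append({"growth_fraction": frac, "amino_acid": None,
                            "fraction": np.nan, "abs_rel_difference": np.nan,
                            "distance": np.nan, "feasible": False})
            continue
        diffs = profile_difference(fit.profile, dist)
        for code in AA_CODES:
            records.append({"growth_fraction": frac, "amino_acid": code,
                            "fraction": fit.profile.as_series(fractions=True)[code],
                            "abs_rel_difference": diffs[code],
                            "distance": fit.distance, "feasible": True})
    frame = pd.DataFrame.from_records(records)
    frame.attrs["reference_growth"] = reference_growth
    frame.attrs["species"] = dist.species
    return frame
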