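"""Growth optimization, amino-acid profiles, drain FVA and chemostat sweeps.

All routines operate on an :class:`~acidfba.model_build.AcidFBAModel` (or, for
plain growth maximization, an :class:`~acidfba.model_build.EcModel`) and leave
the model unchanged by using cobra's context manager.  Flux-sum minimization
follows the parsimonious-FBA idea: with growth pinned, minimize the sum of
absolute fluxes (reversible reactions split into forward/reverse variables),
which selects a unique, enzymatically efficient flux state from the optimal
face.  By default the sum runs over *all* reactions, including enzyme and
drain pseudo-fluxes; ``include_pseudo=False`` restricts it to the metabolic
reactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from optlang.symbolics import Zero

from .amino_acids import AA_CODES
from .model_build import AcidFBAModel, EcModel, mass_closure_gap

logger = logging.getLogger(__name__)

__all__ = [
    "FluxSolution",
    "AminoAcidProfile",
    "ChemostatCurve",
    "Condition",
    "maximize_growth",
    "aa_profile_at_optimum",
    "min_pool_at_growth",
    "drain_fva",
    "chemostat_sweep",
    "compare_modes",
    "relative_deviation",
]

#: Relative tolerance used when pinning the biomass flux at (a fraction of)
#: its optimum, and when re-fixing a minimized pool flux for tie-breaking.
FIX_RTOL = 1e-9

#: Pool slack (g gDW^-1) below which the pool constraint counts as binding.
BINDING_TOL = 1e-8


@dataclass
class FluxSolution:
    """Objective value, full flux vector and solver status of one solve."""

    objective: float
    fluxes: pd.Series
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class AminoAcidProfile:
    """Amino-acid drain mass fluxes (g gDW^-1) in canonical order."""

    mass: np.ndarray

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (len(AA_CODES),):
            raise ValueError("profile must be a 20-vector in canonical order")

    @property
    def total(self) -> float:
        return float(self.mass.sum())

    @property
    def fraction(self) -> np.ndarray:
        """Normalized mass distribution (sums to 1 when total mass > 0)."""
        total = self.total
        if total <= 0:
            return np.zeros_like(self.mass)
        return self.mass / total

    def as_series(self, *, fractions: bool = False) -> pd.Series:
        values = self.fraction if fractions else self.mass
        return pd.Series(values, index=list(AA_CODES),
                         name="fraction" if fractions else "mass")

    @classmethod
    def from_fluxes(cls, acid: AcidFBAModel, fluxes: Mapping[str, float]
                    ) -> "AminoAcidProfile":
        return cls(np.array([float(fluxes[acid.drain_reactions[c]])
                             for c in AA_CODES]))


@dataclass
class Condition:
    """A growth condition: bound overrides, blocked reactions, optional pins.

    ``bounds`` maps reaction id -> (lower, upper); ``None`` keeps the existing
    bound.  ``blocked`` closes reactions entirely.  ``growth_rate`` pins the
    biomass flux (used for e.g. a respiratory reference state) and
    ``pool_bound`` overrides the protein-pool budget (g gDW^-1).
    """

    name: str = ""
    bounds: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    blocked: list[str] = field(default_factory=list)
    growth_rate: float | None = None
    pool_bound: float | None = None

    def apply(self, acid: AcidFBAModel | EcModel) -> None:
        """Apply in place; call inside ``with acid.model:`` to make it revert."""
        model = acid.model
        for rxn_id, (lb, ub) in self.bounds.items():
            rxn = model.reactions.get_by_id(rxn_id)
            if lb is not None:
                rxn.lower_bound = lb
            if ub is not None:
                rxn.upper_bound = ub
        for rxn_id in self.blocked:
            rxn = model.reactions.get_by_id(rxn_id)
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        if self.pool_bound is not None:
            model.reactions.get_by_id(acid.pool_reaction).upper_bound = \
                self.pool_bound

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Condition":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        bounds = {rxn: (pair[0], pair[1])
                  for rxn, pair in (raw.get("bounds") or {}).items()}
        return cls(name=raw.get("name", Path(path).stem), bounds=bounds,
                   blocked=list(raw.get("blocked") or []),
                   growth_rate=raw.get("growth_rate"),
                   pool_bound=raw.get("pool_bound"))


def _solution(model) -> FluxSolution:
    sol = model.optimize()
    if sol.status != "optimal":
        return FluxSolution(float("nan"), pd.Series(dtype=float), sol.status)
    return FluxSolution(float(sol.objective_value), sol.fluxes, sol.status)


def _biomass(acid) -> str:
    if acid.biomass_reaction is None:
        raise ValueError("model has no designated biomass reaction")
    return acid.biomass_reaction


def _fix_flux(model, rxn_id: str, value: float) -> None:
    rxn = model.reactions.get_by_id(rxn_id)
    slack = FIX_RTOL * max(1.0, abs(value))
    rxn.lower_bound = value - slack
    rxn.upper_bound = value + slack


def _minimize_flux_sum(model, reactions: Iterable | None = None) -> None:
    """Set the objective to minimize sum of |v| over ``reactions`` (default all)."""
    rxns = list(reactions) if reactions is not None else list(model.reactions)
    model.objective = model.problem.Objective(Zero, direction="min", sloppy=True)
    coeffs = {}
    for rxn in rxns:
        coeffs[rxn.forward_variable] = 1.0
        coeffs[rxn.reverse_variable] = 1.0
    model.objective.set_linear_coefficients(coeffs)


def maximize_growth(acid: AcidFBAModel | EcModel) -> FluxSolution:
    """Maximal biomass flux under the protein-pool (and bound) constraints.

    Infeasibility is reported through the status flag, not raised.
    """
    biomass = _biomass(acid)
    model = acid.model
    with model:
        model.objective = biomass
        model.objective_direction = "max"
        sol = _solution(model)
    if not sol.ok:
        logger.warning("growth maximization ended with status %r", sol.status)
    return sol


def aa_profile_at_optimum(acid: AcidFBAModel, opt_fraction: float = 1.0, *,
                          include_pseudo: bool = True,
                          condition: Condition | None = None
                          ) -> tuple[FluxSolution, AminoAcidProfile]:
    """Amino-acid profile of the flux-parsimonious state at near-optimal growth.

    Pins the biomass flux at ``opt_fraction`` times its maximum (equality
    within :data:`FIX_RTOL`), minimizes the total flux sum, and reads the
    profile off the 20 drains.
    """
    biomass = _biomass(acid)
    model = acid.model
    with model:
        if condition is not None:
            condition.apply(acid)
        model.objective = biomass
        model.objective_direction = "max"
        opt = _solution(model)
        if not opt.ok:
            return opt, AminoAcidProfile(np.zeros(len(AA_CODES)))
        _fix_flux(model, biomass, opt_fraction * opt.objective)
        reactions = None
        if not include_pseudo:
            pseudo = set(acid.source_reactions.values()) | \
                set(acid.drain_reactions.values()) | {acid.pool_reaction}
            reactions = [r for r in model.reactions if r.id not in pseudo]
        _minimize_flux_sum(model, reactions)
        sol = _solution(model)
    if not sol.ok:
        binding = f"biomass fixed at {opt_fraction:g} x {opt.objective:.6g}"
        logger.warning("flux minimization infeasible (%s)", binding)
        return sol, AminoAcidProfile(np.zeros(len(AA_CODES)))
    sol.objective = float(sol.fluxes[biomass])
    _check_closure(acid, sol)
    return sol, AminoAcidProfile.from_fluxes(acid, sol.fluxes)


def min_pool_at_growth(acid: AcidFBAModel, mu: float, *,
                       tie_break: bool = True,
                       condition: Condition | None = None) -> FluxSolution:
    """Minimal protein-pool flux sustaining growth rate ``mu``.

    The biomass flux is pinned at ``mu`` and the pool exchange flux is
    minimized; with ``tie_break`` (default) the pool flux is then re-fixed at
    its minimum and the total flux sum minimized, selecting a unique
    amino-acid distribution among alternate minimal-pool optima.  A ``mu``
    above the attainable maximum yields an infeasible status.
    """
    biomass = _biomass(acid)
    model = acid.model
    with model:
        if condition is not None:
            condition.apply(acid)
        bio_rxn = model.reactions.get_by_id(biomass)
        bio_rxn.lower_bound = bio_rxn.upper_bound = mu  # exact pin
        pool_rxn = model.reactions.get_by_id(acid.pool_reaction)
        model.objective = model.problem.Objective(pool_rxn.flux_expression,
                                                  direction="min")
        sol = _solution(model)
        if sol.ok and tie_break:
            # cap the pool at its exact minimum (no upward slack: a band would
            # let the flux-sum step trade pool between routes)
            pool_min = float(sol.fluxes[acid.pool_reaction])
            pool_rxn.upper_bound = pool_min
            _minimize_flux_sum(model)
            refined = _solution(model)
            if refined.ok:
                refined.objective = pool_min
                sol = refined
    if sol.ok:
        _check_closure(acid, sol)
    return sol


def drain_fva(acid: AcidFBAModel, opt_fraction: float = 0.99, *,
              equality: bool = False,
              condition: Condition | None = None) -> pd.DataFrame:
    """Flux variability of the 20 amino-acid drains at near-optimal growth.

    With growth constrained to at least ``opt_fraction`` times its maximum
    (``equality=True`` pins it instead), each drain flux is minimized and
    maximized.  Returns a DataFrame indexed by one-letter code with columns
    ``minimum``, ``maximum``, ``midpoint`` and ``rel_variability`` — the flux
    range normalized by its midpoint ``(max + min)/2``.  A drain whose
    midpoint is 0 (amino acid absent from every enzyme) gets NaN as an
    undefined-variability sentinel.
    """
    biomass = _biomass(acid)
    model = acid.model
    records = []
    with model:
        if condition is not None:
            condition.apply(acid)
        model.objective = biomass
        model.objective_direction = "max"
        opt = _solution(model)
        if not opt.ok:
            raise RuntimeError(f"growth maximization failed: {opt.status}")
        target = opt_fraction * opt.objective
        bio_rxn = model.reactions.get_by_id(biomass)
        if equality:
            _fix_flux(model, biomass, target)
        else:
            bio_rxn.lower_bound = target
        for code in AA_CODES:
            rxn = model.reactions.get_by_id(acid.drain_reactions[code])
            bounds = {}
            for direction in ("min", "max"):
                model.objective = model.problem.Objective(
                    rxn.flux_expression, direction=direction)
                sol = model.optimize()
                if sol.status != "optimal":
                    raise RuntimeError(
                        f"FVA {direction} failed for {rxn.id}: {sol.status}")
                bounds[direction] = float(sol.objective_value)
            lo, hi = bounds["min"], bounds["max"]
            lo = max(lo, 0.0)  # drains are irreversible; clip solver noise
            mid = 0.5 * (lo + hi)
            rel = (hi - lo) / mid if mid > 0 else float("nan")
            records.append((code, lo, hi, mid, rel))
    frame = pd.DataFrame(records, columns=["amino_acid", "minimum", "maximum",
                                           "midpoint", "rel_variability"])
    return frame.set_index("amino_acid")


@dataclass
class ChemostatCurve:
    """Result of a growth-rate sweep at condition-dependent protein budgets."""

    mu: np.ndarray
    p_total: np.ndarray
    pool_bound: np.ndarray
    pool_use: np.ndarray
    profiles: pd.DataFrame  # rows: feasible mu values; columns: AA codes (mass)
    feasible: np.ndarray
    critical_mu: float | None

    @property
    def fractions(self) -> pd.DataFrame:
        totals = self.profiles.sum(axis=1)
        return self.profiles.div(totals.where(totals > 0), axis=0)


def as_ptotal_function(table_or_callable) -> Callable[[float], float]:
    """Accept a callable, a 2-column array/TSV path, and return p_total(mu).

    Tables are interpolated monotone piecewise-linearly and clamped at the
    edges.
    """
    if callable(table_or_callable):
        return table_or_callable
    if isinstance(table_or_callable, (str, Path)):
        frame = pd.read_csv(table_or_callable, sep="\t")
        data = frame.iloc[:, :2].to_numpy(dtype=float)
    else:
        data = np.asarray(table_or_callable, dtype=float)
    data = data[np.argsort(data[:, 0])]
    return lambda mu: float(np.interp(mu, data[:, 0], data[:, 1]))


def chemostat_sweep(acid: AcidFBAModel, mu_grid: Sequence[float],
                    ptotal_of_mu, *, sigma: float = 1.0, f: float = 1.0,
                    condition: Condition | None = None) -> ChemostatCurve:
    """Simulate chemostat growth over ``mu_grid``.

    At each growth rate the pool bound is set to ``sigma * f *
    ptotal_of_mu(mu)``, the condition constraints are applied, and the pool
    flux is minimized at pinned growth.  Infeasible grid points are flagged
    and skipped.  The critical rate is the first mu at which the pool
    constraint binds (slack <= :data:`BINDING_TOL` g gDW^-1).
    """
    mu_grid = np.asarray(list(mu_grid), dtype=float)
    if mu_grid.size == 0 or (np.diff(mu_grid) <= 0).any():
        raise ValueError("mu_grid must be non-empty and strictly increasing")
    ptotal = as_ptotal_function(ptotal_of_mu)
    p_totals, bounds_, pool_use = [], [], []
    feasible = np.zeros(mu_grid.size, dtype=bool)
    rows = {}
    critical = None
    for i, mu in enumerate(mu_grid):
        p_total = float(ptotal(mu))
        if not 0 < p_total <= 1:
            raise ValueError(f"p_total({mu:g}) = {p_total:g} outside (0, 1]")
        bound = sigma * f * p_total
        p_totals.append(p_total)
        bounds_.append(bound)
        cond = Condition(bounds=dict(condition.bounds) if condition else {},
                         blocked=list(condition.blocked) if condition else [],
                         pool_bound=bound)
        sol = min_pool_at_growth(acid, float(mu), condition=cond)
        if not sol.ok:
            logger.warning("chemostat point mu=%.4g infeasible (%s); skipped",
                           mu, sol.status)
            pool_use.append(float("nan"))
            continue
        feasible[i] = True
        pool_use.append(sol.objective)
        rows[float(mu)] = AminoAcidProfile.from_fluxes(acid, sol.fluxes).mass
        if critical is None and bound - sol.objective <= BINDING_TOL:
            critical = float(mu)
    profiles = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(AA_CODES))
    profiles.index.name = "mu"
    return ChemostatCurve(mu=mu_grid, p_total=np.array(p_totals),
                          pool_bound=np.array(bounds_),
                          pool_use=np.array(pool_use),
                          profiles=profiles, feasible=feasible,
                          critical_mu=critical)


def relative_deviation(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """|other - reference| / reference with NaN where the reference is 0."""
    reference = np.asarray(reference, dtype=float)
    other = np.asarray(other, dtype=float)
    out = np.full_like(reference, np.nan)
    np.divide(np.abs(other - reference), reference, out=out,
              where=reference > 0)
    out[(reference == 0) & (other == 0)] = 0.0
    return out


def compare_modes(acid: AcidFBAModel, setup_a: Condition, setup_b: Condition,
                  *, opt_fraction: float = 1.0) -> pd.DataFrame:
    """Per-amino-acid deviation between the profiles of two growth modes.

    Each setup is simulated like batch growth — growth maximized under its
    constraints, then the flux sum minimized — unless it pins a growth rate
    (e.g. a respiratory state at 0.2 h^-1), in which case the pool flux is
    minimized at that rate.  Returns a DataFrame with the two fraction
    profiles and ``deviation = |p_a - p_b| / p_b`` (NaN sentinel where
    ``p_b`` is 0 and excluded from medians; ``frame["deviation"].median()``
    skips NaN).
    """
    profiles = {}
    for label, setup in (("a", setup_a), ("b", setup_b)):
        if setup.growth_rate is not None:
            sol = min_pool_at_growth(acid, setup.growth_rate, condition=setup)
            if not sol.ok:
                raise RuntimeError(
                    f"setup {setup.name or label!r} infeasible: {sol.status}")
            profiles[label] = AminoAcidProfile.from_fluxes(acid, sol.fluxes)
        else:
            sol, profile = aa_profile_at_optimum(acid, opt_fraction,
                                                 condition=setup)
            if not sol.ok:
                raise RuntimeError(
                    f"setup {setup.name or label!r} infeasible: {sol.status}")
            profiles[label] = profile
    p_a, p_b = profiles["a"].fraction, profiles["b"].fraction
    deviation = relative_deviation(p_b, p_a)
    n_undefined = int(np.isnan(deviation).sum())
    if n_undefined:
        logger.info("%d amino acid(s) have zero reference fraction; reported "
                    "as NaN and excluded from medians", n_undefined)
    return pd.DataFrame({"fraction_a": p_a, "fraction_b": p_b,
                         "deviation": deviation}, index=list(AA_CODES))


def _check_closure(acid, sol: FluxSolution, tol: float = 1e-9) -> None:
    if not isinstance(acid, AcidFBAModel) or not acid.drain_reactions:
        return
    gap = mass_closure_gap(acid, sol.fluxes)
    if gap > tol:
        logger.warning("amino-acid mass closure gap %.3g g gDW^-1 exceeds %g",
                       gap, tol)
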