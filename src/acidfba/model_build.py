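"""Read GECKO-style enzyme-constrained models and rebuild them as acidFBA models.

A GECKO model supplies each enzyme pseudo-metabolite ``E_k`` through a draw
reaction ``MW_k/1000 E_pool -> E_k`` and caps the pool exchange flux (g gDW^-1)
at the available metabolic enzyme mass (sigma * f * P_total).  The acidFBA
rebuild routes the same mass through 20 amino-acid pseudo-metabolites instead:

* 20 irreversible drain reactions ``E_pool -> A_l`` (1:1 mass stoichiometry,
  flux in g gDW^-1), and
* for every enzyme a rewritten source reaction
  ``sum_l xi_kl A_l -> E_k`` (flux in mmol gDW^-1),

where ``xi`` is the composition matrix of :mod:`acidfba.amino_acids`.  Because
each row of ``xi`` sums to MW_k/1000, the per-enzyme pool cost is unchanged
and the rebuilt model has exactly the parent's optimal growth; what changes is
that every amino acid now carries its own mass balance
``sum_k xi_kl e_k = a_l``, so amino-acid usage becomes a first-class variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from cobra import Metabolite, Model, Reaction
from cobra.io import read_sbml_model, write_sbml_model

from .amino_acids import AA_CODES, AA_NAMES, CompositionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeckoConventions",
    "PoolConfig",
    "EcModel",
    "AcidFBAModel",
    "ModelStructureError",
    "classify_ec_model",
    "read_ec_model",
    "build_acidfba",
    "make_uniform_variant",
    "write_model",
    "read_acidfba_model",
    "mass_closure_gap",
]


class ModelStructureError(ValueError):
    """The SBML file does not follow the expected GECKO/acidFBA structure."""


@dataclass(frozen=True)
class GeckoConventions:
    """Identifier conventions used to classify a GECKO-style model.

    Defaults match the GECKO toolbox: enzyme pseudo-metabolites ``prot_<id>``,
    draw reactions ``draw_prot_<id>``, pool metabolite ``prot_pool`` and pool
    exchange ``prot_pool_exchange``.  The acidFBA identifiers are new species
    ``aa_<code>`` and drains ``draw_aa_<code>`` (bit-stable across runs).
    """

    enzyme_prefix: str = "prot_"
    draw_prefix: str = "draw_prot_"
    pool_metabolite: str = "prot_pool"
    pool_reaction: str = "prot_pool_exchange"
    aa_prefix: str = "aa_"
    aa_drain_prefix: str = "draw_aa_"

    def protein_id(self, enzyme_metabolite_id: str) -> str:
        return enzyme_metabolite_id[len(self.enzyme_prefix):]


@dataclass(frozen=True)
class PoolConfig:
    """Protein-pool budget: bound = sigma * f * p_total unless overridden.

    sigma is the average in-vivo enzyme saturation, f the mass fraction of the
    proteome covered by the model, p_total the total cellular protein fraction
    (g gDW^-1; 0.5 for exponentially growing yeast).  ``pool_bound`` overrides
    the product with an explicit bound in g gDW^-1.
    """

    sigma: float = 1.0
    f: float = 1.0
    p_total: float = 0.5
    pool_bound: float | None = None

    def __post_init__(self):
        for name in ("sigma", "f", "p_total"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.pool_bound is not None and self.pool_bound < 0:
            raise ValueError("explicit pool bound must be non-negative")

    @property
    def effective_bound(self) -> float:
        if self.pool_bound is not None:
            return self.pool_bound
        return self.sigma * self.f * self.p_total


@dataclass
class EcModel:
    """A classified GECKO-style enzyme-constrained model.

    ``draw_reactions`` maps protein id -> draw reaction id; ``kcats`` maps
    (reaction id, protein id) -> turnover number (h^-1).
    """

    model: Model
    conventions: GeckoConventions
    pool_metabolite: str
    pool_reaction: str
    enzyme_metabolites: dict[str, str]
    draw_reactions: dict[str, str]
    kcats: dict[tuple[str, str], float]
    biomass_reaction: str | None = None

    @property
    def n_enzymes(self) -> int:
        return len(self.enzyme_metabolites)

    @property
    def pool_bound(self) -> float:
        return self.model.reactions.get_by_id(self.pool_reaction).upper_bound

    def set_pool_bound(self, bound: float) -> None:
        self.model.reactions.get_by_id(self.pool_reaction).upper_bound = bound

    def draw_mw(self, protein_id: str) -> float:
        """Molecular weight (g mol^-1) implied by the draw-reaction coefficient."""
        rxn = self.model.reactions.get_by_id(self.draw_reactions[protein_id])
        pool = self.model.metabolites.get_by_id(self.pool_metabolite)
        return -rxn.metabolites[pool] * 1000.0

    def copy(self) -> "EcModel":
        return replace(self, model=self.model.copy(),
                       enzyme_metabolites=dict(self.enzyme_metabolites),
                       draw_reactions=dict(self.draw_reactions),
                       kcats=dict(self.kcats))


@dataclass
class AcidFBAModel:
    """An acidFBA model: EcModel structure plus amino-acid drains and a xi."""

    model: Model
    conventions: GeckoConventions
    pool_metabolite: str
    pool_reaction: str
    enzyme_metabolites: dict[str, str]
    source_reactions: dict[str, str]
    drain_reactions: dict[str, str] = field(default_factory=dict)
    xi: CompositionMatrix | None = None
    biomass_reaction: str | None = None

    @property
    def n_enzymes(self) -> int:
        return len(self.enzyme_metabolites)

    @property
    def pool_bound(self) -> float:
        return self.model.reactions.get_by_id(self.pool_reaction).upper_bound

    def set_pool_bound(self, bound: float) -> None:
        self.model.reactions.get_by_id(self.pool_reaction).upper_bound = bound

    def drain_ids(self) -> list[str]:
        """Drain reaction ids in canonical amino-acid order."""
        return [self.drain_reactions[code] for code in AA_CODES]

    def copy(self) -> "AcidFBAModel":
        return replace(self, model=self.model.copy(),
                       enzyme_metabolites=dict(self.enzyme_metabolites),
                       source_reactions=dict(self.source_reactions),
                       drain_reactions=dict(self.drain_reactions))


def _find_pool(model: Model, conv: GeckoConventions):
    if conv.pool_metabolite in model.metabolites:
        pool_met = model.metabolites.get_by_id(conv.pool_metabolite)
    else:
        raise ModelStructureError(
            f"no protein pool metabolite {conv.pool_metabolite!r} in model")
    if conv.pool_reaction in model.reactions:
        pool_rxn = model.reactions.get_by_id(conv.pool_reaction)
    else:
        candidates = [r for r in pool_met.reactions
                      if set(r.metabolites) == {pool_met}
                      and r.metabolites[pool_met] > 0]
        if len(candidates) != 1:
            raise ModelStructureError("no protein pool exchange reaction found")
        pool_rxn = candidates[0]
    return pool_met, pool_rxn


def classify_ec_model(model: Model, *, conventions: GeckoConventions | None = None,
                      biomass_reaction: str | None = None) -> EcModel:
    """Classify pool, enzyme draw reactions and kcat coefficients of a model."""
    conv = conventions or GeckoConventions()
    pool_met, pool_rxn = _find_pool(model, conv)

    enzyme_mets: dict[str, str] = {}
    draws: dict[str, str] = {}
    kcats: dict[tuple[str, str], float] = {}
    for met in model.metabolites:
        if not met.id.startswith(conv.enzyme_prefix) or met.id == pool_met.id:
            continue
        protein_id = conv.protein_id(met.id)
        enzyme_mets[protein_id] = met.id
        producers = [r for r in met.reactions
                     if r.metabolites[met] > 0
                     and set(r.metabolites) == {pool_met, met}]
        if len(producers) != 1:
            raise ModelStructureError(
                f"enzyme metabolite {met.id!r} lacks a unique draw reaction "
                f"from the pool (found {len(producers)})")
        draws[protein_id] = producers[0].id
        for rxn in met.reactions:
            coeff = rxn.metabolites[met]
            if rxn.id == producers[0].id or coeff >= 0:
                continue
            kcats[(rxn.id, protein_id)] = -1.0 / coeff
    if biomass_reaction is None:
        objective_rxns = [r.id for r in model.reactions if r.objective_coefficient]
        biomass_reaction = objective_rxns[0] if objective_rxns else None
    logger.info("classified ecGEM: %d enzymes, %d kcat coefficients, pool %r",
                len(enzyme_mets), len(kcats), pool_rxn.id)
    return EcModel(model=model, conventions=conv, pool_metabolite=pool_met.id,
                   pool_reaction=pool_rxn.id, enzyme_metabolites=enzyme_mets,
                   draw_reactions=draws, kcats=kcats,
                   biomass_reaction=biomass_reaction)


def read_ec_model(path: str | Path, *, conventions: GeckoConventions | None = None,
                  biomass_reaction: str | None = None) -> EcModel:
    """Read an SBML L3 enzyme-constrained model and classify its structure."""
    model = read_sbml_model(str(path))
    model.solver = "glpk"
    return classify_ec_model(model, conventions=conventions,
                             biomass_reaction=biomass_reaction)


def build_acidfba(ec: EcModel, xi: CompositionMatrix,
                  cfg: PoolConfig | None = None, *,
                  missing_policy: str = "strict",
                  copy_numbers: dict[str, float] | None = None,
                  mw_warn_tol: float = 0.005) -> AcidFBAModel:
    """Rebuild ``ec`` with amino-acid drains and xi-mediated enzyme sources.

    Every draw reaction ``MW_k/1000 E_pool -> E_k`` is replaced (same reaction
    id) by ``sum_l xi_kl A_l -> E_k``, and 20 irreversible drains
    ``E_pool -> A_l`` are inserted.  If the draw coefficient's MW disagrees
    with the xi row sum by more than ``mw_warn_tol`` (relative), xi wins and a
    warning is logged — xi is what keeps the amino-acid mass balances
    internally consistent.

    ``missing_policy='strict'`` errors on enzymes absent from xi;
    ``'mean'`` assigns them the mean relative composition of the present
    proteins scaled to the draw reaction's MW (logged).  ``copy_numbers``
    optionally multiplies rows by per-protein subunit copy number (default 1).

    The parent pool bound is preserved verbatim unless ``cfg`` is given.
    """
    if missing_policy not in ("strict", "mean"):
        raise ValueError(f"unknown missing-sequence policy {missing_policy!r}")
    ec = ec.copy()
    model = ec.model
    pool_met = model.metabolites.get_by_id(ec.pool_metabolite)
    conv = ec.conventions

    xi_index = {pid: k for k, pid in enumerate(xi.protein_ids)}
    missing = sorted(set(ec.enzyme_metabolites) - set(xi_index))
    rows: dict[str, np.ndarray] = {}
    if missing and missing_policy == "strict":
        raise ModelStructureError(
            f"no composition row for enzyme(s): {', '.join(missing)}")
    for pid in ec.enzyme_metabolites:
        if pid in xi_index:
            rows[pid] = xi.values[xi_index[pid]].copy()
    if missing:
        present = np.array([rows[p] for p in rows])
        if present.size == 0:
            raise ModelStructureError(
                "cannot impute compositions: xi has no usable rows")
        mean_fraction = present.sum(axis=0) / present.sum()
        for pid in missing:
            rows[pid] = mean_fraction * ec.draw_mw(pid) / 1000.0
        logger.warning("assigned mean composition to %d enzyme(s) without "
                       "sequences: %s", len(missing), ", ".join(missing))
    if copy_numbers:
        for pid, n_copies in copy_numbers.items():
            if pid in rows:
                rows[pid] = rows[pid] * n_copies

    deviating = []
    for pid in rows:
        mw_draw = ec.draw_mw(pid)
        mw_xi = 1000.0 * rows[pid].sum()
        if mw_draw > 0 and abs(mw_xi - mw_draw) / mw_draw > mw_warn_tol:
            deviating.append((pid, mw_draw, mw_xi))
    if deviating:
        logger.warning(
            "draw-reaction MW disagrees with xi row sum for %d protein(s) "
            "(>%.1f%%); using xi: %s", len(deviating), 100 * mw_warn_tol,
            ", ".join(f"{p} ({a:.1f} vs {b:.1f})" for p, a, b in deviating[:5]))

    # amino-acid species and drains
    compartment = pool_met.compartment
    aa_mets: dict[str, Metabolite] = {}
    new_reactions: list[Reaction] = []
    drain_ids: dict[str, str] = {}
    for code in AA_CODES:
        met_id = f"{conv.aa_prefix}{code}"
        drain_id = f"{conv.aa_drain_prefix}{code}"
        if met_id in model.metabolites or drain_id in model.reactions:
            raise ModelStructureError(
                f"identifier collision: {met_id!r}/{drain_id!r} already in model")
        met = Metabolite(met_id, name=f"protein-bound {AA_NAMES[code]}",
                         compartment=compartment)
        drain = Reaction(drain_id, name=f"{AA_NAMES[code]} drain",
                         lower_bound=0.0, upper_bound=1.0e6)
        drain.add_metabolites({pool_met: -1.0, met: 1.0})
        aa_mets[code] = met
        new_reactions.append(drain)
        drain_ids[code] = drain_id

    # rewire draw reactions into amino-acid-mediated sources (same ids)
    source_ids: dict[str, str] = {}
    for pid, draw_id in ec.draw_reactions.items():
        old = model.reactions.get_by_id(draw_id)
        enzyme_met = model.metabolites.get_by_id(ec.enzyme_metabolites[pid])
        model.remove_reactions([old])
        source = Reaction(draw_id, name=f"{pid} synthesis from amino acids",
                          lower_bound=0.0, upper_bound=1.0e6)
        stoich = {enzyme_met: 1.0}
        for l, code in enumerate(AA_CODES):
            if rows[pid][l] > 0:
                stoich[aa_mets[code]] = -float(rows[pid][l])
        source.add_metabolites(stoich)
        new_reactions.append(source)
        source_ids[pid] = draw_id
    model.add_reactions(new_reactions)

    if cfg is not None:
        model.reactions.get_by_id(ec.pool_reaction).upper_bound = cfg.effective_bound

    order = sorted(rows)
    stacked = (np.array([rows[p] for p in order]) if order
               else np.zeros((0, len(AA_CODES))))
    full_xi = CompositionMatrix(stacked, tuple(order))
    return AcidFBAModel(model=model, conventions=conv,
                        pool_metabolite=ec.pool_metabolite,
                        pool_reaction=ec.pool_reaction,
                        enzyme_metabolites=dict(ec.enzyme_metabolites),
                        source_reactions=source_ids, drain_reactions=drain_ids,
                        xi=full_xi, biomass_reaction=ec.biomass_reaction)


def make_uniform_variant(acid: AcidFBAModel, profile) -> AcidFBAModel:
    """Rebuild ``acid`` with every protein sharing one amino-acid distribution.

    ``profile`` is a 20-vector of relative mass fractions (canonical order,
    summing to 1 within 1e-6) or an object with a ``fraction`` attribute.
    Each xi row becomes ``MW_k/1000 * profile``, so the total mass cost of
    every enzyme — and hence the optimal growth — is unchanged; only the
    distribution of that mass over the 20 drains is homogenized.
    """
    fractions = np.asarray(getattr(profile, "fraction", profile), dtype=float)
    if fractions.shape != (len(AA_CODES),):
        raise ValueError("profile must be a 20-vector in canonical order")
    if (fractions < 0).any() or abs(fractions.sum() - 1.0) > 1e-6:
        raise ValueError(
            f"profile must be normalized (sum={fractions.sum():.6g})")
    acid = acid.copy()
    model = acid.model
    new_rows = []
    for pid in acid.xi.protein_ids:
        mw = acid.xi.mw(pid)
        new_rows.append(mw / 1000.0 * fractions)
    new_xi = CompositionMatrix(np.array(new_rows), acid.xi.protein_ids)
    for pid, rxn_id in acid.source_reactions.items():
        rxn = model.reactions.get_by_id(rxn_id)
        enzyme_met = model.metabolites.get_by_id(acid.enzyme_metabolites[pid])
        row = new_xi.row(pid)
        stoich = {enzyme_met: 1.0}
        for l, code in enumerate(AA_CODES):
            if row[l] > 0:
                met = model.metabolites.get_by_id(
                    f"{acid.conventions.aa_prefix}{code}")
                stoich[met] = -float(row[l])
        rxn.subtract_metabolites(rxn.metabolites)
        rxn.add_metabolites(stoich)
    acid.xi = new_xi
    return acid


def write_model(acid: AcidFBAModel | EcModel, path: str | Path) -> None:
    """Write the model to SBML L3 with the documented identifier scheme."""
    write_sbml_model(acid.model, str(path))


def read_acidfba_model(path: str | Path, *,
                       conventions: GeckoConventions | None = None,
                       biomass_reaction: str | None = None) -> AcidFBAModel:
    """Read back an acidFBA SBML file, reclassifying drains, sources and xi."""
    conv = conventions or GeckoConventions()
    model = read_sbml_model(str(path))
    model.solver = "glpk"
    pool_met, pool_rxn = _find_pool(model, conv)

    drain_ids: dict[str, str] = {}
    for code in AA_CODES:
        drain_id = f"{conv.aa_drain_prefix}{code}"
        if drain_id not in model.reactions:
            raise ModelStructureError(f"missing amino-acid drain {drain_id!r}")
        drain_ids[code] = drain_id

    enzyme_mets: dict[str, str] = {}
    source_ids: dict[str, str] = {}
    rows: dict[str, np.ndarray] = {}
    aa_met_ids = {f"{conv.aa_prefix}{code}": l for l, code in enumerate(AA_CODES)}
    for met in model.metabolites:
        if (not met.id.startswith(conv.enzyme_prefix)
                or met.id == pool_met.id):
            continue
        pid = conv.protein_id(met.id)
        enzyme_mets[pid] = met.id
        producers = [r for r in met.reactions
                     if r.metabolites[met] > 0
                     and all(m.id in aa_met_ids or m is met
                             for m in r.metabolites)]
        if len(producers) != 1:
            raise ModelStructureError(
                f"enzyme metabolite {met.id!r} lacks a unique amino-acid source")
        source_ids[pid] = producers[0].id
        row = np.zeros(len(AA_CODES))
        for m, coeff in producers[0].metabolites.items():
            if m.id in aa_met_ids:
                row[aa_met_ids[m.id]] = -coeff
        rows[pid] = row

    order = sorted(rows)
    xi = CompositionMatrix(np.array([rows[p] for p in order]) if order
                           else np.zeros((0, len(AA_CODES))), tuple(order))
    if biomass_reaction is None:
        objective_rxns = [r.id for r in model.reactions if r.objective_coefficient]
        biomass_reaction = objective_rxns[0] if objective_rxns else None
    return AcidFBAModel(model=model, conventions=conv,
                        pool_metabolite=pool_met.id, pool_reaction=pool_rxn.id,
                        enzyme_metabolites=enzyme_mets,
                        source_reactions=source_ids,
                        drain_reactions=drain_ids, xi=xi,
                        biomass_reaction=biomass_reaction)


def mass_closure_gap(acid: AcidFBAModel, fluxes) -> float:
    """|sum of drain fluxes - pool exchange flux| for a solution (g gDW^-1).

    Summing the 20 amino-acid mass balances collapses them onto the pool
    balance, so this gap is zero in every feasible solution up to solver
    round-off.
    """
    drain_sum = float(sum(fluxes[rid] for rid in acid.drain_reactions.values()))
    return abs(drain_sum - float(fluxes[acid.pool_reaction]))
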