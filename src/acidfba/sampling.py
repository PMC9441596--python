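"""Random sampling of nutrient conditions and condition-dependent profiles.

A nutrient condition picks exactly one viable exchange reaction per elemental
class (carbon, nitrogen, phosphorus, sulphur).  For each sampled condition all
other sources of those classes are closed, the selected sources are opened to
a large finite uptake (keeping the LPs bounded), growth is maximized, the
total flux sum minimized, and the amino-acid profile recorded; optionally the
drain variability (FVA) is computed per condition as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amino_acids import AA_CODES
from .model_build import AcidFBAModel, EcModel
from .simulate import (AminoAcidProfile, Condition, aa_profile_at_optimum,
                       drain_fva, maximize_growth)

logger = logging.getLogger(__name__)

__all__ = [
    "ELEMENT_CLASSES",
    "NutrientCondition",
    "ConditionProfileSet",
    "classify_exchanges",
    "find_viable_sources",
    "sample_conditions",
    "profiles_across_conditions",
]

#: Elemental classes sampled, mapped to their element symbols.
ELEMENT_CLASSES: dict[str, str] = {
    "carbon": "C", "nitrogen": "N", "phosphorus": "P", "sulphur": "S",
}

#: Default "unbounded" uptake opened for a selected source (mmol gDW^-1 h^-1).
DEFAULT_UPTAKE = 1000.0

#: A source is viable if it sustains at least this growth rate (h^-1).
VIABILITY_THRESHOLD = 1e-4


@dataclass(frozen=True)
class NutrientCondition:
    """One exchange-reaction identifier per elemental class."""

    carbon: str
    nitrogen: str
    phosphorus: str
    sulphur: str

    def as_dict(self) -> dict[str, str]:
        return {"carbon": self.carbon, "nitrogen": self.nitrogen,
                "phosphorus": self.phosphorus, "sulphur": self.sulphur}


def classify_exchanges(model_like) -> dict[str, list[str]]:
    """Group the model's exchange reactions by the elements their metabolite contains.

    An exchange may appear in several classes (e.g. an amino acid carries both
    C and N).  Metabolites without a formula are skipped with a warning.
    """
    model = getattr(model_like, "model", model_like)
    classes: dict[str, list[str]] = {name: [] for name in ELEMENT_CLASSES}
    skipped = 0
    for rxn in model.exchanges:
        met = next(iter(rxn.metabolites))
        elements = met.elements
        if not elements:
            skipped += 1
            continue
        for name, symbol in ELEMENT_CLASSES.items():
            if elements.get(symbol, 0) > 0:
                classes[name].append(rxn.id)
    if skipped:
        logger.warning("skipped %d exchange(s) whose metabolite has no formula",
                       skipped)
    return classes


def _apply_condition_bounds(model, classes: Mapping[str, Sequence[str]],
                            selected: Mapping[str, str],
                            uptake_bound: float) -> None:
    """Close every class-member exchange except the selected source per class."""
    for members in classes.values():
        for rxn_id in members:
            model.reactions.get_by_id(rxn_id).lower_bound = 0.0
    for class_name, rxn_id in selected.items():
        model.reactions.get_by_id(rxn_id).lower_bound = -uptake_bound


def find_viable_sources(acid: AcidFBAModel | EcModel, element_class: str, *,
                        classes: Mapping[str, Sequence[str]] | None = None,
                        threshold: float = VIABILITY_THRESHOLD,
                        uptake_bound: float = DEFAULT_UPTAKE) -> list[str]:
    """Exchange reactions of ``element_class`` that sustain growth as sole source.

    Each candidate replaces the reference source(s) of its class — all other
    class members are closed, candidate opened to ``uptake_bound`` — while the
    other classes keep their current (reference) medium.  Viable means maximal
    growth >= ``threshold``.
    """
    if element_class not in ELEMENT_CLASSES:
        raise ValueError(f"unknown element class {element_class!r}; expected "
                         f"one of {sorted(ELEMENT_CLASSES)}")
    model = acid.model
    classes = classes or classify_exchanges(acid)
    members = list(classes[element_class])
    viable = []
    for candidate in members:
        with model:
            for rxn_id in members:
                model.reactions.get_by_id(rxn_id).lower_bound = 0.0
            model.reactions.get_by_id(candidate).lower_bound = -uptake_bound
            growth = maximize_growth(acid)
        if growth.ok and growth.objective >= threshold:
            viable.append(candidate)
    if not viable:
        logger.warning("no viable %s source reaches growth %.3g",
                       element_class, threshold)
    return viable


def sample_conditions(sources_by_class: Mapping[str, Sequence[str]], n: int,
                      seed: int) -> list[NutrientCondition]:
    """Draw ``n`` conditions, one source per class uniformly at random.

    Sampling is with replacement (duplicates allowed) and reproducible under
    ``seed``; the per-condition draws come from one seeded generator in a
    fixed class order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    for class_name in ELEMENT_CLASSES:
        if not sources_by_class.get(class_name):
            raise ValueError(f"no sources for class {class_name!r}")
    rng = np.random.default_rng(seed)
    conditions = []
    for _ in range(n):
        picks = {class_name: str(rng.choice(sources_by_class[class_name]))
                 for class_name in ELEMENT_CLASSES}
        conditions.append(NutrientCondition(**{
            "carbon": picks["carbon"], "nitrogen": picks["nitrogen"],
            "phosphorus": picks["phosphorus"], "sulphur": picks["sulphur"]}))
    return conditions


@dataclass
class ConditionProfileSet:
    """Profiles, deviations from the across-sample mean, and per-condition FVA."""

    conditions: list[NutrientCondition]
    fractions: pd.DataFrame          # n_ok x 20 mass fractions
    deviations: pd.DataFrame         # (fraction - mean) / mean, column-wise
    fva: pd.DataFrame | None = None  # long format: condition, amino_acid, ...
    n_infeasible: int = 0
    seed: int | None = None

    @property
    def mean_fraction(self) -> pd.Series:
        return self.fractions.mean(axis=0)


def profiles_across_conditions(acid: AcidFBAModel,
                               conditions: Sequence[NutrientCondition], *,
                               opt_fraction: float = 1.0,
                               run_fva: bool = False,
                               fva_opt_fraction: float = 0.99,
                               uptake_bound: float = DEFAULT_UPTAKE,
                               classes: Mapping[str, Sequence[str]] | None = None,
                               seed: int | None = None) -> ConditionProfileSet:
    """Amino-acid profile (and optionally drain FVA) for each sampled condition.

    Per condition: swap in the selected sources with uptake limits opened,
    maximize growth, minimize the flux sum at ``opt_fraction`` of that
    optimum, and record the normalized profile.  Infeasible (or zero-growth)
    conditions are logged and excluded.  Relative deviations are computed
    column-wise against the arithmetic mean across the feasible conditions.
    """
    classes = classes or classify_exchanges(acid)
    model = acid.model
    rows, fva_frames, keep = [], [], []
    n_bad = 0
    for idx, cond in enumerate(conditions):
        with model:
            _apply_condition_bounds(model, classes, cond.as_dict(), uptake_bound)
            sol, profile = aa_profile_at_optimum(acid, opt_fraction)
            if not sol.ok or profile.total <= 0:
                n_bad += 1
                logger.warning("condition %d (%s) infeasible; excluded",
                               idx, cond.as_dict())
                continue
            if run_fva:
                frame = drain_fva(acid, fva_opt_fraction).reset_index()
                frame.insert(0, "condition", idx)
                fva_frames.append(frame)
        rows.append(profile.fraction)
        keep.append(idx)
    if not rows:
        raise RuntimeError("all sampled conditions were infeasible")
    fractions = pd.DataFrame(np.vstack(rows), index=keep,
                             columns=list(AA_CODES))
    fractions.index.name = "condition"
    mean = fractions.mean(axis=0)
    deviations = (fractions - mean) / mean.replace(0.0, np.nan)
    fva = pd.concat(fva_frames, ignore_index=True) if fva_frames else None
    return ConditionProfileSet(conditions=list(conditions),
                               fractions=fractions, deviations=deviations,
                               fva=fva, n_infeasible=n_bad, seed=seed)
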