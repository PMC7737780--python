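"""Design selection: energy-style ranking and the fuzzy-logic objective.

Each criterion x (computed binding energy, clash count, packing proxy, ...) is
mapped to a fitness f = 1/(1 + e^((x−μ)/σ)) where μ and σ are the mean and
standard deviation of the criterion over the design ensemble; undesirable
criteria are handled by negating x. Fitness approaches 1 for values well below
the ensemble mean and 0 well above it, and f(μ) = 0.5. The per-design
objective O is the product of the individual fitness terms, so a design scores
close to 1 only when it finds a favorable compromise among all features, and
close to 0 whenever any single feature is poor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DESIRABLE = "desirable"
UNDESIRABLE = "undesirable"

# strictly inside (0, 1) even for saturated exponents
_F_FLOOR = 1e-300
_F_CEIL = 1.0 - 1e-16


@dataclass(frozen=True)
class Criterion:
    name: str
    sense: str = DESIRABLE  # lower-is-better by default
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        if self.sense not in (DESIRABLE, UNDESIRABLE):
            raise ValueError(f"sense must be {DESIRABLE!r} or {UNDESIRABLE!r}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def from_ensemble(cls, name, values, sense=DESIRABLE):
        mu, sigma = ensemble_stats(values)
        return cls(name=name, sense=sense, mu=mu, sigma=sigma)


def ensemble_stats(values):
    """Mean and population standard deviation of a criterion over the design
    ensemble; a constant ensemble is rejected (σ would be 0)."""
    arr = np.asarray(list(values), float)
    if len(arr) < 2:
        raise ValueError("need at least 2 values for ensemble statistics")
    mu = float(arr.mean())
    sigma = float(arr.std())  # population std
    if sigma == 0.0:
        raise ValueError("constant ensemble: standard deviation is zero")
    return mu, sigma


def logistic_fitness(x: float, mu: float, sigma: float, sense: str = DESIRABLE) -> float:
    """f = 1/(1 + e^((x−μ)/σ)); undesirable criteria negate x (and μ).
    The value is strictly inside (0, 1)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if sense == UNDESIRABLE:
        x, mu = -x, -mu
    elif sense != DESIRABLE:
        raise ValueError(f"unknown sense {sense!r}")
    z = (x - mu) / sigma
    if z > 700:
        f = _F_FLOOR
    elif z < -700:
        f = _F_CEIL
    else:
        f = 1.0 / (1.0 + math.exp(z))
    return min(max(f, _F_FLOOR), _F_CEIL)


def objective(fitnesses) -> float:
    """Product of fitness terms; in (0, 1)."""
    terms = list(fitnesses)
    if not terms:
        raise ValueError("objective needs at least one fitness term")
    out = 1.0
    for f in terms:
        out *= f
    return out


def candidate_fitnesses(candidate, criteria):
    """Per-criterion fitness values for one design; KeyError on a missing
    feature."""
    out = {}
    for crit in criteria:
        x = candidate.feature_values[crit.name]
        out[crit.name] = logistic_fitness(x, crit.mu, crit.sigma, crit.sense)
    return out


def rank_designs(candidates, mode: str, criteria=None, energy_feature: str | None = None):
    """Order design candidates.

    ``energy`` mode sorts ascending by one energy-like feature column;
    ``fuzzy`` mode sorts descending by the product objective over the given
    criteria. Candidates missing a required feature are excluded with a
    warning; ties are broken by recipe order so rankings are deterministic.
    Returns (ordered candidates, report rows).
    """
    if mode == "energy":
        feature = energy_feature or (criteria[0].name if criteria else None)
        if feature is None:
            raise ValueError("energy mode needs an energy-like feature name")
        scored = []
        for cand in candidates:
            if feature not in cand.feature_values:
                logger.warning("excluding %s: missing feature %r", cand.recipe.label(), feature)
                continue
            scored.append((cand.feature_values[feature], cand))
        scored.sort(key=lambda sc: (sc[0], sc[1].recipe.sort_key()))
        report = [
            {"design": c.recipe.label(), feature: s} for s, c in scored
        ]
        return [c for _, c in scored], report

    if mode == "fuzzy":
        if not criteria:
            raise ValueError("fuzzy mode needs at least one criterion")
        scored = []
        for cand in candidates:
            try:
                fits = candidate_fitnesses(cand, criteria)
            except KeyError as exc:
                logger.warning(
                    "excluding %s: missing feature %s", cand.recipe.label(), exc
                )
                continue
            scored.append((objective(fits.values()), fits, cand))
        scored.sort(key=lambda sfc: (-sfc[0], sfc[2].recipe.sort_key()))
        report = []
        for o, fits, cand in scored:
            row = {"design": cand.recipe.label(), "objective": o}
            row.update({f"f_{k}": v for k, v in fits.items()})
            report.append(row)
        return [c for _, _, c in scored], report

    raise ValueError(f"unknown ranking mode {mode!r}")
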