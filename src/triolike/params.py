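"""Relative-risk and stratification parameter objects and constraints.

The multiplicative relative-risk parameters act on a child's disease
risk:

* ``R1``, ``R2`` — child carries one / two risk alleles;
* ``S1``, ``S2`` — the mother carries one / two risk alleles;
* ``Im``, ``Ip`` — a heterozygous child inherited its risk allele from
  the mother / father (parent-of-origin imprinting);
* ``gamma[i, j]`` — mother carries i and child j risk alleles
  (mother-child interaction), with gamma[0, 0] = 1 as reference.

The nuisance stratification over parental mating types comes in four
flavours: ``HWE`` (random mating at Hardy-Weinberg proportions, a single
allele frequency q), ``PAE`` (parental allelic exchangeability,
mating-symmetry strata with mu4 = mu3), ``CEPG`` (mating symmetry, six
strata) and ``CPG`` (ordered parental pair, nine strata).  The
all-reference-genotype stratum (mu6 under CEPG/PAE, mu9 under CPG) is
fixed at 1; the explicit normalisation over the 15 cells absorbs the
remaining scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RiskParams",
    "StratParams",
    "ModelSpec",
    "apply_constraints",
    "RISK_PARAM_NAMES",
    "GAMMA_NAMES",
    "ASSUMPTIONS",
    "CHILD_MULTIPLICATIVE",
    "MATERNAL_MULTIPLICATIVE",
]

#: interaction-parameter names gij <-> gamma[mother i copies, child j copies]
GAMMA_NAMES = ("g01", "g02", "g10", "g11", "g12", "g20", "g21", "g22")

#: canonical ordering of all risk parameters in free vectors and reports
RISK_PARAM_NAMES = ("R1", "R2", "S1", "S2", "Im", "Ip") + GAMMA_NAMES

ASSUMPTIONS = ("HWE", "PAE", "CEPG", "CPG")

CHILD_MULTIPLICATIVE = "child_multiplicative"  # R2 = R1**2
MATERNAL_MULTIPLICATIVE = "maternal_multiplicative"  # S2 = S1**2

#: number of free mating-type parameters per assumption (reference fixed)
N_FREE_STRAT = {"HWE": 1, "PAE": 4, "CEPG": 5, "CPG": 8}


def _gamma_index(name: str) -> tuple[int, int]:
    return int(name[1]), int(name[2])


@dataclass(frozen=True)
class RiskParams:
    """Multiplicative genotype relative risks; all default to 1 (null)."""

    R1: float = 1.0
    R2: float = 1.0
    S1: float = 1.0
    S2: float = 1.0
    Im: float = 1.0
    Ip: float = 1.0
    gamma: Mapping[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("R1", "R2", "S1", "S2", "Im", "Ip"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite real, got {v}")
        gamma = dict(self.gamma)
        if gamma.get((0, 0), 1.0) != 1.0:
            raise ValueError("gamma(0, 0) is the reference and must equal 1")
        for (i, j), v in gamma.items():
            if i not in (0, 1, 2) or j not in (0, 1, 2):
                raise ValueError(f"gamma index {(i, j)} out of range")
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"gamma{i}{j} must be positive finite, got {v}")
        object.__setattr__(self, "gamma", gamma)

    def gamma_at(self, i: int, j: int) -> float:
        """gamma for mother i copies / child j copies (1 if unset)."""
        return self.gamma.get((i, j), 1.0)

    def gamma_grid(self) -> np.ndarray:
        """3x3 array g[i, j] with unset entries at 1."""
        g = np.ones((3, 3))
        for (i, j), v in self.gamma.items():
            g[i, j] = v
        return g

    def get(self, name: str) -> float:
        if name in GAMMA_NAMES:
            return self.gamma_at(*_gamma_index(name))
        return getattr(self, name)

    def with_values(self, **named: float) -> "RiskParams":
        """Copy with the named parameters replaced (gammas by gij name)."""
        plain = {k: v for k, v in named.items() if k not in GAMMA_NAMES}
        gamma = dict(self.gamma)
        for k, v in named.items():
            if k in GAMMA_NAMES:
                gamma[_gamma_index(k)] = v
        return replace(self, gamma=gamma, **plain)


@dataclass(frozen=True)
class StratParams:
    """Nuisance mating-type stratification.

    ``mu`` holds the full stratum vector (length 6 for CEPG/PAE, 9 for
    CPG, unused under HWE) with the reference stratum at 1.  ``q`` is the
    risk-allele frequency, used only under HWE.
    """

    assumption: str = "CEPG"
    mu: tuple[float, ...] = ()
    q: float = 0.5

    def __post_init__(self):
        if self.assumption not in ASSUMPTIONS:
            raise ValueError(f"unknown assumption {self.assumption!r}")
        if self.assumption == "HWE":
            if not (0.0 < self.q < 1.0) or not np.isfinite(self.q):
                raise ValueError(f"allele frequency must lie in (0, 1), got {self.q}")
            object.__setattr__(self, "mu", ())
            return
        n = 9 if self.assumption == "CPG" else 6
        mu = tuple(float(m) for m in (self.mu or (1.0,) * n))
        if len(mu) != n:
            raise ValueError(
                f"{self.assumption} needs {n} mating-type parameters, got {len(mu)}"
            )
        if any(not np.isfinite(m) or m <= 0 for m in mu):
            raise ValueError("mating-type parameters must be positive finite")
        if self.assumption == "PAE" and not np.isclose(mu[3], mu[2]):
            raise ValueError("PAE requires mu4 == mu3")
        object.__setattr__(self, "mu", mu)

    @property
    def n_strata(self) -> int:
        return 0 if self.assumption == "HWE" else len(self.mu)


def _default_free_strat(assumption: str) -> tuple[str, ...]:
    """Names of the free stratification parameters, in order."""
    if assumption == "HWE":
        return ("q",)
    if assumption == "CPG":
        return tuple(f"mu{i}" for i in range(1, 9))  # mu9 = 1 reference
    if assumption == "CEPG":
        return tuple(f"mu{i}" for i in range(1, 6))  # mu6 = 1 reference
    # PAE: mu4 tied to mu3, mu6 reference
    return ("mu1", "mu2", "mu3", "mu5")


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters to estimate and under which assumption.

    ``free_risk`` lists the relative-risk parameters to maximise over
    (all others held at 1); ``constraints`` may tie R2 = R1**2 and/or
    S2 = S1**2.  At most 7 risk parameters are jointly identifiable from
    complete trio data, but no hard cap is enforced here — rank
    diagnostics live in :func:`triolike.model.max_estimable_risk_params`.
    """

    assumption: str = "HWE"
    free_risk: tuple[str, ...] = ()
    constraints: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.assumption not in ASSUMPTIONS:
            raise ValueError(f"unknown assumption {self.assumption!r}")
        free = tuple(self.free_risk)
        for name in free:
            if name not in RISK_PARAM_NAMES:
                raise ValueError(f"unknown risk parameter {name!r}")
        if len(set(free)) != len(free):
            raise ValueError("duplicate entries in free_risk")
        cons = frozenset(self.constraints)
        unknown = cons - {CHILD_MULTIPLICATIVE, MATERNAL_MULTIPLICATIVE}
        if unknown:
            raise ValueError(f"unknown constraints {sorted(unknown)}")
        if CHILD_MULTIPLICATIVE in cons and "R2" in free:
            raise ValueError("R2 cannot be free under the child-multiplicative constraint")
        if MATERNAL_MULTIPLICATIVE in cons and "S2" in free:
            raise ValueError("S2 cannot be free under the maternal-multiplicative constraint")
        object.__setattr__(self, "free_risk", free)
        object.__setattr__(self, "constraints", cons)

    @property
    def free_names(self) -> tuple[str, ...]:
        """All free parameter names: risk (canonical order) then strat."""
        ordered = tuple(n for n in RISK_PARAM_NAMES if n in self.free_risk)
        return ordered + _default_free_strat(self.assumption)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def nests(self, other: "ModelSpec") -> bool:
        """True if self (null) is nested in ``other`` (alternative)."""
        return (
            self.assumption == other.assumption
            and set(self.free_risk) <= set(other.free_risk)
            and self.constraints >= other.constraints
        )


def apply_constraints(
    spec: ModelSpec, free_values: Sequence[float]
) -> tuple[RiskParams, StratParams]:
    """Expand a free-parameter vector (natural scale, in
    ``spec.free_names`` order) into full parameter objects.

    Applies R2 = R1**2 / S2 = S1**2 when constrained, ties mu4 = mu3
    under PAE, and holds everything else at its reference value.
    """
    names = spec.free_names
    if len(free_values) != len(names):
        raise ValueError(
            f"expected {len(names)} free values ({names}), got {len(free_values)}"
        )
    values = dict(zip(names, (float(v) for v in free_values)))

    risk_named = {k: v for k, v in values.items() if k in RISK_PARAM_NAMES}
    if CHILD_MULTIPLICATIVE in spec.constraints:
        risk_named["R2"] = risk_named.get("R1", 1.0) ** 2
    if MATERNAL_MULTIPLICATIVE in spec.constraints:
        risk_named["S2"] = risk_named.get("S1", 1.0) ** 2
    rp = RiskParams().with_values(**risk_named)

    if spec.assumption == "HWE":
        sp = StratParams("HWE", q=values["q"])
    else:
        n = 9 if spec.assumption == "CPG" else 6
        mu = [1.0] * n
        for name, v in values.items():
            if name.startswith("mu"):
                mu[int(name[2:]) - 1] = v
        if spec.assumption == "PAE":
            mu[3] = mu[2]
        sp = StratParams(spec.assumption, mu=tuple(mu))
    return rp, sp
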