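"""Multinomial cell probabilities and log-likelihood for family sub-units.

The model: conditional on a child being affected, the probability of a
trio genotype configuration i is

    P(cell i | affected)  propto  base_i(strat) * pen_i(risk)

where ``base_i`` is the population probability structure of the cell —
``P(gm) P(gf) * mendel_weight`` under HWE, or ``mu_t(i) * kappa_i`` under
the mating-type stratifications (kappa is the phased transmission count)
— and ``pen_i`` is the product of the relative-risk multipliers that
apply to the cell (the baseline penetrance cancels in the
normalisation).  Control units use ``base`` alone: control genotype
frequencies are assumed to match the general population (a rare-disease
assumption when controls are genuinely unaffected).

Sub-units with unobserved members contribute through the collapsed
(marginalised) probability vector of their unit kind; the total
log-likelihood is the sum over all unit tables at one SNP, sharing one
set of stratification parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import (
    MISSING,
    N_CELLS,
    UnitType,
    cell_index,
    collapse_map,
    collapse_matrix,
    enumerate_trio_cells,
)
from .params import RiskParams, StratParams

__all__ = [
    "CountTable",
    "penetrance_multiplier",
    "case_trio_cell_probs",
    "control_trio_cell_probs",
    "unit_log_likelihood",
    "total_log_likelihood",
]

_CELLS = enumerate_trio_cells()
_GM = np.array([c.gm for c in _CELLS])
_GF = np.array([c.gf for c in _CELLS])
_GC = np.array([c.gc for c in _CELLS])
_CEPG = np.array([c.cepg_type for c in _CELLS]) - 1
_CPG = np.array([c.cpg_type for c in _CELLS]) - 1
_MENDEL = np.array([float(c.mendel_weight) for c in _CELLS])
_KAPPA = np.array([float(c.transmission_count) for c in _CELLS])

# parental origin of a heterozygous child's risk allele, per cell:
# 0 none (gc != 1), 1 maternal, 2 paternal, 3 ambiguous (het x het)
_PHASE = np.zeros(N_CELLS, dtype=int)
for _c in _CELLS:
    if _c.gc == 1:
        maternal = _c.gm > 0 and _c.gf < 2
        paternal = _c.gf > 0 and _c.gm < 2
        _PHASE[_c.index - 1] = 3 if (maternal and paternal) else (1 if maternal else 2)


def penetrance_multiplier(
    gm: int, gf: int, gc: int, phase: str, rp: RiskParams
) -> float:
    """Product of relative-risk factors for one phased configuration.

    ``phase`` ('maternal', 'paternal' or 'none') states the parental
    origin of a heterozygous child's risk allele; it must be 'none' for
    homozygous children and consistent with the parental genotypes
    otherwise.  The baseline penetrance alpha is excluded (it cancels in
    the disease-conditional likelihood).
    """
    idx = cell_index(gm, gf, gc)  # validates Mendelian consistency
    code = _PHASE[idx - 1]
    if gc != 1:
        if phase != "none":
            raise ValueError("phase applies only to heterozygous children")
        imprint = 1.0
    else:
        if phase not in ("maternal", "paternal"):
            raise ValueError(
                "a heterozygous child needs phase 'maternal' or 'paternal'"
            )
        if phase == "maternal":
            if code == 2:
                raise ValueError(
                    f"maternal origin impossible for (gm={gm}, gf={gf}, gc=1)"
                )
            imprint = rp.Im
        else:
            if code == 1:
                raise ValueError(
                    f"paternal origin impossible for (gm={gm}, gf={gf}, gc=1)"
                )
            imprint = rp.Ip
    r = (1.0, rp.R1, rp.R2)[gc]
    s = (1.0, rp.S1, rp.S2)[gm]
    return r * s * rp.gamma_at(gm, gc) * imprint


def _penetrance_vector(rp: RiskParams) -> np.ndarray:
    """Phase-averaged penetrance multipliers for the 15 cells.

    The doubly-ambiguous cell (het x het -> het) averages the two phase
    multipliers: w = R1 S1 gamma(1,1) (Im + Ip) / 2.
    """
    r = np.array([1.0, rp.R1, rp.R2])[_GC]
    s = np.array([1.0, rp.S1, rp.S2])[_GM]
    g = rp.gamma_grid()[_GM, _GC]
    imp = np.choose(_PHASE, (1.0, rp.Im, rp.Ip, 0.5 * (rp.Im + rp.Ip)))
    return r * s * g * imp


def _base_vector(sp: StratParams) -> np.ndarray:
    """Unnormalised population weight of each cell under ``sp``."""
    if sp.assumption == "HWE":
        q = sp.q
        hw = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        return hw[_GM] * hw[_GF] * _MENDEL
    mu = np.asarray(sp.mu)
    strata = _CPG if sp.assumption == "CPG" else _CEPG
    return mu[strata] * _KAPPA


def case_trio_cell_probs(rp: RiskParams, sp: StratParams) -> np.ndarray:
    """15-cell probabilities P(gm, gf, gc | child affected)."""
    u = _base_vector(sp) * _penetrance_vector(rp)
    total = u.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("cell probabilities are degenerate; check parameters")
    return u / total


def control_trio_cell_probs(sp: StratParams) -> np.ndarray:
    """15-cell population probabilities (all risk multipliers at 1)."""
    u = _base_vector(sp)
    total = u.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("cell probabilities are degenerate; check parameters")
    return u / total


@dataclass(frozen=True)
class CountTable:
    """Observed combination counts for one unit kind at one SNP."""

    unit_kind: UnitType
    counts: tuple[int, ...]

    def __post_init__(self):
        expected = len(collapse_map(self.unit_kind))
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != expected:
            raise ValueError(
                f"{self.unit_kind.name} expects {expected} counts, got {len(counts)}"
            )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_units(self) -> int:
        return sum(self.counts)


def unit_log_likelihood(table: CountTable, trio_probs: np.ndarray) -> float:
    """Multinomial log-likelihood contribution of one unit table.

    ``trio_probs`` must be the case 15-cell vector for case units and
    the control vector for control units.  The vector is collapsed to
    the unit's observable combinations and renormalised (a no-op for a
    proper probability vector, asserted).  A positive count on a
    zero-probability combination yields ``-inf``.
    """
    probs = np.asarray(trio_probs, dtype=float)
    if probs.shape != (N_CELLS,):
        raise ValueError(f"expected a length-{N_CELLS} probability vector")
    collapsed = collapse_matrix(table.unit_kind) @ probs
    total = collapsed.sum()
    assert np.isclose(total, 1.0, atol=1e-9), "collapsed probabilities must sum to 1"
    collapsed = collapsed / total
    counts = np.asarray(table.counts, dtype=float)
    active = counts > 0
    if not active.any():
        return 0.0
    if np.any(collapsed[active] <= 0):
        return -np.inf
    return float(counts[active] @ np.log(collapsed[active]))


def total_log_likelihood(tables, rp: RiskParams, sp: StratParams) -> float:
    """Sum of unit log-likelihoods at one SNP, sharing one ``sp``.

    Case tables use the disease-conditional probabilities, control
    tables the population probabilities.  An empty collection yields 0;
    ``-inf`` contributions propagate.
    """
    tables = list(tables)
    if not tables:
        return 0.0
    case_probs = control_probs = None
    out = 0.0
    for table in tables:
        if table.unit_kind.is_case:
            if case_probs is None:
                case_probs = case_trio_cell_probs(rp, sp)
            out += unit_log_likelihood(table, case_probs)
        else:
            if control_probs is None:
                control_probs = control_trio_cell_probs(sp)
            out += unit_log_likelihood(table, control_probs)
    return out
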