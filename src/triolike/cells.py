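"""Mendelian trio genotype configurations and sub-unit collapsing maps.

Genotypes are coded throughout as risk-allele counts (0, 1, 2); the
translation from allele labels happens once, in :mod:`triolike.pedio`.
A *trio cell* is one of the 15 (mother, father, child) genotype
configurations consistent with Mendelian inheritance.  Each cell carries

* a mating-type index under the mating-symmetry (CEPG) stratification,
  which treats the parental pair as unordered (6 types), and under the
  conditional-on-parental-genotypes (CPG) stratification, which keeps
  the pair ordered (9 types);
* the Mendelian segregation probability P(child | parents); and
* a transmission-count factor (the number of distinct phased
  transmissions producing the child genotype, 2 only for the
  het x het -> het cell) used by the mating-type stratifications.

Sub-units with missing members (duos, parental matings, singletons)
observe a marginal of the 15-cell table; :func:`collapse_map` builds the
partition of cells induced by marginalising over the unobserved members.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "MISSING",
    "TrioCell",
    "UnitType",
    "CollapseMap",
    "enumerate_trio_cells",
    "mendelian_weight",
    "collapse_map",
    "collapse_matrix",
    "cell_index",
    "N_CELLS",
]

#: sentinel for a missing genotype (risk-allele count unknown)
MISSING: int = -1

N_CELLS = 15


class MendelianError(ValueError):
    """Raised for a child genotype inconsistent with its parents."""


@dataclass(frozen=True)
class TrioCell:
    """One Mendelian-consistent (gm, gf, gc) configuration.

    Attributes
    ----------
    index : int
        1-based canonical cell index (frozen ordering; see module docs).
    gm, gf, gc : int
        Risk-allele counts of mother, father, child.
    cepg_type : int
        Mating-type index 1-6 under mating symmetry (unordered pair).
    cpg_type : int
        Mating-type index 1-9 with the parental pair ordered.
    mendel_weight : Fraction
        P(gc | gm, gf) under random Mendelian transmission.
    transmission_count : int
        Phased-transmission multiplicity (1 or 2) used by the
        mating-type stratifications; equals
        ``mendel_weight * 2**(#heterozygous parents)``.
    """

    index: int
    gm: int
    gf: int
    gc: int
    cepg_type: int
    cpg_type: int
    mendel_weight: Fraction

    @property
    def n_het_parents(self) -> int:
        return int(self.gm == 1) + int(self.gf == 1)

    @property
    def transmission_count(self) -> int:
        return int(self.mendel_weight * 2**self.n_het_parents)


def mendelian_weight(gm: int, gf: int, gc: int) -> Fraction:
    """P(child has ``gc`` risk alleles | parental counts ``gm``, ``gf``).

    Raises
    ------
    MendelianError
        If the configuration is impossible under Mendelian transmission.
    """
    for g, who in ((gm, "mother"), (gf, "father"), (gc, "child")):
        if g not in (0, 1, 2):
            raise ValueError(f"{who} genotype must be 0, 1 or 2, got {g!r}")
    # each parent transmits one allele: P(transmit risk) = g/2
    pm = Fraction(gm, 2)
    pf = Fraction(gf, 2)
    probs = {
        2: pm * pf,
        1: pm * (1 - pf) + (1 - pm) * pf,
        0: (1 - pm) * (1 - pf),
    }
    w = probs[gc]
    if w == 0:
        raise MendelianError(
            f"child genotype {gc} impossible for parental genotypes ({gm}, {gf})"
        )
    return w


# frozen canonical cell table: (gm, gf, gc, cepg_type, cpg_type),
# ordered by mating type then descending genotypes (the conventional
# published ordering; count files use exactly this row order).
_CELL_TABLE: Sequence[tuple[int, int, int, int, int]] = (
    (2, 2, 2, 1, 1),
    (2, 1, 2, 2, 2),
    (2, 1, 1, 2, 2),
    (1, 2, 2, 2, 3),
    (1, 2, 1, 2, 3),
    (2, 0, 1, 3, 4),
    (0, 2, 1, 3, 5),
    (1, 1, 2, 4, 6),
    (1, 1, 1, 4, 6),
    (1, 1, 0, 4, 6),
    (1, 0, 1, 5, 7),
    (1, 0, 0, 5, 7),
    (0, 1, 1, 5, 8),
    (0, 1, 0, 5, 8),
    (0, 0, 0, 6, 9),
)

_CELLS: tuple[TrioCell, ...] = tuple(
    TrioCell(i + 1, gm, gf, gc, cepg, cpg, mendelian_weight(gm, gf, gc))
    for i, (gm, gf, gc, cepg, cpg) in enumerate(_CELL_TABLE)
)

_INDEX_BY_GENOTYPES = {(c.gm, c.gf, c.gc): c.index for c in _CELLS}


def enumerate_trio_cells() -> tuple[TrioCell, ...]:
    """Return the 15 Mendelian trio cells in canonical order."""
    return _CELLS


def cell_index(gm: int, gf: int, gc: int) -> int:
    """1-based canonical cell index of a trio configuration.

    Raises :class:`MendelianError` for inconsistent configurations.
    """
    try:
        return _INDEX_BY_GENOTYPES[(gm, gf, gc)]
    except KeyError:
        raise MendelianError(
            f"({gm}, {gf}, {gc}) is not a Mendelian-consistent trio configuration"
        ) from None


class UnitType(enum.Enum):
    """The 11 observable pedigree sub-unit kinds, in preference order.

    The value is the extraction preference rank (1 = most informative).
    ``observed`` names which trio members carry observed genotypes.
    """

    CASE_PARENT_TRIO = 1
    CASE_MOTHER_DUO = 2
    CASE_FATHER_DUO = 3
    CASE = 4
    CASE_PARENTAL_MATING = 5
    CASE_MOTHER = 6
    CASE_FATHER = 7
    CONTROL_PARENTAL_MATING = 8
    CONTROL_MOTHER_DUO = 9
    CONTROL_FATHER_DUO = 10
    CONTROL = 11

    @property
    def preference(self) -> int:
        return self.value

    @property
    def is_case(self) -> bool:
        """Case units are ascertained through an affected child and use
        the disease-conditional cell probabilities; control units use
        population probabilities."""
        return self.value <= 7

    @property
    def observed(self) -> tuple[str, ...]:
        """Trio members ('m', 'f', 'c') whose genotypes are observed."""
        return _OBSERVED[self]


_OBSERVED = {
    UnitType.CASE_PARENT_TRIO: ("m", "f", "c"),
    UnitType.CASE_MOTHER_DUO: ("m", "c"),
    UnitType.CASE_FATHER_DUO: ("f", "c"),
    UnitType.CASE: ("c",),
    UnitType.CASE_PARENTAL_MATING: ("m", "f"),
    UnitType.CASE_MOTHER: ("m",),
    UnitType.CASE_FATHER: ("f",),
    UnitType.CONTROL_PARENTAL_MATING: ("m", "f"),
    UnitType.CONTROL_MOTHER_DUO: ("m", "c"),
    UnitType.CONTROL_FATHER_DUO: ("f", "c"),
    UnitType.CONTROL: ("c",),
}


@dataclass(frozen=True)
class CollapseMap:
    """Partition of the 15 trio cells observable for one unit kind.

    ``combinations`` lists, in canonical order, pairs of (observed
    genotype tuple, frozenset of member cell indices).  The observed
    tuple has one entry per observed member, in ``unit_kind.observed``
    order; combinations are sorted by descending genotype counts, which
    reproduces the published duo table ordering.  The trio map is the
    identity (15 singletons in cell order).
    """

    unit_kind: UnitType
    combinations: tuple[tuple[tuple[int, ...], frozenset[int]], ...]

    def __len__(self) -> int:
        return len(self.combinations)

    @property
    def labels(self) -> tuple[str, ...]:
        """Column labels, e.g. ``('m2_c1', ...)`` for a mother duo."""
        return tuple(
            "_".join(f"{who}{g}" for who, g in zip(self.unit_kind.observed, obs))
            for obs, _ in self.combinations
        )

    def matrix(self) -> np.ndarray:
        """0/1 collapse matrix ``C`` with shape (n_combinations, 15);
        collapsed probabilities are ``C @ p``."""
        mat = np.zeros((len(self.combinations), N_CELLS))
        for row, (_, cells) in enumerate(self.combinations):
            for idx in cells:
                mat[row, idx - 1] = 1.0
        return mat


_MEMBER_GETTERS = {"m": lambda c: c.gm, "f": lambda c: c.gf, "c": lambda c: c.gc}


def _build_collapse_map(kind: UnitType) -> CollapseMap:
    getters = [_MEMBER_GETTERS[w] for w in kind.observed]
    groups: dict[tuple[int, ...], set[int]] = {}
    for cell in _CELLS:
        obs = tuple(g(cell) for g in getters)
        groups.setdefault(obs, set()).add(cell.index)
    if kind is UnitType.CASE_PARENT_TRIO:
        ordered = sorted(groups, key=lambda obs: min(groups[obs]))
    else:
        ordered = sorted(groups, reverse=True)  # descending genotype counts
    return CollapseMap(
        kind, tuple((obs, frozenset(groups[obs])) for obs in ordered)
    )


_COLLAPSE_MAPS = {kind: _build_collapse_map(kind) for kind in UnitType}


def collapse_map(kind: UnitType) -> CollapseMap:
    """Collapse map for one unit kind (computed once, from the
    marginalisation rule; the published duo table is a regression test)."""
    return _COLLAPSE_MAPS[kind]


def collapse_matrix(kind: UnitType) -> np.ndarray:
    """0/1 matrix mapping the 15-cell vector to observable combinations."""
    return collapse_map(kind).matrix()
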