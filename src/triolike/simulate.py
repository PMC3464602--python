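"""Synthetic-data generation for the trio multinomial model.

Case units are drawn directly from the disease-conditional collapsed
cell probabilities at the design's risk parameters (the baseline
penetrance is unidentifiable and never needed); control units from the
population probabilities.  A rejection-sampling path with an explicit
baseline penetrance exists as a cross-check oracle.  SNPs are
independent (no linkage disequilibrium); non-causal SNPs use all-1 risk
parameters.

Besides in-memory count tables, the simulator materialises families as
an in-memory :class:`~triolike.pedio.PedigreeSet` (and PLINK .ped/.map
text files) whose per-SNP extraction reproduces the designed unit mix
exactly when there is no missingness: families are expanded
deterministically from the sampled count tables, so the two
construction routes agree count-for-count at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .cells import MISSING, UnitType, collapse_map, collapse_matrix, enumerate_trio_cells
from .likelihood import CountTable, case_trio_cell_probs, control_trio_cell_probs
from .params import RiskParams, StratParams
from .pedio import (
    AFFECTED,
    MISSING_ALLELE,
    UNAFFECTED,
    UNKNOWN,
    Individual,
    PedigreeSet,
)

__all__ = [
    "SimDesign",
    "simulate_unit_tables",
    "simulate_pedigrees",
    "simulate_ped_files",
    "apply_missingness",
    "simulate_case_trios_rejection",
]

_CELLS = enumerate_trio_cells()


@dataclass(frozen=True)
class SimDesign:
    """A simulation design: unit mix, effects, allele frequency.

    Parameters
    ----------
    n_units : mapping UnitType -> int
        How many families of each unit kind to generate.
    risk : RiskParams
        Relative risks at the causal SNP(s); all-1 elsewhere.
    q : float
        Risk-allele frequency (risk allele is minor by construction;
        designs use q < 0.5).
    n_snps : int
        Number of independent SNPs.
    causal_snps : tuple of int
        0-based SNP indices at which ``risk`` applies.
    missingness : float
        Per-genotype independent blanking probability (applied by
        :func:`apply_missingness` when pedigrees are materialised).
    seed : int
        Seed for all randomness in the design.
    """

    n_units: Mapping[UnitType, int] = field(default_factory=dict)
    risk: RiskParams = field(default_factory=RiskParams)
    q: float = 0.3
    n_snps: int = 1
    causal_snps: tuple[int, ...] = (0,)
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.q < 1):
            raise ValueError(f"allele frequency must lie in (0, 1), got {self.q}")
        if not (0 <= self.missingness <= 1):
            raise ValueError("missingness must lie in [0, 1]")
        if any(n < 0 for n in self.n_units.values()):
            raise ValueError("unit counts must be non-negative")
        if any(not (0 <= s < self.n_snps) for s in self.causal_snps):
            raise ValueError("causal SNP index out of range")
        object.__setattr__(self, "n_units", dict(self.n_units))

    def risk_at(self, snp: int) -> RiskParams:
        return self.risk if snp in self.causal_snps else RiskParams()


def _collapsed_probs(kind: UnitType, rp: RiskParams, sp: StratParams) -> np.ndarray:
    probs = case_trio_cell_probs(rp, sp) if kind.is_case else control_trio_cell_probs(sp)
    return collapse_matrix(kind) @ probs


def simulate_unit_tables(
    design: SimDesign, rng: Optional[np.random.Generator] = None
) -> list[dict[UnitType, CountTable]]:
    """Draw per-SNP unit count tables (multinomial over collapsed cells).

    Returns one dict per SNP, keyed by unit kind.  Reproducible given
    the design seed.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    sp = StratParams("HWE", q=design.q)
    out = []
    for snp in range(design.n_snps):
        rp = design.risk_at(snp)
        per_snp = {}
        for kind, n in design.n_units.items():
            cp = _collapsed_probs(kind, rp, sp)
            counts = rng.multinomial(n, cp) if n else np.zeros(len(cp), dtype=int)
            per_snp[kind] = CountTable(kind, tuple(counts))
        out.append(per_snp)
    return out


# ---------------------------------------------------------------------------
# family materialisation

_RISK, _OTHER = "A", "G"


def _pair(code: int) -> tuple[str, str]:
    if code == MISSING:
        return (MISSING_ALLELE, MISSING_ALLELE)
    return ((_OTHER, _OTHER), (_RISK, _OTHER), (_RISK, _RISK))[code]


def _family(
    fid: str, kind: UnitType, obs_by_snp: list[tuple[int, ...]], n_snps: int
) -> list[Individual]:
    """Build one family whose observed members carry the per-SNP
    genotypes in ``obs_by_snp`` (unobserved members are ungenotyped)."""
    observed = kind.observed
    child_phen = AFFECTED if kind.is_case else UNAFFECTED
    singleton = observed == ("c",)

    def genotype_matrix(member: str) -> np.ndarray:
        rows = []
        for obs in obs_by_snp:
            got = dict(zip(observed, obs))
            rows.append(_pair(got.get(member, MISSING)))
        return np.array(rows, dtype="U8")

    if singleton:
        return [Individual(fid, "1", "0", "0", 1, child_phen, genotype_matrix("c"))]
    father = Individual(fid, "1", "0", "0", 1, UNKNOWN, genotype_matrix("f"))
    mother = Individual(fid, "2", "0", "0", 2, UNKNOWN, genotype_matrix("m"))
    child = Individual(fid, "3", "1", "2", 1, child_phen, genotype_matrix("c"))
    return [father, mother, child]


def simulate_pedigrees(design: SimDesign) -> PedigreeSet:
    """Materialise the design as an in-memory pedigree collection.

    The per-SNP tables are sampled first (same RNG stream as
    :func:`simulate_unit_tables`) and expanded into families in
    canonical combination order, so extraction of the result reproduces
    the tables exactly when ``missingness`` is 0.  Missingness is *not*
    applied here; see :func:`apply_missingness`.
    """
    tables = simulate_unit_tables(design)
    snp_ids = [f"snp{i + 1}" for i in range(design.n_snps)]
    families: dict[str, list[Individual]] = {}
    fam_no = 0
    for kind, n in design.n_units.items():
        if n == 0:
            continue
        combos = collapse_map(kind).combinations
        # expand per-SNP counts into per-family combination assignments
        per_family: list[list[tuple[int, ...]]] = [[] for _ in range(n)]
        for snp in range(design.n_snps):
            counts = tables[snp][kind].counts
            j = 0
            for (obs, _), c in zip(combos, counts):
                for _ in range(c):
                    per_family[j].append(obs)
                    j += 1
        for i in range(n):
            fam_no += 1
            fid = f"F{fam_no}"
            families[fid] = _family(fid, kind, per_family[i], design.n_snps)
    return PedigreeSet(
        families,
        snp_ids,
        ["1"] * design.n_snps,
        [1000 * (i + 1) for i in range(design.n_snps)],
    )


def simulate_ped_files(design: SimDesign, prefix) -> tuple[Path, Path]:
    """Write the design as PLINK .ped/.map files (missingness applied
    when the design requests it)."""
    from .pedio import write_ped_files

    peds = simulate_pedigrees(design)
    if design.missingness > 0:
        peds = apply_missingness(
            peds, design.missingness, np.random.default_rng(design.seed + 1)
        )
    return write_ped_files(peds, prefix)


def apply_missingness(
    peds: PedigreeSet, p: float, rng: np.random.Generator
) -> PedigreeSet:
    """Blank each individual genotype call independently with
    probability ``p``; returns a new PedigreeSet."""
    if not (0 <= p <= 1):
        raise ValueError("missingness probability must lie in [0, 1]")
    out = peds.copy()
    if p == 0:
        return out
    for ind in out.individuals():
        mask = rng.random(peds.n_snps) < p
        ind.genotypes[mask] = MISSING_ALLELE
    return out


def simulate_case_trios_rejection(
    n: int,
    rp: RiskParams,
    q: float,
    alpha: float,
    rng: np.random.Generator,
) -> CountTable:
    """Cross-check oracle: sample case trios by explicit rejection.

    Draw parental genotypes at Hardy-Weinberg proportions, transmit
    phased alleles, apply penetrance ``alpha x (risk multipliers)`` and
    keep affected children only.  The resulting 15-cell counts converge
    to the same distribution the direct sampler uses, for any valid
    ``alpha`` (it cancels); kept as an independent validation path.
    """
    max_mult = max(
        (1.0, rp.R1, rp.R2)[c.gc]
        * (1.0, rp.S1, rp.S2)[c.gm]
        * rp.gamma_at(c.gm, c.gc)
        * max(rp.Im, rp.Ip, 1.0)
        for c in _CELLS
    )
    if alpha * max_mult > 1.0:
        raise ValueError("alpha too large: penetrance exceeds 1 for some cell")
    counts = np.zeros(15, dtype=int)
    index = {(c.gm, c.gf, c.gc): c.index - 1 for c in _CELLS}
    kept = 0
    while kept < n:
        gm, gf = rng.binomial(2, q), rng.binomial(2, q)
        a = rng.random() < gm / 2.0  # maternal allele is the risk allele
        b = rng.random() < gf / 2.0
        gc = int(a) + int(b)
        pen = (
            alpha
            * (1.0, rp.R1, rp.R2)[gc]
            * (1.0, rp.S1, rp.S2)[gm]
            * rp.gamma_at(gm, gc)
        )
        if gc == 1:
            pen *= rp.Im if a else rp.Ip
        if rng.random() < pen:
            counts[index[(gm, gf, gc)]] += 1
            kept += 1
    return CountTable(UnitType.CASE_PARENT_TRIO, tuple(counts))
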