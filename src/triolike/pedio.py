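"""PLINK-format pedigree parsing and per-SNP sub-unit extraction.

This module plays the pedigree-preprocessing role: it reads
whitespace-delimited .ped/.map text files, and for each SNP selects from
each family the most informative child-parent sub-unit (in the fixed
preference order of :class:`~triolike.cells.UnitType`), recodes
genotypes to risk-allele counts, estimates allele frequencies from
founders, and reads/writes the canonical count and marker files consumed
by the analysis side.

Extraction is per-SNP: a family may contribute a full trio at one SNP
and a mother duo at another, driven purely by which genotypes are
missing.  Mendelian-inconsistent trios/duos are dropped at the offending
SNP only and tallied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .cells import MISSING, UnitType, cell_index, collapse_map
from .likelihood import CountTable

__all__ = [
    "Individual",
    "MarkerInfo",
    "PedigreeSet",
    "ExtractionLog",
    "read_pedigrees",
    "write_ped_files",
    "assign_risk_allele",
    "extract_units",
    "extract_count_tables",
    "estimate_allele_frequency",
    "write_count_files",
    "read_count_files",
    "write_marker_file",
    "read_marker_file",
]

logger = logging.getLogger(__name__)

NULL_ID = "0"
MISSING_ALLELE = "0"

AFFECTED, UNAFFECTED, UNKNOWN = 2, 1, 0


@dataclass
class Individual:
    """One pedigree member with per-SNP allele pairs.

    ``genotypes`` has shape (n_snps, 2); a pair with either allele
    missing ('0') is wholly missing.
    """

    fid: str
    iid: str
    father: str
    mother: str
    sex: int
    phenotype: int  # AFFECTED / UNAFFECTED / UNKNOWN
    genotypes: np.ndarray

    def allele_pair(self, snp: int) -> tuple[str, str]:
        a, b = self.genotypes[snp]
        return str(a), str(b)

    def genotype_code(self, snp: int, risk_allele: str) -> int:
        """Risk-allele count at a SNP, or MISSING for half/no-calls."""
        a, b = self.genotypes[snp]
        if a == MISSING_ALLELE or b == MISSING_ALLELE:
            return MISSING
        return int(a == risk_allele) + int(b == risk_allele)

    @property
    def is_founder(self) -> bool:
        return self.father == NULL_ID and self.mother == NULL_ID


@dataclass(frozen=True)
class MarkerInfo:
    """Per-SNP marker metadata and the risk-allele choice."""

    snp_id: str
    chrom: str = "0"
    position: int = 0
    alleles: tuple[str, ...] = ()
    risk_allele: str = ""
    frequency: float = float("nan")

    @property
    def polymorphic(self) -> bool:
        return len(self.alleles) == 2


@dataclass
class PedigreeSet:
    """Parsed pedigree collection: families (insertion-ordered) plus the
    map-file marker list."""

    families: dict[str, list[Individual]]
    snp_ids: list[str]
    chroms: list[str]
    positions: list[int]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def individuals(self) -> Iterable[Individual]:
        for members in self.families.values():
            yield from members

    def copy(self) -> "PedigreeSet":
        fams = {
            fid: [
                Individual(
                    m.fid, m.iid, m.father, m.mother, m.sex, m.phenotype,
                    m.genotypes.copy(),
                )
                for m in members
            ]
            for fid, members in self.families.items()
        }
        return PedigreeSet(fams, list(self.snp_ids), list(self.chroms), list(self.positions))


def read_pedigrees(ped_path, map_path) -> PedigreeSet:
    """Parse PLINK text .ped/.map files.

    Phenotype coding: 2 -> affected, 1 -> unaffected, 0/-9 -> unknown.
    Errors name the offending line.
    """
    snp_ids, chroms, positions = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (3, 4):
                raise ValueError(
                    f"{map_path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
                )
            chroms.append(fields[0])
            snp_ids.append(fields[1])
            positions.append(int(fields[-1]))
    n_snps = len(snp_ids)

    families: dict[str, list[Individual]] = {}
    seen: set[tuple[str, str]] = set()
    expected = 6 + 2 * n_snps
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != expected:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {expected} columns "
                    f"(6 + 2 x {n_snps} SNPs), got {len(fields)}"
                )
            fid, iid, father, mother, sex_s, phen_s = fields[:6]
            if (fid, iid) in seen:
                raise ValueError(f"{ped_path}:{lineno}: duplicate individual {fid} {iid}")
            seen.add((fid, iid))
            phen = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}.get(phen_s)
            if phen is None:
                raise ValueError(f"{ped_path}:{lineno}: bad phenotype code {phen_s!r}")
            geno = np.array(fields[6:], dtype="U8").reshape(n_snps, 2)
            # half-calls are wholly missing
            half = (geno == MISSING_ALLELE).any(axis=1)
            geno[half] = MISSING_ALLELE
            families.setdefault(fid, []).append(
                Individual(fid, iid, father, mother, int(sex_s), phen, geno)
            )
    return PedigreeSet(families, snp_ids, chroms, positions)


def write_ped_files(peds: PedigreeSet, prefix) -> tuple[Path, Path]:
    """Write a PedigreeSet as <prefix>.ped and <prefix>.map."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for chrom, sid, pos in zip(peds.chroms, peds.snp_ids, peds.positions):
            fh.write(f"{chrom}\t{sid}\t0\t{pos}\n")
    phen_code = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}
    with open(ped_path, "w") as fh:
        for members in peds.families.values():
            for m in members:
                row = [m.fid, m.iid, m.father, m.mother, str(m.sex), phen_code[m.phenotype]]
                row.extend(m.genotypes.ravel().tolist())
                fh.write(" ".join(row) + "\n")
    return ped_path, map_path


def assign_risk_allele(
    snp_id: str,
    allele_counts: Mapping[str, int],
    override: Optional[str] = None,
    chrom: str = "0",
    position: int = 0,
) -> MarkerInfo:
    """Choose the risk allele (minor by count unless overridden).

    An exact 50/50 tie picks the lexicographically smaller label (a
    documented local convention, logged).  Monomorphic SNPs yield a
    MarkerInfo with ``polymorphic`` False and no risk allele.
    """
    observed = {a: c for a, c in allele_counts.items() if c > 0 and a != MISSING_ALLELE}
    alleles = tuple(sorted(observed))
    if override is not None:
        if override not in observed:
            raise ValueError(
                f"{snp_id}: override allele {override!r} not observed "
                f"(alleles: {alleles})"
            )
        risk = override
    elif len(alleles) < 2:
        return MarkerInfo(snp_id, chrom, position, alleles, "", float("nan"))
    else:
        a, b = alleles
        if observed[a] == observed[b]:
            risk = min(a, b)
            logger.info("%s: allele-count tie, choosing %r by label order", snp_id, risk)
        else:
            risk = a if observed[a] < observed[b] else b
    total = sum(observed.values())
    freq = observed[risk] / total if total else float("nan")
    return MarkerInfo(snp_id, chrom, position, alleles, risk, freq)


def estimate_allele_frequency(
    peds: PedigreeSet, snp: int, risk_allele: str
) -> float:
    """Risk-allele frequency from founder allele counts.

    Falls back (with a warning) to all individuals when no founder is
    genotyped at the SNP.
    """
    def freq_over(people: Iterable[Individual]) -> tuple[int, int]:
        risk = total = 0
        for ind in people:
            g = ind.genotype_code(snp, risk_allele)
            if g != MISSING:
                risk += g
                total += 2
        return risk, total

    risk, total = freq_over(p for p in peds.individuals() if p.is_founder)
    if total == 0:
        logger.warning("SNP %s: no genotyped founders; using all individuals", snp)
        risk, total = freq_over(peds.individuals())
        if total == 0:
            return float("nan")
    return risk / total


# ---------------------------------------------------------------------------
# sub-unit extraction

_DUO_INCONSISTENT = {(2, 0), (0, 2)}  # parent-child risk-count pairs


def _is_control(ind: Individual, unknown_as_control: bool) -> bool:
    return ind.phenotype == UNAFFECTED or (
        unknown_as_control and ind.phenotype == UNKNOWN
    )


def extract_units(
    family: Sequence[Individual],
    snp: int,
    risk_allele: str,
    proband: Optional[str] = None,
    multiple: bool = False,
    unknown_as_control: bool = False,
) -> tuple[list[tuple[UnitType, tuple[int, ...]]], int]:
    """Select the most informative sub-unit(s) from one family at a SNP.

    Returns ``(units, n_inconsistent)`` where each unit is a
    (UnitType, observed genotype tuple) pair, the tuple in the unit's
    ``observed`` member order.  A Mendelian-inconsistent trio or duo
    discards the family's contribution at this SNP (counted, not
    raised).  With ``multiple`` set, every constructible case/parent
    trio (or, failing that, control mating) is emitted; otherwise
    exactly one unit per family.  ``proband`` restricts the case
    candidates to the named individual.
    """
    by_id = {ind.iid: ind for ind in family}

    def code(ind: Optional[Individual]) -> int:
        if ind is None:
            return MISSING
        return ind.genotype_code(snp, risk_allele)

    def parents(ind: Individual) -> tuple[Optional[Individual], Optional[Individual]]:
        return by_id.get(ind.mother), by_id.get(ind.father)

    cases = [ind for ind in family if ind.phenotype == AFFECTED]
    if proband is not None:
        cases = [ind for ind in cases if ind.iid == proband]
    controls = [ind for ind in family if _is_control(ind, unknown_as_control)]

    def consistent_trio(gm: int, gf: int, gc: int) -> bool:
        try:
            cell_index(gm, gf, gc)
            return True
        except ValueError:
            return False

    # --- case units, in preference order -----------------------------------
    trios: list[tuple[UnitType, tuple[int, ...]]] = []
    n_bad = 0
    for child in cases:
        mo, fa = parents(child)
        gm, gf, gc = code(mo), code(fa), code(child)
        if gm != MISSING and gf != MISSING and gc != MISSING:
            if consistent_trio(gm, gf, gc):
                trios.append((UnitType.CASE_PARENT_TRIO, (gm, gf, gc)))
            else:
                n_bad += 1
    if trios and multiple:
        return trios, n_bad
    if n_bad:
        return [], n_bad  # inconsistency discards the family at this SNP
    if trios:
        return trios[:1], 0

    for kind, members in (
        (UnitType.CASE_MOTHER_DUO, "mc"),
        (UnitType.CASE_FATHER_DUO, "fc"),
        (UnitType.CASE, "c"),
        (UnitType.CASE_PARENTAL_MATING, "mf"),
        (UnitType.CASE_MOTHER, "m"),
        (UnitType.CASE_FATHER, "f"),
    ):
        for child in cases:
            mo, fa = parents(child)
            got = {"m": code(mo), "f": code(fa), "c": code(child)}
            if any(got[w] == MISSING for w in members):
                continue
            # members outside the unit must be unobserved, or a higher-
            # preference unit would have matched already; no check needed
            obs = tuple(got[w] for w in members)
            if kind in (UnitType.CASE_MOTHER_DUO, UnitType.CASE_FATHER_DUO):
                if (obs[0], obs[1]) in _DUO_INCONSISTENT:
                    return [], 1
            return [(kind, obs)], 0

    # --- control units ------------------------------------------------------
    matings: list[tuple[UnitType, tuple[int, ...]]] = []
    for child in controls:
        mo, fa = parents(child)
        gm, gf = code(mo), code(fa)
        if gm != MISSING and gf != MISSING:
            matings.append((UnitType.CONTROL_PARENTAL_MATING, (gm, gf)))
    if matings:
        return (matings, 0) if multiple else (matings[:1], 0)

    for kind, members in (
        (UnitType.CONTROL_MOTHER_DUO, "mc"),
        (UnitType.CONTROL_FATHER_DUO, "fc"),
        (UnitType.CONTROL, "c"),
    ):
        for child in controls:
            mo, fa = parents(child)
            got = {"m": code(mo), "f": code(fa), "c": code(child)}
            if any(got[w] == MISSING for w in members):
                continue
            obs = tuple(got[w] for w in members)
            if kind in (UnitType.CONTROL_MOTHER_DUO, UnitType.CONTROL_FATHER_DUO):
                if (obs[0], obs[1]) in _DUO_INCONSISTENT:
                    return [], 1
            return [(kind, obs)], 0
    return [], 0


@dataclass
class ExtractionLog:
    """Per-SNP tallies of dropped/unusable families."""

    inconsistent: dict[str, int] = field(default_factory=dict)
    unusable: dict[str, int] = field(default_factory=dict)
    monomorphic: list[str] = field(default_factory=list)


def extract_count_tables(
    peds: PedigreeSet,
    proband: Optional[Mapping[str, str]] = None,
    multiple: bool = False,
    unknown_as_control: bool = False,
    risk_allele_override: Optional[Mapping[str, str]] = None,
) -> tuple[dict[str, dict[UnitType, CountTable]], list[MarkerInfo], ExtractionLog]:
    """Run extraction over every SNP and family.

    Returns per-SNP count tables (only unit kinds with units present),
    per-SNP marker info (risk allele + founder-based frequency), and an
    extraction log.  ``proband`` maps family id -> individual id;
    ``risk_allele_override`` maps SNP id -> allele label.
    """
    proband = proband or {}
    risk_allele_override = risk_allele_override or {}
    combo_pos = {
        kind: {obs: k for k, (obs, _) in enumerate(collapse_map(kind).combinations)}
        for kind in UnitType
    }
    tables: dict[str, dict[UnitType, CountTable]] = {}
    markers: list[MarkerInfo] = []
    log = ExtractionLog()

    for snp, sid in enumerate(peds.snp_ids):
        counts: dict[str, int] = {}
        for ind in peds.individuals():
            if not ind.is_founder:
                continue
            a, b = ind.allele_pair(snp)
            if a != MISSING_ALLELE:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
        if not counts:  # no genotyped founders: count everyone
            for ind in peds.individuals():
                a, b = ind.allele_pair(snp)
                if a != MISSING_ALLELE:
                    counts[a] = counts.get(a, 0) + 1
                    counts[b] = counts.get(b, 0) + 1
        marker = assign_risk_allele(
            sid,
            counts,
            override=risk_allele_override.get(sid),
            chrom=peds.chroms[snp],
            position=peds.positions[snp],
        )
        markers.append(marker)
        if not marker.polymorphic:
            log.monomorphic.append(sid)
            continue

        acc: dict[UnitType, np.ndarray] = {}
        n_bad = n_unusable = 0
        for fid, family in peds.families.items():
            units, bad = extract_units(
                family,
                snp,
                marker.risk_allele,
                proband=proband.get(fid),
                multiple=multiple,
                unknown_as_control=unknown_as_control,
            )
            n_bad += bad
            if not units and not bad:
                n_unusable += 1
            for kind, obs in units:
                if kind not in acc:
                    acc[kind] = np.zeros(len(collapse_map(kind)), dtype=int)
                acc[kind][combo_pos[kind][obs]] += 1
        if n_bad:
            log.inconsistent[sid] = n_bad
            logger.info("SNP %s: dropped %d Mendelian-inconsistent unit(s)", sid, n_bad)
        if n_unusable:
            log.unusable[sid] = n_unusable
        tables[sid] = {
            kind: CountTable(kind, tuple(vec)) for kind, vec in acc.items()
        }
    return tables, markers, log


# ---------------------------------------------------------------------------
# canonical file formats (all plain text, tab-separated)

def _count_file_name(kind: UnitType) -> str:
    return f"counts_{kind.name.lower()}.txt"


def write_count_files(
    tables: Mapping[str, Mapping[UnitType, CountTable]],
    outdir,
    snp_order: Optional[Sequence[str]] = None,
) -> list[Path]:
    """Write one file per unit type: SNP id then counts in canonical
    combination order (a header comment documents the columns)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snp_order = list(snp_order) if snp_order is not None else list(tables)
    kinds = sorted(
        {k for per_snp in tables.values() for k in per_snp},
        key=lambda k: k.preference,
    )
    paths = []
    for kind in kinds:
        path = outdir / _count_file_name(kind)
        cmap = collapse_map(kind)
        with open(path, "w") as fh:
            fh.write(f"# unit: {kind.name.lower()}\n")
            fh.write("# columns: snp_id\t" + "\t".join(cmap.labels) + "\n")
            for sid in snp_order:
                table = tables.get(sid, {}).get(kind)
                counts = table.counts if table is not None else (0,) * len(cmap)
                fh.write(sid + "\t" + "\t".join(map(str, counts)) + "\n")
        paths.append(path)
    return paths


def read_count_files(indir) -> dict[str, dict[UnitType, CountTable]]:
    """Read back every count file in a directory (inverse of
    :func:`write_count_files`)."""
    indir = Path(indir)
    tables: dict[str, dict[UnitType, CountTable]] = {}
    for kind in UnitType:
        path = indir / _count_file_name(kind)
        if not path.exists():
            continue
        expected = len(collapse_map(kind))
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.split()
                if len(fields) != 1 + expected:
                    raise ValueError(
                        f"{path}:{lineno}: expected 1 + {expected} fields, "
                        f"got {len(fields)}"
                    )
                sid = fields[0]
                tables.setdefault(sid, {})[kind] = CountTable(
                    kind, tuple(int(x) for x in fields[1:])
                )
    return tables


def write_marker_file(markers: Sequence[MarkerInfo], path) -> Path:
    """Write the marker file: SNP id, risk allele, risk-allele frequency."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# columns: snp_id\trisk_allele\tfrequency\n")
        for m in markers:
            risk = m.risk_allele or "NA"
            freq = "NA" if np.isnan(m.frequency) else f"{m.frequency:.6f}"
            fh.write(f"{m.snp_id}\t{risk}\t{freq}\n")
    return path


def read_marker_file(path) -> dict[str, MarkerInfo]:
    """Read a marker file back into MarkerInfo keyed by SNP id."""
    out: dict[str, MarkerInfo] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            sid, risk, freq_s = fields
            freq = float("nan") if freq_s == "NA" else float(freq_s)
            risk = "" if risk == "NA" else risk
            out[sid] = MarkerInfo(sid, risk_allele=risk, frequency=freq)
    return out
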