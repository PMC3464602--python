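"""Independent brute-force oracles for the trio model tests.

Everything here is computed by explicit enumeration over parental
genotype pairs and phased allele transmissions, deliberately sharing no
code with the package's vectorised cell-probability construction.
"""

from fractions import Fraction


def _penetrance(rp, gm, gc, maternal_risk):
    """Risk multipliers for one phased configuration (no baseline)."""
    pen = 1.0
    if gc == 1:
        pen *= rp.R1
    elif gc == 2:
        pen *= rp.R2
    if gm == 1:
        pen *= rp.S1
    elif gm == 2:
        pen *= rp.S2
    pen *= rp.gamma_at(gm, gc)
    if gc == 1:
        pen *= rp.Im if maternal_risk else rp.Ip
    return pen


def _mating_weight(sp, gm, gf):
    """Population weight of an ordered parental genotype pair.

    HWE: product of Hardy-Weinberg genotype probabilities.  Mating-type
    stratifications: mu of the stratum times 2 per heterozygous parent
    (the stratification parameter is per phased parental configuration).
    """
    if sp.assumption == "HWE":
        q = sp.q
        hw = {0: (1 - q) ** 2, 1: 2 * q * (1 - q), 2: q**2}
        return hw[gm] * hw[gf]
    cepg_strata = {
        frozenset({(2, 2)}): 1,
        frozenset({(2, 1), (1, 2)}): 2,
        frozenset({(2, 0), (0, 2)}): 3,
        frozenset({(1, 1)}): 4,
        frozenset({(1, 0), (0, 1)}): 5,
        frozenset({(0, 0)}): 6,
    }
    cpg_strata = {
        (2, 2): 1, (2, 1): 2, (1, 2): 3, (2, 0): 4, (0, 2): 5,
        (1, 1): 6, (1, 0): 7, (0, 1): 8, (0, 0): 9,
    }
    if sp.assumption == "CPG":
        t = cpg_strata[(gm, gf)]
    else:
        t = next(v for k, v in cepg_strata.items() if (gm, gf) in k)
    n_het = (gm == 1) + (gf == 1)
    return sp.mu[t - 1] * 2**n_het


def case_cell_probs_bruteforce(rp, sp):
    """P(gm, gf, gc | child affected) by direct Bayes enumeration.

    Enumerates ordered parental pairs with their population weights and
    all four phased allele transmissions, multiplies by the penetrance
    multipliers, and normalises.  Returns a dict keyed by (gm, gf, gc).
    """
    probs = {}
    for gm in (0, 1, 2):
        for gf in (0, 1, 2):
            w = _mating_weight(sp, gm, gf)
            maternal_alleles = [1] * gm + [0] * (2 - gm)
            paternal_alleles = [1] * gf + [0] * (2 - gf)
            for a in maternal_alleles:
                for b in paternal_alleles:
                    gc = a + b
                    contrib = w * 0.25 * _penetrance(rp, gm, gc, maternal_risk=a == 1)
                    key = (gm, gf, gc)
                    probs[key] = probs.get(key, 0.0) + contrib
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def control_cell_probs_bruteforce(sp):
    """Population trio probabilities: enumeration with penetrance 1."""
    probs = {}
    for gm in (0, 1, 2):
        for gf in (0, 1, 2):
            w = _mating_weight(sp, gm, gf)
            for a in [1] * gm + [0] * (2 - gm):
                for b in [1] * gf + [0] * (2 - gf):
                    key = (gm, gf, a + b)
                    probs[key] = probs.get(key, 0.0) + w * 0.25
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def mendel_weight_enumeration(gm, gf, gc):
    """P(gc | gm, gf) by enumerating the four phased transmissions."""
    hits = total = 0
    for a in [1] * gm + [0] * (2 - gm):
        for b in [1] * gf + [0] * (2 - gf):
            total += 1
            hits += (a + b) == gc
    return Fraction(hits, total)
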