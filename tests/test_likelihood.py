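"""Cell probabilities, penetrance multipliers and log-likelihoods."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triolike import (
    CountTable,
    ModelSpec,
    RiskParams,
    StratParams,
    apply_constraints,
    case_trio_cell_probs,
    control_trio_cell_probs,
    penetrance_multiplier,
    total_log_likelihood,
    unit_log_likelihood,
)
from triolike.cells import UnitType, collapse_matrix, enumerate_trio_cells
from triolike.params import CHILD_MULTIPLICATIVE

from _oracles import case_cell_probs_bruteforce, control_cell_probs_bruteforce
from conftest import random_risk_params

CELLS = enumerate_trio_cells()


# --------------------------------------------------------------------------
# penetrance multipliers

def test_penetrance_maternal_transmission_example():
    """Mother 2 copies, father 0, het child: R1 * S2 * Im * gamma(2,1)."""
    rp = RiskParams(R1=1.5, S2=2.5, Im=1.8, gamma={(2, 1): 1.3})
    expected = 1.5 * 2.5 * 1.8 * 1.3
    assert penetrance_multiplier(2, 0, 1, "maternal", rp) == pytest.approx(expected)


def test_penetrance_identity_at_null_parameters():
    rp = RiskParams()
    for c in CELLS:
        if c.gc == 1:
            phases = {1: ["maternal"], 2: ["paternal"], 3: ["maternal", "paternal"]}
            for phase in ("maternal", "paternal"):
                try:
                    assert penetrance_multiplier(c.gm, c.gf, c.gc, phase, rp) == 1.0
                except ValueError:
                    pass  # phase impossible for this configuration
        else:
            assert penetrance_multiplier(c.gm, c.gf, c.gc, "none", rp) == 1.0


def test_penetrance_paternal_het_het():
    rp = RiskParams(R1=1.5, S1=1.2, Ip=0.7, gamma={(1, 1): 2.0})
    assert penetrance_multiplier(1, 1, 1, "paternal", rp) == pytest.approx(
        1.5 * 1.2 * 0.7 * 2.0
    )


@pytest.mark.parametrize(
    "gm,gf,gc,phase",
    [(2, 2, 2, "maternal"),      # homozygous child takes no phase
     (2, 0, 1, "paternal"),      # father carries no risk allele
     (0, 2, 1, "maternal"),      # mother carries no risk allele
     (1, 1, 1, "none")],         # het child needs a phase
)
def test_penetrance_invalid_phase_rejected(gm, gf, gc, phase):
    with pytest.raises(ValueError):
        penetrance_multiplier(gm, gf, gc, phase, RiskParams())


# --------------------------------------------------------------------------
# cell probabilities

def test_null_case_equals_control():
    sp = StratParams("HWE", q=0.37)
    assert case_trio_cell_probs(RiskParams(), sp) == pytest.approx(
        control_trio_cell_probs(sp)
    )


def test_hwe_half_frequency_het_het_het_cell():
    """q = 0.5, null risks: P(cell 9) = 0.5 * 0.5 * 0.5 = 0.125."""
    p = case_trio_cell_probs(RiskParams(), StratParams("HWE", q=0.5))
    assert p[8] == pytest.approx(0.125)


def test_control_all_reference_cell_is_one_minus_q_fourth():
    q = 0.3
    p = control_trio_cell_probs(StratParams("HWE", q=q))
    assert p[14] == pytest.approx((1 - q) ** 4)


def test_probabilities_sum_to_one_for_random_parameters(rng):
    for _ in range(25):
        rp = random_risk_params(rng)
        sp = StratParams("HWE", q=rng.uniform(0.05, 0.95))
        assert case_trio_cell_probs(rp, sp).sum() == pytest.approx(1.0)


@pytest.mark.parametrize("assumption", ["HWE", "CEPG", "CPG"])
def test_case_probs_match_bruteforce_bayes_enumeration(rng, assumption):
    """The vectorised construction equals direct enumeration of parental
    pairs x phased transmissions x penetrance, for random parameters."""
    for _ in range(30):
        rp = random_risk_params(rng)
        if assumption == "HWE":
            sp = StratParams("HWE", q=rng.uniform(0.05, 0.95))
        else:
            n = 9 if assumption == "CPG" else 6
            mu = np.exp(rng.normal(0, 0.5, size=n))
            mu[-1] = 1.0
            sp = StratParams(assumption, mu=tuple(mu))
        p = case_trio_cell_probs(rp, sp)
        oracle = case_cell_probs_bruteforce(rp, sp)
        for c, pi in zip(CELLS, p):
            assert pi == pytest.approx(oracle[(c.gm, c.gf, c.gc)], abs=1e-13)
        p0 = control_trio_cell_probs(sp)
        oracle0 = control_cell_probs_bruteforce(sp)
        for c, pi in zip(CELLS, p0):
            assert pi == pytest.approx(oracle0[(c.gm, c.gf, c.gc)], abs=1e-13)


def test_cepg_with_hwe_induced_mu_equals_hwe(rng):
    """mu_t = q^a (1-q)^(4-a) (a = parental risk alleles in stratum t,
    reference stratum scaled to 1) reproduces HWE exactly."""
    alleles_per_stratum = {1: 4, 2: 3, 3: 2, 4: 2, 5: 1, 6: 0}
    for q in (0.1, 0.3, 0.5, 0.8):
        mu = tuple(
            q ** alleles_per_stratum[t] * (1 - q) ** (4 - alleles_per_stratum[t])
            / (1 - q) ** 4
            for t in range(1, 7)
        )
        rp = random_risk_params(rng)
        np.testing.assert_allclose(
            case_trio_cell_probs(rp, StratParams("CEPG", mu=mu)),
            case_trio_cell_probs(rp, StratParams("HWE", q=q)),
            atol=1e-15,
        )


def test_mating_symmetry_under_cepg():
    """With Im = Ip and maternal/interaction effects off, swapping the
    parents permutes the probability vector onto itself."""
    rp = RiskParams(R1=1.4, R2=2.2, Im=1.5, Ip=1.5)
    sp = StratParams("CEPG", mu=(1.3, 0.8, 1.1, 0.9, 1.2, 1.0))
    p = case_trio_cell_probs(rp, sp)
    by_genotypes = {(c.gm, c.gf, c.gc): i for i, c in enumerate(CELLS)}
    for c, pi in zip(CELLS, p):
        j = by_genotypes[(c.gf, c.gm, c.gc)]
        assert pi == pytest.approx(p[j])


def test_increasing_a_risk_multiplier_raises_its_cells_mass(rng):
    """Monotonicity: raising R2 strictly increases the probability mass
    of the cells whose child carries two risk alleles; same for S2/Im."""
    sp = StratParams("HWE", q=0.3)
    gc2 = np.array([c.gc == 2 for c in CELLS])
    gm2 = np.array([c.gm == 2 for c in CELLS])
    base = case_trio_cell_probs(RiskParams(), sp)
    up_r = case_trio_cell_probs(RiskParams(R2=1.7), sp)
    up_s = case_trio_cell_probs(RiskParams(S2=1.7), sp)
    assert up_r[gc2].sum() > base[gc2].sum()
    assert up_s[gm2].sum() > base[gm2].sum()


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        RiskParams(R1=-1.0)
    with pytest.raises(ValueError):
        RiskParams(gamma={(0, 0): 2.0})
    with pytest.raises(ValueError):
        StratParams("HWE", q=1.5)
    with pytest.raises(ValueError):
        StratParams("CEPG", mu=(1.0, 1.0))
    with pytest.raises(ValueError):
        StratParams("PAE", mu=(1, 1, 0.5, 0.9, 1, 1))  # mu4 != mu3


# --------------------------------------------------------------------------
# log-likelihood

def test_unit_loglik_zero_counts_is_zero():
    table = CountTable(UnitType.CASE_PARENT_TRIO, (0,) * 15)
    p = case_trio_cell_probs(RiskParams(), StratParams("HWE", q=0.3))
    assert unit_log_likelihood(table, p) == 0.0


def test_unit_loglik_trio_is_direct_multinomial(rng):
    counts = tuple(rng.integers(0, 20, size=15))
    table = CountTable(UnitType.CASE_PARENT_TRIO, counts)
    p = case_trio_cell_probs(RiskParams(R2=1.5), StratParams("HWE", q=0.3))
    direct = sum(n * np.log(pi) for n, pi in zip(counts, p) if n)
    assert unit_log_likelihood(table, p) == pytest.approx(direct)


def test_mother_duo_combination_collapses_three_cells():
    """Count on combination (gm=1, gc=1) sees P5 + P9 + P11."""
    counts = [0] * 7
    counts[3] = 10  # combination 4 in canonical order
    table = CountTable(UnitType.CASE_MOTHER_DUO, tuple(counts))
    p = case_trio_cell_probs(RiskParams(S1=1.4), StratParams("HWE", q=0.3))
    expected = 10 * np.log(p[4] + p[8] + p[10])
    assert unit_log_likelihood(table, p) == pytest.approx(expected)


def test_unit_loglik_zero_probability_combination_is_minus_inf():
    table = CountTable(UnitType.CASE_PARENT_TRIO, (1,) + (0,) * 14)
    probs = np.zeros(15)
    probs[14] = 1.0
    assert unit_log_likelihood(table, probs) == -np.inf


def test_total_loglik_empty_and_single_table():
    rp, sp = RiskParams(R1=1.2), StratParams("HWE", q=0.4)
    assert total_log_likelihood([], rp, sp) == 0.0
    table = CountTable(UnitType.CASE_PARENT_TRIO, tuple(range(15)))
    assert total_log_likelihood([table], rp, sp) == pytest.approx(
        unit_log_likelihood(table, case_trio_cell_probs(rp, sp))
    )


def test_total_loglik_additive_over_split_tables(rng):
    """Splitting one trio table into two adds the same total."""
    counts = rng.integers(0, 30, size=15)
    first = rng.integers(0, counts + 1)
    t_all = CountTable(UnitType.CASE_PARENT_TRIO, tuple(counts))
    t_a = CountTable(UnitType.CASE_PARENT_TRIO, tuple(first))
    t_b = CountTable(UnitType.CASE_PARENT_TRIO, tuple(counts - first))
    rp, sp = RiskParams(R2=1.8, S1=1.2), StratParams("HWE", q=0.3)
    assert total_log_likelihood([t_a, t_b], rp, sp) == pytest.approx(
        total_log_likelihood([t_all], rp, sp)
    )


def test_collapsing_loses_information_but_preserves_probability(rng):
    """A trio table re-expressed as mother-duo counts changes the value
    of the likelihood (information loss) but the collapsed probabilities
    are the exact marginal sums of their member cells."""
    rp, sp = random_risk_params(rng), StratParams("HWE", q=0.3)
    p = case_trio_cell_probs(rp, sp)
    collapsed = collapse_matrix(UnitType.CASE_MOTHER_DUO) @ p
    assert collapsed.sum() == pytest.approx(1.0)
    # spot-check each combination against summed member cells
    from triolike.cells import collapse_map

    for (obs, group), cp in zip(
        collapse_map(UnitType.CASE_MOTHER_DUO).combinations, collapsed
    ):
        assert cp == pytest.approx(sum(p[i - 1] for i in group))


# --------------------------------------------------------------------------
# constraints

def test_child_multiplicative_constraint():
    spec = ModelSpec("HWE", free_risk=("R1",), constraints=frozenset({CHILD_MULTIPLICATIVE}))
    rp, sp = apply_constraints(spec, [1.5, 0.3])
    assert rp.R2 == pytest.approx(1.5**2)
    assert sp.q == pytest.approx(0.3)


def test_pae_ties_mu4_to_mu3():
    spec = ModelSpec("PAE", free_risk=())
    rp, sp = apply_constraints(spec, [1.1, 0.9, 0.7, 1.2])
    assert sp.mu[3] == sp.mu[2] == pytest.approx(0.7)
    assert sp.mu[5] == 1.0  # reference stratum


def test_no_constraints_identity_embedding():
    spec = ModelSpec("HWE", free_risk=("R1", "R2"))
    rp, sp = apply_constraints(spec, [1.5, 2.25, 0.25])
    assert (rp.R1, rp.R2, sp.q) == pytest.approx((1.5, 2.25, 0.25))
    assert rp.S1 == rp.S2 == rp.Im == rp.Ip == 1.0


def test_free_vector_length_mismatch_rejected():
    with pytest.raises(ValueError):
        apply_constraints(ModelSpec("HWE", free_risk=("R1",)), [1.5])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    r1=st.floats(0.3, 3.0), r2=st.floats(0.3, 3.0),
    s1=st.floats(0.3, 3.0), q=st.floats(0.05, 0.95),
)
def test_property_case_probs_valid_distribution(r1, r2, s1, q):
    p = case_trio_cell_probs(
        RiskParams(R1=r1, R2=r2, S1=s1), StratParams("HWE", q=q)
    )
    assert np.all(p > 0)
    assert p.sum() == pytest.approx(1.0)
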