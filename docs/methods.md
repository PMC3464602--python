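# Methods

## Model

At a biallelic SNP with genotypes coded as risk-allele counts, a child's
probability of disease is modelled as a product of multiplicative
relative risks acting on a baseline penetrance α:

- `R1`, `R2` — the child carries one / two risk alleles;
- `S1`, `S2` — the child's mother carries one / two risk alleles
  (maternal genotype effects act regardless of transmission);
- `Im`, `Ip` — a heterozygous child's risk allele was inherited from the
  mother / father (parent-of-origin imprinting);
- `γ(i, j)` — the mother carries i and the child j risk alleles
  (mother–child interaction), with `γ(0, 0) = 1` as reference. The grid
  covers the classical interaction parameters `γ11, γ12, γ21, γ22` as
  well as the incompatibility-type parameters `γ01` (RhD-style:
  mother 0 copies, child 1) and `γ10` (NIMA-style: mother 1 copy, child
  0) without a separate parameterisation. The NIMA model can
  equivalently be fitted as `γ12` with respect to the reassigned
  (swapped) risk allele; this equivalence is a regression test, not a
  code path.

α is not a parameter of the package: conditional on the child being
affected, it cancels in the multinomial normalisation, which is why only
*relative* risks are identifiable from this design.

Imprinting factors apply only to heterozygous children and are keyed to
the parental origin of the single risk allele. A homozygous child
carries neither factor (the alternative convention — counting a
maternally received allele in `gc = 2` children — would confound
`Im · Ip` with `R2`). The one phase-ambiguous configuration
(het × het → het) receives the phase average `(Im + Ip) / 2`, since
both transmission paths are equally likely a priori.

### Cell probabilities and stratification

The 15 Mendelian-consistent trio configurations `(gm, gf, gc)` follow a
multinomial with

    P(cell i | affected)  ∝  base_i · pen_i,

where `pen_i` is the product of the applicable risk multipliers and
`base_i` is the population probability structure:

- **HWE**: `base_i = P_HWE(gm) · P_HWE(gf) · w_i`, with `w_i = P(gc |
  gm, gf)` the Mendelian segregation probability and a single free
  allele frequency `q`;
- **CEPG / PAE**: `base_i = μ_t(i) · κ_i` over the six unordered
  parental mating types;
- **CPG**: the same over the nine ordered mating types.

`κ_i` is the *transmission count* — the number of phased transmissions
producing `gc` (2 for the het × het → het cell, 1 otherwise), i.e.
`w_i · 2^{#het parents}`. With this scaling the stratification
parameters induced by Hardy-Weinberg proportions are
`μ_t ∝ q^a (1-q)^{4-a}` with `a` the number of risk alleles carried by
the parental pair; they depend on `a` alone, so the parental allelic
exchangeability (PAE) assumption is exactly the single constraint
`μ4 = μ3` (the two strata with `a = 2`), and the nesting
HWE ⊂ PAE ⊂ CEPG ⊂ CPG holds. Scaling by the Mendelian weight instead
of the transmission count would be an equivalent reparameterisation of
CEPG/CPG/HWE but would break that correspondence for PAE, which is why
the transmission-count convention is used.

One stratification parameter (the all-reference stratum: `μ6` under
CEPG/PAE, `μ9` under CPG) is fixed at 1; the explicit normalisation over
the 15 cells absorbs the remaining scale.

Control units are assigned the population cell probabilities
(`pen ≡ 1`), i.e. control genotype frequencies are assumed to match the
general population — exact for population-based controls of unknown
status, a rare-disease approximation for screened controls.

### Collapsing

A sub-unit with unobserved members observes a marginal of the 15-cell
table. The collapse map of each of the 11 unit kinds (trio, mother/
father duos, parental matings, single parents, singletons, and their
control counterparts) is generated programmatically by grouping cells on
the observed members' genotypes; the canonical combination order is
descending genotype counts, which reproduces the conventional 7-row
mother-duo table (that table is kept as a regression test rather than a
second source of truth). Collapsed probabilities are exact sums of
member-cell probabilities, so each collapsed vector sums to 1 and needs
no renormalisation (asserted). The total log-likelihood at a SNP is the
sum over all unit tables, case tables using the disease-conditional
vector and control tables the population vector, sharing one set of
stratification parameters.

Zero counts contribute exactly 0 (no pseudo-counts); a positive count on
a zero-probability combination yields −∞, which the optimiser treats as
a rejected point.

## Estimation

All positive parameters are optimised on the log scale (the allele
frequency on the logit scale), making the search unconstrained and
positivity automatic. Constraints (`R2 = R1²`, `S2 = S1²`, `μ4 = μ3`)
are applied by expansion of the free vector, so estimates satisfy them
exactly. Maximisation uses L-BFGS-B with tight tolerances
(`ftol = 1e-13`, `gtol = 1e-7`, ≤ 500 iterations) so likelihood-ratio
statistics are stable to well beyond 4 decimals; fits are deterministic
given (tables, specification, start). Default starts are 1 for every
multiplier and the marker-file allele frequency (fallback 0.5) for `q`.

Standard errors come from the inverse of a central-difference Hessian
(step 1e-4 on the internal scale) at the optimum,
delta-method-transformed to the natural scale; a singular or indefinite
Hessian degrades gracefully to absent SEs. Estimates whose internal
value exceeds `|log θ| > log 1e6` are flagged as boundary solutions; no
boundary correction is attempted and the likelihood-ratio statistic is
simply clipped at 0 and referred to the plain χ² distribution. Raw
p-values are reported; no multiple-testing adjustment is applied.

Identifiability: the number of jointly estimable relative-risk
parameters is computed as a generic-rank property — starting from the
stratification parameters, risk parameters are added greedily, accepting
an addition only when the numerical rank (singular values above
1e-8 × the largest) of the Jacobian of the 15-cell probability map
increases by one, at a fixed randomised interior point. For complete
trio data the count saturates at 7, which is why model building should
proceed from simpler to richer models by nested tests rather than
fitting everything at once.

## Extraction

Pedigrees are read from whitespace-delimited PLINK text .ped/.map files
(phenotype 2 = affected, 1 = unaffected, 0/−9 = unknown; a half-called
genotype is wholly missing). For each SNP and each family, the single
most informative sub-unit is selected in the fixed preference order
(case/parent trio, case/mother duo, case/father duo, case, case parental
mating, case mother, case father, control parental mating, control/
mother duo, control/father duo, control); extraction is per-SNP, so the
same family can contribute different unit types at different SNPs purely
through missingness. When several affected children exist, the first in
file order anchors the unit unless a proband is named; an optional mode
emits every constructible case/parent trio (or control mating) from a
large family, with the usual caveat that this can bias estimates under
some analysis options.

The risk allele defaults to the minor allele by sample count (founders
preferred), with an exact tie broken toward the lexicographically
smaller label — a documented local convention chosen for determinism.
Allele frequencies are estimated from founder allele counts (individuals
without parents in the pedigree), avoiding transmission-induced
dependence; if no founder is genotyped the estimate falls back to all
individuals with a warning. Mendelian-inconsistent trios and duos are
dropped at the offending SNP only (the family still contributes at other
SNPs) and tallied in the extraction log.

Models closed under allele reversal (e.g. free `R1, R2, S1, S2`) attain
identical maximised log-likelihoods under either risk-allele choice;
this recoding invariance is exercised in the tests.

## Simulator

The generator emulates the study conditions of the validation
experiments: mixtures of the 11 unit kinds at one or more independent
SNPs, a shared risk-allele frequency, effect parameters at designated
causal SNPs, and optional per-genotype missingness. Case units are
sampled directly from the disease-conditional collapsed cell
probabilities — exact, fast, and free of the unidentifiable baseline α.
A rejection-sampling path with an explicit α exists as an independent
cross-check oracle and agrees with the direct sampler in distribution.

Families are materialised by expanding the sampled count tables
deterministically, so extraction of the written .ped/.map files
reproduces the generating tables count-for-count at missingness 0 (a
tested invariant). Unobserved members of partial units are written with
missing genotypes; alleles are emitted as A (risk) / G with the risk
allele minor by construction. Defaults follow the validation designs:
allele frequency `q = 0.3` (the single-SNP experiments do not pin this
value elsewhere, so it is fixed once here and used throughout), unit
mixes of 50 per type for the six-unit likelihood-comparison design, 200
trios for the interaction designs, and the 200/200/200/1000 genome-scan
mix.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (each SNP is independent, so multi-SNP runs exercise bookkeeping,
not regional signal structure), genotyping error (missingness is
independent Bernoulli blanking, not error-prone calling), population
stratification or assortative mating (data are generated under HWE and
random mating — the CEPG/CPG robustness assumptions can be *fitted* but
departures from them are not generated), and ascertainment beyond
affected-child/control-child sampling. Passing recovery tests therefore
demonstrate correctness of the likelihood machinery under the stated
sampling model, not robustness to the real-data complications above.

## Replication experiments

The recovery experiments (run by `scripts/acceptance.py` and, at 500
replicates, by the test suite) refit each simulated replicate under HWE
and summarise the replicate estimates by the **mean on the estimation
(log) scale** — the geometric mean. Relative-risk MLEs at these unit
counts have strongly right-skewed sampling distributions (e.g. for a
two-copy maternal effect of 2.0 at 50 units per type, the arithmetic
mean over 1000 replicates is ≈ 2.29 while the log-scale mean and median
are ≈ 1.97); the log-scale mean is the summary on the scale the
parameters are estimated and displayed on, and it is the statistic for
which "unbiased recovery" is the correct description of the estimator's
behaviour. Replicates whose optimiser fails to converge (rare, < 1%)
are excluded from the summary.

Problem sizes: 1000 replicates for the six-unit mixed designs, 500 for
the trio-only interaction designs and the genome-scan mix — sizes chosen
so Monte-Carlo standard errors are a few percent of the estimates.

## Known limitations

- Nuclear-family sub-units only; larger pedigrees contribute through
  extracted trios/duos rather than a joint pedigree likelihood.
- Autosomal, biallelic markers; no X-chromosome or sex-specific risk
  models, no multi-allelic support.
- Single-SNP analyses; no haplotype or multi-marker modelling.
- Boundary MLEs (e.g. an interaction estimate collapsing toward 0) are
  flagged, not corrected; χ² reference p-values are anti-conservative in
  that regime.
- Text .ped/.map only; binary PLINK files should be converted upstream.
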