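"""Maximum-likelihood fitting of the trio multinomial model.

``TrioModel`` bundles the unit count tables observed at one SNP with a
``ModelSpec`` (which relative risks to estimate, under which
stratification assumption); ``fit`` maximises the total log-likelihood
over the free parameters and returns a ``TrioResults`` carrying
estimates, standard errors and diagnostics.  ``likelihood_ratio_test``
compares nested fits against the chi-squared reference.

All positive parameters are optimised on the log scale (the allele
frequency on the logit scale), making the search unconstrained and
positivity automatic.  Standard errors come from the inverse of a
central-difference Hessian at the optimum, delta-method-transformed back
to the natural scale; Hessian failure degrades gracefully to absent SEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .cells import collapse_matrix
from .likelihood import (
    CountTable,
    case_trio_cell_probs,
    control_trio_cell_probs,
)
from .params import (
    ModelSpec,
    RiskParams,
    StratParams,
    apply_constraints,
    RISK_PARAM_NAMES,
)

__all__ = [
    "TrioModel",
    "TrioResults",
    "TestResult",
    "fit",
    "likelihood_ratio_test",
    "max_estimable_risk_params",
]

_BOUNDARY_Z = math.log(1e6)  # |log estimate| beyond this flags a boundary


def _to_internal(names: Sequence[str], natural: Sequence[float]) -> np.ndarray:
    z = np.empty(len(names))
    for k, (name, v) in enumerate(zip(names, natural)):
        z[k] = math.log(v / (1 - v)) if name == "q" else math.log(v)
    return z


def _to_natural(names: Sequence[str], z: np.ndarray) -> np.ndarray:
    out = np.empty(len(names))
    for k, name in enumerate(names):
        if name == "q":
            out[k] = 1.0 / (1.0 + math.exp(-z[k]))
        else:
            out[k] = math.exp(z[k])
    return out


class TrioModel:
    """Trio multinomial likelihood for one SNP.

    Parameters
    ----------
    tables : sequence of CountTable
        Observed unit tables at the SNP (any mix of the 11 kinds).
    spec : ModelSpec
        Assumption, free risk parameters and constraints.
    freq_start : float, optional
        Starting value for the allele frequency under HWE (e.g. from a
        marker file); defaults to 0.5.
    """

    def __init__(
        self,
        tables: Sequence[CountTable],
        spec: ModelSpec,
        freq_start: Optional[float] = None,
    ):
        self.tables = tuple(tables)
        self.spec = spec
        self.freq_start = 0.5 if freq_start is None else float(freq_start)
        if not (0 < self.freq_start < 1):
            raise ValueError("freq_start must lie in (0, 1)")
        if not self.tables:
            raise ValueError("at least one count table is required")
        if all(t.n_units == 0 for t in self.tables):
            raise ValueError("all count tables are empty; nothing to fit")
        # precomputed per-table pieces for fast repeated evaluation
        self._parts = [
            (t.unit_kind.is_case, collapse_matrix(t.unit_kind), np.asarray(t.counts, float))
            for t in self.tables
            if t.n_units > 0
        ]
        self._names = spec.free_names

    @property
    def n_free(self) -> int:
        return len(self._names)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(self._names)

    def loglike(self, free_values: Sequence[float]) -> float:
        """Total log-likelihood at natural-scale free values
        (in ``spec.free_names`` order)."""
        rp, sp = apply_constraints(self.spec, free_values)
        need_case = any(is_case for is_case, _, _ in self._parts)
        need_ctrl = any(not is_case for is_case, _, _ in self._parts)
        case_p = case_trio_cell_probs(rp, sp) if need_case else None
        ctrl_p = control_trio_cell_probs(sp) if need_ctrl else None
        out = 0.0
        for is_case, cmat, counts in self._parts:
            collapsed = cmat @ (case_p if is_case else ctrl_p)
            active = counts > 0
            if np.any(collapsed[active] <= 0):
                return -np.inf
            out += float(counts[active] @ np.log(collapsed[active]))
        return out

    def _neg_loglike_internal(self, z: np.ndarray) -> float:
        ll = self.loglike(_to_natural(self._names, z))
        return 1e12 if not np.isfinite(ll) else -ll

    def default_start(self) -> np.ndarray:
        """Natural-scale default start: all multipliers 1, q from the
        marker frequency (fallback 0.5)."""
        return np.array(
            [self.freq_start if n == "q" else 1.0 for n in self._names]
        )

    def fit(
        self,
        start: Optional[Sequence[float]] = None,
        maxiter: int = 500,
    ) -> "TrioResults":
        """Maximise the log-likelihood; deterministic given inputs."""
        start_nat = self.default_start() if start is None else np.asarray(start, float)
        z0 = _to_internal(self._names, start_nat)
        res = optimize.minimize(
            self._neg_loglike_internal,
            z0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-7},
        )
        z = res.x
        llf = -res.fun
        converged = bool(res.success) and np.isfinite(llf)
        bse_internal = self._hessian_se(z) if converged else None
        natural = _to_natural(self._names, z)
        bse = None
        if bse_internal is not None:
            # delta method: d(theta)/d(log theta) = theta; dq/dlogit = q(1-q)
            scale = np.array(
                [v * (1 - v) if n == "q" else v for n, v in zip(self._names, natural)]
            )
            bse = bse_internal * scale
        return TrioResults(
            model=self,
            llf=float(llf),
            params_internal=z,
            params=dict(zip(self._names, natural)),
            bse=None if bse is None else dict(zip(self._names, bse)),
            converged=converged,
            iterations=int(res.nit),
            boundary=bool(np.any(np.abs(z) > _BOUNDARY_Z)),
        )

    def _hessian_se(self, z: np.ndarray, h: float = 1e-4) -> Optional[np.ndarray]:
        """Central-difference Hessian of -loglik; returns internal-scale
        SEs, or None when the Hessian is not usable."""
        n = len(z)
        f = self._neg_loglike_internal
        hess = np.empty((n, n))
        try:
            f0 = f(z)
            for i in range(n):
                ei = np.zeros(n)
                ei[i] = h
                hess[i, i] = (f(z + ei) - 2 * f0 + f(z - ei)) / h**2
                for j in range(i + 1, n):
                    ej = np.zeros(n)
                    ej[j] = h
                    hess[i, j] = hess[j, i] = (
                        f(z + ei + ej) - f(z + ei - ej) - f(z - ei + ej) + f(z - ei - ej)
                    ) / (4 * h**2)
            cov = np.linalg.inv(hess)
            var = np.diag(cov)
            if np.any(var <= 0) or not np.all(np.isfinite(var)):
                return None
            return np.sqrt(var)
        except np.linalg.LinAlgError:
            return None


@dataclass
class TrioResults:
    """Fit results: maximised log-likelihood, estimates, diagnostics."""

    model: TrioModel
    llf: float
    params_internal: np.ndarray
    params: dict[str, float]
    bse: Optional[dict[str, float]]
    converged: bool
    iterations: int
    boundary: bool

    @property
    def n_free(self) -> int:
        return self.model.n_free

    @property
    def risk_params(self) -> RiskParams:
        return apply_constraints(self.model.spec, list(self.params.values()))[0]

    @property
    def strat_params(self) -> StratParams:
        return apply_constraints(self.model.spec, list(self.params.values()))[1]

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Trio multinomial model",
            "=" * 46,
            f"assumption: {spec.assumption}    free parameters: {self.n_free}",
            f"log-likelihood: {self.llf:.6f}",
            f"converged: {self.converged} ({self.iterations} iterations)"
            + ("    [estimate at boundary]" if self.boundary else ""),
            "-" * 46,
            f"{'parameter':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name, value in self.params.items():
            se = "" if self.bse is None else f"{self.bse[name]:>12.4f}"
            lines.append(f"{name:<10}{value:>12.4f}{se:>12}")
        lines.append("=" * 46)
        return "\n".join(lines)


def fit(
    tables: Sequence[CountTable],
    spec: ModelSpec,
    start: Optional[Sequence[float]] = None,
    freq_start: Optional[float] = None,
) -> TrioResults:
    """Convenience wrapper: build a :class:`TrioModel` and fit it."""
    return TrioModel(tables, spec, freq_start=freq_start).fit(start=start)


@dataclass(frozen=True)
class TestResult:
    """Likelihood-ratio test of nested fits."""

    lrt_stat: float
    df: int
    p_value: float


def likelihood_ratio_test(null_fit: TrioResults, alt_fit: TrioResults) -> TestResult:
    """LRT of a null fit against a nesting alternative fit.

    The statistic 2*(llf_alt - llf_null) is clipped at 0 and referred to
    the chi-squared distribution with df = difference in free-parameter
    counts.
    """
    null_spec, alt_spec = null_fit.model.spec, alt_fit.model.spec
    if not null_spec.nests(alt_spec) or null_fit.n_free >= alt_fit.n_free:
        raise ValueError("null model specification is not nested in the alternative")
    df = alt_fit.n_free - null_fit.n_free
    stat = max(0.0, 2.0 * (alt_fit.llf - null_fit.llf))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return TestResult(lrt_stat=stat, df=df, p_value=p)


def max_estimable_risk_params(
    assumption: str = "CEPG",
    menu: Sequence[str] = RISK_PARAM_NAMES,
    seed: int = 0,
    rank_tol: float = 1e-8,
) -> int:
    """Largest number of jointly identifiable relative-risk parameters.

    Starting from the free stratification parameters of ``assumption``,
    risk parameters from ``menu`` are added greedily; an addition is
    accepted only if it raises the numerical rank of the Jacobian of the
    map (parameters -> 15-cell case probabilities) by one, evaluated at
    a randomised generic interior point (fixed ``seed``).  Rank is
    counted by singular values above ``rank_tol`` times the largest.
    """
    rng = np.random.default_rng(seed)
    base_spec = ModelSpec(assumption=assumption, free_risk=())
    strat_names = base_spec.free_names  # strat only
    # one fixed generic interior point shared by every rank evaluation
    # (internal scale: log-params ~ N(0, 0.3))
    generic = {
        name: float(rng.normal(0.0, 0.3))
        for name in tuple(strat_names) + tuple(menu)
    }

    def jacobian(spec: ModelSpec, point: np.ndarray, h: float = 1e-6) -> np.ndarray:
        names = spec.free_names

        def probs_at(z: np.ndarray) -> np.ndarray:
            rp, sp = apply_constraints(spec, _to_natural(names, z))
            return case_trio_cell_probs(rp, sp)

        cols = []
        for i in range(len(names)):
            e = np.zeros(len(names))
            e[i] = h
            cols.append((probs_at(point + e) - probs_at(point - e)) / (2 * h))
        return np.column_stack(cols)

    def rank_of(spec: ModelSpec) -> int:
        names = spec.free_names
        z = np.array([generic[n] for n in names])
        sv = np.linalg.svd(jacobian(spec, z), compute_uv=False)
        return int(np.sum(sv > rank_tol * sv[0]))

    accepted: list[str] = []
    current_rank = rank_of(base_spec)
    assert current_rank == len(strat_names), "stratification parameters degenerate"
    for name in menu:
        trial = ModelSpec(assumption=assumption, free_risk=tuple(accepted) + (name,))
        r = rank_of(trial)
        if r == current_rank + 1:
            accepted.append(name)
            current_rank = r
    return len(accepted)
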