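"""Discrete-time, density-independent projection of the four-class population.

The population is tracked as abundances of the four functional classes
(ZZ males, intersex WZ males, WZ females, WW females). Each time step
(one generation, nominally ~6 months):

* every functional female mates with one sire drawn with probability
  proportional to male-class abundance (IS males are fully fertile);
* each female recruits ``sigma0 * phi`` surviving newborns on average,
  whose classes follow the Mendelian cross mixture partitioned by ``alpha``;
* adults survive with probability ``sigma_a``.

Because all four classes share the same survival and fecundity, the
long-term stable distribution (LTSD) of class *fractions* depends only on
``alpha`` — survival and fecundity shape the growth rate and the transient,
never the asymptotic structure. At the LTSD the intersex fraction is close
to ``alpha / 2`` and functional males balance functional females 1:1.

Two step operators are provided: the Malthusian :func:`project_step`
(exponential growth at rate ``lambda_inf``) and
:func:`constant_population_step`, where newborns replace exactly the adults
that die so total N is conserved (the carrying-capacity / lambda = 1 view).
Both converge to the same structural fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .genetics import (
    CLASS_ORDER,
    CLASS_GENOTYPE,
    Genotype,
    PhenotypeClass,
    offspring_genotype_distribution,
    phenotype_partition,
)

_IDX = {c: i for i, c in enumerate(CLASS_ORDER)}
_ZZ, _IS, _WZ, _WW = (_IDX[c] for c in CLASS_ORDER)

STEP_CAP = 10_000


class ConvergenceError(RuntimeError):
    """Raised when an iterative solve exceeds its step cap."""


@dataclass(frozen=True)
class DemographicParams:
    """Demographic parameters of the projection model.

    Parameters
    ----------
    alpha:
        Fraction of WZ progeny emerging as intersex (dimensionless, [0, 1]).
    sigma0:
        Newborn survival per step, [0, 1].
    sigma_a:
        Adult survival per step, [0, 1). Adult life expectancy is
        ``1 / (-ln sigma_a)`` steps.
    phi:
        Per-capita female fecundity (offspring per female per step, >= 0).
    step_months:
        Duration of one time step in months (default 6; years = steps / 2).
    """

    alpha: float = 0.04
    sigma0: float = 1.0
    sigma_a: float = 0.6
    phi: float = 1.2
    step_months: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.sigma0 <= 1.0:
            raise ValueError(f"sigma0 must lie in [0, 1], got {self.sigma0}")
        if not 0.0 <= self.sigma_a < 1.0:
            raise ValueError(f"sigma_a must lie in [0, 1), got {self.sigma_a}")
        if self.phi < 0.0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")
        if self.step_months <= 0.0:
            raise ValueError("step_months must be positive")

    @property
    def adult_life_expectancy(self) -> float:
        """Expected adult lifespan in steps, ``1 / (-ln sigma_a)``."""
        if self.sigma_a == 0.0:
            return 0.0
        return 1.0 / (-np.log(self.sigma_a))

    @property
    def recruitment(self) -> float:
        """Surviving newborns per female per step, ``sigma0 * phi``."""
        return self.sigma0 * self.phi


@dataclass(frozen=True)
class PopulationState:
    """Abundances of the four classes at one time step."""

    zz: float
    is_: float
    wz: float
    ww: float
    t: int = 0

    def __post_init__(self) -> None:
        if min(self.zz, self.is_, self.wz, self.ww) < 0:
            raise ValueError("class abundances must be nonnegative")

    @classmethod
    def from_array(cls, arr: np.ndarray, t: int = 0) -> "PopulationState":
        return cls(float(arr[_ZZ]), float(arr[_IS]), float(arr[_WZ]), float(arr[_WW]), t)

    def as_array(self) -> np.ndarray:
        return np.array([self.zz, self.is_, self.wz, self.ww], dtype=float)

    @property
    def total(self) -> float:
        return self.zz + self.is_ + self.wz + self.ww

    @property
    def males(self) -> float:
        """Functional males: ZZ males plus intersex WZ males."""
        return self.zz + self.is_

    @property
    def females(self) -> float:
        """Functional females: WZ plus WW females."""
        return self.wz + self.ww

    def fractions(self) -> dict[PhenotypeClass, float]:
        """Class fractions; raises if the population is empty."""
        n = self.total
        if n <= 0:
            raise ValueError("class fractions are undefined for an empty population")
        a = self.as_array() / n
        return {c: float(a[_IDX[c]]) for c in CLASS_ORDER}


@dataclass
class Trajectory:
    """A simulated sequence of states and the per-step finite growth rates."""

    states: list[PopulationState]
    lambdas: list[float] = field(default_factory=list)
    extinct: bool = False

    @property
    def final(self) -> PopulationState:
        return self.states[-1]

    def totals(self) -> np.ndarray:
        return np.array([s.total for s in self.states])


@dataclass(frozen=True)
class StableDistribution:
    """The LTSD: asymptotic class fractions, growth rate and iterations used."""

    fractions: dict[PhenotypeClass, float]
    lambda_inf: float
    n_iterations: int

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[c] for c in CLASS_ORDER])

    def percentages(self) -> dict[PhenotypeClass, float]:
        """Fractions as percentages rounded to 2 decimals (reporting style)."""
        return {c: round(100.0 * f, 2) for c, f in self.fractions.items()}


def newborn_class_distribution(
    state: PopulationState, alpha: float
) -> dict[PhenotypeClass, float] | None:
    """Class distribution of newborns produced by the current population.

    Sire genotypes are drawn proportional to male-class abundances, dam
    genotypes proportional to female-class abundances; the offspring genotype
    mixture over sire x dam pairs is then partitioned by ``alpha``.

    Returns ``None`` when the population has no functional males or no
    functional females (recruitment is zero).
    """
    if state.males <= 0 or state.females <= 0:
        return None
    sire_w = {Genotype.ZZ: state.zz / state.males, Genotype.WZ: state.is_ / state.males}
    dam_w = {Genotype.WZ: state.wz / state.females, Genotype.WW: state.ww / state.females}
    mix: dict[Genotype, float] = {g: 0.0 for g in Genotype}
    for sg, ps in sire_w.items():
        if ps == 0.0:
            continue
        for dg, pd in dam_w.items():
            if pd == 0.0:
                continue
            for g, p in offspring_genotype_distribution(sg, dg).items():
                mix[g] += ps * pd * p
    return phenotype_partition(mix, alpha)


def _newborn_array(counts: np.ndarray, alpha: float) -> np.ndarray | None:
    state = PopulationState.from_array(counts)
    dist = newborn_class_distribution(state, alpha)
    if dist is None:
        return None
    return np.array([dist[c] for c in CLASS_ORDER])


def project_step(state: PopulationState, params: DemographicParams) -> PopulationState:
    """One deterministic Malthusian step.

    For each class k: ``N'_k = sigma_a * N_k + sigma0 * phi * F * p_k`` where
    F is the functional-female abundance and p the newborn class
    distribution. No density dependence: growth is unbounded.
    """
    n = state.as_array()
    p = _newborn_array(n, params.alpha)
    out = params.sigma_a * n
    if p is not None:
        out = out + params.recruitment * state.females * p
    return PopulationState.from_array(out, state.t + 1)


def constant_population_step(
    state: PopulationState, params: DemographicParams
) -> PopulationState:
    """One step under the constant-total-N assumption.

    Newborns replace exactly the ``(1 - sigma_a) * N`` adults that die, so
    the total is conserved (lambda = 1, or a population at carrying
    capacity). If one sex is absent no recruitment is possible and only the
    survivors remain.
    """
    if state.total <= 0:
        raise ValueError("constant_population_step requires total N > 0")
    n = state.as_array()
    p = _newborn_array(n, params.alpha)
    out = params.sigma_a * n
    if p is not None:
        out = out + (1.0 - params.sigma_a) * state.total * p
    return PopulationState.from_array(out, state.t + 1)


def _stochastic_step(
    state: PopulationState, params: DemographicParams, rng: np.random.Generator
) -> PopulationState:
    n = state.as_array()
    p = _newborn_array(n, params.alpha)
    survivors = rng.binomial(n.astype(np.int64), params.sigma_a)
    out = survivors.astype(float)
    if p is not None:
        total_recruits = rng.poisson(params.recruitment * state.females)
        out = out + rng.multinomial(total_recruits, p)
    return PopulationState.from_array(out, state.t + 1)


def simulate_trajectory(
    initial: PopulationState,
    params: DemographicParams,
    n_steps: int,
    mode: str = "deterministic",
    seed: int | None = None,
    step: str = "malthusian",
) -> Trajectory:
    """Simulate ``n_steps`` of the projection and record finite growth rates.

    ``mode='stochastic'`` draws integer recruits (Poisson totals split
    multinomially over classes) and binomial adult survivors; the initial
    abundances must then be integers. A stochastic population that hits
    N = 0 yields a truncated trajectory flagged ``extinct``.
    ``step='constant'`` uses :func:`constant_population_step` instead of the
    Malthusian operator.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if mode not in {"deterministic", "stochastic"}:
        raise ValueError(f"unknown mode {mode!r}")
    if step not in {"malthusian", "constant"}:
        raise ValueError(f"unknown step operator {step!r}")
    rng = np.random.default_rng(seed) if mode == "stochastic" else None
    states = [initial]
    lambdas: list[float] = []
    extinct = False
    for _ in range(n_steps):
        cur = states[-1]
        if mode == "stochastic":
            nxt = _stochastic_step(cur, params, rng)
        elif step == "constant":
            nxt = constant_population_step(cur, params)
        else:
            nxt = project_step(cur, params)
        lambdas.append(nxt.total / cur.total if cur.total > 0 else float("nan"))
        states.append(nxt)
        if nxt.total <= 0:
            extinct = True
            break
    return Trajectory(states=states, lambdas=lambdas, extinct=extinct)


def stable_distribution(
    alpha: float,
    params: DemographicParams | None = None,
    tol: float = 1e-10,
    step_cap: int = STEP_CAP,
) -> StableDistribution:
    """Solve for the LTSD by iterating the projection from ZZ = WZ = 50%.

    Iterates :func:`project_step` on class fractions until the maximum
    fraction change falls below ``tol``. The result depends only on
    ``alpha``; ``params`` (if given) supplies survival/fecundity, which
    affect ``lambda_inf`` and the iteration count but not the fractions.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if params is None:
        params = DemographicParams(alpha=alpha)
    elif params.alpha != alpha:
        params = DemographicParams(
            alpha=alpha,
            sigma0=params.sigma0,
            sigma_a=params.sigma_a,
            phi=params.phi,
            step_months=params.step_months,
        )
    state = PopulationState(zz=0.5, is_=0.0, wz=0.5, ww=0.0)
    lam = float("nan")
    for it in range(1, step_cap + 1):
        nxt = project_step(state, params)
        lam = nxt.total / state.total
        f_old = state.as_array() / state.total
        f_new = nxt.as_array() / nxt.total
        # renormalize to keep the iteration numerically bounded
        state = PopulationState.from_array(f_new, nxt.t)
        if np.max(np.abs(f_new - f_old)) < tol:
            fr = {c: float(f_new[_IDX[c]]) for c in CLASS_ORDER}
            return StableDistribution(fractions=fr, lambda_inf=float(lam), n_iterations=it)
    raise ConvergenceError(f"LTSD iteration did not converge within {step_cap} steps")


def stable_distribution_fixed_point(alpha: float) -> dict[PhenotypeClass, float]:
    """Direct fixed-point solve of the newborn-fraction equations.

    Independent of the projection iteration: solves for (u, v) — the IS
    share among males and the WW share among females — such that the newborn
    class distribution generated by those shares reproduces them. Used as an
    internal cross-check of :func:`stable_distribution`.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if alpha == 0.0:
        return {
            PhenotypeClass.ZZ_MALE: 0.5,
            PhenotypeClass.IS: 0.0,
            PhenotypeClass.WZ_FEMALE: 0.5,
            PhenotypeClass.WW_FEMALE: 0.0,
        }

    def classes(u: float, v: float) -> np.ndarray:
        # sire transmits W with prob u/2; dam with prob (1 + v) / 2
        pw_s, pw_d = u / 2.0, (1.0 + v) / 2.0
        zz = (1.0 - pw_s) * (1.0 - pw_d)
        ww = pw_s * pw_d
        wz = 1.0 - zz - ww
        return np.array([zz, alpha * wz, (1.0 - alpha) * wz, ww])

    def residual(x: np.ndarray) -> np.ndarray:
        u, v = x
        zz, is_, wzf, wwf = classes(u, v)
        return np.array([is_ / (zz + is_) - u, wwf / (wzf + wwf) - v])

    sol = optimize.fsolve(residual, x0=np.array([alpha, alpha / 4.0]), full_output=True)
    x, info, ier, msg = sol
    if ier != 1:
        raise ConvergenceError(f"fixed-point solve failed: {msg}")
    zz, is_, wzf, wwf = classes(*x)
    return {
        PhenotypeClass.ZZ_MALE: float(zz),
        PhenotypeClass.IS: float(is_),
        PhenotypeClass.WZ_FEMALE: float(wzf),
        PhenotypeClass.WW_FEMALE: float(wwf),
    }


@dataclass(frozen=True)
class ConvergenceResult:
    """Steps (and equivalent years) to reach the LTSD within a tolerance."""

    steps: int
    years: float


def generations_to_convergence(
    initial: PopulationState,
    params: DemographicParams,
    tol_pp: float = 0.1,
    step_cap: int = STEP_CAP,
) -> ConvergenceResult:
    """First step at which every class fraction is within ``tol_pp``
    percentage points of the alpha-LTSD.

    Returns 0 for a population already at the stable structure.
    """
    if tol_pp <= 0:
        raise ValueError("tol_pp must be positive")
    target = stable_distribution(params.alpha, params).as_array()
    tol = tol_pp / 100.0
    state = initial
    for t in range(step_cap + 1):
        if state.total > 0:
            frac = state.as_array() / state.total
            if np.max(np.abs(frac - target)) < tol:
                return ConvergenceResult(
                    steps=t, years=t * params.step_months / 12.0
                )
        state = project_step(state, params)
    raise ConvergenceError(
        f"fractions did not reach the LTSD within {step_cap} steps"
    )


def time_to_threshold(
    initial: PopulationState,
    params: DemographicParams,
    n_target: float,
    step_cap: int = STEP_CAP,
) -> int:
    """First step t at which total N reaches or exceeds ``n_target``.

    Raises :class:`ConvergenceError` for a non-growing population that never
    reaches the target.
    """
    state = initial
    for t in range(step_cap + 1):
        if state.total >= n_target:
            return t
        state = project_step(state, params)
    raise ConvergenceError(
        f"population did not reach N = {n_target} within {step_cap} steps "
        "(non-growing population?)"
    )


def estimate_alpha_from_cohort(is_fraction: float) -> float:
    """Estimate alpha from an observed intersex fraction.

    Valid for populations near the LTSD, where the intersex fraction is
    about half of alpha; the estimator is simply ``2 * is_fraction``.
    """
    if not 0.0 <= is_fraction <= 0.5:
        raise ValueError(
            f"intersex fraction {is_fraction} outside [0, 0.5]: "
            "no alpha in [0, 1] is consistent with the LTSD"
        )
    return 2.0 * is_fraction
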