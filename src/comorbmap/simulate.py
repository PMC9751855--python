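"""Synthetic cohort generation and calibration.

The generator emulates the statistical structure the downstream analysis
assumes, without modelling any individual test item.  A single latent
liability ``L`` per child induces correlated impairments across all
instruments:

* ``L ~ Normal(mu_g, 1)`` with ``mu_EPT = -latent_shift`` and
  ``mu_TERM = 0`` (lower liability = worse performance);
* each score-bearing domain ``d`` draws a z-deviate
  ``z_d = delta_d + lambda_d * L + sqrt(1 - lambda_d^2) * eps`` with
  ``eps ~ Normal(0, 1)``, mapped to the native scale (standard/scaled
  scores are rounded to integers 1–19, SIPT z-scores clipped to [−3, 3]);
* each of the eight Touwen domains is dysfunctional with probit
  probability ``Phi(alpha - slope * L)``, independent across domains given
  ``L``, where ``alpha = Phi^{-1}(touwen_base_rate)``.

``delta_d`` is a per-domain difficulty offset: the marginal z-deviate has
unit variance for every loading, so the term-group impairment rate is
``Phi(c_d - delta_d)`` (``c_d`` the native cutoff on the z scale) and the
EPT rate ``Phi(c_d - delta_d + lambda_d * latent_shift)``.  These closed
forms make calibration to published marginal impairment rates a pair of
probit inversions per domain; only the Touwen-derived MND domain needs
numerical integration (a max over eight correlated Bernoullis).

Missingness is MCAR: each score cell, and the Touwen examination as a
whole, is independently missing with ``missing_rate``.  Covariates are
drawn from the reference study's marginal frequencies, independent of
liability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.optimize import brentq

from .cohort import ChildRecord, CohortTable, Education, Group
from .registry import DEFAULT_REGISTRY, DomainRegistry

_N_TOUWEN = 8

#: Default covariate marginals, per group, from the reference study.
DEFAULT_COVARIATES: dict[str, dict[str, object]] = {
    "EPT": {
        "male_p": 35 / 56,
        "education_p": (26 / 56, 18 / 56, 12 / 56),
        "brain_injury_p": 6 / 56,
        "morbidity_p": 0.60,
    },
    "TERM": {
        "male_p": 19 / 37,
        "education_p": (7 / 37, 11 / 37, 19 / 37),
        "brain_injury_p": 0.0,
        "morbidity_p": 0.0,
    },
}


def _as_domain_map(value: float | Mapping[str, float],
                   registry: DomainRegistry, what: str) -> dict[str, float]:
    domains = registry.abbreviations
    if isinstance(value, Mapping):
        unknown = set(value) - set(domains)
        if unknown:
            raise ValueError(f"{what}: unknown domains {sorted(unknown)}")
        out = {d: float(value.get(d, 0.0)) for d in domains}
    else:
        out = {d: float(value) for d in domains}
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``loadings`` maps each domain to its liability loading in [0, 1]; the
    ``MND`` entry is the probit slope of the Touwen dysfunction model.
    ``offsets`` are the per-domain difficulty shifts ``delta_d`` in SD
    units (ignored for MND, whose marginal is set by
    ``touwen_base_rate``/slope).  A scalar for either broadcasts to all
    domains.
    """

    seed: int
    n_ept: int = 56
    n_term: int = 37
    latent_shift: float = 1.0
    loadings: float | Mapping[str, float] = 0.6
    offsets: float | Mapping[str, float] = 0.0
    touwen_base_rate: float = 0.08
    missing_rate: float = 0.10
    covariates: Mapping[str, Mapping[str, object]] = field(
        default_factory=lambda: DEFAULT_COVARIATES)
    registry: DomainRegistry = DEFAULT_REGISTRY

    def __post_init__(self) -> None:
        if self.n_ept < 2 or self.n_term < 2:
            bad = "n_ept" if self.n_ept < 2 else "n_term"
            raise ValueError(f"{bad} must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 < self.touwen_base_rate < 1:
            raise ValueError("touwen_base_rate must be in (0, 1)")
        if self.latent_shift < 0:
            raise ValueError("latent_shift must be >= 0")
        lam = _as_domain_map(self.loadings, self.registry, "loadings")
        for d, v in lam.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"loadings: {d} loading {v} outside [0, 1]")
        _as_domain_map(self.offsets, self.registry, "offsets")
        if self.seed is None or int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    def loading_map(self) -> dict[str, float]:
        return _as_domain_map(self.loadings, self.registry, "loadings")

    def offset_map(self) -> dict[str, float]:
        return _as_domain_map(self.offsets, self.registry, "offsets")


# ---------------------------------------------------------------------------
# closed-form impairment probabilities

def score_impairment_probability(cutoff_z: float, loading: float,
                                 offset: float, group_mean: float) -> float:
    """P(z-deviate < cutoff) for one score domain under the latent model.

    The marginal z-deviate is Normal(offset + loading * group_mean, 1), so
    the probability is ``Phi(cutoff - offset - loading * group_mean)``.
    """
    return float(ndtr(cutoff_z - offset - loading * group_mean))


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)


def mnd_impairment_probability(base_rate: float, slope: float,
                               group_mean: float) -> float:
    """Marginal P(at least one dysfunctional Touwen domain).

    Integrates ``1 - (1 - Phi(alpha - slope * L))^8`` over
    ``L ~ Normal(group_mean, 1)`` with Gauss–Hermite quadrature.
    """
    alpha = ndtri(base_rate)
    liabilities = group_mean + math.sqrt(2.0) * _GH_NODES
    p_dys = ndtr(alpha - slope * liabilities)
    integrand = 1.0 - (1.0 - p_dys) ** _N_TOUWEN
    return float(np.sum(_GH_WEIGHTS * integrand) / math.sqrt(math.pi))


def expected_impairment_rates(config: SyntheticConfig) -> dict[str, tuple[float, float]]:
    """Model-implied (EPT, term) impairment probability per domain."""
    lam, delta = config.loading_map(), config.offset_map()
    out: dict[str, tuple[float, float]] = {}
    for spec in config.registry:
        d = spec.abbreviation
        if d == "MND":
            out[d] = (
                mnd_impairment_probability(config.touwen_base_rate, lam[d],
                                           -config.latent_shift),
                mnd_impairment_probability(config.touwen_base_rate, lam[d], 0.0),
            )
        else:
            c = spec.cutoff_z()
            out[d] = (
                score_impairment_probability(c, lam[d], delta[d], -config.latent_shift),
                score_impairment_probability(c, lam[d], delta[d], 0.0),
            )
    return out


# ---------------------------------------------------------------------------
# generation

def _native_scores(z: np.ndarray, spec) -> np.ndarray:
    raw = spec.native_mean + spec.native_sd * z
    if spec.is_integer_scale:
        return np.clip(np.rint(raw), 1, 19)
    return np.clip(raw, -3.0, 3.0)


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw a fully reproducible synthetic cohort from ``config``."""
    rng = np.random.default_rng(config.seed)
    registry = config.registry
    lam, delta = config.loading_map(), config.offset_map()
    alpha = ndtri(config.touwen_base_rate)
    slope = lam["MND"]

    children: list[ChildRecord] = []
    for group, n, mu in ((Group.EPT, config.n_ept, -config.latent_shift),
                         (Group.TERM, config.n_term, 0.0)):
        cov = config.covariates[group.value]
        liab = rng.normal(mu, 1.0, size=n)
        sexes = rng.random(n) < cov["male_p"]
        edu = rng.choice(3, size=n, p=np.asarray(cov["education_p"], dtype=float)
                         / np.sum(cov["education_p"]))
        injury = rng.random(n) < cov["brain_injury_p"]
        morbid = rng.random(n) < cov["morbidity_p"]
        touwen_p = ndtr(alpha - slope * liab)
        touwen = rng.random((n, _N_TOUWEN)) < touwen_p[:, None]
        touwen_missing = rng.random(n) < config.missing_rate

        score_specs = registry.score_domains
        native = np.empty((n, len(score_specs)))
        for j, spec in enumerate(score_specs):
            d = spec.abbreviation
            eps = rng.normal(size=n)
            z_d = delta[d] + lam[d] * liab + math.sqrt(1 - lam[d] ** 2) * eps
            native[:, j] = _native_scores(z_d, spec)
        missing = rng.random((n, len(score_specs))) < config.missing_rate

        for i in range(n):
            scores: dict[str, float] = {}
            for j, spec in enumerate(score_specs):
                if missing[i, j]:
                    continue
                scores[spec.abbreviation] = float(native[i, j])
            children.append(ChildRecord(
                child_id=f"{group.value}-{i + 1:03d}",
                group=group,
                sex="M" if sexes[i] else "F",
                mother_education=Education(int(edu[i])),
                brain_injury=bool(injury[i]),
                morbidity=bool(morbid[i]),
                touwen_domains=None if touwen_missing[i] else tuple(
                    bool(b) for b in touwen[i]),
                scores=scores,
            ))
    return CohortTable(children, registry)


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class CalibrationResult:
    """Generator parameters matching a target marginal-rate table."""

    latent_shift: float
    loadings: dict[str, float]
    offsets: dict[str, float]
    touwen_base_rate: float | None
    #: domain -> reason, for targets that no parameter setting can meet
    infeasible: dict[str, str]

    def to_config(self, seed: int, **overrides) -> SyntheticConfig:
        kwargs: dict = dict(
            seed=seed,
            latent_shift=self.latent_shift,
            loadings=self.loadings,
            offsets=self.offsets,
        )
        if self.touwen_base_rate is not None:
            kwargs["touwen_base_rate"] = self.touwen_base_rate
        kwargs.update(overrides)
        return SyntheticConfig(**kwargs)


def calibrate_loadings(
    target_rates: Mapping[str, tuple[float, float]],
    latent_shift: float | None = None,
    registry: DomainRegistry = DEFAULT_REGISTRY,
) -> CalibrationResult:
    """Solve generator parameters so model rates equal ``target_rates``.

    ``target_rates`` maps domain -> (EPT rate, term rate), all in (0, 1).
    For score domains the solution is exact in closed form: the offset
    matches the term rate, the loading (scaled by the shared latent shift)
    matches the EPT rate.  When ``latent_shift`` is not given it is set to
    the largest probit gap so that every loading lies in [0, 1]; equal
    targets take the smallest valid loading (zero).  The MND target is
    solved by nested root-finding on the quadrature closed form.

    Targets no parameter setting can meet (term rate above EPT rate under
    the positive-shift constraint, or a gap exceeding a user-fixed shift)
    are reported per domain in ``infeasible``, never silently clamped.
    """
    for d, (pe, pt) in target_rates.items():
        if d not in registry:
            raise KeyError(f"unknown domain {d!r}")
        if not (0 < pe < 1 and 0 < pt < 1):
            raise ValueError(f"{d}: target rates must be in (0, 1), got {pe}, {pt}")

    gaps = {d: float(ndtri(pe) - ndtri(pt))
            for d, (pe, pt) in target_rates.items() if d != "MND"}
    infeasible: dict[str, str] = {}
    for d, g in list(gaps.items()):
        if g < 0:
            infeasible[d] = (
                f"term rate {target_rates[d][1]:.3f} exceeds EPT rate "
                f"{target_rates[d][0]:.3f}; unreachable with a positive shift")
            del gaps[d]

    if latent_shift is None:
        shift = max(gaps.values(), default=1.0)
        shift = max(shift, 1e-12) if gaps else 1.0
    else:
        shift = float(latent_shift)

    loadings: dict[str, float] = {}
    offsets: dict[str, float] = {}
    for d, g in gaps.items():
        _, pt = target_rates[d]
        offsets[d] = float(registry[d].cutoff_z() - ndtri(pt))
        if g == 0.0:
            loadings[d] = 0.0  # smallest valid loading; any value matches
        elif shift == 0.0:
            infeasible[d] = "nonzero probit gap with latent_shift fixed at 0"
        elif g / shift > 1.0 + 1e-9:
            infeasible[d] = (
                f"needs loading {g / shift:.3f} > 1 at latent_shift {shift:.3f}")
        else:
            loadings[d] = min(g / shift, 1.0)

    base_rate: float | None = None
    if "MND" in target_rates:
        pe, pt = target_rates["MND"]
        if pt > pe:
            infeasible["MND"] = "term rate exceeds EPT rate"
        else:
            base_rate, slope, err = _solve_mnd(pe, pt, shift)
            if err is not None:
                infeasible["MND"] = err
            else:
                loadings["MND"] = slope

    return CalibrationResult(shift, loadings, offsets, base_rate, infeasible)


def _solve_mnd(ept_rate: float, term_rate: float,
               shift: float) -> tuple[float | None, float | None, str | None]:
    """Nested root-finding for the Touwen base rate and probit slope."""

    def base_for(slope: float) -> float:
        # term-group MND rate is increasing in base_rate for fixed slope
        def f(logit_base):
            b = 1.0 / (1.0 + math.exp(-logit_base))
            return mnd_impairment_probability(b, slope, 0.0) - term_rate
        lo, hi = -12.0, 8.0
        x = brentq(f, lo, hi, xtol=1e-12)
        return 1.0 / (1.0 + math.exp(-x))

    def ept_gap(slope: float) -> float:
        b = base_for(slope)
        return mnd_impairment_probability(b, slope, -shift) - ept_rate

    g0, g1 = ept_gap(0.0), ept_gap(1.0)
    if g0 == 0.0:
        slope = 0.0
    elif g0 > 0 or g1 < 0:
        return None, None, (
            f"EPT rate {ept_rate:.3f} unreachable with slope in [0, 1] at "
            f"latent_shift {shift:.3f}")
    else:
        slope = brentq(ept_gap, 0.0, 1.0, xtol=1e-10)
    return base_for(slope), float(slope), None
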