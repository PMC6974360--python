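"""MAP estimation in transformed space, Laplace model evidence, and
random-effects Bayesian model selection.

Parameters are estimated in an unbounded space: learning rates and the
advice weight zeta through the logit transform, the inverse temperature
beta through the log transform.  Gaussian priors are placed in that
space; the defaults are N(logit(0.2), 1) for each learning rate,
N(ln 48, 1) for log beta, and N(0, 100) for logit zeta (an uninformative
prior centred on equal weighting of the two information sources).

The objective is the log-joint posterior density (likelihood plus
log-priors), maximised by a quasi-Newton (BFGS) search from a fixed
starting point: learning rates at logit(0.5) = 0, beta and zeta at their
prior means.  Log model evidence is approximated at the MAP with a
Laplace (Gaussian) approximation, and group-level model comparison uses
the random-effects Dirichlet scheme of Stephan et al. (2009) with the
protected exceedance probabilities of Rigoux et al. (2014).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import digamma, expit, gammaln, logit, logsumexp

from .model import ModelParams, log_likelihood
from .task import SessionRecord, TaskSchedule, TrialSequence

Session = tuple  # (TrialSequence, reward TaskSchedule, advice TaskSchedule)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ParamPrior:
    transform: str  # "logit", "log" or "identity"
    mean: float     # in transformed space
    var: float

    def __post_init__(self) -> None:
        if self.transform not in ("logit", "log", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not self.var > 0:
            raise ValueError("prior variance must be > 0")

    def to_estimation(self, x: float) -> float:
        if self.transform == "logit":
            if not 0.0 < x < 1.0:
                raise ValueError(f"logit transform requires x in (0, 1), got {x}")
            return float(logit(x))
        if self.transform == "log":
            if not x > 0:
                raise ValueError(f"log transform requires x > 0, got {x}")
            return float(np.log(x))
        return float(x)

    def to_native(self, y: float) -> float:
        # clip at the open-interval boundary so saturated transformed values
        # (|y| beyond float precision of expit/exp) stay inside the domain
        if self.transform == "logit":
            return float(np.clip(expit(y), 1e-12, 1.0 - 1e-12))
        if self.transform == "log":
            return float(np.clip(np.exp(y), 1e-12, 1e12))
        return float(y)

    def logpdf(self, y: float) -> float:
        return -0.5 * (_LOG_2PI + math.log(self.var) + (y - self.mean) ** 2 / self.var)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the three parameter families (shared across variants)."""

    alpha: ParamPrior = field(
        default_factory=lambda: ParamPrior("logit", float(logit(0.2)), 1.0)
    )
    beta: ParamPrior = field(
        default_factory=lambda: ParamPrior("log", float(np.log(48.0)), 1.0)
    )
    zeta: ParamPrior = field(default_factory=lambda: ParamPrior("logit", 0.0, 100.0))

    def for_name(self, name: str) -> ParamPrior:
        if name.startswith("alpha"):
            return self.alpha
        return getattr(self, name)


_VARIANT_NAMES = {
    "M1": ("alpha", "beta", "zeta"),
    "M2": ("alpha_stable", "alpha_volatile", "beta", "zeta"),
    "M3": ("alpha_stable_experienced", "alpha_volatile_experienced",
           "alpha_stable_inferred", "alpha_volatile_inferred", "beta", "zeta"),
}


def param_names(variant: str) -> tuple[str, ...]:
    """Free-parameter names, in vector order, for a model variant."""
    try:
        return _VARIANT_NAMES[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}") from None


def to_estimation_space(params: ModelParams, priors: PriorSpec | None = None) -> np.ndarray:
    priors = priors or PriorSpec()
    names = param_names(params.variant)
    values = []
    for name in names:
        if name == "alpha":
            x = params.alpha_stable_experienced
        elif name == "alpha_stable":
            x = params.alpha_stable_experienced
        elif name == "alpha_volatile":
            x = params.alpha_volatile_experienced
        else:
            x = getattr(params, name)
        values.append(priors.for_name(name).to_estimation(x))
    return np.asarray(values)


def from_estimation_space(
    theta: Sequence[float], variant: str = "M3", priors: PriorSpec | None = None
) -> ModelParams:
    priors = priors or PriorSpec()
    names = param_names(variant)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(names),):
        raise ValueError(f"theta must have length {len(names)} for {variant}")
    native = {n: priors.for_name(n).to_native(t) for n, t in zip(names, theta)}
    if variant == "M1":
        a = native["alpha"]
        return ModelParams.m1(a, native["beta"], native["zeta"])
    if variant == "M2":
        return ModelParams.m2(native["alpha_stable"], native["alpha_volatile"],
                              native["beta"], native["zeta"])
    return ModelParams(**native)


def _as_sessions(data) -> list[Session]:
    """Accept one session tuple/record or a sequence of them."""
    if isinstance(data, SessionRecord):
        return [(data.trials, data.reward_schedule, data.advice_schedule)]
    if isinstance(data, tuple) and len(data) == 3 and isinstance(data[0], TrialSequence):
        return [data]
    out = []
    for item in data:
        if isinstance(item, SessionRecord):
            out.append((item.trials, item.reward_schedule, item.advice_schedule))
        else:
            out.append(tuple(item))
    return out


def log_joint(
    theta: Sequence[float],
    data,
    priors: PriorSpec | None = None,
    variant: str = "M3",
) -> float:
    """Log-joint posterior density: likelihood over sessions + log-priors.

    ``data`` may be empty, in which case the log-joint is the prior alone
    (its maximum sits exactly at the prior means).
    """
    priors = priors or PriorSpec()
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        return -np.inf
    names = param_names(variant)
    lp = sum(priors.for_name(n).logpdf(t) for n, t in zip(names, theta))
    sessions = _as_sessions(data)
    if sessions:
        try:
            params = from_estimation_space(theta, variant, priors)
        except ValueError:
            # transform saturated (e.g. expit rounding to exactly 0/1)
            return -np.inf
        for trials, reward, advice in sessions:
            ll = log_likelihood(params, trials, reward, advice)
            if not np.isfinite(ll):
                return -np.inf
            lp += ll
    return float(lp)


@dataclass
class FitResult:
    map_params: ModelParams
    map_transformed: np.ndarray
    log_joint: float
    variant: str
    converged: bool
    n_restarts_used: int
    seed: int | None
    log_evidence: float | None = None
    evidence_flagged: bool = False

    def as_row(self) -> dict:
        p = self.map_params
        return {
            "variant": self.variant,
            "alpha_stable_experienced": p.alpha_stable_experienced,
            "alpha_volatile_experienced": p.alpha_volatile_experienced,
            "alpha_stable_inferred": p.alpha_stable_inferred,
            "alpha_volatile_inferred": p.alpha_volatile_inferred,
            "beta": p.beta,
            "zeta": p.zeta,
            "log_joint": self.log_joint,
            "log_evidence": self.log_evidence,
            "converged": self.converged,
        }


def _initial_theta(variant: str, priors: PriorSpec) -> np.ndarray:
    # learning rates start at logit(0.5) = 0; beta and zeta at prior means
    theta0 = []
    for name in param_names(variant):
        if name.startswith("alpha"):
            theta0.append(0.0)
        else:
            theta0.append(priors.for_name(name).mean)
    return np.asarray(theta0)


def fit_map(
    data,
    variant: str = "M3",
    priors: PriorSpec | None = None,
    n_restarts: int = 0,
    seed: int | None = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
    jitter_sd: float = 1.0,
) -> FitResult:
    """Maximise the log-joint by BFGS from the fixed starting point.

    ``n_restarts`` extra starts are jittered N(0, jitter_sd^2) around the
    fixed start in transformed space; the best optimum is kept.  A fit
    that fails the optimiser's convergence test is returned flagged, not
    raised.
    """
    priors = priors or PriorSpec()
    sessions = _as_sessions(data)

    def negative(theta: np.ndarray) -> float:
        lj = log_joint(theta, sessions, priors, variant)
        return -lj if np.isfinite(lj) else 1e12

    theta0 = _initial_theta(variant, priors)
    starts = [theta0]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        starts += [theta0 + rng.normal(0.0, jitter_sd, size=theta0.shape)
                   for _ in range(n_restarts)]

    best = None
    for start in starts:
        res = optimize.minimize(
            negative, start, method="BFGS", options={"gtol": gtol, "maxiter": maxiter}
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta_hat = np.asarray(best.x, dtype=float)
    # "precision loss" exits with a tiny gradient are converged in practice
    converged = bool(best.success) or (
        best.jac is not None and float(np.max(np.abs(best.jac))) < 1e-3
    )
    return FitResult(
        map_params=from_estimation_space(theta_hat, variant, priors),
        map_transformed=theta_hat,
        log_joint=float(-best.fun),
        variant=variant,
        converged=converged,
        n_restarts_used=len(starts) - 1,
        seed=seed,
    )


def _hessian_fd(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    d = len(x)
    h = np.full(d, step) * np.maximum(1.0, np.abs(x))
    hess = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            if i == j:
                e = np.zeros(d); e[i] = h[i]
                hess[i, i] = (f(x + e) - 2.0 * f0 + f(x - e)) / h[i] ** 2
            else:
                ei = np.zeros(d); ei[i] = h[i]
                ej = np.zeros(d); ej[j] = h[j]
                hess[i, j] = hess[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return hess


def log_model_evidence(
    fit: FitResult,
    data,
    priors: PriorSpec | None = None,
    step: float = 1e-4,
) -> FitResult:
    """Laplace approximation to the log model evidence at the MAP:

        F = log_joint(MAP) + (d/2) ln(2 pi) - (1/2) ln det(-H),

    with H the finite-difference Hessian of the log-joint.  If -H is not
    positive definite the diagonal is inflated until it is, and the
    result is flagged.  Returns the fit with ``log_evidence`` filled in.
    """
    priors = priors or PriorSpec()
    sessions = _as_sessions(data)
    variant = fit.variant

    def lj(theta: np.ndarray) -> float:
        return log_joint(theta, sessions, priors, variant)

    hess = _hessian_fd(lj, fit.map_transformed, step=step)
    neg_h = -hess
    flagged = False
    eigvals = np.linalg.eigvalsh(neg_h)
    if eigvals.min() <= 0:
        flagged = True
        neg_h = neg_h + (abs(eigvals.min()) + 1e-6) * np.eye(len(neg_h))
    sign, logdet = np.linalg.slogdet(neg_h)
    d = len(fit.map_transformed)
    fit.log_evidence = float(fit.log_joint + 0.5 * d * _LOG_2PI - 0.5 * logdet)
    fit.evidence_flagged = flagged
    return fit


# ---------------------------------------------------------------------------
# Random-effects Bayesian model selection


@dataclass
class BMSResult:
    model_names: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_p: np.ndarray          # posterior expected model frequencies
    exceedance_p: np.ndarray
    protected_exceedance_p: np.ndarray
    bor: float                      # Bayes omnibus risk
    fixed_effects_F: np.ndarray     # summed evidences (secondary output)
    n_subjects_used: int
    excluded_subjects: tuple[int, ...] = ()


def _dirichlet_kl(a: np.ndarray, b: np.ndarray) -> float:
    a_s, b_s = a.sum(), b.sum()
    return float(
        gammaln(a_s) - gammaln(a).sum() - gammaln(b_s) + gammaln(b).sum()
        + ((a - b) * (digamma(a) - digamma(a_s))).sum()
    )


def bms(
    F: np.ndarray,
    model_names: Sequence[str] | None = None,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int | None = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> BMSResult:
    """Random-effects model comparison from a subjects x models evidence
    matrix (variational Dirichlet scheme)."""
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] < 2:
        raise ValueError("F must be a subjects x models matrix with >= 2 models")
    finite = np.all(np.isfinite(F), axis=1)
    excluded = tuple(int(i) for i in np.flatnonzero(~finite))
    F = F[finite]
    n, k = F.shape
    if n == 0:
        raise ValueError("no subjects with finite evidences")
    names = tuple(model_names) if model_names else tuple(f"M{i+1}" for i in range(k))

    a0 = np.full(k, float(alpha0))
    alpha = a0.copy()
    g = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        logu = F + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = a0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    xp = np.bincount(winners, minlength=k) / n_samples

    # Bayes omnibus risk: P(model frequencies are all equal | data),
    # from the variational bound for H1 vs the static evidence for H0.
    f0 = float(np.sum(logsumexp(F, axis=1) - math.log(k)))
    f1 = float(
        (g * (F + digamma(alpha) - digamma(alpha.sum()))).sum()
        - (g * np.log(np.clip(g, 1e-300, None))).sum()
        - _dirichlet_kl(alpha, a0)
    )
    bor_val = float(1.0 / (1.0 + math.exp(min(700.0, max(-700.0, f1 - f0)))))
    pxp = xp * (1.0 - bor_val) + bor_val / k

    return BMSResult(
        model_names=names,
        dirichlet_alpha=alpha,
        expected_p=expected,
        exceedance_p=xp,
        protected_exceedance_p=pxp,
        bor=bor_val,
        fixed_effects_F=F.sum(axis=0),
        n_subjects_used=n,
        excluded_subjects=excluded,
    )
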