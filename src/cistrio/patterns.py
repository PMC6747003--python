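"""Six-model maximum-likelihood classification of SNP/mRNA/protein trios.

For a genotype class variable ``S`` (three classes), an mRNA trait ``R``
and a protein trait ``N``, six Markov factorizations of the joint
density are compared:

====  ======================  ==========================================
 id    factorization           interpretation
====  ======================  ==========================================
 1     P(S) P(R|S) P(N)        genetic effect on mRNA only
 2     P(S) P(R) P(N|S)        genetic effect on protein only
 3     P(S) P(R|S) P(N|S)      independent effects on both traits
 4     P(S) P(R|S) P(N|R)      transcriptional mediation (S -> R -> N)
 5     P(S) P(R) P(N|S,R)      post-transcriptional genetic effect
 6     P(S) P(R|S) P(N|R,S)    all three edges
====  ======================  ==========================================

All component densities are Gaussian: ``R|S_j ~ N(mu_RSj, sigma_R^2)``,
``N|S_j ~ N(mu_NSj, sigma_N^2)``, and the mRNA-conditional protein
densities use the bivariate-normal regression form
``N | R (, S_j) ~ N(mu + rho (sigma_N / sigma_R) (R - mu_R),
(1 - rho^2) sigma_N^2)``.

Each model is fit by maximum likelihood, scored with
``BIC = -2 logL + k ln(n)`` at the fixed per-model parameter counts
``k = (6, 6, 8, 8, 7, 10)``, and converted to selection weights
``w_i = exp(-dBIC_i) / sum_k exp(-dBIC_k)``.  The minimum-BIC model is
the selected regulatory pattern.

Two likelihood forms are supported.  The default ``observed`` form
evaluates each individual at their own genotype class,
``sum_i log[p(S_i) f_R(R_i|S_i) f_N(N_i|...)]``, and admits exact
closed-form maximum-likelihood estimates (group means, pooled variances
and ordinary regression identities).  The alternative ``mixture`` form
marginalizes the genotype class inside the likelihood,
``sum_i log[sum_j p(S_j) f_R(R_i|S_j) f_N(N_i|...)]``; it ignores which
class each individual carries and is provided for completeness — it
cannot discriminate genotype-dependent patterns and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .containers import TrioData
from .exceptions import ContractError, DegenerateDataError, ParameterError

PATTERN_IDS = (1, 2, 3, 4, 5, 6)

#: theta composition per pattern (class-mean vectors count as 3 parameters)
PATTERN_FIELDS: dict[int, tuple[str, ...]] = {
    1: ("mu_R_by_class", "sigma_R", "mu_N", "sigma_N"),
    2: ("mu_R", "sigma_R", "mu_N_by_class", "sigma_N"),
    3: ("mu_R_by_class", "sigma_R", "mu_N_by_class", "sigma_N"),
    4: ("mu_R_by_class", "sigma_R", "mu_N", "sigma_N", "rho", "mu_R"),
    5: ("mu_R", "sigma_R", "mu_N_by_class", "sigma_N", "rho"),
    6: ("mu_R_by_class", "mu_R", "sigma_R", "mu_N_by_class", "sigma_N", "rho"),
}

#: fixed parameter counts entering the BIC penalty
PATTERN_K: dict[int, int] = {1: 6, 2: 6, 3: 8, 4: 8, 5: 7, 6: 10}

SIGMA_FLOOR = 1e-6
_RHO_CAP = 1.0 - 1e-9
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class PatternTheta:
    """Parameter set for one pattern; only the fields the pattern's theta
    lists are populated (see :data:`PATTERN_FIELDS`)."""

    mu_R_by_class: np.ndarray | None = None
    sigma_R: float | None = None
    mu_N_by_class: np.ndarray | None = None
    sigma_N: float | None = None
    rho: float | None = None
    mu_R: float | None = None
    mu_N: float | None = None
    degenerate: bool = False

    def validate_for(self, pattern_id: int) -> None:
        if pattern_id not in PATTERN_IDS:
            raise ContractError(f"pattern_id must be 1..6, got {pattern_id}")
        for name in PATTERN_FIELDS[pattern_id]:
            if getattr(self, name) is None:
                raise ContractError(
                    f"pattern {pattern_id} requires theta field '{name}'"
                )
        for name in ("sigma_R", "sigma_N"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.rho is not None and not -1.0 < self.rho < 1.0:
            raise ParameterError("rho must lie in (-1, 1)")


@dataclass
class FitResult:
    theta: PatternTheta
    log_likelihood: float
    converged: bool = True
    method: str = "closed_form"


@dataclass
class PatternFit:
    """Full classification record for one trio."""

    fits: dict[int, FitResult]
    bics: np.ndarray
    dbics: np.ndarray
    weights: np.ndarray
    selected_pattern: int
    form: str
    n: int
    tie_broken: bool = False

    @property
    def log_likelihoods(self) -> np.ndarray:
        return np.array([self.fits[p].log_likelihood for p in PATTERN_IDS])


def _check_trio(trio: TrioData) -> None:
    if not isinstance(trio, TrioData):
        raise ContractError("expected a TrioData instance")


def _gauss_logpdf(x: np.ndarray, mu: np.ndarray | float, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mu) ** 2 / var)


def _r_logdens(pattern_id: int, theta: PatternTheta, r: np.ndarray,
               classes: np.ndarray) -> np.ndarray:
    """log f_R(R_i | class) for the given class assignment per entry."""
    if pattern_id in (1, 3, 4, 6):
        mu = np.asarray(theta.mu_R_by_class)[classes]
    else:  # patterns 2 and 5: marginal R
        mu = theta.mu_R
    return _gauss_logpdf(r, mu, theta.sigma_R**2)


def _n_logdens(pattern_id: int, theta: PatternTheta, r: np.ndarray,
               n_vals: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """log f_N(N_i | ...) under the pattern's protein component."""
    if pattern_id == 1:
        return _gauss_logpdf(n_vals, theta.mu_N, theta.sigma_N**2)
    if pattern_id in (2, 3):
        mu = np.asarray(theta.mu_N_by_class)[classes]
        return _gauss_logpdf(n_vals, mu, theta.sigma_N**2)
    slope = theta.rho * theta.sigma_N / theta.sigma_R
    var = (1.0 - theta.rho**2) * theta.sigma_N**2
    if pattern_id == 4:
        mu = theta.mu_N + slope * (r - theta.mu_R)
    else:  # patterns 5 and 6
        mu = np.asarray(theta.mu_N_by_class)[classes] + slope * (r - theta.mu_R)
    return _gauss_logpdf(n_vals, mu, var)


def pattern_loglik(
    pattern_id: int,
    trio: TrioData,
    theta: PatternTheta,
    form: str = "observed",
) -> float:
    """Log-likelihood of one pattern for a trio.

    ``observed`` evaluates each individual at their own genotype class;
    ``mixture`` marginalizes the class inside the per-individual term.
    """
    _check_trio(trio)
    theta.validate_for(pattern_id)
    priors = trio.class_priors
    if form == "observed":
        with np.errstate(divide="ignore"):
            log_prior = np.log(priors)[trio.S]
        ll = (
            log_prior
            + _r_logdens(pattern_id, theta, trio.R, trio.S)
            + _n_logdens(pattern_id, theta, trio.R, trio.N, trio.S)
        )
        return float(ll.sum())
    if form == "mixture":
        terms = np.full((trio.n, 3), -np.inf)
        for j in range(3):
            if priors[j] <= 0:
                continue
            cls = np.full(trio.n, j)
            terms[:, j] = (
                np.log(priors[j])
                + _r_logdens(pattern_id, theta, trio.R, cls)
                + _n_logdens(pattern_id, theta, trio.R, trio.N, cls)
            )
        return float(logsumexp(terms, axis=1).sum())
    raise ParameterError(f"unknown likelihood form: {form!r}")


# ---------------------------------------------------------------------------
# closed-form maximum likelihood (observed form)
# ---------------------------------------------------------------------------


def _class_means(x: np.ndarray, classes: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class sample means and the pooled MLE variance around them.

    Empty classes get mean 0 (they contribute no likelihood terms and
    the parameter count is deliberately NOT reduced)."""
    means = np.zeros(3)
    ss = 0.0
    for j in range(3):
        mask = classes == j
        if mask.any():
            means[j] = x[mask].mean()
            ss += ((x[mask] - means[j]) ** 2).sum()
    return means, ss / x.size


def _marginal(x: np.ndarray) -> tuple[float, float]:
    mu = float(x.mean())
    return mu, float(((x - mu) ** 2).mean())


def _safe_sigma(var: float) -> tuple[float, bool]:
    sigma = float(np.sqrt(max(var, 0.0)))
    if sigma < SIGMA_FLOOR:
        return SIGMA_FLOOR, True
    return sigma, False


def _regress(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float((resid @ resid) / y.size)


def _bivariate_from_regression(
    slope: float, resid_var: float, sigma_R: float
) -> tuple[float, float, bool]:
    """Recover (sigma_N, rho) from a fitted N-on-R regression.

    The conditional density is parameterized by ``slope = rho sigma_N /
    sigma_R`` and ``resid_var = (1 - rho^2) sigma_N^2``; inverting gives
    ``sigma_N^2 = resid_var + slope^2 sigma_R^2``.
    """
    var_N = resid_var + slope**2 * sigma_R**2
    sigma_N, deg = _safe_sigma(var_N)
    rho = slope * sigma_R / sigma_N
    if abs(rho) >= _RHO_CAP:
        rho = float(np.sign(rho)) * _RHO_CAP
        deg = True
    return sigma_N, float(rho), deg


def closed_form_mle(pattern_id: int, trio: TrioData) -> PatternTheta:
    """Exact observed-form MLE via group means, pooled variances and
    regression identities.

    For the mediated patterns (4-6) the mRNA-conditional protein
    component is an unrestricted linear regression of N on R (plus class
    indicators for 5 and 6); its slope and residual variance map back to
    (rho, sigma_N) with sigma_R taken from the mRNA component.  The free
    marginal mean ``mu_R`` in thetas 4-6 is redundant (only
    ``mu - slope * mu_R`` is identified) and is fixed at the sample mean
    of R.
    """
    _check_trio(trio)
    if pattern_id not in PATTERN_IDS:
        raise ContractError(f"pattern_id must be 1..6, got {pattern_id}")
    r, n_vals, classes = trio.R, trio.N, trio.S
    degenerate = False

    if pattern_id in (1, 3, 4, 6):
        mu_r_cls, var_r = _class_means(r, classes)
        mu_r_marg = float(r.mean())
    else:
        mu_r_marg, var_r = _marginal(r)
        mu_r_cls = None
    sigma_R, deg = _safe_sigma(var_r)
    degenerate |= deg

    theta = PatternTheta(sigma_R=sigma_R)
    if mu_r_cls is not None:
        theta.mu_R_by_class = mu_r_cls
    if pattern_id in (2, 4, 5, 6):
        theta.mu_R = mu_r_marg

    if pattern_id == 1:
        mu_n, var_n = _marginal(n_vals)
        theta.mu_N = mu_n
        theta.sigma_N, deg = _safe_sigma(var_n)
        degenerate |= deg
    elif pattern_id in (2, 3):
        mu_n_cls, var_n = _class_means(n_vals, classes)
        theta.mu_N_by_class = mu_n_cls
        theta.sigma_N, deg = _safe_sigma(var_n)
        degenerate |= deg
    elif pattern_id == 4:
        design = np.column_stack([np.ones(trio.n), r])
        coef, resid_var = _regress(n_vals, design)
        sigma_N, rho, deg = _bivariate_from_regression(coef[1], resid_var, sigma_R)
        theta.sigma_N, theta.rho = sigma_N, rho
        theta.mu_N = float(coef[0] + coef[1] * mu_r_marg)
        degenerate |= deg
    else:  # patterns 5 and 6: N on class indicators + R
        present = sorted(np.unique(classes))
        dummies = np.column_stack([(classes == j).astype(float) for j in present])
        design = np.column_stack([dummies, r])
        coef, resid_var = _regress(n_vals, design)
        slope = float(coef[-1])
        sigma_N, rho, deg = _bivariate_from_regression(slope, resid_var, sigma_R)
        mu_n_cls = np.zeros(3)
        for idx, j in enumerate(present):
            mu_n_cls[j] = coef[idx] + slope * mu_r_marg
        theta.mu_N_by_class = mu_n_cls
        theta.sigma_N, theta.rho = sigma_N, rho
        degenerate |= deg

    theta.degenerate = degenerate
    theta.validate_for(pattern_id)
    return theta


# ---------------------------------------------------------------------------
# numerical maximum likelihood
# ---------------------------------------------------------------------------

# packing order mirrors the printed theta lists; sigmas are
# log-parameterized and rho is atanh-parameterized
_PACKING: dict[int, tuple[str, ...]] = {
    1: ("mu_R_by_class", "log_sigma_R", "mu_N", "log_sigma_N"),
    2: ("mu_R", "log_sigma_R", "mu_N_by_class", "log_sigma_N"),
    3: ("mu_R_by_class", "log_sigma_R", "mu_N_by_class", "log_sigma_N"),
    4: ("mu_R_by_class", "log_sigma_R", "mu_N", "log_sigma_N", "z_rho", "mu_R"),
    5: ("mu_R", "log_sigma_R", "mu_N_by_class", "log_sigma_N", "z_rho"),
    6: ("mu_R_by_class", "mu_R", "log_sigma_R", "mu_N_by_class", "log_sigma_N", "z_rho"),
}

_SLOT_SIZE = {"mu_R_by_class": 3, "mu_N_by_class": 3}


def _unpack(pattern_id: int, x: np.ndarray) -> PatternTheta:
    theta = PatternTheta()
    i = 0
    for slot in _PACKING[pattern_id]:
        size = _SLOT_SIZE.get(slot, 1)
        chunk = x[i : i + size]
        i += size
        if slot == "log_sigma_R":
            theta.sigma_R = float(np.exp(chunk[0]))
        elif slot == "log_sigma_N":
            theta.sigma_N = float(np.exp(chunk[0]))
        elif slot == "z_rho":
            theta.rho = float(np.tanh(chunk[0]))
        elif size == 3:
            setattr(theta, slot, np.asarray(chunk, dtype=float))
        else:
            setattr(theta, slot, float(chunk[0]))
    return theta


def _pack(pattern_id: int, theta: PatternTheta) -> np.ndarray:
    out: list[float] = []
    for slot in _PACKING[pattern_id]:
        if slot == "log_sigma_R":
            out.append(np.log(max(theta.sigma_R, SIGMA_FLOOR)))
        elif slot == "log_sigma_N":
            out.append(np.log(max(theta.sigma_N, SIGMA_FLOOR)))
        elif slot == "z_rho":
            rho = np.clip(theta.rho, -_RHO_CAP, _RHO_CAP)
            out.append(np.arctanh(rho))
        elif _SLOT_SIZE.get(slot, 1) == 3:
            out.extend(np.asarray(getattr(theta, slot), dtype=float))
        else:
            out.append(float(getattr(theta, slot)))
    return np.array(out)


def _n_params_packed(pattern_id: int) -> int:
    return sum(_SLOT_SIZE.get(s, 1) for s in _PACKING[pattern_id])


def _bounds(pattern_id: int) -> list[tuple[float, float]]:
    bounds = []
    for slot in _PACKING[pattern_id]:
        size = _SLOT_SIZE.get(slot, 1)
        if slot.startswith("log_sigma"):
            bounds.append((np.log(SIGMA_FLOOR), 20.0))
        elif slot == "z_rho":
            bounds.append((-15.0, 15.0))
        else:
            bounds.extend([(-1e6, 1e6)] * size)
    return bounds


def fit_pattern_mle(
    pattern_id: int,
    trio: TrioData,
    form: str = "observed",
    n_restarts: int = 2,
) -> FitResult:
    """Numerical maximum likelihood for one pattern.

    Optimization runs in an unconstrained parameterization (log sigmas,
    atanh rho) starting from the standard initial values mean 0, SD 1,
    rho 0, with bounded restarts; for the observed form the closed-form
    estimates provide an additional start, and the best optimum is kept.
    """
    _check_trio(trio)
    if pattern_id not in PATTERN_IDS:
        raise ContractError(f"pattern_id must be 1..6, got {pattern_id}")

    def neg_ll(x: np.ndarray) -> float:
        theta = _unpack(pattern_id, x)
        try:
            return -pattern_loglik(pattern_id, trio, theta, form)
        except (ParameterError, FloatingPointError):
            return np.inf

    starts = [np.zeros(_n_params_packed(pattern_id))]
    if form == "observed":
        starts.append(_pack(pattern_id, closed_form_mle(pattern_id, trio)))
    rng = np.random.default_rng(pattern_id)
    for _ in range(n_restarts):
        starts.append(starts[0] + rng.normal(0, 0.5, size=starts[0].size))

    best_x, best_val, converged = None, np.inf, False
    bounds = _bounds(pattern_id)
    for x0 in starts:
        res = optimize.minimize(
            neg_ll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-10},
        )
        if res.fun < best_val:
            best_x, best_val, converged = res.x, float(res.fun), bool(res.success)
    if best_x is None or not np.isfinite(best_val):
        return FitResult(PatternTheta(), -np.inf, converged=False, method="numeric")
    theta = _unpack(pattern_id, best_x)
    return FitResult(theta, -best_val, converged=converged, method="numeric")


# ---------------------------------------------------------------------------
# scoring and selection
# ---------------------------------------------------------------------------


def bic_score(log_likelihood: float, k: int, n: int) -> float:
    """``BIC = -2 logL + k ln(n)``."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if k < 0:
        raise ParameterError("k must be >= 0")
    return -2.0 * log_likelihood + k * np.log(n)


def bic_weights(bics: np.ndarray, exponent: float = 1.0) -> np.ndarray:
    """Selection weights ``exp(-exponent * dBIC_i) / sum``.

    ``exponent = 1.0`` exponentiates the raw BIC difference; the
    conventional Schwarz-weight variant uses ``exponent = 0.5``.
    """
    b = np.asarray(bics, dtype=float)
    if not np.isfinite(b).all():
        raise ParameterError("BIC values must be finite")
    d = b - b.min()
    w = np.exp(-exponent * d)
    return w / w.sum()


_BIC_TIE_TOL = 1e-9


def classify_trio(
    trio: TrioData,
    form: str = "observed",
    weight_exponent: float = 1.0,
) -> PatternFit:
    """Fit all six patterns, score by BIC, and select the minimum.

    The observed form uses the exact closed-form MLE; the mixture form
    is fit numerically.  BIC ties within 1e-9 resolve to the lower
    pattern id.
    """
    _check_trio(trio)
    fits: dict[int, FitResult] = {}
    for pid in PATTERN_IDS:
        if form == "observed":
            theta = closed_form_mle(pid, trio)
            ll = pattern_loglik(pid, trio, theta, form="observed")
            fits[pid] = FitResult(theta, ll, converged=True, method="closed_form")
        else:
            fits[pid] = fit_pattern_mle(pid, trio, form=form)
    if not all(np.isfinite(f.log_likelihood) for f in fits.values()):
        raise DegenerateDataError("a pattern fit failed; trio excluded")

    bics = np.array(
        [bic_score(fits[p].log_likelihood, PATTERN_K[p], trio.n) for p in PATTERN_IDS]
    )
    near_min = np.nonzero(bics <= bics.min() + _BIC_TIE_TOL)[0]
    selected = int(PATTERN_IDS[near_min[0]])
    weights = bic_weights(bics, exponent=weight_exponent)
    return PatternFit(
        fits=fits,
        bics=bics,
        dbics=bics - bics.min(),
        weights=weights,
        selected_pattern=selected,
        form=form,
        n=trio.n,
        tie_broken=near_min.size > 1,
    )
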