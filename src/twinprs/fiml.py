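"""Multigroup full-information maximum likelihood over pair records.

The Gaussian likelihood is evaluated on each pair's *observed* subvector
(arbitrary per-cell missingness). Rows are grouped by missingness pattern and
reduced to per-pattern sufficient statistics (count, mean, ML scatter), so a
likelihood evaluation costs O(#patterns), not O(#pairs):

    -2LL = sum over patterns  n_p * [ k log 2*pi + log|S_o| + tr(S_o^{-1} W_p)
                                      + (m_p - mu_o)' S_o^{-1} (m_p - mu_o) ]

where (mu_o, S_o) are the model moments marginalized to the pattern's
observed entries and (m_p, W_p) the pattern mean and scatter. Pairs with all
cells missing contribute zero and are counted.

Optimization is bound-constrained L-BFGS-B with multi-start jitter;
confidence intervals are profile-likelihood (re-optimizing the remaining free
parameters), the convention of mainstream SEM software for twin models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .moments import MomentModel, IdentificationReport, check_identification
from .pair_data import PairDataset

__all__ = [
    "PatternData",
    "FitOptions",
    "FitResult",
    "fiml_neg2ll",
    "fit_model",
    "profile_ci",
    "wald_covariance",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class _Pattern:
    mask: np.ndarray      # bool, length 2m, True = observed
    n: int
    mean: np.ndarray      # (k,)
    scatter: np.ndarray   # (k, k), ML (denominator n)


@dataclass
class PatternData:
    """Per-group missingness-pattern sufficient statistics."""

    patterns: dict[str, list[_Pattern]]
    n_pairs: dict[str, int]
    n_all_missing: dict[str, int]
    n_vars: int  # per member

    @classmethod
    def from_dataset(cls, data: PairDataset, variables: list[str],
                     groups=("MZ", "DZ", "SIB"),
                     mz_duplicates=()) -> "PatternData":
        patterns: dict[str, list[_Pattern]] = {}
        n_pairs: dict[str, int] = {}
        n_empty: dict[str, int] = {}
        for g in groups:
            X = data.member_matrix(list(variables), group=g)
            if g == "MZ" and mz_duplicates:
                X = _collapse_duplicates(X, mz_duplicates)
            patterns[g], n_pairs[g], n_empty[g] = cls._summarize(X)
        return cls(patterns, n_pairs, n_empty, len(variables))

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray], n_vars: int,
                    mz_duplicates=()) -> "PatternData":
        patterns, n_pairs, n_empty = {}, {}, {}
        for g, X in arrays.items():
            X = np.asarray(X, float)
            if g == "MZ" and mz_duplicates:
                X = _collapse_duplicates(X, mz_duplicates)
            patterns[g], n_pairs[g], n_empty[g] = cls._summarize(X)
        return cls(patterns, n_pairs, n_empty, n_vars)

    @staticmethod
    def _summarize(X: np.ndarray):
        obs = np.isfinite(X)
        out: list[_Pattern] = []
        n_empty = 0
        if len(X) == 0:
            return out, 0, 0
        # encode each row's pattern as an integer key
        keys = obs @ (1 << np.arange(X.shape[1]))
        for key in np.unique(keys):
            rows = X[keys == key]
            mask = obs[np.argmax(keys == key)]
            if not mask.any():
                n_empty += len(rows)
                continue
            sub = rows[:, mask]
            m = sub.mean(axis=0)
            d = sub - m
            out.append(_Pattern(mask=mask, n=len(rows), mean=m,
                                scatter=(d.T @ d) / len(rows)))
        return out, len(X), n_empty


def _collapse_duplicates(X: np.ndarray, pairs) -> np.ndarray:
    """Keep one observed copy of variables that are exact duplicates (MZ PRSs).

    The joint distribution of both copies is degenerate (singular expected
    covariance), so the likelihood is defined on the reduced vector: where
    both copies are observed the second is dropped; where only the second is
    observed it is moved into the first slot.
    """
    X = X.copy()
    for i, j in pairs:
        move = ~np.isfinite(X[:, i]) & np.isfinite(X[:, j])
        X[move, i] = X[move, j]
        X[:, j] = np.nan
    return X


def _neg2ll_patterns(patterns: PatternData, moments) -> tuple[float, int]:
    """(-2LL, count of non-PSD marginal covariances encountered)."""
    total = 0.0
    bad = 0
    for g, plist in patterns.patterns.items():
        if not plist:
            continue
        mu, sigma = moments[g]
        for pat in plist:
            mu_o = mu[pat.mask]
            sig_o = sigma[np.ix_(pat.mask, pat.mask)]
            try:
                chol = np.linalg.cholesky(sig_o)
            except np.linalg.LinAlgError:
                return np.inf, bad + 1
            d = np.diag(chol)
            if np.any(d < 1e-12):
                return np.inf, bad + 1
            logdet = 2.0 * np.sum(np.log(d))
            dev = pat.mean - mu_o
            y = solve_triangular(chol, dev, lower=True)
            quad = float(y @ y)
            B = solve_triangular(chol, pat.scatter, lower=True)
            A = solve_triangular(chol, B.T, lower=True)
            trace = float(np.trace(A))
            total += pat.n * (len(mu_o) * _LOG2PI + logdet + trace + quad)
    return total, bad


def fiml_neg2ll(model: MomentModel, data, theta, variables: list[str] | None = None) -> float:
    """-2 log-likelihood of ``data`` under ``model`` at parameter vector ``theta``.

    ``data`` may be a PairDataset (``variables`` then selects the observed
    columns, in model order) or a precomputed PatternData.
    """
    patterns = _as_patterns(model, data, variables)
    value, _ = _neg2ll_patterns(patterns, model.group_moments(np.asarray(theta, float)))
    return value


def _as_patterns(model: MomentModel, data, variables) -> PatternData:
    if isinstance(data, PatternData):
        return data
    if variables is None:
        raise ValueError("pass `variables` when data is a PairDataset")
    return PatternData.from_dataset(data, variables, groups=tuple(model.groups),
                                    mz_duplicates=model.mz_duplicate_pairs)


@dataclass
class FitOptions:
    n_starts: int = 5
    jitter: float = 0.1      # jitter scale on standardized data
    seed: int = 0
    gtol: float = 1e-5
    maxiter: int = 500
    check_identification: bool = True
    start: np.ndarray | None = None  # extra user-supplied start


@dataclass
class FitResult:
    estimates: dict[str, float]
    theta: np.ndarray
    minus2LL: float
    n_free: int
    converged: bool
    status: str
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_flags: dict[str, str] = field(default_factory=dict)
    identification: IdentificationReport | None = None
    n_pairs: dict[str, int] = field(default_factory=dict)
    n_nonpsd: int = 0
    param_names: list[str] = field(default_factory=list)

    @property
    def AIC(self) -> float:
        return self.minus2LL + 2.0 * self.n_free

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates, "minus2LL": self.minus2LL,
            "n_free": self.n_free, "AIC": self.AIC, "converged": self.converged,
            "status": self.status, "ci": {k: list(v) for k, v in self.ci.items()},
            "n_pairs": self.n_pairs,
        }


# finite stand-in for +inf inside the optimizer: L-BFGS-B's line search
# cannot interpolate across inf, but backtracks correctly off a large
# finite plateau
_PENALTY = 1e10


def _objective(model, patterns):
    counter = {"bad": 0}

    def f(theta):
        try:
            mom = model.group_moments(theta)
        except (ValueError, np.linalg.LinAlgError):
            counter["bad"] += 1
            return _PENALTY
        val, bad = _neg2ll_patterns(patterns, mom)
        counter["bad"] += bad
        return val if np.isfinite(val) else _PENALTY

    return f, counter


def fit_model(model: MomentModel, data, options: FitOptions | None = None,
              variables: list[str] | None = None) -> FitResult:
    """Minimize the FIML -2LL over the model's free parameters.

    Multi-start: the model's default start plus jittered copies; the best
    optimum is kept. Convergence requires a finite optimum with projected
    gradient below tolerance and, when several starts succeed, the best two
    agreeing in -2LL within 1e-4.
    """
    opts = options or FitOptions()
    patterns = _as_patterns(model, data, variables)
    if all(n == 0 for n in patterns.n_pairs.values()):
        raise ValueError("no data in any included group")
    f, counter = _objective(model, patterns)
    bounds = model.bounds()
    rng = np.random.default_rng(opts.seed)

    starts = [model.start()]
    if opts.start is not None:
        starts.insert(0, np.asarray(opts.start, float))
    while len(starts) < max(1, opts.n_starts):
        starts.append(_jitter(starts[0], bounds, rng, opts.jitter))

    def _minimize(x0):
        return optimize.minimize(f, x0, method="L-BFGS-B", bounds=bounds,
                                 options={"maxiter": opts.maxiter,
                                          "gtol": opts.gtol, "ftol": 1e-12})

    results = []
    for x0 in starts:
        if f(x0) >= _PENALTY:
            x0 = _jitter(x0, bounds, rng, 0.3)
        try:
            res = _minimize(x0)
            # restarting L-BFGS-B resets its curvature memory and escapes
            # premature line-search stalls; repeat while it still improves
            for _ in range(3):
                res2 = _minimize(res.x)
                if res.fun - res2.fun < 1e-8 * max(1.0, abs(res.fun)):
                    res = res2 if res2.fun < res.fun else res
                    break
                res = res2
        except (ValueError, np.linalg.LinAlgError):
            continue
        if np.isfinite(res.fun) and res.fun < _PENALTY / 2:
            results.append(res)

    if not results:
        return FitResult(estimates={}, theta=np.full(model.n_free, np.nan),
                         minus2LL=np.inf, n_free=model.n_free, converged=False,
                         status="all starts failed", n_pairs=patterns.n_pairs,
                         n_nonpsd=counter["bad"], param_names=list(model.param_names))

    results.sort(key=lambda r: r.fun)
    best = results[0]
    gnorm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.inf
    # finite-difference gradient noise scales with |f|, so the tolerance is
    # relative to the -2LL magnitude
    grad_ok = gnorm <= opts.gtol * max(1.0, abs(best.fun))
    agree = True
    if len(results) >= 2:
        agree = (results[1].fun - best.fun) < 1e-4
    converged = bool(best.success or grad_ok) and np.isfinite(best.fun) and (agree or grad_ok)

    ident = None
    if opts.check_identification:
        ident = check_identification(model, best.x)
        if not ident.identified:
            converged = converged  # fit is reported, identification flag carries the warning

    return FitResult(
        estimates=dict(zip(model.param_names, best.x.astype(float))),
        theta=best.x.copy(), minus2LL=float(best.fun), n_free=model.n_free,
        converged=converged, status=str(best.message),
        identification=ident, n_pairs=patterns.n_pairs,
        n_nonpsd=counter["bad"], param_names=list(model.param_names),
    )


def _jitter(x0, bounds, rng, scale):
    x = x0 + rng.normal(0.0, scale, size=len(x0))
    for j, (lo, hi) in enumerate(bounds):
        if lo is not None:
            x[j] = max(x[j], lo + 1e-8 if lo == 0 else lo)
        if hi is not None:
            x[j] = min(x[j], hi)
    return x


def _profile_value(model, patterns, fixed_idx, fixed_value, start, bounds):
    """Min -2LL with one parameter fixed (re-optimizing the rest)."""
    free_idx = [j for j in range(len(start)) if j != fixed_idx]
    f, _ = _objective(model, patterns)

    def g(sub):
        full = np.empty(len(start))
        full[fixed_idx] = fixed_value
        full[free_idx] = sub
        return f(full)

    sub0 = start[free_idx]
    sub_bounds = [bounds[j] for j in free_idx]
    if not free_idx:
        return g(np.empty(0)), start
    res = optimize.minimize(g, sub0, method="L-BFGS-B", bounds=sub_bounds,
                            options={"maxiter": 300, "ftol": 1e-12})
    full = np.empty(len(start))
    full[fixed_idx] = fixed_value
    full[free_idx] = res.x
    return float(res.fun), full


def profile_ci(fit: FitResult, model: MomentModel, data, param: str,
               level: float = 0.95, variables=None) -> tuple[float, float, str]:
    """Profile-likelihood CI: the -2LL rises by the chi-square(1) quantile.

    Returns (lower, upper, flag); flag is "" or contains "lower-boundary" /
    "upper-boundary" when the interval was clipped at a structural bound, or
    "lower-open" / "upper-open" when the profile never reached the threshold.
    """
    if not fit.converged:
        raise ValueError("profile CI requires a converged fit")
    patterns = _as_patterns(model, data, variables)
    q = stats.chi2.ppf(level, df=1)  # 3.841 at 95%
    idx = model.param_names.index(param)
    bounds = model.bounds()
    est = fit.theta[idx]
    target = fit.minus2LL + q

    flags = []
    out = []
    for direction in (-1.0, +1.0):
        bound = bounds[idx][0] if direction < 0 else bounds[idx][1]
        limit = -np.inf if bound is None else bound
        if direction > 0:
            limit = np.inf if bound is None else bound
        step = max(0.1, 0.5 * abs(est))
        x_in, f_in = est, fit.minus2LL
        warm = fit.theta.copy()
        x_out = None
        hit_bound = False
        for _ in range(40):
            cand = x_in + direction * step
            if direction < 0 and cand <= limit:
                cand = limit
                hit_bound = True
            if direction > 0 and cand >= limit:
                cand = limit
                hit_bound = True
            val, warm = _profile_value(model, patterns, idx, cand, warm, bounds)
            if val >= target:
                x_out, f_out = cand, val
                break
            x_in, f_in = cand, val
            if hit_bound:
                break
            step *= 1.6
        side = "lower" if direction < 0 else "upper"
        if x_out is None:
            out.append(x_in)
            flags.append(f"{side}-boundary" if hit_bound else f"{side}-open")
            continue

        def h(v, warm_box=[warm]):
            val, warm_box[0] = _profile_value(model, patterns, idx, v, warm_box[0], bounds)
            return val - target

        lo, hi = sorted((x_in, x_out))
        try:
            root = optimize.brentq(h, lo, hi, xtol=1e-5, rtol=1e-6, maxiter=60)
        except ValueError:
            root = x_out
        out.append(root)
    lower, upper = out
    return float(lower), float(upper), ";".join(flags)


def wald_covariance(model: MomentModel, data, theta, variables=None,
                    step: float = 1e-4) -> np.ndarray:
    """Asymptotic covariance 2*H^{-1} from the numeric Hessian H of -2LL."""
    patterns = _as_patterns(model, data, variables)
    f, _ = _objective(model, patterns)
    theta = np.asarray(theta, float)
    k = len(theta)
    H = np.empty((k, k))
    hs = step * np.maximum(1.0, np.abs(theta))
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            if i == j:
                val = (f(theta + ei) - 2 * f0 + f(theta - ei)) / hs[i] ** 2
            else:
                val = (f(theta + ei + ej) - f(theta + ei - ej)
                       - f(theta - ei + ej) + f(theta - ei - ej)) / (4 * hs[i] * hs[j])
            H[i, j] = H[j, i] = val
    try:
        return 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return 2.0 * np.linalg.pinv(H)
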