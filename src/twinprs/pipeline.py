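"""The analysis sequence: assumption tests, twin correlations, model ladders, FDR.

Mirrors the standard workflow for a polygenic-score-augmented twin study:

1. mean/variance homogeneity checks against the fully saturated pair model;
2. FIML twin-pair correlations per relative group with profile CIs;
3. a univariate ACE/AE/CE/E ladder per phenotype, compared by delta -2LL
   (chi-square with df = difference in free parameters) and preferred by AIC;
4. a two-stage multivariate ladder: residual structure first (with both PRS
   paths and the PRS-PRS correlation free), then path-dropping tests for
   b31, b21, both, and a32 from the preferred structure;
5. Benjamini-Hochberg FDR within analysis groups.

Variance-component likelihood-ratio tests use the naive chi-square reference
(no boundary mixture correction), matching common twin-modelling practice;
this is conservative for parameters on the boundary (c11, a11) and exact for
the sign-free PRS paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import fiml
from .fiml import FitOptions, FitResult, PatternData, fit_model, profile_ci
from .moments import (SUBMODELS, MomentModel, PRSAugmentedModel, SaturatedModel,
                      build_prs_augmented, build_saturated, build_univariate_ace)
from .pair_data import GROUPS, PairDataset

__all__ = [
    "ComparisonRow", "StandardizedSummary", "ScreenRow",
    "homogeneity_tests", "twin_correlations", "falconer_estimate",
    "univariate_ladder", "multivariate_ladder", "bh_fdr",
    "standardize_estimates", "lmm_prs_screen",
    "PUBLISHED_PRS_SCREEN",
]

# Published mixed-model screen of each ROI on its own PRS in the ABCD European
# twin/sibling subsample (beta, SE, t, marginal R^2, conditional R^2); used as
# reference inputs for arithmetic-consistency checks.
PUBLISHED_PRS_SCREEN: dict[str, tuple[float, float, float, float, float]] = {
    "cortical_surface": (-0.06, 0.01, -4.62, 0.00, 0.64),
    "cortical_thickness": (0.18, 0.01, 13.47, 0.03, 0.48),
    "hippocampus": (0.13, 0.01, 9.93, 0.02, 0.56),
    "nucleus_accumbens": (0.10, 0.01, 7.65, 0.01, 0.49),
    "thalamus": (0.11, 0.01, 8.14, 0.01, 0.57),
    "putamen": (0.17, 0.01, 12.70, 0.03, 0.59),
    "caudate": (0.18, 0.01, 13.66, 0.03, 0.58),
    "amygdala": (0.10, 0.01, 7.07, 0.01, 0.53),
}


@dataclass
class ComparisonRow:
    """One model in a nested-comparison ladder."""

    label: str
    minus2LL: float
    n_free: int
    delta_minus2LL: float | None = None  # vs the ladder's reference model
    delta_df: int | None = None
    p_value: float | None = None
    AIC: float = np.nan
    preferred: bool = False
    converged: bool = True

    @classmethod
    def from_fit(cls, label: str, fit: FitResult, reference: FitResult | None = None):
        row = cls(label=label, minus2LL=fit.minus2LL, n_free=fit.n_free,
                  AIC=fit.AIC, converged=fit.converged)
        if reference is not None and reference is not fit:
            row.delta_minus2LL = fit.minus2LL - reference.minus2LL
            row.delta_df = reference.n_free - fit.n_free
            if row.delta_df > 0:
                row.p_value = float(stats.chi2.sf(max(row.delta_minus2LL, 0.0),
                                                  df=row.delta_df))
        return row


@dataclass
class StandardizedSummary:
    """Standardized summary of a fitted PRS-augmented model.

    ``a_share``/``c_share``/``e_share`` are residual-relative (each component
    over a11^2 + c11^2 + e11^2), the convention of published twin-model
    summary tables. The ``*_total`` shares divide by the total phenotypic
    variance including the PRS-explained part and sum to one with
    ``prs_share_total``. b21/b31 are reported as fitted (unit-variance PRSs).
    """

    a_share: float
    c_share: float
    e_share: float
    a_share_total: float
    c_share_total: float
    e_share_total: float
    prs_share_total: float
    b21: float | None
    b31: float | None
    a32: float | None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_row(self, ndigits: int = 2) -> dict:
        r = lambda v: None if v is None else round(v, ndigits)
        return {"A": r(self.a_share), "C": r(self.c_share), "E": r(self.e_share),
                "b21": r(self.b21), "b31": r(self.b31), "a32": r(self.a32)}


@dataclass
class ScreenRow:
    """Random-intercept mixed-model screen of one phenotype on one PRS."""

    beta: float
    se: float
    t_stat: float
    marginal_r2: float
    conditional_r2: float
    flag: str = ""


# --------------------------------------------------------------------------
# Assumption tests and correlations
# --------------------------------------------------------------------------


def _present_groups(data: PairDataset, variable: str):
    groups = []
    for g in GROUPS:
        X = data.member_matrix([variable], group=g)
        if len(X) and np.isfinite(X).any():
            groups.append(g)
        else:
            warnings.warn(f"group {g} empty for {variable!r}; dropped from ladder")
    return tuple(groups)


def homogeneity_tests(data: PairDataset, variable: str,
                      options: FitOptions | None = None,
                      by_sex: bool = False, sex_variable: str = "sex") -> list[ComparisonRow]:
    """Saturated-model ladder testing mean/variance homogeneity.

    Free (unstructured) pair moments per group, then means and variances
    equated within pairs, then additionally across the MZ/DZ/SIB groups, then
    the DZ and sibling correlations equated; each constrained model is
    compared to the free model by delta -2LL. With ``by_sex`` an additional
    row tests mean/variance equality across sex on stacked individuals
    (a plain two-group normal LRT, ignoring family clustering).
    """
    groups = _present_groups(data, variable)
    opts = options or FitOptions(n_starts=2, check_identification=False)
    fits = {}
    for level in ("none", "within-pair", "within-pair+across-group",
                  "within-pair+across-group+dzsib"):
        model = build_saturated(level, groups=groups)
        patterns = PatternData.from_dataset(data, [variable], groups=groups)
        start = _saturated_start(model, patterns)
        o = FitOptions(n_starts=opts.n_starts, seed=opts.seed,
                       check_identification=False, start=start)
        fits[level] = (model, fit_model(model, patterns, o))
    ref = fits["none"][1]
    rows = [ComparisonRow.from_fit("free", ref)]
    labels = {"within-pair": "within-pair equal",
              "within-pair+across-group": "within-pair + across-group equal",
              "within-pair+across-group+dzsib": "+ DZ = SIB correlation"}
    for level, label in labels.items():
        rows.append(ComparisonRow.from_fit(label, fits[level][1], ref))
    _prefer_by_aic(rows)  # pair-likelihood rows only
    if by_sex:
        rows.append(_sex_homogeneity_row(data, variable, sex_variable))
    return rows


def _saturated_start(model: SaturatedModel, patterns: PatternData) -> np.ndarray:
    """Moment-based start from per-group complete-pair sample moments.

    For the unconstrained level on complete data this is already the MLE;
    under constraints or missingness it is a near-optimal warm start.
    """
    stats_g = {}
    for g, plist in patterns.patterns.items():
        best = None
        for p in plist:
            if p.mask.all() and (best is None or p.n > best.n):
                best = p
        if best is not None and best.n > 1:
            stats_g[g] = (best.mean, best.scatter)
    mus = [m for m, _ in stats_g.values()]
    pooled_mu = float(np.mean([m.mean() for m in mus])) if mus else 0.0
    pooled_v = float(np.mean([np.diag(s).mean() for _, s in stats_g.values()])) or 1.0

    def grp(name):
        return name.rsplit("_", 1)[-1]

    out = []
    for name in model.param_names:
        g = grp(name)
        m, s = stats_g.get(g, (None, None))
        if name.startswith("mu1"):
            out.append(m[0] if m is not None else pooled_mu)
        elif name.startswith("mu2"):
            out.append(m[1] if m is not None else pooled_mu)
        elif name.startswith("mu"):
            out.append(m.mean() if m is not None else pooled_mu)
        elif name.startswith("var1"):
            out.append(s[0, 0] if s is not None else pooled_v)
        elif name.startswith("var2"):
            out.append(s[1, 1] if s is not None else pooled_v)
        elif name.startswith("var"):
            out.append(np.diag(s).mean() if s is not None else pooled_v)
        elif name.startswith("cov"):
            out.append(s[0, 1] if s is not None else 0.3 * pooled_v)
        elif name == "r_DZSIB":
            pair = [np.clip(s[0, 1] / np.diag(s).mean(), -0.9, 0.9)
                    for g2, (m2, s) in stats_g.items() if g2 in ("DZ", "SIB")]
            out.append(float(np.mean(pair)) if pair else 0.3)
        else:  # r_<group>
            if s is not None:
                out.append(float(np.clip(s[0, 1] / np.diag(s).mean(), -0.9, 0.9)))
            else:
                out.append(0.3)
    return np.array(out)


def _sex_homogeneity_row(data: PairDataset, variable: str, sex_variable: str) -> ComparisonRow:
    long = data.stacked_individuals([variable, sex_variable])
    y = long[variable].to_numpy(float)
    s = long[sex_variable].to_numpy(float)
    ok = np.isfinite(y) & np.isfinite(s)
    y, s = y[ok], s[ok]
    ll_split = 0.0
    for code in np.unique(s):
        ys = y[s == code]
        ll_split += _norm_neg2ll(ys)
    ll_pool = _norm_neg2ll(y)
    delta = ll_pool - ll_split
    k = len(np.unique(s))
    ddf = 2 * (k - 1)
    return ComparisonRow(label="across-sex equal (individuals)", minus2LL=ll_pool,
                         n_free=2, delta_minus2LL=delta, delta_df=ddf,
                         p_value=float(stats.chi2.sf(max(delta, 0.0), df=ddf)),
                         AIC=ll_pool + 4)


def _norm_neg2ll(y: np.ndarray) -> float:
    v = y.var()  # ML variance
    return len(y) * (np.log(2 * np.pi * v) + 1.0)


def twin_correlations(data: PairDataset, variable: str,
                      options: FitOptions | None = None, ci: bool = True):
    """FIML within-pair correlation per relative group with 95% profile CIs.

    Fits the exchangeable saturated model (means/variances equal within pair,
    free per group) and reads off each group's correlation parameter.
    Returns {group: {"r": ..., "ci": (lo, hi), "flag": ...}}.
    """
    groups = _present_groups(data, variable)
    for g in groups:
        if len(data.member_matrix([variable], group=g)) < 3:
            raise ValueError(f"group {g}: fewer than 3 pairs, correlation undefined")
    model = build_saturated("within-pair", groups=groups)
    patterns = PatternData.from_dataset(data, [variable], groups=groups)
    opts = options or FitOptions(n_starts=2, check_identification=False)
    opts.start = _saturated_start(model, patterns)
    fit = fit_model(model, patterns, opts)
    out = {}
    for g in groups:
        name = f"r_{g}"
        entry = {"r": fit.estimates[name], "ci": None, "flag": ""}
        if ci and fit.converged:
            lo, hi, flag = profile_ci(fit, model, patterns, name)
            entry["ci"] = (lo, hi)
            entry["flag"] = flag
        out[g] = entry
    return out, fit


def falconer_estimate(rmz: float, rdz: float):
    """Classical Falconer decomposition from MZ/DZ correlations.

    h2 = 2(rMZ - rDZ); c2 = 2 rDZ - rMZ; e2 = 1 - rMZ. Raw values are
    returned untruncated with an admissibility flag (components in [0, 1]).
    """
    if abs(rmz) > 1 or abs(rdz) > 1:
        raise ValueError("correlations must lie in [-1, 1]")
    h2 = 2.0 * (rmz - rdz)
    c2 = 2.0 * rdz - rmz
    e2 = 1.0 - rmz
    admissible = all(-1e-12 <= v <= 1 + 1e-12 for v in (h2, c2, e2))
    return h2, c2, e2, admissible


# --------------------------------------------------------------------------
# Model ladders
# --------------------------------------------------------------------------


def univariate_ladder(data: PairDataset, roi: str,
                      options: FitOptions | None = None):
    """Fit ACE, AE, CE, E; compare each submodel to ACE; prefer lowest AIC.

    Returns (rows, preferred_label, fits).
    """
    groups = _present_groups(data, roi)
    patterns = PatternData.from_dataset(data, [roi], groups=groups)
    opts = options or FitOptions(n_starts=3, check_identification=False)
    fits: dict[str, FitResult] = {}
    models: dict[str, MomentModel] = {}
    for sub in ("ACE", "AE", "CE", "E"):
        models[sub] = build_univariate_ace(sub, groups=groups)
        fits[sub] = fit_model(models[sub], patterns, opts)
    rows = [ComparisonRow.from_fit("ACE", fits["ACE"])]
    for sub in ("AE", "CE", "E"):
        rows.append(ComparisonRow.from_fit(sub, fits[sub], fits["ACE"]))
    preferred = _prefer_by_aic(rows)
    return rows, preferred, fits


def _prefer_by_aic(rows: list[ComparisonRow]) -> str:
    ok = [r for r in rows if r.converged and np.isfinite(r.AIC)]
    best = min(ok, key=lambda r: r.AIC)
    for r in rows:
        r.preferred = r is best
    return best.label


def multivariate_ladder(data: PairDataset, roi: str, prs_pair: tuple[str, str],
                        options: FitOptions | None = None,
                        sequential: bool = True, ci: bool = False):
    """Two-stage PRS-augmented model comparison for one phenotype.

    Stage 1: residual-structure ladder (ACE/AE/CE/E, both PRS paths and a32
    free), preferred by AIC. Stage 2: from the preferred structure, drop b31,
    drop b21, drop both (df 2), and drop a32, each tested against the full
    preferred model by delta -2LL. With ``sequential=False`` only the
    single-shot full-ACE comparisons of stage 1 plus the drops from ACE are
    reported. Returns (rows, summary, fits) where ``summary`` is the
    standardized summary of the preferred full model.
    """
    variables = [roi, prs_pair[0], prs_pair[1]]
    groups = _present_groups(data, roi)
    patterns = PatternData.from_dataset(
        data, variables, groups=groups,
        mz_duplicates=PRSAugmentedModel.mz_duplicate_pairs)
    opts = options or FitOptions(n_starts=3, check_identification=False)

    fits: dict[str, FitResult] = {}
    models: dict[str, PRSAugmentedModel] = {}
    for sub in ("ACE", "AE", "CE", "E"):
        models[sub] = build_prs_augmented(sub, groups=groups)
        fits[sub] = fit_model(models[sub], patterns, opts)
    rows = [ComparisonRow.from_fit("ACE", fits["ACE"])]
    for sub in ("AE", "CE", "E"):
        rows.append(ComparisonRow.from_fit(sub, fits[sub], fits["ACE"]))
    structure = _prefer_by_aic(rows) if sequential else "ACE"
    base_model, base_fit = models[structure], fits[structure]

    warm = FitOptions(n_starts=1, seed=opts.seed, check_identification=False,
                      start=None)
    drops = [("drop b31", dict(drop_b31=True)),
             ("drop b21", dict(drop_b21=True)),
             ("drop b21 & b31", dict(drop_b21=True, drop_b31=True)),
             ("drop a32", dict(drop_a32=True))]
    for label, kw in drops:
        m = build_prs_augmented(structure, groups=groups, **kw)
        w = FitOptions(n_starts=warm.n_starts, seed=warm.seed,
                       check_identification=False,
                       start=_restrict_start(base_model, base_fit, m))
        f = fit_model(m, patterns, w)
        row = ComparisonRow.from_fit(f"{structure}: {label}", f, base_fit)
        rows.append(row)
        models[label], fits[label] = m, f

    summary = standardize_estimates(base_fit, base_model, patterns, ci=ci)
    return rows, summary, fits


def _restrict_start(big: MomentModel, big_fit: FitResult, small: MomentModel) -> np.ndarray:
    return np.array([big_fit.estimates.get(n, small.start()[j])
                     for j, n in enumerate(small.param_names)])


# --------------------------------------------------------------------------
# Standardized summaries
# --------------------------------------------------------------------------


def standardize_estimates(fit: FitResult, model: PRSAugmentedModel | None = None,
                          data=None, ci: bool = False,
                          ci_params: tuple[str, ...] = ("a_share", "b21", "b31", "a32"),
                          variables=None) -> StandardizedSummary:
    """Standardized variance shares and PRS paths from a converged fit.

    Residual-relative shares divide each of a11^2/c11^2/e11^2 by their sum;
    total-relative shares divide by the total phenotypic variance
    (a11^2 + c11^2 + e11^2 + b21^2 + b31^2 + 2 b21 b31 a32) and sum to one
    with the PRS-explained share. Path CIs are plain profiles; share CIs
    profile the share itself through an equality-constrained substitution.
    """
    if not fit.converged:
        raise ValueError("standardization requires a converged fit")
    e = fit.estimates
    a2 = e.get("a11", 0.0) ** 2
    c2 = e.get("c11", 0.0) ** 2
    e2 = e.get("e11", 0.0) ** 2
    b21 = e.get("b21")
    b31 = e.get("b31")
    a32 = e.get("a32")
    prs = ((b21 or 0.0) ** 2 + (b31 or 0.0) ** 2
           + 2 * (b21 or 0.0) * (b31 or 0.0) * (a32 or 0.0))
    resid = a2 + c2 + e2
    total = resid + prs
    summary = StandardizedSummary(
        a_share=a2 / resid, c_share=c2 / resid, e_share=e2 / resid,
        a_share_total=a2 / total, c_share_total=c2 / total,
        e_share_total=e2 / total, prs_share_total=prs / total,
        b21=b21, b31=b31, a32=a32,
    )
    if ci:
        if model is None or data is None:
            raise ValueError("share/path CIs need the model and the data")
        patterns = fiml._as_patterns(model, data, variables)
        for name in ci_params:
            if name in ("a_share", "c_share", "e_share"):
                comp = name[0] + "11"
                if comp in model.param_names:
                    summary.ci[name] = _profile_share_ci(fit, model, patterns, comp)
            elif name in model.param_names:
                lo, hi, _ = profile_ci(fit, model, patterns, name)
                summary.ci[name] = (lo, hi)
    return summary


def _profile_share_ci(fit: FitResult, model: PRSAugmentedModel,
                      patterns: PatternData, component: str,
                      level: float = 0.95) -> tuple[float, float]:
    """Profile CI for a residual-relative share via substitution.

    At fixed share s for, say, A, the constraint a11^2 = s/(1-s) *
    (c11^2 + e11^2) eliminates a11 from the free parameters; the profile over
    the remaining parameters is scanned for the chi-square(1) threshold.
    """
    q = stats.chi2.ppf(level, df=1)
    target = fit.minus2LL + q
    idx = model.param_names.index(component)
    others = [n for n in ("a11", "c11", "e11")
              if n != component and n in model.param_names]
    f, _ = fiml._objective(model, patterns)
    free_idx = [j for j in range(model.n_free) if j != idx]
    other_idx = [model.param_names.index(n) for n in others]
    bounds = [model.bounds()[j] for j in free_idx]

    def prof(s: float, start: np.ndarray) -> tuple[float, np.ndarray]:
        ratio = s / (1.0 - s)

        def g(sub):
            full = np.empty(model.n_free)
            full[free_idx] = sub
            resid_other = sum(full[j] ** 2 for j in other_idx)
            full[idx] = np.sqrt(max(ratio * resid_other, 0.0))
            return f(full)

        from scipy.optimize import minimize
        res = minimize(g, start[free_idx], method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300, "ftol": 1e-12})
        full = np.empty(model.n_free)
        full[free_idx] = res.x
        resid_other = sum(full[j] ** 2 for j in other_idx)
        full[idx] = np.sqrt(max(ratio * resid_other, 0.0))
        return float(res.fun), full

    e = fit.estimates
    resid = sum(e.get(n, 0.0) ** 2 for n in ("a11", "c11", "e11"))
    s_hat = e[component] ** 2 / resid
    out = []
    for direction in (-1.0, +1.0):
        s_in, warm = s_hat, fit.theta.copy()
        step = 0.05
        s_out = None
        for _ in range(40):
            cand = s_in + direction * step
            if cand <= 1e-6:
                cand, hit = 1e-6, True
            elif cand >= 1 - 1e-6:
                cand, hit = 1 - 1e-6, True
            else:
                hit = False
            val, warm = prof(cand, warm)
            if val >= target:
                s_out = cand
                break
            s_in = cand
            if hit:
                break
            step *= 1.5
        if s_out is None:
            out.append(max(s_in, 0.0) if direction < 0 else min(s_in, 1.0))
            continue
        from scipy.optimize import brentq
        h = lambda s, box=[warm]: prof(s, box[0])[0] - target
        lo, hi = sorted((s_in, s_out))
        try:
            root = brentq(h, lo, hi, xtol=1e-4, maxiter=50)
        except ValueError:
            root = s_out
        out.append(root)
    return float(out[0]), float(out[1])


# --------------------------------------------------------------------------
# FDR and the mixed-model screen
# --------------------------------------------------------------------------


def bh_fdr(pvalues, grouping=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, optionally within groups.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest down, cap at 1; original order restored. With ``grouping`` the
    correction is applied independently within each group label.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if grouping is not None:
        grouping = np.asarray(grouping)
        out = np.empty_like(p)
        for g in np.unique(grouping):
            sel = grouping == g
            out[sel] = bh_fdr(p[sel])
        return out
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def lmm_prs_screen(data: PairDataset, roi: str, prs: str) -> ScreenRow:
    """Random-intercept-per-family mixed model of one phenotype on one PRS.

    Individuals are the units, family the cluster; fitted by ML. With
    family-intercept variance tau and residual variance sigma^2:

        marginal R^2    = b^2 Var(prs) / (b^2 Var(prs) + tau + sigma^2)
        conditional R^2 = (b^2 Var(prs) + tau) / (b^2 Var(prs) + tau + sigma^2)
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    long = data.stacked_individuals([roi, prs])
    long = long.rename(columns={roi: "y", prs: "x",
                                data.schema.family_col: "fam"})
    long = long.dropna(subset=["y", "x"])
    flag = ""
    fam_sizes = long.groupby("fam").size()
    if (fam_sizes <= 1).all():
        ols = smf.ols("y ~ x", data=long).fit()
        beta, se = ols.params["x"], ols.bse["x"]
        tau, sigma2 = 0.0, float(ols.mse_resid)
        flag = "tau unidentified (singleton families); tau=0 fallback"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("y ~ x", data=long, groups=long["fam"])
            mf = md.fit(reml=False)
        beta, se = float(mf.params["x"]), float(mf.bse["x"])
        tau = float(mf.cov_re.iloc[0, 0])
        sigma2 = float(mf.scale)
    var_x = float(long["x"].var(ddof=1))
    fixed = beta**2 * var_x
    total = fixed + tau + sigma2
    return ScreenRow(beta=beta, se=se, t_stat=beta / se,
                     marginal_r2=fixed / total,
                     conditional_r2=(fixed + tau) / total, flag=flag)


def comparison_table(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "model": r.label, "-2LL": r.minus2LL, "n_free": r.n_free,
        "d-2LL": r.delta_minus2LL, "ddf": r.delta_df, "p": r.p_value,
        "AIC": r.AIC, "preferred": r.preferred, "converged": r.converged,
    } for r in rows])
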