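"""Expected means and pair covariance matrices for twin variance-component models.

Three model families share one interface:

* saturated pair models (unstructured moments under optional equality
  constraints) — the reference models for assumption tests and twin
  correlations;
* the univariate ACE family (ACE / AE / CE / E) — phenotypic variance split
  into additive-genetic (A), shared-environment (C), and unique-environment
  (E) components, with the cross-member genetic coefficient kappa = 1 for MZ
  pairs and 1/2 for DZ and sibling pairs, and the shared-environment
  correlation fixed to 1 in every group (equal environments assumption);
* the PRS-augmented model — two observed polygenic scores load on the
  phenotype via regression paths b21 (trait-specific PRS) and b31
  (substance-use-disorder PRS), the latent unit-variance PRS factors
  correlate via a32, and their standard deviations d11/d22 scale them to the
  observed score scale; residual phenotype variance is split A/C/E.

A model maps a free-parameter vector theta to per-group (mean vector,
covariance matrix) pairs over the 2m observed variables of a pair (member-1
block then member-2 block). Path coefficients, not variance components, are
the free parameters (bounded >= 0 for a11/c11/e11 to resolve the sign
indeterminacy); squares are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUP_KAPPA = {"MZ": 1.0, "DZ": 0.5, "SIB": 0.5}

SUBMODELS = {
    "ACE": ("a11", "c11", "e11"),
    "AE": ("a11", "e11"),
    "CE": ("c11", "e11"),
    "E": ("e11",),
}

__all__ = [
    "GROUP_KAPPA",
    "SUBMODELS",
    "ModelParams",
    "GroupKind",
    "MomentModel",
    "SaturatedModel",
    "UnivariateACEModel",
    "PRSAugmentedModel",
    "build_saturated",
    "build_univariate_ace",
    "build_prs_augmented",
    "IdentificationReport",
    "check_identification",
]


@dataclass(frozen=True)
class GroupKind:
    """A relative group with its fixed genetic sharing coefficient."""

    label: str

    @property
    def kappa(self) -> float:
        return GROUP_KAPPA[self.label]

    shared_env_coef: float = 1.0


@dataclass
class ModelParams:
    """Free parameters of the twin models (structural zeros stay at 0).

    a11/c11/e11: residual A/C/E path coefficients (>= 0 by convention);
    b21: trait-specific-PRS -> phenotype path; b31: SUD-PRS -> phenotype path;
    a32: correlation between the latent unit-variance PRS factors, |a32| <= 1;
    d11/d22: PRS standard deviations (> 0); means per observed variable.
    """

    a11: float = 0.0
    c11: float = 0.0
    e11: float = 1.0
    b21: float = 0.0
    b31: float = 0.0
    a32: float = 0.0
    d11: float = 1.0
    d22: float = 1.0
    mu_roi: float = 0.0
    mu_prs1: float = 0.0
    mu_prs2: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.a32) > 1:
            raise ValueError(f"|a32| must be <= 1, got {self.a32}")
        if self.d11 <= 0 or self.d22 <= 0:
            raise ValueError("PRS standard deviations d11, d22 must be > 0")

    @property
    def prs_explained_variance(self) -> float:
        """Phenotypic variance carried by the two PRS paths jointly."""
        return self.b21**2 + self.b31**2 + 2 * self.b21 * self.b31 * self.a32

    @property
    def total_phenotype_variance(self) -> float:
        return self.a11**2 + self.c11**2 + self.e11**2 + self.prs_explained_variance


class MomentModel:
    """Base: a named free-parameter vector mapped to per-group moments."""

    param_names: list[str]
    groups: list[str]
    n_vars: int  # observed variables per member
    # (i, j) index pairs in the 2m observed vector that are exact copies
    # within MZ pairs (identical genotypes): the likelihood keeps one copy,
    # since the joint distribution of both is degenerate.
    mz_duplicate_pairs: tuple[tuple[int, int], ...] = ()

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        raise NotImplementedError

    def start(self) -> np.ndarray:
        raise NotImplementedError

    def group_moments(self, theta: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        raise NotImplementedError

    def theta_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names, np.asarray(theta, dtype=float)))

    def stacked_moments(self, theta: np.ndarray) -> np.ndarray:
        """All group means plus lower-triangular covariance entries, stacked.

        The unique-moment vector whose Jacobian rank determines local
        identification.
        """
        parts = []
        for g in self.groups:
            mu, sigma = self.group_moments(theta)[g]
            parts.append(mu)
            idx = np.tril_indices(sigma.shape[0])
            parts.append(sigma[idx])
        return np.concatenate(parts)


# --------------------------------------------------------------------------
# Saturated pair models (single phenotype per member)
# --------------------------------------------------------------------------

CONSTRAINT_LEVELS = (
    "none",
    "within-pair",
    "within-pair+across-group",
    "within-pair+across-group+dzsib",
)


class SaturatedModel(MomentModel):
    """Unstructured 2x2 pair moments for one variable, under equality constraints.

    Levels: "none" — per group two means, two variances, one covariance;
    "within-pair" — means and variances equated across the two member slots
    within each group, with the within-pair *correlation* as the free
    parameter (so twin correlations get direct profile CIs);
    "within-pair+across-group" — means and variances additionally equated
    across the MZ/DZ/SIB groups (correlations stay free per group);
    "within-pair+across-group+dzsib" — additionally equates the DZ and
    sibling correlations (the constraint the source data could not sustain
    for cortical surface area).
    """

    n_vars = 1

    def __init__(self, constraints: str = "none", groups=("MZ", "DZ", "SIB")):
        if constraints not in CONSTRAINT_LEVELS:
            raise ValueError(
                f"unknown constraint level {constraints!r}; choose from {CONSTRAINT_LEVELS}")
        self.constraints = constraints
        self.groups = list(groups)
        names: list[str] = []
        if constraints == "none":
            for g in self.groups:
                names += [f"mu1_{g}", f"mu2_{g}", f"var1_{g}", f"var2_{g}", f"cov_{g}"]
        elif constraints == "within-pair":
            for g in self.groups:
                names += [f"mu_{g}", f"var_{g}", f"r_{g}"]
        elif constraints == "within-pair+across-group":
            names = ["mu", "var"] + [f"r_{g}" for g in self.groups]
        else:
            names = ["mu", "var", "r_MZ", "r_DZSIB"]
        self.param_names = names

    def bounds(self):
        b = []
        for name in self.param_names:
            if name.startswith("var"):
                b.append((1e-8, None))
            elif name.startswith("r_"):
                b.append((-0.999, 0.999))
            else:
                b.append((None, None))
        return b

    def start(self):
        s = []
        for name in self.param_names:
            if name.startswith("var"):
                s.append(1.0)
            elif name.startswith(("cov", "r_")):
                s.append(0.3)
            else:
                s.append(0.0)
        return np.array(s)

    def group_moments(self, theta):
        p = self.theta_dict(theta)
        out = {}
        for g in self.groups:
            if self.constraints == "none":
                mu = np.array([p[f"mu1_{g}"], p[f"mu2_{g}"]])
                v1, v2, c = p[f"var1_{g}"], p[f"var2_{g}"], p[f"cov_{g}"]
            elif self.constraints == "within-pair":
                mu = np.array([p[f"mu_{g}"]] * 2)
                v1 = v2 = p[f"var_{g}"]
                c = p[f"r_{g}"] * v1
            elif self.constraints == "within-pair+across-group":
                mu = np.array([p["mu"]] * 2)
                v1 = v2 = p["var"]
                c = p[f"r_{g}"] * v1
            else:
                mu = np.array([p["mu"]] * 2)
                v1 = v2 = p["var"]
                c = (p["r_MZ"] if g == "MZ" else p["r_DZSIB"]) * v1
            out[g] = (mu, np.array([[v1, c], [c, v2]]))
        return out


def build_saturated(constraints: str = "none", groups=("MZ", "DZ", "SIB")) -> SaturatedModel:
    return SaturatedModel(constraints=constraints, groups=groups)


# --------------------------------------------------------------------------
# Univariate ACE family
# --------------------------------------------------------------------------


class UnivariateACEModel(MomentModel):
    """ACE / AE / CE / E decomposition of one phenotype over twin pairs.

    Per-member variance a11^2 + c11^2 + e11^2; cross-member covariance
    kappa * a11^2 + c11^2; one grand mean (homogeneity established upstream).
    """

    n_vars = 1

    def __init__(self, submodel: str = "ACE", groups=("MZ", "DZ", "SIB")):
        if submodel not in SUBMODELS:
            raise ValueError(f"unknown submodel {submodel!r}")
        self.submodel = submodel
        self.groups = list(groups)
        self.param_names = ["mu"] + list(SUBMODELS[submodel])

    def bounds(self):
        b = [(None, None)]  # mu
        for name in SUBMODELS[self.submodel]:
            b.append((1e-8, None) if name == "e11" else (0.0, None))
        return b

    def start(self):
        s = {"mu": 0.0, "a11": 0.6, "c11": 0.3, "e11": 0.5}
        return np.array([s[n] for n in self.param_names])

    def group_moments(self, theta):
        p = self.theta_dict(theta)
        a = p.get("a11", 0.0)
        c = p.get("c11", 0.0)
        e = p.get("e11", 0.0)
        var = a * a + c * c + e * e
        out = {}
        for g in self.groups:
            cov = GROUP_KAPPA[g] * a * a + c * c
            mu = np.array([p["mu"]] * 2)
            out[g] = (mu, np.array([[var, cov], [cov, var]]))
        return out


def build_univariate_ace(submodel: str = "ACE", groups=("MZ", "DZ", "SIB")) -> UnivariateACEModel:
    return UnivariateACEModel(submodel=submodel, groups=groups)


# --------------------------------------------------------------------------
# PRS-augmented model
# --------------------------------------------------------------------------


class PRSAugmentedModel(MomentModel):
    """Phenotype + two observed PRSs per member, A/C/E acting on the phenotype only.

    Observed variables per member ordered (phenotype, trait PRS, SUD PRS).
    Within-person block: Var(P1) = d11^2, Var(P2) = d22^2,
    Cov(P1, P2) = d11 d22 a32, Cov(Y, P1) = d11 (b21 + b31 a32),
    Cov(Y, P2) = d22 (b31 + b21 a32),
    Var(Y) = b21^2 + b31^2 + 2 b21 b31 a32 + a11^2 + c11^2 + e11^2.
    Cross-member block: every PRS-involving covariance times kappa;
    Cov(Y, Y') = kappa (b21^2 + b31^2 + 2 b21 b31 a32) + kappa a11^2 + c11^2.
    """

    n_vars = 3
    mz_duplicate_pairs = ((1, 4), (2, 5))  # member-2 PRS copies of member-1

    def __init__(self, submodel: str = "ACE", drop_b21: bool = False,
                 drop_b31: bool = False, drop_a32: bool = False,
                 groups=("MZ", "DZ", "SIB")):
        if submodel not in SUBMODELS:
            raise ValueError(f"unknown submodel {submodel!r}")
        self.submodel = submodel
        self.drop_b21 = drop_b21
        self.drop_b31 = drop_b31
        self.drop_a32 = drop_a32
        self.groups = list(groups)
        names = ["mu_roi", "mu_prs1", "mu_prs2"] + list(SUBMODELS[submodel])
        if not drop_b21:
            names.append("b21")
        if not drop_b31:
            names.append("b31")
        if not drop_a32:
            names.append("a32")
        names += ["d11", "d22"]
        self.param_names = names

    def bounds(self):
        b = []
        for name in self.param_names:
            if name in ("a11", "c11"):
                b.append((0.0, None))
            elif name == "e11":
                b.append((1e-8, None))
            elif name == "a32":
                b.append((-0.999, 0.999))
            elif name in ("d11", "d22"):
                b.append((1e-6, None))
            else:
                b.append((None, None))
        return b

    def start(self):
        s = {"mu_roi": 0.0, "mu_prs1": 0.0, "mu_prs2": 0.0, "a11": 0.6, "c11": 0.3,
             "e11": 0.5, "b21": 0.1, "b31": 0.05, "a32": 0.0, "d11": 1.0, "d22": 1.0}
        return np.array([s[n] for n in self.param_names])

    def params(self, theta) -> ModelParams:
        p = self.theta_dict(theta)
        return ModelParams(
            a11=p.get("a11", 0.0), c11=p.get("c11", 0.0), e11=p.get("e11", 0.0),
            b21=p.get("b21", 0.0), b31=p.get("b31", 0.0), a32=p.get("a32", 0.0),
            d11=p.get("d11", 1.0), d22=p.get("d22", 1.0),
            mu_roi=p["mu_roi"], mu_prs1=p["mu_prs1"], mu_prs2=p["mu_prs2"],
        )

    def group_moments(self, theta):
        mp = self.params(theta)
        if abs(mp.a32) > 1:
            raise ValueError("|a32| > 1 is inadmissible")
        a, c, e = mp.a11, mp.c11, mp.e11
        b21, b31, a32 = mp.b21, mp.b31, mp.a32
        d11, d22 = mp.d11, mp.d22
        prs_var = mp.prs_explained_variance
        within = np.array([
            [prs_var + a * a + c * c + e * e,
             d11 * (b21 + b31 * a32), d22 * (b31 + b21 * a32)],
            [d11 * (b21 + b31 * a32), d11 * d11, d11 * d22 * a32],
            [d22 * (b31 + b21 * a32), d11 * d22 * a32, d22 * d22],
        ])
        mu1 = np.array([mp.mu_roi, mp.mu_prs1, mp.mu_prs2])
        out = {}
        for g in self.groups:
            k = GROUP_KAPPA[g]
            cross = k * within.copy()
            cross[0, 0] = k * (prs_var + a * a) + c * c
            sigma = np.block([[within, cross], [cross.T, within]])
            out[g] = (np.concatenate([mu1, mu1]), sigma)
        return out


def build_prs_augmented(submodel: str = "ACE", drop_b21: bool = False,
                        drop_b31: bool = False, drop_a32: bool = False,
                        groups=("MZ", "DZ", "SIB")) -> PRSAugmentedModel:
    return PRSAugmentedModel(submodel=submodel, drop_b21=drop_b21,
                             drop_b31=drop_b31, drop_a32=drop_a32, groups=groups)


# --------------------------------------------------------------------------
# Local identification
# --------------------------------------------------------------------------


@dataclass
class IdentificationReport:
    identified: bool
    rank: int
    n_free: int
    null_space_params: list[str] = field(default_factory=list)
    ambiguous_probe: bool = False
    notes: str = ""


def _moment_jacobian(model: MomentModel, theta: np.ndarray, step: float = 1e-6) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    base = model.stacked_moments(theta)
    J = np.empty((base.size, theta.size))
    for j in range(theta.size):
        h = step * max(1.0, abs(theta[j]))
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (model.stacked_moments(up) - model.stacked_moments(dn)) / (2 * h)
    return J


def _rank_and_null(J: np.ndarray, names: list[str]):
    u, s, vt = np.linalg.svd(J)
    tol = max(J.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    tol = max(tol, 1e-10)
    rank = int(np.sum(s > tol))
    null_params: list[str] = []
    for row in vt[rank:]:
        for j in np.flatnonzero(np.abs(row) > 0.3 * np.abs(row).max()):
            if names[j] not in null_params:
                null_params.append(names[j])
    return rank, null_params


def check_identification(model: MomentModel, theta=None, step: float = 1e-6,
                         rng=None) -> IdentificationReport:
    """Local identification via the rank of the moment Jacobian.

    Central-difference Jacobian of the stacked unique moments (group means
    plus lower-triangular covariances) with respect to the free parameters;
    identified iff rank equals the number of free parameters. A second,
    jittered probe point guards against symmetry-collapsed (singular) probes:
    if the two ranks disagree, the report is flagged ambiguous and the larger
    rank is kept (rank deficiency is generic only if it holds at both).
    """
    if theta is None:
        theta = model.start()
    theta = np.asarray(theta, dtype=float)
    rng = np.random.default_rng(rng if rng is not None else 0)
    J = _moment_jacobian(model, theta, step)
    rank, null_params = _rank_and_null(J, model.param_names)

    jitter = theta + rng.uniform(0.01, 0.05, size=theta.size) * np.where(
        theta == 0, 1.0, np.sign(theta))
    J2 = _moment_jacobian(model, jitter, step)
    rank2, null2 = _rank_and_null(J2, model.param_names)

    ambiguous = rank != rank2
    best_rank = max(rank, rank2)
    nulls = null_params if rank >= rank2 else null2
    return IdentificationReport(
        identified=(best_rank == model.n_free),
        rank=best_rank,
        n_free=model.n_free,
        null_space_params=[] if best_rank == model.n_free else nulls,
        ambiguous_probe=ambiguous,
        notes="" if not ambiguous else f"rank {rank} at probe, {rank2} at jittered probe",
    )
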