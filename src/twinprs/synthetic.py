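"""Synthetic twin/sibling pair generator with known truth.

Emulates the statistical structure of a community twin-family neuroimaging
sample (three relative groups, MZ / DZ / non-twin sibling pairs) in which a
brain phenotype loads on two observed polygenic scores plus residual A/C/E
influences:

    y = mu + b21*P1 + b31*P2 + a11*A + c11*C + e11*E + covariate effects

Genetic sharing is implemented as a family-shared + individual-specific
variance split: the latent PRS factors and the residual additive-genetic
factor are fully shared within MZ pairs, and split half family-shared, half
segregation for DZ and sibling pairs, giving cross-member genetic
correlations of exactly 1.0 and 0.5. C is shared exactly within every pair
(equal environments, siblings included); E is independent per member.

Covariates: twins share age exactly, siblings differ by a draw centred on the
configured gap; sex is Bernoulli per individual; standardized intracranial
volume is drawn per individual; genetic principal components are
family-shared (ancestry). Missingness is MCAR per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .moments import ModelParams, PRSAugmentedModel, GROUP_KAPPA
from .pair_data import PairDataset, default_schema

__all__ = ["SimConfig", "TruthRecord", "simulate_pairs", "make_fixture", "PRESETS"]

N_PCS = 10


@dataclass
class SimConfig:
    """True parameter values, group sizes, covariate model, and seed."""

    n_mz: int = 222
    n_dz: int = 328
    n_sib: int = 387
    params: ModelParams = field(default_factory=lambda: ModelParams(
        a11=np.sqrt(0.55), c11=np.sqrt(0.26), e11=np.sqrt(0.18),
        b21=0.13, b31=0.06, a32=0.04))
    age_mean: float = 10.0       # years; cohort assessed at ages 9-11
    age_sd: float = 0.6
    sib_age_gap_mean: float = 1.3  # years
    sib_age_gap_sd: float = 0.5
    age_effect: float = 0.05     # phenotype units per year
    sex_effect: float = 0.1
    icv_effect: float = 0.3      # per SD of standardized ICV
    pc_effects: tuple = tuple([0.02] * N_PCS)
    missing_rate: float = 0.0    # MCAR, per cell
    member2_sd_scale: float = 1.0   # >1 violates within-pair variance homogeneity
    member2_mean_shift: float = 0.0  # nonzero violates within-pair mean homogeneity
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mz, self.n_dz, self.n_sib) < 0:
            raise ValueError("pair counts must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if len(self.pc_effects) != N_PCS:
            raise ValueError(f"expected {N_PCS} PC effects")
        # ModelParams.__post_init__ already validates |a32| <= 1 and deltas > 0


@dataclass
class TruthRecord:
    """The config echoed plus population quantities implied by it.

    ``a_share``/``c_share``/``e_share`` are residual-relative (A/C/E over
    their own sum, the convention of published twin-model summary tables);
    ``*_share_total`` divide by the total phenotypic variance including the
    PRS-explained part, and together with ``prs_share_total`` sum to one.
    """

    config: SimConfig
    total_variance: float
    prs_explained_variance: float
    mz_cross_covariance: float
    dz_cross_covariance: float
    a_share: float
    c_share: float
    e_share: float
    a_share_total: float
    c_share_total: float
    e_share_total: float
    prs_share_total: float

    @classmethod
    def from_config(cls, config: SimConfig) -> "TruthRecord":
        p = config.params
        model = PRSAugmentedModel(submodel="ACE", groups=("MZ", "DZ"))
        theta = np.array([p.mu_roi, p.mu_prs1, p.mu_prs2, p.a11, p.c11, p.e11,
                          p.b21, p.b31, p.a32, p.d11, p.d22])
        mom = model.group_moments(theta)
        total = p.total_phenotype_variance
        prs_part = p.prs_explained_variance
        resid = p.a11**2 + p.c11**2 + p.e11**2
        rec = cls(
            config=config,
            total_variance=total,
            prs_explained_variance=prs_part,
            mz_cross_covariance=mom["MZ"][1][0, 3],
            dz_cross_covariance=mom["DZ"][1][0, 3],
            a_share=p.a11**2 / resid,
            c_share=p.c11**2 / resid,
            e_share=p.e11**2 / resid,
            a_share_total=p.a11**2 / total,
            c_share_total=p.c11**2 / total,
            e_share_total=p.e11**2 / total,
            prs_share_total=prs_part / total,
        )
        # closed-form consistency checks against the moment model
        assert abs(mom["MZ"][1][0, 0] - total) < 1e-12
        expect_mz = prs_part + p.a11**2 + p.c11**2
        expect_dz = 0.5 * (prs_part + p.a11**2) + p.c11**2
        assert abs(rec.mz_cross_covariance - expect_mz) < 1e-12
        assert abs(rec.dz_cross_covariance - expect_dz) < 1e-12
        return rec


def _draw_bivariate(rng, n, corr, scale=1.0):
    """n draws of a bivariate normal with unit variances * scale^2 and given corr."""
    z = rng.standard_normal((n, 2))
    x1 = z[:, 0]
    x2 = corr * z[:, 0] + np.sqrt(1 - corr**2) * z[:, 1]
    return scale * np.column_stack([x1, x2])


def _simulate_group(rng, n, group, cfg: SimConfig):
    p = cfg.params
    kappa = GROUP_KAPPA[group]

    # latent PRS factors (P1, P2), unit variance, correlation a32
    if group == "MZ":
        P_shared = _draw_bivariate(rng, n, p.a32)          # fully shared
        P1 = np.stack([P_shared, P_shared], axis=1)        # (n, member, factor)
    else:
        S = _draw_bivariate(rng, n, p.a32, scale=np.sqrt(0.5))
        U = np.stack([_draw_bivariate(rng, n, p.a32, scale=np.sqrt(0.5))
                      for _ in range(2)], axis=1)
        P1 = S[:, None, :] + U
    prs1 = p.d11 * P1[:, :, 0]
    prs2 = p.d22 * P1[:, :, 1]

    # residual A with cross-member correlation kappa; C shared; E independent
    if group == "MZ":
        A = np.repeat(rng.standard_normal((n, 1)), 2, axis=1)
    else:
        Af = np.sqrt(0.5) * rng.standard_normal((n, 1))
        A = Af + np.sqrt(0.5) * rng.standard_normal((n, 2))
    C = np.repeat(rng.standard_normal((n, 1)), 2, axis=1)
    E = rng.standard_normal((n, 2))

    # covariates
    if group == "SIB":
        age1 = rng.normal(cfg.age_mean, cfg.age_sd, n)
        gap = rng.normal(cfg.sib_age_gap_mean, cfg.sib_age_gap_sd, n)
        gap *= rng.choice([-1.0, 1.0], n)
        age = np.column_stack([age1, age1 + gap])
    else:
        age = np.repeat(rng.normal(cfg.age_mean, cfg.age_sd, (n, 1)), 2, axis=1)
    sex = rng.integers(0, 2, (n, 2)).astype(float)
    icv = rng.standard_normal((n, 2))
    pcs = np.repeat(rng.standard_normal((n, 1, N_PCS)), 2, axis=1)  # family-shared

    cov_part = (cfg.age_effect * (age - cfg.age_mean)
                + cfg.sex_effect * (sex - 0.5)
                + cfg.icv_effect * icv
                + pcs @ np.asarray(cfg.pc_effects))

    y = (p.mu_roi + p.b21 * P1[:, :, 0] + p.b31 * P1[:, :, 1]
         + p.a11 * A + p.c11 * C + p.e11 * E + cov_part)

    if cfg.member2_sd_scale != 1.0 or cfg.member2_mean_shift != 0.0:
        mdl = y[:, 1] - cov_part[:, 1] - p.mu_roi
        y[:, 1] = (p.mu_roi + cfg.member2_mean_shift
                   + cfg.member2_sd_scale * mdl + cov_part[:, 1])

    cols = {"roi": y, "roi_prs": prs1, "sud_prs": prs2, "age": age,
            "sex": sex, "icv": icv}
    for i in range(N_PCS):
        cols[f"pc{i + 1}"] = pcs[:, :, i]
    return cols


def simulate_pairs(config: SimConfig):
    """Generate a pair dataset plus its truth record; pure function of the seed."""
    truth = TruthRecord.from_config(config)  # validates config before sampling
    rng = np.random.default_rng(config.seed)
    schema = default_schema()
    frames = []
    fam = 0
    for group, n in (("MZ", config.n_mz), ("DZ", config.n_dz), ("SIB", config.n_sib)):
        if n == 0:
            continue
        cols = _simulate_group(rng, n, group, config)
        rec = {"family_id": [f"fam{fam + i:05d}" for i in range(n)],
               "group": [group] * n}
        for var, arr in cols.items():
            rec[schema.column(var, 1)] = arr[:, 0]
            rec[schema.column(var, 2)] = arr[:, 1]
        frames.append(pd.DataFrame(rec))
        fam += n
    table = pd.concat(frames, ignore_index=True)

    if config.missing_rate > 0:
        value_cols = schema.member_columns(schema.variables)
        mask = rng.random((len(table), len(value_cols))) < config.missing_rate
        vals = table[value_cols].to_numpy()
        vals[mask] = np.nan
        table[value_cols] = vals

    return PairDataset(table, schema), truth


def _params(a2=0.0, c2=0.0, e2=1.0, b21=0.0, b31=0.0, a32=0.0):
    return ModelParams(a11=np.sqrt(a2), c11=np.sqrt(c2), e11=np.sqrt(e2),
                       b21=b21, b31=b31, a32=a32)


# Preset truths follow published summary rows for an AE-dominant subcortical
# volume (putamen) and an ACE cortical surface area, plus null / nonzero
# b31 cases and a homogeneity-violating case for the assumption tests.
PRESETS: dict[str, dict] = {
    "putamen-like": dict(params=_params(a2=0.91, e2=0.09, b21=0.20), seed=101),
    "cortical-surface-like": dict(params=_params(a2=0.55, c2=0.26, e2=0.18,
                                                 b21=0.13, b31=0.06, a32=0.04),
                                  seed=102),
    "null-b31": dict(params=_params(a2=0.70, e2=0.30, b21=0.15, b31=0.0), seed=103),
    "nonzero-b31": dict(params=_params(a2=0.70, e2=0.30, b21=0.15, b31=0.05,
                                       a32=0.04), seed=104),
    "homogeneity-violating": dict(params=_params(a2=0.60, c2=0.10, e2=0.30),
                                  member2_sd_scale=np.sqrt(2.0), seed=105),
}


def make_fixture(name: str, n_per_group: int | None = None, seed: int | None = None):
    """Deterministic preset dataset (study-sized groups 222/328/387) plus truth."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    if n_per_group is not None:
        kw.update(n_mz=n_per_group, n_dz=n_per_group, n_sib=n_per_group)
    if seed is not None:
        kw["seed"] = seed
    return simulate_pairs(SimConfig(**kw))
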