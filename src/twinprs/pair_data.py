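"""Wide-format twin/sibling pair tables: reading, validation, residualization.

The analysis unit is a relative *pair* (MZ twin, DZ twin, or non-twin sibling
pair). On disk a dataset is one row per pair with suffixed columns per member
slot (default ``<var>_t1`` / ``<var>_t2``). Missing cells are NaN in memory;
on disk the sentinels declared in the schema (``""`` and ``"NA"`` by default).

Member-slot assignment within a pair is arbitrary and preserved from input
order; every downstream model is exchangeable in the two slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

GROUPS = ("MZ", "DZ", "SIB")

__all__ = [
    "GROUPS",
    "VariableSchema",
    "PairDataset",
    "SchemaError",
    "GroupLabelError",
    "read_pair_table",
    "write_pair_table",
    "residualize",
    "standardize_prs",
    "average_hemispheres",
]


class SchemaError(ValueError):
    """A mandatory column is absent or the schema is internally inconsistent."""


class GroupLabelError(ValueError):
    """A relative-group label outside {MZ, DZ, SIB} was encountered."""


@dataclass(frozen=True)
class VariableSchema:
    """Declares which columns hold phenotypes, PRSs, and covariates.

    ``template`` maps (variable, member slot) to a column header, e.g.
    ``"{var}_t{member}"`` resolves ``("putamen", 1)`` to ``"putamen_t1"``.
    """

    roi_names: tuple[str, ...] = ()
    prs_names: tuple[str, ...] = ()
    covariate_names: tuple[str, ...] = ()
    family_col: str = "family_id"
    group_col: str = "group"
    template: str = "{var}_t{member}"
    missing_sentinels: tuple[str, ...] = ("", "NA")

    def __post_init__(self) -> None:
        headers = [self.column(v, m) for v in self.variables for m in (1, 2)]
        if len(set(headers)) != len(headers):
            raise SchemaError("column template produces colliding headers")

    @property
    def variables(self) -> tuple[str, ...]:
        return self.roi_names + self.prs_names + self.covariate_names

    def column(self, var: str, member: int) -> str:
        return self.template.format(var=var, member=member)

    def member_columns(self, names: tuple[str, ...] | list[str]) -> list[str]:
        return [self.column(v, m) for m in (1, 2) for v in names]


@dataclass
class PairDataset:
    """One row per pair; numeric member columns hold NaN where missing.

    Invariants enforced at construction: every family id unique, every group
    label in {MZ, DZ, SIB}, every schema-declared member column present.
    """

    table: pd.DataFrame
    schema: VariableSchema

    def __post_init__(self) -> None:
        t = self.table
        s = self.schema
        missing = [c for c in ([s.family_col, s.group_col] + s.member_columns(s.variables))
                   if c not in t.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        bad = ~t[s.group_col].isin(GROUPS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise GroupLabelError(
                f"row {row + 1}: group label {t[s.group_col].iloc[row]!r} "
                f"not one of {GROUPS}"
            )
        if t[s.family_col].duplicated().any():
            dup = t.loc[t[s.family_col].duplicated(), s.family_col].iloc[0]
            raise SchemaError(f"duplicated family_id {dup!r}")

    def __len__(self) -> int:
        return len(self.table)

    def group_counts(self) -> dict[str, int]:
        vc = self.table[self.schema.group_col].value_counts()
        return {g: int(vc.get(g, 0)) for g in GROUPS}

    def member_matrix(self, variables: list[str], group: str | None = None) -> np.ndarray:
        """(n_pairs, 2m) array ordered member-1 variables then member-2 variables."""
        t = self.table if group is None else self.table[self.table[self.schema.group_col] == group]
        cols = self.schema.member_columns(tuple(variables))
        return t[cols].to_numpy(dtype=float)

    def stacked_individuals(self, variables: list[str]) -> pd.DataFrame:
        """Long format: one row per individual (both members, all groups)."""
        s = self.schema
        frames = []
        for m in (1, 2):
            cols = {s.column(v, m): v for v in variables}
            f = self.table[[s.family_col, s.group_col] + list(cols)].rename(columns=cols)
            f["member"] = m
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def copy(self) -> "PairDataset":
        return PairDataset(self.table.copy(), self.schema)


def read_pair_table(path, schema: VariableSchema) -> PairDataset:
    """Read a CSV/TSV pair table; delimiter inferred from the extension."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(
        path, sep=sep, dtype={schema.family_col: str, schema.group_col: str},
        na_values=list(schema.missing_sentinels), keep_default_na=False,
        skipinitialspace=True,
    )
    if schema.group_col in raw.columns:
        raw[schema.group_col] = raw[schema.group_col].str.strip().str.upper()
    for col in schema.member_columns(schema.variables):
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    return PairDataset(raw, schema)


def write_pair_table(data: PairDataset, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    data.table.to_csv(path, sep=sep, index=False, na_rep=data.schema.missing_sentinels[-1])


def residualize(data: PairDataset, target: str, covariates: list[str]) -> PairDataset:
    """Replace ``target`` with OLS residuals on an intercept plus ``covariates``.

    The regression is pooled over all individuals (both member slots, all
    groups), ignoring family clustering: within-family dependence is handled
    afterwards by the twin model. Individuals with a missing covariate get a
    missing residual.
    """
    s = data.schema
    for v in [target] + list(covariates):
        if v not in s.variables:
            raise SchemaError(f"variable {v!r} not declared in schema")
    long = data.stacked_individuals([target] + list(covariates))
    y = long[target].to_numpy(dtype=float)
    X = long[list(covariates)].to_numpy(dtype=float).reshape(len(long), -1)
    complete = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    n_ok = int(complete.sum())
    if n_ok < X.shape[1] + 1:
        raise ValueError(
            f"insufficient data: {n_ok} complete cases for {X.shape[1]} covariate(s)")
    if covariates:
        sds = X[complete].std(axis=0)
        if np.any(sds == 0):
            dead = covariates[int(np.argmin(sds))]
            raise ValueError(f"degenerate design: covariate {dead!r} has zero variance")
    design = sm.add_constant(X[complete], has_constant="add")
    fit = sm.OLS(y[complete], design).fit()
    resid = np.full_like(y, np.nan)
    resid[complete] = fit.resid
    out = data.copy()
    half = len(long) // 2
    out.table[s.column(target, 1)] = resid[:half]
    out.table[s.column(target, 2)] = resid[half:]
    return out


def standardize_prs(data: PairDataset, prs: str) -> PairDataset:
    """Scale a PRS column to pooled mean 0, sample SD 1 (ddof=1).

    Missing cells stay missing; MZ within-pair equality is preserved because
    the transform is a single affine map applied to every individual.
    """
    s = data.schema
    cols = [s.column(prs, 1), s.column(prs, 2)]
    vals = data.table[cols].to_numpy(dtype=float).ravel()
    obs = vals[np.isfinite(vals)]
    if len(obs) < 2 or obs.std(ddof=1) == 0:
        raise ValueError(f"PRS {prs!r} has zero variance (or < 2 observed values)")
    mu, sd = obs.mean(), obs.std(ddof=1)
    out = data.copy()
    for c in cols:
        out.table[c] = (out.table[c].to_numpy(dtype=float) - mu) / sd
    return out


def average_hemispheres(left, right):
    """Elementwise mean of left/right hemisphere series; NaN if either missing."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError(f"shape mismatch: {left.shape} vs {right.shape}")
    return (left + right) / 2.0


def default_schema(roi_names=("roi",), prs_names=("roi_prs", "sud_prs"),
                   n_pcs: int = 10) -> VariableSchema:
    """Schema matching the generator's column layout (age/sex/ICV + genetic PCs)."""
    covs = ("age", "sex", "icv") + tuple(f"pc{i}" for i in range(1, n_pcs + 1))
    return VariableSchema(roi_names=tuple(roi_names), prs_names=tuple(prs_names),
                          covariate_names=covs)
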