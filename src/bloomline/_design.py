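"""Design-matrix construction shared by the statistical modules.

Factors are coded as treatment-contrast dummies (first level = reference).
For the study's design columns the reference levels are fixed so that
coefficients read as "effect of ACA vs control", "effect of male vs female",
and site effects relative to TJL, matching how the field reports them.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import RankDeficientError

#: canonical level orderings for the study's design factors (reference first)
CANONICAL_LEVELS = {
    "treatment": ["control", "ACA"],
    "sex": ["F", "M"],
    "site": ["TJL", "UM", "UT"],
}


def canonical_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``meta`` with design factors coerced to canonical categoricals."""
    out = meta.copy()
    for col, levels in CANONICAL_LEVELS.items():
        if col in out.columns and set(out[col].dropna().unique()) <= set(levels):
            out[col] = pd.Categorical(out[col], categories=levels)
    return out


def _factor_dummies(meta: pd.DataFrame, name: str, drop_first: bool) -> pd.DataFrame:
    col = meta[name]
    if pd.api.types.is_numeric_dtype(col):
        return pd.DataFrame({name: col.astype(float)}, index=meta.index)
    if not isinstance(col.dtype, pd.CategoricalDtype):
        levels = CANONICAL_LEVELS.get(name)
        if levels is not None and set(col.dropna().unique()) <= set(levels):
            col = pd.Categorical(col, categories=levels)
        else:
            col = pd.Categorical(col)
        col = pd.Series(col, index=meta.index)
    return pd.get_dummies(col, prefix=name, drop_first=drop_first, dtype=float)


def term_columns(meta: pd.DataFrame, term: str, drop_first: bool = True) -> pd.DataFrame:
    """Columns for one model term; ``a:b`` interactions are elementwise products."""
    parts = term.split(":")
    out = _factor_dummies(meta, parts[0], drop_first)
    for part in parts[1:]:
        nxt = _factor_dummies(meta, part, drop_first)
        cols = {}
        for a in out.columns:
            for b in nxt.columns:
                cols[f"{a}:{b}"] = out[a].to_numpy() * nxt[b].to_numpy()
        out = pd.DataFrame(cols, index=meta.index)
    return out


def design_matrix(
    meta: pd.DataFrame,
    terms,
    intercept: bool = True,
    drop_first: bool = True,
    check_rank: bool = False,
) -> pd.DataFrame:
    """Assemble the model matrix for an ordered list of terms."""
    blocks = []
    if intercept:
        blocks.append(pd.DataFrame({"Intercept": np.ones(len(meta))}, index=meta.index))
    for term in terms:
        blocks.append(term_columns(meta, term, drop_first=drop_first))
    X = pd.concat(blocks, axis=1)
    if check_rank:
        arr = X.to_numpy(float)
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            aliased = _aliased_columns(arr, list(X.columns))
            raise RankDeficientError(f"design matrix is rank deficient; aliased columns: {aliased}")
    return X


def _aliased_columns(arr: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    aliased = []
    for j in range(arr.shape[1]):
        cand = arr[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


def parse_formula(formula: str) -> list[str]:
    """Split an additive model formula like ``"site + sex + site:sex"`` into terms."""
    return [t.strip() for t in formula.split("+") if t.strip()]
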