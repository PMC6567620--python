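"""Per-OTU differential abundance with independent filtering.

The survey fits, for every OTU found in at least two samples, a negative
binomial log-linear model with terms for site, sex, treatment and the
sex-by-treatment interaction, offset by median-of-ratios size factors, and
reports per-term Wald tests. Dispersion is a per-OTU method-of-moments
estimate pooled within design cells with a small floor — a deliberate
simplification of empirical-Bayes dispersion shrinkage; the scientific
content reproduced here is the design and the filtering procedure, not any
particular shrinkage estimator.

False-discovery-rate control applies Benjamini-Hochberg *only* to OTUs that
are not "rare" (mean relative abundance >= 0.01% and detected in >= 5% of
samples). The filter statistics are functions of abundance alone — never of
the p-values — which is what makes the filtering independent and the
power gain legitimate.
"""
from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._design import canonical_meta, design_matrix
from .exceptions import DegenerateInputError, InvalidParameterError

DEFAULT_TERMS = ("site", "sex", "treatment", "sex:treatment")
#: terms whose single-column Wald tests are reported per OTU
FOCAL_TERMS = {
    "treatment": "treatment_ACA",
    "sex": "sex_M",
    "sex:treatment": "sex_M:treatment_ACA",
}


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p.

    U counts pairs with x > y plus half the ties. The p-value is exact (full
    enumeration of group assignments) when n_x + n_y <= 12 with no ties, and
    otherwise a normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("mann_whitney requires two non-empty groups")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])

    def u_stat(a: np.ndarray, b: np.ndarray) -> float:
        gt = (a[:, None] > b[None, :]).sum()
        eq = (a[:, None] == b[None, :]).sum()
        return gt + 0.5 * eq

    u = u_stat(x, y)
    mu = n1 * n2 / 2.0
    no_ties = np.unique(combined).size == combined.size
    if n1 + n2 <= 12 and no_ties:
        null = []
        idx = set(range(n1 + n2))
        for comb in itertools.combinations(range(n1 + n2), n1):
            a = combined[list(comb)]
            b = combined[sorted(idx - set(comb))]
            null.append(u_stat(a, b))
        null = np.asarray(null)
        p = float(np.mean(np.abs(null - mu) >= abs(u - mu) - 1e-12))
        return float(u), p
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1.0))
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(u), float(min(1.0, 2.0 * stats.norm.sf(z)))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors with a geometric-mean reference.

    The reference uses OTUs positive in every sample; if none exist, falls
    back to positive-count-only geometric means with a notice.
    """
    X = counts.to_numpy(dtype=float)
    all_positive = (X > 0).all(axis=0)
    if all_positive.any():
        logX = np.log(X[:, all_positive])
        log_ref = logX.mean(axis=0)
        sf = np.exp(np.median(logX - log_ref, axis=1))
    else:
        warnings.warn(
            "no OTU is positive in all samples; size factors use positive-count-only "
            "geometric means (pseudo-reference fallback)"
        )
        with np.errstate(divide="ignore"):
            logX = np.where(X > 0, np.log(X), np.nan)
        log_ref = np.nanmean(logX, axis=0)
        ratios = logX - log_ref
        if np.all(np.isnan(ratios)):
            raise DegenerateInputError("no OTU usable for size-factor estimation")
        sf = np.exp(np.nanmedian(ratios, axis=1))
    return pd.Series(sf, index=counts.index, name="size_factor")


def _mom_dispersion(y: np.ndarray, sf: np.ndarray, cells: np.ndarray, floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion pooled within design cells: var = mu + alpha*mu^2.

    Numerator and denominator are pooled across cells with df weights before
    taking the ratio — a median (or mean) of per-cell ratios is biased low
    because small-df variance estimates are right-skewed, and an
    underestimated dispersion makes every Wald test anticonservative.
    """
    q = y / sf
    num = 0.0
    den = 0.0
    for c in np.unique(cells):
        qc = q[cells == c]
        if qc.size < 2:
            continue
        m = qc.mean()
        if m <= 0:
            continue
        w = qc.size - 1
        num += w * (qc.var(ddof=1) - m)
        den += w * m**2
    if den <= 0:
        return floor
    return max(num / den, floor)


def nb_wald_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    terms=DEFAULT_TERMS,
    focal_terms=("treatment", "sex", "sex:treatment"),
    min_samples_detected: int = 2,
) -> pd.DataFrame:
    """Negative-binomial Wald survey of every OTU detected in >= 2 samples.

    Returns a long DataFrame (one row per OTU x focal term) with the natural
    coefficient, log2 fold change, Wald z, raw p, mean relative abundance and
    incidence. OTUs in fewer than ``min_samples_detected`` samples are omitted.
    """
    meta = canonical_meta(meta.loc[counts.index])
    X = design_matrix(meta, terms, intercept=True, drop_first=True, check_rank=True)
    Xa = X.to_numpy(float)
    colnames = list(X.columns)
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    cells = (
        meta["site"].astype(str) + "/" + meta["sex"].astype(str) + "/" + meta["treatment"].astype(str)
    ).to_numpy()

    rel = counts.div(counts.sum(axis=1), axis=0)
    mean_rel = rel.mean(axis=0)
    incidence = (counts >= 1).mean(axis=0)

    detected = (counts >= 1).sum(axis=0) >= min_samples_detected
    rows = []
    for otu in counts.columns[detected]:
        y = counts[otu].to_numpy(dtype=float)
        alpha = _mom_dispersion(y, sf.to_numpy(), cells)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(
                    y, Xa, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
                ).fit(maxiter=200)
            params, bse = fit.params, fit.bse
        except Exception:
            params = np.full(Xa.shape[1], np.nan)
            bse = np.full(Xa.shape[1], np.nan)
        for term in focal_terms:
            col = FOCAL_TERMS[term]
            j = colnames.index(col)
            coef, se = params[j], bse[j]
            z = coef / se if se and np.isfinite(se) and se > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append(
                {
                    "otu_id": otu,
                    "term": term,
                    "coef": coef,
                    "log2_fold": coef / np.log(2.0),
                    "wald_z": z,
                    "raw_p": p,
                    "mean_rel_abund": mean_rel[otu],
                    "incidence": incidence[otu],
                    "dispersion": alpha,
                }
            )
    return pd.DataFrame(rows)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_i = min over p_j >= p_i of p_j * m / rank_j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def filtered_bh(
    results: pd.DataFrame,
    min_mean_rel: float = 1e-4,
    min_incidence: float = 0.05,
) -> pd.DataFrame:
    """Apply BH only to OTUs passing the rare-OTU filters; rare OTUs get no q.

    Filters (mean relative abundance >= ``min_mean_rel``, incidence >=
    ``min_incidence``) are computed from abundance, never from p. When the
    results table carries a ``term`` column each term is corrected as its own
    family of tests.
    """
    out = results.copy()
    out["tested"] = (out["mean_rel_abund"] >= min_mean_rel) & (out["incidence"] >= min_incidence)
    out["q"] = np.nan
    group_cols = ["term"] if "term" in out.columns else []
    if group_cols:
        for _, idx in out.groupby(group_cols, observed=True).groups.items():
            mask = out.loc[idx, "tested"] & out.loc[idx, "raw_p"].notna()
            sel = out.loc[idx][mask]
            if len(sel):
                out.loc[sel.index, "q"] = bh_adjust(sel["raw_p"].to_numpy())
    else:
        mask = out["tested"] & out["raw_p"].notna()
        if mask.any():
            out.loc[mask, "q"] = bh_adjust(out.loc[mask, "raw_p"].to_numpy())
    return out
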