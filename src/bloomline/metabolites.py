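"""HPLC metabolite quantification and the interaction tests on log concentrations.

External standards (8 levels, 0.1-20 mM) are fit by weighted least squares
with inverse-square-concentration weights; all compounds except propionate
use a through-origin line, for which the weighted slope has the closed form
mean(area_i / conc_i). Extract concentrations convert to umol per gram wet
feces through the extraction volume (fixed 200 uL for the early protocol, or
1:10 weight:volume for the amended one); randomized extraction order means
the two protocols are encoded per sample, never cross-calibrated.

Zeros in a compound are replaced by half its lowest detected concentration
before natural-log transformation. The interaction tests are (a) an ANOVA
F-test for treatment-by-site on the model site + sex + treatment +
treatment:site, and (b) a Gaussian likelihood-ratio test (chi-square, 1 df)
for the sex-by-treatment term with all other two-way interactions retained
in both nested models.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._design import canonical_meta, design_matrix
from .exceptions import DegenerateInputError, InvalidParameterError

COMPOUNDS = ("acetate", "butyrate", "formate", "glucose", "lactate", "propionate", "succinate")
#: the only compound whose standard curve is fit with an intercept
INTERCEPT_COMPOUNDS = ("propionate",)


@dataclass
class StandardCurve:
    compound: str
    slope: float  # peak area per mM
    intercept: float  # peak area; 0 for through-origin fits
    with_intercept: bool
    points: pd.DataFrame  # (concentration_mM, peak_area)


def fit_standard_curve(points, compound: str = "", with_intercept: bool | None = None) -> StandardCurve:
    """Weighted least squares of peak area on concentration, weights 1 / concentration^2."""
    pts = pd.DataFrame(points, columns=["concentration_mM", "peak_area"]) if not isinstance(
        points, pd.DataFrame
    ) else points.rename(
        columns=lambda c: {"level_mM": "concentration_mM"}.get(c, c)
    )
    c = pts["concentration_mM"].to_numpy(dtype=float)
    a = pts["peak_area"].to_numpy(dtype=float)
    if with_intercept is None:
        with_intercept = compound in INTERCEPT_COMPOUNDS
    if (c <= 0).any():
        raise InvalidParameterError("standard concentrations must be strictly positive (weights are 1/c^2)")
    if with_intercept and c.size < 2:
        raise InvalidParameterError("an intercept fit needs at least 2 standard points")
    if c.size < 1:
        raise InvalidParameterError("at least one standard point is required")
    w = 1.0 / c**2
    if with_intercept:
        # weighted normal equations for area ~ intercept + slope * conc
        W = np.diag(w)
        X = np.column_stack([np.ones_like(c), c])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ a)
        intercept, slope = float(beta[0]), float(beta[1])
    else:
        slope = float(np.sum(w * c * a) / np.sum(w * c * c))  # == mean(a / c)
        intercept = 0.0
    return StandardCurve(compound, slope, intercept, with_intercept, pts)


def quantify(
    peak_area: float,
    curve: StandardCurve,
    pellet_weight_g: float,
    extraction_ratio: float = 10.0,
    fixed_volume_mL: float | None = None,
) -> tuple[float, bool]:
    """Concentration in umol per g wet feces; returns (value, clamped_below_zero).

    extract mM = (area - intercept) / slope; extract volume is either the
    fixed homogenization volume (mL) or weight * extraction_ratio (mL per g);
    umol/g = mM * volume / weight. Areas below the intercept clamp to 0.
    """
    if pellet_weight_g <= 0:
        raise InvalidParameterError("pellet weight must be positive")
    mM = (peak_area - curve.intercept) / curve.slope
    clamped = mM < 0
    mM = max(mM, 0.0)
    volume_mL = fixed_volume_mL if fixed_volume_mL is not None else pellet_weight_g * extraction_ratio
    return mM * volume_mL / pellet_weight_g, bool(clamped)


def zero_replace_log(values) -> np.ndarray:
    """Replace zeros by half the lowest detected value, then take the natural log."""
    v = np.asarray(values, dtype=float)
    pos = v[v > 0]
    if pos.size == 0:
        raise DegenerateInputError("all values are zero; cannot log-transform")
    out = np.where(v > 0, v, pos.min() / 2.0)
    return np.log(out)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def interaction_tests(log_conc, meta: pd.DataFrame) -> dict:
    """Treatment-by-site ANOVA p and sex-by-treatment Gaussian LRT p on log concentrations."""
    y = np.asarray(log_conc, dtype=float)
    meta = canonical_meta(meta)
    n = len(y)

    # (a) ANOVA: interaction term entered last of site + sex + treatment + treatment:site
    X0 = design_matrix(meta, ["site", "sex", "treatment"], check_rank=True).to_numpy(float)
    X1 = design_matrix(meta, ["site", "sex", "treatment", "treatment:site"], check_rank=True).to_numpy(float)
    rss0, rss1 = _ols_rss(X0, y), _ols_rss(X1, y)
    q = X1.shape[1] - X0.shape[1]
    df_res = n - X1.shape[1]
    F = ((rss0 - rss1) / q) / (rss1 / df_res)
    anova_p = float(stats.f.sf(F, q, df_res))

    # (b) LRT for sex:treatment with the other two-way interactions retained
    base = ["site", "sex", "treatment", "site:sex", "site:treatment"]
    Xn = design_matrix(meta, base, check_rank=True).to_numpy(float)
    Xf = design_matrix(meta, base + ["sex:treatment"], check_rank=True).to_numpy(float)
    rss_n, rss_f = _ols_rss(Xn, y), _ols_rss(Xf, y)
    lrt = n * np.log(rss_n / rss_f)
    df = Xf.shape[1] - Xn.shape[1]
    lrt_p = float(stats.chi2.sf(lrt, df))
    return {
        "treatment_site_F": float(F),
        "treatment_site_anova_p": anova_p,
        "sex_treatment_lrt_stat": float(lrt),
        "sex_treatment_lrt_p": lrt_p,
    }


def quantify_panel(
    peaks: pd.DataFrame,
    curves: dict[str, StandardCurve],
    meta: pd.DataFrame,
    extraction_ratio: float = 10.0,
    fixed_volume_col: str | None = None,
    weight_col: str = "pellet_weight_g",
) -> pd.DataFrame:
    """Quantify a long peak table (sample_id, compound, peak_area) into a sample x compound panel.

    Adds total SCFA = acetate + butyrate + propionate.
    """
    rows = {}
    for sample, grp in peaks.groupby("sample_id"):
        weight = float(meta.loc[sample, weight_col])
        fixed = float(meta.loc[sample, fixed_volume_col]) if fixed_volume_col else None
        vals = {}
        for _, r in grp.iterrows():
            comp = r["compound"]
            if comp not in curves:
                continue
            vals[comp], _ = quantify(
                float(r["peak_area"]), curves[comp], weight, extraction_ratio, fixed
            )
        rows[sample] = vals
    panel = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    scfas = [c for c in ("acetate", "butyrate", "propionate") if c in panel.columns]
    if len(scfas) == 3:
        panel["total_scfa"] = panel[scfas].sum(axis=1)
    return panel
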