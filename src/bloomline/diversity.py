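"""Alpha diversity (Chao1, Simpson's evenness) with rarefaction, the
partition-then-rarefy procedure, and Bray-Curtis dissimilarity.

Chao1 uses the bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)), finite
even when no doubletons are observed. Simpson's evenness is the inverse
Simpson index divided by observed richness. Rarefaction is a single seeded
subsample without replacement (multivariate hypergeometric), not an average
over realizations.

The partitioned procedure removes a set of focal OTUs *first* and only then
subsamples every sample to the common minimum remaining depth — the order
matters, and is the point: it asks whether diversity among the non-focal
community members changed, free of the compositional shadow a blooming taxon
casts over the rest at fixed sequencing depth.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidParameterError


def subsample_counts(counts, depth: int, seed: int = 0, sample: str = "") -> np.ndarray:
    """Rarefy one sample to ``depth`` reads without replacement (one seeded realization)."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise InvalidParameterError(
            f"cannot subsample to depth {depth} > total reads {total}"
            + (f" for sample {sample!r}" if sample else "")
        )
    if depth == total:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise DegenerateInputError("chao1 requires at least one positive count")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def simpson_evenness(counts) -> float:
    """Inverse-Simpson diversity over observed richness; 1 for a perfectly even sample."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DegenerateInputError("simpson_evenness requires at least one positive count")
    p = counts[counts > 0] / total
    return (1.0 / np.sum(p**2)) / p.size


def alpha_diversity(
    counts: pd.DataFrame, depth: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Chao1 and Simpson's evenness per sample after rarefying to a common depth.

    ``depth`` defaults to the cohort minimum endemic read count.
    """
    totals = counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    rng = np.random.default_rng(seed)
    rows = []
    for sample in counts.index:
        sub = subsample_counts(
            counts.loc[sample].to_numpy(), depth, seed=int(rng.integers(0, 2**31 - 1)), sample=str(sample)
        )
        rows.append((chao1(sub), simpson_evenness(sub)))
    out = pd.DataFrame(rows, index=counts.index, columns=["chao1", "simpson_evenness"])
    out["rarefaction_depth"] = depth
    return out


def partitioned_diversity(
    counts: pd.DataFrame, exclude=(), seed: int = 0
) -> pd.DataFrame:
    """Remove ``exclude`` OTUs first, then rarefy all samples to the minimum remaining total.

    Samples left empty by the partition are dropped with a warning.
    """
    exclude = [o for o in exclude if o in counts.columns]
    kept = counts.drop(columns=exclude)
    totals = kept.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} sample(s) emptied by the partition: "
            f"{list(totals.index[empty])}"
        )
        kept = kept.loc[~empty]
    out = alpha_diversity(kept, depth=int(kept.sum(axis=1).min()), seed=seed)
    out["excluded_otus"] = ",".join(str(e) for e in exclude)
    return out


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1].

    Pairs of all-zero samples are undefined and flagged as NaN with a warning.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise InvalidParameterError("Bray-Curtis requires non-negative values")
    diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    summ = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(summ > 0, diff / np.where(summ > 0, summ, 1.0), np.nan)
    np.fill_diagonal(D, 0.0)
    if np.isnan(D).any():
        warnings.warn("all-zero sample pairs produce undefined Bray-Curtis values (NaN)")
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)
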