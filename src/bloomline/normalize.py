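"""Spike-in normalization: relative and spike-adjusted absolute abundances.

A known volume of a *Sphingopyxis alaskensis* culture is spiked into each
weighed fecal sample before DNA extraction. Reads classified to the spike
organism are separated from the endemic community, and each taxon's density
is expressed in uL-spike-equivalents per gram:

    spike_adjusted = RelativeAbundance
                     * (TotalEndemicReadCount * SpikeVolume)
                     / (TotalSpikeReadCount * SampleWeight)

This statistic decouples taxa from the compositional constraint: a bloom of
one taxon dilutes everyone's *relative* abundance but leaves the others'
spike-adjusted values unchanged in expectation. No attempt is made to convert
to literal 16S copies per gram; units remain uL-spike-equivalents/g.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError


@dataclass
class CountMatrix:
    """Endemic sample x OTU read counts plus per-sample spike recovery and handling data."""

    counts: pd.DataFrame  # sample x OTU, non-negative ints; spike NOT among columns
    spike_counts: pd.Series  # reads classified to the spike organism
    sample_weight: pd.Series  # grams
    spike_volume: pd.Series  # uL

    def __post_init__(self) -> None:
        idx = self.counts.index
        self.spike_counts = self.spike_counts.reindex(idx)
        self.sample_weight = self.sample_weight.reindex(idx)
        self.spike_volume = self.spike_volume.reindex(idx)
        if (self.sample_weight <= 0).any():
            raise InvalidParameterError("sample weights must be strictly positive")
        if (self.spike_volume <= 0).any():
            raise InvalidParameterError("spike volumes must be strictly positive")

    @property
    def total_endemic(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class AbundanceMatrix:
    """Sample x taxon abundances with unit ('relative' or 'spike_equiv') and level metadata."""

    values: pd.DataFrame
    units: str  # 'relative' | 'spike_equiv'
    level: str  # 'otu' | 'family'


def relative_abundance(cm: CountMatrix) -> AbundanceMatrix:
    """Proportions of endemic reads; all-zero samples are excluded with a warning."""
    totals = cm.total_endemic
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"excluding {int(empty.sum())} sample(s) with zero endemic reads: "
            f"{list(totals.index[empty])}"
        )
    counts = cm.counts.loc[~empty]
    rel = counts.div(counts.sum(axis=1), axis=0)
    return AbundanceMatrix(rel, units="relative", level="otu")


def spike_adjusted_values(rel, total_endemic, total_spike, spike_volume, weight):
    """The spike formula for one sample (vectorized over taxa).

    rel * (total_endemic * spike_volume) / (total_spike * weight); summing over
    all taxa yields (total_endemic * spike_volume) / (total_spike * weight).
    """
    if weight <= 0:
        raise InvalidParameterError("weight must be positive")
    if total_spike < 1:
        raise InvalidParameterError("spike_adjusted_values requires at least one spike read")
    return np.asarray(rel, dtype=float) * (total_endemic * spike_volume) / (total_spike * weight)


def spike_adjusted(cm: CountMatrix) -> AbundanceMatrix:
    """Spike-adjusted abundances (uL-spike-equivalents per gram) for every sample.

    Samples with zero spike reads have no defined value; they are returned as
    missing (NaN) with a warning — never imputed with a pseudo-count.
    """
    rel = relative_abundance(cm)
    values = pd.DataFrame(np.nan, index=rel.values.index, columns=rel.values.columns)
    totals = cm.total_endemic
    no_spike = []
    for sample in rel.values.index:
        ts = int(cm.spike_counts.loc[sample])
        if ts == 0:
            no_spike.append(sample)
            continue
        values.loc[sample] = spike_adjusted_values(
            rel.values.loc[sample].to_numpy(),
            float(totals.loc[sample]),
            ts,
            float(cm.spike_volume.loc[sample]),
            float(cm.sample_weight.loc[sample]),
        )
    if no_spike:
        warnings.warn(
            f"{len(no_spike)} sample(s) with zero spike reads left as missing: {no_spike}"
        )
    return AbundanceMatrix(values, units="spike_equiv", level="otu")


def aggregate_family(abund: AbundanceMatrix, taxonomy: pd.Series | dict) -> AbundanceMatrix:
    """Sum member-OTU abundances within each family; unmapped OTUs pool into 'unclassified'.

    Works on either unit; total abundance per sample is conserved.
    """
    if abund.level != "otu":
        raise InvalidParameterError("aggregate_family expects an OTU-level matrix")
    if isinstance(taxonomy, pd.DataFrame):
        taxonomy = taxonomy["family"]
    mapping = dict(taxonomy) if not isinstance(taxonomy, dict) else taxonomy
    fams = [mapping.get(otu, "unclassified") for otu in abund.values.columns]
    out = abund.values.T.groupby(pd.Index(fams, name="family")).sum(min_count=1).T
    return AbundanceMatrix(out, units=abund.units, level="family")
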