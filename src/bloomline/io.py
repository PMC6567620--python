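"""Readers and writers for the tab-separated formats the pipeline consumes.

Count tables may be plain sample x OTU TSVs or mothur "shared"-style files
(label / Group / numOtus columns are tolerated and ignored). Taxonomy tables
follow mothur cons.taxonomy conventions: a semicolon-delimited lineage with
optional bootstrap-confidence suffixes, stripped on read. The spike-in taxon
is identified by a label match against the lineage — read processing itself
is out of scope here — and its reads are split out of the endemic table.
"""
from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .normalize import CountMatrix

_CONFIDENCE = re.compile(r"\(\d+(\.\d+)?\)")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Sample x OTU integer counts from a generic or mothur shared-style TSV."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "group" in cols:  # mothur shared format
        df = df.set_index(cols["group"])
        drop = [cols[c] for c in ("label", "numotus") if c in cols]
        df = df.drop(columns=drop)
    else:
        df = df.set_index(df.columns[0])
    return df.astype(int)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """OTU -> (family, lineage) from a cons.taxonomy-style TSV.

    Confidence suffixes like ``(100)`` are stripped; the family is the
    fifth lineage rank when present, otherwise 'unclassified'.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    otu_col = cols.get("otu", df.columns[0])
    tax_col = cols.get("taxonomy", cols.get("lineage", df.columns[-1]))
    out = []
    for _, row in df.iterrows():
        lineage = _CONFIDENCE.sub("", str(row[tax_col])).strip().strip(";")
        ranks = [r.strip() for r in lineage.split(";") if r.strip()]
        if "family" in cols:
            family = str(row[cols["family"]])
        else:
            family = ranks[4] if len(ranks) > 4 else "unclassified"
            if family.lower().startswith("unclassified") or not family:
                family = "unclassified"
        out.append((str(row[otu_col]), family, lineage))
    return pd.DataFrame(out, columns=["otu", "family", "lineage"]).set_index("otu")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def split_spike(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, spike_taxon: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Separate columns whose lineage (or OTU id) matches the spike taxon label."""
    label = spike_taxon.lower()
    spike_cols = [
        otu
        for otu in counts.columns
        if label in str(otu).lower()
        or (otu in taxonomy.index and label in str(taxonomy.loc[otu, "lineage"]).lower())
    ]
    spike = counts[spike_cols].sum(axis=1) if spike_cols else pd.Series(0, index=counts.index)
    endemic = counts.drop(columns=spike_cols)
    return endemic, spike.rename("spike_reads")


def build_count_matrix(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    meta: pd.DataFrame,
    spike_taxon: str = "Sphingopyxis",
    weight_col: str = "weight_g",
    spike_vol_col: str = "spike_uL",
) -> CountMatrix:
    endemic, spike = split_spike(counts, taxonomy, spike_taxon)
    common = endemic.index.intersection(meta.index)
    return CountMatrix(
        counts=endemic.loc[common],
        spike_counts=spike.loc[common],
        sample_weight=meta.loc[common, weight_col],
        spike_volume=meta.loc[common, spike_vol_col],
    )
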