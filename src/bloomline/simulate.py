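"""Synthetic cohort generator.

Emulates the statistical structure of a multi-site mouse ageing study in which
the α-glucosidase inhibitor acarbose (ACA) shifts starch to the colon: a
3-site × 2-sex × 2-treatment factorial cohort (12 mice per cell by default,
144 samples), 16S OTU read counts with a *Sphingopyxis alaskensis* spike-in,
a treatment-responsive "bloom" OTU whose identity differs by site (OTU-1 at
TJL and UM, OTU-4 at UT; OTU-4 is nearly absent elsewhere), depressed
densities for the remaining *Muribaculaceae*, taxon-coupled fecal metabolite
concentrations, and lifespans coupled to standardized SCFA concentrations
through a Weibull proportional-hazards model with left truncation at the
sampling age.

Two modes are supported: "planted-effect" (the defaults, which plant the
study's reported effect sizes: a 4.3-fold bloom, a 0.5-fold depression of the
other Muribaculaceae, and per-SD hazard ratios of 0.674/0.586/1.576 for
propionate/butyrate/acetate) and "null" (:meth:`GeneratorParams.null`), in
which every planted effect is switched off so downstream tests should reject
at their nominal level.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidParameterError

SITES = ("TJL", "UM", "UT")
SEXES = ("F", "M")
TREATMENTS = ("control", "ACA")
SCFAS = ("propionate", "butyrate", "acetate")
METABOLITES = ("acetate", "butyrate", "propionate", "succinate", "lactate", "glucose")

#: lineage prefixes used when writing mothur-style taxonomy tables
_FAMILY_LINEAGE = {
    "Muribaculaceae": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Muribaculaceae",
    "Lactobacillaceae": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae",
    "Lachnospiraceae": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae",
    "Ruminococcaceae": "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae",
    "Erysipelotrichaceae": "Bacteria;Firmicutes;Erysipelotrichia;Erysipelotrichales;Erysipelotrichaceae",
    "Bacteroidaceae": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Bacteroidaceae",
    "Deferribacteraceae": "Bacteria;Deferribacteres;Deferribacteres;Deferribacterales;Deferribacteraceae",
    "unclassified": "Bacteria;unclassified;unclassified;unclassified;unclassified",
}
SPIKE_LINEAGE = (
    "Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingopyxis"
)
SPIKE_OTU = "OTU-spike"


def default_taxonomy(n_otus: int) -> pd.DataFrame:
    """Deterministic OTU -> family assignment mirroring the dominant mouse gut families."""
    rows = []
    for i in range(1, n_otus + 1):
        if i in (1, 4, 5) or 10 <= i <= 39:
            fam = "Muribaculaceae"
        elif i == 2 or 40 <= i <= 49:
            fam = "Lactobacillaceae"
        elif i == 3 or 50 <= i <= 99:
            fam = "Lachnospiraceae"
        elif 100 <= i <= 139:
            fam = "Ruminococcaceae"
        elif 140 <= i <= 149:
            fam = "Erysipelotrichaceae"
        elif i in (6, 7):
            fam = "Bacteroidaceae"
        elif i in (8, 9):
            fam = "Deferribacteraceae"
        else:
            fam = "unclassified"
        rows.append((f"OTU-{i}", fam, _FAMILY_LINEAGE[fam] + ";unclassified"))
    return pd.DataFrame(rows, columns=["otu", "family", "lineage"]).set_index("otu")


def default_metabolite_coefficients() -> dict[str, dict[str, float]]:
    """Per-taxon log-linear couplings: Muribaculaceae OTUs drive propionate,
    Lachnospiraceae/Ruminococcaceae drive butyrate and acetate, the dominant
    Lactobacillus drives lactate, and the bloom OTUs consume succinate."""
    return {
        "propionate": {"OTU-1": 0.35, "OTU-4": 0.35, "OTU-5": 0.25},
        "butyrate": {"OTU-3": 0.25, "OTU-50": 0.20, "OTU-100": 0.15},
        "acetate": {"OTU-3": 0.15, "OTU-51": 0.15, "OTU-101": 0.10},
        "lactate": {"OTU-2": 0.40},
        "succinate": {"OTU-1": -0.10, "OTU-4": -0.10},
        "glucose": {},
    }


def _default_base_log() -> dict[str, float]:
    # natural-log baseline concentrations (umol/g wet feces) near the reported
    # control medians: acetate ~15, butyrate ~2.5, propionate ~1.4, succinate ~2.9,
    # lactate ~3, glucose ~6
    return {
        "acetate": math.log(15.0),
        "butyrate": math.log(2.5),
        "propionate": math.log(1.4),
        "succinate": math.log(2.9),
        "lactate": math.log(3.0),
        "glucose": math.log(6.0),
    }


@dataclass
class GeneratorParams:
    """Knobs of the synthetic cohort; defaults are the planted study conditions."""

    n_otus: int = 200
    log_density_mean: float = math.log(2e6)  # ln copies/g, typical OTU
    log_density_sd_between_otus: float = 1.2
    log_density_sd: float = 0.7  # mouse-to-mouse, ln scale
    site_offset_sd: float = 0.3
    otu_log_mean_overrides: dict = field(
        default_factory=lambda: {
            "OTU-1": math.log(4e7),
            "OTU-2": math.log(3e7),
            "OTU-3": math.log(3e7),
            "OTU-4": math.log(3e7),
            "OTU-5": math.log(1e7),
        }
    )
    site_restricted: dict = field(default_factory=lambda: {"OTU-4": "UT"})
    bloom_otu_by_site: dict = field(
        default_factory=lambda: {"TJL": "OTU-1", "UM": "OTU-1", "UT": "OTU-4"}
    )
    bloom_fold: float = 4.3
    muribaculaceae_other_fold: float = 0.5
    sequencing_depth: int = 10_000
    spike_copies_per_uL: float = 2e5
    spike_volume: float = 10.0  # uL
    sample_weight_range: tuple = (0.02, 0.08)  # g
    metabolite_coefficients: dict = field(default_factory=default_metabolite_coefficients)
    metabolite_design_effects: dict = field(
        default_factory=lambda: {"glucose": {"treatment": 0.6}}
    )
    metabolite_base_log: dict = field(default_factory=_default_base_log)
    metabolite_noise_sd: float = 0.3
    acetate_butyrate_latent_sd: float = 0.4
    detection_limit: float = 0.05  # umol/g; below this a concentration reads as 0
    hazard_betas: dict = field(
        default_factory=lambda: {
            "propionate": math.log(0.674),
            "butyrate": math.log(0.586),
            "acetate": math.log(1.576),
        }
    )
    weibull_shape: float = 6.0
    weibull_scale: float = 957.0  # days; baseline median ~900 d
    treatment_log_hr: float = 0.0  # design effects on hazard, off by default
    sex_log_hr: float = 0.0
    cage_effect_sd: float = 0.0  # optional; no value is planted by default
    sampling_age_range: tuple = (762, 973)  # days

    def __post_init__(self) -> None:
        for name in ("bloom_fold", "muribaculaceae_other_fold", "weibull_shape", "weibull_scale"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.metabolite_noise_sd < 0:
            raise InvalidParameterError("metabolite_noise_sd must be non-negative")
        if self.n_otus < 1:
            raise InvalidParameterError("n_otus must be >= 1")

    @classmethod
    def null(cls, **overrides) -> "GeneratorParams":
        """Null mode: every planted effect switched off (folds 1, couplings 0, betas 0)."""
        base = dict(
            bloom_fold=1.0,
            muribaculaceae_other_fold=1.0,
            metabolite_coefficients={m: {} for m in METABOLITES},
            metabolite_design_effects={},
            acetate_butyrate_latent_sd=0.0,
            hazard_betas={s: 0.0 for s in SCFAS},
            treatment_log_hr=0.0,
            sex_log_hr=0.0,
        )
        base.update(overrides)
        return cls(**base)


def generate_design(n_per_cell: int = 12, seed: int = 0) -> pd.DataFrame:
    """Fully factorial site x sex x treatment design, one sampled mouse per cage.

    Sampling ages are uniform over the study's collection window (762-973 days).
    """
    if not isinstance(n_per_cell, (int, np.integer)) or n_per_cell < 1:
        raise InvalidParameterError(f"n_per_cell must be a positive integer, got {n_per_cell!r}")
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for site in SITES:
        for sex in SEXES:
            for trt in TREATMENTS:
                for _ in range(n_per_cell):
                    i += 1
                    rows.append((f"m{i:04d}", site, sex, trt, f"c{i:04d}"))
    design = pd.DataFrame(rows, columns=["mouse_id", "site", "sex", "treatment", "cage_id"])
    design = design.set_index("mouse_id")
    lo, hi = 762, 973
    design["sampling_age"] = rng.integers(lo, hi + 1, size=len(design))
    design["site"] = pd.Categorical(design["site"], categories=SITES)
    design["sex"] = pd.Categorical(design["sex"], categories=SEXES)
    design["treatment"] = pd.Categorical(design["treatment"], categories=TREATMENTS)
    return design


def generate_community(
    design: pd.DataFrame,
    params: GeneratorParams,
    seed: int = 0,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Latent absolute densities (16S copies per gram), sample x OTU.

    Log-normal per-OTU baselines with site-specific means; under ACA the site's
    bloom OTU is multiplied by ``bloom_fold`` and the remaining Muribaculaceae
    by ``muribaculaceae_other_fold``. Site-restricted OTUs are essentially
    absent outside their home site.
    """
    rng = np.random.default_rng(seed)
    otus = [f"OTU-{i}" for i in range(1, params.n_otus + 1)]
    if taxonomy is None:
        taxonomy = default_taxonomy(params.n_otus)
    sites_in_design = set(design["site"].astype(str))
    for site in sites_in_design:
        if site not in params.bloom_otu_by_site:
            raise InvalidParameterError(f"bloom_otu_by_site has no entry for site {site!r}")
        if params.bloom_otu_by_site[site] not in otus:
            raise InvalidParameterError(
                f"bloom OTU {params.bloom_otu_by_site[site]!r} for site {site!r} is not a valid OTU"
            )

    base = rng.normal(params.log_density_mean, params.log_density_sd_between_otus, params.n_otus)
    for otu, mu in params.otu_log_mean_overrides.items():
        if otu in otus:
            base[otus.index(otu)] = mu
    site_mu = {}
    for site in SITES:
        offs = rng.normal(0.0, params.site_offset_sd, params.n_otus)
        mu = base + offs
        for otu, home in params.site_restricted.items():
            if otu in otus and site != home:
                mu[otus.index(otu)] = -50.0  # effectively absent
        site_mu[site] = mu

    murib = set(taxonomy.index[taxonomy["family"] == "Muribaculaceae"])
    bloom_set = set(params.bloom_otu_by_site.values())
    other_murib = sorted(murib - bloom_set)

    log_d = np.empty((len(design), params.n_otus))
    for i, (_, row) in enumerate(design.iterrows()):
        log_d[i] = site_mu[str(row["site"])] + rng.normal(0.0, params.log_density_sd, params.n_otus)
    dens = pd.DataFrame(np.exp(log_d), index=design.index, columns=otus)

    treated = (design["treatment"].astype(str) == "ACA").to_numpy()
    for site in sites_in_design:
        in_site = (design["site"].astype(str) == site).to_numpy()
        mask = treated & in_site
        dens.loc[mask, params.bloom_otu_by_site[site]] *= params.bloom_fold
    if other_murib:
        dens.loc[treated, other_murib] *= params.muribaculaceae_other_fold
    return dens


def sequence_sample(
    densities: np.ndarray,
    weight: float,
    spike_volume: float,
    params: GeneratorParams,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Multinomial reads over (endemic copies * weight, spike copies); returns (counts, spike)."""
    if params.sequencing_depth < 1:
        raise InvalidParameterError("sequencing_depth must be >= 1")
    if weight <= 0:
        raise InvalidParameterError("sample weight must be positive")
    rng = np.random.default_rng(seed)
    endemic = np.asarray(densities, dtype=float) * weight
    spike = params.spike_copies_per_uL * spike_volume
    total = endemic.sum() + spike
    if total <= 0:
        raise DegenerateInputError("all endemic densities are zero and no spike is present")
    probs = np.append(endemic, spike) / total
    draw = rng.multinomial(params.sequencing_depth, probs)
    return draw[:-1], int(draw[-1])


def sequence_cohort(
    densities: pd.DataFrame,
    weights: pd.Series,
    params: GeneratorParams,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sequence every sample; returns (counts sample x OTU, spike read counts)."""
    rng = np.random.default_rng(seed)
    counts = np.empty(densities.shape, dtype=int)
    spikes = np.empty(len(densities), dtype=int)
    for i, sample in enumerate(densities.index):
        sub = int(rng.integers(0, 2**31 - 1))
        counts[i], spikes[i] = sequence_sample(
            densities.loc[sample].to_numpy(), float(weights.loc[sample]), params.spike_volume, params, sub
        )
    return (
        pd.DataFrame(counts, index=densities.index, columns=densities.columns),
        pd.Series(spikes, index=densities.index, name="spike_reads"),
    )


def generate_metabolites(
    densities: pd.DataFrame,
    design: pd.DataFrame,
    params: GeneratorParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample metabolite concentrations (umol/g wet feces).

    log-concentration = base + design effects + sum(coeff * centred log1p density)
    + shared acetate/butyrate latent factor + Gaussian noise. Values below the
    detection limit are reported as 0.
    """
    if params.metabolite_noise_sd < 0:
        raise InvalidParameterError("metabolite_noise_sd must be non-negative")
    missing = [m for m in METABOLITES if m not in params.metabolite_coefficients]
    if missing:
        raise InvalidParameterError(f"metabolite_coefficients missing entries for {missing}")
    rng = np.random.default_rng(seed)
    n = len(design)
    z = np.log1p(densities)
    # centred within site so couplings act on within-site density variation; a
    # site-restricted taxon otherwise injects an artificial cross-site offset
    z = z - z.groupby(design["site"].astype(str)).transform("mean")
    treated = (design["treatment"].astype(str) == "ACA").to_numpy().astype(float)
    male = (design["sex"].astype(str) == "M").to_numpy().astype(float)
    latent = rng.normal(0.0, params.acetate_butyrate_latent_sd, n) if params.acetate_butyrate_latent_sd > 0 else np.zeros(n)

    out = {}
    for met in METABOLITES:
        log_c = np.full(n, params.metabolite_base_log[met])
        eff = params.metabolite_design_effects.get(met, {})
        log_c += eff.get("treatment", 0.0) * treated + eff.get("sex", 0.0) * male
        for otu, coeff in params.metabolite_coefficients[met].items():
            if otu in z.columns:
                log_c += coeff * z[otu].to_numpy()
        if met in ("acetate", "butyrate"):
            log_c += latent
        log_c += rng.normal(0.0, params.metabolite_noise_sd, n)
        conc = np.exp(log_c)
        conc[conc < params.detection_limit] = 0.0
        out[met] = conc
    panel = pd.DataFrame(out, index=design.index)
    panel["total_scfa"] = panel["acetate"] + panel["butyrate"] + panel["propionate"]
    return panel


def generate_survival(
    design: pd.DataFrame,
    scfa_std: pd.DataFrame,
    params: GeneratorParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Death ages from a Weibull proportional-hazards model, left-truncated at sampling age.

    Conditional inverse-transform sampling on the survivor function given
    survival to the sampling age: with cumulative hazard H(t) = (t/scale)^shape
    * exp(eta) and E ~ Exp(1), t = scale * ((a/scale)^shape + E*exp(-eta))^(1/shape).
    Every mouse's death is observed (event = 1; no right censoring).
    """
    if params.weibull_shape <= 0 or params.weibull_scale <= 0:
        raise InvalidParameterError("Weibull shape and scale must be positive")
    rng = np.random.default_rng(seed)
    n = len(design)
    eta = np.zeros(n)
    eta += params.treatment_log_hr * (design["treatment"].astype(str) == "ACA").to_numpy()
    eta += params.sex_log_hr * (design["sex"].astype(str) == "M").to_numpy()
    for scfa, beta in params.hazard_betas.items():
        if beta != 0.0 or scfa in scfa_std.columns:
            if scfa not in scfa_std.columns:
                raise InvalidParameterError(f"scfa_std has no column {scfa!r}")
            eta += beta * scfa_std[scfa].to_numpy()
    k, lam = params.weibull_shape, params.weibull_scale
    a = design["sampling_age"].to_numpy(float)
    e = rng.exponential(1.0, n)
    t = lam * ((a / lam) ** k + e * np.exp(-eta)) ** (1.0 / k)
    death = np.floor(t).astype(int)
    death = np.where(death <= a, a.astype(int) + 1, death)
    table = design[["site", "sex", "treatment"]].copy()
    table["entry"] = design["sampling_age"].astype(int)
    table["time"] = death
    table["event"] = 1
    for scfa in scfa_std.columns:
        table[scfa] = scfa_std[scfa].to_numpy()
    return table


def standardize(df: pd.DataFrame, columns=SCFAS) -> pd.DataFrame:
    """Center to mean 0 / scale to SD 1 (population SD) within the analysis set."""
    out = pd.DataFrame(index=df.index)
    for col in columns:
        v = df[col].to_numpy(float)
        out[col] = (v - v.mean()) / v.std()
    return out


@dataclass
class Cohort:
    """A fully simulated cohort: metadata, reads, taxonomy, latent truth, panel, lifespans."""

    metadata: pd.DataFrame  # site, sex, treatment, cage, weight, spike volume, ages
    counts: pd.DataFrame  # sample x OTU endemic reads
    spike_counts: pd.Series
    taxonomy: pd.DataFrame
    densities: pd.DataFrame  # latent copies/g (ground truth)
    metabolites: pd.DataFrame
    params: GeneratorParams

    def write(self, outdir: str | Path) -> None:
        """Write counts/taxonomy/metadata/metabolites TSVs (spike reads as a labelled OTU column)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts = self.counts.copy()
        counts[SPIKE_OTU] = self.spike_counts
        counts.rename_axis("sample").to_csv(outdir / "counts.tsv", sep="\t")
        tax = self.taxonomy.copy()
        tax.loc[SPIKE_OTU] = ["Sphingomonadaceae", SPIKE_LINEAGE]
        tax.rename_axis("otu").to_csv(outdir / "taxonomy.tsv", sep="\t")
        self.metadata.rename_axis("mouse_id").to_csv(outdir / "metadata.tsv", sep="\t")
        self.metabolites.rename_axis("sample").to_csv(outdir / "metabolites.tsv", sep="\t")


def simulate_cohort(
    params: GeneratorParams | None = None,
    seed: int = 0,
    n_per_cell: int = 12,
) -> Cohort:
    """End-to-end cohort simulation from one seed (bit-identical per seed)."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=6)
    design = generate_design(n_per_cell, seed=int(sub[0]))
    taxonomy = default_taxonomy(params.n_otus)
    densities = generate_community(design, params, seed=int(sub[1]), taxonomy=taxonomy)
    wlo, whi = params.sample_weight_range
    weights = pd.Series(
        np.random.default_rng(int(sub[2])).uniform(wlo, whi, len(design)),
        index=design.index,
        name="weight_g",
    )
    counts, spikes = sequence_cohort(densities, weights, params, seed=int(sub[3]))
    metabolites = generate_metabolites(densities, design, params, seed=int(sub[4]))
    scfa_std = standardize(metabolites, SCFAS)
    survival = generate_survival(design, scfa_std, params, seed=int(sub[5]))
    meta = design.copy()
    meta["weight_g"] = weights
    meta["spike_uL"] = params.spike_volume
    meta["death_age"] = survival["time"]
    return Cohort(meta, counts, spikes, taxonomy, densities, metabolites, params)
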