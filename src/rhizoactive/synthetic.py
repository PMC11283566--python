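"""Ground-truthed synthetic data for the whole pipeline.

Emulates a greenhouse drought study at desk scale: two crop-legacy soil
pools x planted/unplanted x (a pre-drought day-0 baseline plus
drought/watered over days 2-6), several replicate tubes per cell, paired
DNA (16S rRNA gene) and cDNA (16S rRNA) libraries per sample, reagent
contaminants enriched in extraction negative controls, and a metabolite
feature matrix with group-shifted discriminating features.

The generative model keeps "activity" well defined: every taxon carries a
latent activity multiplier ``a_t``; a sample's cDNA composition is its DNA
composition reweighted by ``a_t`` and renormalized, then both libraries are
sequenced multinomially at a negative-binomial depth.  Active taxa
(``a_t >= 1``) therefore have inflated rRNA:rRNA-gene count ratios, and the
truth object records exactly which taxa a perfect classifier should call
active, phantom, or contaminant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountTable, PairedAssay, pair_assays

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_paired_assay", "simulate_metabolome"]


@dataclass
class SimulationConfig:
    """Knobs of the paired-assay simulator; the defaults are the study design.

    Depth is reads per library, drawn NB(depth_mean, depth_dispersion) unless
    ``depth_dispersion`` is None (then exact).  Activity multipliers are
    bimodal log-normal: an ``fraction_active`` share of taxa draws from the
    active mode (median ``active_median``), the rest from the dormant mode;
    the two medians are placed so the abundance-weighted mean multiplier is
    ~1, which centers the rRNA:rRNA-gene count-ratio scale at 1.
    Phantom taxa have DNA relative abundance below ``1/depth_mean`` but a
    large multiplier, so they surface in cDNA libraries only.
    """

    n_taxa: int = 500
    replicates: int = 5
    soils: tuple[str, ...] = ("bean", "switchgrass")
    days: tuple[int, ...] = (2, 3, 4, 5, 6)
    depth_mean: float = 20_000.0
    depth_dispersion: float | None = 30.0
    abundance_sigma: float = 0.8
    soil_sigma: float = 1.0
    sample_sigma: float = 0.3
    fraction_active: float = 0.5
    active_median: float = 1.75
    active_sigma: float = 0.4
    dormant_median: float = 0.15
    dormant_sigma: float = 0.4
    phantom_fraction: float = 0.02
    phantom_activity: float = 40.0
    n_contaminants: int = 5
    contaminant_prev_controls: float = 0.9
    contaminant_prev_samples: float = 0.05
    n_negative_controls: int = 6
    control_depth: float = 1_000.0
    n_responders_planted: int | None = None    # default: 10% of taxa
    n_responders_drought: int | None = None    # default: 10% of taxa
    n_responders_interaction: int | None = None  # default: 5% of taxa
    effect_log2fold: float = 1.0
    drought_severity_scaling: bool = True
    rng_seed: int = 0

    def responder_counts(self) -> tuple[int, int, int]:
        planted = (self.n_responders_planted
                   if self.n_responders_planted is not None
                   else int(round(0.10 * self.n_taxa)))
        drought = (self.n_responders_drought
                   if self.n_responders_drought is not None
                   else int(round(0.10 * self.n_taxa)))
        inter = (self.n_responders_interaction
                 if self.n_responders_interaction is not None
                 else int(round(0.05 * self.n_taxa)))
        return planted, drought, inter

    def validate(self) -> None:
        for name in ("fraction_active", "phantom_fraction",
                     "contaminant_prev_controls", "contaminant_prev_samples"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        n_resp = sum(self.responder_counts())
        if n_resp > self.n_taxa:
            raise ValueError(
                f"{n_resp} responder taxa requested but only {self.n_taxa} taxa"
            )


@dataclass
class SyntheticTruth:
    """Latent ground truth paired with a simulated assay."""

    activity: pd.Series            # a_t per taxon (contaminants included, a_t = 1)
    phantom: pd.Series             # bool per taxon
    contaminant: pd.Series         # bool per taxon
    responders: dict[str, set[str]] = field(default_factory=dict)
    composition: pd.DataFrame | None = None   # per-sample expected DNA rel. abundance

    def active_taxa(self, threshold: float = 1.0) -> set[str]:
        return set(self.activity.index[self.activity >= threshold])


def _sample_ids(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for soil in cfg.soils:
        for planted in ("planted", "unplanted"):
            for rep in range(1, cfg.replicates + 1):
                rows.append((f"{soil}_{planted}_pre-drought_d0_r{rep}",
                             soil, planted, "pre-drought", 0, rep))
            for moisture in ("drought", "watered"):
                for day in cfg.days:
                    for rep in range(1, cfg.replicates + 1):
                        rows.append((f"{soil}_{planted}_{moisture}_d{day}_r{rep}",
                                     soil, planted, moisture, day, rep))
    return pd.DataFrame(
        rows, columns=["sample_id", "crop", "planted", "drought", "day", "replicate"]
    )


def simulate_paired_assay(
    cfg: SimulationConfig | None = None,
) -> tuple[PairedAssay, pd.DataFrame, SyntheticTruth]:
    """Simulate paired DNA/cDNA count tables, metadata, and ground truth.

    Negative controls appear in both tables and in the metadata
    (``is_negative_control=True``); their libraries are dominated by the
    contaminant taxa at ``contaminant_prev_controls`` prevalence, with a
    small cross-talk background of real taxa.  The same seed always yields
    byte-identical output.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    taxa = [f"otu{i:04d}" for i in range(cfg.n_taxa)]
    contam = [f"contam{i:02d}" for i in range(cfg.n_contaminants)]
    all_taxa = taxa + contam

    # latent activity multipliers
    n_active = int(round(cfg.fraction_active * cfg.n_taxa))
    is_active = np.zeros(cfg.n_taxa, dtype=bool)
    is_active[rng.choice(cfg.n_taxa, size=n_active, replace=False)] = True
    a = np.where(
        is_active,
        rng.lognormal(math.log(cfg.active_median), cfg.active_sigma, cfg.n_taxa),
        rng.lognormal(math.log(cfg.dormant_median), cfg.dormant_sigma, cfg.n_taxa),
    )

    # base composition of each soil pool (shared lognormal core + soil tilt)
    base = rng.lognormal(0.0, cfg.abundance_sigma, cfg.n_taxa)
    soil_weights = {
        soil: base * rng.lognormal(0.0, cfg.soil_sigma, cfg.n_taxa)
        for soil in cfg.soils
    }

    # phantom taxa: DNA relative abundance pinned below 1/depth_mean, huge a_t
    n_phantom = int(round(cfg.phantom_fraction * cfg.n_taxa))
    is_phantom = np.zeros(cfg.n_taxa, dtype=bool)
    if n_phantom:
        idx = rng.choice(cfg.n_taxa, size=n_phantom, replace=False)
        is_phantom[idx] = True
        a[idx] = cfg.phantom_activity
        for soil in cfg.soils:
            w = soil_weights[soil]
            target = 0.5 / cfg.depth_mean * w.sum()
            w[idx] = target  # fixed before renormalization; stays ~0.5 reads deep

    # responder assignments (disjoint, non-phantom)
    n_rp, n_rd, n_ri = cfg.responder_counts()
    free = rng.permutation(np.flatnonzero(~is_phantom))
    resp_planted = {taxa[i] for i in free[:n_rp]}
    resp_drought = {taxa[i] for i in free[n_rp: n_rp + n_rd]}
    resp_inter = {taxa[i] for i in free[n_rp + n_rd: n_rp + n_rd + n_ri]}
    effect = 2.0 ** cfg.effect_log2fold
    planted_mask = np.isin(taxa, sorted(resp_planted))
    drought_mask = np.isin(taxa, sorted(resp_drought))
    inter_mask = np.isin(taxa, sorted(resp_inter))

    meta = _sample_ids(cfg)
    max_day = max([0, *cfg.days])

    dna_rows, cdna_rows, comp_rows = {}, {}, {}
    a_full = np.concatenate([a, np.ones(cfg.n_contaminants)])
    for row in meta.itertuples(index=False):
        w = soil_weights[row.crop].copy()
        if row.planted == "planted":
            w[planted_mask] *= effect
        if row.drought == "drought":
            severity = 1.0
            if cfg.drought_severity_scaling and max_day:
                severity = row.day / max_day
            w[drought_mask] *= effect ** severity
            if row.planted == "planted":
                w[inter_mask] *= effect ** severity
        w *= rng.lognormal(0.0, cfg.sample_sigma, cfg.n_taxa)

        # contaminant carry-over into real samples
        w_full = np.concatenate([w, np.zeros(cfg.n_contaminants)])
        hit = rng.random(cfg.n_contaminants) < cfg.contaminant_prev_samples
        w_full[cfg.n_taxa:][hit] = w.sum() * 20.0 / cfg.depth_mean

        p_dna = w_full / w_full.sum()
        q = p_dna * a_full
        p_cdna = q / q.sum()
        depth_d = _draw_depth(rng, cfg.depth_mean, cfg.depth_dispersion)
        depth_c = _draw_depth(rng, cfg.depth_mean, cfg.depth_dispersion)
        dna_rows[row.sample_id] = rng.multinomial(depth_d, p_dna)
        cdna_rows[row.sample_id] = rng.multinomial(depth_c, p_cdna)
        comp_rows[row.sample_id] = p_dna

    # negative controls: contaminants + faint cross-talk background
    control_meta = []
    for i in range(cfg.n_negative_controls):
        sid = f"negctrl_r{i + 1}"
        control_meta.append(sid)
        w_full = np.zeros(cfg.n_taxa + cfg.n_contaminants)
        hit = rng.random(cfg.n_contaminants) < cfg.contaminant_prev_controls
        w_full[cfg.n_taxa:][hit] = 1.0
        bg = rng.choice(cfg.n_taxa, size=20, replace=False)
        w_full[bg] = 0.1 / 20.0 * max(hit.sum(), 1)
        p = w_full / w_full.sum()
        depth_d = _draw_depth(rng, cfg.control_depth, cfg.depth_dispersion)
        depth_c = _draw_depth(rng, cfg.control_depth, cfg.depth_dispersion)
        dna_rows[sid] = rng.multinomial(depth_d, p)
        cdna_rows[sid] = rng.multinomial(depth_c, p)

    dna = CountTable(pd.DataFrame.from_dict(dna_rows, orient="index", columns=all_taxa))
    cdna = CountTable(pd.DataFrame.from_dict(cdna_rows, orient="index", columns=all_taxa))
    assay = pair_assays(dna, cdna)

    meta["is_negative_control"] = False
    meta["dna_concentration"] = np.round(rng.lognormal(math.log(10.0), 0.4, len(meta)), 3)
    ctrl = pd.DataFrame({
        "sample_id": control_meta,
        "crop": pd.NA, "planted": pd.NA, "drought": pd.NA,
        "day": pd.NA, "replicate": pd.NA,
        "is_negative_control": True,
        "dna_concentration": np.round(rng.lognormal(math.log(0.5), 0.4, len(control_meta)), 3),
    })
    metadata = pd.concat([meta, ctrl], ignore_index=True).set_index("sample_id")
    metadata = metadata.astype({"day": "Int64", "replicate": "Int64"})

    truth = SyntheticTruth(
        activity=pd.Series(a_full, index=all_taxa, name="activity"),
        phantom=pd.Series(
            np.concatenate([is_phantom, np.zeros(cfg.n_contaminants, bool)]),
            index=all_taxa, name="phantom",
        ),
        contaminant=pd.Series(
            np.concatenate([np.zeros(cfg.n_taxa, bool), np.ones(cfg.n_contaminants, bool)]),
            index=all_taxa, name="contaminant",
        ),
        responders={"planted": resp_planted, "drought": resp_drought,
                    "interaction": resp_inter},
        composition=pd.DataFrame.from_dict(comp_rows, orient="index", columns=all_taxa),
    )
    return assay, metadata, truth


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if dispersion is None:
        return int(round(mean))
    p = dispersion / (dispersion + mean)
    return max(int(rng.negative_binomial(dispersion, p)), 1)


def simulate_metabolome(
    n_features: int = 200,
    n_per_group: int = 7,
    n_discriminating: int = 10,
    shift_sd_units: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Simulate an LC-MS style feature-intensity matrix for two groups.

    Intensities are log-normal per feature; the discriminating features are
    shifted upward in the second group by ``shift_sd_units`` standard
    deviations on the log scale.  Feature names follow the ``RT_mz``
    convention.  Returns (intensity matrix, group labels, truth feature set).
    """
    if n_features < 1 or n_per_group < 2:
        raise ValueError("n_features must be >= 1 and n_per_group >= 2")
    if n_discriminating > n_features:
        raise ValueError("n_discriminating cannot exceed n_features")
    rng = np.random.default_rng(seed)
    rt = np.round(rng.uniform(0.5, 14.5, n_features), 2)
    mz = np.round(rng.uniform(100.0, 1200.0, n_features), 4)
    features = [f"{r:.2f}_{m:.4f}" for r, m in zip(rt, mz)]
    # RT_mz pairs are effectively unique at this resolution; guard anyway
    if len(set(features)) != n_features:
        features = [f"{f}_{i}" for i, f in enumerate(features)]

    mu = rng.normal(4.0, 0.8, n_features)          # log10 mean intensity
    sd = rng.uniform(0.15, 0.45, n_features)       # log10 sd
    disc = set(rng.choice(n_features, size=n_discriminating, replace=False))

    groups = ["watered"] * n_per_group + ["drought"] * n_per_group
    sample_ids = [f"{g}_r{i % n_per_group + 1}" for i, g in enumerate(groups)]
    log10_x = np.empty((2 * n_per_group, n_features))
    for j in range(n_features):
        m = np.full(2 * n_per_group, mu[j])
        if j in disc:
            m[n_per_group:] += shift_sd_units * sd[j]
        log10_x[:, j] = rng.normal(m, sd[j])
    matrix = pd.DataFrame(10.0 ** log10_x, index=sample_ids, columns=features)
    labels = pd.Series(groups, index=sample_ids, name="group")
    return matrix, labels, {features[j] for j in sorted(disc)}
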