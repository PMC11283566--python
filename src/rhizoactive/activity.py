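"""Rarefaction and rRNA:rRNA-gene activity classification with phantom handling.

The core procedure: after both libraries of a sample are rarefied to a
common depth, a taxon is called *active* in that sample when its
cDNA (16S rRNA) to DNA (16S rRNA gene) count ratio is at or above a
threshold (default 1).  Taxa observed in a sample's cDNA but not its DNA
library are *phantom* detections; taxa whose phantom detections occur in
more than a prevalence cutoff (default 5%) of samples get those DNA zeros
recoded to 1 and are treated as active ("rescued"), while all other phantom
cells are excluded.  The DNA counts of active cells — with the 1
substitution — form the active community table used for all downstream
ecology; consequently active-table row sums vary across samples even though
the inputs were rarefied evenly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountTable, PairedAssay

__all__ = [
    "State",
    "ActivityParams",
    "ActivityTable",
    "rarefy",
    "classify_activity",
    "activity_summary",
    "heatmap_code_and_standardize",
]


class State(enum.IntEnum):
    """Per-cell activity state (sample x taxon)."""

    UNDETECTED = 0        # DNA = 0, cDNA = 0
    INACTIVE = 1          # cDNA = 0 with DNA > 0, or ratio below threshold
    ACTIVE = 2            # cDNA > 0 and cDNA/DNA >= threshold
    PHANTOM_RESCUED = 3   # DNA = 0, cDNA > 0, taxon phantom-prevalent -> DNA := 1
    PHANTOM_DROPPED = 4   # DNA = 0, cDNA > 0, taxon not phantom-prevalent


@dataclass(frozen=True)
class ActivityParams:
    """Classification parameters.

    depth: rarefaction depth in reads (the classifier itself only checks
    alignment; rarefy first).  ratio_threshold: minimum cDNA:DNA count ratio
    for an active call; ties are active.  phantom_prevalence: fraction of
    samples above which a taxon's phantom detections are rescued.
    prevalence_mode: "phantom" counts only phantom cells (cDNA>0, DNA=0)
    toward that prevalence; "cdna" counts any cDNA detection.
    """

    depth: int = 15_000
    ratio_threshold: float = 1.0
    phantom_prevalence: float = 0.05
    resample_seed: int = 0
    prevalence_mode: str = "phantom"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.ratio_threshold < 0:
            raise ValueError("ratio_threshold must be >= 0")
        if not 0.0 <= self.phantom_prevalence <= 1.0:
            raise ValueError("phantom_prevalence must be in [0, 1]")
        if self.prevalence_mode not in ("phantom", "cdna"):
            raise ValueError("prevalence_mode must be 'phantom' or 'cdna'")


@dataclass(frozen=True)
class ActivityTable:
    """Per-cell states plus the DNA counts masked to active cells."""

    states: pd.DataFrame        # sample x taxon, State codes (int8)
    active_counts: CountTable   # DNA counts for active/rescued cells, else 0
    params: ActivityParams
    dna: CountTable = field(repr=False, default=None)
    cdna: CountTable = field(repr=False, default=None)

    def state_mask(self, state: State) -> pd.DataFrame:
        return self.states == int(state)


def rarefy(
    table: CountTable,
    depth: int,
    seed: int = 0,
    dropped_log: list[str] | None = None,
) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained row is a uniform draw from the sample's reads (multivariate
    hypergeometric), so row sums equal ``depth`` exactly and expected
    relative abundances are preserved.  Samples with fewer than ``depth``
    total reads are dropped (listed in ``dropped_log`` if given).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums.index[sums >= depth]
    if dropped_log is not None:
        dropped_log.extend(
            f"{sid} dropped: {sums[sid]} reads < depth {depth}"
            for sid in sums.index if sums[sid] < depth
        )
    if len(keep) == 0:
        raise ValueError(f"all samples have fewer than {depth} reads")
    out = {}
    for sid in keep:
        row = table.data.loc[sid].to_numpy()
        if row.sum() == depth:
            out[sid] = row
        else:
            out[sid] = rng.multivariate_hypergeometric(row, depth, method="marginals")
    return CountTable(pd.DataFrame.from_dict(out, orient="index", columns=table.taxon_ids))


def classify_activity(assay: PairedAssay, params: ActivityParams | None = None) -> ActivityTable:
    """Classify every sample x taxon cell of an aligned paired assay.

    See the module docstring for the rule set.  The assay's components must
    already be rarefied to a common depth; this function does not resample.
    """
    params = params or ActivityParams()
    dna = assay.dna.data
    cdna = assay.cdna.data
    d = dna.to_numpy().astype(float)
    c = cdna.to_numpy().astype(float)
    n_samples = d.shape[0]

    phantom_cell = (d == 0) & (c > 0)
    if params.prevalence_mode == "phantom":
        prevalence = phantom_cell.sum(axis=0) / n_samples
    else:
        prevalence = (c > 0).sum(axis=0) / n_samples
    rescued_taxon = prevalence > params.phantom_prevalence

    states = np.full(d.shape, int(State.UNDETECTED), dtype=np.int8)
    detected_dna = d > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(detected_dna, c / np.where(detected_dna, d, 1.0), np.nan)
    active = detected_dna & (c > 0) & (ratio >= params.ratio_threshold)
    inactive = detected_dna & ~active
    states[inactive] = int(State.INACTIVE)
    states[active] = int(State.ACTIVE)
    rescued = phantom_cell & rescued_taxon[np.newaxis, :]
    dropped = phantom_cell & ~rescued_taxon[np.newaxis, :]
    states[rescued] = int(State.PHANTOM_RESCUED)
    states[dropped] = int(State.PHANTOM_DROPPED)

    counts = np.where(active, d, 0.0)
    counts[rescued] = 1.0
    active_counts = CountTable(
        pd.DataFrame(counts.astype(np.int64), index=dna.index, columns=dna.columns)
    )
    state_df = pd.DataFrame(states, index=dna.index, columns=dna.columns)
    return ActivityTable(
        states=state_df, active_counts=active_counts, params=params,
        dna=assay.dna, cdna=assay.cdna,
    )


def activity_summary(at: ActivityTable) -> pd.DataFrame:
    """Per-sample tallies: percent of DNA-observed taxa active, reads, states.

    percent_active uses the DNA-observed taxa of the sample (DNA > 0) as the
    denominator; samples observing no taxa report NaN.
    """
    states = at.states.to_numpy()
    observed = (at.dna.data.to_numpy() > 0).sum(axis=1)
    active_like = ((states == int(State.ACTIVE))).sum(axis=1)
    rows = {
        "n_observed": observed,
        "n_active": active_like,
        "percent_active": np.where(observed > 0, 100.0 * active_like / np.maximum(observed, 1), np.nan),
        "active_reads": at.active_counts.data.sum(axis=1).to_numpy(),
    }
    for st in State:
        rows[f"n_{st.name.lower()}"] = (states == int(st)).sum(axis=1)
    return pd.DataFrame(rows, index=at.states.index)


def heatmap_code_and_standardize(
    at: ActivityTable,
    taxa_subset: list[str],
    warn: list[str] | None = None,
) -> pd.DataFrame:
    """Four-state abundance coding followed by per-taxon maximum standardization.

    Coding per cell: DNA=0 & cDNA=0 -> NaN (never detected); DNA>0 & cDNA=0
    -> 0 (present but not active); DNA>0 & cDNA>0 -> the DNA count;
    DNA=0 & cDNA>0 (phantom) -> 1.  Each taxon's non-missing values are then
    divided by that taxon's maximum; all-zero taxa stay at 0, all-missing
    taxa stay NaN (with a warning).
    """
    if not taxa_subset:
        raise ValueError("taxa_subset must be non-empty")
    missing = set(taxa_subset) - set(at.states.columns)
    if missing:
        raise ValueError(f"taxa not in activity table: {sorted(missing)}")
    d = at.dna.data[taxa_subset].to_numpy().astype(float)
    c = at.cdna.data[taxa_subset].to_numpy().astype(float)
    coded = np.where((d > 0) & (c > 0), d, 0.0)
    coded[(d == 0) & (c > 0)] = 1.0
    coded[(d == 0) & (c == 0)] = np.nan
    with np.errstate(invalid="ignore"):
        col_max = np.nanmax(np.where(np.isnan(coded), -np.inf, coded), axis=0)
    out = coded.copy()
    for j, taxon in enumerate(taxa_subset):
        if not np.isfinite(col_max[j]):
            if warn is not None:
                warn.append(f"taxon {taxon} has no detections; left as missing")
            continue
        if col_max[j] > 0:
            out[:, j] = coded[:, j] / col_max[j]
    return pd.DataFrame(out, index=at.states.index, columns=taxa_subset)
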