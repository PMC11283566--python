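"""Prevalence-based reagent-contaminant screening with negative controls.

Reagent contaminants ride along in every extraction, so they are detected in
a larger fraction of negative-control libraries than of true samples.  Each
taxon's presence/absence (count > 0, no normalization) is cross-tabulated
against control/sample status and scored with a one-sided Fisher exact test
for over-representation in controls; a taxon is flagged when the test is
significant at ``alpha`` AND its control prevalence exceeds its sample
prevalence.  Organelle lineages (mitochondria, chloroplast) are removed by
taxonomy pattern irrespective of the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact

from .core_io import CountTable

__all__ = [
    "ContaminantReport",
    "prevalence_contaminant_test",
    "remove_contaminants",
    "organelle_taxa",
]

ORGANELLE_PATTERNS = ("Mitochondria", "Chloroplast")


@dataclass(frozen=True)
class ContaminantReport:
    taxon_id: str
    prevalence_in_controls: float
    prevalence_in_samples: float
    p_value: float
    flagged: bool


def prevalence_contaminant_test(
    table: CountTable,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
) -> list[ContaminantReport]:
    """Score every taxon for contaminant-like prevalence.

    ``metadata`` must carry a boolean ``is_negative_control`` column indexed
    by sample_id and covering every sample in ``table``.
    """
    is_ctrl = metadata.loc[table.sample_ids, "is_negative_control"].astype(bool)
    n_ctrl = int(is_ctrl.sum())
    n_samp = int((~is_ctrl).sum())
    if n_ctrl == 0:
        raise ValueError(
            "no negative controls in metadata; skip decontamination explicitly "
            "rather than running the prevalence test without controls"
        )
    if n_samp == 0:
        raise ValueError("no true samples present")

    present = table.data > 0
    ctrl_hits = present.loc[is_ctrl.values].sum(axis=0)
    samp_hits = present.loc[(~is_ctrl).values].sum(axis=0)

    reports = []
    for taxon in table.taxon_ids:
        a = int(ctrl_hits[taxon])
        b = int(samp_hits[taxon])
        prev_c = a / n_ctrl
        prev_s = b / n_samp
        # one-sided: detections concentrated in controls
        _, p = fisher_exact(
            [[a, n_ctrl - a], [b, n_samp - b]], alternative="greater"
        )
        reports.append(ContaminantReport(
            taxon_id=taxon,
            prevalence_in_controls=prev_c,
            prevalence_in_samples=prev_s,
            p_value=float(p),
            flagged=bool(p < alpha and prev_c > prev_s),
        ))
    return reports


def organelle_taxa(taxonomy: pd.DataFrame, patterns=ORGANELLE_PATTERNS) -> set[str]:
    """Taxa whose lineage matches any organelle pattern (case-insensitive)."""
    joined = taxonomy.astype(str).apply(";".join, axis=1).str.lower()
    hits: set[str] = set()
    for pat in patterns:
        hits |= set(joined.index[joined.str.contains(pat.lower())])
    return hits


def remove_contaminants(
    table: CountTable,
    reports: list[ContaminantReport],
    taxonomy: pd.DataFrame | None = None,
    removal_log: list[str] | None = None,
) -> CountTable:
    """Drop flagged taxa (and organelle lineages, if a taxonomy is given)."""
    flagged = {r.taxon_id for r in reports if r.flagged}
    unknown = flagged - set(table.taxon_ids)
    if unknown:
        raise ValueError(f"report names taxa absent from the table: {sorted(unknown)}")
    to_drop = set(flagged)
    if taxonomy is not None:
        to_drop |= organelle_taxa(taxonomy) & set(table.taxon_ids)
    if removal_log is not None:
        removal_log.extend(
            f"removed {t} ({'contaminant' if t in flagged else 'organelle'})"
            for t in sorted(to_drop)
        )
    if not to_drop:
        return table
    return table.drop_taxa(to_drop)
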