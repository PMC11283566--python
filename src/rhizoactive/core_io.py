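"""Domain types and table I/O for paired 16S rRNA / rRNA gene surveys.

The central objects are :class:`CountTable` (a sample x taxon matrix of
non-negative integer sequence counts), sample metadata describing the
factorial design (crop-legacy soil, planted/unplanted, drought regime, day,
replicate, negative-control flag), and :class:`PairedAssay`, which aligns a
DNA (16S rRNA gene) table with its cDNA (16S rRNA) partner over shared
samples and a unioned taxon universe.  Everything downstream — contaminant
screening, rarefaction, activity classification, ecology statistics —
consumes these types.

Tables are exchanged as plain TSV (first row/column hold labels) with an
optional minimal BIOM 2.1 (HDF5) dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "PairedAssay",
    "MoistureRecord",
    "CountTableError",
    "MetadataError",
    "PairingError",
    "read_count_table",
    "write_count_table",
    "read_biom",
    "write_biom",
    "read_metadata",
    "validate_metadata",
    "read_taxonomy",
    "pair_assays",
    "gravimetric_moisture",
]

CROPS = frozenset({"bean", "switchgrass"})
PLANTED = frozenset({"planted", "unplanted"})
DROUGHT = frozenset({"pre-drought", "drought", "watered"})
METADATA_FACTORS = ("crop", "planted", "drought", "day", "replicate")

DNA_SUFFIX = "__DNA"
CDNA_SUFFIX = "__cDNA"


class CountTableError(ValueError):
    """Structural problem in a count table (duplicates, negatives, non-integers)."""


class MetadataError(ValueError):
    """Sample metadata violates the controlled vocabulary or design invariants."""


class PairingError(ValueError):
    """DNA and cDNA tables cannot be paired unambiguously."""


@dataclass(frozen=True)
class CountTable:
    """A sample x taxon matrix of non-negative integer sequence counts.

    ``data`` rows are samples, columns are taxa; both axes carry unique,
    order-preserving string labels.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise CountTableError(f"duplicate sample identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise CountTableError(f"duplicate taxon identifiers: {dups}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0) or np.any(~np.isfinite(arr.astype(float))):
                bad = np.argwhere(frac != 0)
                r, c = bad[0]
                raise CountTableError(
                    f"non-integer count {arr[r, c]!r} at sample "
                    f"{df.index[r]!r}, taxon {df.columns[c]!r}"
                )
        if arr.size and (arr.astype(np.int64) < 0).any():
            bad = np.argwhere(arr.astype(np.int64) < 0)
            r, c = bad[0]
            raise CountTableError(
                f"negative count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        object.__setattr__(
            self,
            "data",
            df.astype(np.int64).rename_axis(index="sample_id", columns="taxon_id"),
        )

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def drop_taxa(self, taxa: Iterable[str]) -> "CountTable":
        taxa = set(taxa)
        keep = [t for t in self.taxon_ids if t not in taxa]
        return CountTable(self.data[keep])

    def select_samples(self, samples: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[list(samples)])

    def relative_abundance(self) -> pd.DataFrame:
        sums = self.data.sum(axis=1).replace(0, 1)
        return self.data.div(sums, axis=0)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)


@dataclass(frozen=True)
class PairedAssay:
    """Aligned DNA/cDNA count tables: identical sample order, unioned taxa."""

    dna: CountTable
    cdna: CountTable
    pair_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dna.sample_ids != self.cdna.sample_ids:
            raise PairingError("DNA and cDNA tables must share identical sample order")
        if self.dna.taxon_ids != self.cdna.taxon_ids:
            raise PairingError("DNA and cDNA tables must share an identical taxon universe")

    @property
    def sample_ids(self) -> list[str]:
        return self.dna.sample_ids

    @property
    def taxon_ids(self) -> list[str]:
        return self.dna.taxon_ids


@dataclass(frozen=True)
class MoistureRecord:
    """Wet and oven-dry soil masses (g) for gravimetric moisture."""

    mass_wet: float
    mass_dry: float


def gravimetric_moisture(rec: MoistureRecord) -> float:
    """Percent water mass relative to dry soil mass.

    ``100 * (mass_wet - mass_dry) / mass_dry``; mass_wet < mass_dry is
    physically suspicious but tolerated (returns a negative percentage).
    """
    if rec.mass_dry <= 0:
        raise ValueError(f"mass_dry must be positive, got {rec.mass_dry}")
    return 100.0 * (rec.mass_wet - rec.mass_dry) / rec.mass_dry


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path,
    orientation: str = "auto",
    known_sample_ids: Iterable[str] | None = None,
) -> CountTable:
    """Read a TSV count table, resolving whether rows are samples or taxa.

    orientation: ``"samples_rows"``, ``"taxa_rows"``, or ``"auto"``.  Auto
    mode needs ``known_sample_ids`` (e.g. from metadata): whichever axis
    overlaps them more is taken as the sample axis; ties raise, because a
    silently transposed table is the classic amplicon-pipeline bug.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "auto":
        if known_sample_ids is None:
            raise ValueError("orientation='auto' requires known_sample_ids")
        ids = set(known_sample_ids)
        row_hits = len(ids & set(df.index))
        col_hits = len(ids & set(df.columns))
        if row_hits == col_hits:
            raise CountTableError(
                "cannot auto-detect orientation (equal sample-id overlap on both "
                "axes); pass orientation='samples_rows' or 'taxa_rows'"
            )
        orientation = "samples_rows" if row_hits > col_hits else "taxa_rows"
    if orientation == "taxa_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            sample = df.index[vals.isna()][0]
            raise CountTableError(
                f"non-numeric count at sample {sample!r}, taxon {col!r}"
            )
        df[col] = vals
    return CountTable(df)


def write_count_table(
    table: CountTable, path: str | Path, orientation: str = "samples_rows"
) -> None:
    df = table.data if orientation == "samples_rows" else table.data.T
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Minimal BIOM 2.1 (HDF5) dialect
# ---------------------------------------------------------------------------

def write_biom(table: CountTable, path: str | Path) -> None:
    """Write a minimal BIOM 2.1 HDF5 file (CSR observation-major layout)."""
    import h5py
    from scipy import sparse

    mat = sparse.csr_matrix(table.counts.T)  # observations (taxa) x samples
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "No Table ID"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = "http://biom-format.org"
        h5.attrs["format-version"] = [2, 1]
        h5.attrs["generated-by"] = "rhizoactive"
        h5.attrs["shape"] = mat.shape
        h5.attrs["nnz"] = mat.nnz
        obs = h5.create_group("observation")
        obs.create_dataset("ids", data=np.array(table.taxon_ids, dtype="S"))
        om = obs.create_group("matrix")
        om.create_dataset("data", data=mat.data.astype(np.float64))
        om.create_dataset("indices", data=mat.indices.astype(np.int32))
        om.create_dataset("indptr", data=mat.indptr.astype(np.int32))
        smp = h5.create_group("sample")
        smp.create_dataset("ids", data=np.array(table.sample_ids, dtype="S"))


def read_biom(path: str | Path) -> CountTable:
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as h5:
        taxa = [t.decode() for t in h5["observation/ids"][:]]
        samples = [s.decode() for s in h5["sample/ids"][:]]
        data = h5["observation/matrix/data"][:]
        indices = h5["observation/matrix/indices"][:]
        indptr = h5["observation/matrix/indptr"][:]
    mat = sparse.csr_matrix((data, indices, indptr), shape=(len(taxa), len(samples)))
    df = pd.DataFrame(mat.toarray().T, index=samples, columns=taxa)
    return CountTable(df)


# ---------------------------------------------------------------------------
# Metadata & taxonomy
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Enforce the factorial-design vocabulary and invariants.

    Non-control samples must carry every factor level; drought level
    ``pre-drought`` must coincide exactly with day 0.
    """
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        dups = sorted(meta.index[meta.index.duplicated()].unique())
        raise MetadataError(f"duplicate sample_id in metadata: {dups}")
    if "is_negative_control" not in meta.columns:
        meta["is_negative_control"] = False
    meta["is_negative_control"] = meta["is_negative_control"].astype(bool)
    real = meta.loc[~meta["is_negative_control"]]
    for col in METADATA_FACTORS:
        if col not in meta.columns:
            raise MetadataError(f"metadata missing required column {col!r}")
        if real[col].isna().any():
            bad = sorted(real.index[real[col].isna()])
            raise MetadataError(f"missing {col!r} for non-control samples {bad}")
    for col, vocab in (("crop", CROPS), ("planted", PLANTED), ("drought", DROUGHT)):
        extra = set(real[col].unique()) - vocab
        if extra:
            raise MetadataError(f"unknown {col} levels {sorted(extra)}; allowed {sorted(vocab)}")
    day = real["day"].astype(int)
    pre = real["drought"] == "pre-drought"
    if not (pre == (day == 0)).all():
        bad = sorted(real.index[pre != (day == 0)])
        raise MetadataError(
            f"drought='pre-drought' must coincide with day=0; violated by {bad}"
        )
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"))


def read_taxonomy(path: str | Path, lineage_col: str = "lineage") -> pd.DataFrame:
    """Read a taxonomy TSV with semicolon-delimited 7-rank lineage strings.

    Returns a frame indexed by taxon_id with columns domain..genus (species
    kept if present); absent ranks become 'unclassified'.
    """
    ranks = ["domain", "phylum", "class", "order", "family", "genus", "species"]
    raw = pd.read_csv(path, sep="\t")
    idx_col = raw.columns[0]
    raw = raw.set_index(idx_col)
    raw.index = raw.index.astype(str)
    if lineage_col not in raw.columns:
        raise ValueError(f"taxonomy file lacks a {lineage_col!r} column")
    parsed = {}
    for tid, lin in raw[lineage_col].items():
        parts = [re.sub(r"^[a-z]__", "", p.strip()) for p in str(lin).split(";")]
        parts = [p if p else "unclassified" for p in parts]
        parts += ["unclassified"] * (len(ranks) - len(parts))
        parsed[tid] = parts[: len(ranks)]
    out = pd.DataFrame.from_dict(parsed, orient="index", columns=ranks)
    out.index.name = "taxon_id"
    if "confidence" in raw.columns:
        out["confidence"] = raw["confidence"].astype(float)
    return out


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def _strip_assay_suffix(sid: str) -> tuple[str, str | None]:
    if sid.endswith(DNA_SUFFIX):
        return sid[: -len(DNA_SUFFIX)], "dna"
    if sid.endswith(CDNA_SUFFIX):
        return sid[: -len(CDNA_SUFFIX)], "cdna"
    return sid, None


def pair_assays(
    dna: CountTable,
    cdna: CountTable,
    pair_map: Mapping[str, tuple[str, str]] | None = None,
    warn: list[str] | None = None,
) -> PairedAssay:
    """Align a DNA and a cDNA table into a :class:`PairedAssay`.

    Pairing keys, in priority order: an explicit ``pair_map`` of
    ``{pair_id: (dna_sample, cdna_sample)}``; the ``<id>__DNA``/``<id>__cDNA``
    suffix convention; otherwise identical sample ids in both tables.
    Samples lacking a partner are dropped (recorded in ``warn`` if given);
    taxon universes are unioned with zero fill.  Duplicate pair keys raise.
    """
    if warn is None:
        warn = []
    if pair_map is None:
        pair_map = {}
        for table, kind in ((dna, "dna"), (cdna, "cdna")):
            for sid in table.sample_ids:
                base, suffix_kind = _strip_assay_suffix(sid)
                if suffix_kind is not None and suffix_kind != kind:
                    raise PairingError(
                        f"sample {sid!r} carries the wrong nucleic-acid suffix "
                        f"for the {kind} table"
                    )
                pair_map.setdefault(base, [None, None])
                slot = 0 if kind == "dna" else 1
                if pair_map[base][slot] is not None:
                    raise PairingError(f"duplicate {kind} record for pair key {base!r}")
                pair_map[base][slot] = sid
        pair_map = {k: tuple(v) for k, v in pair_map.items()}
    else:
        seen_d, seen_c = set(), set()
        for key, (d, c) in pair_map.items():
            if d in seen_d or c in seen_c:
                raise PairingError(f"duplicate sample in pair_map at key {key!r}")
            seen_d.add(d)
            seen_c.add(c)

    complete: dict[str, tuple[str, str]] = {}
    for key, (d, c) in pair_map.items():
        if d in set(dna.sample_ids) and c in set(cdna.sample_ids):
            complete[key] = (d, c)
        else:
            warn.append(f"sample pair {key!r} dropped: missing partner")
    if not complete:
        raise PairingError("no sample pairs shared between DNA and cDNA tables")

    keys = sorted(complete)
    taxa = sorted(set(dna.taxon_ids) | set(cdna.taxon_ids))
    dna_df = dna.data.reindex(
        index=[complete[k][0] for k in keys], columns=taxa, fill_value=0
    )
    cdna_df = cdna.data.reindex(
        index=[complete[k][1] for k in keys], columns=taxa, fill_value=0
    )
    dna_df.index = keys
    cdna_df.index = keys
    return PairedAssay(
        dna=CountTable(dna_df), cdna=CountTable(cdna_df), pair_map=complete
    )
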