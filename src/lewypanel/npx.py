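"""NPX data model and I/O for proximity-extension-assay proteomics.

The central container is :class:`NPXMatrix`: a samples x assays matrix of
log2-scale NPX values, with one lower limit of detection (LOD) per assay and
one batch (measurement round) label per sample.  Replicate assays of the same
protein on different panels are kept as distinct columns; the per-assay
``protein`` and ``panel`` annotations preserve the mapping.

Long-format files use one row per (sample, assay) with columns
``sample_id, assay_id, panel, npx, lod, batch`` (aliases configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lewypanel.errors import DataError, FormatError, ParseError

REQUIRED_COLUMNS = ("sample_id", "assay_id", "panel", "npx", "lod", "batch")

#: default separator used when composing a unique column key for a protein
#: measured on several panels
_KEY_SEP = "_"


@dataclass
class NPXMatrix:
    """Samples x assays matrix of log2 NPX values with per-assay LOD.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per assay key.
        Missing measurements are NaN.
    lod
        Per-assay LOD (log2 NPX units), indexed like ``values.columns``.
    batch
        Per-sample batch / measurement-round label, indexed like
        ``values.index``.
    assay_meta
        Optional per-assay annotation with columns ``protein`` and ``panel``.
        Defaults to protein == assay key, panel == "NA".
    """

    values: pd.DataFrame
    lod: pd.Series
    batch: pd.Series
    assay_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        if self.values.index.has_duplicates:
            raise DataError("duplicate sample_ids in NPX matrix")
        if self.values.columns.has_duplicates:
            raise DataError("duplicate assay_ids in NPX matrix")
        self.lod = pd.Series(self.lod, dtype=float).reindex(self.values.columns)
        if self.lod.isna().any() or not np.isfinite(self.lod.to_numpy()).all():
            bad = self.lod.index[~np.isfinite(self.lod.to_numpy())].tolist()
            raise DataError(f"every assay needs one finite LOD; offending: {bad}")
        self.batch = pd.Series(self.batch).reindex(self.values.index)
        if self.batch.isna().any():
            bad = self.batch.index[self.batch.isna()].tolist()
            raise DataError(f"missing batch label for samples: {bad}")
        if self.assay_meta is None:
            self.assay_meta = pd.DataFrame(
                {"protein": self.values.columns, "panel": "NA"},
                index=self.values.columns,
            )
        else:
            self.assay_meta = self.assay_meta.reindex(self.values.columns)

    # -- basic views -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "NPXMatrix":
        """Row subset preserving LOD/assay annotations."""
        return NPXMatrix(
            values=self.values.loc[list(sample_ids)],
            lod=self.lod.copy(),
            batch=self.batch.loc[list(sample_ids)],
            assay_meta=self.assay_meta.copy(),
        )

    def subset_assays(self, assay_ids: Sequence[str]) -> "NPXMatrix":
        return NPXMatrix(
            values=self.values.loc[:, list(assay_ids)],
            lod=self.lod.loc[list(assay_ids)],
            batch=self.batch.copy(),
            assay_meta=self.assay_meta.loc[list(assay_ids)],
        )

    def replicate_map(self) -> dict[str, list[str]]:
        """Proteins measured by more than one assay -> their assay keys."""
        groups = self.assay_meta.groupby("protein").groups
        return {p: list(keys) for p, keys in groups.items() if len(keys) > 1}


@dataclass
class SampleMetadata:
    """Per-sample clinical annotation.

    ``table`` is indexed by sample id and must contain ``diagnosis``,
    ``age`` and ``sex``; any further columns (cohort, medication,
    AD biomarkers, MMSE, stages...) ride along untouched.
    """

    table: pd.DataFrame

    REQUIRED = ("diagnosis", "age", "sex")

    def __post_init__(self) -> None:
        self.table = pd.DataFrame(self.table)
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample metadata missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise DataError("duplicate sample_ids in metadata")
        if self.table["diagnosis"].isna().any():
            bad = self.table.index[self.table["diagnosis"].isna()].tolist()
            raise DataError(f"diagnosis missing for samples: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def diagnosis(self) -> pd.Series:
        return self.table["diagnosis"]

    def aligned_to(self, m: NPXMatrix) -> pd.DataFrame:
        """Metadata rows in matrix order; errors if any sample is missing."""
        absent = [s for s in m.sample_ids if s not in self.table.index]
        if absent:
            raise DataError(f"metadata lacks samples present in matrix: {absent[:5]}")
        return self.table.loc[m.sample_ids]


# ---------------------------------------------------------------------------
# long-format I/O
# ---------------------------------------------------------------------------

def _resolve_columns(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename alias columns to canonical names using ``dialect``."""
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"NPX long file missing required columns: {missing}")
    return df


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_npx_long(path, dialect: Mapping[str, str] | None = None) -> NPXMatrix:
    """Read a long-format NPX file (one row per sample/assay measurement).

    Duplicate (sample, assay, panel) rows are an error; absent combinations
    become missing values in the pivoted matrix.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df = _resolve_columns(df, dialect)
    npx = pd.to_numeric(df["npx"], errors="coerce")
    bad = npx.isna() & df["npx"].notna() & (df["npx"].str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric NPX value {df['npx'].iloc[row]!r} at data row {row}", row=row
        )
    lod = pd.to_numeric(df["lod"], errors="coerce")
    if lod.isna().any():
        row = int(np.flatnonzero(lod.isna().to_numpy())[0])
        raise ParseError(f"non-numeric LOD at data row {row}", row=row)
    df = df.assign(npx=npx, lod=lod)

    dup = df.duplicated(subset=["sample_id", "assay_id", "panel"], keep=False)
    if dup.any():
        first = df.loc[dup, ["sample_id", "assay_id", "panel"]].iloc[0]
        raise FormatError(
            "duplicated (sample, assay) row: "
            f"({first['sample_id']}, {first['assay_id']}_{first['panel']})"
        )

    # a protein measured on several panels gets a composite column key
    multi = df.groupby("assay_id")["panel"].nunique() > 1
    multi_proteins = set(multi.index[multi])
    key = np.where(
        df["assay_id"].isin(multi_proteins),
        df["assay_id"] + _KEY_SEP + df["panel"],
        df["assay_id"],
    )
    df = df.assign(_key=key)

    lod_per_assay = df.groupby("_key")["lod"].nunique()
    if (lod_per_assay > 1).any():
        bad_assays = lod_per_assay.index[lod_per_assay > 1].tolist()
        raise FormatError(f"conflicting LOD values for assays: {bad_assays}")
    batch_per_sample = df.groupby("sample_id")["batch"].nunique()
    if (batch_per_sample > 1).any():
        bad_samples = batch_per_sample.index[batch_per_sample > 1].tolist()
        raise FormatError(f"conflicting batch labels for samples: {bad_samples}")

    values = df.pivot(index="sample_id", columns="_key", values="npx")
    # preserve first-appearance order of samples and assays
    values = values.reindex(
        index=pd.unique(df["sample_id"]), columns=pd.unique(df["_key"])
    )
    lod_s = df.groupby("_key")["lod"].first().reindex(values.columns)
    batch_s = df.groupby("sample_id")["batch"].first().reindex(values.index)
    meta = (
        df.groupby("_key")[["assay_id", "panel"]]
        .first()
        .rename(columns={"assay_id": "protein"})
        .reindex(values.columns)
    )
    return NPXMatrix(values=values, lod=lod_s, batch=batch_s, assay_meta=meta)


def write_npx_long(m: NPXMatrix, path) -> None:
    """Write the matrix back to the long dialect read by :func:`read_npx_long`."""
    long = (
        m.values.reset_index(names="sample_id")
        .melt(id_vars="sample_id", var_name="_key", value_name="npx")
        .dropna(subset=["npx"])
    )
    long["assay_id"] = long["_key"].map(m.assay_meta["protein"])
    long["panel"] = long["_key"].map(m.assay_meta["panel"])
    long["lod"] = long["_key"].map(m.lod)
    long["batch"] = long["sample_id"].map(m.batch)
    long = long[["sample_id", "assay_id", "panel", "npx", "lod", "batch"]]
    long.to_csv(path, sep=_sep_for(path), index=False)


def read_sample_metadata(path, dialect: Mapping[str, str] | None = None) -> SampleMetadata:
    df = pd.read_csv(path, sep=_sep_for(path))
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    if "sample_id" not in df.columns:
        raise FormatError("metadata file missing 'sample_id' column")
    return SampleMetadata(df.set_index("sample_id"))


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.table.reset_index(names="sample_id").to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# QC operations
# ---------------------------------------------------------------------------

def filter_by_detectability(
    m: NPXMatrix, min_frac: float = 0.85
) -> tuple[NPXMatrix, list[str]]:
    """Drop assays detected (strictly above their LOD) in < ``min_frac`` of samples.

    The fraction is taken over non-missing measurements.  Values at exactly
    the LOD count as not detected.  Retained below-LOD values are kept raw.
    """
    if not 0 < min_frac <= 1:
        raise DataError(f"min_frac must be in (0, 1], got {min_frac}")
    if m.n_samples == 0 or m.n_assays == 0:
        raise DataError("cannot filter an empty NPX matrix")
    vals = m.values.to_numpy()
    above = vals > m.lod.to_numpy()[None, :]
    measured = ~np.isnan(vals)
    with np.errstate(invalid="ignore"):
        frac = np.where(
            measured.sum(axis=0) > 0,
            (above & measured).sum(axis=0) / np.maximum(measured.sum(axis=0), 1),
            0.0,
        )
    keep = frac >= min_frac
    dropped = [a for a, k in zip(m.assay_ids, keep) if not k]
    kept_ids = [a for a, k in zip(m.assay_ids, keep) if k]
    return m.subset_assays(kept_ids), dropped


def _bridge_pairs(
    m: NPXMatrix,
    bridge_sample_ids: Iterable[str] | Mapping[str, Mapping[str, str]],
) -> dict[str, dict[str, str]]:
    """Normalize the bridge spec to {base_id: {batch: row_sample_id}}.

    A plain sequence of base ids assumes the generator's ``base__batch``
    row-naming convention; a mapping is taken verbatim.
    """
    if isinstance(bridge_sample_ids, Mapping):
        return {b: dict(v) for b, v in bridge_sample_ids.items()}
    out: dict[str, dict[str, str]] = {}
    index = set(m.sample_ids)
    batches = pd.unique(m.batch)
    for base in bridge_sample_ids:
        rows = {}
        for b in batches:
            rid = f"{base}__{b}"
            if rid in index:
                rows[str(b)] = rid
        if len(rows) >= 2:
            out[str(base)] = rows
    if not out:
        raise DataError("no bridge samples found in >=2 batches")
    return out


def bridge_normalize(
    m: NPXMatrix,
    bridge_sample_ids: Iterable[str] | Mapping[str, Mapping[str, str]],
    reference_batch: str,
) -> NPXMatrix:
    """Reference-sample normalization across measurement rounds.

    For every non-reference batch and assay, the median over bridge samples
    of (batch value - reference value) is subtracted from all measurements
    of that batch.  The reference batch is returned unchanged.
    """
    batches = list(pd.unique(m.batch))
    if reference_batch not in batches:
        raise DataError(f"reference batch {reference_batch!r} not present")
    if len(batches) == 1:
        return NPXMatrix(
            m.values.copy(), m.lod.copy(), m.batch.copy(), m.assay_meta.copy()
        )
    pairs = _bridge_pairs(m, bridge_sample_ids)
    values = m.values.copy()
    for b in batches:
        if b == reference_batch:
            continue
        diffs = []
        for rows in pairs.values():
            if str(b) in rows and str(reference_batch) in rows:
                diffs.append(
                    m.values.loc[rows[str(b)]].to_numpy()
                    - m.values.loc[rows[str(reference_batch)]].to_numpy()
                )
        if not diffs:
            raise DataError(
                f"no shared bridge samples between batch {b!r} and "
                f"reference {reference_batch!r}"
            )
        offset = np.nanmedian(np.vstack(diffs), axis=0)
        rows_b = m.batch.index[m.batch == b]
        values.loc[rows_b] = values.loc[rows_b].to_numpy() - offset[None, :]
    return NPXMatrix(values, m.lod.copy(), m.batch.copy(), m.assay_meta.copy())


def replicate_correlation(
    m: NPXMatrix, replicate_map: Mapping[str, Sequence[str]] | None = None
) -> pd.DataFrame:
    """Spearman correlation for each pair of replicate assays of one protein.

    Pairs with fewer than 3 complete observations report a missing r.
    Returns a table with columns protein, assay_a, assay_b, r, n.
    """
    if replicate_map is None:
        replicate_map = m.replicate_map()
    records = []
    for protein, assays in replicate_map.items():
        assays = [a for a in assays if a in m.values.columns]
        if len(assays) < 2:
            raise DataError(f"protein {protein!r} has fewer than 2 mapped assays")
        for i in range(len(assays)):
            for j in range(i + 1, len(assays)):
                a, b = assays[i], assays[j]
                pair = m.values[[a, b]].dropna()
                if len(pair) < 3:
                    r = np.nan
                else:
                    r = stats.spearmanr(pair[a], pair[b]).statistic
                records.append(
                    {"protein": protein, "assay_a": a, "assay_b": b,
                     "r": r, "n": len(pair)}
                )
    return pd.DataFrame.from_records(
        records, columns=["protein", "assay_a", "assay_b", "r", "n"]
    )
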