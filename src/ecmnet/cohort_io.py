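"""Readers and writers for all tabular inputs and results.

This is the single place where file dialects are defined:

* abundance matrices: TSV, first column protein symbol, remaining columns
  samples, log2-normalized intensities, missing encoded as empty or ``NA``;
* clinical tables: CSV indexed by sample id, survival endpoints as paired
  ``<label>_time`` / ``<label>_event`` columns with labels restricted to
  OS / LRFS / MFS / DSS;
* gene sets: standard GMT (name, description, members);
* cell tracks: the CSV export shape of common Fiji tracking plugins
  (TRACK_ID, FRAME, POSITION_T, POSITION_X, POSITION_Y), times in minutes
  and positions in micrometres.

All writers emit deterministically ordered output so files are diffable,
and every reader/writer pair round-trips value-bearing fields exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ENDPOINT_LABELS = ("OS", "LRFS", "MFS", "DSS")

_NA_VALUES = ["", "NA", "NaN", "nan"]


class FormatError(ValueError):
    """Malformed input file (bad header, non-numeric cell, negative time...)."""


# ---------------------------------------------------------------------------
# Abundance matrix


@dataclass
class AbundanceMatrix:
    """Protein x sample matrix of log2-normalized intensities.

    Missing values are NaN; ids are unique and ordered.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup[:5]}")
        values = self.data.to_numpy()
        if values.size and np.isinf(values[~np.isnan(values)]).any():
            raise FormatError("abundance values must be finite where observed")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()


def as_frame(matrix) -> pd.DataFrame:
    """Accept an AbundanceMatrix or a bare proteins-x-samples DataFrame."""
    if isinstance(matrix, AbundanceMatrix):
        return matrix.data
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"expected AbundanceMatrix or DataFrame, got {type(matrix)!r}")


def read_abundance(path) -> AbundanceMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES,
                     keep_default_na=False, dtype=str)
    if df.index.name is None or df.shape[1] == 0:
        raise FormatError(f"{path}: expected a TSV with a protein column and >=1 sample")
    numeric = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str),
                           dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise FormatError(
                f"{path}: non-numeric abundance cell at protein {row!r}, sample {col!r}"
            )
        numeric[str(col)] = converted.to_numpy()
    return AbundanceMatrix(numeric)


def write_abundance(matrix, path) -> None:
    as_frame(matrix).to_csv(path, sep="\t", na_rep="NA", index_label="protein")


# ---------------------------------------------------------------------------
# Clinical table


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates plus survival endpoints.

    Endpoints are stored as paired ``<label>_time`` (months) and
    ``<label>_event`` (0/1) columns; only OS/LRFS/MFS/DSS labels are
    accepted.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids in clinical table")
        for label in self.endpoint_labels():
            t = self.data[f"{label}_time"]
            e = self.data[f"{label}_event"]
            tv = pd.to_numeric(t, errors="coerce")
            if (tv.dropna() < 0).any():
                raise FormatError(f"negative time in endpoint {label}")
            ev = pd.to_numeric(e, errors="coerce").dropna()
            if not ev.isin([0, 1]).all():
                raise FormatError(f"event flags for {label} must be 0/1")
        for col in self.data.columns:
            if col.endswith("_time") or col.endswith("_event"):
                label = col.rsplit("_", 1)[0]
                if label not in ENDPOINT_LABELS:
                    raise FormatError(
                        f"unknown survival endpoint label {label!r}; "
                        f"allowed: {ENDPOINT_LABELS}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def endpoint_labels(self) -> list[str]:
        return [
            lab for lab in ENDPOINT_LABELS
            if f"{lab}_time" in self.data.columns and f"{lab}_event" in self.data.columns
        ]

    def endpoint(self, label: str) -> pd.DataFrame:
        """(time, event) frame for one endpoint, rows with missing time dropped."""
        if label not in self.endpoint_labels():
            raise KeyError(f"endpoint {label!r} not present")
        out = self.data[[f"{label}_time", f"{label}_event"]].copy()
        out.columns = ["time", "event"]
        out = out.dropna()
        out["time"] = out["time"].astype(float)
        out["event"] = out["event"].astype(int)
        return out


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, index_col=0, na_values=_NA_VALUES, keep_default_na=False)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, na_rep="NA", index_label="sample_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self.sets[n] for n in names},
            {n: self.descriptions.get(n, "") for n in names},
        )


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, description, *genes = parts
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = genes
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


# ---------------------------------------------------------------------------
# Cell tracks


_TRACK_COLUMN_MAP = {
    "track_id": "track_id", "frame": "frame", "position_t": "t",
    "position_x": "x", "position_y": "y", "t": "t", "x": "x", "y": "y",
    "condition": "condition", "cell_line": "cell_line",
}


@dataclass
class TrackTable:
    """Time-ordered 2-D positions of tracked cells.

    Columns: track_id, frame, t (minutes), x, y (micrometres) and the
    optional grouping columns condition / cell_line.  Within a track,
    frames are strictly increasing.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"track_id", "frame", "t", "x", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"track table missing columns: {sorted(missing)}")
        df = self.data.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
        for col in ("t", "x", "y"):
            vals = df[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise FormatError(f"non-finite value in track column {col!r}")
        if (df["t"].to_numpy(dtype=float) < 0).any():
            raise FormatError("negative time in track table")
        frame_diff = df.groupby("track_id")["frame"].diff().dropna()
        if (frame_diff <= 0).any():
            raise FormatError("frames must be strictly increasing within a track")
        object.__setattr__(self, "data", df)

    @property
    def track_ids(self) -> list:
        return list(pd.unique(self.data["track_id"]))

    def __len__(self) -> int:
        return len(self.track_ids)

    def tracks(self):
        """Yield (track_id, frame-sorted sub-frame) pairs."""
        for tid, grp in self.data.groupby("track_id", sort=False):
            yield tid, grp


def read_tracks(path) -> TrackTable:
    raw = pd.read_csv(path, dtype=str, na_values=_NA_VALUES, keep_default_na=False)
    raw.columns = [c.strip().lower() for c in raw.columns]
    unknown = [c for c in raw.columns if c not in _TRACK_COLUMN_MAP]
    raw = raw.drop(columns=unknown)
    raw = raw.rename(columns=_TRACK_COLUMN_MAP)
    required = {"track_id", "frame", "t", "x", "y"}
    if not required <= set(raw.columns):
        raise FormatError(
            f"{path}: expected columns TRACK_ID, FRAME, POSITION_T, POSITION_X, POSITION_Y"
        )
    # Fiji exports carry extra non-numeric header rows below the header:
    # keep only rows whose FRAME parses as a number.
    numeric_frame = pd.to_numeric(raw["frame"], errors="coerce")
    raw = raw[numeric_frame.notna()].copy()
    for col in ("frame", "t", "x", "y"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            raise FormatError(f"{path}: non-numeric value in column {col!r}")
        raw[col] = converted
    raw["frame"] = raw["frame"].astype(int)
    return TrackTable(raw.reset_index(drop=True))


def write_tracks(table: TrackTable, path) -> None:
    df = table.data.rename(columns={
        "track_id": "TRACK_ID", "frame": "FRAME", "t": "POSITION_T",
        "x": "POSITION_X", "y": "POSITION_Y",
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result bundles


def write_results(report: dict, out_dir) -> list[Path]:
    """Write a {name: DataFrame | dict} bundle as TSV tables + one JSON summary.

    DataFrames become ``<name>.tsv``; everything JSON-serializable is merged
    into ``run_summary.json`` (keys sorted for diffability).  Returns the
    list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {}
    for name in sorted(report):
        value = report[name]
        if isinstance(value, AbundanceMatrix):
            value = value.data
        if isinstance(value, pd.DataFrame):
            target = out_dir / f"{name}.tsv"
            value.to_csv(target, sep="\t", na_rep="NA")
            written.append(target)
        else:
            summary[name] = value
    target = out_dir / "run_summary.json"
    with open(target, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    written.append(target)
    return written
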