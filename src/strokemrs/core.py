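"""Domain types and delimited-text I/O for single-voxel MRS cohorts.

A processed single-voxel spectrum is stored as a vector of real-part
intensities on a common chemical-shift (ppm) axis.  The axis runs from
4.5 ppm down to 0 ppm (NMR display order: index 0 is the left edge at
4.5 ppm) and is digitized with 1383 datapoints by default.

Cohorts are exchanged as plain delimited text: one table with one
spectrum per row (first column the spectrum id, remaining columns the
intensities, column headers carrying the ppm values) and one metadata
table keyed by spectrum id.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_N_POINTS",
    "PPM_MAX",
    "REGIONS",
    "PHASES",
    "CohortFormatError",
    "ValidationError",
    "SpectrumRecord",
    "Cohort",
    "FeatureEntry",
    "FeatureSet",
    "default_axis",
    "ppm_to_index",
    "read_cohort",
    "write_cohort",
]

DEFAULT_N_POINTS = 1383
PPM_MAX = 4.5

REGIONS = ("non_infarcted", "svz", "infarcted")
PHASES = ("healthy", "acute", "subacute")
HEMISPHERES = ("left", "right", "n/a")
SPLITS = ("train", "test", "unassigned")


class CohortFormatError(ValueError):
    """Raised when an on-disk cohort table violates the expected layout."""


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated."""


def default_axis(n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Chemical-shift axis: `n_points` evenly spaced values from 4.5 down to 0 ppm."""
    return np.linspace(PPM_MAX, 0.0, n_points)


def ppm_to_index(axis: np.ndarray, target: float) -> int:
    """Index of the datapoint nearest `target` ppm; exact ties go to the lower ppm.

    Raises ValueError if `target` lies outside the axis range.
    """
    axis = np.asarray(axis, dtype=float)
    lo, hi = float(axis.min()), float(axis.max())
    if not (lo <= target <= hi):
        raise ValueError(f"target {target} ppm outside axis range [{lo}, {hi}]")
    diffs = np.abs(axis - target)
    best = diffs.min()
    candidates = np.flatnonzero(diffs == best)
    # tie-break: lower ppm value among equally near datapoints
    return int(candidates[np.argmin(axis[candidates])])


@dataclass
class SpectrumRecord:
    """One processed spectrum with its acquisition metadata.

    `intensities` are in arbitrary units before normalization and in
    UL2CA units (percent of the contralateral Euclidean norm) after.
    """

    animal_id: str
    spectrum_id: str
    region: str
    phase: str
    label: str
    ppm_axis: np.ndarray
    intensities: np.ndarray
    hemisphere: str = "n/a"
    split: str = "unassigned"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.ppm_axis.shape != self.intensities.shape or self.ppm_axis.ndim != 1:
            raise ValidationError(
                f"{self.spectrum_id}: axis length {self.ppm_axis.shape} != "
                f"intensity length {self.intensities.shape}"
            )
        d = np.diff(self.ppm_axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError(f"{self.spectrum_id}: ppm axis not strictly monotone")
        if self.ppm_axis.min() < -1e-9 or self.ppm_axis.max() > PPM_MAX + 1e-9:
            raise ValidationError(f"{self.spectrum_id}: ppm values outside [0, {PPM_MAX}]")
        if self.region not in REGIONS:
            raise ValidationError(f"{self.spectrum_id}: unknown region {self.region!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"{self.spectrum_id}: unknown phase {self.phase!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"{self.spectrum_id}: unknown hemisphere {self.hemisphere!r}")
        if self.split not in SPLITS:
            raise ValidationError(f"{self.spectrum_id}: unknown split {self.split!r}")

    @property
    def n_points(self) -> int:
        return self.intensities.size

    def copy_with(self, **kw) -> "SpectrumRecord":
        return replace(self, **kw)


@dataclass
class Cohort:
    """A set of spectra with class labels and contralateral reference pairing.

    `contralateral_map` maps each spectrum id to the id of the same
    animal's non-infarcted reference spectrum (possibly itself).
    """

    records: list
    class_labels: Sequence[str]
    contralateral_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.class_labels)
        ids = [r.spectrum_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate spectrum ids in cohort")
        for r in self.records:
            if r.label not in labels:
                raise ValidationError(
                    f"{r.spectrum_id}: class {r.label!r} not in {sorted(labels)}"
                )
        known = set(ids)
        for sid, ref in self.contralateral_map.items():
            if sid not in known or ref not in known:
                raise ValidationError(f"contralateral_map entry {sid!r}->{ref!r} unknown")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, spectrum_id: str) -> SpectrumRecord:
        for r in self.records:
            if r.spectrum_id == spectrum_id:
                return r
        raise KeyError(spectrum_id)

    def subset(self, split: str) -> "Cohort":
        recs = [r for r in self.records if r.split == split]
        keep = {r.spectrum_id for r in recs}
        cmap = {k: v for k, v in self.contralateral_map.items() if k in keep and v in keep}
        return Cohort(recs, list(self.class_labels), cmap)

    @property
    def axis(self) -> np.ndarray:
        if not self.records:
            return default_axis()
        return self.records[0].ppm_axis

    def matrix(self) -> tuple:
        """Stacked intensity matrix (n_spectra x n_points) and label vector."""
        X = np.vstack([r.intensities for r in self.records])
        y = np.array([r.label for r in self.records])
        return X, y

    def class_sizes(self) -> dict:
        return {c: sum(r.label == c for r in self.records) for c in self.class_labels}


@dataclass(frozen=True)
class FeatureEntry:
    selection_order: int
    datapoint_index: int
    ppm: float
    assigned_metabolite: Optional[str] = None


@dataclass
class FeatureSet:
    """Ordered spectral datapoints chosen by feature selection."""

    entries: list

    def __post_init__(self) -> None:
        orders = [e.selection_order for e in self.entries]
        if orders != list(range(1, len(orders) + 1)):
            raise ValidationError("selection_order must be consecutive from 1")
        idx = [e.datapoint_index for e in self.entries]
        if len(set(idx)) != len(idx):
            raise ValidationError("duplicate datapoint indices in FeatureSet")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def indices(self) -> np.ndarray:
        return np.array([e.datapoint_index for e in self.entries], dtype=int)

    @property
    def ppms(self) -> np.ndarray:
        return np.array([e.ppm for e in self.entries], dtype=float)

    def head(self, k: int) -> "FeatureSet":
        return FeatureSet(list(self.entries[:k]))

    @classmethod
    def from_indices(cls, indices: Iterable[int], axis: np.ndarray) -> "FeatureSet":
        return cls(
            [
                FeatureEntry(i + 1, int(j), float(axis[int(j)]))
                for i, j in enumerate(indices)
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "selection_order": [e.selection_order for e in self.entries],
                "datapoint_index": [e.datapoint_index for e in self.entries],
                "ppm": [e.ppm for e in self.entries],
                "assigned_metabolite": [e.assigned_metabolite for e in self.entries],
            }
        )


# ---------------------------------------------------------------------------
# delimited-text I/O

_META_COLUMNS = [
    "spectrum_id",
    "animal_id",
    "label",
    "region",
    "phase",
    "hemisphere",
    "split",
    "contralateral_id",
    "normalized",
]


def _read_table(path, **kwargs) -> pd.DataFrame:
    """Read a delimited text table, sniffing tab vs comma."""
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.splitlines() else ""
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    return pd.read_csv(io.StringIO(text), sep=sep, **kwargs)


def read_cohort(table_path, metadata_path) -> Cohort:
    """Load a cohort from an intensity table and a metadata table.

    The intensity table holds one spectrum per row: a `spectrum_id`
    column (or an unnamed first column) followed by one column per
    datapoint.  When the datapoint headers parse as floats they are used
    as the ppm axis; otherwise the default axis (evenly spaced over
    [0, 4.5] ppm) is synthesized.  Tab and comma delimiters are sniffed.
    """
    tab = _read_table(table_path)
    # hemisphere "n/a" is a legal value, not a missing one
    meta = _read_table(metadata_path, keep_default_na=False, dtype=str)
    if tab.shape[1] < 2:
        raise CohortFormatError("intensity table needs id column plus datapoints")
    id_col = tab.columns[0]
    value_cols = list(tab.columns[1:])
    values = tab[value_cols]
    if values.isna().any().any():
        raise CohortFormatError("ragged or non-numeric rows in intensity table")
    try:
        axis = np.array([float(c) for c in value_cols])
        d = np.diff(axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError
    except (TypeError, ValueError):
        axis = default_axis(len(value_cols))

    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise CohortFormatError(f"metadata table missing columns: {missing}")
    meta = meta.set_index("spectrum_id")

    records, cmap = [], {}
    for sid, row in zip(tab[id_col].astype(str), values.to_numpy(dtype=float)):
        if sid not in meta.index:
            raise CohortFormatError(f"no metadata for spectrum {sid!r}")
        m = meta.loc[sid]
        records.append(
            SpectrumRecord(
                animal_id=str(m["animal_id"]),
                spectrum_id=sid,
                region=str(m["region"]),
                phase=str(m["phase"]),
                label=str(m["label"]),
                hemisphere=str(m["hemisphere"]),
                split=str(m["split"]),
                ppm_axis=axis,
                intensities=row,
                normalized=str(m["normalized"]).strip().lower() in ("true", "1", "yes"),
            )
        )
        ref = str(m["contralateral_id"]).strip()
        if ref and ref != "none":
            cmap[sid] = ref
    class_labels = list(dict.fromkeys(r.label for r in records))
    return Cohort(records, class_labels, cmap)


def write_cohort(cohort: Cohort, table_path, metadata_path, sep: str = "\t") -> None:
    """Write a cohort as two delimited text tables, losslessly re-readable."""
    axis = cohort.axis
    cols = ["spectrum_id"] + [f"{p:.6f}" for p in axis]
    rows = [[r.spectrum_id] + list(r.intensities) for r in cohort.records]
    pd.DataFrame(rows, columns=cols).to_csv(table_path, sep=sep, index=False, float_format="%.17g")
    meta = pd.DataFrame(
        {
            "spectrum_id": [r.spectrum_id for r in cohort.records],
            "animal_id": [r.animal_id for r in cohort.records],
            "label": [r.label for r in cohort.records],
            "region": [r.region for r in cohort.records],
            "phase": [r.phase for r in cohort.records],
            "hemisphere": [r.hemisphere for r in cohort.records],
            "split": [r.split for r in cohort.records],
            "contralateral_id": [
                cohort.contralateral_map.get(r.spectrum_id, "none") for r in cohort.records
            ],
            "normalized": [r.normalized for r in cohort.records],
        }
    )
    meta.to_csv(metadata_path, sep=sep, index=False)
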