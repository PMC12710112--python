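"""Shared data model and delimited-file IO.

All on-disk exchange formats are tab-separated UTF-8 tables with a header
row.  The canonical region ordering for a cohort is the row order of the
parcel metadata file; every matrix produced downstream uses that order.
Only parcellated tables are accepted — voxel-space images are preprocessing
and out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ParcellatedSeries",
    "ParcelMetadata",
    "ReceptorTable",
    "CohortTable",
    "CANONICAL_RECEPTOR_MAPS",
    "SEED_NAMES",
    "load_parcellated_series",
    "write_parcellated_series",
    "load_parcel_metadata",
    "write_parcel_metadata",
    "load_receptor_table",
    "write_receptor_table",
    "load_cohort_table",
    "write_cohort_table",
    "new_result_table",
    "validate_result_table",
]

#: Receptor / transporter density maps with a canonical meaning:
#: cholinergic (A4B2 nicotinic receptor, M1 muscarinic receptor, vesicular
#: acetylcholine transporter), dopaminergic (D1, D2 receptors, dopamine
#: transporter) and noradrenergic (norepinephrine transporter).
CANONICAL_RECEPTOR_MAPS = ("A4B2", "M1", "VAChT", "D1", "D2", "DAT", "NET")

#: Subcortical seed regions: nucleus basalis of Meynert (cholinergic),
#: locus coeruleus (noradrenergic), basal ganglia (caudate + putamen).
SEED_NAMES = ("NBM", "LC", "BG")

_WRITE_FLOAT_FORMAT = "%.10g"  # 10 significant digits: stable round-trip


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """A table parses but violates a data-model invariant."""


@dataclass
class ParcellatedSeries:
    """One subject-visit's region × timepoint BOLD matrix.

    ``values[i, t]`` is the parcel-mean BOLD signal (arbitrary units) of
    region ``region_labels[i]`` at scan timepoint ``t`` (sampling interval
    ``tr_seconds``).
    """

    subject_id: str
    visit_id: str
    tr_seconds: float
    values: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D region × time matrix")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if len(self.region_labels) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.region_labels)} labels for {self.values.shape[0]} rows"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            dupes = _duplicates(self.region_labels)
            raise ValidationError(f"duplicate region labels: {sorted(dupes)}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at region {self.region_labels[bad[0]]!r}, "
                f"timepoint {bad[1]}"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def reordered(self, labels: Sequence[str]) -> "ParcellatedSeries":
        """Return a copy with rows re-sorted to ``labels`` (the canonical order)."""
        index = {lab: i for i, lab in enumerate(self.region_labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise ValidationError(f"series lacks regions: {missing[:5]}")
        order = [index[lab] for lab in labels]
        return ParcellatedSeries(
            self.subject_id,
            self.visit_id,
            self.tr_seconds,
            self.values[order],
            list(labels),
        )


@dataclass
class ParcelMetadata:
    """Region → (role, network, hemisphere) assignment.

    Cortical regions are grouped into the eight broad resting-state networks;
    subcortical rows carry a seed name (NBM / LC / BG) instead.  The frame's
    row order is the canonical region order for the cohort.
    """

    frame: pd.DataFrame
    require_eight_networks: bool = False

    _ROLES = ("cortical", "subcortical_seed")
    _HEMIS = ("L", "R", "bilateral")

    def __post_init__(self) -> None:
        required = {"region_label", "role", "network", "hemisphere"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        f = self.frame.reset_index(drop=True)
        if f["region_label"].duplicated().any():
            dupes = f.loc[f["region_label"].duplicated(), "region_label"]
            raise ValidationError(f"duplicate region labels: {sorted(set(dupes))}")
        bad_role = set(f["role"]) - set(self._ROLES)
        if bad_role:
            raise ValidationError(f"unknown roles: {sorted(bad_role)}")
        bad_hemi = set(f["hemisphere"]) - set(self._HEMIS)
        if bad_hemi:
            raise ValidationError(f"unknown hemispheres: {sorted(bad_hemi)}")
        seed_named_cortical = f[
            (f["role"] == "cortical") & (f["network"].isin(SEED_NAMES))
        ]
        if len(seed_named_cortical):
            raise ValidationError(
                "cortical regions carry seed network names: "
                f"{sorted(seed_named_cortical['region_label'])}"
            )
        if self.require_eight_networks and len(self.networks) != 8:
            raise ValidationError(
                f"expected exactly 8 cortical networks, found {len(self.networks)}: "
                f"{self.networks}"
            )
        self.frame = f

    @property
    def networks(self) -> list[str]:
        """Distinct cortical network names, in order of first appearance."""
        cort = self.frame[self.frame["role"] == "cortical"]
        return list(dict.fromkeys(cort["network"]))

    @property
    def cortical_labels(self) -> list[str]:
        return list(self.frame.loc[self.frame["role"] == "cortical", "region_label"])

    @property
    def seed_labels(self) -> list[str]:
        return list(
            self.frame.loc[self.frame["role"] == "subcortical_seed", "region_label"]
        )

    @property
    def region_labels(self) -> list[str]:
        return list(self.frame["region_label"])

    def network_of(self) -> dict[str, str]:
        return dict(zip(self.frame["region_label"], self.frame["network"]))

    def validate_series(self, series: ParcellatedSeries) -> None:
        """Cross-validate a series against this metadata (label set equality)."""
        s, m = set(series.region_labels), set(self.frame["region_label"])
        if s != m:
            raise ValidationError(
                f"series/metadata region mismatch: only in series {sorted(s - m)[:5]}, "
                f"only in metadata {sorted(m - s)[:5]}"
            )


@dataclass
class ReceptorTable:
    """Cortical region × receptor-map density table."""

    frame: pd.DataFrame  # index: region_label; columns: map names

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise ValidationError("duplicate region labels in receptor table")
        if self.frame.isna().any().any():
            raise ValidationError("missing values in receptor table")

    @property
    def map_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def non_canonical_maps(self) -> list[str]:
        return [m for m in self.frame.columns if m not in CANONICAL_RECEPTOR_MAPS]

    def validate_metadata(self, meta: ParcelMetadata) -> None:
        missing = set(meta.cortical_labels) - set(self.frame.index)
        if missing:
            raise ValidationError(
                f"receptor table missing cortical regions: {sorted(missing)[:5]}"
            )


@dataclass
class CohortTable:
    """Subject-visit roster with demographics and conversion outcomes."""

    frame: pd.DataFrame

    _REQUIRED = (
        "subject_id",
        "visit_id",
        "group",
        "months_from_baseline",
        "age",
        "sex",
        "education",
        "conversion_event",
        "months_to_event_or_censor",
    )

    def __post_init__(self) -> None:
        missing = set(self._REQUIRED) - set(self.frame.columns)
        if missing:
            raise FormatError(f"cohort table missing columns: {sorted(missing)}")
        f = self.frame.reset_index(drop=True)
        bad_group = set(f["group"]) - {"case", "control"}
        if bad_group:
            raise ValidationError(f"unknown groups: {sorted(bad_group)}")
        bad_event = set(f["conversion_event"].dropna()) - {"none", "PD", "DLB"}
        if bad_event:
            raise ValidationError(f"unknown conversion events: {sorted(bad_event)}")
        first = f.sort_values("months_from_baseline").groupby("subject_id").first()
        nonzero = first[first["months_from_baseline"] != 0]
        if len(nonzero):
            raise ValidationError(
                "first visit months_from_baseline must be 0 for subjects: "
                f"{sorted(nonzero.index)[:5]}"
            )
        cases = f[f["group"] == "case"]
        if cases["months_to_event_or_censor"].isna().any():
            raise ValidationError("months_to_event_or_censor undefined for some cases")
        if (cases["months_to_event_or_censor"] <= 0).any():
            raise ValidationError("months_to_event_or_censor must be positive")
        self.frame = f

    def baseline(self) -> pd.DataFrame:
        return self.frame[self.frame["months_from_baseline"] == 0].copy()


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        (dup if it in seen else seen).add(it)
    return dup


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", encoding="utf-8", **kwargs)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc


def load_parcellated_series(
    path: str | Path,
    tr_seconds: float,
    subject_id: str | None = None,
    visit_id: str | None = None,
) -> ParcellatedSeries:
    """Load one region × time BOLD table.

    First column holds region labels; remaining columns are timepoints in
    scan order.  The loader fails rather than imputing: any empty or
    non-numeric cell is a format error naming the offending row and column.
    """
    path = Path(path)
    frame = _read_tsv(path, index_col=0)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()]
        raise FormatError(f"{path.name}: duplicate region labels {sorted(set(dupes))}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path.name}: missing or non-numeric cell at region "
            f"{frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    stem_parts = path.stem.split("__")
    if subject_id is None:
        subject_id = stem_parts[0]
    if visit_id is None:
        visit_id = stem_parts[1] if len(stem_parts) > 1 else "V1"
    return ParcellatedSeries(
        subject_id=subject_id,
        visit_id=visit_id,
        tr_seconds=tr_seconds,
        values=numeric.to_numpy(dtype=float),
        region_labels=[str(lab) for lab in frame.index],
    )


def write_parcellated_series(series: ParcellatedSeries, path: str | Path) -> None:
    frame = pd.DataFrame(
        series.values,
        index=pd.Index(series.region_labels, name="region_label"),
        columns=[f"t{t}" for t in range(series.n_timepoints)],
    )
    frame.to_csv(path, sep="\t", float_format=_WRITE_FLOAT_FORMAT, encoding="utf-8")


def load_parcel_metadata(path: str | Path, strict: bool = True) -> ParcelMetadata:
    """Load and validate the parcel metadata table.

    With ``strict`` (the default) the cortical rows must partition into
    exactly eight networks, matching the broad resting-state network scheme.
    """
    frame = _read_tsv(path)
    return ParcelMetadata(frame, require_eight_networks=strict)


def write_parcel_metadata(meta: ParcelMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def load_receptor_table(path: str | Path) -> ReceptorTable:
    """Load a cortical region × receptor-map density table.

    Unknown map names are retained under their given name with a warning so
    exploratory maps can flow through the same pipeline.
    """
    frame = _read_tsv(path, index_col=0)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"missing or non-numeric receptor density at region "
            f"{frame.index[r]!r}, map {frame.columns[c]!r}"
        )
    table = ReceptorTable(numeric)
    if table.non_canonical_maps:
        warnings.warn(
            f"non-canonical receptor maps retained: {table.non_canonical_maps}",
            stacklevel=2,
        )
    return table


def write_receptor_table(table: ReceptorTable, path: str | Path) -> None:
    frame = table.frame.copy()
    frame.index.name = "region_label"
    frame.to_csv(path, sep="\t", float_format=_WRITE_FLOAT_FORMAT, encoding="utf-8")


def load_cohort_table(path: str | Path) -> CohortTable:
    frame = _read_tsv(path)
    return CohortTable(frame)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    cohort.frame.to_csv(
        path, sep="\t", index=False, float_format=_WRITE_FLOAT_FORMAT, encoding="utf-8"
    )


_RESULT_COLUMNS = (
    "analysis_name",
    "unit_of_analysis",
    "estimate",
    "standard_error",
    "statistic",
    "p_raw",
    "p_fdr",
    "family_id",
)


def new_result_table(rows: list[dict] | None = None) -> pd.DataFrame:
    frame = pd.DataFrame(rows or [], columns=list(_RESULT_COLUMNS))
    return frame


def validate_result_table(frame: pd.DataFrame) -> None:
    missing = set(_RESULT_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"result table missing columns: {sorted(missing)}")
    p = frame[["p_raw", "p_fdr"]].dropna()
    if ((p < 0) | (p > 1)).any().any():
        raise ValidationError("p values outside [0, 1]")
    if (p["p_fdr"] + 1e-12 < p["p_raw"]).any():
        raise ValidationError("p_fdr smaller than p_raw")
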