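"""Raw probe-intensity matrices and proximal/distal region signals.

The screen deliberately works on non-normalized raw probe intensities:
the proximal/distal ratio R is formed within a single array, so any
per-array scale factor (labelling efficiency, scanner gain,
normalization constant) cancels exactly.  No background correction,
quantile normalization or log transform is applied here; preprocessing,
if any, must happen upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import SplitProbeSet
from .errors import ValidationError

GROUPS = ("treated", "control")
SAMPLE_SHEET_COLUMNS = ("array_id", "series_id", "group")


@dataclass
class IntensityExperiment:
    """A probes x arrays raw-intensity matrix plus its sample sheet.

    ``values`` is indexed by probe_id with one column per array;
    ``sample_sheet`` is indexed by array_id with columns ``series_id``
    and ``group`` (treated/control).  Every array must appear in the
    sheet and every series must contain at least one array per group.
    """

    values: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("intensity matrix contains non-numeric values")
        if not np.isfinite(vals).all() or (vals <= 0).any():
            bad = np.argwhere(~(np.isfinite(vals) & (vals > 0)))[0]
            raise ValidationError(
                f"non-positive or non-finite intensity at probe "
                f"{self.values.index[bad[0]]!r}, array {self.values.columns[bad[1]]!r}"
            )
        missing_cols = {"series_id", "group"} - set(self.sample_sheet.columns)
        if missing_cols:
            raise ValidationError(f"sample sheet lacks columns {sorted(missing_cols)}")
        unknown = set(self.sample_sheet["group"]) - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown group labels {sorted(unknown)}")
        absent = [a for a in self.values.columns if a not in self.sample_sheet.index]
        if absent:
            raise ValidationError(f"arrays missing from sample sheet: {absent}")
        for series_id, grp in self.sample_sheet.loc[
            list(self.values.columns)
        ].groupby("series_id"):
            present = set(grp["group"])
            if not present >= set(GROUPS):
                raise ValidationError(
                    f"series {series_id!r} lacks group(s) {sorted(set(GROUPS) - present)}"
                )

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def series_ids(self) -> list[str]:
        return sorted(self.sample_sheet.loc[self.array_ids, "series_id"].unique())

    def arrays_of(self, series_id: str, group: str | None = None) -> list[str]:
        sheet = self.sample_sheet.loc[self.array_ids]
        mask = sheet["series_id"] == series_id
        if group is not None:
            mask &= sheet["group"] == group
        return list(sheet.index[mask])


@dataclass(frozen=True)
class RegionSignal:
    """Proximal/distal mean intensities and their ratio on one array."""

    probeset_id: str
    site_id: str
    array_id: str
    prox_mean: float
    dist_mean: float

    @property
    def ratio(self) -> float:
        return self.prox_mean / self.dist_mean


def load_experiment(matrix_path, sample_sheet_path) -> IntensityExperiment:
    """Load an intensity TSV (first column probe_id, one column per
    array) and a sample-sheet TSV (array_id, series_id, group)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValidationError(
            f"{sample_sheet_path}: sample sheet lacks columns {sorted(missing)}"
        )
    sheet = sheet.set_index("array_id")
    return IntensityExperiment(values=values, sample_sheet=sheet)


def _summarize(x: np.ndarray, how: str) -> float:
    if how == "mean":
        return float(np.mean(x))
    if how == "median":
        return float(np.median(x))
    if how == "trimmed":
        return float(stats.trim_mean(x, 0.1))
    raise ValidationError(f"unknown region summary {how!r}")


def region_means(
    exp: IntensityExperiment,
    split: SplitProbeSet,
    array_id: str,
    summary: str = "mean",
) -> RegionSignal:
    """Mean proximal and distal probe intensity of one array, on the
    linear scale; excluded probes are ignored."""
    table = region_ratio_table(exp, split, summary=summary)
    row = table.loc[array_id]
    return RegionSignal(
        probeset_id=split.probeset_id,
        site_id=split.site_id,
        array_id=array_id,
        prox_mean=float(row["prox_mean"]),
        dist_mean=float(row["dist_mean"]),
    )


def region_ratio_table(
    exp: IntensityExperiment, split: SplitProbeSet, summary: str = "mean"
) -> pd.DataFrame:
    """Per-array proximal/distal means and ratio R for one split.

    Returns a DataFrame indexed by array_id with columns ``prox_mean``,
    ``dist_mean``, ``ratio``, ``series_id``, ``group``.
    """
    prox = sorted(split.proximal_probe_ids)
    dist = sorted(split.distal_probe_ids)
    missing = [p for p in prox + dist if p not in exp.values.index]
    if missing:
        raise ValidationError(
            f"split {split.probeset_id}/{split.site_id}: probes missing from "
            f"intensity matrix: {missing}"
        )
    prox_vals = exp.values.loc[prox].to_numpy()
    dist_vals = exp.values.loc[dist].to_numpy()
    if summary == "mean":
        prox_mean = prox_vals.mean(axis=0)
        dist_mean = dist_vals.mean(axis=0)
    else:
        prox_mean = np.array([_summarize(prox_vals[:, j], summary) for j in range(prox_vals.shape[1])])
        dist_mean = np.array([_summarize(dist_vals[:, j], summary) for j in range(dist_vals.shape[1])])
    table = pd.DataFrame(
        {
            "prox_mean": prox_mean,
            "dist_mean": dist_mean,
            "ratio": prox_mean / dist_mean,
        },
        index=pd.Index(exp.values.columns, name="array_id"),
    )
    sheet = exp.sample_sheet.loc[table.index]
    table["series_id"] = sheet["series_id"].to_numpy()
    table["group"] = sheet["group"].to_numpy()
    return table
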