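"""Per-series fold changes, product combination across series, and the
candidate screen.

For each split probe set the per-array proximal/distal ratio R is
summarized per treated and control group (geometric mean by default,
ratios being multiplicative) and the series fold is

    F = R_treated / R_control .

A fold above 1 means the proximal (both-isoform) signal rose relative
to the distal (long-isoform-only) signal upon treatment — the
expression signature of 3'-UTR shortening.  Independent series are
combined multiplicatively (the product approach); the default flag
rule additionally requires every series to individually reach the fold
threshold, so only candidates consistent across datasets survive.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.base import BaseEstimator

from . import annotation as ann
from .annotation import SplitProbeSet
from .errors import ValidationError
from .intensities import IntensityExperiment, load_experiment, region_ratio_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class APAScoreRecord:
    """Treated/control ratio summaries and fold for one split in one series."""

    probeset_id: str
    site_id: str
    series_id: str
    r_treated: float
    r_control: float
    n_treated: int
    n_control: int

    @property
    def fold(self) -> float:
        return self.r_treated / self.r_control


@dataclass(frozen=True)
class CombinedScore:
    """Per-series folds and their product for one probe set/site."""

    probeset_id: str
    site_id: str
    series_ids: tuple
    per_series_folds: tuple

    @property
    def product_score(self) -> float:
        return float(np.prod(self.per_series_folds))


def _group_summary(values: np.ndarray, how: str) -> float:
    if how == "geometric":
        return float(stats.gmean(values))
    if how == "arithmetic":
        return float(np.mean(values))
    raise ValidationError(f"unknown group summary {how!r}")


def series_fold(
    ratios: pd.Series,
    sample_sheet: pd.DataFrame,
    series_id: str,
    probeset_id: str = "",
    site_id: str = "",
    group_summary: str = "geometric",
) -> APAScoreRecord:
    """Fold F = R_treated / R_control for one split in one series.

    ``ratios`` maps array_id -> per-array R; arrays of other series are
    ignored.  Both groups must be non-empty.
    """
    sheet = sample_sheet.loc[sample_sheet["series_id"] == series_id]
    out = {}
    for group in ("treated", "control"):
        arrays = [a for a in sheet.index[sheet["group"] == group] if a in ratios.index]
        if not arrays:
            raise ValidationError(f"series {series_id!r}: no {group} arrays")
        out[group] = (_group_summary(ratios.loc[arrays].to_numpy(), group_summary), len(arrays))
    return APAScoreRecord(
        probeset_id=probeset_id,
        site_id=site_id,
        series_id=series_id,
        r_treated=out["treated"][0],
        r_control=out["control"][0],
        n_treated=out["treated"][1],
        n_control=out["control"][1],
    )


def combine_series(records: list[APAScoreRecord]) -> CombinedScore:
    """Combine one split's per-series records into a product score.

    The product is invariant to series order; records are sorted by
    series id for a canonical representation.
    """
    if not records:
        raise ValidationError("combine_series: no records")
    keys = {(r.probeset_id, r.site_id) for r in records}
    if len(keys) != 1:
        raise ValidationError(f"combine_series: mixed probe sets/sites {sorted(keys)}")
    ordered = sorted(records, key=lambda r: r.series_id)
    return CombinedScore(
        probeset_id=ordered[0].probeset_id,
        site_id=ordered[0].site_id,
        series_ids=tuple(r.series_id for r in ordered),
        per_series_folds=tuple(r.fold for r in ordered),
    )


def screen_candidates(
    scores: list[CombinedScore],
    threshold: float = 1.5,
    require_all_series: bool = True,
) -> pd.DataFrame:
    """Rank combined scores and flag screen hits.

    With ``require_all_series`` (default) a candidate is flagged iff
    every per-series fold is >= ``threshold``; otherwise iff the product
    score is >= ``threshold ** n_series``.  Each probe set is
    represented by its best site (highest product score); output is
    sorted by product score descending, ties broken by probeset_id.
    """
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    if not scores:
        return pd.DataFrame(
            columns=["rank", "probeset_id", "site_id", "product_score", "flag"]
        )
    rows = []
    for s in scores:
        row = {
            "probeset_id": s.probeset_id,
            "site_id": s.site_id,
            "product_score": s.product_score,
            "n_series": len(s.per_series_folds),
        }
        for sid, f in zip(s.series_ids, s.per_series_folds):
            row[f"fold_{sid}"] = f
        if require_all_series:
            row["flag"] = all(f >= threshold for f in s.per_series_folds)
        else:
            row["flag"] = s.product_score >= threshold ** len(s.per_series_folds)
        rows.append(row)
    table = pd.DataFrame(rows)
    # best site per probe set, then deterministic ranking
    table = table.sort_values(
        ["product_score", "site_id"], ascending=[False, True], kind="mergesort"
    ).drop_duplicates("probeset_id", keep="first")
    table = table.sort_values(
        ["product_score", "probeset_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


class APAScreen(BaseEstimator):
    """Probe-level screen for alternative polyadenylation.

    Fits per-array proximal/distal intensity ratios for every split
    probe set, summarizes them into per-series treated/control folds,
    combines series by the product approach and flags candidates.

    Parameters
    ----------
    threshold : float, default 1.5
        Per-series fold threshold (>= 1) for flagging.
    min_per_side : int, default 1
        Minimum probes required on each flank of a poly(A) site for the
        probe set to be split (used only when splits are computed from
        probes/sites inside :meth:`fit`).
    require_all_series : bool, default True
        Flag only candidates reaching the threshold in every series;
        if False, flag on product score >= threshold ** n_series.
    region_summary : {'mean', 'median', 'trimmed'}, default 'mean'
        Per-array summary of probe intensities within a region.
    group_summary : {'geometric', 'arithmetic'}, default 'geometric'
        Summary of per-array ratios within a treatment group.

    Attributes
    ----------
    splits_ : list of SplitProbeSet
        The partitions screened.
    ratios_ : pandas.DataFrame
        Long table of per-array region signals (one row per split x array).
    records_ : list of APAScoreRecord
        Per split x series fold records.
    combined_ : list of CombinedScore
        Per-split product scores across series.
    candidates_ : pandas.DataFrame
        Ranked candidate table (one row per probe set, best site).
    series_ids_ : list of str
    """

    def __init__(
        self,
        threshold: float = 1.5,
        min_per_side: int = 1,
        require_all_series: bool = True,
        region_summary: str = "mean",
        group_summary: str = "geometric",
    ):
        self.threshold = threshold
        self.min_per_side = min_per_side
        self.require_all_series = require_all_series
        self.region_summary = region_summary
        self.group_summary = group_summary

    def fit(
        self,
        experiment: IntensityExperiment,
        splits: list[SplitProbeSet] | None = None,
        probes: pd.DataFrame | None = None,
        sites=None,
    ):
        """Run the screen on one experiment.

        Either ``splits`` or both ``probes`` and ``sites`` must be given.
        """
        if self.threshold < 1:
            raise ValidationError("threshold must be >= 1")
        if splits is None:
            if probes is None or sites is None:
                raise ValidationError("fit needs splits, or probes and sites")
            splits = ann.split_all_probesets(probes, sites, self.min_per_side)
        self.splits_ = list(splits)
        self.series_ids_ = experiment.series_ids

        ratio_frames = []
        records: list[APAScoreRecord] = []
        combined: list[CombinedScore] = []
        for split in self.splits_:
            table = region_ratio_table(experiment, split, summary=self.region_summary)
            tagged = table.reset_index()
            tagged.insert(0, "site_id", split.site_id)
            tagged.insert(0, "probeset_id", split.probeset_id)
            ratio_frames.append(tagged)
            per_series = [
                series_fold(
                    table["ratio"],
                    experiment.sample_sheet,
                    series_id,
                    probeset_id=split.probeset_id,
                    site_id=split.site_id,
                    group_summary=self.group_summary,
                )
                for series_id in self.series_ids_
            ]
            records.extend(per_series)
            combined.append(combine_series(per_series))
        self.ratios_ = (
            pd.concat(ratio_frames, ignore_index=True)
            if ratio_frames
            else pd.DataFrame()
        )
        self.records_ = records
        self.combined_ = combined
        self.candidates_ = screen_candidates(
            combined,
            threshold=self.threshold,
            require_all_series=self.require_all_series,
        )
        return self

    def flagged(self) -> pd.DataFrame:
        """Flagged rows of the fitted candidate table."""
        self._check_fitted()
        return self.candidates_.loc[self.candidates_["flag"]].reset_index(drop=True)

    def _check_fitted(self):
        if not hasattr(self, "candidates_"):
            raise ValidationError("APAScreen is not fitted; call fit first")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_screen(config, out_dir=None):
    """End-to-end screen from a config mapping (or YAML path).

    Config keys: ``probes`` (TSV path; optional ``probeset_map`` for BED
    input), ``sites`` (BED path), ``matrix`` and ``sample_sheet`` (paths;
    alternatively ``series``: list of {matrix, sample_sheet} merged by
    column), ``threshold``, ``min_per_side``, ``require_all_series``,
    ``one_based``.  Returns ``(candidates, log)``; when ``out_dir`` is
    given also writes ``candidates.tsv`` and ``run_log.json``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    one_based = bool(config.get("one_based", False))
    paths = {"probes": config["probes"], "sites": config["sites"]}
    try:
        probes = ann.read_probe_alignments(
            config["probes"],
            probeset_map=config.get("probeset_map"),
            one_based=one_based,
        )
        sites = ann.read_polya_sites(config["sites"], one_based=one_based)
    except Exception as exc:
        raise type(exc)(f"annotation stage: {exc}") from exc

    try:
        if "series" in config:
            parts = [
                load_experiment(s["matrix"], s["sample_sheet"]) for s in config["series"]
            ]
            for i, s in enumerate(config["series"]):
                paths[f"matrix_{i}"] = s["matrix"]
                paths[f"sample_sheet_{i}"] = s["sample_sheet"]
            values = pd.concat([p.values for p in parts], axis=1)
            sheet = pd.concat([p.sample_sheet for p in parts], axis=0)
            experiment = IntensityExperiment(values=values, sample_sheet=sheet)
        else:
            paths["matrix"] = config["matrix"]
            paths["sample_sheet"] = config["sample_sheet"]
            experiment = load_experiment(config["matrix"], config["sample_sheet"])
    except Exception as exc:
        raise type(exc)(f"intensity stage: {exc}") from exc

    screen = APAScreen(
        threshold=float(config.get("threshold", 1.5)),
        min_per_side=int(config.get("min_per_side", 1)),
        require_all_series=bool(config.get("require_all_series", True)),
        region_summary=config.get("region_summary", "mean"),
        group_summary=config.get("group_summary", "geometric"),
    )
    try:
        screen.fit(experiment, probes=probes, sites=sites)
    except Exception as exc:
        raise type(exc)(f"screen stage: {exc}") from exc

    log = {
        "parameters": screen.get_params(),
        "n_probes": int(len(probes)),
        "n_sites": int(len(sites)),
        "n_splits": int(len(screen.splits_)),
        "n_candidates": int(len(screen.candidates_)),
        "n_flagged": int(screen.candidates_["flag"].sum())
        if len(screen.candidates_)
        else 0,
        "series_ids": screen.series_ids_,
        "input_checksums": {k: _sha256(v) for k, v in paths.items()},
    }
    logger.info("screen: %d splits, %d flagged", log["n_splits"], log["n_flagged"])
    candidates = screen.candidates_
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        candidates.to_csv(out_dir / "candidates.tsv", sep="\t", index=False, float_format="%.6g")
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    return candidates, log
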