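"""Probe alignments, poly(A)-site annotations and proximal/distal partitioning.

A 3' expression array interrogates each transcript with a probe set of
~11 25-mers tiled across the 3'-UTR.  When a tandem poly(A) site lies
inside the tiled region, the probes transcript-5' of the cleavage point
("proximal") report both the short and the long isoform, while probes
between the proximal and distal sites ("distal") report only the long
isoform.  This module reads the two annotation inputs, performs the
partition, and classifies arbitrary UTR positions relative to the
proximal/distal poly(A) boundary.

Coordinates are 0-based half-open internally (BED convention); a
``one_based`` flag converts fully-closed 1-based TSVs on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

PROBE_COLUMNS = ["chrom", "start", "end", "probe_id", "probeset_id", "strand"]
_STRANDS = {"+", "-"}


def _normalize_strand(s: str) -> str:
    # accept the unicode minus that turns up in copy-pasted annotation
    return "-" if s in ("-", "−") else s


@dataclass(frozen=True)
class PolyASite:
    """An annotated cleavage/poly(A) position.

    ``order_index`` ranks the site in transcript 5'->3' order among all
    sites sharing ``key`` (ascending genomic coordinate on ``+``,
    descending on ``-``): the lowest rank is the proximal site (P-pA),
    the highest the distal site (D-pA).
    """

    site_id: str
    key: str
    chrom: str
    strand: str
    cleavage_pos: int
    order_index: int = 1

    def __post_init__(self):
        if self.strand not in _STRANDS:
            raise ValidationError(f"site {self.site_id}: strand {self.strand!r}")
        if self.cleavage_pos < 0:
            raise ValidationError(f"site {self.site_id}: negative cleavage_pos")
        if self.order_index < 1:
            raise ValidationError(f"site {self.site_id}: order_index < 1")


@dataclass(frozen=True)
class SplitProbeSet:
    """A probe set partitioned at one poly(A) site.

    The three id sets partition the probe set: probes strictly
    transcript-5' of the cleavage point are proximal, probes strictly
    3' are distal, and probes overlapping the point are excluded so the
    downstream ratio never mixes isoform-specific signal.
    """

    probeset_id: str
    site_id: str
    cleavage_pos: int
    strand: str
    order_index: int
    proximal_probe_ids: frozenset = field(default_factory=frozenset)
    distal_probe_ids: frozenset = field(default_factory=frozenset)
    excluded_probe_ids: frozenset = field(default_factory=frozenset)

    @property
    def n_prox(self) -> int:
        return len(self.proximal_probe_ids)

    @property
    def n_dist(self) -> int:
        return len(self.distal_probe_ids)


def read_probe_alignments(
    path,
    probeset_map=None,
    one_based: bool = False,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read probe genomic alignments from a TSV/BED-like file.

    Two dialects are accepted: a 6-column TSV with columns
    ``chrom, start, end, probe_id, probeset_id, strand`` (default), or a
    6-column BED (``chrom, start, end, probe_id, score, strand``) plus a
    ``probeset_map`` sidecar (path to a 2-column TSV ``probe_id,
    probeset_id`` or a mapping).  ``columns`` overrides the column order
    of the main file.  Lines starting with ``#`` or a ``chrom`` header
    are skipped.

    Returns a DataFrame with :data:`PROBE_COLUMNS`, coordinates 0-based
    half-open.
    """
    if columns is None:
        columns = (
            ["chrom", "start", "end", "probe_id", "score", "strand"]
            if probeset_map is not None
            else PROBE_COLUMNS
        )
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":  # header row
                continue
            if len(fields) < len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(columns)} columns, got {len(fields)}"
                )
            rec = dict(zip(columns, fields))
            try:
                start, end = int(rec["start"]), int(rec["end"])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if one_based:
                start -= 1  # 1-based fully-closed -> 0-based half-open
            strand = _normalize_strand(rec["strand"])
            if strand not in _STRANDS:
                raise ParseError(f"{path}:{lineno}: bad strand {rec['strand']!r}")
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: empty or inverted interval {start}..{end}"
                )
            rows.append(
                {
                    "chrom": rec["chrom"],
                    "start": start,
                    "end": end,
                    "probe_id": rec["probe_id"],
                    "probeset_id": rec.get("probeset_id", ""),
                    "strand": strand,
                }
            )
    probes = pd.DataFrame(rows, columns=PROBE_COLUMNS)
    if probeset_map is not None:
        if not isinstance(probeset_map, dict):
            m = pd.read_csv(
                probeset_map, sep="\t", names=["probe_id", "probeset_id"], comment="#"
            )
            probeset_map = dict(zip(m["probe_id"], m["probeset_id"]))
        probes["probeset_id"] = probes["probe_id"].map(probeset_map)
        if probes["probeset_id"].isna().any():
            missing = probes.loc[probes["probeset_id"].isna(), "probe_id"].tolist()
            raise ValidationError(f"probes missing from probeset map: {missing[:5]}")
    dup = probes.duplicated(subset=["probeset_id", "probe_id"])
    if dup.any():
        raise ValidationError(
            f"duplicate probe ids within a probe set: "
            f"{probes.loc[dup, 'probe_id'].tolist()[:5]}"
        )
    return probes


def read_polya_sites(path, one_based: bool = False) -> list[PolyASite]:
    """Read poly(A) sites from a 6-column BED (key in the name field).

    The cleavage position is the BED start.  ``order_index`` is assigned
    per key in transcript 5'->3' order: ascending genomic coordinate on
    ``+``, descending on ``-``.
    """
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":
                continue
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 columns")
            chrom, start, _end, key, _score, strand = fields[:6]
            try:
                pos = int(start)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer position") from exc
            if one_based:
                pos -= 1
            strand = _normalize_strand(strand)
            if strand not in _STRANDS:
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            raw.append((key, chrom, strand, pos))
    return assign_site_order(raw)


def assign_site_order(raw: Iterable[tuple]) -> list[PolyASite]:
    """Build :class:`PolyASite` records from ``(key, chrom, strand, pos)``
    tuples, assigning per-key 5'->3' ``order_index``."""
    sites: list[PolyASite] = []
    frame = pd.DataFrame(raw, columns=["key", "chrom", "strand", "pos"])
    if frame.empty:
        return sites
    dup = frame.duplicated(subset=["key", "pos"])
    if dup.any():
        pairs = frame.loc[dup, ["key", "pos"]].itertuples(index=False)
        raise ValidationError(
            "duplicate (key, cleavage_pos): " + ", ".join(f"{k}@{p}" for k, p in pairs)
        )
    for key, grp in frame.groupby("key", sort=True):
        minus = (grp["strand"] == "-").all()
        ordered = grp.sort_values("pos", ascending=not minus)
        for rank, row in enumerate(ordered.itertuples(index=False), start=1):
            sites.append(
                PolyASite(
                    site_id=f"{key}@{row.pos}",
                    key=key,
                    chrom=row.chrom,
                    strand=row.strand,
                    cleavage_pos=int(row.pos),
                    order_index=rank,
                )
            )
    return sites


def split_probeset(
    probes: pd.DataFrame, site: PolyASite, min_per_side: int = 1
) -> SplitProbeSet | None:
    """Partition one probe set's probes at ``site``.

    On ``+``: a probe is proximal iff ``end <= cleavage_pos``, distal iff
    ``start >= cleavage_pos``; on ``-`` the comparisons mirror.  Probes
    overlapping the cleavage point are excluded.  Returns ``None`` when
    either side holds fewer than ``min_per_side`` probes.
    """
    if probes.empty:
        return None
    chroms = set(probes["chrom"])
    strands = set(probes["strand"])
    if chroms != {site.chrom} or strands != {site.strand}:
        raise ValidationError(
            f"site {site.site_id} on {site.chrom}{site.strand} does not match "
            f"probes on {sorted(chroms)}{sorted(strands)}"
        )
    pos = site.cleavage_pos
    start = probes["start"].to_numpy()
    end = probes["end"].to_numpy()
    if site.strand == "+":
        prox = end <= pos
        dist = start >= pos
    else:
        prox = start >= pos
        dist = end <= pos
    excl = ~(prox | dist)
    if prox.sum() < min_per_side or dist.sum() < min_per_side:
        return None
    ids = probes["probe_id"].to_numpy()
    probeset_id = probes["probeset_id"].iloc[0]
    return SplitProbeSet(
        probeset_id=probeset_id,
        site_id=site.site_id,
        cleavage_pos=pos,
        strand=site.strand,
        order_index=site.order_index,
        proximal_probe_ids=frozenset(ids[prox]),
        distal_probe_ids=frozenset(ids[dist]),
        excluded_probe_ids=frozenset(ids[excl]),
    )


def split_all_probesets(
    probes: pd.DataFrame, sites: Iterable[PolyASite], min_per_side: int = 1
) -> list[SplitProbeSet]:
    """Partition every probe set at every matching internal poly(A) site.

    Sites are linked to probe sets via ``site.key == probeset_id``.  Each
    site of a multi-site probe set is evaluated independently and emitted
    separately when both flanks hold ``min_per_side`` probes; downstream
    screening takes the per-probe-set best site.  Sites whose key matches
    no probe set, or that lie on a different chrom/strand than the probe
    set, yield nothing.  Output is ordered by (probeset_id, order_index).
    """
    by_set = {pid: grp for pid, grp in probes.groupby("probeset_id", sort=True)}
    splits: list[SplitProbeSet] = []
    for site in sorted(sites, key=lambda s: (s.key, s.order_index)):
        grp = by_set.get(site.key)
        if grp is None:
            continue
        if set(grp["chrom"]) != {site.chrom} or set(grp["strand"]) != {site.strand}:
            continue
        sp = split_probeset(grp, site, min_per_side=min_per_side)
        if sp is not None:
            splits.append(sp)
    return splits


def splits_to_frame(splits: Iterable[SplitProbeSet]) -> pd.DataFrame:
    """Tabulate splits for TSV output (probe id sets comma-joined)."""
    rows = [
        {
            "probeset_id": s.probeset_id,
            "site_id": s.site_id,
            "cleavage_pos": s.cleavage_pos,
            "strand": s.strand,
            "order_index": s.order_index,
            "n_prox": s.n_prox,
            "n_dist": s.n_dist,
            "proximal_probe_ids": ",".join(sorted(s.proximal_probe_ids)),
            "distal_probe_ids": ",".join(sorted(s.distal_probe_ids)),
            "excluded_probe_ids": ",".join(sorted(s.excluded_probe_ids)),
        }
        for s in splits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "probeset_id",
            "site_id",
            "cleavage_pos",
            "strand",
            "order_index",
            "n_prox",
            "n_dist",
            "proximal_probe_ids",
            "distal_probe_ids",
            "excluded_probe_ids",
        ],
    )


def splits_from_frame(frame: pd.DataFrame) -> list[SplitProbeSet]:
    """Inverse of :func:`splits_to_frame`."""

    def _ids(cell) -> frozenset:
        if pd.isna(cell) or cell == "":
            return frozenset()
        return frozenset(str(cell).split(","))

    return [
        SplitProbeSet(
            probeset_id=str(r.probeset_id),
            site_id=str(r.site_id),
            cleavage_pos=int(r.cleavage_pos),
            strand=str(r.strand),
            order_index=int(r.order_index),
            proximal_probe_ids=_ids(r.proximal_probe_ids),
            distal_probe_ids=_ids(r.distal_probe_ids),
            excluded_probe_ids=_ids(r.excluded_probe_ids),
        )
        for r in frame.itertuples(index=False)
    ]


@dataclass(frozen=True)
class RegionCounts:
    """Counts of UTR positions relative to the P-pA/D-pA boundary."""

    common_region: int
    long_specific: int
    outside: int

    @property
    def total(self) -> int:
        return self.common_region + self.long_specific + self.outside

    @property
    def percent_long_specific(self) -> int:
        return int(round(100.0 * self.long_specific / self.total))


def classify_positions_by_region(
    positions: Sequence[int],
    p_pa: int,
    d_pa: int,
    strand: str = "+",
    p_pa_inclusive: bool = True,
) -> RegionCounts:
    """Classify UTR positions against the proximal/distal poly(A) sites.

    ``common_region`` is transcript-5' of the proximal site P-pA (present
    in both isoforms), ``long_specific`` lies between P-pA and the distal
    site D-pA (present only in the long isoform), ``outside`` is at or
    past D-pA.  By default a position exactly at P-pA counts as
    long-specific and one exactly at D-pA as outside
    (``p_pa_inclusive=False`` flips the P-pA boundary).
    """
    positions = np.asarray(positions)
    if positions.size == 0:
        raise ValidationError("no positions: long-specific percentage undefined")
    if strand not in _STRANDS:
        raise ValidationError(f"bad strand {strand!r}")
    if strand == "-":
        # mirror so the proximal site has the lower coordinate
        if not p_pa > d_pa:
            raise ValidationError("on '-' P-pA must be genomically 3' of D-pA")
        positions, p_pa, d_pa = -positions, -p_pa, -d_pa
    if not p_pa < d_pa:
        raise ValidationError("P-pA must be transcript-5' of D-pA")
    if p_pa_inclusive:
        common = positions < p_pa
        long_specific = (positions >= p_pa) & (positions < d_pa)
    else:
        common = positions <= p_pa
        long_specific = (positions > p_pa) & (positions < d_pa)
    outside = positions >= d_pa
    return RegionCounts(
        common_region=int(common.sum()),
        long_specific=int(long_specific.sum()),
        outside=int(outside.sum()),
    )
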