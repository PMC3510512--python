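"""Synthetic tandem-UTR microarray data with full ground truth.

The generator emulates the structure the screen assumes in real 3'
expression arrays: each gene expresses a short and a long 3'-UTR
isoform (abundances S and L); probes 5' of the internal poly(A) site
hybridize to both isoforms (signal ∝ S+L) while probes between the
internal and the terminal site see only the long isoform (∝ L).
Observed intensity of probe p on array a is

    I[p, a] = affinity_p * scale_a * abundance * noise,

with log-normal probe affinities (sequence-dependent hybridization
strength, mean 1), a log-uniform per-array scale factor (labelling and
scanner gain, the reason raw intensities need no normalization for a
within-array ratio), and multiplicative log-normal noise of a given
coefficient of variation.  Treatment multiplies total abundance by
``effect_total`` and the long-isoform fraction by ``effect_long_frac``;
``effect_long_frac < 1`` plants a 3'-UTR shortening event.

The closed-form expectations are R = (S+L)/L per condition and

    F = [(S_t+L_t)/L_t] / [(S_c+L_c)/L_c],

emitted in a truth table so every pipeline stage can be tested against
known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import PolyASite, assign_site_order
from .errors import ValidationError
from .intensities import IntensityExperiment

PROBE_LENGTH = 25
PROBE_SPACING = 100


@dataclass
class SimConfig:
    """Parameters of one simulated screen dataset.

    Defaults model the screen's study conditions: three independent
    series (one per expression dataset) of 3 treated vs 3 control
    arrays, 11-probe sets, a two-fold total upregulation with a halved
    long-isoform fraction for planted events (closed-form F = 2), 20%
    multiplicative noise and 0.3 log-SD probe affinities.
    """

    n_probesets: int = 200
    probes_per_set: int = 11
    frac_two_site: float = 1.0
    frac_event: float = 0.5
    arrays_per_group: int = 3
    n_series: int = 3
    s_control: float = 200.0
    l_control: float = 200.0
    effect_total: float = 2.0
    effect_long_frac: float = 0.5
    affinity_sd: float = 0.3
    noise_cv: float = 0.2
    array_scale_range: tuple = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_probesets", "probes_per_set", "arrays_per_group", "n_series"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("s_control", "l_control", "effect_total"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0.0 < self.effect_long_frac <= 1.0:
            raise ValidationError("effect_long_frac must be in (0, 1]")
        for name in ("frac_two_site", "frac_event"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.noise_cv < 0 or self.affinity_sd < 0:
            raise ValidationError("noise_cv and affinity_sd must be >= 0")
        lo, hi = self.array_scale_range
        if not 0 < lo <= hi:
            raise ValidationError("array_scale_range must satisfy 0 < lo <= hi")
        if self.frac_two_site > 0 and self.probes_per_set < 2:
            raise ValidationError(
                "probes_per_set must be >= 2 when frac_two_site > 0"
            )

    def abundances(self, has_event: bool) -> dict:
        """Closed-form short/long abundances per condition.

        Non-event genes receive the total-abundance effect only (their
        isoform mix is unchanged).
        """
        s_c, l_c = self.s_control, self.l_control
        total_c = s_c + l_c
        total_t = self.effect_total * total_c
        long_frac_c = l_c / total_c
        long_frac_t = (self.effect_long_frac if has_event else 1.0) * long_frac_c
        l_t = total_t * long_frac_t
        return {"s_control": s_c, "l_control": l_c, "s_treated": total_t - l_t, "l_treated": l_t}


def expected_fold(truth_row) -> float:
    """Closed-form F = [(S_t+L_t)/L_t] / [(S_c+L_c)/L_c] for a two-site
    truth entry (mapping or namedtuple-like)."""
    get = truth_row.get if hasattr(truth_row, "get") else lambda k: getattr(truth_row, k)
    if not get("has_site"):
        raise ValidationError("expected_fold undefined for a single-isoform probe set")
    r_c = (get("s_control") + get("l_control")) / get("l_control")
    r_t = (get("s_treated") + get("l_treated")) / get("l_treated")
    return r_t / r_c


def _genomic(base: int, t_start: int, t_end: int, utr_len: int, strand: str):
    """Map a transcript-coordinate interval to genomic coordinates."""
    if strand == "+":
        return base + t_start, base + t_end
    return base + utr_len - t_end, base + utr_len - t_start


def simulate_annotation(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Generate probe alignments, poly(A) sites and a truth skeleton.

    Probes tile each synthetic 3'-UTR uniformly (25-mers every 100 nt).
    Two-site probe sets get an internal site in a gap between two
    probes (both flanks hold >= 1 probe) and a terminal site 3' of all
    probes.  Deterministic given ``cfg.seed``.

    Returns ``(probes, sites, truth)``: a probe DataFrame, a list of
    :class:`~apascreen.annotation.PolyASite` and a truth-skeleton
    DataFrame (probeset_id, strand, has_site, has_apa_event).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    utr_len = cfg.probes_per_set * PROBE_SPACING
    probe_rows, raw_sites, truth_rows = [], [], []
    for i in range(cfg.n_probesets):
        pid = f"PS{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        base = i * (utr_len + 1000)
        has_site = rng.random() < cfg.frac_two_site
        has_event = bool(has_site and rng.random() < cfg.frac_event)
        cut = int(rng.integers(1, cfg.probes_per_set)) if has_site else None
        # probe k occupies transcript [k*spacing, k*spacing + 25)
        for k in range(cfg.probes_per_set):
            g_start, g_end = _genomic(
                base, k * PROBE_SPACING, k * PROBE_SPACING + PROBE_LENGTH, utr_len, strand
            )
            probe_rows.append(
                {
                    "chrom": "chrS",
                    "start": g_start,
                    "end": g_end,
                    "probe_id": f"{pid}_p{k:02d}",
                    "probeset_id": pid,
                    "strand": strand,
                }
            )
        if has_site:
            # internal site in the gap 3' of probe cut-1 (transcript order)
            t_pos = (cut - 1) * PROBE_SPACING + PROBE_LENGTH + 40
            for t in (t_pos, utr_len):
                g_pos = _genomic(base, t, t, utr_len, strand)[0]
                raw_sites.append((pid, "chrS", strand, g_pos))
        truth_rows.append(
            {
                "probeset_id": pid,
                "strand": strand,
                "has_site": has_site,
                "has_apa_event": has_event,
                "n_prox_true": cut if has_site else cfg.probes_per_set,
                "n_dist_true": cfg.probes_per_set - cut if has_site else 0,
            }
        )
    probes = pd.DataFrame(probe_rows)
    sites = assign_site_order(raw_sites)
    truth = pd.DataFrame(truth_rows).set_index("probeset_id", drop=False)
    return probes, sites, truth


def _lognormal_sigma_from_cv(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _mean_one_lognormal(rng, sigma: float, size) -> np.ndarray:
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_experiment(cfg: SimConfig, probes: pd.DataFrame, truth: pd.DataFrame,
                        rng: np.random.Generator | None = None):
    """Generate the intensity matrix for an annotation from
    :func:`simulate_annotation`.

    Returns ``(experiment, truth)`` where truth now carries the
    abundances and closed-form R/F.  Probe affinities are drawn once
    (they are chip properties shared by every array and series); arrays
    get independent scale factors and noise.  Array ids are
    ``{series}_{t|c}{replicate}``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    truth = truth.copy()
    for col, val in (("expected_r_control", np.nan), ("expected_r_treated", np.nan),
                     ("expected_f", np.nan)):
        truth[col] = val
    ab = {pid: cfg.abundances(bool(truth.at[pid, "has_apa_event"]))
          for pid in truth.index}
    for pid, a in ab.items():
        for k, v in a.items():
            truth.at[pid, k] = v
        if truth.at[pid, "has_site"]:
            truth.at[pid, "expected_r_control"] = (a["s_control"] + a["l_control"]) / a["l_control"]
            truth.at[pid, "expected_r_treated"] = (a["s_treated"] + a["l_treated"]) / a["l_treated"]
            truth.at[pid, "expected_f"] = (
                truth.at[pid, "expected_r_treated"] / truth.at[pid, "expected_r_control"]
            )

    # per-probe condition abundances; distal probes (beyond the internal
    # site) see only the long isoform
    probes = probes.sort_values(["probeset_id", "probe_id"]).reset_index(drop=True)
    n_probes = len(probes)
    abundance = {"control": np.empty(n_probes), "treated": np.empty(n_probes)}
    for idx, row in enumerate(probes.itertuples(index=False)):
        t = truth.loc[row.probeset_id]
        a = ab[row.probeset_id]
        # probe index within the set encodes transcript order by construction
        k = int(row.probe_id.rsplit("p", 1)[1])
        is_distal = bool(t["has_site"]) and k >= int(t["n_prox_true"])
        for cond in ("control", "treated"):
            s, l = a[f"s_{cond}"], a[f"l_{cond}"]
            abundance[cond][idx] = l if is_distal else s + l

    affinity = _mean_one_lognormal(rng, cfg.affinity_sd, n_probes)
    noise_sigma = _lognormal_sigma_from_cv(cfg.noise_cv)
    lo, hi = cfg.array_scale_range

    columns, data = [], []
    for s in range(cfg.n_series):
        series_id = f"S{s + 1}"
        for group, tag in (("treated", "t"), ("control", "c")):
            for r in range(cfg.arrays_per_group):
                scale = math.exp(rng.uniform(math.log(lo), math.log(hi)))
                noise = _mean_one_lognormal(rng, noise_sigma, n_probes)
                data.append(affinity * scale * abundance[group] * noise)
                columns.append((f"{series_id}_{tag}{r + 1}", series_id, group))
    values = pd.DataFrame(
        np.column_stack(data),
        index=pd.Index(probes["probe_id"], name="probe_id"),
        columns=[c[0] for c in columns],
    )
    sheet = pd.DataFrame(
        [{"array_id": a, "series_id": s, "group": g} for a, s, g in columns]
    ).set_index("array_id")
    return IntensityExperiment(values=values, sample_sheet=sheet), truth


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper: annotation + experiment from one config.

    Returns ``(probes, sites, experiment, truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    probes, sites, truth = simulate_annotation(cfg, rng)
    experiment, truth = simulate_experiment(cfg, probes, truth, rng)
    return probes, sites, experiment, truth


def random_annotation(
    rng: np.random.Generator,
    n_probesets: int = 50,
    max_probes: int = 14,
    max_sites: int = 3,
):
    """Irregular probe/site placements for stress-testing the partition.

    Unlike :func:`simulate_annotation`, probes have random starts and
    lengths, may overlap each other and the cleavage positions, and
    sites fall anywhere in (or just outside) the probed span — the
    degenerate geometries real chip annotation contains.

    Returns ``(probes, sites)``.
    """
    rows, raw = [], []
    for i in range(n_probesets):
        pid = f"R{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        base = int(rng.integers(100, 10_000))
        n_probes = int(rng.integers(2, max_probes + 1))
        span = 60 * n_probes
        for k in range(n_probes):
            start = base + int(rng.integers(0, span))
            length = int(rng.integers(20, 31))
            rows.append(
                {
                    "chrom": "chrR",
                    "start": start,
                    "end": start + length,
                    "probe_id": f"{pid}_p{k:02d}",
                    "probeset_id": pid,
                    "strand": strand,
                }
            )
        positions = rng.choice(
            np.arange(base - 50, base + span + 80),
            size=int(rng.integers(1, max_sites + 1)),
            replace=False,
        )
        raw.extend((pid, "chrR", strand, int(p)) for p in positions)
    return pd.DataFrame(rows), assign_site_order(raw)


def write_dataset(cfg: SimConfig, out_dir) -> dict:
    """Write probes.tsv, sites.bed, matrix.tsv, sample_sheet.tsv and
    truth.tsv for a simulated dataset; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probes, sites, experiment, truth = simulate_dataset(cfg)
    paths = {k: out / v for k, v in {
        "probes": "probes.tsv", "sites": "sites.bed", "matrix": "matrix.tsv",
        "sample_sheet": "sample_sheet.tsv", "truth": "truth.tsv",
        "config": "sim_config.tsv"}.items()}
    probes[["chrom", "start", "end", "probe_id", "probeset_id", "strand"]].to_csv(
        paths["probes"], sep="\t", index=False, header=False
    )
    with open(paths["sites"], "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.cleavage_pos}\t{s.cleavage_pos + 1}\t{s.key}\t0\t{s.strand}\n")
    experiment.values.to_csv(paths["matrix"], sep="\t", float_format="%.6f")
    experiment.sample_sheet.to_csv(paths["sample_sheet"], sep="\t")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg_frame = pd.DataFrame(sorted(asdict(cfg).items()), columns=["parameter", "value"])
    cfg_frame.to_csv(paths["config"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
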