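"""Annotation parsing, proximal/distal partitioning and region classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apascreen import (
    ParseError,
    PolyASite,
    ValidationError,
    classify_positions_by_region,
    read_polya_sites,
    read_probe_alignments,
    split_all_probesets,
    split_probeset,
)
from apascreen.annotation import splits_from_frame, splits_to_frame
from apascreen.simulate import random_annotation

from conftest import make_probes


# ---------------------------------------------------------------- parsing


def test_read_probe_alignments_tsv(tmp_path):
    path = tmp_path / "probes.tsv"
    lines = [f"chr17\t{s}\t{s + 25}\tp{i}\tPS_A\t+" for i, s in enumerate(range(0, 1100, 100))]
    path.write_text("\n".join(lines) + "\n")
    probes = read_probe_alignments(path)
    assert len(probes) == 11
    assert set(probes["probeset_id"]) == {"PS_A"}
    first = probes.iloc[0]
    assert (first["start"], first["end"], first["strand"]) == (0, 25, "+")


def test_read_probe_alignments_bed_with_sidecar(tmp_path):
    bed = tmp_path / "probes.bed"
    bed.write_text("chr1\t10\t35\tpA\t0\t+\nchr1\t50\t75\tpB\t0\t+\n")
    sidecar = tmp_path / "map.tsv"
    sidecar.write_text("pA\tPS_1\npB\tPS_1\n")
    probes = read_probe_alignments(bed, probeset_map=sidecar)
    assert list(probes["probeset_id"]) == ["PS_1", "PS_1"]


def test_read_probe_alignments_one_based(tmp_path):
    path = tmp_path / "probes.tsv"
    path.write_text("chr1\t101\t125\tp1\tPS\t+\n")
    probes = read_probe_alignments(path, one_based=True)
    assert (probes.iloc[0]["start"], probes.iloc[0]["end"]) == (100, 125)


@pytest.mark.parametrize(
    "line, err, fragment",
    [
        ("chr1\t100\t100\tp1\tPS\t+", ValidationError, "empty"),
        ("chr1\t100\tp1\tPS\t+", ParseError, ":1"),
        ("chr1\tX\t120\tp1\tPS\t+", ParseError, "non-integer"),
        ("chr1\t100\t120\tp1\tPS\t*", ParseError, "strand"),
    ],
)
def test_read_probe_alignments_bad_rows(tmp_path, line, err, fragment):
    path = tmp_path / "bad.tsv"
    path.write_text(line + "\n")
    with pytest.raises(err, match=fragment):
        read_probe_alignments(path)


def test_read_polya_sites_order(tmp_path):
    path = tmp_path / "sites.bed"
    path.write_text("chr1\t870\t871\tG1\t0\t+\nchr1\t1500\t1501\tG1\t0\t+\n")
    sites = read_polya_sites(path)
    assert [(s.cleavage_pos, s.order_index) for s in sites] == [(870, 1), (1500, 2)]


def test_read_polya_sites_minus_strand_reverses_order(tmp_path):
    path = tmp_path / "sites.bed"
    path.write_text("chr1\t870\t871\tG1\t0\t-\nchr1\t1500\t1501\tG1\t0\t-\n")
    sites = read_polya_sites(path)
    by_pos = {s.cleavage_pos: s.order_index for s in sites}
    assert by_pos == {1500: 1, 870: 2}


def test_read_polya_sites_single_and_duplicate(tmp_path):
    single = tmp_path / "one.bed"
    single.write_text("chr1\t500\t501\tG2\t0\t+\n")
    assert read_polya_sites(single)[0].order_index == 1
    dup = tmp_path / "dup.bed"
    dup.write_text("chr1\t500\t501\tG2\t0\t+\nchr1\t500\t501\tG2\t0\t+\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_polya_sites(dup)


# ------------------------------------------------------------ partitioning


def test_split_nine_proximal_two_distal(cdc6_like_probes, cdc6_like_site):
    split = split_probeset(cdc6_like_probes, cdc6_like_site, min_per_side=1)
    assert (split.n_prox, split.n_dist) == (9, 2)
    assert split.proximal_probe_ids == frozenset(f"p{i:02d}" for i in range(9))
    assert split.distal_probe_ids == {"p09", "p10"}
    assert not split.excluded_probe_ids


def test_probe_spanning_site_is_excluded(cdc6_like_probes, cdc6_like_site):
    spanning = make_probes([860])
    spanning["probe_id"] = ["px"]
    probes = pd.concat([cdc6_like_probes, spanning], ignore_index=True)
    split = split_probeset(probes, cdc6_like_site, min_per_side=1)
    assert split.excluded_probe_ids == {"px"}
    assert (split.n_prox, split.n_dist) == (9, 2)


def test_site_outside_probed_span_gives_no_split(cdc6_like_probes):
    site = PolyASite(site_id="s", key="PS_A", chrom="chr17", strand="+", cleavage_pos=5000)
    assert split_probeset(cdc6_like_probes, site) is None


def test_min_per_side_filters(cdc6_like_probes, cdc6_like_site):
    assert split_probeset(cdc6_like_probes, cdc6_like_site, min_per_side=2) is not None
    assert split_probeset(cdc6_like_probes, cdc6_like_site, min_per_side=3) is None


def test_chrom_strand_mismatch_raises(cdc6_like_probes):
    site = PolyASite(site_id="s", key="PS_A", chrom="chr17", strand="-", cleavage_pos=870)
    with pytest.raises(ValidationError, match="does not match"):
        split_probeset(cdc6_like_probes, site)


def test_partition_is_complete(cdc6_like_probes, cdc6_like_site):
    split = split_probeset(cdc6_like_probes, cdc6_like_site)
    union = split.proximal_probe_ids | split.distal_probe_ids | split.excluded_probe_ids
    assert union == set(cdc6_like_probes["probe_id"])
    assert not split.proximal_probe_ids & split.distal_probe_ids


@settings(max_examples=50, deadline=None)
@given(st.data())
def test_strand_mirror_symmetry(data):
    """Reflecting all coordinates and flipping strand preserves memberships."""
    starts = data.draw(
        st.lists(st.integers(0, 2000), min_size=2, max_size=12, unique=True)
    )
    pos = data.draw(st.integers(0, 2100))
    probes = make_probes(starts)
    site = PolyASite(site_id="s", key="PS_A", chrom="chr17", strand="+", cleavage_pos=pos)
    fwd = split_probeset(probes, site)

    C = 5000
    mirrored = probes.copy()
    mirrored["start"], mirrored["end"] = C - probes["end"], C - probes["start"]
    mirrored["strand"] = "-"
    msite = PolyASite(site_id="s", key="PS_A", chrom="chr17", strand="-", cleavage_pos=C - pos)
    rev = split_probeset(mirrored, msite)

    if fwd is None:
        assert rev is None
    else:
        assert rev.proximal_probe_ids == fwd.proximal_probe_ids
        assert rev.distal_probe_ids == fwd.distal_probe_ids
        assert rev.excluded_probe_ids == fwd.excluded_probe_ids


def brute_force_splits(probes, sites, min_per_side=1):
    """Independent oracle: classify every probe of every set against every
    site by comparing each covered base to the cleavage point."""
    out = {}
    for site in sites:
        grp = probes[probes["probeset_id"] == site.key]
        if grp.empty:
            continue
        if set(grp["chrom"]) != {site.chrom} or set(grp["strand"]) != {site.strand}:
            continue
        prox, dist, excl = set(), set(), set()
        for row in grp.itertuples(index=False):
            bases = range(row.start, row.end)
            if site.strand == "+":
                upstream = all(b < site.cleavage_pos for b in bases)
                downstream = all(b >= site.cleavage_pos for b in bases)
            else:
                upstream = all(b >= site.cleavage_pos for b in bases)
                downstream = all(b < site.cleavage_pos for b in bases)
            (prox if upstream else dist if downstream else excl).add(row.probe_id)
        if len(prox) >= min_per_side and len(dist) >= min_per_side:
            out[(site.key, site.site_id)] = (
                frozenset(prox), frozenset(dist), frozenset(excl)
            )
    return out


def test_split_all_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        probes, sites = random_annotation(rng, n_probesets=50)
        splits = split_all_probesets(probes, sites, min_per_side=1)
        got = {
            (s.probeset_id, s.site_id): (
                s.proximal_probe_ids, s.distal_probe_ids, s.excluded_probe_ids
            )
            for s in splits
        }
        assert got == brute_force_splits(probes, sites, min_per_side=1)


def test_split_all_ordering_and_roundtrip():
    rng = np.random.default_rng(3)
    probes, sites = random_annotation(rng, n_probesets=20)
    splits = split_all_probesets(probes, sites)
    keys = [(s.probeset_id, s.order_index) for s in splits]
    assert keys == sorted(keys)
    assert splits_from_frame(splits_to_frame(splits)) == splits


def test_split_all_empty_sites(cdc6_like_probes):
    assert split_all_probesets(cdc6_like_probes, []) == []


# ------------------------------------------------------ region classification


def test_region_classification_table1_arithmetic():
    """58 of 67 miRNA-site predictions between P-pA and D-pA -> 87%."""
    positions = list(range(100, 158)) + list(range(0, 9))
    counts = classify_positions_by_region(positions, p_pa=100, d_pa=200)
    assert (counts.common_region, counts.long_specific, counts.outside) == (9, 58, 0)
    assert counts.percent_long_specific == 87


@pytest.mark.parametrize(
    "positions, expected_pct",
    [([10, 20, 150, 160], 50), ([10, 20, 30], 0)],
)
def test_region_classification_small_cases(positions, expected_pct):
    counts = classify_positions_by_region(positions, p_pa=100, d_pa=200)
    assert counts.percent_long_specific == expected_pct


def test_region_classification_boundaries():
    at_p = classify_positions_by_region([100], p_pa=100, d_pa=200)
    assert at_p.long_specific == 1
    at_p_excl = classify_positions_by_region([100], p_pa=100, d_pa=200, p_pa_inclusive=False)
    assert at_p_excl.common_region == 1
    at_d = classify_positions_by_region([200], p_pa=100, d_pa=200)
    assert at_d.outside == 1


def test_region_classification_minus_strand():
    # transcript runs right to left: P-pA at 200, D-pA at 100
    counts = classify_positions_by_region([250, 150, 50], p_pa=200, d_pa=100, strand="-")
    assert (counts.common_region, counts.long_specific, counts.outside) == (1, 1, 1)


def test_region_classification_errors():
    with pytest.raises(ValidationError, match="undefined"):
        classify_positions_by_region([], p_pa=100, d_pa=200)
    with pytest.raises(ValidationError):
        classify_positions_by_region([1], p_pa=200, d_pa=100)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(-500, 500), min_size=1, max_size=40),
    st.integers(-100, 99),
    st.integers(100, 300),
)
def test_region_counts_sum_to_total(positions, p_pa, d_pa):
    counts = classify_positions_by_region(positions, p_pa=p_pa, d_pa=d_pa)
    assert counts.total == len(positions)
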