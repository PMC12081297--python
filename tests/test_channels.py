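"""Channel schemes: cardinalities, partition, merge and catalogs."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import indeltax as ix
from indeltax.channels import (
    apply_merge_map,
    canonical_merge_map,
    consolidate,
    merge_catalog,
    scheme_table,
)
from indeltax.io_formats import Catalog, NormalizedIndel
from indeltax import synthdata as sd

DATA_DIR = Path(ix.__file__).parent / "data"


def test_scheme_cardinalities(full_scheme, ind89_scheme, cosmic83_scheme):
    assert len(full_scheme) == 476
    assert len(ind89_scheme) == 89
    assert len(cosmic83_scheme) == 83
    assert len(ind89_scheme.divisions) == 6


def test_partition_each_indel_maps_to_one_channel(
    fuzzed_indels, full_scheme, ind89_scheme, cosmic83_scheme
):
    """Totality and uniqueness: every fuzzed InDel gets exactly one
    channel id per scheme, and the id exists in the scheme."""
    for scheme in (full_scheme, ind89_scheme, cosmic83_scheme):
        ids = set(scheme.channel_ids)
        for v in fuzzed_indels:
            assert scheme.classify(v) in ids


def test_classify_examples(full_scheme, ind89_scheme, cosmic83_scheme):
    run8_del = NormalizedIndel(
        chrom="c", pos0=10, op_class="deletion", motif="T",
        flank5="AGCAG", flank3="T" * 7 + "A" + "G" * 50)
    assert ind89_scheme.classify(run8_del) == "del1:T:r8"
    assert cosmic83_scheme.classify(run8_del) == "1:Del:T:5"

    run5_ins = NormalizedIndel(
        chrom="c", pos0=10, op_class="insertion", motif="T",
        flank5="AGCAG", flank3="T" * 5 + "A" + "G" * 50)
    assert ind89_scheme.classify(run5_ins) == "ins1:T:r5"
    assert cosmic83_scheme.classify(run5_ins) == "1:Ins:T:5"

    mh = NormalizedIndel(
        chrom="c", pos0=10, op_class="deletion", motif="ACGTT",
        flank5="AGCAG", flank3="ACGAA" + "C" * 50)
    assert ind89_scheme.classify(mh) == "mh:L5+:M3"
    assert full_scheme.classify(mh) == "mh:L5:M3"
    assert cosmic83_scheme.classify(mh) == "5:Del:M:3"

    # purine event is reported on the pyrimidine strand
    a_ins = NormalizedIndel(
        chrom="c", pos0=10, op_class="insertion", motif="A",
        flank5="AGCAC", flank3="G" + "C" * 50)
    assert ind89_scheme.classify(a_ins) == "ins1:T:r0:3G"  # comp(5'=C) = G


def test_merge_map_consistency(fuzzed_indels, full_scheme, ind89_scheme):
    """classify_ind89(x) == merge_map[classify_full(x)] for all fuzz."""
    mm = canonical_merge_map(full_scheme)
    assert set(mm) == set(full_scheme.channel_ids)
    assert set(mm.values()) == set(ind89_scheme.channel_ids)
    for v in fuzzed_indels:
        assert mm[full_scheme.classify(v)] == ind89_scheme.classify(v)


def test_merged_scheme_order_matches_direct_builder(full_scheme, ind89_scheme):
    derived = apply_merge_map(full_scheme, canonical_merge_map(full_scheme))
    assert derived.channel_ids == ind89_scheme.channel_ids


def test_catalog_aggregation_equals_direct_classification(
    fuzzed_indels, full_scheme, ind89_scheme
):
    sub = fuzzed_indels[:4000]
    cat_full = ix.build_catalog(sub, scheme=full_scheme)
    cat_89 = ix.build_catalog(sub, scheme=ind89_scheme)
    merged = merge_catalog(cat_full, canonical_merge_map(full_scheme), ind89_scheme)
    assert merged == cat_89


def test_long_run_1bp_channels_sum_to_cosmic_terminal_bins(
    fuzzed_indels, ind89_scheme, cosmic83_scheme
):
    """The per-length long-run bins of the consolidated scheme aggregate
    exactly onto the legacy scheme's terminal 1 bp bins."""
    sub = [v for v in fuzzed_indels if v.op_class != "complex" and len(v.motif) == 1]
    cat89 = ix.build_catalog(sub, scheme=ind89_scheme)
    cat83 = ix.build_catalog(sub, scheme=cosmic83_scheme)
    for m in "CT":
        del_long = sum(
            cat89.counts[:, ind89_scheme.index_of(f"del1:{m}:r{r}")].sum()
            for r in ["6", "7", "8", "9+"])
        assert del_long == cat83.counts[:, cosmic83_scheme.index_of(f"1:Del:{m}:5")].sum()
        ins_long = sum(
            cat89.counts[:, ind89_scheme.index_of(f"ins1:{m}:r{r}")].sum()
            for r in ["5", "6", "7", "8", "9+"])
        assert ins_long == cat83.counts[:, cosmic83_scheme.index_of(f"1:Ins:{m}:5")].sum()


def test_consolidate_identity_when_fully_populated(full_scheme):
    counts = np.ones((1, 476), dtype=int)
    cat = Catalog(["s"], full_scheme.channel_ids, counts)
    merged, mapping = consolidate(full_scheme, cat, zero_drop=True, low_signal_fraction=0.0)
    assert len(merged) == 476
    assert all(k == v for k, v in mapping.items())


def test_consolidate_drops_zero_signal_channels(full_scheme):
    counts = np.ones((1, 476), dtype=int)
    dead = full_scheme.index_of("mh:L12+:M9+")
    counts[0, dead] = 0
    cat = Catalog(["s"], full_scheme.channel_ids, counts)
    merged, mapping = consolidate(full_scheme, cat)
    assert "mh:L12+:M9+" not in merged.channel_ids
    assert mapping["mh:L12+:M9+"] == "mh:L5+:M4+"


def test_consolidate_to_canonical_89(full_scheme, ind89_scheme):
    # an empty cohort sends every channel to its parent aggregate
    cat = Catalog(["s"], full_scheme.channel_ids, np.zeros((1, 476), dtype=int))
    merged, _ = consolidate(full_scheme, cat, zero_drop=True)
    assert merged.channel_ids == ind89_scheme.channel_ids


def test_build_catalog_counts_and_duplicates(planted, ind89_scheme):
    reference, variants, truth = planted
    cat = ix.build_catalog(variants, reference, ind89_scheme)
    assert cat.counts.sum() == len(variants)
    expected = truth.groupby(["sample_id", "channel_ind89"]).size()
    for (sid, cid), n in expected.items():
        got = cat.counts[cat.sample_ids.index(sid), ind89_scheme.index_of(cid)]
        assert got == n
    # duplicated variant counted twice, no dedup
    dup = ix.build_catalog([variants[0], variants[0]], reference, ind89_scheme)
    assert dup.counts.sum() == 2


def test_empty_variant_list_gives_zero_row(ind89_scheme):
    cat = ix.build_catalog([], scheme=ind89_scheme, sample_ids=["s"])
    assert cat.counts.shape == (1, 89) and cat.counts.sum() == 0


def test_channel_assets_match_builders():
    """The shipped TSV assets are generated from, and must agree with,
    the in-code scheme builders (single source of truth check)."""
    for name in ("full476", "ind89", "cosmic83"):
        asset = pd.read_csv(DATA_DIR / f"channels_{name}.tsv", sep="\t",
                            comment="#", keep_default_na=False)
        table = scheme_table(ix.get_scheme(name)).astype(str)
        pd.testing.assert_frame_equal(asset.astype(str), table)
    mm_asset = pd.read_csv(DATA_DIR / "merge_full476_to_ind89.tsv", sep="\t", comment="#")
    mm = canonical_merge_map()
    assert dict(zip(mm_asset["full476_channel"], mm_asset["ind89_channel"])) == mm


def test_consolidate_everything_low_signal_reaches_canonical_89(full_scheme):
    rng = np.random.default_rng(0)
    cat = Catalog(["s"], full_scheme.channel_ids,
                  rng.integers(1, 5, size=(1, 476)))
    merged, _ = consolidate(full_scheme, cat, low_signal_fraction=1.1)
    assert len(merged) == 89
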