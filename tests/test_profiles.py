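"""Profile statistics: envelopes, subtraction, refitting, testing,
hypermutators, clustering, strand asymmetry and the NMF harness."""

import numpy as np
import pandas as pd
import pytest

import indeltax as ix
from indeltax import profiles as pf
from indeltax import synthdata as sd
from indeltax.io_formats import Catalog, NormalizedIndel, StrandAnnotation


@pytest.fixture(scope="module")
def chan(ind89_scheme):
    return ind89_scheme.channel_ids


# -- cosine -----------------------------------------------------------------


def test_cosine_identity_orthogonal_and_closed_form():
    a = pf.Profile(("x", "y"), np.array([0.3, 0.7]))
    assert pf.cosine(a, a) == pytest.approx(1.0)
    b = pf.Profile(("x", "y"), np.array([1.0, 0.0]))
    c = pf.Profile(("x", "y"), np.array([0.0, 1.0]))
    assert pf.cosine(b, c) == pytest.approx(0.0)
    p = pf.Profile(("x", "y"), np.array([3, 4]) / 7)
    q = pf.Profile(("x", "y"), np.array([4, 3]) / 7)
    assert pf.cosine(p, q) == pytest.approx(24 / 25)
    with pytest.raises(ValueError):
        pf.cosine(np.zeros(2), np.ones(2))


# -- bootstrap envelope -----------------------------------------------------


def test_envelope_null_and_extreme_queries(chan):
    rng = np.random.default_rng(1)
    density = rng.dirichlet(np.ones(89) * 0.4)
    controls = Catalog([f"c{i}" for i in range(7)], chan,
                       np.vstack([rng.multinomial(700, density) for _ in range(7)]))
    env = pf.bootstrap_background_envelope(controls, n_boot=100, seed=2)
    assert env.sd >= 0 and len(env.replicate_cosines) == 100
    assert not env.is_distinct(env.background)
    spike = np.zeros(89)
    spike[int(np.argmin(density))] = 1.0
    assert env.is_distinct(pf.Profile(tuple(chan), spike))
    with pytest.raises(ValueError):
        pf.bootstrap_background_envelope(controls, n_boot=1)


def test_envelope_calibration_null_false_positive_rate(chan):
    """Draws from the background density at control burden are called
    distinct in under 1% of trials at the mean - 3 sd threshold."""
    rng = np.random.default_rng(0)
    density = rng.dirichlet(np.ones(89))
    controls = Catalog([f"c{i}" for i in range(5)], chan,
                       np.vstack([rng.multinomial(2000, density) for _ in range(5)]))
    env = pf.bootstrap_background_envelope(controls, n_boot=1000, seed=100)
    rng2 = np.random.default_rng(200)
    trials = 2000
    false_pos = sum(
        env.is_distinct(pf.Profile.from_counts(
            chan, rng2.multinomial(2000, env.background.densities)))
        for _ in range(trials)
    )
    assert false_pos / trials < 0.01


# -- background subtraction -------------------------------------------------


def test_subtraction_recovers_planted_spike(chan):
    rng = np.random.default_rng(3)
    bg = rng.dirichlet(np.ones(89))
    bg_prof = pf.Profile(tuple(chan), bg)
    spike = np.zeros(89)
    spike[5] = 1.0
    edited_counts = bg * 2000 + spike * 800
    edited = pf.Profile.from_counts(chan, edited_counts)
    sig = pf.subtract_background(edited, edited_counts.sum(), bg_prof, 2000)
    assert int(np.argmax(sig.densities)) == 5
    assert sig.densities[5] > 0.9


def test_subtraction_edge_cases(chan):
    rng = np.random.default_rng(4)
    bg = pf.Profile(tuple(chan), rng.dirichlet(np.ones(89)))
    with pytest.raises(ValueError, match="annihilated"):
        pf.subtract_background(bg, 100.0, bg, 100.0)
    assert pf.subtract_background(bg, 100.0, bg, 0.0) is bg


# -- exposure refitting -----------------------------------------------------


def _block_signatures(chan, k=3, width=4):
    """Orthogonal block signatures with exactly representable mixes."""
    S = np.zeros((len(chan), k))
    for j in range(k):
        S[j * width : (j + 1) * width, j] = 1.0 / width
    return pd.DataFrame(S, index=chan, columns=[f"s{j}" for j in range(k)])


def test_refit_exact_recovery(chan):
    S = _block_signatures(chan)
    E = pd.DataFrame([[400, 80, 1200], [40, 0, 800]],
                     index=["a", "b"], columns=S.columns, dtype=float)
    counts = np.rint(E.to_numpy() @ S.to_numpy().T).astype(int)  # exactly S.E
    cat = Catalog(["a", "b"], list(chan), counts)
    got = pf.refit_exposures(cat, S)
    assert np.allclose(got.to_numpy(), E.to_numpy(), rtol=1e-6, atol=1e-6)


def test_refit_single_signature_and_orthogonal_catalog(chan):
    S = _block_signatures(chan)
    counts = np.zeros((2, len(chan)), dtype=int)
    counts[0, 0:4] = 25            # exactly signature s0, burden 100
    counts[1, 40:44] = 10          # outside every signature's support
    cat = Catalog(["only", "orth"], list(chan), counts)
    got = pf.refit_exposures(cat, S)
    assert got.loc["only"].to_numpy() == pytest.approx([100.0, 0.0, 0.0])
    assert got.loc["orth"].to_numpy() == pytest.approx([0.0, 0.0, 0.0])


def test_refit_residual_nonincreasing_with_generating_signature(chan):
    rng = np.random.default_rng(5)
    S3 = pd.DataFrame(rng.dirichlet(np.ones(89), size=3).T, index=chan,
                      columns=["s0", "s1", "s2"])
    extra = pd.Series(rng.dirichlet(np.ones(89)), index=chan, name="gen")
    counts = np.rint(extra.to_numpy() * 5000).astype(int)[None, :]
    cat = Catalog(["x"], list(chan), counts)

    def resid(sigs):
        e = pf.refit_exposures(cat, sigs)
        return float(np.abs(cat.counts[0] - pf.reconstruct(sigs, e)[0]).sum())

    assert resid(pd.concat([S3, extra], axis=1)) <= resid(S3) + 1e-9


# -- excess variation -------------------------------------------------------


def test_excess_variation_deterministic_and_spike_sensitive(chan):
    rng = np.random.default_rng(6)
    S = pd.DataFrame(rng.dirichlet(np.ones(89) * 2, size=2).T, index=chan,
                     columns=["s0", "s1"])
    density = (S.to_numpy() @ [0.6, 0.4])
    y = rng.multinomial(1000, density / density.sum())
    r1 = pf.excess_variation_test(y, S, n_sim=300, seed=11)
    r2 = pf.excess_variation_test(y, S, n_sim=300, seed=11)
    assert r1.p == r2.p
    # a large unmodeled spike must be detected at the simulation floor
    y_spiked = y.copy()
    y_spiked[int(np.argmin(density))] += 600
    r3 = pf.excess_variation_test(y_spiked, S, n_sim=300, seed=12)
    assert r3.p <= 1 / 300


def test_excess_variation_cohort_flags_with_bh(chan):
    rng = np.random.default_rng(13)
    S = pd.DataFrame(rng.dirichlet(np.ones(89) * 2, size=2).T, index=chan,
                     columns=["s0", "s1"])
    density = S.to_numpy() @ [0.5, 0.5]
    density /= density.sum()
    counts = np.vstack([rng.multinomial(600, density) for _ in range(8)])
    counts[0, int(np.argmin(density))] += 500  # one clear outlier
    cat = Catalog([f"s{i}" for i in range(8)], list(chan), counts)
    out = pf.excess_variation_cohort(cat, S, n_sim=300, seed=14)
    assert bool(out["excess_variation"].iloc[0])
    assert (out["q"] >= out["p"] - 1e-12).all()


# -- hypermutators ----------------------------------------------------------


def test_hypermutators_unimodal_only_iqr_outliers(chan):
    rng = np.random.default_rng(15)
    density = rng.dirichlet(np.ones(89))
    burdens = rng.integers(400, 600, size=30)
    counts = np.vstack([rng.multinomial(b, density) for b in burdens])
    cat = Catalog([f"s{i}" for i in range(30)], list(chan), counts)
    out = pf.detect_hypermutators(cat)
    q1, q3 = np.percentile(out["burden"], [25, 75])
    iqr_out = (out["burden"] > q3 + 1.5 * (q3 - q1)).sum()
    assert (out["label"] == "hypermutator").sum() <= max(iqr_out, 2)


def test_hypermutators_planted_tenfold_subpopulation(chan):
    rng = np.random.default_rng(16)
    density = rng.dirichlet(np.ones(89))
    burdens = np.concatenate([rng.integers(300, 500, 40),
                              rng.integers(3500, 4500, 6)])
    counts = np.vstack([rng.multinomial(int(b), density) for b in burdens])
    cat = Catalog([f"s{i}" for i in range(46)], list(chan), counts)
    out = pf.detect_hypermutators(cat)
    assert (out["label"].to_numpy()[40:] == "hypermutator").all()


def test_hypermutators_degenerate_two_samples(chan):
    rng = np.random.default_rng(17)
    counts = np.vstack([rng.multinomial(300, rng.dirichlet(np.ones(89)))
                        for _ in range(2)])
    cat = Catalog(["a", "b"], list(chan), counts)
    out = pf.detect_hypermutators(cat)  # IQR rule only, no crash
    assert set(out["label"]) <= {"normal", "hypermutator"}
    assert (pf.detect_hypermutators(cat)["burden"] >= 100).all()


def test_hypermutators_min_burden_filter(chan):
    counts = np.zeros((3, 89), dtype=int)
    counts[0, 0] = 50   # below the burden floor, removed
    counts[1, 0] = 400
    counts[2, 0] = 420
    cat = Catalog(["low", "a", "b"], list(chan), counts)
    out = pf.detect_hypermutators(cat)
    assert "low" not in out.index


# -- signature clustering ---------------------------------------------------


def test_cluster_signatures_families_and_order_invariance(chan):
    rng = np.random.default_rng(18)
    fam1 = rng.dirichlet(np.ones(10))
    fam2 = rng.dirichlet(np.ones(10))
    cols = {}
    for i in range(4):
        v = np.zeros(89)
        v[:10] = fam1 + rng.normal(0, 0.003, 10).clip(0)
        cols[f"a{i}"] = v / v.sum()
    for i in range(4):
        v = np.zeros(89)
        v[40:50] = fam2 + rng.normal(0, 0.003, 10).clip(0)
        cols[f"b{i}"] = v / v.sum()
    sigs = pd.DataFrame(cols, index=chan)
    _, labels = pf.cluster_signatures(sigs)
    parts = {frozenset(labels.index[labels == c]) for c in labels.unique()}
    expected = {frozenset(f"a{i}" for i in range(4)),
                frozenset(f"b{i}" for i in range(4))}
    assert parts == expected
    # permuted column order yields the same partition
    perm = sigs[list(rng.permutation(sigs.columns))]
    _, labels2 = pf.cluster_signatures(perm)
    assert {frozenset(labels2.index[labels2 == c]) for c in labels2.unique()} == expected


def test_cluster_signatures_duplicates_and_singleton(chan):
    rng = np.random.default_rng(19)
    v = rng.dirichlet(np.ones(89))
    sigs = pd.DataFrame({"dup1": v, "dup2": v, "other": rng.dirichlet(np.ones(89))},
                        index=chan)
    Z, labels = pf.cluster_signatures(sigs)
    assert labels["dup1"] == labels["dup2"]
    assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)  # zero-distance pair merges first
    _, single = pf.cluster_signatures(sigs[["dup1"]])
    assert list(single) == [1]


# -- strand asymmetry -------------------------------------------------------


def _asym_setup(seed, planted_strand=None, n_events=300):
    """Reference with T homopolymers, alternating annotation, and 1 bp
    deletions either uniform or confined to one strand label."""
    rng = np.random.default_rng(seed)
    reqs = [{"op": "del1", "base": b, "run": r, "count": 30}
            for b in "TA" for r in (5, 6, 7)]
    ref, feats = sd.make_reference(sd.reference_spec_for(reqs, seed=seed))
    ann = sd.simulate_strand_annotation(ref, 120, seed=seed + 1)
    variants, _ = sd.plant_indels(ref, feats, seed=seed + 2)
    normed = [ix.normalize(v, ref) for v in variants]
    if planted_strand is not None:
        kept = []
        for v in normed:
            lab = ann.label_at(v.chrom, v.pos0 + 1)
            if lab is None:
                continue
            if v.motif in "AG":
                lab = "leading" if lab == "lagging" else "lagging"
            if lab == planted_strand:
                kept.append(v)
        normed = kept
    return normed, ann, ref


def test_asymmetry_null_no_significant_groups():
    normed, ann, ref = _asym_setup(21)
    res = pf.strand_asymmetry(normed, ann, ref)
    assert len(res) > 0
    assert (res["q"] > 0.05).all()
    assert ((res["odds_ratio"] > 0.25) & (res["odds_ratio"] < 4.0)).all()


def test_asymmetry_planted_leading_bias_detected():
    normed, ann, ref = _asym_setup(22, planted_strand="leading")
    res = pf.strand_asymmetry(normed, ann, ref)
    big = res[res["leading"] + res["lagging"] >= 20]
    assert (big["odds_ratio"] > 3).all()
    assert (big["q"] < 0.05).any()


def test_asymmetry_label_swap_reciprocity():
    normed, ann, ref = _asym_setup(23, planted_strand="leading")
    swapped = StrandAnnotation(tuple(
        (c, s, e, "leading" if lab == "lagging" else "lagging")
        for c, s, e, lab in ann.intervals))
    r1 = pf.strand_asymmetry(normed, ann, ref).set_index(["op_class", "motif", "run_bin"])
    r2 = pf.strand_asymmetry(normed, swapped, ref).set_index(["op_class", "motif", "run_bin"])
    common = r1.index.intersection(r2.index)
    assert len(common) > 0
    for key in common:
        assert r1.loc[key, "odds_ratio"] == pytest.approx(
            1.0 / r2.loc[key, "odds_ratio"])


def test_asymmetry_missing_strand_class_fatal():
    normed, ann, ref = _asym_setup(24)
    only_leading = StrandAnnotation(tuple(
        (c, s, e, "leading") for c, s, e, lab in ann.intervals))
    with pytest.raises(ValueError):
        pf.strand_asymmetry(normed, only_leading, ref)


# -- de novo harness --------------------------------------------------------


def test_denovo_rank_recovery_two_orthogonal_signatures(chan):
    rng = np.random.default_rng(25)
    s1 = np.zeros(89); s1[:8] = rng.dirichlet(np.ones(8))
    s2 = np.zeros(89); s2[30:38] = rng.dirichlet(np.ones(8))
    sigs = pd.DataFrame({"A": s1, "B": s2}, index=chan)
    expo = pd.DataFrame(rng.integers(200, 2000, size=(40, 2)).astype(float),
                        index=[f"m{i}" for i in range(40)], columns=["A", "B"])
    cat = sd.simulate_catalogs(sigs, expo, seed=26)
    res = pf.extract_denovo(cat, range(1, 4), n_boot=10, seed=27)
    assert res.rank == 2
    recovered = res.signatures.to_numpy().T
    for truth in (s1, s2):
        assert max(pf.cosine(r, truth) for r in recovered) >= 0.95


def test_denovo_rank_one_catalog(chan):
    rng = np.random.default_rng(28)
    s1 = rng.dirichlet(np.ones(89))
    sigs = pd.DataFrame({"A": s1}, index=chan)
    expo = pd.DataFrame({"A": rng.integers(300, 3000, 30).astype(float)},
                        index=[f"m{i}" for i in range(30)])
    cat = sd.simulate_catalogs(sigs, expo, seed=29)
    res = pf.extract_denovo(cat, range(1, 4), n_boot=10, seed=30)
    assert res.rank == 1


def test_denovo_k_max_guard(chan):
    cat = Catalog(["a", "b"], list(chan), np.ones((2, 89), dtype=int))
    with pytest.raises(ValueError):
        pf.extract_denovo(cat, range(1, 3), seed=0)
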