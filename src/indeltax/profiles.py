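"""Profile statistics: bootstrap envelopes, background subtraction,
exposure refitting, excess-variation testing, hypermutator detection,
signature clustering and replicative strand asymmetry.

A *profile* is a per-channel density (counts normalized to 1); a
*catalog* keeps raw counts so that sampling noise can be modelled at
the observed burden.  Signature matrices are channels x signatures with
unit column sums; exposures are samples x signatures mutation counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binomtest, chi2_contingency
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .io_formats import Catalog, NormalizedIndel, StrandAnnotation
from .segmentation import homopolymer_run

log = logging.getLogger("indeltax")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYR = {"A": "T", "G": "C", "C": "C", "T": "T"}


# ---------------------------------------------------------------------------
# profiles and cosine similarity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Profile:
    channel_ids: tuple[str, ...]
    densities: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "densities", d)
        if d.shape != (len(self.channel_ids),):
            raise ValueError("density length does not match channels")
        if (d < 0).any():
            raise ValueError("densities must be non-negative")
        if abs(d.sum() - 1.0) > 1e-9:
            raise ValueError("densities must sum to 1")

    @classmethod
    def from_counts(cls, channel_ids, counts) -> "Profile":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("cannot form a profile from an empty count vector")
        return cls(tuple(channel_ids), counts / total)


def cosine(p: Profile | np.ndarray, q: Profile | np.ndarray) -> float:
    """Cosine similarity of two profiles on the same channel set."""
    if isinstance(p, Profile) and isinstance(q, Profile):
        if p.channel_ids != q.channel_ids:
            raise ValueError("profiles are on different channel sets")
        a, b = p.densities, q.densities
    else:
        a = p.densities if isinstance(p, Profile) else np.asarray(p, float)
        b = q.densities if isinstance(q, Profile) else np.asarray(q, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


# ---------------------------------------------------------------------------
# bootstrap background envelope
# ---------------------------------------------------------------------------


@dataclass
class BootstrapEnvelope:
    """Null distribution of cosine(control resample, background).

    A query profile is called distinct from background when its cosine
    to the background falls below ``mean - 3 sd`` of the replicates.
    """

    replicate_cosines: np.ndarray
    background: Profile
    control_burdens: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.replicate_cosines.mean())

    @property
    def sd(self) -> float:
        return float(self.replicate_cosines.std(ddof=1))

    @property
    def threshold(self) -> float:
        return self.mean - 3.0 * self.sd

    def is_distinct(self, query: Profile) -> bool:
        return cosine(query, self.background) < self.threshold


def bootstrap_background_envelope(
    control_catalog: Catalog, n_boot: int = 100, seed: int | None = None
) -> BootstrapEnvelope:
    """Aggregate control samples into a background profile and measure
    how far multinomial resamples at each control's own burden stray
    from it (cosine similarity, n_boot replicates)."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if len(control_catalog.sample_ids) < 1:
        raise ValueError("at least one control sample is required")
    rng = np.random.default_rng(seed)
    agg = control_catalog.counts.sum(axis=0)
    background = Profile.from_counts(control_catalog.channel_ids, agg)
    burdens = control_catalog.burdens
    sims = np.empty(n_boot)
    for i in range(n_boot):
        burden = int(burdens[i % len(burdens)])
        draw = rng.multinomial(burden, background.densities)
        sims[i] = cosine(draw.astype(float), background.densities)
    return BootstrapEnvelope(sims, background, burdens.astype(int))


def subtract_background(
    edited_profile: Profile,
    edited_burden: float,
    background_profile: Profile,
    background_burden: float,
) -> Profile:
    """Remove the expected background contribution from an edited
    clone's profile: ``max(0, edited_counts - background_density *
    background_burden)``, renormalized.  A zero background burden
    returns the edited profile unchanged."""
    if edited_burden <= 0:
        raise ValueError("edited burden must be positive")
    if background_burden < 0:
        raise ValueError("background burden must be non-negative")
    if background_burden == 0:
        return edited_profile
    if edited_profile.channel_ids != background_profile.channel_ids:
        raise ValueError("profiles are on different channel sets")
    residual = np.maximum(
        0.0,
        edited_profile.densities * edited_burden
        - background_profile.densities * background_burden,
    )
    if residual.sum() <= 0:
        raise ValueError("background subtraction annihilated the profile; no signature")
    return Profile.from_counts(edited_profile.channel_ids, residual)


# ---------------------------------------------------------------------------
# exposure refitting
# ---------------------------------------------------------------------------


def _nnls_fit(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _ = nnls(S, y)
    return coef


def refit_exposures(
    catalog: Catalog,
    signatures: pd.DataFrame,
    sparsity_threshold: float = 0.0,
) -> pd.DataFrame:
    """Non-negative least-squares signature exposures per sample.

    Exposures at or below ``sparsity_threshold`` (mutation counts) are
    zeroed and the remaining signatures re-fit.  Returns samples x
    signatures mutation counts.
    """
    if list(signatures.index) != list(catalog.channel_ids):
        raise ValueError("signature channels do not match the catalog")
    S = signatures.to_numpy(dtype=float)
    S = S / S.sum(axis=0, keepdims=True)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        log.warning("signature matrix is rank deficient; NNLS solution may be non-unique")
    rows = []
    for i in range(len(catalog.sample_ids)):
        y = catalog.counts[i].astype(float)
        coef = _nnls_fit(S, y)
        if sparsity_threshold > 0:
            keep = coef > sparsity_threshold
            if keep.any() and not keep.all():
                coef = np.zeros_like(coef)
                coef[keep] = _nnls_fit(S[:, keep], y)
        rows.append(coef)
    return pd.DataFrame(rows, index=catalog.sample_ids, columns=signatures.columns)


def reconstruct(signatures: pd.DataFrame, exposures: pd.DataFrame) -> np.ndarray:
    S = signatures.to_numpy(dtype=float)
    S = S / S.sum(axis=0, keepdims=True)
    return exposures.to_numpy(dtype=float) @ S.T


# ---------------------------------------------------------------------------
# excess-variation testing (parametric bootstrap)
# ---------------------------------------------------------------------------


@dataclass
class ExcessVariationResult:
    p: float
    observed_error: float
    simulated_errors: np.ndarray = field(repr=False)


def _refit_error(S: np.ndarray, y: np.ndarray) -> float:
    """L1 residual of an NNLS refit, normalized by the burden."""
    coef = _nnls_fit(S, y)
    return float(np.abs(y - S @ coef).sum() / y.sum())


def excess_variation_test(
    sample_counts: np.ndarray,
    signatures: pd.DataFrame,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> ExcessVariationResult:
    """Parametric-bootstrap test for unexplained profile variation.

    The sample is refit against the signature set; its reconstruction
    defines a multinomial null at the sample's burden.  ``n_sim``
    profiles are simulated from that null, each refit, and the fitting
    error (L1 residual / burden) distribution gives an empirical p
    value: the fraction of simulated errors at least as large as the
    observed one.
    """
    if n_sim < 100:
        log.warning("excess_variation_test: n_sim=%d gives an unstable p value", n_sim)
    y = np.asarray(sample_counts, dtype=float)
    burden = y.sum()
    if burden < 1:
        raise ValueError("sample burden must be >= 1")
    rng = np.random.default_rng(seed)
    S = signatures.to_numpy(dtype=float)
    S = S / S.sum(axis=0, keepdims=True)
    coef = _nnls_fit(S, y)
    recon = S @ coef
    if recon.sum() <= 0:
        raise ValueError("empty reconstruction; cannot build the null")
    density = recon / recon.sum()
    observed = float(np.abs(y - recon).sum() / burden)
    sims = np.empty(n_sim)
    n = int(round(burden))
    for i in range(n_sim):
        draw = rng.multinomial(n, density).astype(float)
        sims[i] = _refit_error(S, draw)
    p = float((sims >= observed).mean())
    return ExcessVariationResult(p, observed, sims)


def excess_variation_cohort(
    catalog: Catalog,
    signatures: pd.DataFrame,
    n_sim: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-sample excess-variation p values with Benjamini-Hochberg
    control of the false-discovery rate at ``alpha``."""
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(catalog.sample_ids))
    recs = []
    for i, sid in enumerate(catalog.sample_ids):
        res = excess_variation_test(catalog.counts[i], signatures, n_sim=n_sim, seed=int(seeds[i]))
        recs.append({"sample_id": sid, "p": res.p, "observed_error": res.observed_error})
    out = pd.DataFrame(recs).set_index("sample_id")
    flagged, q, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["excess_variation"] = flagged
    return out


# ---------------------------------------------------------------------------
# hypermutator detection
# ---------------------------------------------------------------------------


def _silhouette_cut(D: np.ndarray, Z: np.ndarray, k_max: int) -> np.ndarray:
    """Flat clusters at the dendrogram cut maximizing mean silhouette."""
    n = D.shape[0]
    best_labels = np.ones(n, dtype=int)
    best_score = -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(Z, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(D, labels, metric="precomputed")
        if score > best_score:
            best_score, best_labels = score, labels
    return best_labels


def detect_hypermutators(catalog: Catalog, min_burden: int = 100) -> pd.DataFrame:
    """Flag burden outliers relative to their profile cluster.

    Samples under ``min_burden`` InDels are removed first.  Remaining
    profiles are clustered (complete linkage, cosine distance; cut at
    the silhouette-optimal height) and within each cluster a one- vs
    two-component Gaussian mixture on burden is chosen by BIC.
    Hypermutators are the union of global IQR outliers
    (burden > Q3 + 1.5 IQR) and samples assigned with > 50% probability
    to the higher-mean component of a winning two-component fit.
    Clusters with fewer than 3 samples skip the mixture fit.
    """
    keep = catalog.burdens >= min_burden
    if not keep.any():
        raise ValueError("no samples pass the minimum burden filter")
    ids = [s for s, k in zip(catalog.sample_ids, keep) if k]
    counts = catalog.counts[keep]
    burdens = counts.sum(axis=1).astype(float)
    n = len(ids)

    if n >= 10:
        dens = counts / burdens[:, None]
        D = squareform(pdist(dens, metric="cosine"))
        Z = linkage(pdist(dens, metric="cosine"), method="complete")
        clusters = _silhouette_cut(D, Z, k_max=8)
    else:
        log.info("detect_hypermutators: %d samples; IQR rule only", n)
        clusters = np.ones(n, dtype=int)

    q1, q3 = np.percentile(burdens, [25, 75])
    iqr_flag = burdens > q3 + 1.5 * (q3 - q1)

    gmm_flag = np.zeros(n, dtype=bool)
    if n >= 10:
        for c in np.unique(clusters):
            idx = np.where(clusters == c)[0]
            if len(idx) < 3:
                continue
            x = burdens[idx].reshape(-1, 1)
            g1 = GaussianMixture(1, random_state=0).fit(x)
            g2 = GaussianMixture(2, random_state=0).fit(x)
            if g2.bic(x) < g1.bic(x):
                hi = int(np.argmax(g2.means_.ravel()))
                post = g2.predict_proba(x)[:, hi]
                gmm_flag[idx[post > 0.5]] = True

    return pd.DataFrame(
        {
            "cluster": clusters,
            "burden": burdens.astype(int),
            "label": np.where(iqr_flag | gmm_flag, "hypermutator", "normal"),
        },
        index=pd.Index(ids, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# signature clustering
# ---------------------------------------------------------------------------


def cluster_signatures(
    signatures: pd.DataFrame,
    method: str = "average",
    metric: str = "cosine",
) -> tuple[np.ndarray, pd.Series]:
    """Hierarchical clustering of signature columns; flat clusters at
    the silhouette-optimal dendrogram cut.  Returns (linkage matrix,
    per-signature cluster labels)."""
    X = signatures.to_numpy(dtype=float).T
    names = list(signatures.columns)
    if X.shape[0] == 1:
        return np.empty((0, 4)), pd.Series([1], index=names)
    dist = pdist(X, metric=metric)
    Z = linkage(dist, method=method)
    labels = _silhouette_cut(squareform(dist), Z, k_max=X.shape[0] - 1)
    return Z, pd.Series(labels, index=names)


# ---------------------------------------------------------------------------
# replicative strand asymmetry
# ---------------------------------------------------------------------------

_RUN_BINS: tuple[tuple[int, int | None], ...] = ((0, 4), (5, 7), (8, None))


def _run_bin_label(run: int) -> str:
    for lo, hi in _RUN_BINS:
        if run >= lo and (hi is None or run <= hi):
            return f"{lo}-{hi}" if hi is not None else f"{lo}+"
    raise AssertionError


def _count_run_loci(seq: str, base: str, lo: int, hi: int | None) -> int:
    """Maximal runs of ``base`` in ``seq`` with length in [max(lo,1), hi]."""
    lo = max(lo, 1)
    count = 0
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            run = j - i
            if run >= lo and (hi is None or run <= hi):
                count += 1
            i = j
        else:
            i += 1
    return count


def strand_asymmetry(
    variants_1bp: list[NormalizedIndel],
    annotation: StrandAnnotation,
    reference,
    test: str = "binomial",
) -> pd.DataFrame:
    """Leading/lagging replication-strand bias of 1 bp InDels.

    InDels are pyrimidine-aligned: an event whose reference motif is a
    purine has its pyrimidine context on the reverse strand, so the
    region's strand label is flipped for it.  Observed counts per
    channel group (op x pyrimidine base x run bin) are compared with the
    expected leading/lagging split given the matching homopolymer locus
    content of the annotated regions; the odds ratio, a binomial (or
    chi-square) p value and Benjamini-Hochberg q values are reported.
    """
    from .io_formats import fetch  # local import to avoid cycles at module load

    labels = {lab for *_, lab in annotation.intervals}
    if "leading" not in labels or "lagging" not in labels:
        raise ValueError("annotation must contain both leading and lagging intervals")

    obs: dict[tuple[str, str, str], dict[str, int]] = {}
    excluded = 0
    for v in variants_1bp:
        if v.op_class not in ("insertion", "deletion") or len(v.motif) != 1:
            raise ValueError("strand_asymmetry accepts 1 bp insertions/deletions only")
        lab = annotation.label_at(v.chrom, v.pos0 + 1)
        if lab is None:
            excluded += 1
            continue
        if v.motif in "AG":  # pyrimidine on the reverse strand
            lab = "leading" if lab == "lagging" else "lagging"
        run = homopolymer_run(v)
        key = (v.op_class, _PYR[v.motif], _run_bin_label(run))
        obs.setdefault(key, {"leading": 0, "lagging": 0})[lab] += 1
    if excluded:
        log.info("strand_asymmetry: %d InDels outside annotated regions excluded", excluded)

    # expected locus content per (pyrimidine base, run bin) and strand
    region_seqs = {
        lab: [fetch(reference, c, s, e) for c, s, e, l in annotation.intervals if l == lab]
        for lab in ("leading", "lagging")
    }
    expected: dict[tuple[str, str], dict[str, float]] = {}
    for pyr in "CT":
        for lo, hi in _RUN_BINS:
            bin_label = f"{lo}-{hi}" if hi is not None else f"{lo}+"
            exp = {"leading": 0.0, "lagging": 0.0}
            for lab in ("leading", "lagging"):
                for seq in region_seqs[lab]:
                    # pyrimidine-strand loci on the forward strand
                    exp[lab] += _count_run_loci(seq, pyr, lo, hi)
                    # purine runs carry the locus on the reverse strand
                    flipped = "leading" if lab == "lagging" else "lagging"
                    exp[flipped] += _count_run_loci(seq, _COMP[pyr], lo, hi)
            expected[(pyr, bin_label)] = exp

    rows = []
    for (op, pyr, bin_label), counts in sorted(obs.items()):
        exp = expected[(pyr, bin_label)]
        if exp["leading"] == 0 or exp["lagging"] == 0:
            log.warning(
                "strand_asymmetry: no matching loci on one strand for group %s; skipped",
                (op, pyr, bin_label),
            )
            continue
        n_lead, n_lag = counts["leading"], counts["lagging"]
        total = n_lead + n_lag
        if total == 0:
            continue
        p_exp = exp["leading"] / (exp["leading"] + exp["lagging"])
        if test == "binomial":
            p = binomtest(n_lead, total, p_exp).pvalue
        elif test == "chi2":
            table = [[n_lead, n_lag],
                     [exp["leading"], exp["lagging"]]]
            p = chi2_contingency(table)[1]
        else:
            raise ValueError(f"unknown test {test!r}")
        obs_ratio = (n_lead + 0.5) / (n_lag + 0.5)
        exp_ratio = exp["leading"] / exp["lagging"]
        rows.append({
            "op_class": op, "motif": pyr, "run_bin": bin_label,
            "leading": n_lead, "lagging": n_lag,
            "expected_leading": exp["leading"], "expected_lagging": exp["lagging"],
            "odds_ratio": obs_ratio / exp_ratio, "p": float(p),
        })
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
    return out


# ---------------------------------------------------------------------------
# de novo factorization harness
# ---------------------------------------------------------------------------


@dataclass
class DenovoResult:
    signatures: pd.DataFrame
    rank: int
    stability: pd.Series  # mean silhouette / stability per candidate rank


def _nmf_signatures(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    model = NMF(n_components=k, init="random", random_state=seed, max_iter=3000, tol=1e-5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X)
    H = model.components_
    H = H[H.sum(axis=1) > 0]  # degenerate all-zero components carry no signature
    return H / H.sum(axis=1, keepdims=True)  # rows sum to 1


def extract_denovo(
    catalog: Catalog,
    k_range=range(1, 5),
    n_boot: int = 12,
    seed: int | None = None,
    stability_threshold: float = 0.9,
) -> DenovoResult:
    """Bootstrap NMF rank selection by signature-cluster stability.

    For each candidate rank, samples are resampled with replacement and
    factorized; the pooled replicate signatures are clustered back into
    k groups and scored by mean silhouette width (cosine distance).
    Rank 1 stability is the mean cosine of replicate signatures to
    their centroid.  The selected rank is the largest whose replicate
    clustering is stable (silhouette >= ``stability_threshold``) — the
    rank just before the silhouette width collapses, mirroring
    signature-number selection by maximal silhouette drop.  This is a
    property-testing harness, not a production extractor.
    """
    k_range = sorted(k_range)
    n_samples = len(catalog.sample_ids)
    if k_range[-1] >= n_samples:
        raise ValueError("k_max must be smaller than the number of samples")
    rng = np.random.default_rng(seed)
    X = catalog.counts.astype(float)
    stability: dict[int, float] = {}
    for k in k_range:
        sigs = []
        for b in range(n_boot):
            idx = rng.integers(0, n_samples, size=n_samples)
            Xb = X[idx]
            Xb = Xb[Xb.sum(axis=1) > 0]
            sigs.append(_nmf_signatures(Xb, k, seed=int(rng.integers(0, 2**31 - 1))))
        P = np.vstack(sigs)
        if k == 1:
            centroid = P.mean(axis=0)
            centroid /= np.linalg.norm(centroid)
            Pn = P / np.linalg.norm(P, axis=1, keepdims=True)
            stability[k] = float((Pn @ centroid).mean())
        else:
            dist = pdist(P, metric="cosine")
            labels = fcluster(linkage(dist, method="average"), k, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                stability[k] = 0.0
            else:
                stability[k] = float(
                    silhouette_score(squareform(dist), labels, metric="precomputed")
                )
    stable = [k for k, s in stability.items() if s >= stability_threshold]
    rank = max(stable) if stable else min(stability)
    H = _nmf_signatures(X, rank, seed=int(rng.integers(0, 2**31 - 1)))
    sigs = pd.DataFrame(
        H.T, index=catalog.channel_ids,
        columns=[f"Denovo{i + 1}" for i in range(rank)],
    )
    return DenovoResult(sigs, rank, pd.Series(stability, name="stability"))
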