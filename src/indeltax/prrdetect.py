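"""PRRDetect: a multinomial elastic-net classifier of post-replicative
repair status.

Tumors are classified into four classes — mismatch-repair deficient
(MMRd), replicative-polymerase proofreading dysfunction (Pol-dys),
mixed MMRd/Pol-dys, and PRR-proficient (Neg) — from seven genomic
features: grouped exposures of MMRd-, Pol-dys- and mixed-associated
substitution signatures (SBS 6/15/26/44/97; SBS 10a/10d; SBS 14/20),
the corresponding InDel signature groups (InD 7/19; InD 14/15;
InD 16a/16b/20/21), and the total InDel-to-SNV ratio.  Features are
log2 transformed and z-scored using training-set moments; the model is
fit by repeated cross-validated grid search over the elastic-net
mixing (alpha) and penalty strength (lambda), minimizing multinomial
log loss.  A sample is called PRR-proficient when P(Neg) > 0.5,
otherwise the highest-probability positive class is assigned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, precision_recall_curve, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .synthdata import IND_GROUPS, SBS_GROUPS

log = logging.getLogger("indeltax")

CLASSES = ("MMRd", "Pol-dys", "MMRd/Pol-dys", "Neg")
FEATURES = ("f1_sbs_mmrd", "f2_sbs_pol", "f3_sbs_mixed",
            "f4_ind_mmrd", "f5_ind_pol", "f6_ind_mixed", "f7_indel_snv_ratio")

_SBS_FEATURE_GROUPS = {
    "f1_sbs_mmrd": SBS_GROUPS["MMRd"],
    "f2_sbs_pol": SBS_GROUPS["Pol-dys"],
    "f3_sbs_mixed": SBS_GROUPS["MMRd/Pol-dys"],
}
_IND_FEATURE_GROUPS = {
    "f4_ind_mmrd": IND_GROUPS["MMRd"],
    "f5_ind_pol": IND_GROUPS["Pol-dys"],
    "f6_ind_mixed": IND_GROUPS["MMRd/Pol-dys"],
}

#: log2 pseudocounts per normalization mode (raw counts vs proportions)
PSEUDOCOUNT = {"absolute": 1.0, "proportional": 1e-6}


def _group_sum(exposures: pd.DataFrame, names: list[str]) -> pd.Series:
    missing = [n for n in names if n not in exposures.columns]
    if missing:
        log.warning("exposure table lacks signatures %s; treated as 0", missing)
    present = [n for n in names if n in exposures.columns]
    if not present:
        return pd.Series(0.0, index=exposures.index)
    return exposures[present].sum(axis=1)


def build_features(
    sbs_exposures: pd.DataFrame,
    ind_exposures: pd.DataFrame,
    counts: pd.DataFrame,
    mode: str = "proportional",
) -> pd.DataFrame:
    """Seven-feature table (samples x features).

    In proportional mode the three SBS group sums are divided by each
    sample's total SBS exposure and the InD group sums by the total InD
    exposure; f7 is always indel_count / snv_count.
    """
    if mode not in PSEUDOCOUNT:
        raise ValueError(f"unknown mode {mode!r}")
    if (counts["snv_count"] <= 0).any():
        bad = counts.index[counts["snv_count"] <= 0].tolist()
        raise ValueError(f"snv_count must be positive; offending samples: {bad}")
    idx = sbs_exposures.index
    if not (ind_exposures.index.equals(idx) and counts.index.equals(idx)):
        raise ValueError("exposure and count tables must share the same sample index")
    out = pd.DataFrame(index=idx)
    for feat, names in _SBS_FEATURE_GROUPS.items():
        out[feat] = _group_sum(sbs_exposures, names)
    for feat, names in _IND_FEATURE_GROUPS.items():
        out[feat] = _group_sum(ind_exposures, names)
    if mode == "proportional":
        sbs_tot = sbs_exposures.sum(axis=1).replace(0.0, np.nan)
        ind_tot = ind_exposures.sum(axis=1).replace(0.0, np.nan)
        for feat in _SBS_FEATURE_GROUPS:
            out[feat] = (out[feat] / sbs_tot).fillna(0.0)
        for feat in _IND_FEATURE_GROUPS:
            out[feat] = (out[feat] / ind_tot).fillna(0.0)
    out["f7_indel_snv_ratio"] = counts["indel_count"] / counts["snv_count"]
    return out[list(FEATURES)]


# ---------------------------------------------------------------------------
# feature transform
# ---------------------------------------------------------------------------


def transform(
    features: pd.DataFrame,
    mu: pd.Series | None = None,
    sigma: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """log2(x + pseudocount) then z-score: x' = (log2(x+pc) - mu)/sigma.

    When ``mu``/``sigma`` are omitted they are estimated from
    ``features`` (training data) and returned for reuse at prediction
    time.  A zero training standard deviation is fatal.
    """
    logged = np.log2(features + pseudocount)
    if mu is None:
        mu = logged.mean(axis=0)
    if sigma is None:
        sigma = logged.std(axis=0, ddof=0)
    bad = sigma[sigma <= 0]
    if len(bad):
        raise ValueError(f"zero variance in features: {list(bad.index)}")
    return (logged - mu) / sigma, mu, sigma


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class PRRModel:
    classes: list[str]
    feature_names: list[str]
    coef: np.ndarray        # n_classes x n_features
    intercept: np.ndarray   # n_classes
    mu: pd.Series
    sigma: pd.Series
    alpha: float
    lam: float
    mode: str
    pseudocount: float
    report: dict = field(default_factory=dict, repr=False)

    def to_json(self, path) -> None:
        payload = {
            "classes": self.classes,
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "alpha": self.alpha,
            "lambda": self.lam,
            "mode": self.mode,
            "pseudocount": self.pseudocount,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PRRModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            classes=d["classes"],
            feature_names=d["feature_names"],
            coef=np.asarray(d["coef"]),
            intercept=np.asarray(d["intercept"]),
            mu=pd.Series(d["mu"], index=d["feature_names"]),
            sigma=pd.Series(d["sigma"], index=d["feature_names"]),
            alpha=d["alpha"],
            lam=d["lambda"],
            mode=d["mode"],
            pseudocount=d["pseudocount"],
        )


def _make_estimator(alpha: float, lam: float, n: int, seed: int) -> LogisticRegression:
    # glmnet-style lambda mapped onto sklearn's C = 1 / (n * lambda)
    return LogisticRegression(
        solver="saga", l1_ratio=alpha,
        C=1.0 / (n * lam), max_iter=8_000, tol=1e-5, random_state=seed,
    )


def _cv_log_loss(X, y, alpha, lam, folds, repeats, seed) -> float:
    classes = sorted(set(y))
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    losses = []
    for tr, te in cv.split(X, y):
        est = _make_estimator(alpha, lam, len(tr), seed)
        est.fit(X[tr], y[tr])
        prob = est.predict_proba(X[te])
        losses.append(log_loss(y[te], prob, labels=est.classes_))
    _ = classes
    return float(np.mean(losses))


def _grid_search(X, y, alpha_grid, lambda_grid, folds, repeats, seed):
    best = (np.inf, None, None)
    for a in alpha_grid:
        for lam in lambda_grid:
            loss = _cv_log_loss(X, y, a, lam, folds, repeats, seed)
            if loss < best[0]:
                best = (loss, a, lam)
    return best[1], best[2], best[0]


def train(
    features: pd.DataFrame,
    labels: pd.Series,
    n_partitions: int = 10,
    cv_folds: int = 10,
    cv_repeats: int = 10,
    alpha_grid=None,
    lambda_grid=None,
    seed: int | None = None,
    mode: str = "proportional",
    pseudocount: float | None = None,
) -> PRRModel:
    """Train PRRDetect with a repeated 70:30 partition protocol.

    Each partition is a stratified 70:30 split; the (alpha, lambda)
    grid is searched on the 70% by repeated stratified k-fold
    cross-validated log loss, and the winning model is scored on the
    held-out 30%.  Coefficient means and dispersions across partitions
    quantify stability.  The returned model is refit on the full
    cohort with the same cross-validation protocol; its transform
    moments are estimated on the full cohort and stored.
    """
    labels = labels.reindex(features.index)
    present = sorted(labels.unique())
    if len(present) < 2:
        raise ValueError("training requires at least two classes")
    class_counts = labels.value_counts()
    folds = cv_folds
    if class_counts.min() < cv_folds:
        folds = max(2, int(class_counts.min()))
        log.warning("smallest class has %d members; reducing CV folds to %d",
                    class_counts.min(), folds)
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.0, 1.01, 0.1), 2)
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 1, 6)
    if pseudocount is None:
        pseudocount = PSEUDOCOUNT[mode]
    rng = np.random.default_rng(seed)
    y_all = labels.to_numpy()

    partition_rows = []
    coef_stack = []
    for part in range(n_partitions):
        pseed = int(rng.integers(0, 2**31 - 1))
        tr_idx, te_idx = train_test_split(
            np.arange(len(features)), test_size=0.3,
            stratify=y_all, random_state=pseed,
        )
        Xtr_raw = features.iloc[tr_idx]
        Xtr, mu, sd = transform(Xtr_raw, pseudocount=pseudocount)
        Xte, _, _ = transform(features.iloc[te_idx], mu, sd, pseudocount)
        a, lam, cv_loss = _grid_search(
            Xtr.to_numpy(), y_all[tr_idx], alpha_grid, lambda_grid,
            folds, cv_repeats, pseed,
        )
        est = _make_estimator(a, lam, len(tr_idx), pseed)
        est.fit(Xtr.to_numpy(), y_all[tr_idx])
        prob = est.predict_proba(Xte.to_numpy())
        pred = est.classes_[prob.argmax(axis=1)]
        acc = float((pred == y_all[te_idx]).mean())
        partition_rows.append({
            "partition": part, "alpha": a, "lambda": lam,
            "cv_log_loss": cv_loss, "test_accuracy": acc,
        })
        order = [list(est.classes_).index(c) for c in present]
        coef_stack.append(est.coef_[order])

    coef_stack_arr = np.array(coef_stack)
    # final model: grid search and fit on the full cohort
    fseed = int(rng.integers(0, 2**31 - 1))
    Xf, mu, sd = transform(features, pseudocount=pseudocount)
    a, lam, _ = _grid_search(
        Xf.to_numpy(), y_all, alpha_grid, lambda_grid, folds, cv_repeats, fseed
    )
    est = _make_estimator(a, lam, len(features), fseed)
    est.fit(Xf.to_numpy(), y_all)
    order = [list(est.classes_).index(c) for c in present]
    report = {
        "partitions": pd.DataFrame(partition_rows),
        "coef_mean": pd.DataFrame(
            coef_stack_arr.mean(axis=0), index=present, columns=features.columns
        ) if len(coef_stack_arr) else None,
        "coef_sd": pd.DataFrame(
            coef_stack_arr.std(axis=0), index=present, columns=features.columns
        ) if len(coef_stack_arr) else None,
    }
    return PRRModel(
        classes=present,
        feature_names=list(features.columns),
        coef=est.coef_[order],
        intercept=est.intercept_[order],
        mu=mu, sigma=sd, alpha=float(a), lam=float(lam),
        mode=mode, pseudocount=pseudocount, report=report,
    )


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------


def predict(model: PRRModel, features: pd.DataFrame) -> pd.DataFrame:
    """Class probabilities and the PRRDetect call per sample.

    Decision rule: PRR-proficient iff P(Neg) > 0.5 (strict); otherwise
    the positive class with the highest probability.
    """
    if not np.isfinite(features.to_numpy(dtype=float)).all():
        raise ValueError("feature table contains non-finite values")
    X, _, _ = transform(
        features[model.feature_names], model.mu, model.sigma, model.pseudocount
    )
    z = X.to_numpy() @ model.coef.T + model.intercept
    prob = softmax(z, axis=1)
    out = pd.DataFrame(prob, index=features.index, columns=model.classes)
    out["call"] = decide(out[model.classes])
    return out


def decide(probabilities: pd.DataFrame) -> pd.Series:
    """Apply the PRRDetect decision rule to a probability table."""
    if "Neg" not in probabilities.columns:
        raise ValueError("probability table lacks the Neg class")
    positives = [c for c in probabilities.columns if c != "Neg"]
    calls = []
    for _, row in probabilities.iterrows():
        if row["Neg"] > 0.5:
            calls.append("Neg")
        else:
            calls.append(row[positives].idxmax())
    return pd.Series(calls, index=probabilities.index, name="call")


def evaluate(model: PRRModel, features: pd.DataFrame, labels: pd.Series) -> dict:
    """ROC/AUROC and precision-recall/AUPRC for PRRd-positive vs
    proficient (score = 1 - P(Neg)), plus the per-class confusion
    matrix of the categorical calls."""
    labels = labels.reindex(features.index)
    if labels.nunique() < 2:
        raise ValueError("evaluation requires both positive and negative samples")
    pred = predict(model, features)
    score = 1.0 - pred["Neg"].to_numpy()
    y_bin = (labels != "Neg").astype(int).to_numpy()
    if len(np.unique(y_bin)) < 2:
        raise ValueError("evaluation requires both positive and negative samples")
    fpr, tpr, _ = roc_curve(y_bin, score)
    auroc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y_bin, score)
    order = np.argsort(recall)
    auprc = float(np.trapezoid(precision[order], recall[order]))
    confusion = pd.crosstab(labels, pred["call"], dropna=False)
    macro_acc = float(np.mean([
        (pred["call"][labels == c] == c).mean() for c in sorted(labels.unique())
    ]))
    return {
        "auroc": auroc, "auprc": auprc,
        "roc": (fpr, tpr), "pr": (precision, recall),
        "confusion": confusion, "macro_accuracy": macro_acc,
        "accuracy": float((pred["call"] == labels).mean()),
    }
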