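"""Classifier-based cell label transfer between datasets.

A multiclass gradient-boosted tree ensemble (XGBoost) is trained on a
reference dataset's cluster labels using the intersection of highly
variable genes, with a per-cluster sampling protocol: 70% of each cluster's
cells (capped at 1,000) go to training, small clusters are bootstrapped up
to 100 training cells, and the unsampled cells are held out for
validation. At prediction time a cell is assigned the argmax label only if
its top probability strictly exceeds 1.2/r (r = number of reference
labels); otherwise it is Unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import xgboost as xgb
from scipy import stats

__all__ = [
    "split_train_validation",
    "train_mapper",
    "predict_labels",
    "validation_accuracy",
    "frequency_concordance",
    "overcluster_diagnostic",
    "MappingModel",
    "MappingResult",
]

DEFAULT_PARAMS = {
    "objective": "multi:softprob",
    "eval_metric": "mlogloss",
    "eta": 0.2,
    "max_depth": 6,
    "subsample": 0.6,
}


def split_train_validation(labels, frac: float = 0.7, cap: int = 1000,
                           min_train: int = 100, seed: int = 0):
    """Per-cluster train/held-out split with bootstrap upsampling.

    For each cluster of size n: n_train = min(floor(frac*n), cap) cells are
    sampled without replacement for training; if n_train < min_train the
    sampled cells are bootstrapped (with replacement) up to min_train. All
    unsampled cells are held out. Returns (train_idx, heldout_idx, manifest);
    train_idx may contain duplicates from upsampling.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must be in (0,1)")
    if cap < min_train:
        raise ValueError("cap must be >= min_train")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, held = [], []
    manifest = {"frac": frac, "cap": cap, "min_train": min_train, "seed": seed,
                "clusters": {}}
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n = len(idx)
        n_train = min(int(np.floor(frac * n)), cap)
        if n_train == 0:
            warnings.warn(f"cluster {lab!r} has {n} cell(s); training on all of them")
            n_train = n
        perm = rng.permutation(idx)
        tr, ho = perm[:n_train], perm[n_train:]
        upsampled = False
        if len(tr) < min_train:
            tr = np.concatenate([tr, rng.choice(tr, size=min_train - len(tr), replace=True)])
            upsampled = True
        train.append(tr)
        held.append(ho)
        manifest["clusters"][str(lab)] = {
            "n": int(n), "n_sampled": int(n_train), "n_train": int(len(tr)),
            "n_heldout": int(len(ho)), "upsampled": upsampled}
    return np.concatenate(train), np.concatenate(held), manifest


@dataclass
class MappingModel:
    booster: xgb.Booster
    feature_genes: list[str]
    label_vocabulary: list[str]
    manifest: dict = field(default_factory=dict)

    @property
    def r(self) -> int:
        return len(self.label_vocabulary)


@dataclass
class MappingResult:
    probabilities: pd.DataFrame   # cells x labels
    assigned: pd.Series           # label or "Unassigned"
    max_prob: pd.Series
    reject_factor: float


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense(), dtype=np.float32) if sp.issparse(x) \
        else np.asarray(x, dtype=np.float32)


def train_mapper(
    x,
    labels,
    feature_genes,
    gene_names,
    params: dict | None = None,
    num_rounds: int = 200,
    early_stopping_rounds: int = 10,
    tune_frac: float = 0.1,
    seed: int = 0,
    nthread: int = 1,
) -> MappingModel:
    """Train the multiclass ensemble on a (cells x genes) expression matrix.

    ``feature_genes`` selects and orders the features (typically the HVG
    intersection of reference and test, in reference order). Training rows
    should come from :func:`split_train_validation`. A 10% tune split of
    the training rows drives mlogloss early stopping. Deterministic under a
    fixed seed and thread count.
    """
    labels = np.asarray(labels, dtype=object)
    vocab = sorted(pd.unique(labels))
    if len(vocab) < 2:
        raise ValueError("need at least two labels")
    gene_names = list(gene_names)
    col = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in feature_genes if g not in col]
    if missing:
        raise ValueError(f"feature genes absent from training matrix: {missing[:5]}...")
    cols = [col[g] for g in feature_genes]
    Xf = _dense(x[:, cols] if not sp.issparse(x) else x.tocsc()[:, cols])
    y = np.array([vocab.index(v) for v in labels])

    rng = np.random.default_rng(seed)
    n = len(y)
    perm = rng.permutation(n)
    n_tune = max(1, int(round(tune_frac * n)))
    tune_idx, fit_idx = perm[:n_tune], perm[n_tune:]
    if len(np.unique(y[fit_idx])) < len(vocab):
        raise ValueError("a label is absent from the training split")

    p = dict(DEFAULT_PARAMS)
    p.update(params or {})
    p["num_class"] = len(vocab)
    p["seed"] = seed
    p["nthread"] = nthread
    dfit = xgb.DMatrix(Xf[fit_idx], label=y[fit_idx])
    dtune = xgb.DMatrix(Xf[tune_idx], label=y[tune_idx])
    booster = xgb.train(p, dfit, num_boost_round=num_rounds,
                        evals=[(dtune, "tune")],
                        early_stopping_rounds=early_stopping_rounds,
                        verbose_eval=False)
    manifest = {"params": {k: v for k, v in p.items()},
                "num_rounds": num_rounds, "best_iteration": booster.best_iteration,
                "n_train": int(len(fit_idx)), "n_tune": int(len(tune_idx)),
                "seed": seed}
    return MappingModel(booster=booster, feature_genes=list(feature_genes),
                        label_vocabulary=vocab, manifest=manifest)


def predict_labels(model: MappingModel, x, gene_names,
                   cell_names=None, reject_factor: float = 1.2) -> MappingResult:
    """Probabilistic label assignment with the 1.2/r rejection rule.

    Feature genes missing from the test matrix are zero-filled (with a
    warning), since gene panels differ across datasets.
    """
    r = model.r
    if r < 2:
        raise ValueError("rejection threshold is unattainable with r < 2")
    gene_names = list(gene_names)
    col = {g: i for i, g in enumerate(gene_names)}
    n = x.shape[0]
    Xf = np.zeros((n, len(model.feature_genes)), dtype=np.float32)
    missing = 0
    xc = x.tocsc() if sp.issparse(x) else np.asarray(x)
    for j, g in enumerate(model.feature_genes):
        if g in col:
            cj = xc[:, col[g]]
            Xf[:, j] = np.asarray(cj.todense()).ravel() if sp.issparse(cj) else cj
        else:
            missing += 1
    if missing:
        warnings.warn(f"{missing} feature gene(s) absent from test matrix; zero-filled")
    probs = model.booster.predict(xgb.DMatrix(Xf))
    if cell_names is None:
        cell_names = pd.RangeIndex(n)
    probs = pd.DataFrame(probs, index=cell_names, columns=model.label_vocabulary)
    max_prob = probs.max(axis=1)
    argmax = probs.idxmax(axis=1)
    threshold = reject_factor / r
    assigned = argmax.where(max_prob > threshold, "Unassigned")
    return MappingResult(probabilities=probs, assigned=assigned,
                         max_prob=max_prob, reject_factor=reject_factor)


def validation_accuracy(model: MappingModel, x, labels, gene_names,
                        heldout_idx, reject_factor: float = 1.2):
    """Overall and per-cluster held-out accuracy (Unassigned counts as wrong)."""
    labels = np.asarray(labels, dtype=object)
    res = predict_labels(model, x[heldout_idx], gene_names,
                         reject_factor=reject_factor)
    truth = labels[heldout_idx]
    correct = res.assigned.to_numpy() == truth
    per_cluster = pd.Series(correct).groupby(truth).mean()
    return float(correct.mean()), per_cluster, res


def frequency_concordance(labels_a, labels_b, vocabulary=None,
                          log10: bool = False) -> tuple[pd.DataFrame, float]:
    """Relative-frequency table of two label vectors and their Pearson r.

    Frequencies are normalized within each vector over the shared
    vocabulary (Unassigned excluded). With ``log10=True`` the correlation is
    computed on log10 frequencies (zero-frequency labels excluded), since
    frequencies span orders of magnitude and figures use log axes.
    """
    a = pd.Series(list(labels_a), dtype=object)
    b = pd.Series(list(labels_b), dtype=object)
    a, b = a[a != "Unassigned"], b[b != "Unassigned"]
    if vocabulary is None:
        vocabulary = sorted(set(a) | set(b))
    fa = a.value_counts(normalize=True).reindex(vocabulary, fill_value=0.0)
    fb = b.value_counts(normalize=True).reindex(vocabulary, fill_value=0.0)
    table = pd.DataFrame({"freq_a": fa, "freq_b": fb})
    with np.errstate(divide="ignore"):
        table["log2_ratio"] = np.log2(fa.to_numpy() / fb.to_numpy())
    if log10:
        keep = (table["freq_a"] > 0) & (table["freq_b"] > 0)
        va, vb = np.log10(table.loc[keep, "freq_a"]), np.log10(table.loc[keep, "freq_b"])
    else:
        va, vb = table["freq_a"], table["freq_b"]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant frequency vector; correlation undefined")
    r = float(stats.pearsonr(va, vb)[0])
    return table, r


def overcluster_diagnostic(x, labels_at_resolutions: dict, gene_names,
                           feature_genes=None, frac: float = 0.7, cap: int = 1000,
                           min_train: int = 100, seed: int = 0,
                           error_threshold: float = 0.10, **train_kw) -> pd.DataFrame:
    """Held-out validation error per clustering resolution.

    For each resolution, runs the split/train protocol and records the mean
    per-cluster held-out error. The smallest resolution whose error exceeds
    ``error_threshold`` is flagged as the onset of over-clustering.
    """
    if len(labels_at_resolutions) < 1:
        raise ValueError("need at least one resolution")
    if feature_genes is None:
        feature_genes = list(gene_names)
    rows = []
    for res_value in sorted(labels_at_resolutions):
        labels = np.asarray(labels_at_resolutions[res_value], dtype=object)
        tr, ho, _ = split_train_validation(labels, frac=frac, cap=cap,
                                           min_train=min_train, seed=seed)
        model = train_mapper(x[tr], labels[tr], feature_genes, gene_names,
                             seed=seed, **train_kw)
        _, per_cluster, _ = validation_accuracy(model, x, labels, gene_names, ho)
        err = float(1.0 - per_cluster.mean())
        rows.append({"resolution": res_value, "n_clusters": len(np.unique(labels)),
                     "mean_heldout_error": err})
    out = pd.DataFrame(rows)
    out["overclustered"] = False
    above = out.index[out["mean_heldout_error"] > error_threshold]
    if len(out) > 1 and len(above):
        out.loc[above[0], "overclustered"] = True
    return out
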