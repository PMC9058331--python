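"""Supervised chain: PCA, ANOVA component selection, LDA, and
leave-one-sample-out cross-validation with majority voting.

Per fold, the held-out sample contributes nothing to the fitted model: PCA,
the ANOVA screen and the LDA are all recomputed from training spectra only
(a ``global_pca`` flag reproduces the leaky single-PCA variant for
comparison).  Every spectrum of the test sample is predicted, and the sample
is called by majority vote: a class holding more than 50% of the spectra
wins decisively; otherwise the plurality class is returned with
``decisive=False``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .core import InvariantError, PATHOLOGY_ORDER, Pathology, SpectraTable

_CANON = [p.value for p in PATHOLOGY_ORDER]


def _sorted_classes(labels: Sequence[str]) -> list[str]:
    present = set(str(l) for l in labels)
    ordered = [c for c in _CANON if c in present]
    ordered += sorted(present - set(_CANON))
    return ordered


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Mean-centered PCA by SVD; loadings sign-fixed for determinism."""

    mean: np.ndarray
    loadings: np.ndarray                # (n_components, n_channels)
    explained_variance_ratio: np.ndarray
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean.size:
            raise InvariantError("spectra are not on the training axis")
        return (X - self.mean) @ self.loadings.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.loadings + self.mean


def fit_pca(data: SpectraTable | np.ndarray, n_components_cap: int = 50) -> PCAModel:
    """PCA of spectra with at most ``n_components_cap`` components kept."""
    X = data.spectra if isinstance(data, SpectraTable) else np.asarray(data, float)
    if X.shape[0] < 2:
        raise InvariantError("PCA needs at least 2 records")
    if n_components_cap < 1:
        raise InvariantError("n_components_cap must be >= 1")
    mean = X.mean(axis=0)
    centered = X - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    keep = max(1, min(n_components_cap, rank))
    loadings = vt[:keep].copy()
    # sign convention: each loading's largest-magnitude entry is positive
    for i in range(keep):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    total_var = float((s**2).sum())
    evr = (s[:keep] ** 2) / total_var if total_var > 0 else np.zeros(keep)
    return PCAModel(mean, loadings, evr, keep)


# ---------------------------------------------------------------------------
# ANOVA screening of component scores
# ---------------------------------------------------------------------------

@dataclass
class SelectedComponents:
    """Components whose scores differ across pathology groups by one-way
    ANOVA at level alpha, capped at ``max_keep`` (smallest p first)."""

    indices: np.ndarray
    p_values: np.ndarray   # p-value per tested component (all of them)
    alpha: float = 0.05
    max_keep: int = 25


def anova_select(
    scores: np.ndarray,
    labels: Sequence[str],
    alpha: float = 0.05,
    max_keep: int = 25,
) -> SelectedComponents:
    """One-way fixed-effects F-test per component across groups."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray([str(l) for l in labels])
    classes = _sorted_classes(labels)
    if len(classes) < 2:
        raise InvariantError("ANOVA needs at least 2 groups")
    groups = []
    for c in classes:
        g = scores[labels == c]
        if g.shape[0] < 2:
            raise InvariantError(f"group '{c}' has fewer than 2 records")
        groups.append(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.f_oneway(*groups, axis=0)
    p = np.asarray(result.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)  # constant components never selected
    candidates = np.nonzero(p < alpha)[0]
    order = np.lexsort((candidates, p[candidates]))
    selected = candidates[order][:max_keep]
    return SelectedComponents(np.asarray(selected, int), p, alpha, max_keep)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Classic multiclass LDA with ridge-regularized pooled covariance."""

    classes: list[str]
    means: np.ndarray              # (C, d)
    pooled_cov: np.ndarray         # regularized, (d, d)
    directions: np.ndarray         # (d, C-1) discriminant directions
    priors: np.ndarray             # (C,)
    grand_mean: np.ndarray         # (d,)
    _prec_means: np.ndarray = field(repr=False, default=None)  # Σ^-1 μ_k^T

    def __post_init__(self):
        if self._prec_means is None:
            self._prec_means = linalg.solve(
                self.pooled_cov, self.means.T, assume_a="pos"
            )

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Gaussian equal-covariance discriminants δ_k(x)."""
        X = np.atleast_2d(X)
        lin = X @ self._prec_means
        const = -0.5 * np.einsum("kd,dk->k", self.means, self._prec_means)
        return lin + const + np.log(self.priors)

    def predict_posteriors(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        d -= d.max(axis=1, keepdims=True)
        e = np.exp(d)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.decision_function(X), axis=1)
        return np.asarray(self.classes)[idx]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores (n, C-1)."""
        return (np.atleast_2d(X) - self.grand_mean) @ self.directions


def fit_lda(
    X: np.ndarray,
    labels: Sequence[str],
    ridge: float | None = None,
    priors: Sequence[float] | None = None,
) -> LDAModel:
    """Fit multiclass LDA.

    ``ridge`` is added to the pooled within-class covariance diagonal; the
    default 1e-6 * trace/dim guards near-singular covariances in the up-to-
    25-dimensional selected-component space.  Priors default to equal
    (balanced design).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray([str(l) for l in labels])
    classes = _sorted_classes(labels)
    if len(classes) < 2:
        raise InvariantError("LDA needs at least 2 classes")
    n, d = X.shape
    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    counts = np.array([(labels == c).sum() for c in classes])
    sw = np.zeros((d, d))
    for c, mu in zip(classes, means):
        diff = X[labels == c] - mu
        sw += diff.T @ diff
    dof = max(n - len(classes), 1)
    sw /= dof
    if ridge is None:
        ridge = 1e-6 * np.trace(sw) / d
    cov = sw + ridge * np.eye(d)
    try:
        linalg.cholesky(cov)
    except linalg.LinAlgError:
        raise InvariantError(
            "pooled covariance is singular; pass ridge > 0"
        ) from None
    grand_mean = X.mean(axis=0)
    sb = np.zeros((d, d))
    for mu, nk in zip(means, counts):
        diff = (mu - grand_mean)[:, None]
        sb += nk * (diff @ diff.T)
    sb /= max(n - 1, 1)
    evals, evecs = linalg.eigh(sb, cov)
    order = np.argsort(evals)[::-1][: len(classes) - 1]
    directions = evecs[:, order]
    directions /= np.linalg.norm(directions, axis=0, keepdims=True)
    # deterministic sign: largest-magnitude entry positive
    for j in range(directions.shape[1]):
        i = int(np.argmax(np.abs(directions[:, j])))
        if directions[i, j] < 0:
            directions[:, j] = -directions[:, j]
    if priors is None:
        priors_arr = np.full(len(classes), 1.0 / len(classes))
    else:
        priors_arr = np.asarray(priors, dtype=float)
        priors_arr = priors_arr / priors_arr.sum()
    return LDAModel(classes, means, cov, directions, priors_arr, grand_mean)


# ---------------------------------------------------------------------------
# Prediction and voting
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    classes: list[str]
    predicted: np.ndarray        # (n,) class per spectrum
    posteriors: np.ndarray       # (n, C)
    ld_scores: np.ndarray        # (n, C-1)


def predict_spectra(
    pca: PCAModel,
    selection: SelectedComponents,
    lda: LDAModel,
    spectra: SpectraTable | np.ndarray,
) -> PredictionResult:
    """Project spectra through the fitted chain and classify each one."""
    X = spectra.spectra if isinstance(spectra, SpectraTable) else np.asarray(spectra, float)
    scores = pca.transform(X)[:, selection.indices]
    posteriors = lda.predict_posteriors(scores)
    predicted = np.asarray(lda.classes)[np.argmax(posteriors, axis=1)]
    return PredictionResult(
        classes=list(lda.classes),
        predicted=predicted,
        posteriors=posteriors,
        ld_scores=lda.transform(scores),
    )


@dataclass
class VoteResult:
    prediction: str
    fractions: dict[str, float]
    decisive: bool   # True iff some class holds > 50% of the spectra


def majority_vote(
    predicted: Sequence[str],
    posteriors: np.ndarray | None = None,
    classes: Sequence[str] | None = None,
) -> VoteResult:
    """Sample-level call from per-spectrum predictions.

    A class with more than half the spectra wins decisively.  Otherwise the
    plurality class is returned (``decisive=False``), ties broken by highest
    mean posterior when posteriors are supplied, else by class order.
    """
    predicted = np.asarray([str(p) for p in predicted])
    if predicted.size == 0:
        raise InvariantError("majority_vote needs at least one prediction")
    if classes is None:
        classes = _sorted_classes(predicted)
    classes = [str(c) for c in classes]
    n = predicted.size
    fractions = {c: float((predicted == c).sum()) / n for c in classes}
    best = max(fractions.values())
    leaders = [c for c in classes if fractions[c] == best]
    if best > 0.5:
        return VoteResult(leaders[0], fractions, True)
    if len(leaders) > 1 and posteriors is not None:
        mean_post = posteriors.mean(axis=0)
        leaders.sort(key=lambda c: -mean_post[classes.index(c)])
    return VoteResult(leaders[0], fractions, False)


# ---------------------------------------------------------------------------
# Leave-one-sample-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    alpha: float = 0.05
    max_pcs: int = 25
    pca_cap: int = 50
    ridge: float | None = None
    global_pca: bool = False
    seed: int = 0
    subsample_per_sample: int | None = None


@dataclass
class CVResult:
    """LOSOCV outcome: per-spectrum and per-sample predictions."""

    classes: list[str]
    spectrum_df: pd.DataFrame   # sample_id, true, predicted, posterior_*, ld_*
    sample_df: pd.DataFrame     # sample_id, true, predicted, decisive, frac_*
    config: dict
    fold_audit: list[dict]      # per-fold training-id hash and test id

    @property
    def spectrum_accuracy(self) -> float:
        df = self.spectrum_df
        return float((df["true"] == df["predicted"]).mean())

    @property
    def sample_accuracy(self) -> float:
        df = self.sample_df
        return float((df["true"] == df["predicted"]).mean())

    def per_sample_spectrum_accuracy(self) -> pd.Series:
        df = self.spectrum_df
        return (df["true"] == df["predicted"]).groupby(df["sample_id"]).mean()


def _train_hash(sample_ids: Sequence[str]) -> str:
    joined = "\n".join(sorted(set(sample_ids)))
    return hashlib.sha256(joined.encode()).hexdigest()


def losocv(
    table: SpectraTable,
    groups: Sequence[str | Pathology] | None = None,
    config: CVConfig | None = None,
) -> CVResult:
    """Leave-one-sample-out cross-validation of the PCA→ANOVA→LDA chain."""
    config = config or CVConfig()
    if groups is not None:
        wanted = {str(Pathology(str(g))) if not isinstance(g, Pathology) else g.value
                  for g in groups}
        table = table.select(table.meta["pathology"].isin(wanted).to_numpy())
    if len(table) == 0:
        raise InvariantError("no spectra in the requested groups")
    meta = table.meta
    samples = list(pd.unique(meta["sample_id"]))
    per_group = meta.drop_duplicates("sample_id").groupby("pathology")["sample_id"].count()
    thin = per_group[per_group < 2]
    if len(thin):
        raise InvariantError(
            f"groups with a single sample cannot be cross-validated: "
            f"{list(thin.index)}"
        )
    if config.subsample_per_sample is not None:
        rng = np.random.default_rng(config.seed)
        keep = np.zeros(len(table), dtype=bool)
        for s in samples:
            idx = np.nonzero(meta["sample_id"].to_numpy() == s)[0]
            if idx.size > config.subsample_per_sample:
                idx = rng.choice(idx, size=config.subsample_per_sample,
                                 replace=False)
            keep[idx] = True
        table = table.select(keep)
        meta = table.meta
    sample_ids = meta["sample_id"].to_numpy()
    labels_all = meta["pathology"].to_numpy()
    classes = _sorted_classes(labels_all)
    global_model = fit_pca(table, config.pca_cap) if config.global_pca else None

    spectrum_rows = []
    sample_rows = []
    audit = []
    for test_id in samples:
        test_mask = sample_ids == test_id
        train_mask = ~test_mask
        train_ids = sample_ids[train_mask]
        assert test_id not in set(train_ids), "leakage: test sample in training"
        audit.append(
            {"test_sample": test_id, "train_hash": _train_hash(train_ids),
             "n_train": int(train_mask.sum())}
        )
        X_train = table.spectra[train_mask]
        y_train = labels_all[train_mask]
        pca = global_model or fit_pca(X_train, config.pca_cap)
        train_scores = pca.transform(X_train)
        selection = anova_select(train_scores, y_train,
                                 alpha=config.alpha, max_keep=config.max_pcs)
        if selection.indices.size == 0:
            # nothing passes the screen (possible under a null); keep the
            # single most significant component so the chain stays operable
            best = int(np.argmin(selection.p_values))
            selection = SelectedComponents(
                np.array([best]), selection.p_values,
                selection.alpha, selection.max_keep,
            )
        lda = fit_lda(train_scores[:, selection.indices], y_train,
                      ridge=config.ridge)
        pred = predict_spectra(pca, selection, lda, table.spectra[test_mask])
        true_label = labels_all[test_mask][0]
        vote = majority_vote(pred.predicted, pred.posteriors, classes=pred.classes)
        n_ld = pred.ld_scores.shape[1]
        fold_df = pd.DataFrame(
            {
                "sample_id": test_id,
                "true": true_label,
                "predicted": pred.predicted,
                **{f"posterior_{c}": pred.posteriors[:, i]
                   for i, c in enumerate(pred.classes)},
                **{f"ld{j + 1}": pred.ld_scores[:, j] for j in range(n_ld)},
            }
        )
        spectrum_rows.append(fold_df)
        sample_rows.append(
            {
                "sample_id": test_id,
                "true": true_label,
                "predicted": vote.prediction,
                "decisive": vote.decisive,
                **{f"frac_{c}": vote.fractions.get(c, 0.0) for c in classes},
            }
        )
    spectrum_df = pd.concat(spectrum_rows, ignore_index=True)
    sample_df = pd.DataFrame(sample_rows)
    snapshot = {
        "alpha": config.alpha,
        "max_pcs": config.max_pcs,
        "pca_cap": config.pca_cap,
        "ridge": config.ridge,
        "global_pca": config.global_pca,
        "seed": config.seed,
        "subsample_per_sample": config.subsample_per_sample,
        "groups": classes,
        "n_samples": len(samples),
    }
    return CVResult(classes, spectrum_df, sample_df, snapshot, audit)
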