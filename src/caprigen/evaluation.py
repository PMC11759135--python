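"""Cross-validated benchmarking of genomic-prediction methods.

Protocol: records are randomized and split into k near-equal folds
(k = 10 by default); each method trains on k-1 folds and predicts the
held-out animals; prediction accuracy is the Pearson correlation between
predicted breeding values and phenotypes adjusted for fixed effects, with
the fixed-effect solutions estimated on the training records only (no
information flows from a validation animal into its own prediction).
Per-trait accuracy is the mean over the k validation folds, reported with
the across-fold SD and a normal-approximation 95% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PhenotypeTable, RelationshipMatrix
from .ensemble import (
    KernelSpec,
    adaboost_rt_fit,
    adaboost_rt_predict,
    kernel_grid_search,
    krr_fit,
    relationship_features,
)
from .mixedmodel import fit_reml, fixed_effect_design, gblup_predict

logger = logging.getLogger("caprigen")

METHODS = ("gblup", "krr", "adaboost_rt")


@dataclass
class FoldAssignment:
    """Partition of the sample into k folds; sizes differ by at most one."""

    sample_ids: list[str]
    fold_index: np.ndarray
    k: int
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in zip(self.sample_ids, self.fold_index) if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [s for s, f in zip(self.sample_ids, self.fold_index) if f != fold]


def make_folds(sample_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Seeded random split into k near-equal folds."""
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_index = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold_index[chunk] = f
    return FoldAssignment(sample_ids, fold_index, k, seed)


def fit_fixed_effects(phenos: PhenotypeTable, trait) -> dict:
    """OLS fit of intercept + milk status + birth year on training records."""
    X, names, levels = fixed_effect_design(phenos.data)
    y = phenos.values(trait)
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    return {"coef": b, "names": names, "levels": levels}


def adjust_phenotypes(phenos: PhenotypeTable, fixed_fit: dict, trait) -> np.ndarray:
    """y - X b_hat with the design built from the training-set factor levels."""
    X, _, _ = fixed_effect_design(phenos.data, levels=fixed_fit["levels"])
    return phenos.values(trait) - X @ fixed_fit["coef"]


def accuracy(predictions: np.ndarray, adjusted: np.ndarray) -> float:
    """Pearson correlation between predictions and adjusted phenotypes.

    Returns NaN (with a warning) when either vector is constant; callers
    exclude such folds from the mean.
    """
    predictions = np.asarray(predictions, dtype=float)
    adjusted = np.asarray(adjusted, dtype=float)
    if predictions.shape != adjusted.shape or predictions.size < 3:
        raise ValueError("need at least 3 prediction/observation pairs")
    if np.std(predictions) == 0.0 or np.std(adjusted) == 0.0:
        logger.warning("zero variance in accuracy computation; returning NaN")
        return float("nan")
    return float(stats.pearsonr(predictions, adjusted)[0])


def improvement_pct(acc_method: float, acc_baseline: float) -> int:
    """Percent improvement over the baseline, rounded to the nearest integer."""
    if acc_baseline <= 0.0:
        raise ValueError("baseline accuracy must be positive")
    return int(round(100.0 * (acc_method - acc_baseline) / acc_baseline))


def descriptive_stats(phenos: PhenotypeTable, trait) -> dict:
    """Count, range, mean, sample SD and coefficient of variation (2 dp)."""
    y = phenos.values(trait)
    if y.size < 2:
        raise ValueError("need at least 2 records")
    mean = float(np.mean(y))
    sd = float(np.std(y, ddof=1))
    if mean == 0.0:
        raise ZeroDivisionError("zero mean; coefficient of variation undefined")
    return {
        "n": int(y.size),
        "min": float(np.min(y)),
        "max": float(np.max(y)),
        "mean": mean,
        "sd": sd,
        "cv": round(sd / mean, 2),
    }


@dataclass
class CVReport:
    """Per-fold accuracies plus per-(method, trait) summaries."""

    folds: pd.DataFrame  # columns: method, trait, fold, accuracy
    k: int
    seed: int
    details: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for (method, trait), grp in self.folds.groupby(["method", "trait"],
                                                       sort=False):
            acc = grp["accuracy"].dropna().to_numpy()
            mean = float(np.mean(acc))
            sd = float(np.std(acc, ddof=1)) if acc.size > 1 else 0.0
            half = 1.96 * sd / np.sqrt(max(acc.size, 1))
            rows.append({
                "method": method, "trait": trait, "n_folds": int(acc.size),
                "mean_accuracy": mean, "sd": sd,
                "ci95_low": mean - half, "ci95_high": mean + half,
            })
        return pd.DataFrame(rows)

    def mean_accuracy(self, method: str, trait) -> float:
        s = self.summary()
        row = s[(s["method"] == method) & (s["trait"] == trait)]
        return float(row["mean_accuracy"].iloc[0])

    def improvements(self, baseline: str = "gblup") -> pd.DataFrame:
        s = self.summary()
        rows = []
        for trait in s["trait"].unique():
            base = float(s[(s.method == baseline) & (s.trait == trait)]
                         ["mean_accuracy"].iloc[0])
            for method in s["method"].unique():
                if method == baseline:
                    continue
                acc = float(s[(s.method == method) & (s.trait == trait)]
                            ["mean_accuracy"].iloc[0])
                try:
                    pct = improvement_pct(acc, base)
                except ValueError:  # non-positive baseline: undefined
                    pct = float("nan")
                rows.append({
                    "trait": trait, "method": method, "baseline": baseline,
                    "improvement_pct": pct,
                })
        return pd.DataFrame(rows)


def _predict_fold(
    method: str,
    phenos_train: PhenotypeTable,
    G: RelationshipMatrix,
    train_ids: list[str],
    test_ids: list[str],
    trait,
    adj_train: np.ndarray,
    seed: int,
    krr_alpha: float = 1.0,
    krr_grid=None,
    adaboost_phi: float = 0.1,
    n_estimators: int = 100,
) -> np.ndarray:
    if method == "gblup":
        vc = fit_reml(phenos_train, G, traits=[trait if isinstance(trait, str)
                                               else phenos_train.trait_names[trait]])
        return gblup_predict(phenos_train, G, vc, test_ids, trait=0)
    feats_train = relationship_features(G, train_ids, train_ids)
    feats_test = relationship_features(G, train_ids, test_ids)
    if method == "krr":
        spec = kernel_grid_search(feats_train, adj_train, candidate_grid=krr_grid,
                                  inner_folds=5, seed=seed, alpha=krr_alpha)
        model = krr_fit(feats_train, adj_train, spec, alpha=krr_alpha)
        return model.predict(feats_test)
    if method == "adaboost_rt":
        ens = adaboost_rt_fit(feats_train, adj_train, n_estimators=n_estimators,
                              phi=adaboost_phi, seed=seed)
        return adaboost_rt_predict(ens, feats_test)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def cross_validate(
    methods,
    phenos: PhenotypeTable,
    G: RelationshipMatrix,
    folds: FoldAssignment,
    traits=None,
    krr_alpha: float = 1.0,
    krr_grid=None,
    adaboost_phi: float = 0.1,
    n_estimators: int = 100,
) -> CVReport:
    """Run the k-fold protocol for the requested methods and traits.

    Within every training split, GBLUP re-estimates its variance components
    by REML and KRR re-selects its kernel by an inner 5-fold grid search;
    fixed effects for both training targets and validation adjustment come
    from the training records alone.
    """
    if isinstance(methods, str):
        methods = [methods]
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    traits = list(phenos.trait_names) if traits is None else [
        phenos.trait_names[t] if isinstance(t, int) else t for t in traits
    ]
    rows = []
    for trait in traits:
        for fold in range(folds.k):
            train_ids = folds.train_ids(fold)
            test_ids = folds.fold_ids(fold)
            ptrain = phenos.subset(train_ids)
            ptest = phenos.subset(test_ids)
            ffit = fit_fixed_effects(ptrain, trait)
            adj_train = adjust_phenotypes(ptrain, ffit, trait)
            adj_test = adjust_phenotypes(ptest, ffit, trait)
            for method in methods:
                try:
                    pred = _predict_fold(
                        method, ptrain, G, train_ids, test_ids, trait,
                        adj_train, seed=folds.seed * 1000 + fold,
                        krr_alpha=krr_alpha, krr_grid=krr_grid,
                        adaboost_phi=adaboost_phi, n_estimators=n_estimators,
                    )
                    acc = accuracy(pred, adj_test)
                except Exception as e:  # per-fold failures are reported
                    logger.warning("fold %d %s/%s failed: %s",
                                   fold, method, trait, e)
                    acc = float("nan")
                rows.append({"method": method, "trait": trait,
                             "fold": fold, "accuracy": acc})
    return CVReport(pd.DataFrame(rows), folds.k, folds.seed)
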