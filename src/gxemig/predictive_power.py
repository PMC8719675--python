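"""Predictive power of nested feature sets for migraine case status.

Four nested models are compared:

* **M0** — age, sex, population (the demographic baseline);
* **M1** — M0 plus the replicated main-effect SNPs;
* **M2** — M0 plus lifetime depression;
* **M3** — M2 plus the clumped interaction SNPs.

Each is scored with a small feed-forward classifier (10-unit input and
hidden layers, ReLU activations, logistic output, binary cross-entropy
loss, Adam optimizer, batch size 20, 50 epochs) under repeated stratified
cross-validation (k = 10 folds × n = 10 repetitions).  The score is a
weighted accuracy w·sensitivity + (1−w)·specificity with w equal to the
case fraction (a balanced w = 0.5 variant is selectable), averaged over
the n×k test folds.  A logistic-regression ladder with explicit SNP×DEPR
product terms and AIC comparison provides a classical confirmation.

Feature scaling is fit on each training fold only (age min-max scaled,
dosages divided by 2, binary features as 0/1) so no test information leaks
into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neural_network import MLPClassifier

from gxemig.genio import GenotypeMatrix

LADDER = ("M0", "M1", "M2", "M3")


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training settings of the fold-level classifier."""

    hidden_layers: tuple[int, ...] = (10, 10)
    batch_size: int = 20
    epochs: int = 50
    seed: int = 0

    def build(self, seed: int) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=self.hidden_layers,
            activation="relu",
            solver="adam",
            batch_size=self.batch_size,
            max_iter=self.epochs,
            random_state=seed,
        )


@dataclass(frozen=True)
class CvScheme:
    """Stratified k-fold cross-validation repeated n times."""

    k: int = 10
    n_repeats: int = 10
    seed: int = 0

    def splitter(self) -> RepeatedStratifiedKFold:
        return RepeatedStratifiedKFold(
            n_splits=self.k, n_repeats=self.n_repeats,
            random_state=self.seed)


def weighted_accuracy(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    weighting: Literal["case_fraction", "balanced"] = "case_fraction",
) -> float:
    """w·sensitivity + (1−w)·specificity with w the case fraction of
    ``y_true`` (or 0.5 for the balanced variant)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    cases = y_true == 1
    if not cases.any() or cases.all():
        raise ValueError("both classes must be present")
    sens = float((y_pred[cases] == 1).mean())
    spec = float((y_pred[~cases] == 0).mean())
    w = float(cases.mean()) if weighting == "case_fraction" else 0.5
    return w * sens + (1 - w) * spec


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def _base_features(pheno: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "AGE": pheno["AGE"].to_numpy(dtype=float),
        "SEX": (pheno["SEX"].to_numpy(dtype=float) == 2).astype(float),
        "POP": pd.Categorical(pheno["POP"]).codes.astype(float),
    })


def build_features(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    model: str,
    hits_main: Sequence[str] = (),
    hits_interaction: Sequence[str] = (),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table and outcome vector for one ladder model; rows with a
    missing dosage in a required SNP are dropped (complete-case)."""
    X = _base_features(pheno)
    snps: Sequence[str] = ()
    if model == "M1":
        snps = hits_main
    elif model in ("M2", "M3"):
        X["DEPR"] = pheno["DEPR"].to_numpy(dtype=float)
        if model == "M3":
            snps = hits_interaction
    elif model != "M0":
        raise ValueError(f"unknown ladder model {model!r}")
    for s in snps:
        X[s] = G.dosages[:, G.snp_index(s)]
    y = pheno["MIGR"].to_numpy(dtype=float)
    complete = ~X.isna().any(axis=1).to_numpy()
    return X.loc[complete].reset_index(drop=True), y[complete]


def _scale_fold(train: np.ndarray, test: np.ndarray,
                columns: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Min-max scale AGE from the training fold; dosages to [0, 1]."""
    train = train.copy()
    test = test.copy()
    for c, name in enumerate(columns):
        if name == "AGE":
            lo, hi = train[:, c].min(), train[:, c].max()
            span = hi - lo if hi > lo else 1.0
            train[:, c] = (train[:, c] - lo) / span
            test[:, c] = np.clip((test[:, c] - lo) / span, 0, 1)
        elif name not in ("SEX", "POP", "DEPR"):
            train[:, c] = train[:, c] / 2.0
            test[:, c] = test[:, c] / 2.0
    return train, test


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelScore:
    model: str
    score: float
    sensitivity: float
    specificity: float
    fold_scores: list[float] = field(default_factory=list)
    n_folds_skipped: int = 0


def evaluate_model(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    cv: CvScheme = CvScheme(),
    weighting: str = "case_fraction",
    model_name: str = "model",
) -> ModelScore:
    """Mean weighted accuracy over the n×k cross-validation test folds."""
    if len(X) < cv.k:
        raise ValueError("too few rows for the requested fold count")
    cols = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    scores, sens_list, spec_list = [], [], []
    skipped = 0
    rng = np.random.default_rng(spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_idx, test_idx in cv.splitter().split(Xm, y):
            y_test = y[test_idx]
            if len(np.unique(y_test)) < 2 or len(np.unique(y[train_idx])) < 2:
                skipped += 1
                continue
            Xtr, Xte = _scale_fold(Xm[train_idx], Xm[test_idx], cols)
            clf = spec.build(int(rng.integers(2**31)))
            clf.fit(Xtr, y[train_idx])
            y_pred = clf.predict(Xte)
            scores.append(weighted_accuracy(y_test, y_pred, weighting))
            cases = y_test == 1
            sens_list.append(float((y_pred[cases] == 1).mean()))
            spec_list.append(float((y_pred[~cases] == 0).mean()))
    if not scores:
        raise ValueError("every fold was single-class")
    return ModelScore(model=model_name, score=float(np.mean(scores)),
                      sensitivity=float(np.mean(sens_list)),
                      specificity=float(np.mean(spec_list)),
                      fold_scores=scores, n_folds_skipped=skipped)


@dataclass
class PowerResult:
    scores: dict[str, ModelScore]
    weighting: str

    def table(self) -> pd.DataFrame:
        base = self.scores.get("M0")
        rows = []
        for m in LADDER:
            if m not in self.scores:
                continue
            s = self.scores[m]
            diff = (np.nan if m == "M0" or base is None
                    else (s.score - base.score) / base.score * 100)
            rows.append({"model": m, "score": s.score,
                         "sensitivity": s.sensitivity,
                         "specificity": s.specificity,
                         "diff_vs_M0_pct": diff})
        return pd.DataFrame(rows)


def run_ladder(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    hits_main: Sequence[str],
    hits_interaction: Sequence[str],
    spec: ClassifierSpec = ClassifierSpec(),
    cv: CvScheme = CvScheme(),
    weighting: str = "case_fraction",
) -> PowerResult:
    """Evaluate M0–M3; a model whose hit list is empty is skipped."""
    out: dict[str, ModelScore] = {}
    for m in LADDER:
        if m == "M1" and not hits_main:
            continue
        if m == "M3" and not hits_interaction:
            continue
        X, y = build_features(G, pheno, m, hits_main, hits_interaction)
        out[m] = evaluate_model(X, y, spec, cv, weighting, model_name=m)
    return PowerResult(scores=out, weighting=weighting)


def relative_difference(score: float, base: float) -> float:
    """Percent difference of a model score from the baseline score."""
    return (score - base) / base * 100.0


# ---------------------------------------------------------------------------
# Logistic-regression ladder with AIC
# ---------------------------------------------------------------------------

def _logistic_design(X: pd.DataFrame, products_with: str | None = None,
                     snps: Sequence[str] = ()) -> pd.DataFrame:
    design = X.copy()
    if products_with is not None:
        for s in snps:
            design[f"{products_with}:{s}"] = design[products_with] * design[s]
    design.insert(0, "const", 1.0)
    return design


def logistic_ladder_aic(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    hits_main: Sequence[str],
    hits_interaction: Sequence[str],
    single_snp_variants: bool = True,
) -> pd.DataFrame:
    """Fit the M0–M3 ladder as logistic regressions and compare by AIC.

    M3 contains SNP main effects *and* explicit SNP×DEPR product terms.
    With ``single_snp_variants``, M3 is additionally refit with one SNP's
    main + interaction pair at a time.  Returns one row per model with
    AIC, log-likelihood and the per-term Wald p-values.
    """
    rows = []

    def fit_one(name: str, X: pd.DataFrame, y: np.ndarray,
                products: Sequence[str] = ()) -> None:
        design = _logistic_design(X, "DEPR" if products else None, products)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design.to_numpy()).fit(
                method="newton", maxiter=100, disp=0, warn_convergence=False)
        pvals = dict(zip(design.columns, np.asarray(res.pvalues)))
        rows.append({"model": name, "aic": float(res.aic),
                     "loglik": float(res.llf), "n": int(len(y)),
                     "k": design.shape[1], "term_p": pvals})

    for m in LADDER:
        if m == "M1" and not hits_main:
            continue
        if m == "M3" and not hits_interaction:
            continue
        X, y = build_features(G, pheno, m, hits_main, hits_interaction)
        fit_one(m, X, y, products=hits_interaction if m == "M3" else ())
    if single_snp_variants:
        for s in hits_interaction:
            X, y = build_features(G, pheno, "M3", hits_main, [s])
            fit_one(f"M3[{s}]", X, y, products=[s])
    return pd.DataFrame(rows)
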