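"""Linear ddG model: training, cross-validation, classification metrics.

The predictor is an ordinary-least-squares multiple linear regression of
experimental binding-affinity changes (ddG, kcal/mol; positive =
destabilizing) on the nine structural features.  Model quality is assessed
by three cross-validation schemes — random 50/50 and 80/20 mutation splits
repeated 50 times (CV1, CV2) and leave-one-complex-out (CV3) — and by
ROC/precision-recall analysis of the ability to flag deleterious mutations
(experimental ddG >= 1 kcal/mol).  The operating threshold on predicted
ddG is chosen by minimizing ER = sqrt((1-TPR)^2 + FPR^2), the ROC-space
distance to the perfect-classifier corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve, precision_recall_curve, auc

from .energetics import FEATURE_NAMES, FeatureVector

DELETERIOUS_DDG_PRED = 1.10   # kcal/mol, operating threshold on predictions
DELETERIOUS_DDG_EXP = 1.0     # kcal/mol, label threshold on experiments

DATASET_COLUMNS = ("complex_id", "chain", "wt", "pos", "mut", "ddg_exp",
                   *FEATURE_NAMES)


class DatasetError(ValueError):
    pass


# --------------------------------------------------------------------------
# dataset curation
# --------------------------------------------------------------------------

def curate_dataset(raw: pd.DataFrame) -> pd.DataFrame:
    """Clean a raw mutation table into one row per (complex, mutation).

    Multi-mutation entries (e.g. ``R124A+K130A`` in the ``mut`` column or a
    ``mutation`` column) are dropped; duplicated measurements of the same
    single mutation are averaged; rows are ordered deterministically.
    """
    df = raw.copy()
    if "mutation" in df.columns and "wt" not in df.columns:
        parsed = []
        for idx, text in df["mutation"].items():
            if "+" in str(text) or "," in str(text):
                parsed.append(None)
                continue
            s = str(text).strip()
            try:
                wt, pos, mut = s[0], int(s[1:-1]), s[-1]
            except (ValueError, IndexError):
                raise DatasetError(f"row {idx}: cannot parse mutation {text!r}")
            parsed.append((wt, pos, mut))
        keep = [p is not None for p in parsed]
        df = df[keep].copy()
        trip = [p for p in parsed if p is not None]
        df["wt"] = [t[0] for t in trip]
        df["pos"] = [t[1] for t in trip]
        df["mut"] = [t[2] for t in trip]
        df = df.drop(columns=["mutation"])
    else:
        multi = df["mut"].astype(str).str.contains(r"[+,]")
        df = df[~multi].copy()

    if not np.isfinite(df["ddg_exp"]).all():
        raise DatasetError("non-finite ddg_exp values")

    keys = ["complex_id", "chain", "wt", "pos", "mut"]
    agg = {c: ("mean" if c == "ddg_exp" or c in FEATURE_NAMES else "first")
           for c in df.columns if c not in keys}
    df = df.groupby(keys, as_index=False).agg(agg)
    df = df.sort_values(["complex_id", "chain", "pos", "mut"],
                        kind="mergesort").reset_index(drop=True)
    return df


# --------------------------------------------------------------------------
# the linear model
# --------------------------------------------------------------------------

@dataclass
class MLRModel:
    """Fitted multiple linear regression over the nine features."""
    intercept: float
    coefficients: dict                    # feature name -> coefficient
    std_coefficients: dict = field(default_factory=dict)   # importance
    p_values: dict = field(default_factory=dict)
    training_r: float = float("nan")
    training_rmse: float = float("nan")
    training_slope: float = float("nan")
    n_training: int = 0

    def predict(self, features) -> float | np.ndarray:
        if isinstance(features, FeatureVector):
            features = features.as_dict()
        if isinstance(features, dict):
            missing = [k for k in self.coefficients if k not in features]
            if missing:
                raise KeyError(f"missing features: {missing}")
            return self.intercept + sum(
                self.coefficients[k] * features[k] for k in self.coefficients)
        x = np.asarray(features, dtype=float)
        w = np.array([self.coefficients[k] for k in FEATURE_NAMES])
        return self.intercept + x @ w

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        return self.predict(df[list(FEATURE_NAMES)].to_numpy())

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "MLRModel":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                data = json.loads(text)
            else:
                with open(text) as fh:
                    data = json.load(fh)
        return cls(**data)


def fit_mlr(dataset: pd.DataFrame) -> MLRModel:
    """OLS fit of ddg_exp on the nine features, with coefficient p-values
    (two-sided t) and standardized coefficients (importance)."""
    n = len(dataset)
    if n < len(FEATURE_NAMES) + 2:
        raise DatasetError(
            f"need at least {len(FEATURE_NAMES) + 2} rows, got {n}")
    x = dataset[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = dataset["ddg_exp"].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise DatasetError("non-finite feature values")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), x]))
    if rank < x.shape[1] + 1:
        bad = [FEATURE_NAMES[j] for j in range(x.shape[1])
               if np.std(x[:, j]) == 0.0]
        raise DatasetError(
            "rank-deficient design matrix"
            + (f": constant/collinear features {bad}" if bad else ""))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    coef = dict(zip(FEATURE_NAMES, res.params[1:]))
    pvals = dict(zip(FEATURE_NAMES, res.pvalues[1:]))
    sy = float(np.std(y, ddof=1))
    std_coef = {k: coef[k] * float(np.std(x[:, j], ddof=1)) / sy
                for j, k in enumerate(FEATURE_NAMES)}
    pred = res.fittedvalues
    return MLRModel(
        intercept=float(res.params[0]),
        coefficients={k: float(v) for k, v in coef.items()},
        std_coefficients={k: float(v) for k, v in std_coef.items()},
        p_values={k: float(v) for k, v in pvals.items()},
        training_r=_pearson(pred, y),
        training_rmse=float(np.sqrt(np.mean((pred - y) ** 2))),
        training_slope=_slope(pred, y),
        n_training=n,
    )


def predict_ddg(model: MLRModel, features) -> float:
    """Predicted ddG (kcal/mol); positive = destabilizing."""
    return float(model.predict(features))


def classify_deleterious(ddg_pred: float,
                         threshold: float = DELETERIOUS_DDG_PRED) -> bool:
    """Deleterious iff predicted ddG >= threshold (default 1.10 kcal/mol)."""
    return bool(ddg_pred >= threshold)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def _pearson(a, b) -> float:
    return float(stats.pearsonr(a, b)[0])


def _slope(pred, exp) -> float:
    """Slope of the regression of predicted on experimental values."""
    return float(stats.linregress(exp, pred).slope)


@dataclass
class EvaluationReport:
    r: float
    rmse: float
    slope: float
    roc: tuple                 # (fpr, tpr, thresholds)
    pr: tuple                  # (precision, recall, thresholds)
    auc_roc: float
    auc_pr: float
    mcc: float
    er_threshold: float
    n: int
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {"n": self.n, "R": self.r, "RMSE": self.rmse,
                "slope": self.slope, "AUC-ROC": self.auc_roc,
                "AUC-PR": self.auc_pr, "MCC": self.mcc,
                "threshold": self.er_threshold, **self.extras}


def matthews_cc(tp: int, tn: int, fp: int, fn: int) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))."""
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


def select_threshold_er(fpr, tpr, thresholds) -> float:
    """Prediction threshold minimizing ER = sqrt((1-TPR)^2 + FPR^2);
    ties resolve to the larger (more specific) threshold."""
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    er = np.sqrt((1.0 - tpr) ** 2 + fpr ** 2)
    best = np.min(er)
    candidates = thresholds[er <= best + 1e-12]
    return float(np.max(candidates[np.isfinite(candidates)]))


def evaluate(pred, exp, deleterious_cut_exp: float = DELETERIOUS_DDG_EXP,
             operating_threshold: float | None = None) -> EvaluationReport:
    """Regression and classification quality of predictions vs experiment.

    Labels are ``exp >= deleterious_cut_exp``.  The MCC is reported at the
    ER-optimal prediction threshold unless ``operating_threshold`` is given.
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValueError("pred/exp must be equal-length vectors, n >= 3")
    labels = exp >= deleterious_cut_exp
    if labels.all() or not labels.any():
        raise ValueError("single-class labels: ROC analysis undefined")

    fpr, tpr, roc_thr = roc_curve(labels, pred)
    precision, recall, pr_thr = precision_recall_curve(labels, pred)
    auc_roc = float(auc(fpr, tpr))
    auc_pr = float(auc(recall, precision))
    thr = (select_threshold_er(fpr, tpr, roc_thr)
           if operating_threshold is None else operating_threshold)
    hard = pred >= thr
    tp = int(np.sum(hard & labels))
    tn = int(np.sum(~hard & ~labels))
    fp = int(np.sum(hard & ~labels))
    fn = int(np.sum(~hard & labels))
    return EvaluationReport(
        r=_pearson(pred, exp),
        rmse=float(np.sqrt(np.mean((pred - exp) ** 2))),
        slope=_slope(pred, exp),
        roc=(fpr, tpr, roc_thr), pr=(precision, recall, pr_thr),
        auc_roc=auc_roc, auc_pr=auc_pr,
        mcc=matthews_cc(tp, tn, fp, fn),
        er_threshold=float(thr), n=len(pred),
        extras={"TP": tp, "TN": tn, "FP": fp, "FN": fn,
                "TPR": tp / max(tp + fn, 1), "FPR": fp / max(fp + tn, 1)},
    )


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

CV_SCHEMES = ("CV1", "CV2", "CV3")
_CV_TRAIN_FRACTION = {"CV1": 0.5, "CV2": 0.8}


@dataclass
class CrossValidationResult:
    scheme: str
    pooled: EvaluationReport
    per_fold_r: list
    per_fold_rmse: list
    coefficient_mean: dict
    coefficient_sd: dict
    predictions: pd.DataFrame      # row index, ddg_exp, ddg_pred, fold


def cross_validate(dataset: pd.DataFrame, scheme: str = "CV3",
                   n_repeats: int = 50, seed: int = 0,
                   deleterious_cut_exp: float = DELETERIOUS_DDG_EXP,
                   ) -> CrossValidationResult:
    """CV1: random 50/50 split x n_repeats; CV2: 80/20 x n_repeats;
    CV3: leave-one-complex-out.  Metrics are computed on the pooled
    out-of-fold predictions; per-fold R/RMSE and per-fold coefficient
    statistics are also reported.  Reproducible given the seed."""
    if scheme not in CV_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; pick from {CV_SCHEMES}")
    n = len(dataset)
    rng = np.random.default_rng(seed)
    dataset = dataset.reset_index(drop=True)

    folds = []
    if scheme == "CV3":
        complexes = sorted(dataset["complex_id"].unique())
        if len(complexes) < 2:
            raise DatasetError("CV3 needs at least two complexes")
        for c in complexes:
            test_idx = np.flatnonzero(dataset["complex_id"] == c)
            train_idx = np.flatnonzero(dataset["complex_id"] != c)
            folds.append((train_idx, test_idx, c))
    else:
        frac = _CV_TRAIN_FRACTION[scheme]
        n_train = int(round(frac * n))
        for rep in range(n_repeats):
            perm = rng.permutation(n)
            folds.append((perm[:n_train], perm[n_train:], rep))

    rows, fold_r, fold_rmse, coef_rows = [], [], [], []
    for train_idx, test_idx, tag in folds:
        model = fit_mlr(dataset.iloc[train_idx])
        pred = model.predict_frame(dataset.iloc[test_idx])
        exp = dataset.iloc[test_idx]["ddg_exp"].to_numpy()
        for i, p, e in zip(test_idx, pred, exp):
            rows.append({"row": int(i), "fold": tag,
                         "ddg_exp": float(e), "ddg_pred": float(p)})
        if len(test_idx) >= 3 and np.std(exp) > 0:
            fold_r.append(_pearson(pred, exp))
        fold_rmse.append(float(np.sqrt(np.mean((pred - exp) ** 2))))
        coef_rows.append({**model.coefficients, "intercept": model.intercept})

    preds = pd.DataFrame(rows)
    pooled = evaluate(preds["ddg_pred"], preds["ddg_exp"],
                      deleterious_cut_exp)
    coefs = pd.DataFrame(coef_rows)
    return CrossValidationResult(
        scheme=scheme, pooled=pooled,
        per_fold_r=fold_r, per_fold_rmse=fold_rmse,
        coefficient_mean=coefs.mean().to_dict(),
        coefficient_sd=coefs.std(ddof=1).to_dict(),
        predictions=preds,
    )


# --------------------------------------------------------------------------
# multicollinearity
# --------------------------------------------------------------------------

@dataclass
class VIFReport:
    correlation: pd.DataFrame
    vif: dict
    flagged: list                  # constant features (VIF undefined)


def multicollinearity(dataset: pd.DataFrame) -> VIFReport:
    """Pairwise feature correlations and variance inflation factors
    (VIF_j = 1/(1 - R_j^2) from regressing feature j on the others,
    with intercept)."""
    x = dataset[list(FEATURE_NAMES)].to_numpy(dtype=float)
    n, p = x.shape
    if n < p + 2:
        raise DatasetError("too few rows for a VIF analysis")
    corr = dataset[list(FEATURE_NAMES)].corr()
    vif, flagged = {}, []
    for j, name in enumerate(FEATURE_NAMES):
        yj = x[:, j]
        if np.std(yj) == 0.0:
            flagged.append(name)
            vif[name] = float("nan")
            continue
        others = np.delete(x, j, axis=1)
        a = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(a, yj, rcond=None)
        resid = yj - a @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vif[name] = float(1.0 / max(1.0 - r2, 1e-12))
    return VIFReport(correlation=corr, vif=vif, flagged=flagged)
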