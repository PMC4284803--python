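"""Tumour/normal qPCR biomarker signature.

Expression of candidate lncRNA markers is measured as ΔCt = marker Ct −
reference-gene (GAPDH) Ct, so higher ΔCt means lower expression; the
markers of interest are silenced in tumours and therefore have HIGHER
ΔCt in tumour tissue. Per marker, tumour vs matched normal is compared
with a paired two-tailed t-test and classification performance with a
ROC curve (positive class = tumour, score = ΔCt). Markers with AUC
strictly above 0.7 form the signature, whose joint performance is
estimated by tenfold patient-grouped, stratified cross-validated
logistic regression pooling the out-of-fold predicted probabilities
into one ROC/AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)

AUC_CUTOFF = 0.7
SIGNIFICANCE_ALPHA = 0.01
TISSUES = ("tumour", "normal")


# --- cohort container --------------------------------------------------


@dataclass
class CohortTable:
    """Paired tumour/normal ΔCt measurements.

    ``delta_ct`` is indexed by (patient, tissue) with one column per
    marker; the paired design requires both tissues for every patient.
    Missing Ct values surface as NaN and are flagged, never imputed as
    zero.
    """

    delta_ct: pd.DataFrame  # MultiIndex (patient, tissue) x markers

    def __post_init__(self) -> None:
        idx = self.delta_ct.index
        if idx.names != ["patient", "tissue"]:
            raise ValueError("delta_ct must be indexed by (patient, tissue)")
        for p in self.patients:
            tissues = set(self.delta_ct.loc[p].index)
            if not set(TISSUES) <= tissues:
                raise ValueError(f"patient {p} lacks a paired tumour/normal sample")

    @property
    def patients(self) -> list[str]:
        return list(self.delta_ct.index.get_level_values("patient").unique())

    @property
    def markers(self) -> list[str]:
        return list(self.delta_ct.columns)

    def tissue_matrix(self, tissue: str) -> pd.DataFrame:
        """Patients × markers ΔCt for one tissue."""
        return self.delta_ct.xs(tissue, level="tissue").loc[self.patients]

    def long_format(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, patient_idx): one row per sample, y=1 for tumour."""
        frames, labels, groups = [], [], []
        for tissue, lab in (("tumour", 1), ("normal", 0)):
            m = self.tissue_matrix(tissue)
            frames.append(m.to_numpy(float))
            labels.append(np.full(len(m), lab))
            groups.append(np.arange(len(m)))
        return (
            np.vstack(frames),
            np.concatenate(labels),
            np.concatenate(groups),
        )

    @classmethod
    def from_ct_table(cls, df: pd.DataFrame) -> "CohortTable":
        """Build from a long Ct table with columns patient, tissue,
        marker, ct, reference_ct."""
        required = {"patient", "tissue", "marker", "ct", "reference_ct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
        df = df.copy()
        df["delta_ct"] = delta_ct(
            df["ct"].to_numpy(float), df["reference_ct"].to_numpy(float)
        )
        wide = df.pivot_table(
            index=["patient", "tissue"], columns="marker", values="delta_ct",
            aggfunc="mean", dropna=False,
        )
        wide.columns.name = None
        if wide.isna().any().any():
            logger.warning(
                "cohort table contains %d missing ΔCt cells", int(wide.isna().sum().sum())
            )
        return cls(wide)


def read_ct_table(path: str | Path | IO[str]) -> CohortTable:
    return CohortTable.from_ct_table(pd.read_csv(path, sep="\t", dtype={"patient": str}))


def delta_ct(target_ct, reference_ct):
    """ΔCt = target Ct − reference Ct (higher ΔCt ⇔ lower expression).
    NaN propagates so that missing wells stay flagged."""
    return np.asarray(target_ct, float) - np.asarray(reference_ct, float)


def fold_change(delta_ct_tumour, delta_ct_normal):
    """Relative expression 2^−ΔΔCt with ΔΔCt = tumour − normal."""
    return 2.0 ** -(np.asarray(delta_ct_tumour, float) - np.asarray(delta_ct_normal, float))


# --- paired test -------------------------------------------------------


def paired_differential(
    tumour_dct: Sequence[float], normal_dct: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed paired t-test on per-patient tumour−normal ΔCt
    differences; returns (mean difference, p-value).

    Degenerate inputs: identical pairs everywhere give p = 1; a
    constant nonzero difference is reported at the smallest positive
    float (perfect separation of the paired design).
    """
    t = np.asarray(tumour_dct, float)
    n = np.asarray(normal_dct, float)
    mask = ~(np.isnan(t) | np.isnan(n))
    t, n = t[mask], n[mask]
    if len(t) < 2:
        raise ValueError("paired test requires at least two complete pairs")
    diff = t - n
    mean = float(diff.mean())
    if np.allclose(diff, diff[0]):
        return mean, 1.0 if math.isclose(mean, 0.0, abs_tol=1e-300) else float(np.nextafter(0, 1))
    res = stats.ttest_rel(t, n)
    return mean, float(res.pvalue)


# --- ROC / AUC ---------------------------------------------------------


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray  # 1 - specificity, starts at 0 ends at 1
    tpr: np.ndarray  # sensitivity
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC over all distinct score thresholds with trapezoidal AUC.

    Positive class = 1; a higher score is called positive first. Tied
    scores cross their threshold simultaneously, producing diagonal
    segments, so the trapezoid area equals the tie-corrected
    concordance (concordant + ties/2) / (n1·n0).
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and congruent")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted == 1)[distinct]
    fp = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, auc)


def select_signature(
    per_marker_auc: Mapping[str, float], cutoff: float = AUC_CUTOFF
) -> list[str]:
    """Markers with AUC strictly greater than the cutoff, in input
    order; an empty selection is legal and logged."""
    selected = [m for m, a in per_marker_auc.items() if a > cutoff]
    if not selected:
        logger.warning("no marker exceeds AUC cutoff %.2f", cutoff)
    return selected


# --- logistic regression (IRLS) ----------------------------------------


@dataclass
class LogisticModel:
    coef: np.ndarray
    intercept: float
    n_iter: int
    converged: bool
    log_likelihood: float
    separation: bool = False

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = np.clip(np.asarray(x, float) @ self.coef + self.intercept, -700, 700)
        return 1.0 / (1.0 + np.exp(-z))


def fit_logistic(
    x: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    weight_cap: float = 30.0,
) -> LogisticModel:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares (no regularisation).

    Convergence: change in log-likelihood below ``tol``. Complete
    separation is detected when any coefficient magnitude exceeds
    ``weight_cap``; the fit stops with converged=False and coefficients
    clipped at the cap (a usable, flagged model).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("x must be (n, p) with matching labels")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) < 2:
        raise ValueError("labels must contain both classes 0 and 1")
    n, p = x.shape
    design = np.c_[np.ones(n), x]
    beta = np.zeros(p + 1)
    last_ll = -np.inf
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(design @ beta, -700, 700)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * np.log(mu + 1e-320) + (1 - y) * np.log(1 - mu + 1e-320)))
        if abs(ll - last_ll) < tol:
            converged = True
            last_ll = ll
            break
        last_ll = ll
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        xw = design * w[:, None]
        prev = beta
        try:
            beta = np.linalg.solve(design.T @ xw, xw.T @ z)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(design.T @ xw, xw.T @ z, rcond=None)
        if np.abs(beta).max() > weight_cap:
            # complete (quasi-)separation: coefficients diverge; keep the
            # last finite iterate, which already classifies the data
            separation = True
            beta = prev
            break
    if last_ll > -1e-6:
        # log-likelihood at its supremum of 0: every sample fitted with
        # probability ~1, i.e. the classes are completely separated
        separation = True
    return LogisticModel(
        coef=beta[1:],
        intercept=float(beta[0]),
        n_iter=it,
        converged=converged and not separation,
        log_likelihood=last_ll,
        separation=separation,
    )


# --- cross-validated signature -----------------------------------------


@dataclass
class SignatureResult:
    markers: list[str]
    per_marker_auc: dict[str, float]
    selected: list[str]
    pooled_auc: float
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    fold_of_patient: dict[str, int]
    k: int
    seed: int


def crossval_signature(
    cohort: CohortTable,
    markers: Sequence[str] | None = None,
    k: int = 10,
    seed: int = 0,
    auc_cutoff: float = AUC_CUTOFF,
    use_all_when_empty: bool = False,
) -> SignatureResult:
    """Per-marker ROC, AUC-cutoff selection, then k-fold cross-validated
    logistic regression on the selected panel.

    Folds are assigned at the patient level (both tissues of a patient
    share a fold, which also stratifies the classes exactly in this
    paired design); the assignment is deterministic given ``seed``.
    Out-of-fold predicted probabilities are pooled into a single ROC.
    """
    markers = list(markers) if markers is not None else cohort.markers
    patients = cohort.patients
    if k > len(patients):
        raise ValueError(f"k={k} folds exceed {len(patients)} patients")
    tum = cohort.tissue_matrix("tumour")[markers]
    nor = cohort.tissue_matrix("normal")[markers]
    per_marker_auc: dict[str, float] = {}
    for m in markers:
        scores = np.r_[tum[m].to_numpy(float), nor[m].to_numpy(float)]
        labels = np.r_[np.ones(len(tum)), np.zeros(len(nor))]
        per_marker_auc[m] = roc_auc(scores, labels).auc
    selected = select_signature(per_marker_auc, auc_cutoff)
    panel = selected if selected or not use_all_when_empty else markers
    if not panel:
        raise ValueError("empty signature: no marker exceeded the AUC cutoff")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(patients))
    fold_of = {patients[int(j)]: int(i % k) for i, j in enumerate(perm)}
    x_t = tum[panel].to_numpy(float)
    x_n = nor[panel].to_numpy(float)
    pooled_scores = np.empty(2 * len(patients))
    pooled_labels = np.r_[np.ones(len(patients)), np.zeros(len(patients))]
    folds = np.array([fold_of[p] for p in patients])
    for f in range(k):
        test = folds == f
        train = ~test
        x_train = np.vstack([x_t[train], x_n[train]])
        y_train = np.r_[np.ones(train.sum()), np.zeros(train.sum())]
        model = fit_logistic(x_train, y_train)
        pooled_scores[np.flatnonzero(test)] = model.predict_proba(x_t[test])
        pooled_scores[len(patients) + np.flatnonzero(test)] = model.predict_proba(
            x_n[test]
        )
    pooled = roc_auc(pooled_scores, pooled_labels)
    return SignatureResult(
        markers=markers,
        per_marker_auc=per_marker_auc,
        selected=selected,
        pooled_auc=pooled.auc,
        pooled_scores=pooled_scores,
        pooled_labels=pooled_labels,
        fold_of_patient=fold_of,
        k=k,
        seed=seed,
    )


def marker_statistics(cohort: CohortTable, alpha: float = SIGNIFICANCE_ALPHA) -> pd.DataFrame:
    """Per-marker paired test, mean ΔΔCt, fold change and AUC."""
    tum = cohort.tissue_matrix("tumour")
    nor = cohort.tissue_matrix("normal")
    rows = []
    for m in cohort.markers:
        mean_diff, p = paired_differential(tum[m], nor[m])
        scores = np.r_[tum[m].to_numpy(float), nor[m].to_numpy(float)]
        labels = np.r_[np.ones(len(tum)), np.zeros(len(nor))]
        rows.append(
            {
                "marker": m,
                "mean_delta_delta_ct": mean_diff,
                "mean_fold_change": float(np.nanmean(fold_change(tum[m], nor[m]))),
                "p_value": p,
                "significant": p < alpha,
                "auc": roc_auc(scores, labels).auc,
            }
        )
    return pd.DataFrame(rows)


# --- clustering --------------------------------------------------------


def cluster_samples(matrix: pd.DataFrame) -> tuple[list, list]:
    """Agglomerative clustering (Euclidean, average linkage) of a
    markers × patients ΔCt matrix; returns (row order, column order) as
    leaf orderings. Axes with fewer than two items keep their input
    order. Missing cells must be handled upstream."""
    if matrix.isna().any().any():
        raise ValueError("clustering input contains missing cells")

    def order(data: np.ndarray, names: list) -> list:
        if len(names) < 2:
            return list(names)
        link = hierarchy.linkage(data, method="average", metric="euclidean")
        return [names[i] for i in hierarchy.leaves_list(link)]

    rows = order(matrix.to_numpy(float), list(matrix.index))
    cols = order(matrix.to_numpy(float).T, list(matrix.columns))
    return rows, cols
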