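"""Three-class aggressiveness classifier from methylation beta values.

Training protocol:

1. rank probes by the absolute mean-beta difference between the aggressive
   and non-aggressive groups and keep the top k (default 3000);
2. fit an L1-regularized (lasso; elastic-net mixing configurable)
   multinomial logistic regression, choosing the penalty strength by
   cross-validated log-loss; the "random start" of a fit is the seed of its
   CV fold assignment;
3. repeat with ``n_restarts`` distinct fold seeds, take the union of probes
   selected by any restart, and refit once on that union — the refit's
   nonzero probes and coefficients are the final model;
4. predict by softmax; a call is confident only when the winning class
   probability strictly exceeds the threshold (default 0.67, which forces
   every other class to 0.33 or less).

Class order (also the tie-break at exactly equal probabilities) is
``normal < non_aggressive < aggressive``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import log_loss
from sklearn.svm import l1_min_c
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CLASS_ORDER = ("normal", "non_aggressive", "aggressive")


# ---------------------------------------------------------------------------
# differential methylation


def differential_probes(
    beta: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-probe Welch t-tests between two sample groups with BH adjustment.

    Returns a frame indexed by probe with columns ``mean_diff`` (group1 -
    group2), ``t``, ``p``, ``q`` (Benjamini-Hochberg), ``significant`` (q <
    ``fdr``). Probes with zero variance in both groups and equal means get
    p = 1 by convention (logged); zero variance with unequal means gives
    p = 0 (perfect separation).
    """
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    (name1, s1), (name2, s2) = groups.items()
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs >= 2 samples for a Welch t-test")
    x1 = beta[list(s1)].to_numpy(float)
    x2 = beta[list(s2)].to_numpy(float)
    n1 = np.sum(~np.isnan(x1), axis=1)
    n2 = np.sum(~np.isnan(x2), axis=1)
    m1 = np.nanmean(x1, axis=1)
    m2 = np.nanmean(x2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v1 = np.nanvar(x1, axis=1, ddof=1)
        v2 = np.nanvar(x2, axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    flat = se2 == 0
    if flat.any():
        log.info("%d probes with zero variance in both groups", int(flat.sum()))
        equal = flat & (m1 == m2)
        t[equal] = 0.0
        p[equal] = 1.0
        t[flat & ~equal] = np.sign((m1 - m2)[flat & ~equal]) * np.inf
        p[flat & ~equal] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"mean_diff": m1 - m2, "t": t, "p": p, "q": q, "significant": q < fdr},
        index=beta.index,
    )


def top_mean_diff_probes(
    beta: pd.DataFrame,
    aggressive: Sequence[str],
    non_aggressive: Sequence[str],
    k: int = 3000,
) -> list[str]:
    """Top-k probes by |mean(aggressive) - mean(non_aggressive)| beta difference.

    Ties are broken by probe order in the matrix.
    """
    if k > beta.shape[0]:
        raise ValueError(f"k={k} exceeds the {beta.shape[0]} available probes")
    diff = np.abs(
        beta[list(aggressive)].mean(axis=1).to_numpy() - beta[list(non_aggressive)].mean(axis=1).to_numpy()
    )
    order = np.argsort(-diff, kind="stable")
    return list(beta.index[order[:k]])


# ---------------------------------------------------------------------------
# penalized multinomial fits


@dataclass
class GlmFit:
    """One regularized multinomial fit (raw beta scale) and its CV trace."""

    probes: list[str]
    classes: list[str]
    coef: np.ndarray  # (n_classes, n_probes), raw scale
    intercept: np.ndarray
    chosen_C: float
    cv_Cs: np.ndarray
    cv_mean_loss: np.ndarray
    seed: int

    @property
    def selected_probes(self) -> list[str]:
        nz = np.any(np.abs(self.coef) > 1e-8, axis=0)
        return [p for p, m in zip(self.probes, nz) if m]


def _canonical_xy(beta: pd.DataFrame, labels: pd.Series):
    """Samples sorted by id (fold assignment is then order-invariant)."""
    samples = sorted(labels.index)
    X = beta[samples].T.to_numpy(float)
    y = labels.loc[samples].to_numpy()
    return X, y, samples


@dataclass
class _Design:
    """Standardized design shared between the path fit and CV restarts."""

    Xs: np.ndarray
    y: np.ndarray
    classes: list[str]
    mu: np.ndarray
    sd: np.ndarray
    probes: list[str]


@dataclass
class _Path:
    """Regularization path on the full data, truncated at deviance saturation."""

    Cs: np.ndarray  # sparse -> dense
    coefs: list[np.ndarray]  # standardized scale, (n_classes, n_probes)
    intercepts: list[np.ndarray]
    dev_ratio: np.ndarray


def _prepare(beta: pd.DataFrame, labels: pd.Series) -> _Design:
    classes = sorted(set(labels), key=lambda c: CLASS_ORDER.index(c) if c in CLASS_ORDER else 99)
    if len(classes) < 2:
        raise ValueError("degenerate input: need >= 2 classes to fit")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError(f"every class needs >= 2 samples, got {counts.to_dict()}")
    X, y, _ = _canonical_xy(beta, labels)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return _Design(Xs=(X - mu) / sd, y=y, classes=classes, mu=mu, sd=sd, probes=list(beta.index))


def _make_clf(C: float, l1_ratio: float, max_iter: int, tol: float) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=l1_ratio, C=C, solver="saga", max_iter=max_iter, tol=tol, warm_start=True, random_state=0
    )


def _ordered_coef(clf: LogisticRegression, classes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    order = [list(clf.classes_).index(c) for c in classes]
    return clf.coef_[order], clf.intercept_[order]


def _softmax_proba(Xs: np.ndarray, coef: np.ndarray, icpt: np.ndarray) -> np.ndarray:
    Z = Xs @ coef.T + icpt
    Z -= Z.max(axis=1, keepdims=True)
    P = np.exp(Z)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _l1_fit(
    Xs: np.ndarray,
    y: np.ndarray,
    classes: list[str],
    C: float,
    l1_ratio: float,
    max_iter: int,
    tol: float,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """L1 multinomial fit via a working-set strategy.

    The saga solver runs on a small working set of features — those active
    in (or violating the zero-coefficient KKT condition |grad| <= 1/C at)
    the warm-start solution — and the KKT conditions for all discarded
    coordinates are then verified on the full design; violators are added
    and the fit repeated until clean. This yields the exact L1 solution at
    a fraction of the full-design cost, the same device coordinate-descent
    packages use for p >> n problems.

    Returns (coef (k, p), intercept (k,)) with exact zeros off the final
    working set.
    """
    n, p = Xs.shape
    k = len(classes)
    Y = np.zeros((n, k))
    cls_idx = {c: i for i, c in enumerate(classes)}
    Y[np.arange(n), [cls_idx[c] for c in y]] = 1.0
    thr = 1.0 / C
    if warm is None:
        p0 = Y.mean(axis=0)
        P = np.tile(p0, (n, 1))
        coef = np.zeros((k, p))
    else:
        coef, icpt0 = warm
        P = _softmax_proba(Xs, coef, icpt0)
    G = np.abs(Xs.T @ (P - Y)).max(axis=1)  # per-feature KKT score
    ws = (np.abs(coef).max(axis=0) > 1e-12) | (G >= thr)
    if not ws.any():
        ws[int(np.argmax(G))] = True
    icpt = np.zeros(k)
    for _ in range(10):
        clf = _make_clf(C, l1_ratio, max_iter, tol)
        with warnings.catch_warnings():
            # short solver budgets are deliberate; selection only needs
            # approximate coefficients and the KKT loop guards the support
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xs[:, ws], y)
        sub_coef, sub_icpt = _ordered_coef(clf, classes)
        coef = np.zeros((k, p))
        coef[:, ws] = sub_coef
        icpt = sub_icpt
        G = np.abs(Xs.T @ (_softmax_proba(Xs, coef, icpt) - Y)).max(axis=1)
        violators = (~ws) & (G > thr * 1.05 + 1e-8)
        if not violators.any():
            break
        ws = ws | violators
    if np.abs(coef).max() <= 1e-12:
        # all-zero model: the unpenalized-intercept optimum is analytic
        coef = np.zeros((k, p))
        icpt = np.log(np.clip(Y.mean(axis=0), 1e-12, None))
        icpt -= icpt.mean()
    return coef, icpt


def _multinomial_deviance(proba: np.ndarray, y: np.ndarray, classes: list[str]) -> float:
    idx = np.array([classes.index(c) for c in y])
    return float(-2.0 * np.sum(np.log(np.clip(proba[np.arange(len(y)), idx], 1e-12, None))))


def _fit_path(
    design: _Design,
    l1_ratio: float,
    n_penalties: int,
    max_iter: int,
    tol: float,
    devmax: float = 0.999,
) -> _Path:
    """Warm-started L1 path on the full data, sparse -> dense.

    Following glmnet's convention, the path stops early once the training
    deviance ratio reaches ``devmax``: on strongly separating data the dense
    tail of the grid is never visited, which keeps selected sets small.
    """
    Xs, y, classes = design.Xs, design.y, design.classes
    c_min = l1_min_c(Xs, y, loss="log") / max(l1_ratio, 1e-3)
    # head of the path is the empty (intercept-only) model, as in glmnet's
    # lambda_max; pure-noise inputs can then legitimately select nothing
    grid = c_min * np.concatenate([[0.99], np.logspace(0.05, 2, n_penalties - 1)])
    _, freq = np.unique(y, return_counts=True)
    null_dev = float(-2.0 * np.sum(np.log(freq / len(y)) * freq))
    Cs, coefs, icpts, ratios = [], [], [], []
    warm = None
    for C in grid:
        coef, icpt = _l1_fit(Xs, y, classes, C, l1_ratio, max_iter, tol, warm=warm)
        warm = (coef, icpt)
        dev = _multinomial_deviance(_softmax_proba(Xs, coef, icpt), y, classes)
        ratio = 1.0 - dev / null_dev
        Cs.append(C)
        coefs.append(coef)
        icpts.append(icpt)
        ratios.append(ratio)
        if len(Cs) >= 2 and (ratio >= devmax or ratio - ratios[-2] < 1e-4):
            break
    return _Path(Cs=np.array(Cs), coefs=coefs, intercepts=icpts, dev_ratio=np.array(ratios))


def _cv_choose(
    design: _Design,
    path: _Path,
    seed: int,
    n_folds: int,
    rule: str,
    l1_ratio: float,
    max_iter: int,
    tol: float,
) -> tuple[int, np.ndarray]:
    """Pick a penalty index on the truncated path by seeded K-fold CV."""
    Xs, y = design.Xs, design.y
    counts = pd.Series(y).value_counts()
    n_folds_eff = min(n_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    classes = design.classes
    cls_idx = {c: i for i, c in enumerate(classes)}
    losses = np.zeros((n_folds_eff, len(path.Cs)))
    for f, (tr, va) in enumerate(skf.split(Xs, y)):
        warm = None
        yv = np.array([cls_idx[c] for c in y[va]])
        for j, C in enumerate(path.Cs):
            coef, icpt = _l1_fit(Xs[tr], y[tr], classes, C, l1_ratio, max_iter, tol, warm=warm)
            warm = (coef, icpt)
            P = _softmax_proba(Xs[va], coef, icpt)
            losses[f, j] = float(-np.mean(np.log(np.clip(P[np.arange(len(va)), yv], 1e-12, None))))
    mean_loss = losses.mean(axis=0)
    se = losses.std(axis=0, ddof=1) / np.sqrt(n_folds_eff)
    j_min = int(np.argmin(mean_loss))
    if rule == "1se":
        j_pick = int(np.where(mean_loss <= mean_loss[j_min] + se[j_min])[0][0])  # sparsest within 1 SE
    elif rule == "min":
        j_pick = j_min
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return j_pick, mean_loss


def _to_raw(design: _Design, coef_std: np.ndarray, icpt_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coef_raw = coef_std / design.sd
    icpt_raw = icpt_std - (coef_std * (design.mu / design.sd)).sum(axis=1)
    return coef_raw, icpt_raw


def fit_multinomial_elasticnet(
    beta: pd.DataFrame,
    labels: pd.Series,
    l1_ratio: float = 1.0,
    seed: int = 0,
    n_folds: int = 3,
    n_penalties: int = 16,
    rule: str = "1se",
    max_iter: int = 600,
    tol: float = 1e-3,
    C: float | None = None,
) -> GlmFit:
    """L1/elastic-net multinomial logistic regression with CV-chosen penalty.

    ``labels`` maps sample id -> class. Features are standardized
    internally; coefficients are returned on the raw beta scale. The
    regularization path is fit once on the full data and truncated when the
    training deviance ratio saturates (glmnet's early-stopping convention);
    ``seed`` controls the CV fold assignment used to choose the penalty on
    that path — the protocol's "random start". ``rule`` is ``"1se"``
    (default: sparsest model within one standard error of the CV-minimum
    log-loss, the standard parsimony convention) or ``"min"``
    (CV-minimum, which on separable data sits at the dense end of the
    truncated path). Passing an explicit ``C`` skips path and CV entirely.
    """
    design = _prepare(beta, labels)
    if C is not None:
        coef_std, icpt_std = _l1_fit(design.Xs, design.y, design.classes, C, l1_ratio, max_iter, tol)
        coef_raw, icpt_raw = _to_raw(design, coef_std, icpt_std)
        return GlmFit(
            probes=design.probes, classes=design.classes, coef=coef_raw, intercept=icpt_raw,
            chosen_C=float(C), cv_Cs=np.array([C]), cv_mean_loss=np.array([np.nan]), seed=seed,
        )
    path = _fit_path(design, l1_ratio, n_penalties, max_iter, tol)
    j, mean_loss = _cv_choose(design, path, seed, n_folds, rule, l1_ratio, max_iter, tol)
    coef_raw, icpt_raw = _to_raw(design, path.coefs[j], path.intercepts[j])
    return GlmFit(
        probes=design.probes,
        classes=design.classes,
        coef=coef_raw,
        intercept=icpt_raw,
        chosen_C=float(path.Cs[j]),
        cv_Cs=path.Cs,
        cv_mean_loss=mean_loss,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# consensus protocol and final model


@dataclass
class ClassifierModel:
    """Final probe-panel classifier (raw-beta-scale multinomial coefficients)."""

    probes: list[str]
    class_order: list[str]
    coef: np.ndarray  # (n_classes, n_probes)
    intercept: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "probes": self.probes,
            "class_order": self.class_order,
            "coef": [list(row) for row in self.coef],
            "intercept": list(self.intercept),
            "metadata": self.metadata,
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, src: str | Path) -> "ClassifierModel":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        return cls(
            probes=list(d["probes"]),
            class_order=list(d["class_order"]),
            coef=np.array(d["coef"], float),
            intercept=np.array(d["intercept"], float),
            metadata=d.get("metadata", {}),
        )


def consensus_refinement(
    beta: pd.DataFrame,
    labels: pd.Series,
    n_restarts: int = 15,
    seed: int = 0,
    **fit_kwargs,
) -> ClassifierModel:
    """Union-of-restarts probe selection followed by a single refit.

    Runs ``fit_multinomial_elasticnet`` with ``n_restarts`` distinct CV-fold
    seeds derived from ``seed``, takes the union of selected probes across
    restarts, refits once on the union; the refit's nonzero probes and
    coefficients form the final model.

    The restart fits use a short solver budget (penalty choice only needs
    approximate coefficients); the union refit is low-dimensional and is run
    to full convergence so its L1 zeros are exact and the final panel is not
    inflated by unconverged coefficient residue.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    states = np.random.SeedSequence(seed).generate_state(n_restarts + 1) % (2**31)
    l1_ratio = fit_kwargs.get("l1_ratio", 1.0)
    n_folds = fit_kwargs.get("n_folds", 3)
    n_penalties = fit_kwargs.get("n_penalties", 16)
    rule = fit_kwargs.get("rule", "1se")
    max_iter = fit_kwargs.get("max_iter", 600)
    tol = fit_kwargs.get("tol", 1e-3)

    # the full-data path is deterministic given the data; restarts differ
    # only in their CV fold assignment, so fit the path once
    design = _prepare(beta, labels)
    path = _fit_path(design, l1_ratio, n_penalties, max_iter, tol)
    union: set[str] = set()
    for i in range(n_restarts):
        j, _ = _cv_choose(design, path, int(states[i]), n_folds, rule, l1_ratio, max_iter, tol)
        nz = np.any(np.abs(path.coefs[j]) > 1e-8, axis=0)
        union |= {p for p, m in zip(design.probes, nz) if m}
    if not union:
        raise ValueError("no discriminative probes found: every restart selected an empty model")
    union_probes = [p for p in beta.index if p in union]  # matrix order, deterministic
    refit_kwargs = {**fit_kwargs, "max_iter": 5000, "tol": 1e-4}
    refit = fit_multinomial_elasticnet(beta.loc[union_probes], labels, seed=int(states[-1]), **refit_kwargs)
    panel = refit.selected_probes
    if not panel:
        raise ValueError("no discriminative probes found: the union refit selected an empty model")
    keep = [refit.probes.index(p) for p in panel]
    log.info(
        "consensus: %d restarts, union of %d probes, final panel of %d", n_restarts, len(union_probes), len(panel)
    )
    return ClassifierModel(
        probes=panel,
        class_order=list(refit.classes),
        coef=refit.coef[:, keep],
        intercept=refit.intercept,
        metadata={
            "n_restarts": n_restarts,
            "seed": seed,
            "restart_seeds": [int(s) for s in states[:-1]],
            "refit_seed": int(states[-1]),
            "union_size": len(union_probes),
            "panel_size": len(panel),
            "chosen_C": refit.chosen_C,
        },
    )


# ---------------------------------------------------------------------------
# prediction


@dataclass
class PredictionResult:
    """Per-sample class probabilities, argmax call, and confidence flag."""

    frame: pd.DataFrame  # p_<class> columns, predicted, confident
    rejected: dict[str, str] = field(default_factory=dict)
    threshold: float = 0.67

    def confident_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["confident"]]


def predict(model: ClassifierModel, beta: pd.DataFrame, threshold: float = 0.67) -> PredictionResult:
    """Softmax prediction for every sample with complete model-probe data.

    Samples with any missing value among the model probes are rejected per
    sample (listed in ``rejected`` with a reason). The call is confident only
    if the winning probability strictly exceeds ``threshold``. Exactly-equal
    probabilities break ties by class order.
    """
    missing = [p for p in model.probes if p not in beta.index]
    if missing:
        raise KeyError(f"model probes absent from beta matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    X = beta.loc[model.probes].T  # samples x probes
    rejected: dict[str, str] = {}
    rows = []
    ok_samples = []
    for sid, row in zip(X.index, X.to_numpy(float)):
        if np.isnan(row).any():
            rejected[sid] = "missing values among model probes"
            continue
        ok_samples.append(sid)
        rows.append(row)
    if rows:
        Z = np.array(rows) @ model.coef.T + model.intercept
        Z -= Z.max(axis=1, keepdims=True)
        P = np.exp(Z)
        P /= P.sum(axis=1, keepdims=True)
    else:
        P = np.empty((0, len(model.class_order)))
    pred = [model.class_order[i] for i in np.argmax(P, axis=1)]  # first max wins ties
    frame = pd.DataFrame(P, index=ok_samples, columns=[f"p_{c}" for c in model.class_order])
    frame["predicted"] = pred
    frame["confident"] = P.max(axis=1) > threshold if len(rows) else pd.Series(dtype=bool)
    frame.index.name = "sample_id"
    return PredictionResult(frame=frame, rejected=rejected, threshold=threshold)


# ---------------------------------------------------------------------------
# label assembly


def group_labels(
    sample_sheet: pd.DataFrame,
    calls: Sequence,
    include_nl: bool = False,
) -> pd.Series:
    """Training labels: AN samples -> normal; categorized foci -> their class.

    ``calls`` are AggressivenessCall objects; undecided foci are excluded,
    as are PL/PIN samples. NL samples join the normal group only when
    ``include_nl`` is set.
    """
    labels: dict[str, str] = {}
    normal_types = ("AN", "NL") if include_nl else ("AN",)
    for _, row in sample_sheet.iterrows():
        if row["tissue_type"] in normal_types:
            labels[row["sample_id"]] = "normal"
    for call in calls:
        for fc in call.calls:
            if fc.category in ("aggressive", "non_aggressive"):
                labels[fc.sample_id] = fc.category
    return pd.Series(labels, name="class")
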