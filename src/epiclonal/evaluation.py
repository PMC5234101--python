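"""Confusion metrics with cancer-vs-normal collapsing, and association tests.

The three-class prediction (normal / non-aggressive / aggressive) is
collapsed to a binary cancer call (cancer = non-aggressive or aggressive)
and compared with the histological tissue type (tumor vs adjacent normal) to
give sensitivity, specificity, and negative/positive predictive values.
Association of predicted aggressiveness with clinical covariates uses Welch
t-tests for continuous covariates and two-tailed Fisher exact (per level)
plus Pearson chi-square tests for categorical ones, restricted to confident
predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CANCER_CLASSES = ("non_aggressive", "aggressive")


@dataclass
class ConfusionSummary:
    """Counts of true tissue x predicted class plus derived metrics (percent).

    Metrics are held at full precision; ``rounded()`` gives the one-decimal
    display convention. A metric with a zero denominator is None and flagged
    in ``undefined``.
    """

    an_counts: dict[str, int]
    tumor_counts: dict[str, int]
    sensitivity: float | None
    specificity: float | None
    npv: float | None
    ppv: float | None
    undefined: list[str]

    def rounded(self) -> dict[str, float | None]:
        return {
            k: (None if v is None else round(v, 1))
            for k, v in {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "npv": self.npv,
                "ppv": self.ppv,
            }.items()
        }


def confusion_metrics(
    an_counts: Mapping[str, int], tumor_counts: Mapping[str, int]
) -> ConfusionSummary:
    """Derive sensitivity/specificity/NPV/PPV from prediction count tables.

    ``an_counts`` / ``tumor_counts`` map predicted class (normal,
    non_aggressive, aggressive) to the number of adjacent-normal / tumor
    samples receiving that call. Predicted "cancer" pools the non-aggressive
    and aggressive calls. All metrics are percentages.
    """
    for name, counts in (("an_counts", an_counts), ("tumor_counts", tumor_counts)):
        for k, v in counts.items():
            if v < 0 or int(v) != v:
                raise ValueError(f"{name}[{k!r}] = {v} is not a nonnegative integer")
    an_normal = int(an_counts.get("normal", 0))
    an_cancer = sum(int(an_counts.get(c, 0)) for c in CANCER_CLASSES)
    tum_normal = int(tumor_counts.get("normal", 0))
    tum_cancer = sum(int(tumor_counts.get(c, 0)) for c in CANCER_CLASSES)
    n_an = an_normal + an_cancer
    n_tum = tum_normal + tum_cancer
    pred_normal = an_normal + tum_normal
    pred_cancer = an_cancer + tum_cancer

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return 100.0 * num / den

    return ConfusionSummary(
        an_counts=dict(an_counts),
        tumor_counts=dict(tumor_counts),
        sensitivity=ratio(tum_cancer, n_tum, "sensitivity"),
        specificity=ratio(an_normal, n_an, "specificity"),
        npv=ratio(an_normal, pred_normal, "npv"),
        ppv=ratio(tum_cancer, pred_cancer, "ppv"),
        undefined=undefined,
    )


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 table (hypergeometric tail sum)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, t.astype(int)):
        raise ValueError("need a 2x2 table of nonnegative integers")
    return float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])


def welch_t(group1, group2) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances); returns (statistic, p).

    Zero variance in both groups with equal means returns (0, 1) by
    convention.
    """
    x = np.asarray(group1, float)
    y = np.asarray(group2, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def chi_square_association(contingency) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table.

    Rows/columns with zero margin are dropped with a warning.
    """
    t = np.asarray(contingency, float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        log.warning("dropping %d zero-margin rows and %d columns", int((~keep_r).sum()), int((~keep_c).sum()))
        t = t[keep_r][:, keep_c]
        if t.shape[0] < 2 or t.shape[1] < 2:
            raise ValueError("table degenerate after dropping zero margins")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def association_report(
    predictions: pd.DataFrame,
    covariates: pd.DataFrame,
    min_level_count: int = 1,
) -> pd.DataFrame:
    """Test covariates against predicted aggressiveness (confident calls only).

    ``predictions`` is the frame from :func:`epiclonal.classifier.predict`
    (needs ``predicted`` and ``confident`` columns); ``covariates`` is
    indexed by sample id. Continuous covariates get a Welch t-test between
    the aggressive and non-aggressive groups; categorical covariates get an
    overall chi-square plus a per-level two-tailed Fisher exact test
    (level vs rest), mirroring per-stage/per-grade reporting conventions.
    """
    conf = predictions[predictions["confident"] & predictions["predicted"].isin(CANCER_CLASSES)]
    joined = conf.join(covariates, how="inner")
    agg = joined[joined["predicted"] == "aggressive"]
    non = joined[joined["predicted"] == "non_aggressive"]
    rows = []
    for cov in covariates.columns:
        a = agg[cov].dropna()
        n = non[cov].dropna()
        if len(a) == 0 or len(n) == 0:
            rows.append(
                {"covariate": cov, "level": "", "test": "skipped", "n_aggressive": len(a), "n_non_aggressive": len(n), "statistic": np.nan, "p": np.nan, "note": "one group empty"}
            )
            continue
        if pd.api.types.is_numeric_dtype(joined[cov]) and joined[cov].nunique() > 5:
            t, p = welch_t(a.to_numpy(), n.to_numpy())
            rows.append(
                {"covariate": cov, "level": "", "test": "welch_t", "n_aggressive": len(a), "n_non_aggressive": len(n), "statistic": t, "p": p, "note": ""}
            )
        else:
            levels = sorted(pd.concat([a, n]).unique(), key=str)
            table = np.array(
                [[int((a == lv).sum()) for lv in levels], [int((n == lv).sum()) for lv in levels]]
            )
            if len(levels) >= 2:
                try:
                    stat, p = chi_square_association(table)
                    rows.append(
                        {"covariate": cov, "level": "(all)", "test": "chi_square", "n_aggressive": len(a), "n_non_aggressive": len(n), "statistic": stat, "p": p, "note": ""}
                    )
                except ValueError as e:
                    rows.append(
                        {"covariate": cov, "level": "(all)", "test": "chi_square", "n_aggressive": len(a), "n_non_aggressive": len(n), "statistic": np.nan, "p": np.nan, "note": str(e)}
                    )
            for j, lv in enumerate(levels):
                if table[:, j].sum() < min_level_count:
                    continue
                sub = np.array(
                    [
                        [table[0, j], table[0].sum() - table[0, j]],
                        [table[1, j], table[1].sum() - table[1, j]],
                    ]
                )
                p = fisher_exact_2x2(sub)
                rows.append(
                    {"covariate": cov, "level": str(lv), "test": "fisher_exact", "n_aggressive": len(a), "n_non_aggressive": len(n), "statistic": np.nan, "p": p, "note": ""}
                )
    return pd.DataFrame(rows)
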