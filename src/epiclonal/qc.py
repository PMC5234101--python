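"""Beta computation, probe masking, and methylation-based purity filters.

The purity filters address two failure modes of dissected FFPE tissue:

* leukocyte infiltration — scored as the mean beta over a panel of probes
  that are unmethylated in peripheral blood but methylated in normal
  prostate; a low score means the DNA is mostly of blood origin;
* normal-cell contamination of tumor foci — scored as the mean beta over
  four GSTP1 promoter probes that gain methylation in prostate tumors; a low
  score in a nominal tumor sample means it is mostly normal epithelium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import IntensityMatrixPair

log = logging.getLogger(__name__)

#: the four GSTP1 HM450 probes used for tumor-purity scoring on real arrays
GSTP1_HM450_PROBES = ("cg06928838", "cg09038676", "cg22224704", "cg26250609")


@dataclass
class ProbeMask:
    """Probes to exclude, with reason tags (snp_at_cpg, repeat_within_15b, ...)."""

    probes: dict[str, str]

    @classmethod
    def from_file(cls, path) -> "ProbeMask":
        probes = {}
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            probes[parts[0]] = parts[1] if len(parts) > 1 else "custom"
        return cls(probes)

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class PuritySummary:
    """Per-sample purity scores and exclusion flags.

    ``table`` is indexed by sample id with columns ``score``, ``excluded``,
    ``reason``; scores are in [0, 1] (NaN where the filter does not apply).
    """

    table: pd.DataFrame
    filter_name: str

    @property
    def excluded_samples(self) -> list[str]:
        return list(self.table.index[self.table["excluded"]])

    def to_csv(self, path) -> None:
        self.table.rename_axis("sample_id").to_csv(path)


def compute_beta(intensities: IntensityMatrixPair) -> pd.DataFrame:
    """beta = M / (M + U); entries with M + U = 0 become missing (NaN)."""
    M = intensities.methylated
    U = intensities.unmethylated
    total = M.to_numpy(float) + U.to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M.to_numpy(float) / total, np.nan)
    return pd.DataFrame(beta, index=M.index, columns=M.columns)


def apply_detection_mask(
    beta: pd.DataFrame, detection_p: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Set entries with detection p strictly greater than ``threshold`` missing."""
    if not beta.index.equals(detection_p.index) or not beta.columns.equals(detection_p.columns):
        raise ValueError("detection_p misaligned with beta matrix")
    return beta.mask(detection_p > threshold)


def apply_probe_mask(beta: pd.DataFrame, mask: ProbeMask | Iterable[str]) -> pd.DataFrame:
    """Drop masked probe rows (SNP/repeat-overlapping probes etc.)."""
    ids = set(mask.probes) if isinstance(mask, ProbeMask) else set(mask)
    keep = ~beta.index.isin(ids)
    out = beta.loc[keep]
    if out.shape[0] == 0:
        log.warning("probe mask removed every probe; downstream analyses are degenerate")
    return out


def build_leukocyte_panel(
    blood: pd.DataFrame,
    an_prostate: pd.DataFrame,
    blood_beta_max: float = 0.2,
    panel_size: int = 500,
) -> list[str]:
    """Select the leukocyte-infiltration scoring panel.

    Probes with mean beta > ``blood_beta_max`` across the blood reference are
    excluded; the remaining candidates are ranked by descending mean beta in
    adjacent-normal prostate and the top ``panel_size`` returned (ties broken
    by probe order).
    """
    if blood.shape[1] < 1 or an_prostate.shape[1] < 1:
        raise ValueError("need >= 1 blood and >= 1 AN prostate column")
    shared = blood.index.intersection(an_prostate.index)
    blood_mean = blood.loc[shared].mean(axis=1)
    candidates = shared[blood_mean.to_numpy() <= blood_beta_max]
    if len(candidates) < panel_size:
        raise ValueError(
            f"only {len(candidates)} probes pass the blood filter (beta <= {blood_beta_max}); "
            f"cannot build a panel of {panel_size}"
        )
    an_mean = an_prostate.loc[candidates].mean(axis=1).to_numpy()
    order = np.argsort(-an_mean, kind="stable")  # ties keep probe order
    return list(candidates[order[:panel_size]])


def leukocyte_filter(
    beta: pd.DataFrame, panel: Sequence[str], min_mean: float = 0.6
) -> PuritySummary:
    """Flag samples whose mean beta over the leukocyte panel is below ``min_mean``."""
    missing = [p for p in panel if p not in beta.index]
    if missing:
        raise KeyError(f"panel probes absent from beta matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    score = beta.loc[list(panel)].mean(axis=0)
    excluded = score < min_mean  # strictly below
    table = pd.DataFrame(
        {
            "score": score,
            "excluded": excluded,
            "reason": np.where(excluded, f"leukocyte panel mean < {min_mean}", ""),
        }
    )
    return PuritySummary(table=table, filter_name="leukocyte")


def gstp1_purity_filter(
    beta: pd.DataFrame,
    gstp1_probes: Sequence[str],
    tumor_samples: Sequence[str],
    min_mean: float = 0.4,
) -> PuritySummary:
    """Flag tumor samples with low GSTP1 methylation (high normal content).

    Non-tumor samples are never flagged by this filter (their score is NaN).
    """
    missing = [p for p in gstp1_probes if p not in beta.index]
    if missing:
        raise KeyError(f"GSTP1 probes absent from beta matrix: {missing}")
    score = beta.loc[list(gstp1_probes)].mean(axis=0)
    is_tumor = beta.columns.isin(tumor_samples)
    score = score.where(is_tumor)
    excluded = (score < min_mean).fillna(False)
    table = pd.DataFrame(
        {
            "score": score,
            "excluded": excluded,
            "reason": np.where(excluded, f"GSTP1 4-probe mean < {min_mean}", ""),
        }
    )
    return PuritySummary(table=table, filter_name="gstp1")


def combine_purity(*summaries: PuritySummary) -> pd.DataFrame:
    """Merge purity filters into one table with a union exclusion flag."""
    if not summaries:
        raise ValueError("no purity summaries given")
    idx = summaries[0].table.index
    out = pd.DataFrame(index=idx)
    excluded = pd.Series(False, index=idx)
    reasons = pd.Series("", index=idx)
    for s in summaries:
        out[f"{s.filter_name}_score"] = s.table["score"]
        excluded |= s.table["excluded"].reindex(idx, fill_value=False)
        r = s.table["reason"].reindex(idx, fill_value="")
        sep = np.where((reasons != "") & (r != ""), "; ", "")
        reasons = pd.Series(reasons.to_numpy(object) + sep + r.to_numpy(object), index=idx)
    out["excluded"] = excluded
    out["reason"] = reasons
    return out
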