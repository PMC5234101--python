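"""Copy-number profiles from methylation-array intensities.

Total probe fluorescence (methylated + unmethylated) tracks local DNA copy
number. Per-probe log2 ratios against the mean of a normal reference panel,
median-centered per sample, are segmented by recursive binary splitting
(a CBS-like t-statistic rule) and segments are called gain/loss at a fixed
absolute threshold on the segment mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import IntensityMatrixPair

log = logging.getLogger(__name__)


@dataclass
class Segment:
    chrom: int
    start: int  # probe offset within chrom, half-open
    end: int
    n_probes: int
    mean: float
    call: str = "neutral"


@dataclass
class CNAProfile:
    """Per-sample copy-number profile: probe log2 ratios plus called segments."""

    sample_id: str
    log2_ratio: pd.Series  # indexed by probe id, ordered by (chrom, pos)
    segments: list[Segment] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "n_probes": s.n_probes,
                    "seg_mean": s.mean,
                    "call": s.call,
                }
                for s in self.segments
            ]
        )


def log_ratio_profile(
    intensities: IntensityMatrixPair,
    reference: IntensityMatrixPair,
) -> pd.DataFrame:
    """Per-probe log2 total-intensity ratios against the reference panel mean.

    ratio = log2((M+U)_sample / mean_ref(M+U)), then each sample's ratios are
    median-centered at 0 (making calls invariant to uniform intensity
    scaling of a sample). Probes with zero reference intensity are dropped.
    """
    if reference.methylated.shape[1] < 1:
        raise ValueError("need >= 1 reference sample")
    shared = intensities.methylated.index.intersection(reference.methylated.index)
    if len(shared) == 0:
        raise ValueError("no shared probe ids between sample and reference intensities")
    tot = intensities.total.loc[shared]
    ref_mean = reference.total.loc[shared].mean(axis=1)
    keep = ref_mean > 0
    if (~keep).any():
        log.warning("dropping %d probes with zero reference intensity", int((~keep).sum()))
    tot = tot.loc[keep]
    ref_mean = ref_mean.loc[keep]
    ratios = np.log2(tot.div(ref_mean, axis=0))
    return ratios - ratios.median(axis=0)


def _best_split(x: np.ndarray, min_probes: int):
    """Best two-sided Welch-t breakpoint in x, or None.

    Candidate breakpoints leave >= min_probes on each side; returns
    (index, p-value Bonferroni-corrected over candidates).
    """
    n = len(x)
    if n < 2 * min_probes:
        return None
    ks = np.arange(min_probes, n - min_probes + 1)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = csum[ks - 1]
    s2 = csum[-1] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    v1 = np.maximum((csq[ks - 1] - n1 * m1**2) / np.maximum(n1 - 1, 1), 0.0)
    v2 = np.maximum((csq[-1] - csq[ks - 1] - n2 * m2**2) / np.maximum(n2 - 1, 1), 0.0)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, (m1 - m2) / np.sqrt(se2), 0.0)
        df = np.where(
            se2 > 0,
            se2**2 / np.maximum((v1 / n1) ** 2 / np.maximum(n1 - 1, 1) + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1), 1e-300),
            1.0,
        )
    best = int(np.argmax(np.abs(t)))
    if t[best] == 0:
        return None
    p = 2.0 * stats.t.sf(abs(t[best]), df[best])
    return int(ks[best]), min(1.0, p * len(ks))


def _segment_chrom(x: np.ndarray, start: int, min_probes: int, alpha: float, out: list[tuple[int, int]]):
    split = _best_split(x, min_probes)
    if split is not None and split[1] < alpha:
        k = split[0]
        _segment_chrom(x[:k], start, min_probes, alpha, out)
        _segment_chrom(x[k:], start + k, min_probes, alpha, out)
    else:
        out.append((start, start + len(x)))


def segment_profile(
    ratios: pd.Series,
    annotation: pd.DataFrame,
    min_probes: int = 10,
    alpha: float = 0.01,
) -> list[Segment]:
    """Segment one sample's log2 ratios by recursive binary splitting.

    At each step the breakpoint maximizing the two-sided Welch t-statistic
    between flanks is placed and accepted if its Bonferroni-corrected p-value
    (over candidate positions) is below ``alpha`` and both sides keep at
    least ``min_probes`` probes. Probes must carry (chrom, pos) annotation;
    segments never span a chromosome boundary. Deterministic.
    """
    ann = annotation.loc[ratios.index]
    order = np.lexsort((ann["pos"].to_numpy(), ann["chrom"].to_numpy()))
    ratios = ratios.iloc[order]
    ann = ann.iloc[order]
    segments: list[Segment] = []
    for chrom in pd.unique(ann["chrom"]):
        mask = (ann["chrom"] == chrom).to_numpy()
        x = ratios.to_numpy()[mask]
        bounds: list[tuple[int, int]] = []
        _segment_chrom(x, 0, min_probes, alpha, bounds)
        for s, e in bounds:
            segments.append(
                Segment(chrom=int(chrom), start=s, end=e, n_probes=e - s, mean=float(x[s:e].mean()))
            )
    return segments


def call_segments(segments: list[Segment], threshold: float = 0.3) -> list[Segment]:
    """Call each segment gain (mean >= +threshold), loss (<= -threshold), or neutral."""
    for s in segments:
        if s.mean >= threshold:
            s.call = "gain"
        elif s.mean <= -threshold:
            s.call = "loss"
        else:
            s.call = "neutral"
    return segments


def cna_profile(
    intensities: IntensityMatrixPair,
    reference: IntensityMatrixPair,
    annotation: pd.DataFrame,
    sample_id: str,
    min_probes: int = 10,
    alpha: float = 0.01,
    threshold: float = 0.3,
) -> CNAProfile:
    """Full per-sample pipeline: log-ratios -> segmentation -> gain/loss calls."""
    ratios = log_ratio_profile(intensities, reference)[sample_id]
    segments = call_segments(segment_profile(ratios, annotation, min_probes, alpha), threshold)
    return CNAProfile(sample_id=sample_id, log2_ratio=ratios, segments=segments)
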