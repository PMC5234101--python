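"""Per-patient clonal analysis of methylation profiles.

A lymph-node metastasis (PL) shares its subclone of origin's methylation
profile, so the primary focus nearest to the PL in Euclidean beta space is
taken as the seeding — hence aggressive — lesion. The remaining foci are
categorized by how much farther they sit from the PL than the nearest focus
(the "additional distance" dist2): within ``gap_low`` units they are still
called aggressive (monoclonal tumors stay one group), beyond ``gap_high``
they are non-aggressive, and the band in between is left undecided to keep
the training groups clean.

Note on units: the gap defaults (10 and 20) refer to Euclidean distances
over the full ~396k-probe filtered array. Euclidean distance grows like
sqrt(#probes), so analyses on a different probe universe must rescale the
gaps accordingly; they are plain parameters here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

log = logging.getLogger(__name__)


def pairwise_pearson(beta: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between samples.

    Probes missing in either member of a pair are dropped for that pair;
    pairs with fewer than 2 overlapping probes get NaN (logged).
    """
    sub = beta[samples] if samples is not None else beta
    if sub.shape[1] < 2:
        raise ValueError("need >= 2 samples for pairwise correlation")
    corr = sub.corr(method="pearson", min_periods=2)
    if corr.isna().to_numpy().any():
        log.warning("some sample pairs had <2 overlapping probes; correlations set to NaN")
    return corr


def top_variable_probes(
    beta: pd.DataFrame, samples: list[str] | None = None, fraction: float = 0.01
) -> list[str]:
    """The ceil(fraction * n) most variably methylated complete-case probes.

    Variability is the per-probe standard deviation across ``samples``
    (typically all of a patient's samples except the PLs). Probes with any
    missing value among those samples are excluded first. Ties are broken by
    probe order.
    """
    sub = beta[samples] if samples is not None else beta
    complete = sub.dropna(axis=0)
    if complete.shape[0] == 0:
        raise ValueError("no complete-case probes available for variability ranking")
    sd = complete.std(axis=1, ddof=1).to_numpy()
    k = math.ceil(fraction * complete.shape[0])
    order = np.argsort(-sd, kind="stable")
    return list(complete.index[order[:k]])


@dataclass
class ClusterResult:
    """Complete-linkage dendrogram over Euclidean sample distances."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    def leaves(self) -> list[str]:
        return [self.labels[i] for i in sch.leaves_list(self.linkage)]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hierarchical_cluster(beta: pd.DataFrame, samples: list[str] | None = None) -> ClusterResult:
    """Unsupervised complete-linkage clustering on Euclidean distances."""
    sub = beta[samples] if samples is not None else beta
    if sub.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    complete = sub.dropna(axis=0)
    Z = sch.linkage(complete.T.to_numpy(), method="complete", metric="euclidean")
    return ClusterResult(labels=list(sub.columns), linkage=Z)


@dataclass
class AveragedReference:
    """Per-probe mean profile of one tissue type, with a homogeneity diagnostic.

    ``sd_above_fraction`` is the fraction of probes whose between-sample SD
    exceeds ``sd_threshold`` — small values justify collapsing the tissue
    type to a single averaged pseudo-sample.
    """

    profile: pd.Series
    n_probes: int
    n_sd_above: int
    sd_threshold: float

    @property
    def sd_above_fraction(self) -> float:
        return self.n_sd_above / self.n_probes

    @property
    def sd_above_percent(self) -> float:
        return 100.0 * self.sd_above_fraction


def average_reference(
    beta: pd.DataFrame, samples: list[str], sd_threshold: float = 0.15
) -> AveragedReference:
    """Average samples of one tissue type into a pseudo-sample.

    The mean is over non-missing values per probe (missing only if missing in
    every sample). Also reports how many probes have between-sample SD above
    ``sd_threshold``.
    """
    if len(samples) < 1:
        raise ValueError("need >= 1 sample to average")
    sub = beta[list(samples)]
    profile = sub.mean(axis=1)
    if len(samples) > 1:
        sd = sub.std(axis=1, ddof=1)
        n_above = int((sd > sd_threshold).sum())
    else:
        n_above = 0
    return AveragedReference(
        profile=profile, n_probes=beta.shape[0], n_sd_above=n_above, sd_threshold=sd_threshold
    )


@dataclass
class EuclideanResult:
    """Distance matrix plus the complete-case probe count it was computed on."""

    dm: DistanceMatrix
    n_probes_used: int


def euclidean_distances(beta: pd.DataFrame, samples: list[str] | None = None) -> EuclideanResult:
    """Euclidean distances between samples over complete-case probes.

    Probes with a missing value in any involved sample are dropped
    (complete-case within the sample set); the number used is recorded.
    """
    sub = beta[samples] if samples is not None else beta
    complete = sub.dropna(axis=0)
    n = complete.shape[0]
    if n == 0:
        raise ValueError("no complete-case probes shared by the samples")
    log.info("euclidean_distances using %d complete-case probes for %d samples", n, sub.shape[1])
    d = squareform(pdist(complete.T.to_numpy(), metric="euclidean"))
    return EuclideanResult(dm=DistanceMatrix(d, ids=list(sub.columns)), n_probes_used=n)


@dataclass
class FocusCall:
    sample_id: str
    category: str  # aggressive | undecided | non_aggressive
    t_pl_dist1: float  # actual distance of this focus to the chosen PL
    t_pl_dist2: float  # excess over the nearest focus's distance


@dataclass
class AggressivenessCall:
    """Per-patient categorization of primary foci by distance to the metastasis."""

    patient_id: str
    chosen_pl: str
    dist1: float  # shortest focus-PL distance
    calls: list[FocusCall] = field(default_factory=list)

    def category_of(self, sample_id: str) -> str:
        for c in self.calls:
            if c.sample_id == sample_id:
                return c.category
        raise KeyError(sample_id)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": self.patient_id,
                    "sample_id": c.sample_id,
                    "category": c.category,
                    "t_pl_dist1": c.t_pl_dist1,
                    "t_pl_dist2": c.t_pl_dist2,
                    "chosen_pl": self.chosen_pl,
                }
                for c in self.calls
            ]
        )


def categorize_aggressiveness(
    dist: DistanceMatrix,
    sample_sheet: pd.DataFrame,
    patient_id: str,
    gap_low: float = 10.0,
    gap_high: float = 20.0,
) -> AggressivenessCall:
    """Categorize a patient's primary foci as aggressive/undecided/non-aggressive.

    The reference PL is the one with the shortest distance to any primary
    focus (relevant when a patient has several metastases). The nearest focus
    is aggressive; other foci by their additional distance dist2:
    [0, gap_low] aggressive, (gap_low, gap_high] undecided,
    (gap_high, inf) non-aggressive.
    """
    rows = sample_sheet[sample_sheet["patient_id"] == patient_id]
    foci = [s for s in rows.loc[rows["tissue_type"] == "T", "sample_id"] if s in dist.ids]
    pls = [s for s in rows.loc[rows["tissue_type"] == "PL", "sample_id"] if s in dist.ids]
    if not pls:
        raise ValueError(f"patient {patient_id} has no metastasis reference")
    if not foci:
        raise ValueError(f"patient {patient_id} has no primary focus in the distance matrix")

    # reference PL = the one achieving the minimal PL-focus distance
    best = min(((float(dist[pl, t]), pl) for pl in pls for t in foci), key=lambda x: x[0])
    chosen_pl = best[1]
    d = {t: float(dist[chosen_pl, t]) for t in foci}
    dist1 = min(d.values())

    call = AggressivenessCall(patient_id=patient_id, chosen_pl=chosen_pl, dist1=dist1)
    for t in foci:
        dist2 = d[t] - dist1
        if dist2 <= gap_low:
            cat = "aggressive"
        elif dist2 <= gap_high:
            cat = "undecided"
        else:
            cat = "non_aggressive"
        call.calls.append(FocusCall(sample_id=t, category=cat, t_pl_dist1=d[t], t_pl_dist2=dist2))
    return call


def classical_mds(dist: DistanceMatrix, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Returns coordinates centered at the origin; the embedding is unique up
    to rotation/reflection. Requires at least dims + 1 samples.
    """
    n = dist.shape[0]
    if n < dims + 1:
        raise ValueError(f"need >= {dims + 1} samples for a {dims}-d embedding")
    D2 = np.asarray(dist.data, float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    lam[lam < lam.max() * 1e-12] = 0.0  # degenerate dimensions collapse exactly
    coords = v[:, order] * np.sqrt(lam)
    return pd.DataFrame(coords, index=list(dist.ids), columns=[f"dim{i + 1}" for i in range(dims)])
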