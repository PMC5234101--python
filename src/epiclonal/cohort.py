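"""Synthetic multifocal-cancer methylation cohorts with known ground truth.

Real studies of metastasis origin in multifocal prostate cancer profile
formalin-fixed primary tumor foci, adjacent-normal prostate (AN), negative
and positive pelvic lymph nodes (NL/PL) on a 450K-style beta-value array.
That data cannot be shipped, so this module generates cohorts with the same
statistical structure and a fully known ground truth:

* per-probe bimodal baseline betas (low ~0.08 / high ~0.85), mimicking the
  characteristic two-humped distribution of CpG methylation arrays;
* patient-specific tumor subclones, each defined by a private set of
  methylation-shifted probes; foci of the same subclone share the shift set;
* one lymph-node metastasis (PL) per patient seeded from exactly one
  subclone (the planted "aggressive" lineage);
* affine contamination mixtures (blood or normal prostate) for purity-filter
  testing;
* methylated/unmethylated intensities with total intensity scaled by a copy
  ratio inside planted copy-number segments, so that beta = M/(M+U) holds
  exactly and intensity log-ratios recover the planted segments.

Probe-index convention (documented, fixed):
    indices 0..3                    GSTP1 stand-in probes (tumor-high)
    next  n_leukocyte_design_probes leukocyte panel design block
                                    (blood-low, prostate-high)
    next  n_blood_high_probes       blood-high block (blood-high, tissue-low)
    next  n_node_probes             node block (NL differs from AN)
    remainder                       bulk probes; subclone shifts are drawn
                                    from these only
Chromosomes are contiguous equal blocks of the probe order (1..n_chromosomes);
positions are 1000*(offset within chromosome) + 1.
"""

from __future__ import annotations

import fnmatch
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TISSUE_TYPES = ("AN", "T", "NL", "PL", "PIN")

#: nominal total (M+U) fluorescence intensity at copy ratio 1
NOMINAL_TOTAL_INTENSITY = 5000.0
#: lognormal sigma of total intensity around its nominal value
INTENSITY_LOG_SD = 0.1


@dataclass(frozen=True)
class CNASegment:
    """Planted copy-number segment, in probe offsets within a chromosome.

    ``start``/``end`` are half-open probe offsets on ``chrom``; ``copy_ratio``
    multiplies total probe intensity (1.5 ~ single-copy gain, 0.5 ~ loss).
    """

    chrom: int
    start: int
    end: int
    copy_ratio: float


@dataclass(frozen=True)
class Contamination:
    """Affine admixture applied to all samples matching a glob pattern.

    ``beta_mix = fraction * beta_contaminant + (1 - fraction) * beta_sample``.
    ``contaminant`` is ``"blood"`` or ``"normal_prostate"``.
    """

    sample_pattern: str
    contaminant: str
    fraction: float


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic multifocal cohort.

    Defaults describe the scaled-down study conditions used throughout the
    test-suite: 10 patients, 2-4 foci from 2 subclones each, 5000 probes,
    beta-scale measurement noise 0.02 and subclone shifts of 0.10 (five times
    the noise), which is the regime where clonality is recoverable.
    """

    n_patients: int = 10
    foci_per_patient: tuple[int, int] = (2, 4)
    n_probes: int = 5000
    n_subclones_per_patient: tuple[int, int] = (2, 2)
    metastasis_source: str = "one_focus"  # or "per_subclone"
    shift_probe_fraction: float = 0.05
    shift_magnitude: float = 0.10
    noise_sd: float = 0.02
    contamination: tuple[Contamination, ...] = ()
    cna_segments: tuple[tuple[CNASegment, ...], ...] = ()
    seed: int = 0
    n_chromosomes: int = 4
    n_an_per_patient: int = 1
    n_nl_per_patient: int = 1
    n_leukocyte_design_probes: int = 500
    n_blood_high_probes: int = 500
    n_node_probes: int = 200
    detection_fail_rate: float = 0.0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        def bad(name: str, why: str) -> ValueError:
            return ValueError(f"invalid CohortSpec.{name}: {why}")

        if self.n_patients < 1:
            raise bad("n_patients", "must be >= 1")
        if self.n_probes < 1000:
            raise bad("n_probes", "must be >= 1000 so top-1% selection is non-degenerate")
        lo, hi = self.foci_per_patient
        if not (1 <= lo <= hi):
            raise bad("foci_per_patient", f"range {self.foci_per_patient} must satisfy 1 <= lo <= hi")
        slo, shi = self.n_subclones_per_patient
        if not (1 <= slo <= shi):
            raise bad("n_subclones_per_patient", f"range {self.n_subclones_per_patient} must satisfy 1 <= lo <= hi")
        if shi > lo:
            raise bad("n_subclones_per_patient", "max subclones cannot exceed min foci per patient")
        if self.metastasis_source not in ("one_focus", "per_subclone"):
            raise bad("metastasis_source", "must be 'one_focus' or 'per_subclone'")
        for name in ("shift_probe_fraction", "detection_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise bad(name, f"{v} not in [0, 1]")
        if self.shift_magnitude < 0:
            raise bad("shift_magnitude", "must be >= 0")
        if self.noise_sd < 0:
            raise bad("noise_sd", "must be >= 0")
        for c in self.contamination:
            if c.contaminant not in ("blood", "normal_prostate"):
                raise bad("contamination", f"unknown contaminant {c.contaminant!r}")
            if not 0.0 <= c.fraction <= 1.0:
                raise bad("contamination", f"mixing fraction {c.fraction} not in [0, 1]")
        if self.n_chromosomes < 1:
            raise bad("n_chromosomes", "must be >= 1")
        if self._n_special + self._max_shift_probes > self.n_probes:
            raise bad(
                "n_probes",
                f"{self.n_probes} probes cannot hold {self._n_special} designated probes "
                f"plus {self._max_shift_probes} shiftable probes",
            )
        for segs in self.cna_segments:
            for s in segs:
                if not 1 <= s.chrom <= self.n_chromosomes:
                    raise bad("cna_segments", f"chrom {s.chrom} outside 1..{self.n_chromosomes}")
                if not (0 <= s.start < s.end <= self._chrom_size):
                    raise bad("cna_segments", f"segment [{s.start}, {s.end}) outside chromosome of size {self._chrom_size}")
                if s.copy_ratio <= 0:
                    raise bad("cna_segments", f"copy ratio {s.copy_ratio} must be > 0")

    # -- layout helpers -----------------------------------------------------
    @property
    def _n_special(self) -> int:
        return 4 + self.n_leukocyte_design_probes + self.n_blood_high_probes + self.n_node_probes

    @property
    def _max_shift_probes(self) -> int:
        return int(round(self.shift_probe_fraction * self.n_probes)) * self.n_subclones_per_patient[1]

    @property
    def _chrom_size(self) -> int:
        return math.ceil(self.n_probes / self.n_chromosomes)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index([f"cg{i:07d}" for i in range(self.n_probes)], name="probe_id")

    @property
    def gstp1_probes(self) -> list[str]:
        return list(self.probe_ids[:4])

    @property
    def leukocyte_design_probes(self) -> list[str]:
        return list(self.probe_ids[4 : 4 + self.n_leukocyte_design_probes])

    @property
    def blood_high_probes(self) -> list[str]:
        a = 4 + self.n_leukocyte_design_probes
        return list(self.probe_ids[a : a + self.n_blood_high_probes])

    @property
    def node_probes(self) -> list[str]:
        a = 4 + self.n_leukocyte_design_probes + self.n_blood_high_probes
        return list(self.probe_ids[a : a + self.n_node_probes])

    def probe_annotation(self) -> pd.DataFrame:
        """Probe -> (chrom, pos) under the contiguous-block convention."""
        idx = np.arange(self.n_probes)
        chrom = idx // self._chrom_size + 1
        pos = (idx % self._chrom_size) * 1000 + 1
        return pd.DataFrame({"chrom": chrom, "pos": pos}, index=self.probe_ids)


@dataclass
class IntensityMatrixPair:
    """Aligned methylated/unmethylated signal matrices (probes x samples)."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.methylated.index.equals(self.unmethylated.index):
            raise ValueError("intensity matrices misaligned on probe axis")
        if not self.methylated.columns.equals(self.unmethylated.columns):
            raise ValueError("intensity matrices misaligned on sample axis")
        if self.detection_p is not None:
            if not self.detection_p.index.equals(self.methylated.index) or not self.detection_p.columns.equals(
                self.methylated.columns
            ):
                raise ValueError("detection_p misaligned with intensity matrices")

    @property
    def total(self) -> pd.DataFrame:
        return self.methylated + self.unmethylated


@dataclass
class GroundTruth:
    """Planted truth of a synthetic cohort.

    ``sample_subclone`` maps tumor-derived samples (T and PL) to subclone
    labels like ``"P01:S1"``; normal samples map to ``None``.
    ``seeding_subclone`` names, per patient, the subclone that seeded the PL
    — its foci are the truly aggressive ones.
    """

    sample_subclone: dict[str, str | None]
    seeding_subclone: dict[str, str]
    shifted_probes: dict[str, list[str]]
    subclone_cna: dict[str, list[CNASegment]]
    focus_true_class: dict[str, str]
    gstp1_probes: list[str]
    leukocyte_design_probes: list[str]
    blood_high_probes: list[str]
    node_probes: list[str]

    def true_class(self, sample_id: str, tissue_type: str) -> str:
        """Three-class label used for classifier training/evaluation."""
        if tissue_type in ("AN", "NL"):
            return "normal"
        if tissue_type == "T":
            return self.focus_true_class[sample_id]
        if tissue_type == "PL":
            return "aggressive"
        return "undecided"

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["subclone_cna"] = {
            k: [[s.chrom, s.start, s.end, s.copy_ratio] for s in v] for k, v in self.subclone_cna.items()
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["subclone_cna"] = {
            k: [CNASegment(int(c), int(s), int(e), float(r)) for c, s, e, r in v]
            for k, v in d["subclone_cna"].items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# baseline profiles


def _baseline_profiles(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Deterministic tissue baseline beta profiles shared by all generators.

    AN prostate is the anchor; blood equals AN except at the designated
    leukocyte-design (blood-low / prostate-high) and blood-high blocks, so
    the leukocyte-panel construction recovers exactly the design block.
    NL differs from AN only at the node block.
    """
    rng = np.random.default_rng([1, spec.seed])
    P = spec.n_probes
    high = rng.random(P) < 0.5
    base = np.where(
        high,
        rng.normal(0.85, 0.05, P),
        rng.normal(0.08, 0.03, P),
    )
    base = np.clip(base, 0.01, 0.99)

    an = base.copy()
    an[0:4] = rng.normal(0.05, 0.01, 4)  # GSTP1 stand-ins: unmethylated in normal
    a = 4
    b = a + spec.n_leukocyte_design_probes
    an[a:b] = rng.normal(0.85, 0.03, b - a)  # prostate-high
    c = b + spec.n_blood_high_probes
    an[b:c] = rng.normal(0.08, 0.02, c - b)  # tissue-low
    an = np.clip(an, 0.01, 0.99)

    blood = an.copy()
    blood[a:b] = np.clip(rng.normal(0.06, 0.02, b - a), 0.01, 0.15)
    blood[b:c] = np.clip(rng.normal(0.85, 0.03, c - b), 0.5, 0.99)

    nl = an.copy()
    d = c + spec.n_node_probes
    # node tissue flips the node block relative to AN
    nl[c:d] = np.clip(np.where(an[c:d] < 0.5, rng.normal(0.8, 0.05, d - c), rng.normal(0.1, 0.03, d - c)), 0.01, 0.99)

    return {"AN": an, "NL": nl, "blood": blood}


def _subclone_profile(
    spec: CohortSpec, an_baseline: np.ndarray, shift_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    prof = an_baseline.copy()
    prof[0:4] = 0.85  # GSTP1 gain of methylation, shared by all tumor lineages
    direction = np.where(an_baseline[shift_idx] < 0.5, 1.0, -1.0)
    prof[shift_idx] = np.clip(prof[shift_idx] + direction * spec.shift_magnitude, 0.0, 1.0)
    return prof


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, IntensityMatrixPair, pd.DataFrame, GroundTruth]:
    """Generate one cohort: (beta, intensities, sample sheet, ground truth).

    Deterministic in ``spec`` (identical spec -> bit-identical output). Betas
    are clipped to [0, 1]; intensities satisfy ``beta = M / (M + U)`` exactly,
    with total intensity scaled by the planted copy ratio inside CNA segments.
    """
    spec.validate()
    rng = np.random.default_rng([3, spec.seed])
    baselines = _baseline_profiles(spec)
    P = spec.n_probes
    n_shift = int(round(spec.shift_probe_fraction * P))
    bulk_start = spec._n_special
    annotation = spec.probe_annotation()
    chrom = annotation["chrom"].to_numpy()
    offset = (np.arange(P) % spec._chrom_size)

    clean_profiles: list[np.ndarray] = []
    sample_rows: list[dict] = []
    sample_subclone: dict[str, str | None] = {}
    seeding: dict[str, str] = {}
    shifted_probes: dict[str, list[str]] = {}
    subclone_cna: dict[str, list[CNASegment]] = {}
    focus_true: dict[str, str] = {}
    copy_ratio_cols: list[np.ndarray] = []

    def cna_ratio_vector(segs: Sequence[CNASegment]) -> np.ndarray:
        r = np.ones(P)
        for s in segs:
            sel = (chrom == s.chrom) & (offset >= s.start) & (offset < s.end)
            r[sel] = s.copy_ratio
        return r

    probe_ids = spec.probe_ids

    for p in range(spec.n_patients):
        pid = f"P{p + 1:02d}"
        n_foci = int(rng.integers(spec.foci_per_patient[0], spec.foci_per_patient[1] + 1))
        n_sub = int(rng.integers(spec.n_subclones_per_patient[0], spec.n_subclones_per_patient[1] + 1))
        n_sub = min(n_sub, n_foci)

        # disjoint shift sets per subclone, drawn from the bulk block
        perm = bulk_start + rng.permutation(P - bulk_start)
        sub_labels = [f"{pid}:S{k + 1}" for k in range(n_sub)]
        sub_profiles = {}
        for k, lab in enumerate(sub_labels):
            idx = np.sort(perm[k * n_shift : (k + 1) * n_shift])
            shifted_probes[lab] = [probe_ids[i] for i in idx]
            sub_profiles[lab] = _subclone_profile(spec, baselines["AN"], idx, rng)
            segs = (
                list(spec.cna_segments[k % len(spec.cna_segments)]) if spec.cna_segments else []
            )
            subclone_cna[lab] = segs

        # every subclone gets >=1 focus; remaining foci assigned at random
        assign = list(range(n_sub)) + list(rng.integers(0, n_sub, n_foci - n_sub))
        assign = [assign[i] for i in rng.permutation(n_foci)]

        seed_sub = sub_labels[int(rng.integers(0, n_sub))]
        seeding[pid] = seed_sub

        def add_sample(sid: str, tissue: str, profile: np.ndarray, subclone: str | None) -> None:
            sample_rows.append({"sample_id": sid, "patient_id": pid, "tissue_type": tissue, "subclone_truth": subclone or ""})
            clean_profiles.append(profile)
            sample_subclone[sid] = subclone
            copy_ratio_cols.append(cna_ratio_vector(subclone_cna[subclone]) if subclone else np.ones(P))

        for i in range(spec.n_an_per_patient):
            add_sample(f"{pid}_AN{i + 1}", "AN", baselines["AN"], None)
        for i in range(spec.n_nl_per_patient):
            add_sample(f"{pid}_NL{i + 1}", "NL", baselines["NL"], None)
        for i in range(n_foci):
            lab = sub_labels[assign[i]]
            sid = f"{pid}_T{i + 1}"
            add_sample(sid, "T", sub_profiles[lab], lab)
            focus_true[sid] = "aggressive" if lab == seed_sub else "non_aggressive"
        if spec.metastasis_source == "one_focus":
            add_sample(f"{pid}_PL1", "PL", sub_profiles[seed_sub], seed_sub)
        else:
            for k, lab in enumerate(sub_labels):
                add_sample(f"{pid}_PL{k + 1}", "PL", sub_profiles[lab], lab)

    sheet = pd.DataFrame(sample_rows)
    sample_ids = sheet["sample_id"].tolist()
    clean = np.column_stack(clean_profiles)  # probes x samples

    # contamination mixtures (affine, before measurement noise)
    contaminant_profile = {"blood": baselines["blood"], "normal_prostate": baselines["AN"]}
    for c in spec.contamination:
        for j, sid in enumerate(sample_ids):
            if fnmatch.fnmatch(sid, c.sample_pattern):
                clean[:, j] = c.fraction * contaminant_profile[c.contaminant] + (1 - c.fraction) * clean[:, j]

    beta = np.clip(clean + rng.normal(0.0, spec.noise_sd, clean.shape), 0.0, 1.0) if spec.noise_sd > 0 else clean.copy()

    # intensities: total ~ lognormal around nominal, scaled by copy ratio
    ratio = np.column_stack(copy_ratio_cols)
    total = rng.lognormal(np.log(NOMINAL_TOTAL_INTENSITY), INTENSITY_LOG_SD, beta.shape) * ratio
    M = beta * total
    U = (1.0 - beta) * total

    if spec.detection_fail_rate > 0:
        fail = rng.random(beta.shape) < spec.detection_fail_rate
        det = rng.uniform(0.0, 0.04, beta.shape)
        det[fail] = rng.uniform(0.06, 1.0, int(fail.sum()))
    else:
        det = rng.uniform(0.0, 0.04, beta.shape)

    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)
    intensities = IntensityMatrixPair(
        methylated=pd.DataFrame(M, index=probe_ids, columns=sample_ids),
        unmethylated=pd.DataFrame(U, index=probe_ids, columns=sample_ids),
        detection_p=pd.DataFrame(det, index=probe_ids, columns=sample_ids),
    )
    truth = GroundTruth(
        sample_subclone=sample_subclone,
        seeding_subclone=seeding,
        shifted_probes=shifted_probes,
        subclone_cna=subclone_cna,
        focus_true_class=focus_true,
        gstp1_probes=spec.gstp1_probes,
        leukocyte_design_probes=spec.leukocyte_design_probes,
        blood_high_probes=spec.blood_high_probes,
        node_probes=spec.node_probes,
    )
    return beta_df, intensities, sheet, truth


def generate_blood_reference(n_samples: int, spec: CohortSpec) -> pd.DataFrame:
    """Peripheral-blood beta reference panel (probes x n_samples).

    The designated leukocyte-design block is hypomethylated here (<= ~0.15
    baseline) and hypermethylated in synthetic AN prostate, so the
    leukocyte-panel construction and purity filter are exercisable.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    spec.validate()
    rng = np.random.default_rng([2, spec.seed])
    blood = _baseline_profiles(spec)["blood"]
    noise = rng.normal(0.0, spec.noise_sd, (spec.n_probes, n_samples)) if spec.noise_sd > 0 else 0.0
    vals = np.clip(blood[:, None] + noise, 0.0, 1.0)
    cols = [f"Blood{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame(vals, index=spec.probe_ids, columns=cols)


def generate_signal_matrix(
    group_sizes: Mapping[str, int],
    n_probes: int = 3000,
    n_signal: int = 5,
    effect: float = 0.1,
    noise_sd: float = 0.02,
    seed: int = 0,
    baseline_seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Beta matrix with a planted probe signal separating labeled groups.

    Probes have bimodal baselines; the first ``n_signal`` probes carry the
    signal, mimicking the two kinds of methylation change seen in tumors:
    the first half shift by ``effect`` (toward the free end of the beta
    range) in both cancer classes (cancer-general changes), the second half
    shift only in the aggressive class (aggressiveness-specific changes).
    Everything else is exchangeable noise at ``noise_sd``. Used for
    classifier recovery experiments: the planted probes are the only
    informative features.

    ``baseline_seed`` fixes the per-probe baseline profile separately from
    the sampling seed, so training and held-out matrices drawn with
    different ``seed`` values share the same probe baselines (as replicate
    cohorts from one population would).

    Returns (beta, labels) with samples named ``<class>_<i>``.
    """
    base_rng = np.random.default_rng([4, baseline_seed])
    high = base_rng.random(n_probes) < 0.5
    base = np.clip(
        np.where(high, base_rng.normal(0.85, 0.05, n_probes), base_rng.normal(0.08, 0.03, n_probes)), 0.05, 0.95
    )
    rng = np.random.default_rng([5, seed])
    n_cancer = (n_signal + 1) // 2  # cancer-general probes; rest aggressive-specific
    direction = np.where(base[:n_signal] < 0.5, 1.0, -1.0)
    shift = {
        "normal": np.zeros(n_signal),
        "non_aggressive": np.concatenate([np.ones(n_cancer), np.zeros(n_signal - n_cancer)]),
        "aggressive": np.ones(n_signal),
    }
    cols, labels = [], []
    for cls in ("normal", "non_aggressive", "aggressive"):
        n = int(group_sizes.get(cls, 0))
        for i in range(n):
            prof = base.copy()
            prof[:n_signal] = prof[:n_signal] + direction * effect * shift[cls]
            cols.append(np.clip(prof + rng.normal(0.0, noise_sd, n_probes), 0.0, 1.0))
            labels.append((f"{cls}_{i + 1}", cls))
    probe_ids = pd.Index([f"cg{i:07d}" for i in range(n_probes)], name="probe_id")
    beta = pd.DataFrame(np.column_stack(cols), index=probe_ids, columns=[s for s, _ in labels])
    y = pd.Series({s: c for s, c in labels}, name="class")
    return beta, y


def mix_betas(sample: pd.Series | np.ndarray, contaminant: pd.Series | np.ndarray, fraction: float) -> np.ndarray:
    """Affine contamination mixture, clipped to [0, 1]."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"mixing fraction {fraction} not in [0, 1]")
    return np.clip(fraction * np.asarray(contaminant, float) + (1 - fraction) * np.asarray(sample, float), 0.0, 1.0)


# ---------------------------------------------------------------------------
# disk round-trip (plain-text pipeline inputs)


def write_cohort(
    outdir: str | Path,
    beta: pd.DataFrame,
    intensities: IntensityMatrixPair,
    sheet: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    beta.to_csv(out / "beta.tsv", sep="\t")
    intensities.methylated.to_csv(out / "intensity_M.tsv", sep="\t")
    intensities.unmethylated.to_csv(out / "intensity_U.tsv", sep="\t")
    if intensities.detection_p is not None:
        intensities.detection_p.to_csv(out / "detection_p.tsv", sep="\t")
    sheet.to_csv(out / "samples.csv", index=False)
    truth.to_json(out / "ground_truth.json")
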