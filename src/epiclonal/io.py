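"""Plain-text readers/writers for the pipeline's standard inputs and outputs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from skbio import DistanceMatrix

from .cohort import IntensityMatrixPair


def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    """Beta matrix TSV: rows = probe ids, columns = sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_beta_tsv(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t")


def read_intensities(m_path: str | Path, u_path: str | Path, detection_path: str | Path | None = None) -> IntensityMatrixPair:
    det = pd.read_csv(detection_path, sep="\t", index_col=0) if detection_path else None
    return IntensityMatrixPair(
        methylated=pd.read_csv(m_path, sep="\t", index_col=0),
        unmethylated=pd.read_csv(u_path, sep="\t", index_col=0),
        detection_p=det,
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet CSV with sample_id, patient_id, tissue_type columns."""
    sheet = pd.read_csv(path, dtype=str).fillna("")
    required = {"sample_id", "patient_id", "tissue_type"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def read_mask_list(path: str | Path) -> list[str]:
    """Probe mask list: one probe id per line (optional tab-separated reason)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(path, sep="\t")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))
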