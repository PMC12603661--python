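"""Delimited-text readers/writers and run configuration.

All artefacts are plain tab-delimited text so results are diffable and
language-neutral: adjacency matrices as labelled square grids, tables in
long format, and a plain-text ``key: value`` manifest recording the spec
and seed of every run.  Each written file starts with a comment line
carrying the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort, RegionGeometry, StructuralConnectome

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Declared configuration for an end-to-end pipeline run."""

    output_dir: str = "zerolag_output"
    n_regions: int = 68
    n_participants: int = 153
    epoch_seconds: float = 20.0
    sampling_rate: float = 250.0
    leakage_sigma: float = 20.0
    bands: tuple = ("theta", "alpha")
    methods: tuple = ("coherence", "img_coh", "plv", "wpli", "aec", "orth_aec")
    near_zero_threshold: float = 0.3   # radians
    bin_width_mm: float = 10.0
    flatness_alpha: float = 0.05
    n_null: int = 500
    n_boot: int = 1000
    n_perm: int = 1000
    cv_folds: int = 10
    pathlength_band: str = "theta"
    use_structural: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_participants", "n_null", "n_boot",
                     "n_perm", "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0 < self.near_zero_threshold < np.pi / 2:
            raise ValueError("near_zero_threshold must lie in (0, pi/2)")

    @classmethod
    def demo(cls, output_dir: str = "zerolag_demo", seed: int = 0) -> "RunConfig":
        """A desk-scale configuration that exercises every stage quickly."""
        return cls(output_dir=output_dir, n_regions=8, n_participants=12,
                   epoch_seconds=10.0, bands=("theta", "alpha"),
                   n_null=50, n_boot=300, n_perm=200, cv_folds=4, seed=seed)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")    # paths are not analysis parameters
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_line(self) -> str:
        return f"# zerolag config={self.config_hash()} seed={self.seed}"


# ---------------------------------------------------------------------------
# adjacency matrices


def write_adjacency(matrix: np.ndarray, path, labels=None,
                    header_line: str | None = None) -> None:
    """Write a labelled square matrix as tab-delimited text."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("adjacency matrix must be square")
    n = m.shape[0]
    labels = list(labels) if labels is not None else [f"r{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")
    path = Path(path)
    with path.open("w") as fh:
        if header_line:
            fh.write(header_line + "\n")
        fh.write("\t".join([""] + labels) + "\n")
        for lab, row in zip(labels, m):
            fh.write(lab + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_adjacency(path) -> tuple[np.ndarray, list[str]]:
    """Read a labelled square matrix; symmetrise (with a warning) if needed."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    col_labels = header[1:]
    row_labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        row_labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    m = np.asarray(rows, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or len(col_labels) != m.shape[0]:
        raise ValueError(f"{path}: not a square labelled matrix")
    if row_labels != col_labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    if np.isnan(m).any():
        raise ValueError(f"{path}: matrix contains NaN cells")
    if not np.allclose(m, m.T):
        warnings.warn(f"{path}: asymmetric matrix symmetrised by average",
                      stacklevel=2)
        m = (m + m.T) / 2.0
    return m, row_labels


# ---------------------------------------------------------------------------
# tables and manifests


def write_table(df: pd.DataFrame, path, header_line: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_line:
            fh.write(header_line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_manifest(path, entries: dict) -> None:
    with Path(path).open("w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}: {value}\n")


def read_manifest(path) -> dict:
    out = {}
    for ln in Path(path).read_text().splitlines():
        if ":" in ln:
            key, value = ln.split(":", 1)
            out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# cohort writers


def geometry_frame(geometry: RegionGeometry) -> pd.DataFrame:
    return pd.DataFrame({
        "region_id": np.arange(geometry.n_regions),
        "name": geometry.names,
        "hemisphere": geometry.hemisphere,
        "lobe": geometry.lobe,
        "x_mm": geometry.centroids[:, 0],
        "y_mm": geometry.centroids[:, 1],
        "z_mm": geometry.centroids[:, 2],
        "homotopic_partner": geometry.homotopic_partner,
    })


def connectome_frame(conn: StructuralConnectome) -> pd.DataFrame:
    """Long-format pair table: count, normalised log count, length, HMOA."""
    n = conn.streamline_count.shape[0]
    iu = np.triu_indices(n, k=1)
    names = conn.region_names or [f"r{i}" for i in range(n)]
    return pd.DataFrame({
        "region_i": [names[i] for i in iu[0]],
        "region_j": [names[j] for j in iu[1]],
        "streamline_count": conn.streamline_count[iu],
        "norm_log_count": conn.norm_log_count[iu],
        "median_length_mm": conn.median_length[iu],
        "median_hmoa": conn.median_hmoa[iu],
    })


def write_cohort(cohort: Cohort, out_dir,
                 header_line: str | None = None) -> Path:
    """Write a cohort's tables, epochs and manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(geometry_frame(cohort.geometry), out / "regions.tsv", header_line)
    write_table(cohort.table, out / "participants.tsv", header_line)
    for p, conn in enumerate(cohort.connectomes):
        write_table(connectome_frame(conn),
                    out / f"sub-{p:03d}_connectome.tsv", header_line)
    for p, (a, b) in enumerate(cohort.epochs):
        np.savetxt(out / f"sub-{p:03d}_epoch-a.tsv", a.data, fmt=_FLOAT_FMT,
                   delimiter="\t")
        np.savetxt(out / f"sub-{p:03d}_epoch-b.tsv", b.data, fmt=_FLOAT_FMT,
                   delimiter="\t")
    spec = asdict(cohort.spec)
    spec["generator"] = "zerolag.synthetic.simulate_cohort"
    write_manifest(out / "manifest.txt", spec)
    return out
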