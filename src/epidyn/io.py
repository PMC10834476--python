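"""Matrix and parcellation I/O, run manifests, and seed handling.

Dense matrices travel as tab-separated text (full double precision on
write) or as a binary ``.npy`` container (bit-exact round-trip).
Parcellation tables are TSV with columns ``name``, ``hemisphere``,
``network``, ``x``, ``y``, ``z``; region order in the file defines the
0-based internal region index used everywhere downstream.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("epidyn")

VALID_HEMISPHERES = ("left", "right")
VALID_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal-attention",
    "ventral-attention",
    "limbic",
    "frontoparietal",
    "default-mode",
    "unassigned",
)


class FormatError(ValueError):
    """Malformed matrix or table file."""


@dataclasses.dataclass(frozen=True)
class Parcellation:
    """A named cortical parcellation with centroid coordinates.

    Region ids are contiguous 0-based indices in file order. ``network``
    holds one of the seven functional-community labels or ``unassigned``.
    """

    names: tuple[str, ...]
    hemisphere: np.ndarray  # array of "left"/"right"
    network: np.ndarray
    centroids: np.ndarray  # (n_regions, 3), mm

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def distance_matrix(self) -> np.ndarray:
        """Euclidean distance between centroids; symmetric, zero diagonal."""
        diff = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def hemisphere_mask(self, side: str) -> np.ndarray:
        if side not in VALID_HEMISPHERES:
            raise ValueError(f"unknown hemisphere {side!r}")
        return self.hemisphere == side

    def network_regions(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.network == label)


@dataclasses.dataclass
class RegionalTimeSeries:
    """One subject's parcellated BOLD: a regions x frames matrix."""

    subject_id: str
    group: str
    data: np.ndarray  # (n_regions, n_frames)
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D regions x frames matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite frames")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def read_matrix(path: str | Path, layout: str | None = None) -> np.ndarray:
    """Read a dense matrix from TSV or from the ``.npy`` binary container.

    ``layout`` is ``"dense-delimited"`` or ``"binary-container"``; when None
    it is inferred from the file suffix.
    """
    path = Path(path)
    if layout is None:
        layout = "binary-container" if path.suffix == ".npy" else "dense-delimited"
    if layout == "binary-container":
        return np.load(path, allow_pickle=False)
    if layout != "dense-delimited":
        raise ValueError(f"unknown layout {layout!r}")

    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise FormatError(
                    f"{path}: ragged row {lineno}: expected {width} columns, got {len(cells)}"
                )
            parsed = []
            for col, cell in enumerate(cells, start=1):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell at row {lineno}, column {col}: {cell!r}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def write_matrix(matrix: np.ndarray, path: str | Path, layout: str | None = None) -> Path:
    """Write a dense matrix as TSV (full double precision) or ``.npy``."""
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("only 2-D matrices are written")
    if layout is None:
        layout = "binary-container" if path.suffix == ".npy" else "dense-delimited"
    if layout == "binary-container":
        np.save(path, matrix, allow_pickle=False)
        # np.save appends .npy when missing; normalise the returned path
        return path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    if layout != "dense-delimited":
        raise ValueError(f"unknown layout {layout!r}")
    np.savetxt(path, matrix, delimiter="\t", fmt="%.17g")
    return path


def load_parcellation(path: str | Path) -> Parcellation:
    """Load and validate a parcellation table (TSV)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    required = ["name", "hemisphere", "network", "x", "y", "z"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    names = table["name"].astype(str).tolist()
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"{path}: duplicate region names {dupes}")
    hemi = table["hemisphere"].astype(str).to_numpy()
    bad = sorted(set(hemi) - set(VALID_HEMISPHERES))
    if bad:
        raise FormatError(f"{path}: unknown hemisphere token(s) {bad}")
    network = table["network"].astype(str).to_numpy()
    centroids = table[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(centroids)):
        raise FormatError(f"{path}: non-finite centroid coordinates")
    return Parcellation(tuple(names), hemi, network, centroids)


def write_parcellation(parc: Parcellation, path: str | Path) -> Path:
    path = Path(path)
    table = pd.DataFrame(
        {
            "name": parc.names,
            "hemisphere": parc.hemisphere,
            "network": parc.network,
            "x": parc.centroids[:, 0],
            "y": parc.centroids[:, 1],
            "z": parc.centroids[:, 2],
        }
    )
    table.to_csv(path, sep="\t", index=False)
    return path


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]


def write_manifest(path: str | Path, *, config: dict, seed: int | None,
                   inputs: dict[str, str] | None = None) -> Path:
    """Record everything needed to reproduce a run of a pipeline stage."""
    payload = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": config,
        "inputs": inputs or {},
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def save_cohort(subjects: Sequence[RegionalTimeSeries], outdir: str | Path,
                layout: str = "dense-delimited") -> Path:
    """Write one matrix file per subject plus a cohort manifest TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".npy" if layout == "binary-container" else ".tsv"
    records = []
    for subj in subjects:
        fname = f"{subj.subject_id}{suffix}"
        write_matrix(subj.data, outdir / fname, layout)
        records.append(
            {"subject": subj.subject_id, "group": subj.group,
             "tr_seconds": subj.tr_seconds, "file": fname}
        )
    manifest = outdir / "cohort.tsv"
    pd.DataFrame(records).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cohort(manifest: str | Path) -> list[RegionalTimeSeries]:
    manifest = Path(manifest)
    table = pd.read_csv(manifest, sep="\t")
    subjects = []
    for rec in table.itertuples():
        data = read_matrix(manifest.parent / rec.file)
        subjects.append(
            RegionalTimeSeries(str(rec.subject), str(rec.group), data,
                               float(rec.tr_seconds))
        )
    return subjects
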