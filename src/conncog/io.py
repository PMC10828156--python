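"""Plain-text readers and writers plus the run manifest.

All pipeline products are delimited text: per-subject square connectome
matrices (TSV), a two-column parcellation file, subject/target/feature
CSVs and a JSON manifest recording config, seeds and file hashes.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .base import Connectome, FeatureMatrix, ParcellationScheme

__all__ = [
    "write_parcellation",
    "read_parcellation",
    "write_connectome",
    "read_connectome",
    "write_connectome_dir",
    "read_connectome_dir",
    "write_feature_matrix",
    "read_feature_matrix",
    "file_hash",
    "write_manifest",
    "read_manifest",
]

READ_SYMMETRY_TOL = 1e-8
_CONNECTOME_NAME = re.compile(r"^(?P<subject>.+)_(?P<modality>FC|SC)\.tsv$")


def write_parcellation(parcellation: ParcellationScheme, path: str | Path) -> Path:
    """Two-column (node, network) file with names in a header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# networks: " + ",".join(parcellation.network_names) + "\n")
        fh.write("node\tnetwork\n")
        for node, net in enumerate(parcellation.network_of):
            fh.write(f"{node}\t{int(net)}\n")
    return path


def read_parcellation(path: str | Path) -> ParcellationScheme:
    path = Path(path)
    names: list[str] = []
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# networks:"):
            names = first.split(":", 1)[1].strip().split(",")
    table = pd.read_csv(path, sep="\t", comment="#")
    table = table.sort_values("node")
    if not np.array_equal(table["node"].to_numpy(), np.arange(len(table))):
        raise ValueError(f"{path}: node indices are not a contiguous 0-based range")
    return ParcellationScheme(table["network"].to_numpy(), names)


def write_connectome(connectome: Connectome, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{connectome.subject_id}_{connectome.modality}.tsv"
    np.savetxt(path, connectome.matrix, delimiter="\t", fmt="%.12g")
    return path


def read_connectome(
    path: str | Path, parcellation: ParcellationScheme | None = None
) -> Connectome:
    """Load one delimited square matrix; validates shape and symmetry."""
    path = Path(path)
    m = _CONNECTOME_NAME.match(path.name)
    if not m:
        raise ValueError(f"{path.name}: filename must look like '<subject>_<FC|SC>.tsv'")
    matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{path.name}: matrix is {matrix.shape[0]}x{matrix.shape[1]}, not square")
    if parcellation is not None and matrix.shape[0] != parcellation.n_nodes:
        raise ValueError(
            f"{path.name}: {matrix.shape[0]} nodes but parcellation has {parcellation.n_nodes}"
        )
    asym = np.max(np.abs(matrix - matrix.T)) if matrix.size else 0.0
    if asym > READ_SYMMETRY_TOL:
        raise ValueError(f"{path.name}: asymmetric beyond tolerance ({asym:.3g})")
    matrix = (matrix + matrix.T) / 2.0
    np.fill_diagonal(matrix, 0.0)
    return Connectome(m.group("subject"), m.group("modality"), matrix)


def write_connectome_dir(connectomes: list[Connectome], directory: str | Path) -> list[Path]:
    return [write_connectome(c, directory) for c in connectomes]


def read_connectome_dir(
    path: str | Path, parcellation: ParcellationScheme | None = None
) -> dict[str, list[Connectome]]:
    """Load every ``*_FC.tsv`` / ``*_SC.tsv`` file, keyed by modality."""
    path = Path(path)
    out: dict[str, list[Connectome]] = {"FC": [], "SC": []}
    for file in sorted(path.glob("*.tsv")):
        if not _CONNECTOME_NAME.match(file.name):
            continue
        c = read_connectome(file, parcellation)
        out[c.modality].append(c)
    return out


def write_feature_matrix(fm: FeatureMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Values CSV plus a sidecar feature-metadata CSV."""
    prefix = Path(prefix)
    values_path = prefix.with_suffix(".csv")
    meta_path = prefix.parent / (prefix.name + "_meta.csv")
    fm.to_frame().to_csv(values_path)
    fm.feature_meta.to_csv(meta_path, index=False)
    return values_path, meta_path


def read_feature_matrix(prefix: str | Path) -> FeatureMatrix:
    prefix = Path(prefix)
    frame = pd.read_csv(prefix.with_suffix(".csv"), index_col=0)
    meta = pd.read_csv(prefix.parent / (prefix.name + "_meta.csv"))
    return FeatureMatrix(frame.to_numpy(), meta, [str(s) for s in frame.index])


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    seed: int,
    outputs: dict[str, str],
    stages: dict | None = None,
) -> Path:
    path = Path(path)
    manifest = {
        "config": config,
        "seed": seed,
        "outputs": outputs,
        "output_hashes": {
            k: file_hash(v) for k, v in outputs.items() if Path(v).is_file()
        },
        "stages": stages or {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
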