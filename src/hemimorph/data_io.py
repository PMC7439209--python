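"""Readers and writers for pipeline artifacts, plus the cohort filter.

Vertex tables are TSV (one file per subject), cohort manifests CSV, and
matrices dense TSV with a ``#``-prefixed metadata header — everything is
plain text, human-inspectable and diff-able, and every writer/reader pair is
an exact inverse on valid artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import VERTEX_COLUMNS

__all__ = [
    "ParseError",
    "MatrixArtifact",
    "read_vertex_table",
    "write_vertex_table",
    "read_manifest",
    "write_manifest",
    "filter_cohort",
    "read_matrix",
    "write_matrix",
]

MANIFEST_COLUMNS = ("subject_id", "gender", "age", "handedness", "family_id")

FLOAT_FMT = "%.17g"  # shortest-exact round trip for float64


class ParseError(ValueError):
    """An artifact file violates its documented contract."""


# ---------------------------------------------------------------------------
# vertex tables
# ---------------------------------------------------------------------------

def write_vertex_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = set(VERTEX_COLUMNS) - set(table.columns)
    if missing:
        raise ParseError(f"vertex table missing columns {sorted(missing)}")
    table.to_csv(path, sep="\t", index=False, columns=list(VERTEX_COLUMNS),
                 float_format=FLOAT_FMT)


def read_vertex_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(VERTEX_COLUMNS) - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = ~table["hemisphere"].isin(("L", "R"))
    if bad.any():
        raise ParseError(f"{path}: unknown hemisphere code at row "
                         f"{int(np.flatnonzero(bad)[0]) + 2}")
    nonpos = table["thickness"] <= 0
    if nonpos.any():
        raise ParseError(f"{path}: non-positive thickness at row "
                         f"{int(np.flatnonzero(nonpos)[0]) + 2}")
    dup = table["vertex_id"].duplicated()
    if dup.any():
        raise ParseError(f"{path}: duplicate vertex id at row "
                         f"{int(np.flatnonzero(dup)[0]) + 2}")
    norms = np.linalg.norm(table[["x", "y", "z"]].to_numpy(), axis=1)
    off = np.abs(norms - 1.0) > 1e-6
    if off.any():
        raise ParseError(f"{path}: coordinates not unit-norm at row "
                         f"{int(np.flatnonzero(off)[0]) + 2}")
    return table


# ---------------------------------------------------------------------------
# cohort manifests
# ---------------------------------------------------------------------------

def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if manifest["subject_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate subject ids")
    return manifest


def filter_cohort(manifest: pd.DataFrame, handedness_min: int = 50) -> pd.DataFrame:
    """Keep right-handed subjects (handedness >= threshold) and exactly one
    subject per family (first in subject-id order)."""
    kept = manifest[manifest["handedness"] >= handedness_min]
    kept = kept.sort_values("subject_id", kind="stable")
    kept = kept.drop_duplicates(subset="family_id", keep="first")
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

@dataclass
class MatrixArtifact:
    """A per-subject hemispheric matrix (JSS weights or one binary level)."""

    subject_id: str
    hemisphere: str
    kind: str                      # 'weights' or 'binary'
    labels: list[int]
    values: np.ndarray
    sparsity: float | None = None  # only for kind == 'binary'

    def validate(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ParseError("matrix dimension does not match label count")
        if self.kind not in ("weights", "binary"):
            raise ParseError(f"unknown matrix kind {self.kind!r}")
        if (self.kind == "binary") != (self.sparsity is not None):
            raise ParseError("sparsity must be set exactly for binary matrices")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ParseError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ParseError("matrix diagonal must be zero")
        if self.kind == "binary" and not np.all(np.isin(self.values, (0, 1))):
            raise ParseError("binary matrix contains values other than 0/1")


def write_matrix(artifact: MatrixArtifact, path: str | Path) -> None:
    artifact.validate()
    with open(path, "w") as fh:
        fh.write(f"# subject_id={artifact.subject_id}\n")
        fh.write(f"# hemisphere={artifact.hemisphere}\n")
        fh.write(f"# kind={artifact.kind}\n")
        if artifact.sparsity is not None:
            fh.write(f"# sparsity={artifact.sparsity!r}\n")
        fh.write("# labels=" + ",".join(str(l) for l in artifact.labels) + "\n")
        for row in artifact.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path: str | Path) -> MatrixArtifact:
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition("=")
                meta[key] = val
            elif line:
                rows.append([float(v) for v in line.split("\t")])
    for key in ("subject_id", "hemisphere", "kind", "labels"):
        if key not in meta:
            raise ParseError(f"{path}: missing header field {key!r}")
    artifact = MatrixArtifact(
        subject_id=meta["subject_id"],
        hemisphere=meta["hemisphere"],
        kind=meta["kind"],
        labels=[int(l) for l in meta["labels"].split(",")],
        values=np.asarray(rows, dtype=float),
        sparsity=float(meta["sparsity"]) if "sparsity" in meta else None,
    )
    artifact.validate()
    return artifact
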