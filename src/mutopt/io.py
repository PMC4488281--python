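"""File formats and run manifests.

Matrices and stationary vectors travel as labeled TSV (rows and columns in
A, T, G, C order) or as nested JSON keyed by nucleotide; coding sequences
as FASTA with an optional ``strand=leading|lagging`` tag in the
description.  Every artifact-writing command records a run manifest with
the parameters, seeds and fixture checksums needed to reproduce the run.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .errors import ParseError, ValidationError
from .spectral import ALPHABET, StationaryDistribution, TransitionMatrix

_ROW_SUM_FILE_TOL = 1e-6
_IUPAC = set("ACGTNRYSWKMBDHVU")


def write_matrix(P: TransitionMatrix, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        obj = {a: {b: P.entries[i, j] for j, b in enumerate(ALPHABET)}
               for i, a in enumerate(ALPHABET)}
        path.write_text(json.dumps(obj, indent=1) + "\n")
        return
    lines = ["\t" + "\t".join(ALPHABET)]
    for i, a in enumerate(ALPHABET):
        lines.append(a + "\t" + "\t".join(f"{x:.17g}" for x in P.entries[i]))
    path.write_text("\n".join(lines) + "\n")


def read_matrix(path) -> TransitionMatrix:
    path = Path(path)
    if path.suffix == ".json":
        try:
            obj = json.loads(path.read_text())
            arr = np.array([[float(obj[a][b]) for b in ALPHABET] for a in ALPHABET])
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ParseError(f"{path}: malformed matrix JSON ({exc})") from exc
    else:
        arr = _read_matrix_tsv(path)
    rowsum = arr.sum(axis=1)
    if np.max(np.abs(rowsum - 1.0)) > _ROW_SUM_FILE_TOL:
        raise ValidationError(
            f"{path}: row sums {rowsum.tolist()} deviate from 1 beyond {_ROW_SUM_FILE_TOL}"
        )
    arr = arr / rowsum[:, None]  # remove sub-tolerance rounding from files
    return TransitionMatrix(arr)


def _read_matrix_tsv(path: Path) -> np.ndarray:
    rows = {}
    lines = path.read_text().splitlines()
    data_lines = [(n, ln) for n, ln in enumerate(lines, 1)
                  if ln.strip() and not ln.startswith("#")]
    if not data_lines:
        raise ParseError(f"{path}: empty matrix file")
    header_no, header = data_lines[0]
    cols = header.strip().split("\t")
    if [c for c in cols if c] != list(ALPHABET):
        raise ParseError(
            f"{path}:{header_no}: header must be the nucleotides {' '.join(ALPHABET)}"
        )
    for n, ln in data_lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 5 or parts[0] not in ALPHABET:
            raise ParseError(f"{path}:{n}: expected '<nuc>\\t' plus 4 values")
        try:
            rows[parts[0]] = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{n}: non-numeric entry ({exc})") from exc
    missing = [a for a in ALPHABET if a not in rows]
    if missing:
        raise ParseError(f"{path}: missing rows for {missing}")
    return np.array([rows[a] for a in ALPHABET])


def write_stationary(pi: StationaryDistribution, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(pi.as_dict(), indent=1) + "\n")
        return
    path.write_text("\t".join(ALPHABET) + "\n"
                    + "\t".join(f"{x:.17g}" for x in pi.pi) + "\n")


def read_stationary(path) -> StationaryDistribution:
    path = Path(path)
    if path.suffix == ".json":
        obj = json.loads(path.read_text())
        vals = [float(obj[a]) for a in ALPHABET]
    else:
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if len(lines) < 2 or lines[0].split("\t") != list(ALPHABET):
            raise ParseError(f"{path}: expected header {' '.join(ALPHABET)} and one value row")
        vals = [float(x) for x in lines[1].split("\t")]
    return StationaryDistribution.from_values(vals, renormalize=True)


@dataclass(frozen=True)
class GeneRecord:
    id: str
    strand: str
    sequence: str


def read_fasta(path) -> list[GeneRecord]:
    """Read coding sequences; strand parsed from a ``strand=`` description tag."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise ValidationError(
                f"{path}: record {rec.id!r} has non-IUPAC characters {sorted(bad)}"
            )
        m = re.search(r"strand=(\w+)", rec.description)
        records.append(GeneRecord(rec.id, m.group(1) if m else "unlabeled", seq))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(genes, path, width: int = 70) -> None:
    """Write synthetic genes (anything with .fasta_header()/.sequence)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.fasta_header()}\n")
            for k in range(0, len(g.sequence), width):
                fh.write(g.sequence[k:k + width] + "\n")


def _fixture_checksums() -> dict[str, str]:
    out = {}
    data_dir = resources.files("mutopt") / "data"
    for item in sorted(data_dir.iterdir(), key=lambda p: p.name):
        if item.name.endswith(".tsv"):
            out[item.name] = hashlib.sha256(item.read_bytes()).hexdigest()[:16]
    return out


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    command: str
    parameters: dict
    seed: int
    started: str = ""
    finished: str = ""
    package_version: str = ""
    fixtures: dict = field(default_factory=dict)

    @classmethod
    def start(cls, command: str, parameters: dict, seed: int) -> "RunManifest":
        from . import __version__

        return cls(command=command, parameters=parameters, seed=seed,
                   started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
                   package_version=__version__,
                   fixtures=_fixture_checksums())

    def finish(self) -> "RunManifest":
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        return self

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str) + "\n")
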