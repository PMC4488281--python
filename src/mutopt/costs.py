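"""Amino-acid replacement cost schemes.

Each scheme is a symmetric nonnegative 20x20 table of replacement costs,
either given directly as a matrix or derived from a 20-vector
physicochemical index v as cost(a, b) = |v_a - v_b|.  Nonsense mutations
(sense codon -> stop) are costed at the scheme's maximum pairwise cost.

Packaged schemes (TSV fixtures under ``mutopt/data``):

``grantham_chemical_distance``
    Grantham's (1974) chemical distance, computed from his published
    composition/polarity/volume properties and weighting constants.
``kd_hydropathy``
    Kyte-Doolittle (1982) hydropathy index (AAindex KYTJ820101),
    index-derived.
``polar_requirement``
    Woese (1973) polar requirement (AAindex WOEC730101), index-derived.
``aa_pair_distance``
    SYNTHETIC stand-in for an amino-acid pair-distance matrix: the
    dissimilarity transform s(aa)+s(bb)-2s(ab) of PAM250.
``empar``
    SYNTHETIC stand-in for an empirical replacement-cost matrix: the same
    transform applied to BLOSUM62.
``unit``
    All pairwise costs 1 (built in, no fixture); useful as a consistency
    check because the mean unit cost equals the non-synonymous probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ValidationError

#: Canonical amino-acid order for all cost tables.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_SCHEME_FILES = {
    "grantham_chemical_distance": "grantham_chemical_distance.tsv",
    "kd_hydropathy": "kd_hydropathy.tsv",
    "aa_pair_distance": "aa_pair_distance.synthetic.tsv",
    "empar": "empar.synthetic.tsv",
    "polar_requirement": "polar_requirement.tsv",
}

AVAILABLE_SCHEMES = tuple(sorted([*_SCHEME_FILES, "unit"]))


@dataclass(frozen=True)
class CostScheme:
    """Symmetric amino-acid replacement cost table plus the stop-cost rule."""

    name: str
    cost: np.ndarray  # (20, 20), indexed by AA_ORDER
    stop_cost: float
    derived_from_index: bool

    def __post_init__(self):
        c = np.asarray(self.cost, dtype=float)
        if c.shape != (20, 20):
            raise ValidationError("cost table must be 20x20")
        if np.any(c < 0):
            raise ValidationError("costs must be nonnegative")
        if np.max(np.abs(c - c.T)) > 1e-12:
            raise ValidationError("cost table must be symmetric")
        if self.derived_from_index and np.max(np.abs(np.diag(c))) > 1e-12:
            raise ValidationError("index-derived scheme must have zero diagonal")
        if abs(self.stop_cost - c.max()) > 1e-12:
            raise ValidationError("stop cost must equal the maximum pairwise cost")
        object.__setattr__(self, "cost", c)

    def pair_cost(self, a: str, b: str) -> float:
        return float(self.cost[AA_INDEX[a], AA_INDEX[b]])


def _parse_fixture(text: str) -> tuple[list[str], np.ndarray]:
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = rows[0].strip("\t").split("\t")
    body = [r.split("\t") for r in rows[1:]]
    if len(body) == 1:  # 20-vector index
        return header, np.array([float(x) for x in body[0]])
    labels = [r[0] for r in body]
    mat = np.array([[float(x) for x in r[1:]] for r in body])
    if labels != header:
        raise ValidationError("fixture row labels do not match header")
    return header, mat


def load_cost_scheme(name: str) -> CostScheme:
    """Load a packaged cost scheme by name.

    Index fixtures (a single row of 20 values) are expanded to pairwise
    costs |v_a - v_b|; matrix fixtures are used as-is.  The stop cost is
    always the maximum pairwise cost of the resulting table.
    """
    if name == "unit":
        c = 1.0 - np.eye(20)
        return CostScheme("unit", c, 1.0, derived_from_index=False)
    if name not in _SCHEME_FILES:
        raise KeyError(
            f"unknown cost scheme {name!r}; available: {', '.join(AVAILABLE_SCHEMES)}"
        )
    text = (resources.files("mutopt") / "data" / _SCHEME_FILES[name]).read_text()
    header, data = _parse_fixture(text)
    if header != list(AA_ORDER):
        # reorder to canonical order if the fixture uses another one
        perm = [header.index(a) for a in AA_ORDER]
        data = data[perm] if data.ndim == 1 else data[np.ix_(perm, perm)]
    if data.ndim == 1:
        cost = np.abs(data[:, None] - data[None, :])
        derived = True
    else:
        cost = 0.5 * (data + data.T)
        derived = False
    return CostScheme(name, cost, float(cost.max()), derived_from_index=derived)
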