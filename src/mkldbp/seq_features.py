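"""Profile-free sequence descriptors: GE, MCD and NMBAC.

Three encoders that need only the amino-acid string:

* **GE** (Global Encoding): residues are mapped to 6 physicochemical
  classes; the sequence is partitioned by successive halving into
  1 + 2 + 4 + 8 = 15 segments; each segment contributes 6 class-composition
  frequencies and 15 unordered class-transition frequencies (315 dims).
* **MCD** (Multi-scale Continuous and Discontinuous descriptor): residues
  are mapped to 7 classes; the sequence is cut into quarters Q1..Q4 and 14
  continuous/discontinuous regions are formed; each region contributes the
  standard Composition / Transition / Distribution triple (882 dims).
* **NMBAC** (Normalized Moreau-Broto autocorrelation): lagged
  autocorrelation of 6 standardized physicochemical property profiles
  (6 * lg_max dims, 180 at the default lg_max = 30).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from itertools import combinations

import numpy as np

from .sequence_io import AMINO_ACIDS, ProteinRecord

FEATURE_NAMES = ("GE", "MCD", "NMBAC", "PSSM-AB", "PSSM-DWT", "PsePSSM")


@dataclasses.dataclass
class FeatureMatrix:
    """N samples x d descriptor values for one named feature type."""

    feature_name: str
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count must match sample_ids length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.feature_name} features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class PropertyTable:
    """Six standardized physicochemical property vectors over the 20 residues."""

    names: list[str]
    values: np.ndarray  # 6 x 20, each row mean 0, sd 1 (population)

    def lookup(self, sequence: str) -> np.ndarray:
        """6 x L matrix of property values along a sequence."""
        idx = [_AA_INDEX[aa] for aa in sequence]
        return self.values[:, idx]


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# 6-class physicochemical grouping used by GE.
GE_CLASSES = ("AVLIMC", "FWYH", "STNQ", "KR", "DE", "GP")
# 7-class grouping used by MCD.
MCD_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

# The 14 MCD regions as tuples of quarter indices; Q1..Q4 are 0..3.  First
# the 10 contiguous runs, then the 4 discontinuous unions.
MCD_REGIONS: tuple[tuple[int, ...], ...] = (
    (0,), (1,), (2,), (3,),
    (0, 1), (1, 2), (2, 3),
    (0, 1, 2), (1, 2, 3), (0, 1, 2, 3),
    (0, 2), (1, 3), (0, 3), (0, 1, 3),
)


def _class_map(groups: tuple[str, ...]) -> dict[str, int]:
    mapping: dict[str, int] = {}
    for ci, residues in enumerate(groups):
        for aa in residues:
            mapping[aa] = ci
    assert len(mapping) == 20
    return mapping


_GE_MAP = _class_map(GE_CLASSES)
_MCD_MAP = _class_map(MCD_CLASSES)


# ---------------------------------------------------------------------------
# Property table
# ---------------------------------------------------------------------------

def standardize_properties(raw: np.ndarray, names: list[str] | None = None) -> PropertyTable:
    """Standardize each property row to mean 0, sd 1 over the 20 residues.

    Population (divide-by-N) standard deviation, the convention used for
    every standardization in this package.  A zero-variance row is an error.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 20:
        raise ValueError(f"expected a k x 20 property matrix, got {raw.shape}")
    mean = raw.mean(axis=1, keepdims=True)
    std = raw.std(axis=1, keepdims=True)
    if np.any(std < 1e-12):
        bad = int(np.argmin(std))
        raise ValueError(f"property row {bad} has zero variance")
    if names is None:
        names = [f"prop{j}" for j in range(raw.shape[0])]
    return PropertyTable(names=list(names), values=(raw - mean) / std)


def load_property_table() -> PropertyTable:
    """Load and standardize the packaged six-property table."""
    text = (
        resources.files("mkldbp").joinpath("data/physicochemical_properties.tsv")
    ).read_text()
    names, rows = [], []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts[1:]
            continue
        names.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    assert header is not None
    perm = [header.index(aa) for aa in AMINO_ACIDS]
    raw = np.asarray(rows, dtype=float)[:, perm]
    return standardize_properties(raw, names)


# ---------------------------------------------------------------------------
# NMBAC
# ---------------------------------------------------------------------------

def encode_nmbac(
    record: ProteinRecord, table: PropertyTable | None = None, lg_max: int = 30
) -> np.ndarray:
    """Normalized Moreau-Broto autocorrelation, 6 * lg_max values.

    Entry (j, d) = (1 / (L - d)) * sum_i P_j(s_i) * P_j(s_{i+d}) for
    standardized property j and lag d = 1..lg_max; property-major ordering.
    """
    if table is None:
        table = load_property_table()
    L = len(record.sequence)
    if L <= lg_max:
        raise ValueError(
            f"sequence {record.id!r} has length {L} <= lg_max={lg_max}; "
            "lower lg_max"
        )
    props = table.lookup(record.sequence)  # 6 x L
    out = np.empty((props.shape[0], lg_max))
    for d in range(1, lg_max + 1):
        out[:, d - 1] = (props[:, :-d] * props[:, d:]).mean(axis=1)
    return out.ravel()


# ---------------------------------------------------------------------------
# Shared composition/transition helpers
# ---------------------------------------------------------------------------

def _composition(classes: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(classes, minlength=n_classes) / len(classes)


def _transitions(classes: np.ndarray, n_classes: int) -> np.ndarray:
    """Unordered adjacent-pair frequencies (i->j and j->i pooled)."""
    pairs = list(combinations(range(n_classes), 2))
    out = np.zeros(len(pairs))
    if len(classes) < 2:
        return out
    a, b = classes[:-1], classes[1:]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    idx = {p: k for k, p in enumerate(pairs)}
    for l, h in zip(lo, hi):
        if l != h:
            out[idx[(int(l), int(h))]] += 1
    return out / (len(classes) - 1)


def _distribution(classes: np.ndarray, n_classes: int) -> np.ndarray:
    """Positions (fraction of region length) of the 1st, 25%, 50%, 75% and
    100% occurrences of each class; absent classes contribute five zeros."""
    L = len(classes)
    out = np.zeros((n_classes, 5))
    for c in range(n_classes):
        pos = np.flatnonzero(classes == c) + 1  # 1-based positions
        n = len(pos)
        if n == 0:
            continue
        ranks = [0, int(np.ceil(0.25 * n)) - 1, int(np.ceil(0.5 * n)) - 1,
                 int(np.ceil(0.75 * n)) - 1, n - 1]
        out[c] = pos[ranks] / L
    return out.ravel()


def _segments(L: int, parts: int) -> list[np.ndarray]:
    """Split indices 0..L-1 into `parts` contiguous chunks; earlier chunks
    absorb the remainder."""
    return list(map(np.asarray, np.array_split(np.arange(L), parts)))


# ---------------------------------------------------------------------------
# GE
# ---------------------------------------------------------------------------

def encode_ge(record: ProteinRecord) -> np.ndarray:
    """Global Encoding: 15 halving segments x (6 composition + 15 transition)."""
    L = len(record.sequence)
    if L < 50:
        raise ValueError(f"sequence {record.id!r} shorter than 50 residues")
    classes = np.array([_GE_MAP[aa] for aa in record.sequence])
    blocks = []
    for level in range(4):  # 1, 2, 4, 8 segments
        for seg in _segments(L, 2**level):
            sub = classes[seg]
            blocks.append(_composition(sub, 6))
            blocks.append(_transitions(sub, 6))
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# MCD
# ---------------------------------------------------------------------------

def encode_mcd(record: ProteinRecord) -> np.ndarray:
    """Multi-scale Continuous and Discontinuous descriptor (882 values)."""
    L = len(record.sequence)
    if L < 50:
        raise ValueError(f"sequence {record.id!r} shorter than 50 residues")
    classes = np.array([_MCD_MAP[aa] for aa in record.sequence])
    quarters = _segments(L, 4)
    blocks = []
    for region in MCD_REGIONS:
        sub = np.concatenate([classes[quarters[q]] for q in region])
        blocks.append(_composition(sub, 7))
        blocks.append(_transitions(sub, 7))
        blocks.append(_distribution(sub, 7))
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# Batch encoding
# ---------------------------------------------------------------------------

def encode_sequences(
    records: list[ProteinRecord],
    feature_name: str,
    table: PropertyTable | None = None,
    lg_max: int = 30,
) -> FeatureMatrix:
    """Encode a list of records with one sequence-only descriptor."""
    if feature_name == "GE":
        rows = [encode_ge(r) for r in records]
    elif feature_name == "MCD":
        rows = [encode_mcd(r) for r in records]
    elif feature_name == "NMBAC":
        if table is None:
            table = load_property_table()
        rows = [encode_nmbac(r, table, lg_max) for r in records]
    else:
        raise ValueError(f"unknown sequence feature {feature_name!r}")
    return FeatureMatrix(
        feature_name=feature_name,
        values=np.vstack(rows),
        sample_ids=[r.id for r in records],
    )
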