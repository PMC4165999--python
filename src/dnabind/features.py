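"""Fixed-length numeric descriptors of protein sequences.

Three extractor families are provided:

* **188D composition/physicochemical descriptor** — 20 amino-acid
  composition frequencies followed by, for each of 8 physicochemical
  properties whose 3-way residue-class partition is configurable, a 21-dim
  block: 3 class-composition frequencies, 3 bivalent class-transition
  frequencies, and 15 per-segment class-distribution frequencies (the
  sequence split into five equal parts).  20 + 8x21 = 188.
* **n-gram frequencies** — 1-gram is the 20-dim composition; 2-gram the 400
  ordered dipeptide frequencies; together 420 dims.
* **Type-1 pseudo amino-acid composition (PseAAC)** — composition augmented
  with lambda sequence-order correlation factors computed from z-scored
  hydrophobicity, hydrophilicity and side-chain-mass scales, weighted by w,
  the whole vector normalised to sum to 1.

The default 8 property partitions (hydrophobicity, normalised van der Waals
volume, polarity, polarizability, charge, secondary-structure propensity,
solvent accessibility, surface tension) follow the standard CTD groupings
and ship as an editable JSON config.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, ProteinRecord

__all__ = [
    "PropertyPartition",
    "ExtractorSpec",
    "load_partitions",
    "default_partitions",
    "aa_composition",
    "class_composition",
    "class_transitions",
    "class_distribution",
    "extract_ctd188",
    "extract_ngram",
    "extract_pseaac",
    "extract_matrix",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Scales for type-1 PseAAC: hydrophobicity (Tanford-style consensus values),
# hydrophilicity (Hopp-Woods), and side-chain mass.
PSEAAC_SCALES: dict[str, dict[str, float]] = {
    "hydrophobicity": {
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
        "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
        "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
        "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
    },
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
        "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
        "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
        "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
    },
    "side_chain_mass": {
        "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
        "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
        "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
        "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
    },
}


@dataclasses.dataclass(frozen=True)
class PropertyPartition:
    """A named 3-way disjoint partition of the 20 amino acids."""

    property_name: str
    class1: frozenset[str]
    class2: frozenset[str]
    class3: frozenset[str]

    def __post_init__(self) -> None:
        classes = (self.class1, self.class2, self.class3)
        union = self.class1 | self.class2 | self.class3
        total = sum(len(c) for c in classes)
        if total != 20 or union != frozenset(AMINO_ACIDS):
            raise ValueError(
                f"partition {self.property_name!r} must cover the 20 amino "
                f"acids exactly once (got {sorted(union)} with {total} letters)"
            )

    @classmethod
    def from_strings(cls, name: str, c1: str, c2: str, c3: str) -> "PropertyPartition":
        return cls(name, frozenset(c1), frozenset(c2), frozenset(c3))

    def class_of(self) -> dict[str, int]:
        """Residue letter -> class index 0/1/2."""
        out = {}
        for i, cls_set in enumerate((self.class1, self.class2, self.class3)):
            for aa in cls_set:
                out[aa] = i
        return out


def load_partitions(path: str | Path) -> list[PropertyPartition]:
    """Load property partitions from a JSON list of {property, class1..3}."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        PropertyPartition.from_strings(
            d["property"], d["class1"], d["class2"], d["class3"]
        )
        for d in raw
    ]


def default_partitions() -> list[PropertyPartition]:
    """The 8 standard physicochemical partitions shipped with the package."""
    text = (
        resources.files("dnabind.data")
        .joinpath("property_partitions.json")
        .read_text()
    )
    raw = json.loads(text)
    return [
        PropertyPartition.from_strings(
            d["property"], d["class1"], d["class2"], d["class3"]
        )
        for d in raw
    ]


@dataclasses.dataclass(frozen=True)
class ExtractorSpec:
    """Which extractor to run and its parameters."""

    method: str = "ctd188"  # ctd188 | ngram | pseaac
    partitions: tuple[PropertyPartition, ...] | None = None
    n_values: frozenset[int] = frozenset({1, 2})
    lam: int = 10
    w: float = 0.05

    def resolved_partitions(self) -> tuple[PropertyPartition, ...]:
        parts = self.partitions
        if parts is None:
            parts = tuple(default_partitions())
        if self.method == "ctd188" and len(parts) != 8:
            raise ValueError(f"ctd188 requires exactly 8 partitions, got {len(parts)}")
        return tuple(parts)


def _check_sequence(seq: str) -> None:
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid letters in sequence: {sorted(bad)}")
    if not seq:
        raise ValueError("empty sequence")


def aa_composition(seq: str) -> np.ndarray:
    """Frequency of each of the 20 amino acids, in alphabet order. Sums to 1."""
    _check_sequence(seq)
    counts = np.zeros(20)
    for c in seq:
        counts[_AA_INDEX[c]] += 1
    return counts / len(seq)


def class_composition(seq: str, p: PropertyPartition) -> np.ndarray:
    """Fraction of residues in each of the partition's 3 classes."""
    _check_sequence(seq)
    cls = p.class_of()
    counts = np.zeros(3)
    for c in seq:
        counts[cls[c]] += 1
    return counts / len(seq)


def class_transitions(seq: str, p: PropertyPartition) -> np.ndarray:
    """Frequencies of the 3 unordered between-class adjacencies.

    For class pairs (1,2), (1,3), (2,3): the number of adjacent residue pairs
    whose classes form that pair in either order, divided by L-1.  A
    single-residue sequence has no adjacent pairs and returns zeros.
    """
    _check_sequence(seq)
    if len(seq) < 2:
        return np.zeros(3)
    cls = p.class_of()
    pair_index = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
    counts = np.zeros(3)
    for a, b in zip(seq, seq[1:]):
        ca, cb = cls[a], cls[b]
        if ca != cb:
            counts[pair_index[(min(ca, cb), max(ca, cb))]] += 1
    return counts / (len(seq) - 1)


def segment_bounds(length: int, parts: int = 5) -> list[tuple[int, int]]:
    """Half-open [floor(iL/p), floor((i+1)L/p)) boundaries covering 0..L."""
    return [
        (length * i // parts, length * (i + 1) // parts) for i in range(parts)
    ]


def class_distribution(seq: str, p: PropertyPartition) -> np.ndarray:
    """Per-segment class frequencies over five equal contiguous segments.

    15 values in class-major order: class 1 in segments 1..5, then class 2,
    then class 3.  Each value is the fraction of that segment's residues
    belonging to the class, so for a fixed segment the three class values sum
    to 1.
    """
    _check_sequence(seq)
    if len(seq) < 5:
        raise ValueError("sequence too short for distribution descriptor")
    cls = p.class_of()
    out = np.zeros((3, 5))
    for s, (lo, hi) in enumerate(segment_bounds(len(seq))):
        seg = seq[lo:hi]
        for c in seg:
            out[cls[c], s] += 1
        out[:, s] /= len(seg)
    return out.ravel()


def ctd_feature_names(partitions: Sequence[PropertyPartition]) -> list[str]:
    names = [f"comp.{aa}" for aa in AMINO_ACIDS]
    for p in partitions:
        pn = p.property_name
        names += [f"{pn}.comp.c{i}" for i in (1, 2, 3)]
        names += [f"{pn}.trans.c1c2", f"{pn}.trans.c1c3", f"{pn}.trans.c2c3"]
        names += [f"{pn}.dist.c{c}.s{s}" for c in (1, 2, 3) for s in range(1, 6)]
    return names


def extract_ctd188(
    seq: str, partitions: Sequence[PropertyPartition] | None = None
) -> np.ndarray:
    """The full 188-dim descriptor: 20 composition + 8 x 21 property blocks."""
    if partitions is None:
        partitions = default_partitions()
    if len(partitions) != 8:
        raise ValueError(f"expected 8 property partitions, got {len(partitions)}")
    blocks = [aa_composition(seq)]
    for p in partitions:
        blocks.append(class_composition(seq, p))
        blocks.append(class_transitions(seq, p))
        blocks.append(class_distribution(seq, p))
    return np.concatenate(blocks)


DIPEPTIDES = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=2)]


def ngram_feature_names(n_values: Iterable[int]) -> list[str]:
    names: list[str] = []
    for n in sorted(set(n_values)):
        if n == 1:
            names += [f"g1.{aa}" for aa in AMINO_ACIDS]
        elif n == 2:
            names += [f"g2.{dp}" for dp in DIPEPTIDES]
        else:
            raise ValueError(f"unsupported n-gram order: {n}")
    return names


def extract_ngram(seq: str, n_values: Iterable[int] = (1, 2)) -> np.ndarray:
    """Word frequencies for n in n_values: 20 monomer + 400 dipeptide dims."""
    _check_sequence(seq)
    n_values = sorted(set(n_values))
    if not n_values or not set(n_values) <= {1, 2}:
        raise ValueError(f"n_values must be a non-empty subset of {{1, 2}}")
    if len(seq) < max(n_values):
        raise ValueError("sequence shorter than the largest n-gram order")
    blocks = []
    for n in n_values:
        if n == 1:
            blocks.append(aa_composition(seq))
        else:
            counts = np.zeros(400)
            for i in range(len(seq) - 1):
                dp = seq[i : i + 2]
                counts[_AA_INDEX[dp[0]] * 20 + _AA_INDEX[dp[1]]] += 1
            blocks.append(counts / (len(seq) - 1))
    return np.concatenate(blocks)


def _normalized_scales() -> np.ndarray:
    """The 3 PseAAC scales z-scored over the 20 amino acids (population SD)."""
    mat = np.array(
        [[PSEAAC_SCALES[s][aa] for aa in AMINO_ACIDS] for s in PSEAAC_SCALES]
    )
    mean = mat.mean(axis=1, keepdims=True)
    sd = np.sqrt(((mat - mean) ** 2).mean(axis=1, keepdims=True))
    return (mat - mean) / sd


def pseaac_feature_names(lam: int) -> list[str]:
    return [f"pse.comp.{aa}" for aa in AMINO_ACIDS] + [
        f"pse.theta.{j}" for j in range(1, lam + 1)
    ]


def extract_pseaac(seq: str, lam: int = 10, w: float = 0.05) -> np.ndarray:
    """Type-1 pseudo amino-acid composition: 20 + lam values summing to 1.

    The j-th sequence-order factor theta_j is the mean, over residue pairs
    (i, i+j), of the mean squared difference of the three normalised property
    values; the composition block and the w-weighted factors are jointly
    normalised.  lam=0 reduces exactly to amino-acid composition.
    """
    _check_sequence(seq)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if w <= 0:
        raise ValueError("w must be positive")
    if len(seq) <= lam:
        raise ValueError(
            f"sequence length {len(seq)} must exceed lambda={lam}"
        )
    comp = aa_composition(seq)
    scales = _normalized_scales()  # 3 x 20
    profile = scales[:, [_AA_INDEX[c] for c in seq]]  # 3 x L
    thetas = np.zeros(lam)
    for j in range(1, lam + 1):
        diff = profile[:, j:] - profile[:, :-j]
        thetas[j - 1] = (diff**2).mean(axis=0).mean()
    denom = comp.sum() + w * thetas.sum()
    return np.concatenate([comp, w * thetas]) / denom


def extract_matrix(
    records: Sequence[ProteinRecord], spec: ExtractorSpec | None = None
) -> pd.DataFrame:
    """Extract one feature row per record into a records x features DataFrame."""
    if spec is None:
        spec = ExtractorSpec()
    if spec.method == "ctd188":
        parts = spec.resolved_partitions()
        names = ctd_feature_names(parts)
        fn = lambda s: extract_ctd188(s, parts)
    elif spec.method == "ngram":
        names = ngram_feature_names(spec.n_values)
        fn = lambda s: extract_ngram(s, spec.n_values)
    elif spec.method == "pseaac":
        names = pseaac_feature_names(spec.lam)
        fn = lambda s: extract_pseaac(s, spec.lam, spec.w)
    else:
        raise ValueError(f"unknown extractor method: {spec.method!r}")
    rows = []
    for rec in records:
        try:
            rows.append(fn(rec.sequence))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    data = np.vstack(rows) if rows else np.empty((0, len(names)))
    return pd.DataFrame(data, index=[r.id for r in records], columns=names)
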