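"""Cysteine-anchored sequence space for defensin families.

Defensin sequences are too divergent for conventional phylogenetics
(bootstrap support collapses), so family structure is explored in a
projected *sequence space* instead.  The pipeline here is:

1. **Anchored alignment** — every sequence is partitioned on its eight
   scaffold cysteines; within each of the nine segments (N-tail, loops
   1–7, C-tail) sequences are padded right with gaps to the segment-wise
   maximum length.  The eight anchor columns are pure cysteine by
   construction, guaranteeing alignment of homologous cysteines.  This
   is a deterministic stand-in for a substitution-matrix alignment
   constrained to the same anchors; within-loop alignment is an
   extension point.
2. **Redundancy reduction** — a greedy scan drops any sequence with
   ≥99% identity to an already-retained one.
3. **Numericization** — each aligned residue becomes the 5-component
   Atchley factor vector (standardized physicochemical descriptors:
   polarity/hydrophobicity, secondary-structure propensity, size,
   codon composition, charge); gaps become zero vectors.
4. **Projection** — classical (Torgerson) multidimensional scaling of
   the Euclidean distance matrix: double-center the squared distances,
   eigendecompose, keep the top-d axes scaled by the square root of
   their eigenvalues.  Deterministic, no random initialization; axis
   signs are fixed so the coordinate of largest magnitude on each axis
   is positive.

Nearest-neighbour retrieval and per-loop histidine profiles (the
summary used to show where histidine enrichment sits within a cluster)
operate on the same objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import MatureDefensin
from .scaffold import CysteineScaffold, ScaffoldError, detect_scaffold

GAP = "-"

# Atchley et al. five-factor solution of amino-acid variability:
# (I) polarity/accessibility/hydrophobicity, (II) secondary-structure
# propensity, (III) molecular size/volume, (IV) codon composition,
# (V) electrostatic charge.  Standardized scores.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

# Segment keys in N-to-C order: N-tail, loops 1..7, C-tail.
SEGMENTS: tuple[str, ...] = (
    "n_tail", "loop1", "loop2", "loop3", "loop4", "loop5", "loop6", "loop7",
    "c_tail",
)


@dataclass(frozen=True)
class AnchoredAlignment:
    """Gapped alignment whose eight cysteine columns are pure anchors."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]  # aligned sequences, equal length, '-' gaps
    anchor_columns: tuple[int, ...]  # 8 column indices, 0-based
    loop_spans: Mapping[str, tuple[int, int]]  # segment -> [start, stop) columns

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degap(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


@dataclass(frozen=True)
class SequenceSpace:
    """Low-dimensional embedding of a sequence collection."""

    ids: tuple[str, ...]
    coords: np.ndarray  # n x d
    eigenvalues: np.ndarray  # d, non-increasing, non-negative
    stress: float  # relative error of recovered vs input distances
    distance_metadata: str = "Atchley 5-factor encoding, Euclidean distance"


@dataclass(frozen=True)
class LoopHisProfile:
    """Mean histidine count per scaffold segment for one labeled group."""

    label: str
    n: int
    loop_means: tuple[float, ...]  # loops 1..7
    tail_means: tuple[float, float]  # (n_tail, c_tail)


def anchored_align(ds: Sequence[MatureDefensin]) -> AnchoredAlignment:
    """Build the cysteine-anchored alignment of a collection.

    Every sequence must carry a detectable 8-cysteine scaffold; a
    :class:`ScaffoldError` listing the offending ids is raised
    otherwise.  Per segment, sequences are right-padded with gaps to
    the segment-wise maximum length, so anchor columns contain only
    cysteine and removing gaps from any row reproduces its sequence.
    """
    scaffolds: list[CysteineScaffold] = []
    bad: list[str] = []
    for d in ds:
        try:
            scaffolds.append(detect_scaffold(d))
        except ScaffoldError:
            bad.append(d.id)
    if bad:
        raise ScaffoldError(", ".join(bad)) from None

    def segments(s: CysteineScaffold) -> list[str]:
        return [s.n_tail, *s.loops, s.c_tail]

    seg_max = [
        max(len(segments(s)[j]) for s in scaffolds) for j in range(9)
    ] if scaffolds else [0] * 9

    rows: list[str] = []
    for s in scaffolds:
        parts: list[str] = []
        for j, seg in enumerate(segments(s)):
            parts.append(seg.ljust(seg_max[j], GAP))
            if j < 8:
                parts.append("C")
        rows.append("".join(parts))

    anchor_columns: list[int] = []
    loop_spans: dict[str, tuple[int, int]] = {}
    col = 0
    for j, name in enumerate(SEGMENTS):
        loop_spans[name] = (col, col + seg_max[j])
        col += seg_max[j]
        if j < 8:
            anchor_columns.append(col)
            col += 1

    return AnchoredAlignment(
        ids=tuple(d.id for d in ds),
        rows=tuple(rows),
        anchor_columns=tuple(anchor_columns),
        loop_spans=loop_spans,
    )


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical columns among columns where either row is non-gap."""
    shared = 0
    match = 0
    for a, b in zip(row_a, row_b):
        if a == GAP and b == GAP:
            continue
        shared += 1
        if a == b:
            match += 1
    return match / shared if shared else 0.0


def redundancy_reduce(a: AnchoredAlignment, threshold: float = 0.99) -> list[str]:
    """Greedy redundancy filter: drop sequences ≥ threshold identity.

    Scans in input order; a sequence is dropped when its identity to
    any already-retained sequence reaches the threshold.  Returns the
    retained ids.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    retained_idx: list[int] = []
    for i in range(len(a.ids)):
        if all(
            pairwise_identity(a.rows[i], a.rows[j]) < threshold
            for j in retained_idx
        ):
            retained_idx.append(i)
    return [a.ids[i] for i in retained_idx]


def numericize(a: AnchoredAlignment) -> np.ndarray:
    """Encode an alignment as an (n, 5L) Atchley-factor feature matrix.

    Each residue cell contributes its five factor scores; gap cells
    contribute zeros.  Features are ordered column-major by alignment
    column then factor index, so a single substitution perturbs exactly
    five features.
    """
    n, width = len(a.rows), a.width
    out = np.zeros((n, 5 * width))
    for i, row in enumerate(a.rows):
        for c, ch in enumerate(row):
            if ch != GAP:
                out[i, 5 * c: 5 * c + 5] = ATCHLEY_FACTORS[ch]
    return out


def project_mds(
    features: np.ndarray,
    d: int = 2,
    ids: Sequence[str] | None = None,
) -> SequenceSpace:
    """Classical (Torgerson) MDS of the Euclidean feature distances.

    Double-centers the squared-distance matrix, eigendecomposes, and
    keeps the top ``d`` axes scaled by the square roots of their
    eigenvalues.  Requires n ≥ 3.  If fewer than ``d`` eigenvalues are
    positive, the dimensionality is reduced with a warning.  Axis signs
    are fixed so the coordinate of largest magnitude on each axis is
    positive; the relative residual of recovered vs input distances is
    reported as ``stress``.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 3:
        raise ValueError("classical MDS needs at least 3 points")
    dist = squareform(pdist(features))
    sq = dist ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ sq @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(n, 1) * np.abs(eigvals[0]) * np.finfo(float).eps if eigvals.size else 0.0
    n_pos = int(np.sum(eigvals > tol))
    if n_pos < d:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; reducing dimensions "
            f"from {d} to {n_pos}",
            stacklevel=2,
        )
        d = n_pos
    vals = eigvals[:d]
    coords = eigvecs[:, :d] * np.sqrt(vals)

    # fix axis orientation: largest-magnitude coordinate positive
    for j in range(d):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col

    recovered = squareform(pdist(coords)) if d > 0 else np.zeros_like(dist)
    denom = np.linalg.norm(dist)
    stress = float(np.linalg.norm(recovered - dist) / denom) if denom > 0 else 0.0

    if ids is None:
        ids = tuple(str(i) for i in range(n))
    return SequenceSpace(
        ids=tuple(ids),
        coords=coords,
        eigenvalues=vals,
        stress=stress,
    )


def nearest_neighbours(s: SequenceSpace, query: str, k: int = 30) -> list[str]:
    """The k nearest sequences to ``query`` by Euclidean distance.

    The query itself is excluded; ties are broken by input order.
    """
    try:
        qi = s.ids.index(query)
    except ValueError:
        raise KeyError(f"unknown id {query!r}") from None
    if not 0 < k < len(s.ids):
        raise ValueError("k must satisfy 0 < k < n")
    dists = np.linalg.norm(s.coords - s.coords[qi], axis=1)
    order = np.argsort(dists, kind="stable")
    ranked = [int(i) for i in order if i != qi]
    return [s.ids[i] for i in ranked[:k]]


def loop_his_profile(
    ds: Sequence[MatureDefensin],
    groups: Mapping[str, str],
) -> list[LoopHisProfile]:
    """Mean histidine count per scaffold segment, per labeled group.

    Every sequence must have a scaffold and a group label; profiles are
    returned in first-appearance order of the labels.
    """
    missing = [d.id for d in ds if d.id not in groups]
    if missing:
        raise ValueError(f"missing group label for: {', '.join(missing)}")
    by_label: dict[str, list[CysteineScaffold]] = {}
    for d in ds:
        by_label.setdefault(groups[d.id], []).append(detect_scaffold(d))
    profiles = []
    for label, scaffolds in by_label.items():
        n = len(scaffolds)
        loop_means = tuple(
            sum(s.loops[j].count("H") for s in scaffolds) / n for j in range(7)
        )
        tail_means = (
            sum(s.n_tail.count("H") for s in scaffolds) / n,
            sum(s.c_tail.count("H") for s in scaffolds) / n,
        )
        profiles.append(
            LoopHisProfile(label=label, n=n, loop_means=loop_means,
                           tail_means=tail_means)
        )
    return profiles


def k_medoids(
    dist: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
) -> np.ndarray:
    """Partition-around-medoids clustering of a precomputed distance matrix.

    A small deterministic PAM: medoids are initialized by a seeded
    draw, then alternately (a) points are assigned to the nearest
    medoid and (b) each cluster's medoid is moved to its
    cost-minimizing member, until assignments stabilize.  Returns the
    integer label of each point.
    """
    dist = np.asarray(dist)
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must satisfy 1 <= k <= n")
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    labels = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if members.size == 0:
                continue
            costs = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(costs)]
        new_labels = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_labels, labels) and np.array_equal(
            new_medoids, medoids
        ):
            break
        medoids, labels = new_medoids, new_labels
    return labels
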