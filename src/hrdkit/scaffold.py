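"""CSαβ scaffold detection, loop partition and disulfide connectivity.

Plant defensins fold into the cysteine-stabilized alpha-beta (CSαβ)
motif: an α-helix packed against a triple-stranded β-sheet, cross-linked
by four disulfide bonds between eight absolutely conserved cysteines.
This module locates those eight cysteines in a mature sequence,
partitions the sequence into the seven inter-cysteine loops (numbered
1–7, with the N- and C-terminal tails tracked separately), and assigns
disulfide connectivity under two pairing rules:

* ``standard`` — the canonical plant-defensin pairing C1–C8, C2–C5,
  C3–C6, C4–C7 (exemplified by SlD26);
* ``shifted`` — the alternative pairing C1–C5, C2–C6, C3–C7, C4–C8
  observed structurally in AtD90.

All residue coordinates are 1-based and count the N-terminal alanine
added by the expression system, so e.g. SlD26's second cysteine is
"Cys15".

The ``classify_connectivity_pattern`` rule — nearest template gap vector
under L1 distance — is a predictive heuristic built on the observation
that the shifted pattern is expected to recur in sequences with similar
cysteine spacing; it is not an experimentally determined rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import MatureDefensin

STANDARD = "standard"
SHIFTED = "shifted"
UNASSIGNED = "unassigned"

# Cysteine-rank pairings for the two connectivity patterns.
_PATTERNS: dict[str, tuple[tuple[int, int], ...]] = {
    STANDARD: ((1, 8), (2, 5), (3, 6), (4, 7)),
    SHIFTED: ((1, 5), (2, 6), (3, 7), (4, 8)),
}

# Gap vectors of the two structurally characterized study peptides,
# used as default classification templates.
SLD26_GAP_VECTOR: tuple[int, ...] = (10, 4, 3, 10, 4, 1, 3)
ATD90_GAP_VECTOR: tuple[int, ...] = (11, 4, 3, 7, 3, 8, 1)
DEFAULT_TEMPLATES: tuple[tuple[tuple[int, ...], str], ...] = (
    (SLD26_GAP_VECTOR, STANDARD),
    (ATD90_GAP_VECTOR, SHIFTED),
)


class ScaffoldError(ValueError):
    """Raised when a sequence does not carry exactly eight cysteines."""

    def __init__(self, defensin_id: str, observed: int | None = None):
        self.defensin_id = defensin_id
        self.observed = observed
        if observed is None:
            msg = f"no 8-cysteine scaffold: {defensin_id}"
        else:
            msg = f"{defensin_id}: expected 8 cysteines, found {observed}"
        super().__init__(msg)


@dataclass(frozen=True)
class CysteineScaffold:
    """The eight cysteine positions and loop partition of one sequence.

    ``loops[i]`` holds the residues strictly between the (i+1)-th and
    (i+2)-th cysteine (0-based list index; loops are numbered 1–7 in
    the field's convention).  Concatenating
    ``n_tail + C + loop1 + C + ... + loop7 + C + c_tail`` reconstructs
    the sequence exactly.
    """

    defensin_id: str
    cys_positions: tuple[int, ...]  # 8 positions, 1-based, increasing
    n_tail: str
    loops: tuple[str, ...]  # 7 inter-cysteine segments
    c_tail: str

    @property
    def gap_vector(self) -> tuple[int, ...]:
        """The seven loop lengths — the cysteine-spacing summary."""
        return tuple(len(s) for s in self.loops)

    def reconstruct(self) -> str:
        parts = [self.n_tail]
        for loop in self.loops:
            parts.append("C")
            parts.append(loop)
        parts.append("C")
        parts.append(self.c_tail)
        return "".join(parts)


@dataclass(frozen=True)
class DisulfideAssignment:
    """Four disulfide pairs as 1-based residue positions, plus the pattern label."""

    pairs: tuple[tuple[int, int], ...]
    pattern: str

    def __post_init__(self) -> None:
        used = [p for pair in self.pairs for p in pair]
        if len(used) != 8 or len(set(used)) != 8:
            raise ValueError("pairs must form a perfect matching on 8 positions")


def detect_scaffold(d: MatureDefensin) -> CysteineScaffold:
    """Locate the 8-cysteine scaffold of a mature defensin.

    Raises :class:`ScaffoldError` (reporting the observed count) when
    the sequence does not contain exactly eight cysteines; batch callers
    may catch it and route such sequences to a non-canonical bin.
    """
    positions = tuple(
        i for i, ch in enumerate(d.sequence, start=1) if ch == "C"
    )
    if len(positions) != 8:
        raise ScaffoldError(d.id, len(positions))
    seq = d.sequence
    n_tail = seq[: positions[0] - 1]
    loops = tuple(
        seq[positions[i]: positions[i + 1] - 1] for i in range(7)
    )
    c_tail = seq[positions[7]:]
    return CysteineScaffold(
        defensin_id=d.id,
        cys_positions=positions,
        n_tail=n_tail,
        loops=loops,
        c_tail=c_tail,
    )


def assign_connectivity(s: CysteineScaffold, pattern: str) -> DisulfideAssignment:
    """Map a cysteine-rank pairing rule onto residue positions.

    ``pattern`` is ``"standard"`` (C1–C8, C2–C5, C3–C6, C4–C7) or
    ``"shifted"`` (C1–C5, C2–C6, C3–C7, C4–C8).
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"unknown connectivity pattern {pattern!r}")
    pairs = tuple(
        (s.cys_positions[a - 1], s.cys_positions[b - 1])
        for a, b in _PATTERNS[pattern]
    )
    return DisulfideAssignment(pairs=pairs, pattern=pattern)


def classify_connectivity_pattern(
    s: CysteineScaffold,
    templates: Sequence[tuple[Sequence[int], str]] = DEFAULT_TEMPLATES,
) -> tuple[str, int]:
    """Predict the connectivity pattern from cysteine spacing.

    Returns ``(label, distance)`` where ``label`` is the label of the
    template whose gap vector is closest to the query's under L1
    distance, and ``distance`` is that minimum.  If templates carrying
    different labels tie at the minimum the result is ``"unassigned"``.
    Depends only on the gap vector, never on loop residue content.
    """
    if not templates:
        raise ValueError("at least one template is required")
    q = s.gap_vector
    best: int | None = None
    best_labels: set[str] = set()
    for gaps, label in templates:
        if len(gaps) != 7:
            raise ValueError("template gap vectors must have length 7")
        dist = sum(abs(a - b) for a, b in zip(q, gaps))
        if best is None or dist < best:
            best = dist
            best_labels = {label}
        elif dist == best:
            best_labels.add(label)
    assert best is not None
    if len(best_labels) > 1:
        return UNASSIGNED, best
    return best_labels.pop(), best
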