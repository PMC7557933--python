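"""Ground-truthed synthetic data for every pipeline stage.

The curated defensin database behind the published sequence space is
not deposited, so the generator here produces collections with the
same *statistical structure* the analysis assumes, plus exact ground
truth: 8-cysteine scaffolded sequences with configurable loop lengths,
per-loop histidine enrichment, planted sequence clusters built by
mutating a template, near-duplicate entries at ≥99% identity (the
redundancy the 99% filter is meant to remove), and two-fold-dilution
dose–response series with additive Gaussian noise.

Ground truth records *realized* quantities (actual His counts, actual
loop boundaries) rather than intended ones, so classifier tests can be
exact instead of probabilistic.  Everything is reproducible from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .binding import DoseResponseSeries, design_dilution_series, fraction_bound
from .io import MatureDefensin
from .physchem import DEFAULT_HRD_CUTOFF
from .scaffold import ATD90_GAP_VECTOR, SLD26_GAP_VECTOR, detect_scaffold

NON_CYS_RESIDUES = "ADEFGHIKLMNPQRSTVWY"

# Loop-length ranges bracketing the spacings seen in canonical
# 8-cysteine defensins (gap vectors of the structurally characterized
# study peptides fall inside these).
DEFAULT_LOOP_RANGES: tuple[tuple[int, int], ...] = (
    (9, 12), (3, 5), (2, 4), (6, 10), (2, 5), (1, 8), (1, 3),
)
DEFAULT_TAIL_RANGES: tuple[tuple[int, int], ...] = ((1, 3), (0, 5))

# Templates for connectivity-labeled clusters: loop lengths are drawn
# near the gap vector characteristic of each pattern.
_CLASS_GAP_VECTORS = {"standard": SLD26_GAP_VECTOR, "shifted": ATD90_GAP_VECTOR}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic defensin collection.

    ``his_enrichment`` maps a loop index (1–7) to a His probability
    boost b: within that loop each residue is H with probability
    b + (1−b)·p_bg(H).  With ``n_clusters`` ≥ 1, cluster members are
    template mutants at ``within_cluster_mutations`` random non-Cys
    positions; ``cluster_his_enrichment`` optionally overrides the
    global enrichment per cluster.  ``duplicate_fraction`` of the
    sequences are near-copies (≤1% of positions changed, hence ≥99%
    identity) of an earlier sequence.
    """

    n_sequences: int = 100
    seed: int = 0
    loop_length_ranges: tuple[tuple[int, int], ...] = DEFAULT_LOOP_RANGES
    tail_length_ranges: tuple[tuple[int, int], ...] = DEFAULT_TAIL_RANGES
    background_frequencies: Mapping[str, float] | None = None  # uniform default
    his_enrichment: Mapping[int, float] = field(default_factory=dict)
    n_clusters: int = 0
    within_cluster_mutations: int = 5
    duplicate_fraction: float = 0.0
    connectivity_class: tuple[str, ...] = ()  # one label per cluster, optional
    cluster_his_enrichment: tuple[Mapping[int, float], ...] = ()


@dataclass(frozen=True)
class GroundTruthRecord:
    """What was actually planted for one emitted sequence."""

    id: str
    cluster: int | None
    is_hrd: bool
    cys_positions: tuple[int, ...]
    loop_his_counts: tuple[int, ...]  # loops 1..7, realized
    duplicate_of: str | None
    connectivity_class: str | None


def _background_probs(spec: SyntheticSpec) -> tuple[np.ndarray, str]:
    letters = NON_CYS_RESIDUES
    if spec.background_frequencies is None:
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        if set(spec.background_frequencies) != set(letters):
            raise ValueError(
                "background_frequencies must cover exactly the 19 non-Cys residues"
            )
        probs = np.array([spec.background_frequencies[ch] for ch in letters])
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("background frequencies must form a distribution")
        probs = probs / probs.sum()
    return probs, letters


def _validate(spec: SyntheticSpec) -> None:
    if spec.n_sequences < 1:
        raise ValueError("n_sequences must be positive")
    if len(spec.loop_length_ranges) != 7 or len(spec.tail_length_ranges) != 2:
        raise ValueError("need 7 loop ranges and 2 tail ranges")
    for lo, hi in (*spec.loop_length_ranges, *spec.tail_length_ranges):
        if lo < 0 or hi < lo:
            raise ValueError("length ranges must be non-negative intervals")
    for boost in spec.his_enrichment.values():
        if not 0 <= boost <= 1:
            raise ValueError("his_enrichment boosts must lie in [0, 1]")
    if not 0 <= spec.duplicate_fraction < 1:
        raise ValueError("duplicate_fraction must lie in [0, 1)")
    n_dup = round(spec.duplicate_fraction * spec.n_sequences)
    if n_dup > 0 and spec.n_sequences - n_dup < 1:
        raise ValueError("duplicate_fraction leaves no parent sequences")
    if spec.connectivity_class and len(spec.connectivity_class) != spec.n_clusters:
        raise ValueError("connectivity_class needs one label per cluster")
    if (
        spec.cluster_his_enrichment
        and len(spec.cluster_his_enrichment) != spec.n_clusters
    ):
        raise ValueError("cluster_his_enrichment needs one mapping per cluster")


def _draw_segment(
    rng: np.random.Generator,
    length: int,
    probs: np.ndarray,
    letters: str,
    his_boost: float,
) -> str:
    out = []
    for _ in range(length):
        if his_boost > 0 and rng.random() < his_boost:
            out.append("H")
        else:
            out.append(letters[rng.choice(len(letters), p=probs)])
    return "".join(out)


def _assemble(n_tail: str, loops: Sequence[str], c_tail: str) -> str:
    parts = [n_tail]
    for loop in loops:
        parts.append("C")
        parts.append(loop)
    parts.append("C")
    parts.append(c_tail)
    return "".join(parts)


def _draw_sequence(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    probs: np.ndarray,
    letters: str,
    enrichment: Mapping[int, float],
    gap_center: tuple[int, ...] | None,
) -> str:
    if gap_center is None:
        loop_lens = [rng.integers(lo, hi + 1) for lo, hi in spec.loop_length_ranges]
    else:
        loop_lens = [max(0, g + int(rng.integers(-1, 2))) for g in gap_center]
    tail_lens = [rng.integers(lo, hi + 1) for lo, hi in spec.tail_length_ranges]
    n_tail = _draw_segment(rng, tail_lens[0], probs, letters, 0.0)
    loops = [
        _draw_segment(rng, loop_lens[j], probs, letters, enrichment.get(j + 1, 0.0))
        for j in range(7)
    ]
    c_tail = _draw_segment(rng, tail_lens[1], probs, letters, 0.0)
    return _assemble(n_tail, loops, c_tail)


def _mutate(
    rng: np.random.Generator, seq: str, n_mutations: int, letters: str
) -> str:
    chars = list(seq)
    non_cys_positions = [i for i, ch in enumerate(chars) if ch != "C"]
    if not non_cys_positions:
        return seq
    n = min(n_mutations, len(non_cys_positions))
    for i in rng.choice(len(non_cys_positions), size=n, replace=False):
        pos = non_cys_positions[i]
        alternatives = [ch for ch in letters if ch != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def generate_defensins(
    spec: SyntheticSpec,
) -> tuple[list[MatureDefensin], list[GroundTruthRecord]]:
    """Generate a scaffolded collection plus its ground truth.

    Every emitted sequence carries exactly eight cysteines, so it
    passes scaffold detection; ground-truth loop boundaries equal the
    detected ones by construction.
    """
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    probs, letters = _background_probs(spec)

    n_dup = round(spec.duplicate_fraction * spec.n_sequences)
    n_primary = spec.n_sequences - n_dup

    cluster_templates: list[str] = []
    cluster_enrich: list[Mapping[int, float]] = []
    for c in range(spec.n_clusters):
        enrich = (
            spec.cluster_his_enrichment[c]
            if spec.cluster_his_enrichment
            else spec.his_enrichment
        )
        label = spec.connectivity_class[c] if spec.connectivity_class else None
        gap_center = _CLASS_GAP_VECTORS[label] if label else None
        cluster_templates.append(
            _draw_sequence(rng, spec, probs, letters, enrich, gap_center)
        )
        cluster_enrich.append(enrich)

    seqs: list[str] = []
    clusters: list[int | None] = []
    for i in range(n_primary):
        if spec.n_clusters > 0:
            c = i % spec.n_clusters
            seq = _mutate(
                rng, cluster_templates[c], spec.within_cluster_mutations, letters
            )
            clusters.append(c)
        else:
            seq = _draw_sequence(rng, spec, probs, letters, spec.his_enrichment, None)
            clusters.append(None)
        seqs.append(seq)

    duplicate_of: list[int | None] = [None] * n_primary
    for _ in range(n_dup):
        parent = int(rng.integers(n_primary))
        seq = seqs[parent]
        max_changes = len(seq) // 100  # keep identity at >= 99%
        n_changes = int(rng.integers(0, max_changes + 1)) if max_changes else 0
        seqs.append(_mutate(rng, seq, n_changes, letters))
        clusters.append(clusters[parent])
        duplicate_of.append(parent)

    records: list[MatureDefensin] = []
    truth: list[GroundTruthRecord] = []
    for i, seq in enumerate(seqs):
        rid = f"syn{i:04d}"
        d = MatureDefensin(id=rid, sequence=seq, notes="synthetic")
        s = detect_scaffold(d)
        cluster = clusters[i]
        records.append(d)
        truth.append(
            GroundTruthRecord(
                id=rid,
                cluster=cluster,
                is_hrd=seq.count("H") >= DEFAULT_HRD_CUTOFF,
                cys_positions=s.cys_positions,
                loop_his_counts=tuple(loop.count("H") for loop in s.loops),
                duplicate_of=(
                    f"syn{duplicate_of[i]:04d}" if duplicate_of[i] is not None else None
                ),
                connectivity_class=(
                    spec.connectivity_class[cluster]
                    if spec.connectivity_class and cluster is not None
                    else None
                ),
            )
        )
    return records, truth


def generate_binding_series(
    kd: float,
    protein: float,
    top: float = 20e-3,
    steps: int = 15,
    mix_ratio: float = 0.5,
    signal_unbound: float = 800.0,
    signal_bound: float = 850.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    metal: str | None = None,
) -> DoseResponseSeries:
    """Simulate a dose–response series on the two-fold dilution design.

    ``noise_sd`` is the Gaussian noise standard deviation as a fraction
    of the signal amplitude |signal_bound − signal_unbound|.  With
    ``noise_sd = 0`` the signals lie exactly on the isotherm.  The
    default design is the fifteen-step series from a 20 mM top, mixed
    1:1 with protein.
    """
    if kd <= 0 or protein <= 0:
        raise ValueError("kd and protein concentration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    conc = design_dilution_series(top, steps, mix_ratio)
    amplitude = signal_bound - signal_unbound
    clean = [
        signal_unbound + amplitude * fraction_bound(protein, c, kd) for c in conc
    ]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd * abs(amplitude), size=len(clean))
    signals = tuple(float(s + e) for s, e in zip(clean, noise))
    return DoseResponseSeries(
        ligand_concentrations=tuple(conc),
        signals=signals,
        protein_concentration=protein,
        metal=metal,
        buffer="synthetic",
    )
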