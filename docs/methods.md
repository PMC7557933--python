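# Methods

## Scope and units

The unit of analysis is the mature defensin domain (signal peptide
removed). The four expressed study peptides (AtD90, AtD212, CrD26,
SlD26) are stored with the extra N-terminal alanine left by signal
cleavage in the *Pichia pastoris* expression system, and **all residue
numbering is 1-based counting that alanine** — this is what makes
"Cys15" of SlD26 land on sequence position 15.

## Scaffold and connectivity

A sequence is scaffold-valid iff it contains exactly eight cysteines.
Sequences with any other count are flagged (`ScaffoldError`) rather than
force-fit: forcing a 7- or 9-cysteine sequence onto the 8-cysteine frame
would silently corrupt loop statistics, and batch callers can route the
flagged sequences to a non-canonical bin (the CLI pipeline does).

Loop *i* (1–7) is the segment strictly between the i-th and (i+1)-th
cysteine; the N- and C-terminal tails are tracked separately and are
never counted in loops. The seven loop lengths form the gap vector.

Connectivity patterns are defined on cysteine *ranks* and mapped to
residue positions:

- standard: C1–C8, C2–C5, C3–C6, C4–C7
- shifted:  C1–C5, C2–C6, C3–C7, C4–C8

`classify_connectivity_pattern` predicts a pattern from cysteine spacing
alone: the query's gap vector is compared to labeled templates (defaults:
SlD26's vector → standard, AtD90's vector → shifted) under L1 distance,
and ties across labels return `unassigned`. No published rule states
*which* spacing feature discriminates the patterns; L1 on gap vectors is
the simplest auditable choice, and the output should be read as a
prediction, not a determination. Classification is by construction
invariant to loop residue content.

One numbering caveat: loop indices here are consecutive inter-cysteine
segments of the query itself. Alignment-based loop numbering transferred
from a reference defensin (e.g. NaD1) can map His-rich Brassicaceae
segments to a different loop index than the consecutive scheme does; when
that matters, report both indexings rather than forcing agreement.

## Physicochemical conventions

- **Mass.** Isotope-averaged ExPASy-style residue masses (pinned as a
  table in `physchem.py`) plus one water, 18.01524 Da. Each disulfide
  removes two hydrogens (2.01588 Da); canonical scaffolds use four
  disulfides. Masses are reported at 1 decimal and compared at ±0.1 Da.
  This convention reproduces the published masses of SlD26, AtD90 and
  CrD26 to within 0.1 Da. The published AtD212 mass (6548.0 Da) is *not*
  reproducible from its published sequence under any standard convention
  (computed oxidized 6554.0, reduced 6562.0); the reduced mass sits
  exactly one CH₂ (14.03 Da) above the published value, consistent with a
  single-residue discrepancy (e.g. E↔D or T↔S) in whatever sequence the
  published figure was computed from. We keep the documented convention
  rather than tuning to the outlier.
- **Charge and pI.** Henderson–Hasselbalch sums over the N-terminus, K,
  R, H (basic) and C-terminus, D, E, C, Y (acidic). Default pKa set is
  Bjellqvist/ExPASy-style (N-term 7.5, C-term 3.55, K 10.0, R 12.0,
  H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0); an EMBOSS-style set is included
  so the convention is an explicit, swappable parameter rather than an
  implicit default. Cysteines remain titratable in the oxidized molecule
  because that is the convention of the tools that produced the published
  pI values, which this set reproduces to ±0.1 for all four peptides. The
  charge curve is strictly decreasing in pH, so the pI is the unique root,
  found by bisection to |charge| < 1e-4 and reported at 1 decimal.
- **HRD cutoff.** ≥6 His in the mature domain, deliberately exposed as a
  parameter (`cutoff=6`) since the threshold is semi-arbitrary.
- **Hydrophobicity.** Kyte–Doolittle GRAVY (mean per-residue hydropathy).
  No particular scale is canonical for defensins and only sign-level
  claims are made downstream, so the community default is used.

## Sequence space

- **Anchored alignment.** Per segment (N-tail, loops 1–7, C-tail),
  sequences are right-padded with `-` to the segment-wise maximum length;
  the eight anchor columns are pure cysteine. This is a deterministic,
  reproducible stand-in for a Clustal-style alignment constrained to
  anchored cysteines; it performs no substitution-matrix optimization
  within loops (an extension point, not a claim that loops are unaligned
  in reality).
- **Identity for redundancy reduction.** Matching columns divided by
  columns where at least one of the two rows is non-gap (double-gap
  columns excluded). The filter is a greedy scan in input order dropping
  anything ≥ threshold (default 0.99) identical to a retained sequence.
  Identity is computed on mature domains.
- **Numericization.** Atchley's five standardized physicochemical factors
  per residue, zeros for gaps, giving an n × 5L matrix. The encoding is
  deliberately confined to one function: any fixed physicochemical
  encoding slots in without touching the rest of the pipeline.
- **Projection.** Classical (Torgerson) MDS: double-center the squared
  Euclidean distance matrix, eigendecompose, scale the top-d eigenvectors
  by √eigenvalue. Chosen over stress-majorization (SMACOF) because it is
  deterministic with no random initialization. Axis signs are fixed by
  making the largest-magnitude coordinate on each axis positive. If fewer
  than d eigenvalues are positive the dimensionality is reduced with a
  warning. The relative residual between recovered and input distances is
  reported as `stress`.
- **Clustering.** Cluster membership in a 2-D sequence space is a visual
  judgement in the source material; the package reports coordinates plus
  an *optional* k-medoids (PAM) labeling with configurable k and seed,
  rather than claiming to reproduce anyone's cluster boundaries.
  k-medoids is implemented in-package (a small deterministic PAM) because
  no installed library provides it.

## Binding model

Exact 1:1 mass action with protein depletion:
`f = ((P+L+Kd) − √((P+L+Kd)² − 4PL)) / 2P`. The hyperbolic approximation
`L/(Kd+L)` is wrong at these scales — protein at 20–40 µM is not
negligible against Kd values of ~44 µM. The dilution designer produces
the assay's design: a fifteen-step two-fold series from a 20 mM top,
halved again by 1:1 mixing with protein, plus a no-ligand control (16
points).

The fit is least squares over (log Kd, s_unbound, s_bound); log
parameterization enforces Kd > 0, and the optimizer starts at the
geometric mean of the nonzero concentrations. The Kd standard error is
`Kd · SE(log Kd)` from the Jacobian at the optimum. "No binding" is
declared when the fitted amplitude ≤ 3 × residual SD (threshold
configurable) plus a tiny signal-scaled floor that makes the rule well
defined for exactly flat noiseless series; the floor scales with the
signals, so the classification, like Kd, is invariant to rescaling all
signals. The signal model is the generic amplitude × fraction-bound form;
instrument-specific signal physics (thermophoresis + T-jump) is not
modeled.

## Synthetic data

The generator emulates the statistical structure of a curated defensin
database — which is not deposited — not its actual sequences:

- Loop-length ranges default to intervals bracketing canonical defensin
  spacing (the study peptides' gap vectors fall inside them); tails are
  short. Background residue frequencies are uniform over the 19 non-Cys
  letters (no composition table exists to calibrate against; a
  defensin-like composition can be supplied).
- His enrichment in loop j: each residue of that loop is H with
  probability `b + (1−b)·p_bg(H)` for boost b.
- Clusters are template mutants (default 5 random non-Cys substitutions
  per member); a cluster may be tied to a connectivity class, in which
  case its template's loop lengths are drawn within ±1 of the
  corresponding study gap vector.
- Near-duplicates copy a parent with at most ⌊L/100⌋ substitutions, which
  for typical defensin lengths (<100) means exact copies — guaranteeing
  the planted ≥99% identity.
- Ground truth records *realized* values (actual His counts after
  sampling), so classification tests are exact rather than probabilistic.

What passing on synthetic data does **not** show: real defensin loops are
not compositionally uniform, real clusters are not single-template mutant
clouds, and real redundancy is phylogenetic rather than planted. The
synthetic checks validate the algorithms' contracts (identity filtering,
embedding faithfulness, profile detection, parameter recovery), not any
biological claim about the undeposited database.

## Problem sizes and numerical choices

Test and validation runs use desk-scale collections (30–100 synthetic
sequences, 20–100 replicate seeds, 50-point neighbour spaces) — large
enough to exercise every code path and the statistical assertions, small
enough to run in seconds. MDS faithfulness is asserted at 1e-6 on exactly
embeddable point sets; bisection terminates at |charge| < 1e-4;
nearest-neighbour and redundancy ties break by input order;
k-medoids is deterministic given its seed.

## Known limitations

- The anchored alignment does not optimize within-loop alignment; very
  different loop sequences of equal length are treated as column-wise
  comparable.
- The connectivity classifier is a spacing heuristic validated on two
  templates; it reports its distance so callers can treat large-distance
  assignments with suspicion.
- The binding model assumes a single site and no cooperative or
  precipitation behaviour (metal-induced precipitation is exactly the
  regime where such a fit is meaningless, which is why precipitating
  peptides are assayed differently).
- Published experimental Kd values come from instrument data that is not
  deposited; the binding module is validated by parameter recovery on
  simulated series, not by reproducing those values.
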