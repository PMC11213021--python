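# Methods

## Alignment processing

Input alignments (Stockholm 1.0 or FASTA) are normalised to upper case with
`.` gaps mapped to `-` and ambiguity codes (B, Z, J, O, U) mapped to a 21st
"unknown" state `X`. Processing restricts columns to the non-gap positions of
a chosen reference sequence (so every retained column carries a residue
number), then removes columns with gap fraction above `max_col_gap_fraction`
(default 0.4), sequences with gap fraction above `max_seq_gap_fraction`
(default 0.2), and sequences whose fractional identity to the reference falls
below `min_ref_identity` (default 0.2). The defaults follow common coupling-
analysis practice for homologous protein families; all three are exposed in
the configuration. Identity between aligned rows is matches divided by the
columns where at least one row is non-gap (switchable to all mapped columns);
`X` never matches anything. For gap-fraction purposes `X` counts as gap, and
for frequency counting it is pooled with the gap state — inventing
frequencies for ambiguity codes would add noise with no information.

The synthetic alignments are processed with permissive thresholds
(1.0 / 1.0 / 0.0): the generator plants covariation on an iid background with
no gaps, so column/gap filtering is structurally a no-op, and the reference-
identity filter is meaningless for sequences that share no homology-level
identity by construction.

## Statistical coupling analysis

Sequence weights are `w_s = 1/|{t: identity(s,t) ≥ c}|` with identity the
fraction of identical columns and cutoff `c = 0.8`; `M_eff = Σ w_s`.
Weighted frequencies use a uniform pseudocount `λ = 0.03` over 21 states:
`f1 = (1−λ) f_emp + λ/21`, `f2 = (1−λ) f2_emp + λ/21²`, which keeps the pair
marginals exactly consistent with the singles. Conservation is the binary
relative entropy `D_i^a = f ln(f/q) + (1−f) ln((1−f)/(1−q))` against a
background `q`; its derivative `φ_i^a = ln[f(1−q)/(q(1−f))]` weights the
covariance. Two backgrounds ship as constants: a large-database amino-acid
frequency table (the real-data default) and the uniform background used by
the tests and synthetic studies so that no result depends on the constant
table. Frequencies are clipped into `[1e-12, 1−1e-12]` before the logarithms
so `λ = 0` inputs stay finite.

The coupling matrix is
`C̃_ij = sqrt(Σ_{a,b≤20} [φ_i^a φ_j^b (f2_ij^ab − f1_i^a f1_j^b)]²)`; the gap
state is counted in the frequencies but excluded from the norm, matching the
convention that gap–gap covariation is not scored as coevolution.

Eigenmode significance is decided against a randomisation null: each trial
independently permutes every column across sequences (preserving column
compositions and the fixed sequence weights), rebuilds the full coupling
matrix, and records its top eigenvalue; `k*` counts true eigenvalues above
the maximum over 10 trials. `k* = 0` is an explicit "no significant modes"
result. This max-over-trials rule is conservative by design — with 10 trials
it approximates a 9% family-wise criterion on the top of the null spectrum.

## ICA rotation and membership

The top-`k*` eigenvectors are rotated by a fixed-point ICA with the cube
contrast and **symmetric decorrelation**, initialised at the eigenvector
basis so the procedure is deterministic (tolerance 1e-10 on the rotation
update, max 10⁴ iterations; the seed only feeds a jitter restart taken if an
update degenerates). Symmetric decorrelation was chosen over one-by-one
deflation deliberately: with deflation only the first extracted component is
an unconstrained fixed point, so re-running the rotation on its own output
drifts by the constrained-gradient residual (~1e-4 observed), whereas the
symmetric update makes the converged rotation a genuine fixed point and the
operation idempotent to numerical precision. Output components are unit-norm,
sign-fixed so the largest-magnitude loading is positive, and ordered by
decreasing kurtosis of their loadings.

Per IC, a Student-t location-scale distribution is fitted to the loadings and
positions with fitted CDF ≥ 0.95 become candidates; a position passing for
several ICs is assigned to the one where its loading rank is best (ties break
on CDF, then IC order), so memberships are disjoint — a requirement of the
downstream category definitions. A degenerate fit falls back to the empirical
quantile with a warning; all-identical loadings yield no members. Note that
when the number of genuine outliers equals the nominal tail mass the 95%
boundary is data-driven and a background position can straddle it; the tests
therefore assert complete recovery of planted outliers with at most a couple
of boundary extras rather than knife-edge exactness.

## Trajectory dynamics

Trajectories come from multi-model PDB files or a TSV frame table (columns
frame, residue_number, residue_name, atom_name, x, y, z), with an atom-name
selection filter. Superposition is the Kabsch least-squares fit (proper
rotations only, reflections rejected, ≥3 non-collinear points); the default
reference is the mean structure with one refinement pass (fit to the first
frame, recompute the mean, refit all frames). No mass weighting anywhere.

The DCC matrix uses one representative atom per residue — CA by default,
switchable to the residue centre of geometry — and all frames unless an
inclusive 0-based frame range is given. A residue with zero positional
variance is an error naming the residue.

One numerical caveat documented because it shapes the studies below:
per-frame least-squares fitting absorbs whatever projection the *genuine*
correlated fluctuations have onto the rigid-body modes. On the synthetic
block trajectory this is large — a ρ = 0.8 block of 10 residues in a
50-residue chain drops to an apparent within-block correlation of ≈ 0.49
after re-fitting an already-aligned trajectory, because the block's common
displacement looks partly like a global translation/rotation of the extended
chain. The generator emits coordinates in a fixed laboratory frame, so the
recovery studies compute DCC directly on the clean trajectory; superposition
is applied to remove *injected* rigid-body noise, and superposed runs are
compared like-for-like (noisy-superposed against clean-superposed), where the
two agree to < 0.02. Real trajectories must of course be superposed, and the
same absorption affects real DCC analyses equally across the conditions being
contrasted.

Dihedrals follow the IUPAC sign convention (verified against an independent
geometry library), reported in degrees on (−180, 180]; ψ and χ1(Ser) are
available by name, any four (residue, atom) pairs explicitly.

## Pair categories and enrichment statistics

Residue pairs within two sequence positions of each other are excluded
(separation ≤ 2 dropped, ≥ 3 kept — consecutive and next-nearest neighbours
trivially co-move). Separation is computed on reference residue numbering
*after* insertion renumbering, which shifts residues at positions ≥ the
insertion site by the offset (site 23, offset +1: residue 23 → 24). Each
retained pair's |DCC| lands in: `IC_k` when both residues belong to IC k
(and also `any IC`); `any IC` + `not in same IC` when the residues belong to
two different ICs; `not in same IC` when at most one residue has an IC, plus
`no IC` when neither does.

Mann–Whitney U uses `U = #(a_i > b_j) + ½#(a_i = b_j)`; the p-value is exact
by enumeration for tie-free samples with `n·m ≤ 64` and otherwise the normal
approximation with midrank tie correction and continuity correction. |DCC|
values are continuous so ties are measure-zero, but file rounding can create
them, hence the midrank path. When U equals its null mean the two-sided p is
reported as exactly 1 (the tie-corrected variance can degenerate there). The
within-condition battery contrasts each `IC_k` against `not in same IC` and
against `no IC`, plus `any IC` against `no IC`; the between-condition battery
contrasts every category across conditions. Reports carry two-sided and
one-sided p (direction of the mean difference), sample sizes, category means,
the star convention (\*p≤0.05 … \*\*\*\*p≤0.0001) and — purely informational,
since the raw p-values are the primary output — a Holm-adjusted column.

## Synthetic data

The alignment generator draws, per sequence, a uniform latent state; the
planted sector positions carry that state's preferred residue with
probability 1−ε (ε = 0.05) and a background draw otherwise; all other
positions are iid background (uniform over 20 amino acids by default). A
redundancy fraction (0.2) of sequences is then replaced by copies of earlier
sequences mutated per-position at rate 0.02 — a star-tree cartoon of database
redundancy, chosen so duplicates stay above the 0.8 weighting cutoff. The
defaults (M = 500, L = 50, sector {7,12,19,24,33,41}, 2 states) are the study
conditions used everywhere; state profiles are drawn once per run, distinct
across states at every sector position.

The trajectory generator draws per-frame, per-axis residue displacements from
a multivariate normal whose correlation is ρ inside the planted block and 0
elsewhere (unit diagonal; the equicorrelation block requires
ρ > −1/(|block|−1), enforced with the bound in the error message), scaled by
σ = 1 Å around an extended chain with 3.8 Å CA spacing. Frames are iid by
default — DCC depends only on the spatial covariance, so temporal correlation
would slow the suite without testing anything extra; an AR(1) knob exists for
realism and defaults off. Optional rigid-body noise applies a uniformly
random rotation and a 3 Å-scale translation per frame. Defaults: N = 50
residues, F = 2000 frames, ρ = 0.8. All randomness flows from a single seed
through one named generator.

What the generator does **not** emulate: phylogenetic tree structure beyond
star-tree duplicates, gaps and indels, position-specific conservation outside
the sector, anharmonic or time-correlated dynamics, side chains and solvent.
Passing tests therefore demonstrate the statistical machinery — weighting,
coupling, mode selection, rotation, tail assignment, correlation, ranking
statistics — not force-field realism or robustness to alignment pathologies.

## Study design choices

- **Knockdown condition:** the same planted network resimulated at ρ = 0.1,
  with the same trajectory seed as the baseline, mirroring a dynamics-
  knockout mutant; selectivity means the IC category shifts while `no IC`
  does not.
- **Null calibration:** type-I error of the `any IC` vs `no IC` contrast is
  measured on trajectories with *no* correlation structure while the category
  labels come from the planted-sector record. Running the full SCA chain on
  structureless alignments would mostly return `k* = 0` and make the
  calibration vacuous; fixing the labels isolates the false-positive rate of
  the enrichment statistic itself. Observed ≈ 2–5% at the nominal 5% level
  over 100 runs.
- **Problem sizes:** 10 alignments for recovery and enrichment, 100 runs for
  calibration, 2000-frame trajectories — sizes at which the Monte-Carlo error
  of a ρ = 0.8 block mean is ≈ 0.01 and the whole battery completes in a few
  minutes on one CPU.

## Known limitations

- The eigenmode-significance rule (max over 10 randomised trials) is one of
  several defensible choices; denser nulls or percentile rules would shift
  `k*` on marginal data.
- Whether the Frobenius sum should include gap terms is a genuine convention
  split in the field; this package excludes them.
- t location-scale membership is knife-edge when outlier mass equals the
  nominal tail mass (see above).
- Per-frame superposition absorbs rigid-mode projections of genuine
  correlated motion (see above); contrasts between conditions remain valid
  because the absorption applies to both sides.
- No multiple-testing correction is applied to the primary p-values (raw
  values are reported, with Holm as an extra column), and no effect-size
  estimators beyond category means are computed.
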