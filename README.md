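# sectordyn

Coevolving residue sectors and correlated protein motions.

Protein families accumulate correlated substitutions: groups of positions
("sectors") that evolve together because they jointly support folding,
catalysis or allostery. Statistical coupling analysis (SCA) extracts these
groups from a multiple sequence alignment; molecular-dynamics analysis
extracts correlated *motions* from a trajectory. `sectordyn` implements both
ends and, crucially, the statistic that connects them: whether residue pairs
inside a coevolving group move together more than the rest of the protein,
and whether a mutation selectively knocks that coupling down. The motivating
system is dihydrofolate reductase (DHFR), where an active-site-loop double
mutation is known to rigidify millisecond dynamics, but the machinery is
generic: any alignment plus any trajectory pair.

## The method

Given an alignment of M sequences and L positions (processed so every column
maps to a reference residue number):

1. **Sequence weights.** `w_s = 1 / |{t : identity(s,t) ≥ 0.8}|`, giving
   `M_eff = Σ w_s` effective sequences.
2. **Frequencies.** Weighted single- and pair-column frequencies `f_i^a`,
   `f_ij^ab` over 21 states (20 amino acids + gap) with a uniform pseudocount
   λ = 0.03.
3. **Conservation weights.** `φ_i^a = ln[f_i^a(1−q_a) / (q_a(1−f_i^a))]`, the
   derivative of the binary relative entropy `D_i^a` of `f_i^a` against a
   background distribution `q`.
4. **Coupling matrix.**
   `C̃_ij = ‖ φ_i^a φ_j^b (f_ij^ab − f_i^a f_j^b) ‖_F` with the Frobenius
   norm over the 20×20 amino-acid pairs (gap excluded).
5. **Significant eigenmodes.** `k*` = number of eigenvalues of `C̃` above the
   maximum eigenvalue observed over column-shuffled null alignments
   (10 trials, weights preserved).
6. **Independent components.** The top-`k*` eigenvectors are rotated by a
   symmetric fixed-point ICA (cube contrast) toward maximally non-Gaussian
   loading patterns; each position is assigned to the IC whose t
   location-scale fit places its loading in the upper p = 0.95 tail.
7. **Dynamics.** For a (superposed) trajectory, the dynamic cross-correlation
   `C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)` over one CA per residue.
8. **Enrichment.** Every residue pair more than two sequence positions apart
   is labelled `IC_k` (both members of IC k), `no IC` (neither in any IC),
   `any IC` (both in ICs), or `not in same IC`; the |C_ij| distributions are
   contrasted with two-sided and one-sided Mann–Whitney U tests, within a
   condition and between conditions (wild type vs mutant), with insertion
   renumbering support for insertion mutants.

A synthetic-data module generates alignments with a planted coevolving sector
and trajectories with a planted correlated-motion network (the same residues),
so the entire chain is testable with exact ground truth and no downloads.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic data
(about a minute in total):

```bash
python analysis/01_simulate_datasets.py
python analysis/02_identify_sectors.py
python analysis/03_trajectory_correlations.py
python analysis/04_enrichment_contrasts.py
python analysis/05_motif_census.py
```

`02_identify_sectors.py` reports the alignment statistics and the recovered
coevolving group:

```
processed: 500 x 50, effective sequences m_eff = 400.0
significant eigenmodes: k* = 1
IC1 members: [7, 12, 19, 24, 33, 41]
planted sector [7, 12, 19, 24, 33, 41]: precision 1.00, recall 1.00
```

`m_eff = 400` reflects the 20% planted near-duplicate redundancy (100 of 500
sequences collapse onto their sources); the single significant eigenmode is
the planted 6-position sector, recovered exactly.

`04_enrichment_contrasts.py` prints the enrichment battery. In the baseline
condition the IC's pairwise |DCC| values (mean 0.80 over 15 pairs) dwarf the
no-IC background (mean 0.010 over 873 pairs):

```
             contrast  n    m   mean_a   mean_b  p_two_sided stars
IC1 vs not_in_same_ic 15 1113 0.800301 0.010496 2.736384e-11  ****
         IC1 vs no_ic 15  873 0.800301 0.010291 2.990135e-11  ****
```

and the between-condition battery shows the knockdown (network correlation
0.8 → 0.1) is selective — the IC category collapses while the background is
untouched:

```
                             contrast   mean_a   mean_b  p_two_sided stars
           IC1: baseline vs knockdown 0.800301 0.100407     0.000003  ****
         no_ic: baseline vs knockdown 0.010291 0.010346     0.851196    ns
```

The same pipeline runs from a shell on real inputs via the `sectordyn` CLI
(`process-msa`, `sca`, `dcc`, `compare`, `motif`, `simulate-*`, `run` with a
YAML config), e.g. a PFAM Stockholm alignment plus multi-model PDB
trajectories for a wild-type/mutant pair, with per-condition insertion
renumbering.

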