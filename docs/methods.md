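# Methods

## Problem and scope

`ankplex` re-scores rigid-body docking poses of ankyrin repeat proteins
(DARPins) bound to target proteins. It does not generate poses and does not
minimize them: pose generation and CHARMm-style refinement belong to the
docking suite upstream. The package takes coordinate sets (docked, and
optionally the first and second minimized structures of the same pose),
computes 11 pairwise energy features, labels poses against an X-ray
reference, trains an ensemble re-ranker, and evaluates it with the #PP
statistic (number of complexes with ≥ 1 near-native pose in the top 10).

## Energy model

All features are sums over receptor–ligand atom pairs; intra-chain pairs
never contribute, and every pair term is symmetric in the two atoms.

- **Lennard-Jones (E, F, H)**: ε[(σ/r)¹² − 2(σ/r)⁶], σ being the pair
  minimum, summed over pairs strictly closer than 5.0 Å (the cutoff is
  exclusive: a pair at exactly 5.0 Å does not count).
- **Coulomb (B, G, I)**: 332·qᵢqⱼ/r² (kcal·Å/(mol·e²)). The long-range term
  B has no distance cutoff and is restricted to pairs whose atoms both sit
  on Arg/Lys/Asp/Glu/His side chains. The minimized-pose terms G and I use
  every charged atom within 12 Å. The source method distinguishes a
  "long-range, fully-charged side chain" electrostostatic term from the
  refined-pose electrostatics without stating cutoffs; both choices here are
  explicit configuration (`ScoringParams.elec_min_cutoff`).
- **ACE desolvation (C, J)**: Σ aᵢⱼ over heavy-atom contact pairs within
  6.0 Å. No ACE contact distance is fixed by the method description; 6 Å is
  the standard atomic-contact definition and is configurable
  (`ScoringParams.ace_cutoff`).
- **Composite docking score (A)**: α·PSC + DE + β·ELEC with α = 0.01,
  β = 0.06. Grid-based pairwise shape complementarity (PSC) is a property of
  the docking program's FFT search and is not recomputed; feature A takes
  the program's PSC when supplied, otherwise a documented proxy — the
  cross-complex heavy-atom contact count within 5 Å — stands in. The proxy
  approximates interface contact density and is never claimed equal to the
  grid score.
- **Derived features**: D = B + C + E and K = J + 0.9·I hold to 1e-6
  whenever all components are computed by this engine.

When minimized coordinate sets are absent, F–K are computed on the docked
coordinates and a warning is logged, so single-structure workflows still
produce complete feature vectors.

### Parameter tables

The shipped vdW/charge/ACE tables are a *reduced demonstration set*:
element-class Lennard-Jones parameters (Lorentz–Berthelot combined),
(residue, atom) partial charges for backbone and polar/charged side-chain
atoms, and a 5-class ACE matrix (aliphatic/hydrophobic carbon, polar-residue
carbon, N, O, S) with hydrophobic–hydrophobic contacts favourable. They have
force-field-like magnitudes and give a consistent, symmetric, additive
energy model, which is all the learning pipeline requires; they are not a
published force field. Users reproduce a specific force field by passing
their own TSV tables (`load_params_from_tables`).

## Labelling

- **Cα-RMSD** uses Kabsch superposition (SVD, proper rotation enforced) of
  the pose onto the reference over the receptor Cα trace, then RMSD over the
  ligand Cα atoms — the ligand-RMSD convention of docking assessment. An
  all-Cα mode (`measure="all"`) is available because the source description
  does not fix the convention. Residue correspondence is by (chain, author
  residue number); numbering is never rewritten.
- **Near-native threshold**: Cα-RMSD ≤ 10 Å, inclusive.
- **Recognition-area filter (regKp)**: a pose passes when at least
  `min_contact_residues` (default 1) of the user-supplied recognition
  residues on the ankyrin second domain have any atom within 5 Å
  (inclusive) of any ligand atom. The residue identities are configuration,
  not constants: they are defined per complex by the scaffold's variable
  positions.

## Learning pipeline

- **Balancing**: negatives are shuffled with a seeded generator and split
  into nearly equal disjoint blocks (sizes differ by at most one);
  `n_groups` defaults to ⌊n_neg/n_pos⌋ and is overridable (the benchmark's
  own grouping used 65 where the ratio gives 66; both are expressible).
- **Feature subsets**: all 2ⁿ − 1 non-empty subsets in (size, lexicographic)
  order — 2,047 for the 11 features. (The benchmark description prints
  4,095 for this count; that equals 2¹² − 1 and is not reachable from 11
  features, so the package enumerates the mathematically correct set.)
- **Decision tree**: scikit-learn's CART inducer (entropy splits, minimum
  leaf size 2) stands behind the C4.5-style contract. Pruning is
  reduced-error-style: a stratified held-out fold (1/`rep_folds`, default
  1/3) selects the cost-complexity pruning strength minimizing held-out
  error, ties resolved toward the simpler tree. The confidence factor
  (0.25) is carried in the config but does not drive pruning when the
  held-out fold is in use — the same behaviour as J48 with reduced-error
  pruning enabled. Trees are stored as flattened arrays
  (children/feature/threshold/leaf class), making predictions
  library-independent and models JSON-serializable.
- **Ridge logistic**: L2-penalized maximum likelihood (scikit-learn lbfgs),
  ridge 10⁻⁸ — a nominal penalty that guarantees a finite optimum under
  complete separation — iterated to convergence with a 10,000-iteration hard
  cap treated as failure. Features enter raw (no standardization), matching
  the defaults of the toolkit the benchmark used. The logistic score (LGS)
  is the linear predictor; it is a strictly monotone transform of the
  predicted probability, so rankings are identical.
- **Model retention**: true-positive rate TP/(TP+FN) ≥ 50 % (inclusive) on
  all training-complex rows. Near-native is the positive class everywhere.
- **Re-scoring**: DT-positive filter → LGS descending, ties broken by pose
  id ascending (for determinism; the method description is silent on ties)
  → top 10. Zero DT-positives yield an empty ranking and Y = 0.
- **Ensemble search**: pairs are enumerated exhaustively when feasible
  (default cap 10⁶), otherwise a seeded uniform sample without replacement.
  The objective is lexicographic — #PP on training complexes, then #PP on
  test complexes, then lower mean first-true-positive rank — because the
  benchmark states only that its winning pair attained the maxima, and a
  total order is needed for reproducible search.

## Synthetic data generator

The generator emulates the statistical structure of the benchmark's feature
tables: class-conditional Gaussians whose default means/SDs are the
published per-class summaries (e.g. ZRank −54.03 ± 25.84 near-native vs
−21.82 ± 31.33 non-near-native), with D and K recomputed exactly from their
components and all other features independent. Only marginals are published,
so independence is the default; a correlation matrix over the nine drawn
features can be injected for stress tests. Rows are assigned round-robin to
pseudo-complexes, separately per class, so every complex holds both classes.

What passing tests on this generator show: the pipeline's machinery —
balancing, training, selection, search, ranking, #PP — behaves correctly
and recovers a strong ensemble when the class-conditional structure matches
the published summaries. What they do not show: performance on real docking
decoys, whose features are correlated, non-Gaussian, multimodal across
binding modes, and complex-dependent. The toy structure generator likewise
produces idealized extended chains (known ligand-RMSD by construction), not
physical protein geometry.

## Problem sizes and defaults

The default pipeline conditions are 669 near-native and 10,000
non-near-native poses spread over 7 pseudo-training + 2 pseudo-test
complexes — the benchmark's positive count and class layout with the
negative pool scaled to roughly 1:15. The default subset sweep is the
demonstration-scale set (all 1- and 2-feature subsets plus the benchmark's
two named ensemble subsets ABEHIJ and CDFGHJ, 68 subsets), with the full
2,047-subset sweep available via `subset_sweep="full"`; the default pair
budget is 2,000 seeded samples. These sizes keep a full run under a minute
while exercising every stage; all are configuration, not constants.

## Numerical choices and degenerate inputs

- Kabsch superposition requires ≥ 3 non-collinear points; collinear or
  mismatched inputs raise.
- Precision with no positive predictions is reported missing (NaN), never
  0, and fold means average over defined folds only.
- Pearson correlations of zero-variance contributions are missing (NaN).
- The vdW cutoff boundary is exclusive (< 5.0 Å); the regKp and ACE contact
  boundaries are inclusive (≤).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global RNG state is used. Reruns with
  the same config produce byte-identical artifacts, and every output file
  carries the config hash and seed.

## Known limitations

- The shipped parameter tables are demonstration values; absolute energies
  are not comparable to any published force field, only internally
  consistent.
- PSC is proxied by a contact count when the docking program's value is not
  supplied.
- Energy minimization is not performed; "minimized" features require the
  caller to supply refined coordinate sets.
- The learners are not bit-compatible with WEKA's J48/SimpleLogistic; they
  satisfy the same contract (parameters, class orientation, determinism,
  ranking behaviour) but can differ on individual splits or weights.
- mmCIF, multi-model NMR input (beyond the first MODEL) and symmetry
  expansion are unsupported.
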