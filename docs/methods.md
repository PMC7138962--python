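# Methods

## The model

The genetic code maps 64 codons to 20 amino acids and 3 stops. At the second
codon position the code is a polarity code: 2nd-base U specifies the nonpolar
amino acids (F, L, I, M, V), 2nd-base A the polar ones (Y, H, Q, N, K, D, E)
and 2nd-base C/G the neutral ones (S, P, T, A, C, W, R, G). The Davis score
renders this as +1 / −1 / 0 per amino acid; the score is well defined because
every amino acid's codons agree on the class (asserted at import time).

A sense codon read on one strand has an antisense codon on the other. Two
reading conventions exist and both are supported: *parallel* (3′→5′), the
base-wise complement in the same order, and *antiparallel* (5′→3′), the
reverse complement. Either way the 2nd position pairs Watson–Crick, so the
pair group is forced: polar sense ↔ nonpolar antisense and neutral ↔ neutral.
This "2nd-base theorem" is checked exhaustively over all 64 codons in the
test suite. Pairs in which either strand encodes a stop are excluded from all
statistics — no property value exists for a stop (9 of 64 sense codons drop
out in the parallel direction, 6 in the antiparallel).

Hydrophobicity is measured by log₁₀ K_w>c, the log₁₀ equilibrium constant for
transferring an amino-acid side chain from neutral aqueous solution to
cyclohexane; larger means more hydrophobic. Scales are tabulated at 25 °C and
100 °C (see *Data provenance*).

## Pair correlation statistic

For each complementary pair one member is the *ligand* — the one whose own
codon carries a purine (A/G), or under the mirrored rule a pyrimidine (U/C),
at the 2nd position — and the partner is the *receptor*. Each pair yields a
point x = ligand hydrophobicity, y = |ligand − receptor|, and Pearson r is
computed per pair group × reading direction × ligand rule × temperature,
with the two-sided p from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.

Two conventions were genuinely open and are fixed as follows:

- **Sign / axis orientation.** The x axis is the free-energy orientation
  (x = −log₁₀ K_w>c, up to the positive factor 2.303·RT that Pearson r
  ignores). On the raw log K axis all purine-rule correlations are negative
  with the same magnitudes; the free-energy orientation makes them positive.
  `build_pair_points(..., as_free_energy=False)` gives the raw axis.
- **Point multiplicity.** Points can be built per codon pair or per unique
  amino-acid pair (`dedup`). The correlation table defaults to per-codon
  construction, which matched reference statistics most closely during
  development; both modes are exposed and differ only in multiplicities,
  never in group membership.

A pooled correlation across both groups is also provided. Because the pooled
figure statistic is not unambiguously defined, three candidates are
implemented (`pooled_pair_correlation`): pooled Pearson of the (x, y) points
(default — methodologically continuous with the per-group table), the
cophenetic correlation of a UPGMA tree on (ligand, receptor) value pairs, and
the plain ligand-vs-receptor Pearson r. None is promoted as "the" published
pooled value; the default choice is documented here rather than inferred from
a match.

## Amino-acid clustering

Each amino acid is a point in two dimensions: (log₁₀ K_w>c at the chosen
temperature, Davis score). Both variables are standardized by subtracting the
mean and dividing by the **mean absolute deviation** (the Kaufman–Rousseeuw
convention of the classic S-language clustering suites; z-scoring is available
but not the default since the mean-deviation convention is the one those
suites document). Dissimilarity is Manhattan.

- **Trees** come from Lance–Williams updates on the given dissimilarities
  (scipy linkage). Ward on Manhattan input is deliberate non-Euclidean Ward —
  the update formula is applied to whatever dissimilarities are supplied.
  UPGMA heights are monotone and are asserted to be; Ward heights on
  non-Euclidean input may in principle invert and are reported as produced.
- **Agglomerative coefficient**: AC = mean over leaves of
  1 − (height of the leaf's first merge)/(final merge height). AC is 0 for
  two leaves by construction and approaches 1 for tight, well-separated
  clusters.
- **FANNY** fuzzy partitioning minimizes
  Σ_v [Σ_{ij} u²_{iv} u²_{jv} d(i,j)] / [2 Σ_j u²_{jv}] with membership
  exponent 2, by cyclic per-object updates (membership ∝ inverse of the
  objective gradient, projected to the simplex; an object at or past a
  cluster "centre", where the gradient is non-positive, is assigned crisply).
  Initialization is deterministic — the UPGMA k-cut softened to 0.7 own /
  uniform rest — so results are reproducible without an RNG. Convergence:
  relative objective change ≤ 1e-9, at most 500 sweeps; non-convergence warns
  and returns the best-so-far.
- **Silhouette**: mean over points of (b−a)/max(a,b); singleton clusters
  contribute 0 (scikit-learn's convention, matching the original definition).

With k = 3 the Ward cut and the FANNY crisp labels both recover exactly the
three 2nd-base groups at 25 °C **and** at 100 °C — the partition-level
statement of temperature independence — with AC = 0.96 at both temperatures.

## Spectral fold calling

A sequence is converted to a numeric series (positions 1..n, one scale value
per residue) and its mean-subtracted Lomb least-squares periodogram is
evaluated on a grid of oversample × ⌊n/2⌋ frequencies spanning (0, 0.5]
cycles/residue (oversample default 4). Power is normalized as the
least-squares variance reduction of a single sinusoid, P(f) = (RSS₀ −
RSS(f))/2, which at Fourier frequencies of evenly spaced data equals the
classical |FFT|²/n; a Parseval check at Fourier frequencies (odd n) holds to
1e-6 in the tests. At exactly f = 0.5 with integer positions the sine basis
vanishes and the general Lomb formula degenerates; the cosine-only closed
form is used there. The dominant peak is the global power maximum (ties break
toward lower frequency), refined by local quadratic interpolation and
reported to 2 d.p. Peak *location* is robust to grid and normalization
choices; absolute power values are normalization-dependent and are not used
for classification.

Zones: X = (0, 1/6), Y = [1/6, 1/3), Z = [1/3, 0.5], half-open at the lower
edge of Y and Z. Printed boundaries like 0.166/0.167 are treated as rounded
thirds of the 0–0.5 axis. Call: Y → alpha, Z → beta, X → indeterminate.

## Phase decision lists

The rule set is data, not learned here:

    IF mean_buried_area > 97.8 AND log₁₀ K_w>c(T) ≤ θ_T AND mean_buried_area > 113.9
    THEN phase2 ELSE phase1        θ_25 = 2.64, θ_100 = 2.60

Comparators are exactly as stated (strict > for area, ≤ for hydrophobicity).
The two area thresholds coincide with the aspartate (97.8 Å²) and glutamate
(113.9 Å²) entries of the buried-area table, which is how the rule excludes
both from Phase 2 while keeping the redundant-looking first clause: dropping
the 113.9 Å² clause changes labels, and the tests guard that. Against the
reference Phase 1/Phase 2 sets the rule scores 19/20 at either temperature;
asparagine (buried area 103.3 Å² ≤ 113.9) is the single error, predicted
phase1 but listed phase2. The 25 °C and 100 °C lists produce identical
labelings because only L, I and V exceed either hydrophobicity threshold.

## Synthetic designs (what they emulate, what they don't)

The generator emulates binary-code protein design: a deterministic
polar/nonpolar template (alpha: positions with fractional phase i/period in
the first half-cycle are nonpolar; beta: strict alternation; turns between
segments), realized by drawing residues uniformly from the 2nd-base
alphabets — nonpolar {F,L,I,M,V}, polar {Y,H,Q,N,K,D,E}, turns {G,S,P} — with
a seeded generator recorded in the FASTA headers.

Defaults: alpha = 4 segments × 14 residues, period 3.6, 3-residue turns
(65 aa); beta = 6 strands × 6 residues, 3-residue turns (51 aa). These were
chosen once as a plausible four-helix-bundle / six-strand-sheet topology; at
these defaults the alpha designs peak at 0.29 cycles/residue and the beta
designs near 0.45 — inside Y and Z respectively — at both temperatures.

What passing tests show: the spectral pipeline separates the two patterning
classes essentially perfectly (≥ 95% required, 100% observed over 100 designs
per class × 5 seeds), identically at 25 °C and 100 °C, and scrambling
residues destroys the call (negative control). What they do not show:
performance on real designed or natural proteins, whose patterning is noisier
and whose composition is not drawn uniformly from three alphabets.

## Data provenance and known limitations

- **25 °C hydrophobicity**: transcribed from the published water→cyclohexane
  distribution coefficients of side-chain analogs (log₁₀ K_w>c =
  ΔG(c→w)/1.364 at 25 °C). Proline has no measured side-chain analog; it is
  shipped as the documented estimate 1.00, mid-range of the neutral group.
  Consistency checks that this transcription passes: the clustering pipeline
  reproduces the expected partition with AC = 0.96, and the phase rule scores
  exactly 19/20 with asparagine the sole error.
- **100 °C hydrophobicity**: a **synthetic stand-in**, not a transcription:
  v₁₀₀ = v₂₅ + 0.15·max(0, 1.7 − v₂₅), rounded to 2 d.p. It encodes the
  qualitative temperature dependence of the measurements (hydrophilic side
  chains become less hydrophilic as temperature rises; hydrophobic ones are
  nearly unchanged; the single attenuation parameter 0.15 reflects a ≈2 log
  unit rise of the arginine value over 75 °C). Order statistics and cluster
  structure are preserved; second-decimal agreement with analyses of the
  measured 100 °C table is not expected, and the acceptance-level checks that
  need it (the 100 °C correlation row, the printed silhouette values) document
  their residuals rather than reproduce the numbers.
- **Mean buried area**: transcribed from the published per-residue
  mean-buried-area table for globular proteins.
- The classic designed α/β protein sequences themselves are not
  redistributable here; the spectral acceptance checks run on the labelled
  synthetic designs instead, and `hydrocode spectrum` accepts any FASTA for
  analysis of real sequences.

## Numerical choices

- Pearson p-values use the exact t distribution (two-sided).
- Correlations are undefined (raised) for n < 3 or zero variance.
- Standardization requires strictly positive spread; constant variables raise.
- Tree tie-breaks follow scipy's deterministic linkage ordering; the k-cut
  uses merge heights with merge-order tie-breaking (`fcluster` maxclust).
- FANNY: exponent 2, tolerance 1e-9, ≤ 500 sweeps, deterministic UPGMA
  initialization (no RNG anywhere in the clustering path).
- Periodogram: positions are 1-based integers, no windowing or tapering,
  oversample 4, quadratic peak refinement, 2 d.p. reporting.
- All CLI subcommands are pure functions of (inputs, options, seed) and write
  a provenance JSON (options, package version, input digests) next to their
  results.
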