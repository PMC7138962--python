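# hydrocode

Tools for studying how the genetic code organizes amino-acid hydrophobicity —
and how little temperature changes that organization.

The central observation: because the second codon position pairs Watson–Crick
between a sense codon and its complement, every sense/antisense amino-acid
pair is constrained by the code itself. Second-base U specifies the nonpolar
amino acids (F, L, I, M, V), second-base A the polar ones (Y, H, Q, N, K, D,
E), and second-base C/G the neutral ones (S, P, T, A, C, W, R, G) — so polar
residues can only pair with nonpolar partners and neutral with neutral, in
both reading directions. `hydrocode` quantifies this structure with the
side-chain hydrophobicity scale log₁₀ K_w>c (the log₁₀ equilibrium constant
for transfer of a side chain from water to cyclohexane) at 25 °C and 100 °C,
and provides the downstream analyses that use it:

- **codebook** — the standard genetic code, base complementation, antisense
  codons in both reading directions (parallel 3′→5′ = base-wise complement,
  antiparallel 5′→3′ = reverse complement), Davis 2nd-base polarity scores,
  and exhaustive enumeration of complementary amino-acid pairs.
- **scales** — a registry of property scales (log₁₀ K_w>c at 25 °C and
  100 °C, mean buried area, Davis scores), Kaufman–Rousseeuw
  mean-absolute-deviation standardization, and conversion of protein
  sequences to positional numeric series.
- **pairstats** — the pair statistic: for each complementary pair, x = the
  ligand member's hydrophobicity (free-energy orientation) and
  y = |ligand − receptor|; Pearson correlations per pair group, reading
  direction, ligand rule (purine vs pyrimidine 2nd base) and temperature.
- **clusterkit** — Ward and UPGMA trees on Manhattan dissimilarities
  (Lance–Williams updates), the Kaufman–Rousseeuw agglomerative coefficient,
  FANNY fuzzy partitioning with average silhouette widths, cophenetic
  correlations, and the two-variable amino-acid clustering pipeline.
- **spectral** — Lomb least-squares periodograms of hydrophobicity series and
  fold-class calls: a dominant peak in zone Y = [1/6, 1/3) cycles/residue is
  α-like (helical periodicity ≈ 3.6 residues), in zone Z = [1/3, 1/2]
  β-like (alternation ≈ 2 residues).
- **phaserules** — decision lists separating prebiotic Phase 1 amino acids
  (L, I, V, S, P, T, A, D, E, G) from Phase 2 (F, M, Y, H, Q, N, K, C, W, R)
  using mean buried area and log₁₀ K_w>c thresholds.
- **synthgen** — a seeded generator of binary-patterned α/β protein designs
  (polar/nonpolar templates with turns) and statistical fixtures, so the whole
  pipeline is testable without external downloads.

A note on the packaged data: the 25 °C hydrophobicity values are transcribed
from the published water→cyclohexane side-chain measurements (proline, which
has no measured analog, carries a documented estimate). The 100 °C scale is a
**synthetic stand-in** constructed from the 25 °C values by attenuating the
hydrophilic end (see `docs/methods.md`); analyses needing the measured 100 °C
table to printed precision will differ in the second decimal.

## Worked example

```python
>>> from hydrocode import enumerate_pairs, Direction, fold_call
>>> from hydrocode.clusterkit import amino_acid_clustering
>>> from hydrocode.pairstats import table1
>>> from hydrocode import synthgen

>>> pairs = enumerate_pairs(Direction.ANTIPARALLEL_5TO3)
>>> len(pairs), pairs[0].sense_aa, pairs[0].antisense_aa, pairs[0].group
(52, 'K', 'F', 'polar-nonpolar')
```

Lysine (codon AAA, 2nd base A → polar) can only meet phenylalanine (UUU,
2nd base U → nonpolar) on the complementary strand: 52 unique amino-acid
pairs exist in this direction, every one polar–nonpolar or neutral–neutral.

```python
>>> res = amino_acid_clustering(25)
>>> [''.join(sorted(g)) for g in res.groups]
['DEHKNQY', 'FILMV', 'ACGPRSTW']
>>> round(res.agglomerative_coefficient, 2), round(res.avg_silhouette_width, 2)
(0.96, 0.69)
```

Clustering the 20 amino acids on just two standardized variables —
hydrophobicity and Davis polarity score — recovers exactly the three
2nd-codon-base groups, with a high agglomerative coefficient (0.96; 1 would
be perfectly tight clusters) and a solid silhouette. The same partition comes
back at 100 °C: the code's polarity organization is temperature independent.

```python
>>> t = table1()
>>> t[(t.ligand_rule == "second_base_purine") & (t.temperature_C == 25)][
...     ["group", "direction", "r", "n"]].round(2)
          group         direction    r  n
 polar-nonpolar     parallel_3to5 0.97 28
neutral-neutral     parallel_3to5 0.91 30
 polar-nonpolar antiparallel_5to3 0.95 28
neutral-neutral antiparallel_5to3 0.94 30
```

With the purine-2nd-base member of each pair as ligand, the ligand's
hydrophobicity strongly predicts the hydrophobic contrast of the pair
(r ≥ 0.85 in every group, direction and temperature); with the pyrimidine
member as ligand the correlations collapse — the purine base carries the
information.

```python
>>> seq = synthgen.realize_sequence(
...     synthgen.make_binary_pattern(synthgen.ALPHA_DEFAULT), seed=1)
>>> call = fold_call(seq)
>>> call.call, call.zone, round(call.peak_frequency, 2)
('alpha', 'Y', 0.29)
```

A synthetic four-segment design with nonpolar period 3.6 is called α from its
hydrophobicity periodogram alone — the dominant peak sits at 0.29
cycles/residue, inside zone Y. Strictly alternating designs peak near 0.45 in
zone Z and are called β.

The same analyses are available from the shell:

```sh
hydrocode table1 --out results
hydrocode cluster --temperature 25 --out results
hydrocode simulate --n-alpha 15 --n-beta 17 --seed 1 --out results
hydrocode spectrum results/synthetic_designs.fasta --out results
hydrocode phases --out results
```

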