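# Methods

This note records the model choices, conventions and numerical decisions
behind `faahscreen`, and what the synthetic-data tests do and do not show.

## Curation

Activity values enter as molar IC50. Qualified entries (">", "<", "~",
non-numeric) carry no usable potency and are dropped before duplicate
merging. Duplicates are identified by canonical SMILES (the largest organic
fragment of the input, canonicalized by RDKit); the merged IC50 is the
arithmetic mean of the member IC50s and pIC50 = −log10 of that mean — not
the mean of the pIC50s, which would be a geometric-mean IC50.

Potency labels use strict inequalities: strong iff pIC50 > 8, weak iff
pIC50 < 5; boundary compounds stay unlabeled. Property windows
(MW 150–620 g/mol, logP −0.8–9.2, HBA 1–12, HBD 0–4) are closed intervals;
HBA/HBD are Lipinski-style counts (N+O atoms; N–H/O–H hydrogens), and logP
is the Wildman–Crippen estimate everywhere so the curation filter and the
descriptor panel cannot disagree. "Organometallic" means any atom outside
{H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}; a disconnected metal
counter-ion is not organometallic because salt stripping removes it first.
Decoys are drawn uniformly without replacement from the pre-filtered pool,
excluding structures already in the active set, at a 10:1 ratio — this fixes
the prior π = 1/11 = 0.0909… used by the enrichment score.

## Scaffold conventions

* **Murcko framework (MF)**: RDKit's Murcko scaffold — rings, linker
  atoms/bonds, and exocyclic multi-bonded atoms attached to retained atoms;
  atom types and bond orders preserved. Acyclic molecules map to a null
  framework.
* **Generic skeleton (BM)**: the MF with every atom set to carbon and every
  bond to single order, then pruned by one more framework pass. The pruning
  step exists because flattening bond orders turns a retained ring carbonyl
  oxygen into an ordinary terminal atom; without it the transformation
  would not be idempotent. Acyclic molecules count as the *null skeleton*
  and are included in null-skeleton statistics.
* **Plain rings (PR)**: one fragment per fused ring system (sharing an atom
  or bond merges rings; spiro counts as fused). All single-bonded
  substituents are erased; double-bonded heteroatoms directly attached to a
  ring atom are kept (2-pyridone retains its =O; an exocyclic =CH2 does
  not qualify). An aromatic nitrogen that loses its substituent is
  re-protonated when required for kekulization — only nitrogens that
  actually lost a single-bonded neighbour, so imidazoles keep exactly one
  N–H. Fragments that still fail sanitization are dropped with a warning.

Side-chain size SC is MW(molecule) − MW(framework as a hydrogen-completed
fragment); for acyclic molecules SC is reported as the full MW with an
`acyclic` flag and such compounds are excluded from SC summaries.
Substitution groups are SMARTS counts over the whole molecule, defined so
the groups stay disjoint: hydroxyl excludes carboxylic OH, primary amine
excludes primary amide, nitro matches both charge-separated and neutral
forms.

## Enrichment and repurposing scores

The enrichment score is P = (n_FI/(n_FI+n_DCY))/π, which is 1 at random
expectation and capped at 1/π for active-exclusive scaffolds. A literal
"ratio of the two counts divided by the prior" reading
(n_FI/n_DCY/π) would not have the stated random-expectation property and
disagrees with the reference worked value for the null skeleton (9.26
instead of ≈5); the implemented form reproduces it (5.03). Significance
uses Pearson's chi-square on the 2×2 containment table without continuity
correction at α = 0.05; scaffolds contained in every compound (or none)
are reported as p = 1. The potency score I is the mean pIC50 of the active
compounds containing the scaffold, defined only when at least one active
contains it.

RpS = mean(I-PR over contained *filter* ring systems) + I-BM(skeleton);
a missing term contributes 0. The screening threshold is strict
(RpS > 5.17), as is the probability cut (P > 0.7).

ROC machinery: AUC is the Mann–Whitney rank statistic with half-credit
ties (the test suite checks it against brute-force pairwise concordance
and against an independent reference implementation). Threshold selection
at a target sensitivity classifies positives strictly above the threshold
and enumerates candidate thresholds at midpoints between consecutive
distinct pooled scores, returning the largest feasible one; any value
inside the same inter-score gap is an equivalent class boundary, so tests
assert the boundary interval and the resulting sensitivity rather than one
arbitrary representative. Discretization cutoffs (flag rules) instead use
the ≥ convention, orientation-flipped when AUC < 0.5, maximizing
sensitivity + specificity subject to floors of 0.75 each and requiring
AUC ≥ 0.8.

## Descriptor panel

Eleven descriptors feed the classifier work. 2D: Crippen logP (RDKit);
SpMAD_D, the mean absolute deviation of the eigenvalue spectrum of the
heavy-atom topological distance matrix; SpMax5_Bhi, the 5th largest
absolute eigenvalue of a Burden matrix whose diagonal carries first
ionization energies relative to carbon and whose off-diagonals follow
Burden's convention (0.1 × bond order, 0.15 aromatic, +0.01 at terminal
atoms, 0.001 fill). Molecules with fewer than five heavy atoms return the
smallest available eigenvalue, flagged as degenerate.

3D descriptors operate on one deterministic conformer: ETKDG
distance-geometry embedding (seeded), MMFF94 minimization with UFF
fallback, Gasteiger partial charges (an iterative
electronegativity-equalization scheme) with hydrogen charges folded onto
their heavy atoms. Embedding failure falls back to planar depiction
coordinates and flags the conformer.

* **WHIM A indices** (Au/Ae/Ai/As/Av): the second elementary symmetric
  function λ1λ2+λ1λ3+λ2λ3 of the eigenvalues of the weighted covariance of
  centered heavy-atom coordinates. Weights relative to carbon: unit,
  Sanderson electronegativity, first ionization energy, electrotopological
  state (clipped at zero, since E-state indices of buried atoms can be
  slightly negative and weights must stay non-negative), and van der Waals
  volume from Bondi radii.
* **RDF85m**: g(r) = Σ_{i<j} w_i w_j exp(−β(r − r_ij)²) at r = 8.5 Å with
  β = 100 Å⁻², masses relative to carbon. The code number is read as the
  8.5 Å sampling radius under the common 0.5 Å grid convention.
* **WPSA1/WPSA2**: surface-weighted charged partial surface areas.
  Per-atom solvent-accessible surface areas come from an own deterministic
  Shrake–Rupley implementation (960 golden-spiral points, probe 1.4 Å,
  Bondi radii); PPSA1 sums the surface of positively charged atoms, PPSA2
  multiplies it by the total positive charge, and each is scaled by total
  surface / 1000. A van der Waals surface (probe 0) is available via the
  probe parameter.

The published cutoff table is applied to *these* descriptor values. The
original values were produced by other software with different conformers
and charge models, so cutoff transferability is approximate for the 3D
descriptors; the published logistic model itself is exact, and every
reference-value check in the tests targets quantities that do not depend
on conformer details.

## Classifier

Descriptor screening uses the classic pooled-variance two-sided t-test
(the equal-variance form; the choice between pooled and Welch is not
dictated by the reference and is documented here as a fixed convention).
Descriptors that are constant within both classes with equal means are
dropped as undefined; zero variance with different means yields p = 0.
The logistic refit is unregularized maximum likelihood (statsmodels);
(quasi-)separation — detected either by the optimizer or by a slope
exceeding 20 — raises an error naming the offending flag. Optional
backward elimination drops the largest-p slope until all remaining are
below 0.05, possibly down to an intercept-only model. The published
four-flag model is stored as constants and never passes through the
fitting code.

## Screening cascade

Stages run in order (property window + organometallic removal → halogen
substitution ranges → RpS → probability → docking), and a failed stage
leaves later ones unevaluated, so per-stage survivor counts are
non-increasing by construction. Output ordering is total: RpS descending,
then id. Ligand efficiency is |ΔG| per heavy atom (docking energies are
negative, reported efficiencies positive). Covalent poses can optionally be
exempted from the ΔG ≤ −6 threshold — their scores are not comparable to
non-covalent ones — but the exemption is off by default. Heavy-atom counts
always come from the structure table, never from the docking file.

## Synthetic data

The generator emulates the *statistical shape* of a curated
inhibitor/decoy study: ring scaffolds drawn with enrichment odds (actives
proportional to odds, decoys to 1/odds), decorated with 2–5 acyclic
substituents until the structure passes the property window, deduplicated
across both sets, with pIC50 drawn from N(8.5, 0.6) for enriched-scaffold
compounds and N(4.5, 0.4) otherwise, so the strong/weak thresholds capture
most of each class and the overall range spans roughly 3–10. The default
scaffold pool holds ring systems prominent among known FAAH inhibitors
(benzene, piperazine, pyridine, piperidine) plus background rings.
Substituents are deliberately acyclic so the ring landscape equals the
scaffold pool and planted enrichment can be recovered exactly. Docking
scores are Gaussian with a class shift: intercept −8.12 kcal/mol (weak
mean), slope −1.59 (strong mean −9.71), noise 1.2 kcal/mol.

What this does *not* emulate: real chemical-space diversity (a handful of
scaffolds versus thousands), assay noise structure, activity cliffs,
correlated descriptor distributions, or the content of any real compound
database. Passing tests therefore demonstrate the correctness and
statistical behaviour of the pipeline's operations, not predictive
performance on real screening data.

Problem sizes used in the statistical checks — 100 actives with a 10:1
decoy ratio over 20 seeds for enrichment recovery, 5000 observations over
20 seeds for logistic coefficient recovery, 2000 per class for docking
means — were chosen as the smallest sizes at which the checked quantities
are stable (binomial/CLT error well inside the asserted bounds).

## Known limitations

* Descriptor values are not numerically interchangeable with those of other
  descriptor packages; only definitions, invariances and determinism are
  guaranteed.
* The plain-ring repair protonates aromatic nitrogens only; exotic
  extraction failures (unusual charged ring systems) drop the fragment with
  a warning rather than guessing a valence model.
* No multiple-testing correction is applied across scaffolds, matching the
  reference protocol; with thousands of scaffolds the chi-square p-values
  are screening heuristics, not confirmatory statistics.
* `rps_threshold` reports one representative of the optimal threshold's
  equivalence class (gap midpoint); any other value in the same gap yields
  identical classifications.
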