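# Methods

This note documents the conventions, parameter choices and limitations of the
`azoleqsar` pipeline: what each component computes, where the design was
genuinely open, and what the tests do and do not demonstrate.

## Molecular graphs and azole taxonomy

All descriptors are computed on the hydrogen-suppressed molecular graph with
RDKit's default aromaticity perception.  Mixtures (disconnected SMILES) are
rejected at parse time; salts must be stripped first (`strip_salts` keeps the
largest fragment).  Ring perception uses RDKit's SSSR, which satisfies the
cyclomatic identity |SSSR| = E − V + 1 on connected graphs.  Ring *systems*
are maximal sets of SSSR rings connected through shared atoms, so fused and
spiro assemblies count once while rings joined by an acyclic bond count
separately; the edge/vertex formula NRS = (E_t − E_r) − (V_t − V_r) + 1
provably equals that component count on connected graphs, and both routes are
cross-checked in the tests.

Azole classing scans all five-membered aromatic rings and takes the maximum
ring-nitrogen count (mono/di/tri/tetrazole); a sulfur or oxygen co-member in a
qualifying ring raises the thiazole/oxazole flag.  Tetrazoles are reported
although no regression model covers them.

Alert SMARTS are matched exactly as published.  Note that the published
patterns mix aromatic and aliphatic notation deliberately: the bare
imidazole-ring pattern matches any imidazole, while the benzylimidazole alert
(SA6) additionally requires the benzylic substituent; and the "carbon chain"
alert SA10 (`CC`) matches any two bonded aliphatic carbons.  SA10 is retained
as published — its low LR (1.67) means it only ever decides a prediction when
nothing stronger matches.

## ETA descriptors and the β-weight calibration

Per-atom ETA parameters: core count α = [(Z − Z_v)/Z_v]·1/(PN − 1) (carbon
0.5, nitrogen 0.4, oxygen 1/3, sulfur 5/6, chlorine 5/7, …; supported set
C, N, O, S, P and halogens), valence electron mobility β, and vertex weight
γ = α/β.  The local composite index is the bond sum
η_local = Σ √(γ_i γ_j), and the branching index is

    η′B = η_local(reference) − η_local(molecule) + 0.086·N_R
    ETA_etaP_B = η′B / N_v

with the reference the normal alkane of equal heavy-atom count,
η_local(ref) = √2 + 0.5·(N_v − 3).  Two conventions deserve comment:

* **Reference coefficient 0.5.**  Direct evaluation of the bond sum for a
  normal alkane (terminal γ = 1, interior γ = 0.5) gives
  √2 + 0.5·(N_v − 3) — e.g. 1.914 for n-butane — fixing the per-σ-bond
  contribution at 0.5.  A coefficient of 0.05 sometimes quoted for this
  closed form is inconsistent with the bond sum and is not used.
* **N_R is the molecule's SSSR ring count.**  Reading it as the ring count of
  the (acyclic) reference alkane would make the term vanish identically; the
  reference skeleton is taken to retain the molecule's rings.

**β weights.**  σ (single) bonds contribute 0.5 per bond, as fixed by the
reference.  The contributions of aromatic bonds, localized multiple bonds and
delocalised lone pairs are not derivable from first principles — published
ETA schemes disagree in detail, and the software that produced the published
azole branching indices is not available for inspection.  They were therefore
**calibrated once** by least squares against seven published branching-index
values of azole drugs (imazalil 0.01112, sertaconazole 0.01111, liarazole
0.00474, imazodan 0.00486, fadrozole 0.0019, bifonazole −0.007, medetomidine
0.014) and then frozen:

| contribution | weight |
|---|---|
| σ (single) bond | 0.5 (fixed) |
| aromatic bond | 0.4625 |
| localized double bond | 0.3093 |
| triple bond | 0.371 |
| halogen lone pair on an aromatic ring | +0.4202 |

The calibration residual is ≤ 6×10⁻³ in ETA_etaP_B units (fadrozole and
medetomidine are reproduced to ~5 significant figures, liarazole and
bifonazole are the worst cases).  An exhaustive search over discrete
convention families (per-atom vs per-bond π sharing, electronegativity-gated
σ = 0.75, lone-pair increments, ring-term variants) and unconstrained
continuous fits both bottom out at a few ×10⁻³, so the published 5-decimal
values are not exactly representable by any additive valence-mobility scheme
on these 2-D structures; the residual presumably reflects unrecoverable
conventions of the original descriptor software.  Downstream consequences are
mild — the diazole-antagonist model coefficient (−103.96) turns a 5×10⁻³
branching error into ≈ 0.5 pIC50 units worst case — but predictions from
`ETA_etaP_B` should be treated as convention-sensitive.

The other ETA descriptors are convention-free given α: `Eta_shape_Y` is the
α-fraction on atoms with exactly three heavy neighbours, `Eta_dAlpha_B` is
max(0, (0.5·N_v − Σα)/N_v) against the all-carbon reference skeleton (each N
adds 0.1/N_v, each O 1/6/N_v; clipped at zero so sulfur-rich molecules do not
go negative), and `Eta_betans_d` counts 0.5 per lone pair entering
conjugation: pyrrole-type ring heteroatoms (three-coordinate aromatic N,
aromatic O/S) and heteroatoms with a lone pair attached directly to a π
system (aniline N, amide N, aryl ether O).  Pyridine-type nitrogens keep
their in-plane lone pair and are not counted.

Gálvez charge indices follow the matrix definition: with adjacency A and
B = d⁻² (off-diagonal), CT = AB − (AB)ᵀ and GGI_k = Σ_{i<j, d_ij=k} |CT_ij|,
computed on the unweighted hydrogen-suppressed graph (no heteroatom
weighting).  Atom-pair frequencies F0k count unordered element pairs at
topological distance *exactly* k.

## Electronic descriptors and units

Conceptual-DFT descriptors are computed exactly as the models use them:
χ = (−E_HOMO − E_LUMO)/2, η = E_LUMO − E_HOMO (no ½ factor), ω = χ²/2η.
Energies are never converted between units; every record carries method and
unit tags, and prediction refuses mismatches.  The built-in models record the
working assumptions: the ω_HF term of the triazole model (coefficient 488.5)
is only dimensionally consistent with hartree-scale energies, and the PM7
HOMO−1 term of the diazole model (coefficient −22.4, typical descriptor value
≈ −0.35) likewise implies a hartree-scale input, whereas the PM7 LUMO term
matches the eV-scale ranges of the underlying semi-empirical calculations
(active-azole LUMOs around −1.65…−0.34 eV).  These assumptions are encoded in
`ModelSpec.expected_units` so that a mismatched table fails loudly rather
than silently producing nonsense.

Qmax⁺ is the largest positive partial charge on a *heavy* atom; a table with
no positive heavy atom raises an explicit error instead of returning 0,
because a silent zero would feed a fake neutral center into the agonist
model.

## Regression, GA selection and validation

OLS fits always include an intercept, name the collinear columns on rank
deficiency (via the null-space loadings), and warn when the
compounds-per-descriptor ratio drops below 5:1.

The GA uses set-encoded chromosomes (equivalent to binary masks), tournament
selection of size 2, uniform crossover at rate 0.8, a bit-swap mutation at
rate 0.2, elitism of 1 and leave-one-out Q² as fitness, memoized per subset.
The published setting "population size 10,000 generations" cannot be both a
population and a generation count; it is read as a total fitness-evaluation
budget, with defaults population 100 × generations 100.  Both a fixed subset
size and a 1..k search mode are provided.  Determinism is guaranteed per
seed.

Validation statistics:

* **Q²_LOO** uses the leverage shortcut e_i/(1 − h_i), which is algebraically
  identical to n refits (verified to 1e−10 against an explicit-refit oracle).
* **Q²_LMO** (default 30% out, 2000 iterations) is aggregated as the mean of
  per-iteration 1 − PRESS/TSS values, the convention of QSAR validation
  software; a pooled aggregation (1 − ΣPRESS/ΣTSS) is also provided and is
  the form that converges to Q²_LOO as the held-out block shrinks to one
  compound — the per-iteration mean is unstable for one-compound validation
  sets.
* **Y-scrambling** permutes the response and refits the *same* descriptor
  subset (no re-selection), 2000 iterations by default; the summary reports
  the scrambled mean and maximum against the real Q²_LOO.
* **QUIK rule**: K is computed from the eigenvalues of the column correlation
  matrix, K = Σ|λ_j/Σλ − 1/m|/(2(m−1)/m), so K = 0 for mutually uncorrelated
  columns and 1 for a duplicated pair; ΔK = K_xy − K_xx with acceptance
  threshold 0.05.
* **Williams plot**: leverages from the hat matrix with intercept,
  h* = 3p′/n with p′ = descriptors + 1, standardized residuals e/s with
  s² = RSS/(n − p′); response outliers at |r| > 3, structural at h > h*.

## Structural alerts

Alert statistics follow the published definitions: Acc = true/all predictions
by the alert; LR = (true/wrong) × (total antagonists/total agonists) for
agonist alerts, with the factor inverted for antagonist alerts; zero wrong
predictions gives LR = ∞.  Multi-alert molecules are predicted by the
highest-LR match (∞ outranks all finite values).  Two tie rules are defined
beyond the published material, which never encounters them: equal top LR
across opposite classes — whether finite or both infinite — yields
no-prediction with a warning, since silently picking a side would hide a real
ambiguity.  Molecules matching no alert are excluded from Q₂'s denominator
and reported separately.

Q₂rand uses the squared class marginals (P² + N²)/T² — the most probable
random accuracy, which gives 50.3% for the 36/42 totals of the curated active
set and exactly 50% for balanced classes; the fuller marginal-product form
[(TP+FP)(TP+FN) + (TN+FN)(TN+FP)]/N² is exposed alongside for comparison.
ΔQ₂ = Q₂ − Q₂rand has a maximum of 0.5.

## Curation

AC50 (nM) converts to the p-scale as 9 − log10(AC50).  Duplicate structures
(same canonical SMILES) are merged when their AC50 spread satisfies
max/min ≤ 3 ("1:3 rule", applied on the AC50 scale; on the p-scale it would
be a 0.477-unit rule) using the arithmetic mean of AC50 on the stored scale —
the geometric mean is available behind a flag since either reading of "mean
of the activity" is defensible.  Wider spreads and groups mixing agonist with
antagonist outcomes are rejected with a logged reason.  Tautomer and
chemotype normalization are out of scope; structures are canonicalized and
salts stripped only.

Tanimoto similarity T = |A∩B|/|A∪B| defaults to MACCS keys; the original
analysis used PubChem fingerprints, for which no maintained Python
implementation exists, and MACCS is the closest substructure-key scheme
available in RDKit (Morgan and RDKit path fingerprints are selectable).
Similarity *values* therefore differ from the original heat maps; the matrix
properties (symmetry, unit diagonal, [0,1] range) do not.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the pipeline needs to be
testable, not pharmacology:

* `gen_descriptor_matrix` draws equicorrelated Gaussian columns (feasible for
  −1/(p−1) < ρ < 1) with per-column location/scale so descriptor ranges can
  mimic the real ones (e.g. PM7 HOMO−1 ≈ −0.35 ± 0.03, branching ≈
  0.008 ± 0.004, NRS ≈ 3 ± 0.9).
* `gen_response` plants a known linear model (typically one of the built-in
  equations) plus Gaussian noise, enabling exact (σ = 0) and statistical
  (σ > 0) recovery tests.
* `gen_azole_library` assembles imidazole/thiazole/1,2,4-triazole scaffolds
  with alkyl linkers and an alert-bearing head group (carboxylic acid or
  amide for agonists; chloro- or p-ethyl-chlorobenzene for antagonists), a
  small valence-safe fragment pool that guarantees parseable, chemically sane
  SMILES.  Scaffold assignments respect the alert classes, so the planted
  alert is always the deciding one; the default 36/42 composition mirrors the
  curated active set.
* `gen_orbital_tables` samples frontier energies within method-typical ranges
  (PM7 LUMOs in −1.65…−0.344 eV) with HOMO−1 ≤ HOMO ≤ LUMO ≤ LUMO+1 and
  zero-sum partial charges.

Passing tests on these generators shows the *machinery* is correct —
descriptor formulas, selection, validation statistics, alert bookkeeping —
not that the published models generalize: real Tox21 descriptors are
non-Gaussian, mutually correlated in structured ways, and the real azole
chemical space is far more diverse than the combinatorial library.

Problem sizes in the test suite follow the study where stated (n = 26 for the
diazole-antagonist recovery experiment, 10 candidate descriptors, σ = 0.2,
100 repetitions; 2000 scrambling iterations; the 36/42 library) and stay
small elsewhere so the full suite runs in seconds.

## Known limitations

* The ETA β weights are an empirical calibration, not a first-principles
  scheme; branching indices agree with the published values to a few ×10⁻³
  but not to all printed decimals (see the calibration discussion above).
* The published model fit statistics (R², Q²_LOO, Q²_LMO, ΔK) and the 92.3%
  classification accuracy of the alert model require the original appendix
  compound tables and quantum-chemistry outputs, which are not shipped; the
  built-in models carry them as metadata, and property-based surrogates
  (planted-model recovery, the validation-identity checks, the synthetic
  library) cover the corresponding machinery.
* Electronic descriptors depend entirely on the quality and unit discipline
  of the supplied tables; only unit *tags* are checked, not physical
  plausibility.
* No 3-D, conformer or stereochemical information enters any descriptor.
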