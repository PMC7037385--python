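# azoleqsar

QSAR and structural-alert modeling of azole activity on human aromatase
(CYP19A1).

Azoles — five-membered aromatic heterocycles with one to four ring nitrogens —
are widely used antifungals and agrochemicals that can disrupt the endocrine
system by acting on aromatase, the cytochrome P450 enzyme (CYP19A1) that
converts androgens into estrogens.  Depending on their structure they behave as
**antagonists** (inhibitors, quantified as pIC50) or **agonists** (enhancers,
pEC50).  This package implements, as a tested and reusable pipeline, the
published analysis of azole agonism/antagonism from the Tox21 aromatase assay:
descriptor computation, four class-specific multilinear regression (MLR)
models, genetic-algorithm model rebuilding with the standard QSAR validation
battery, and a structural-alert classifier.  It is aimed at computational
toxicologists and cheminformaticians who want to apply, stress-test or rebuild
these models.

## What it computes

**Topological descriptors** (from SMILES, via RDKit graphs):

* Extended topochemical atom (ETA) indices built from per-atom core counts
  α = [(Z − Z_v)/Z_v]·1/(PN − 1) and valence electron mobility counts β, with
  γ = α/β.  The branching index compares a molecule with the normal alkane of
  the same heavy-atom count N_v:

  η′B = η_local(ref) − η_local(mol) + 0.086·N_R,  η_local = Σ_{bonds} √(γ_i γ_j)

  and ETA_etaP_B = η′B/N_v.  Also the shape index Eta_shape_Y (core-count
  fraction on tertiary atoms), the hydrogen-bond-acceptor measure Eta_dAlpha_B
  and the conjugated-lone-pair count Eta_betans_d.
* Number of ring systems NRS = (E_t − E_r) − (V_t − V_r) + 1.
* Gálvez topological charge index GGI_k and atom-pair frequencies F03(C–C),
  F04(N–O).

**Electronic descriptors** from user-supplied quantum-chemistry tables (the
pipeline never runs a QM engine): electronegativity χ = (−E_HOMO − E_LUMO)/2,
hardness η = E_LUMO − E_HOMO, electrophilicity ω = χ²/2η, correlation
differences D_CORR = D_B3LYP − D_HF, and the maximum positive atomic charge
Qmax⁺.

**The four published MLR models**, coefficients exactly as printed:

| class | activity | equation |
|---|---|---|
| triazole antagonist | pIC50 | 1.4676 + 488.5007·ω_HF + 4.3535·E_LUMO(PM7) + 5.6602·Eta_shape_Y |
| diazole antagonist | pIC50 | 3.5936 − 22.4173·E_HOMO−1(PM7) − 103.9622·ETA_etaP_B − 0.6724·NRS |
| diazole agonist | pEC50 | 8.6983 − 0.7252·Qmax⁺(PM7) − 19.4372·Eta_dAlpha_B + 1.1130·Eta_betans_d |
| thiazole agonist | pEC50 | 7.3704 − 8.0767·GGI9 + 0.1177·F03(C−C) + 0.5873·F04(N−O) |

**Model building and validation**: OLS fitting with collinearity diagnostics
and the 5:1 compounds-per-descriptor rule, genetic-algorithm subset selection
with leave-one-out Q² as fitness (crossover 0.8, mutation 0.2), Q²LMO
(30% out, 2000 iterations), Y-scrambling, the QUIK ΔK ≥ 0.05 rule and the
Williams applicability-domain plot (h* = 3p′/n, |standardized residual| > 3).

**Structural alerts**: the 11 published SMARTS alerts with per-alert accuracy
Acc = true/all predictions and likelihood ratio
LR = (true/wrong)·(class-prior factor), highest-LR prediction, and model-level
real/random/delta accuracy (Q₂, Q₂rand = (P² + N²)/T², ΔQ₂).

**Curation & synthetic data**: AC50→p-activity conversion, the 1:3 duplicate
rule, azole classing, Tanimoto similarity matrices, and seeded generators for
descriptor matrices with planted linear models, azole libraries with planted
alerts, and orbital-energy tables.

## Worked example

```python
from azoleqsar import (parse_smiles, azole_class, nrs, eta_branching,
                       builtin_models, predict, builtin_alerts, classify)

g = parse_smiles("Clc1cccc(c1)C(n1ccnc1)c1ccc2nc[nH]c2c1", "liarozole")
print(azole_class(g))          # ('diazole', False)
print(nrs(g))                  # 3 — three ring systems
print(round(eta_branching(g)[1], 5))   # 0.01026 — size-normalised branching

model = {m.name: m for m in builtin_models()}["diazole_antagonist"]
pic50 = predict(model, {"E_HOMONL_PM7": -0.345,
                        "ETA_etaP_B": eta_branching(g)[1],
                        "NRS": nrs(g)})
print(round(pic50, 3))         # 8.244 — predicted inhibition (pIC50)

pred = classify(g, builtin_alerts())
print(pred.matched, pred.winning, pred.label)
# ['SA6', 'SA9'] SA6 antagonist
```

Liarozole is recognised as a diazole with three ring systems; the diazole
antagonist model predicts a sub-10-nM inhibitor (pIC50 ≈ 8.2), and the alert
classifier flags it as an antagonist through the benzylimidazole alert (SA6, a
perfect classifier in the training set) with the chlorobenzene alert (SA9)
matching as well.

A command-line interface mirrors the library:
`azoleqsar descriptors`, `predict`, `validate`, `classify`, `simulate`.

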