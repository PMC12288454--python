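# allosterik

Desk-scale analysis toolkit for characterising natural variants of a
dimeric bacterial transcription factor — here a GntR/FadR-family repressor
with an N-terminal winged helix-turn-helix DNA-binding domain (DBD), a
linker, and a C-terminal effector-binding/oligomerisation (E-O) domain.
The repressor sits on its operator until a small-molecule effector
(D-galactonate) binds the C-terminal domain and, through allosteric
coupling, releases the DNA. Natural amino-acid variants can perturb any
link in that chain: DNA affinity, effector affinity, or the communication
between the two domains.

The package covers the three computational layers such a study needs:

1. **Trajectory dynamics** — dynamic cross-correlation (DCC) maps,
   `C_ij = ⟨Δr_i·Δr_j⟩ / (⟨|Δr_i|²⟩⟨|Δr_j|²⟩)^{1/2}` over superposed Cα
   trajectories, essential-dynamics PCA with porcupine (PC1 arrow) fields,
   RMSD/RMSF profiles, and correlation-weighted dynamical networks
   (`w_ij = −ln|C_ij|` on persistent contacts) with Girvan–Newman
   communities and exhaustive-within-tolerance **suboptimal path**
   enumeration between the DBD and E-O node sets.
2. **Variant-panel scanning** — alignment-based substitution calling
   (Needleman–Wunsch, BLOSUM62) of a homolog FASTA panel against a
   reference, exact-length filtering, de-duplication into unique variants
   with carrier lists, and per-domain classification.
3. **Assay models** — Hill fits for gel-shift DNA titrations
   (`f = Pⁿ/(K_Dⁿ + Pⁿ)`), exact 1:1 quadratic isotherm fits for
   thermophoresis effector titrations, effector-release titration calls,
   affinity fold ratios, growth-curve kinetics (doubling time, lag), and
   fluorescence/OD normalisation.

Because trajectory and strain-panel raw data of this kind are not
redistributable, a first-class `synthetic` module generates every input
with known ground truth: elastic-network Gaussian dimer trajectories whose
analytic covariance is returned alongside the frames (the oracle for every
dynamics stage), isolate sequence panels with planted substitutions, and
noisy binding/growth curves. Four ligand states (APO, effector-bound E,
DNA-bound D, doubly bound ED) differ only in planted spring sets, so
downstream stages can be tested for recovering the planted direction.

## Worked example

Fit a synthetic 12-point gel-shift titration generated at K_D = 494 nM
(the study's wild-type promoter affinity) with 2% multiplicative noise:

```python
import numpy as np
from allosterik import BindingModel, fold_ratio
from allosterik.synthetic import CurveSpec, generate_curve

x = tuple(np.linspace(1600/12, 1600, 12))                 # nM titration
curve = generate_curve(CurveSpec("hill", (("K_D", 494.0), ("n", 1.0)), x, 0.02, 1))
print(BindingModel(curve, model="hill").fit().summary())
```

```
Binding fit             hill
N observations          12
Converged               True
Residual norm           0.02257
--------------------------------------------
param           estimate       std err
K_D                489.7         5.237 nM
n                  1.007       0.01483
```

The fit recovers the planted K_D (489.7 ± 5.2 nM vs 494 nM truth) and a
Hill coefficient of ~1. Comparing the weakened-variant promoter affinity
against wild type gives the headline fold change:

```python
ratio, fold = fold_ratio(1945.0, 494.0, unit_a="nM", unit_b="nM")
# ratio = 3.94 -> approximately 4-fold weaker DNA binding
```

The variant census runs from the shell. Generate the packaged 340-isolate
panel and re-scan it by alignment:

```bash
allosterik simulate panel --seed 1 --out panel/
allosterik scan --reference panel/reference.fasta --panel panel/panel.fasta --out variants.tsv
# 12 unique variants in 42 carriers (domain split: {'DBD': 4, 'linker': 1, 'EO': 7})
```

`variants.tsv` lists each substitution (L3F, K15R, H19Q, P24L, R71C, P92L,
A128S, A152E, T180S, A186V, S220C, T222I) with its domain and carrier ids.

An end-to-end dynamics run (synthetic four-state suite → superposition →
DCC → network → communities → suboptimal paths → cross-state comparison)
is driven by a YAML config:

```bash
allosterik run --config run.yaml     # kind: dynamics, variants: [WT, R71C], ...
```

and writes per-system TSVs plus a manifest with content hashes, so reruns
are bit-reproducible.

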