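# samdcscreen

Analytics for discovering inhibitors of human S-adenosylmethionine
decarboxylase (AdoMetDC/SAMDC), the rate-limiting enzyme of polyamine
biosynthesis and a long-standing anticancer/antiparasitic target.  The
package re-implements, as a tested and reusable library, the two halves of
a structure-based inhibitor-discovery campaign:

* **Computational triage** — preparing a docking-compatible receptor model
  by grafting an unprocessed Ser68 into the catalytic pyruvoyl-68 slot of
  an active-form structure (Kabsch backbone superposition + residue
  replacement), then filtering large docking runs with three quantitative
  rules and quantified expert-selection proxies, and measuring whether
  known inhibitors' crystallographic poses are recaptured by re-docking.
* **Experimental analytics** — analysing the non-radioactive
  AdoMetDC–PEPC–MDH coupled assay, in which released CO₂ (as bicarbonate)
  is condensed by PEP carboxylase and the product reduced by malate
  dehydrogenase while NADH (absorbing at 340 nm) is oxidised 1:1:
  ΔAU extraction, blank correction, NaHCO₃ calibration, Michaelis–Menten
  fitting, inhibition percentages, plate screening with background-artifact
  flags, and replicate-CV validation statistics.

A forward kinetic simulator generates ground-truth-labeled synthetic inputs
for every stage, so the whole pipeline is testable end to end without
licensed compound libraries or wet-lab data.

## The core quantities

Docking-pose triage applies, per molecule with poses scored $s_1 \le s_2
\le \dots$ (lower = better) and $n$ heavy atoms:

* **Score Rule**: $\min_i s_i < -7.5$;
* **Cluster Rule**: $\frac{1}{N}\,\#\{i : \mathrm{RMSD}(x_i, x_{\text{best}})
  \le 3.0\,\text{Å}\} \ge 0.75$ (identity atom mapping, shared receptor
  frame, reference pose included);
* **Score Density Rule**: $\min_i s_i / n < -0.28$ (a ligand-efficiency-style
  cut).

Assay kinetics fits initial rates $v$ against substrate $S$ with the
Michaelis–Menten law $v = V_{\max} S / (K_m + S)$, deriving $k_{cat} =
V_{\max}/[E]$ and the catalytic efficiency $k_{cat}/K_m$; the screen
computes inhibition as $[1 - \Delta AU_{\text{inh}} /
\Delta AU_{\text{ctrl}}] \times 100\%$ over the 0→5 min window, and
validation reports $CV = 100 \cdot SD/\text{mean}$ at 0 %, 50 % and 80 %
activity.

## Worked example

`examples/` holds one short script per capability (kinetic fitting, pose
filtering, compound screening, residue grafting, pose recapture, assay
validation).  For instance:

```bash
$ python examples/fit_kinetics.py
[S] =     5.0 uM   v = 2.2759 uM/min
...
[S] =  1000.0 uM   v = 3.7085 uM/min

Km      = 3.16 +/- 0.0078 uM
Vmax    = 3.72 +/- 0.0011 uM/min
kcat    = 0.062 1/s  (assuming 1 uM fully active enzyme)
kcat/Km = 1.96e+04 1/(M s)
R^2     = 1.0000
```

The script simulates noise-free A340 progress curves at the assay's
substrate series (5–1000 µM AdoMet, 1 µM enzyme), extracts initial rates
from the early linear decline, and fits them: the recovered Km (≈3.1 µM)
and kcat/Km (≈2.0×10⁴ M⁻¹s⁻¹) match the simulator's inputs, with the small
residual deviation coming from substrate depletion during the rate window.

```bash
$ python examples/screen_compounds.py
compound_id  concentration_uM  inhibition_pct     background_flag
    CMP-001             100.0       49.192238               clean
    CMP-006             100.0       31.968458 coupling_inhibition
    CMP-015             100.0       12.228212               clean
...
```

Here a 26-compound plate with one planted ~50 %-inhibition compound, one
PEPC/MDH coupling poison and one 340 nm chromophore is screened: the true
inhibitor ranks first and exactly the two artifact compounds are flagged.

A thin CLI (`samdc prep-structure | filter-poses | recapture | assay-fit |
assay-screen | simulate`) wraps the same functions for shell use.

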