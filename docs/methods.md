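# Methods

## Receptor preparation (structio)

Structures are held as flat ordered atom lists (`AtomRecord` /
`StructureModel`) read from fixed-column PDB via biotite; alternate
locations are resolved to the highest-occupancy conformer, first-listed on
ties, which is deterministic and matches common practice.  Non-standard
residues such as the catalytic pyruvoyl group are carried as opaque HETATM
residues — no chemical perception is attempted, and the ATOM/HETATM
distinction is preserved so files round-trip exactly.

Backbone superposition is a least-squares proper rigid fit (Kabsch SVD
construction, reflection-corrected) over atoms paired by exact
`(chain, residue number, atom name)` identity restricted to N, CA, C, O by
default (configurable; some protocols prefer CA-only).  Fewer than three
pairs, or a collinear point set (second singular value of the centered
coordinates below 1e-8 of the first), is an error: the rotation would be
under-determined.  The transform convention is `x → R x + t` mapping the
mobile structure onto the reference; the reported RMSD is the post-fit
value over the paired atoms.

`graft_residue` composes superposition with residue replacement: the donor
is aligned to the target over the shared backbone *excluding the residue
being swapped* — its atoms differ between the two structures by
construction (pyruvoyl vs serine) and would bias the fit; with them
excluded, grafting a residue back restores the original coordinates
exactly.  The donor residue's atoms are inserted at the target slot in
donor order, renumbered and rechained to the target's slot so downstream
tools see one continuous chain.  A donor residue with fewer than 4 atoms
is rejected as a suspect fragment.  Side-chain repacking and energy
minimisation of the chimera are out of scope (external tools do this);
the output is the geometric chimera only.

## Pose triage (pose_triage)

Ligand RMSD uses the identity atom mapping with no re-superposition: poses
of one molecule share the receptor frame and the quantity of interest is
displacement within it.  Symmetry (automorphism) correction is a known
limitation — for symmetric ligands the reported RMSD can overestimate.

Boundary semantics follow the rules' wording literally: the Score and
Score Density rules are strict (`< -7.5`, `< -0.28` per heavy atom); the
Cluster Rule is inclusive on both the 3.0 Å cut and the 75 % fraction, and
the reference (lowest-score) pose counts in numerator and denominator.
The cascade applies the three rules conjunctively as one "autodock filter"
stage; per-molecule records keep every verdict plus the first failing rule
in Score → Cluster → Density order, so per-rule failure attributions sum
to the stage loss.  Stage percentages are reported relative to the
immediately preceding stage (with percentages of the original input also
emitted); an empty preceding stage defines the next percentage as 0.

Expert-selection proxies: `pocket_fit_fraction` counts heavy atoms outside
a pocket given either as a sphere (distance to center > radius) or a grid
cloud (nearest grid point farther than the spacing), with a default
acceptance of ≤30 % outside.  `dedupe_similar` keeps the better-scored of
two molecules whose best poses overlap; because atom mappings do not exist
across different molecules, similarity is the symmetric mean of per-atom
nearest-neighbor distances (default cut 1.0 Å), processed greedily in
ascending best-score order (ties broken by molecule id), which makes the
result independent of input order.  Recapture reports per-pose RMSDs for
the up-to-5 lowest-score poses against a reference conformation; the
default 2.0 Å recapture threshold is the field's customary redocking
success cut and is configurable.

An upstream shape-complementarity score stage (e.g. Pscore) is consumed as
given counts/files, never re-implemented; the cascade is agnostic about
which docking program produced the scores.

## Coupled-assay analytics (assay_kinetics)

The primary signal is ΔAU = A(t₀) − A(t₁) with the 0→5 min default window
(configurable, since background drift grows at longer times); readings are
linearly interpolated when the exact timestamps were not sampled.  Blank
correction subtracts a no-enzyme ΔAU over the same window.  Calibration
fits an ordinary least-squares line (intercept included) through NaHCO₃
standards and inverts it; samples outside the standards' span are flagged
as extrapolated.

Initial rates use the OLS slope of A340 over the first 1 min by default,
converted through ε·l.  The short window matters: at the default
parameters, 5 min at saturation consumes ~19 µM substrate, which would
bias rates at low [S].  Michaelis–Menten fitting is bounded nonlinear
least squares (`scipy.optimize.curve_fit`, positive parameters), with
standard errors from the covariance matrix.  kcat = Vmax/[E]·(1/60) s⁻¹
assumes fully active enzyme at the stated concentration — reported as an
assumption.  Km is flagged unidentifiable when its estimate collapses
below a tenth of the smallest measured substrate concentration or its
standard error explodes (data without curvature).

Inhibition is `(1 − ΔAU_with/ΔAU_without) × 100 %` on blank-corrected
values; results may fall below 0 (apparent activation) or above 100
(over-suppression plus noise) and are not clamped.  Validation statistics
use the sample SD (n−1), CV = 100·SD/mean and SEM = SD/√n per activity
level (0 / 50 / 80 %); a zero mean leaves CV as NaN.

`screen_plate` scores each compound against the no-compound control and
sets background flags from dedicated no-enzyme wells:

* *absorbance interference* — the compound's no-enzyme trace deviates from
  the blanks in mean A340 **level** (not ΔAU: a constant chromophore
  offset cancels in a difference, so the level is the right observable);
* *coupling inhibition* — the compound + NaHCO₃-standard well
  under-reports the compound-free standard's ΔAU (the compound poisons
  the PEPC/MDH readout itself).  This more specific flag wins if both
  checks trip.

The tolerance is `max(3 × SD of blank-replicate ΔAU, 0.01 AU)`.  The
absolute floor encodes a minimum meaningful absorbance difference: with a
handful of blank replicates the 3σ estimate is noisy and, across dozens of
compound wells, pure read noise would otherwise trip occasional false
flags.

A 4-parameter logistic IC₅₀ fit is included as an optional utility for
dose–response follow-up; single-concentration screens do not use it.

## Forward simulator (synthetic_data)

`simulate_assay` integrates dS/dt = −kcat·E·S/(Kₘ,app + S) with classical
fixed-step RK4 (default dt = 0.1 min over 5 min; halving dt moves the
endpoint by far less than 1e-6 µM at these scales).  Competitive
inhibition scales the apparent Km by (1 + I/Ki) — a simulator convention,
not a mechanistic claim about any particular compound; putrescine
stimulation is a plain kcat multiplier (~2 reproduces the reported
magnitude).  Cumulative CO₂ plus a linear exogenous drift are drawn from
the NADH pool through a coupling factor (1 = healthy readout; <1 models a
poisoned PEPC/MDH leg), NADH is floored at zero with an exhaustion flag,
and A340 = ε·l·NADH + constant compound offset + Gaussian read noise.
While NADH is unclamped and coupling is 1, the trajectory satisfies
S(0) − S(t) + NADH(t) + drift·t = NADH(0) identically.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| Km | 3.1 µM | the assay's reported estimate |
| kcat | 0.062 s⁻¹ | from kcat/Km = 2.0×10⁴ M⁻¹s⁻¹ at that Km |
| enzyme | 1 µM | protocol concentration |
| AdoMet | 1000 µM | protocol upper limit (self-absorbance above) |
| NADH₀ | 105.75 µM | 0.45 mM in reagent R2 diluted 47/200 into the mix |
| ε·l | 0.00348 AU/µM | 6220 M⁻¹cm⁻¹ × ~0.56 cm depth of 200 µL in a 96-well |
| drift | 0.5 µM/min | small, slow linear exogenous-CO₂ background |
| noise | 0.002 AU | typical plate-reader read noise |

Calibration standards are simulated as instantaneous consumption of the
standard's CO₂ just after t = 0 (the first read still shows the full
pool), then drift only.  Note the ~106 µM working NADH pool bounds the
assay's linear detection range; standards beyond it clamp.

`make_pose_set` constructs docking results whose rule outcomes are known:
the best score is drawn inside the interval jointly compatible with the
requested Score/Score-Density outcomes (0.05 margin off the strict
boundaries), and coordinates form one tight cluster around the best pose
(per-pose RMSD drawn in 0.2–0.8 of the cut) plus rigid outliers ≥2 cuts
away, with the within-cut count on the requested side of 75 %.
Unrealizable requests — a failing Score Rule with a passing Score Density
Rule at ≥27 heavy atoms (where −0.28·n ≤ −7.5), or a failing Cluster Rule
with a single pose — raise instead of silently adjusting.

`make_screening_plate` assembles blanks (×3), compound-free standards
(×3, 50 µM — safely inside the NADH pool), positive controls (×2) and,
per compound, an enzyme well, a no-enzyme background well and a
compound + standard well.  Planted classes: a true inhibitor whose Ki is
solved from the competitive-inhibition algebra to give ~50 % inhibition at
the 100 µM screen concentration (the positive-control level); a coupling
poison at coupling factor 0.8 (≈20 % apparent inhibition, so it does not
outrank the true inhibitor but clearly fails the standard check); a
chromophore at +0.15 AU.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: compound solubility/aggregation, concentration-
dependent compound absorbance, slow-binding or covalent inhibition,
coupled-enzyme lag at early times, plate-position effects, pipetting
covariance between wells, and real docking-score physics (scores and
geometries are constructed, not docked).  Conclusions about the analytics
transfer to real plates; conclusions about discovery rates do not.

## Problem sizes and determinism

All generators take explicit integer seeds (NumPy `default_rng`); the same
seed reproduces bit-identical outputs.  The test and acceptance workloads
use desk-scale sizes chosen to exercise the statistics without waste: 100
pose sets for rule-truth equivalence, 20 plates of 26 compounds for the
end-to-end screen, 200 Monte-Carlo replicates (5 % CV) for noisy Km
recovery, and a coarse-to-fine rotational grid search (6° → 0.1°) as the
superposition oracle — a full 0.1° three-angle grid would be ~5×10¹⁰
evaluations for the same answer.

## Known limitations

* Ligand RMSD has no symmetry correction (documented above).
* The screening-cascade's manual-inspection stage is represented only by
  its quantifiable proxies (pocket fraction, top-5 fit, dedup).
* kcat assumes 100 % active enzyme; a specific-activity correction would
  scale kcat and kcat/Km linearly.
* The reported Km of the assay (3.1 µM) sits far below older
  radioassay-based literature values (60–320 µM); the package takes the
  assay's own value as the simulator default and does not arbitrate.
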