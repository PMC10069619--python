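# Model and methods

`heterosim` is a particle-based Monte Carlo model of HP1-mediated
heterochromatin formation: a coarse-grained chromatin fiber whose H3K9
sites carry discrete methylation states (me0–me3), plus diffusing HP1,
three H3K9 methyltransferases (G9a, SUV39H, SETDB1) and one generic
lysine demethylase (KDM) in a periodic cubic box. The model's point is
the *reader–writer feedback loop*: HP1 reads me2/me3 marks through its
chromodomain, recruits methyltransferases through its chromoshadow
domain, and the recruited writers deposit further marks that recruit
more HP1 — so methylation spreads outward from a permanently methylated
nucleation site, in competition with continuous demethylation.

## Geometry and composition

* Fiber: `n` nucleosome core beads (radius 5 nm) on a linear chain of
  tethers, each core carrying one H3K9 tail-site bead (radius 1 nm).
  One site per nucleosome keeps the per-nucleosome state well defined.
  The default fiber is 102 nucleosomes spanning ~20 kb (≈196
  bp/nucleosome); the two central nucleosomes are permanently
  tri-methylated and stand in for the chemically induced HP1 recruitment
  site that nucleates the domain. Demethylation attempts on them are
  silently refused.
* HP1 is a two-bead chain — chromodomain (CD) + chromoshadow domain
  (CSD), 1.5 nm beads. Each HMT is a two-bead chain — a chromatin/HP1
  anchor (*bind*) + a catalytic SET domain (*cat*), 1.5 nm beads. KDM is
  a single 1.5 nm bead.
* The box edge is derived from copy number and concentration
  (`copies/(N_A·L³) = c`); 102 copies of each species at the nominal
  10 µM give a 257 nm box. The box is periodic; all distances are
  minimum-image.

## Tethers and moves

A tether contributes an acceptance weight

    w(d) = 0                       d < min_len      (hard contact)
    w(d) = 1                       min_len ≤ d ≤ free_len
    w(d) = exp(−k·(d − free_len))  beyond            (k = 0.3 nm⁻¹)

The intramolecular bind–cat and CD–CSD tethers use min 3 nm / free 4 nm
(the disordered-linker standard distance); fiber tethers use the sum of
radii plus 3 nm (core–site) or 6 nm (core–core) of slack; dynamically
formed bonds use the sum of radii plus 1.5 nm. Accepting a move with
probability ∏w makes the stationary pair-distance density ∝ r²·w(r);
because the damping is exponential in distance while the radial volume
element grows as r², this density has a long tail (mean CD–CSD distance
≈ 10.6 nm), which the test suite checks against direct 1D integration.

Mobile units move once per sweep in freshly randomized order:

* single beads (cores, sites, KDM) receive an isotropic Gaussian
  displacement with per-axis variance 2·D·Δt;
* two-bead molecules receive a *centre-of-mass* Gaussian displacement at
  the species diffusivity plus (on alternating sweeps) a COM-preserving
  antisymmetric internal displacement (±e/2 on the beads) that relaxes
  the tether coordinate.

The COM/internal split is deliberate: per-bead Metropolis moves of a
tightly tethered pair are rejected so often that centre-of-mass
transport drops ~3.5-fold below the input diffusivity, whereas COM moves
leave the internal coordinate untouched and are essentially
rejection-free for an unobstructed molecule, so the calibrated species
diffusion coefficient (HP1: 0.550 µm²/s, enzymes Stokes-scaled from it
by mass^(−1/3), 1 µs steps) is realized directly and is recovered from
trajectory MSD fits within a few percent. Proposed displacements are
capped at 6 nm (resampled), ~1.5× the tether free length; the truncated
mass is <0.1% for every species. Moves are rejected outright on
hard-core overlap with any non-tethered particle; nucleosome cores are
slow but mobile (D = 0.01 nm²/µs) so the fiber folds and breathes.

Neighbor search uses a linked-cell list whose cell edge is at least the
largest interaction distance; scans visit only the cells a given search
radius can reach, which stays exhaustive because no search radius
exceeds the cell edge. Below three cells per dimension the search
degrades to an exhaustive scan.

## Binding rules

Six rule families, each with per-step probabilities (pa, pd):

| rule | pair | eligibility |
|---|---|---|
| CD–H3K9 | HP1 chromodomain ↔ tail site | me2, me3 |
| CSD–CSD | chromoshadow dimerization | — |
| BIND–CSD | HMT anchor ↔ chromoshadow | — (per HMT) |
| KME–H3K9 | Kme reader module ↔ tail site | me1–me3; G9a and SETDB1 only |
| CAT–H3K9 | SET domain ↔ substrate site | me0–me2 |
| KDM–H3K9 | demethylase ↔ tail site | me1–me3 |

While an eligible free pair sits inside the capture radius (sum of radii
+ 0.5 nm) an association fires with pa per step; a bond dissociates with
pd per step, so residence times are geometric with mean 1/pd steps.
Eligibility is checked at bond creation only; a bond survives a state
change of its partner until it stochastically dissociates. Valence: a
tail site has one *reader* slot (CD, Kme, or KDM) and one *catalytic*
slot (cat); a CSD has one dimerization slot and one HMT-recruitment
slot; everything else is monovalent.

### Calibration

`pd = koff·Δt` maps the off-rate directly. For pa two conversions exist:

* the well-mixed relation `pa = pd·[F]·kon/koff` (used by the
  ideal-mixing mode and exposed as `calibration.pa_from_kinetics`);
* the contact-gated relation `pa = pd/(KD·N_A·V_shell)`, where
  `V_shell` is the capture-shell volume between hard contact and the
  capture radius. In the spatial engine association only fires in
  contact; balancing association flux `pa·⟨contact pairs⟩` against
  dissociation flux `pd·n_bonds` for a dilute solution makes the
  *emergent* trajectory KD equal the anchor. Engine defaults use this
  route, and the round trip anchors → (pa, pd) → trajectory →
  estimated (koff, KD) is the calibration module's headline test.

Default anchors: HP1-CD↔H3K9me koff = 4 s⁻¹ (the measured
heterochromatin off-rate) with an effective affinity of 10 µM (the
µM-scale anchor; the raw koff/kon ratio of the printed rates, ~4 mM,
would give ~0.25% occupancy at 10 µM and no feedback on any feasible
timescale — we read the µM figures as avidity-corrected effective
affinities). All enzyme bindings (HMT–CSD, Kme, substrate engagement,
KDM–substrate) are 10 µM; CSD dimerization 2 µM. Unprinted off-rates
are set faster than the chromodomain's — 40 s⁻¹ for recruitment/reader
bonds, 100 s⁻¹ for transient substrate engagement — so bond populations
equilibrate well below the methylation timescale.

Known estimator bias: at large pa the association sink depletes the
contact shell below its ideal-gas density, so emergent KD runs ~20–30%
above the anchor; this is inside every tolerance used and is visible in
the two-particle equilibrium test, which therefore probes the
reaction-limited regime.

## Catalysis

A methylation event needs three simultaneous conditions: (i) the HMT's
*bind* bead anchored to chromatin — docked on the CSD of an HP1 whose CD
is currently site-bound, or (G9a/SETDB1) directly on a methylated site
through its Kme module; (ii) the *cat* bead bound to a substrate site in
me0–me2; (iii) a uniform draw below pt(enzyme, state). The substrate
then steps up one state and the cat turns inactive, re-activating when
its substrate bond dissociates (a fixed-refractory-timer variant is
available but off by default). Demethylation needs only binding to a
methylated, non-permanent site and a draw below pt(KDM, state). All
transitions are ±1; an event log (step, enzyme, nucleosome, from, to)
is kept and its replay must reproduce the sampled methylation field
exactly (tested).

### pt defaults and their reconstruction

The per-step transform probabilities are not printed in the source
material and are reconstructed under four constraints, in this order of
priority:

1. each enzyme's primary activity carries the largest entry of its row
   (G9a → mono, SETDB1 → di, SUV39H → tri), with secondary activities
   50× lower — writer state-specificity is strong;
2. firing per substrate engagement stays far from saturation
   (pt ≪ pd_cat), also under the ×100 scaled-down proxy, so relative
   enzyme activities keep their meaning at both scales;
3. the whole-system turnover per enzyme, measured from event counts in
   a wild-type run and expressed at pt_scale = 1, sits in the 10–10² s
   range of enzymatic turnover times;
4. the eraser strength places the wild-type stationary me3 level high
   but clearly below saturation — the regime in which the wild-type
   fiber approaches its maximum methylation while enzyme knockdowns
   register as a level decrease, and in which the stationary level's
   slow collective fluctuations are small enough to measure knockdown
   effects with replicated runs.

Defaults: primary 1×10⁻⁵, secondary 2×10⁻⁷, KDM 2.5×10⁻⁷ per step.
During development we also explored a more balanced writer/eraser
regime (stationary me3 ≈ 0.5); it produces the same knockdown ordering
but with stationary-level fluctuations (per-replica sd ≈ 0.1) dominated
by the slow HP1 exchange time (the pinned 4 s⁻¹ chromodomain off-rate,
2.5×10⁵ steps), which would make level comparisons impractically noisy.
The constraint-4 regime was chosen for the defaults and frozen.

## Update order and reproducibility

One step = one sweep of (1) moves in randomized order, (2) dissociation
attempts over all bonds, (3) association attempts — enumerated once per
eligible pair from the target side (tail sites and CSDs) in randomized
order, (4) reactions (HMTs, then KDM), (5) sampling every
`report_interval` steps. All randomness in a replica comes from a
single numpy stream seeded from the replica seed; a (config, seed) pair
reproduces trajectories bit for bit, and per-replica seeds derive only
from (master seed, replica index), so serial and concurrent scenario
execution give identical ensembles.

## Observables

* **Time charts** — fiber-averaged f_me1/f_me2/f_me3 per sample, mean ±
  replica dispersion; the averaging region is the full fiber by default
  (a central-half option exists because the reported averages are
  ambiguous between a 10-kb window and the full 20-kb fiber).
* **Plateau** ("maximum methylation level") — the mean over the final
  quartile of samples.
* **Site profiles** — per-nucleosome me3 probability in time windows.
* **Centrifugal index** — Spearman rank correlation between a
  nucleosome's distance from the fiber centre and its first-passage
  time to me3, pooled over replicas; never-methylated nucleosomes are
  censored at the run length, permanent ones excluded. Positive values
  mean marks spread outward from the nucleation centre.

## Scaled-down knockdown proxy

Full-scale runs (102 nucleosomes, 25 replicas, plateau-length
trajectories) are long; knockdown comparisons run on a desk-scale proxy:
a 24-nucleosome fiber, every pt multiplied by 100 (ratios preserved),
12 copies per species at the unchanged 10 µM concentrations, ≥10
replicas per arm. Two methodological choices matter:

* **Downhill plateau estimation.** The stationary me3 level is estimated
  from replicas initialized *fully methylated* and relaxed down to the
  stationary state, rather than grown up from the nucleated state.
  Uphill runs show all-or-nothing ignition with large replica-to-replica
  timing noise (as the underlying biology does); the stationary level
  they eventually reach is the same, but measuring it uphill at matched
  precision costs roughly an order of magnitude more compute. Spreading
  kinetics and the centrifugal effect are still measured on uphill runs.
* **What the proxy preserves and what it does not.** Affinities,
  concentrations, off-rates and the pt ratios are unchanged; only the
  absolute catalytic scale is boosted. Because primary pt approaches the
  engagement pd under the boost, per-engagement firing begins to
  saturate (0.9 primary / 0.5⁻ secondary at ×100 versus 0.09/0.002 at
  full scale), which compresses — but does not erase — writer
  specificity; knockdown effect sizes on the proxy are therefore
  expected to be near, not identical to, full-scale ones.

What passing proxy tests shows: the feedback loop's stationary level
responds to enzyme dosage in the right order — SETDB1 knockdowns lower
it, SETDB1's effect is the strongest of the three writers, G9a and
SUV39H respond weakly — and methylation spreads centrifugally from the
nucleation site. The *magnitude* of the 75%-SETDB1 response in this
reconstruction is a few percent, smaller than at 50% copies (~13%);
the dose-response curve is shallower at mild knockdown — a residual of
reconstructing rate tables that are not publicly available, explored and
documented during calibration. What the proxy
does not show: quantitative full-scale kinetics (the time axis is Monte
Carlo steps; no claim links it to the wet-lab day scale),
nucleosome-resolution profile shapes at 102-nucleosome scale, or
robustness to features absent from the model (other marks,
transcription, nucleosome turnover, explicit complexes).

## Degenerate inputs and numerical details

Zero copies of any species, zero pt rows (controls), pt_scale = 0 and
knockdown fractions of 0 or 1 are all valid; a two-nucleosome fiber is
the degenerate minimum (both nucleosomes are then the permanent pair).
Copy counts after knockdown round half-to-even. Probabilities derived
from anchors are clamped to [0, 1] with a warning (boosted test fixtures
trip this deliberately). Fiber folding and protein placement are
rejection samplers with explicit retry budgets; an over-crowded box
fails loudly. Self-tethered or double-counted bonds are structurally
impossible (typed slots, reciprocal pointers), and a state audit
(`System.validate_state`) checks box membership, bond reciprocity and
hard-core separation after any run.

## Limitations

* The chromatin fiber has no sequence, no nucleosome turnover, no other
  histone marks, and no transcription; the eGFP-silencing phenotype of
  the wet-lab system is outside the model.
* HP1 dimerization is pairwise (no oligomer networks beyond CSD–CSD
  bridges); large epigenetic complexes are collapsed into effective
  HMT↔CSD recruitment.
* Hydrodynamics, electrostatics and explicit solvent are absent; motion
  is overdamped Monte Carlo diffusion with excluded volume.
* The µM-scale affinity anchors are effective (avidity-corrected)
  values; the raw printed kon/koff ratio for HP1 is mM-scale and is not
  used.
* pt values are reconstructions constrained as described above, not
  measured constants; absolute time courses should be read as
  model-relative.
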