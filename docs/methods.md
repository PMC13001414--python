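# Methods

This note records the models, parameters, numerical choices and known
limitations behind `idpensemble`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The system and the questions

The study system is a 15-residue intrinsically disordered mitochondrial
localization peptide (MLP), `MEVQLGLGRVYPRPP`, together with all 19
variants obtained by substituting the glutamate at position 2. A
disordered peptide is an ensemble, not a structure, so the package asks
ensemble questions at three levels: global compactness (R_g, end-to-end
distance, SASA), residue-level secondary-structure occupancy
(Ramachandran-region statistics), and multivariate ensemble similarity
(PCA of occupancy features, distance-to-wild-type ranking). A fourth
component explores free-energy landscapes along an α-helical-content
collective variable with well-tempered metadynamics, at toy scale.

The experimental design throughout is 16 independent replicas per
variant (320 trajectory systems for the full panel), with all replica
statistics computed replica-first: per-replica means are formed before
the grand mean, and the spread (standard deviation and standard error)
is taken across replica means, never across pooled frames. For unequal
replica lengths the two disagree; replica-first is the design-respecting
estimator.

## Synthetic ensemble generator

Real replica-MD trajectories are replaced by a synthetic generator whose
*target quantities are known exactly*, so every downstream statistic can
be validated by parameter recovery.

Per interior residue (2..L−1; terminal residues have incomplete
dihedrals and are excluded everywhere), each frame draws a class from a
per-residue propensity vector over {αR, αL, β, PPII, unassigned}, then
draws (φ, ψ) from that class's basin — a wrapped bivariate normal:

| basin | center (φ, ψ) ° | σ (φ, ψ) ° |
|-------|-----------------|------------|
| αR    | (−60, −45)      | (11, 11)   |
| αL    | (60, 45)        | (11, 11)   |
| β     | (−140, 145)     | (11, 11)   |
| PPII  | (−65, 150)      | (10, 11)   |

"Unassigned" samples uniformly from the complement region by rejection.
Basin centers sit ≥ 3.3σ inside their region rectangles, so the mass a
basin leaks into a neighbouring class is ≤ ~1e-4 and the generating
weights are recovered by classification to well within binomial error —
this is what makes the round-trip tests exact in expectation.

Frames are i.i.d. — the statistics of interest are time averages, which
i.i.d. sampling reproduces in expectation. An optional first-order hold
probability (`hold_probability`) re-uses the previous frame's class to
stress-test autocorrelation sensitivity; default off.

Residue-type defaults: every residue's αR weight follows a relative
helix-propensity scale in the spirit of experimental host-guest scales
(Ala 0.30 down to Gly 0.07), with the remainder split mostly between β
and PPII (disordered baseline); glycine gains αL access (0.18 of the
remainder); proline is PPII-biased with its φ basin restricted to
−65° ± 8° and *no β weight* — the ring-restricted φ is incompatible with
the β region (φ < −100°), so proline's β mass is folded into PPII. This
keeps generator→classifier parameter recovery exact by construction for
every residue type. Position-2 variants therefore differ only through
the substituted residue's default propensities; sequence-context
coupling (neighbour effects) is *not* modelled.

Replica seeding: replica i of a run with master seed s uses seed s + i;
the pipeline gives variant v the master seed s + 1000·v. Same seed,
bit-identical output.

Coordinates are realised by natural-extension-reference-frame (NeRF)
chain building with ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°
throughout, including pre-proline — cis-proline is a documented
omission). The dihedral series carries interior residues only, so two
torsions needed for building are unspecified; they are fixed to
extended-region values (ψ₁ = 150°, φ_L = −135°). Rebuilt coordinates
reproduce the input torsions to < 1e-3°. Side chains are not built; a
CB-like pseudo-atom is placed at ideal tetrahedral geometry on
non-glycine residues. Absolute SASA values therefore sit below all-atom
values and are *not* comparable to all-atom references; they are
labelled synthetic wherever reported.

## Compactness metrics

R_g is mass-weighted by default (standard atomic masses; unit-weight
option). End-to-end distance is CA(1)→CA(L) — the most reproducible
convention when the terminal atoms are not specified. SASA is
Shrake–Rupley with Bondi radii, probe 1.4 Å, and a deterministic
golden-angle spiral lattice of 960 points per atom (configurable;
n < 32 rejected as an accuracy floor). An isolated sphere is exact at
any point count; the two-sphere case is validated against a 10⁶-point
Monte-Carlo surface integration to < 1%.

## Ramachandran classification

Five motifs via axis-aligned rectangles on the wrapped (φ, ψ) torus,
half-open (lower edge inclusive) after wrapping into (−180, 180]:

- αR: φ ∈ [−160, −20), ψ ∈ [−120, 50)
- αL: φ ∈ [20, 160), ψ ∈ [−50, 120)
- β: φ ∈ [−180, −100), ψ ∈ [100, 200) (wrapped: ψ ≥ 100 or ψ < −160)
- PPII: φ ∈ [−100, −20), ψ ∈ [100, 200) (wrapped)
- unassigned: the complement

Region boundaries differ between labs; these defaults are validated for
pairwise disjointness by a 1°-grid scan and are fully user-overridable
via a YAML region map. Every statistic in the package depends only on
the classification being a total, deterministic function — not on these
particular boundaries.

Deviation profiles are Δ = variant replica-mean − wild-type replica-mean
per residue and class, with uncertainty √(SEM_v² + SEM_wt²). SEM (not
std) is the default uncertainty because the comparison is between means
of replicas.

## PCA comparison and ranking

Feature vectors collapse the five classes to three broad ones —
helix {αR}, extended {β, PPII}, unstructured {αL, unassigned} — per
interior residue (39 columns for a 15-mer), one row per trajectory
(replica). Merging αL into "unstructured" is the conservative choice for
a three-class scheme (αL is a minority class for non-glycine residues);
the grouping is a configurable partition. Columns are centered but not
standardized (occupancies are already commensurate fractions; an option
exists). PCA is a full SVD; component signs are fixed by making each
component's largest-magnitude loading positive, so runs are
reproducible. Rank-0 input (all rows identical) yields zero explained
variance and all-zero scores rather than an error.

Ranking projects every trajectory into the first k = 2 components,
averages replicas per variant in projected space (identical, by
linearity, to projecting the mean row), and sorts by Euclidean distance
from the wild-type mean; ties break alphabetically. PCA is fitted on
trajectory rows, with means projected afterwards — fitting on means
instead is available by passing averaged profiles.

## Toy well-tempered metadynamics

The collective variable is a smooth per-residue membership bump around
the αR center, exp(−Δφ²/2σφ²)·exp(−Δψ²/2σψ²) with σ = 15°, averaged over
interior residues — a differentiable proxy for α-helical content whose
≥ 0.5 level set lies inside the αR region of the default classifier.

Dynamics are overdamped Langevin on 1-D model landscapes s ∈ [0, 1]
(reflecting boundaries), with Gaussian hills deposited every
`deposit_stride` steps at well-tempered heights
h_dep = h·exp(−V(s)/k_B ΔT), ΔT = (γ−1)T, and PMFs reconstructed from
the accumulated bias at trajectory fractions f as
F(s) = −((T+ΔT)/ΔT)·V^(f)(s), min-shifted. Units: kcal/mol, T = 310 K.
The bias and its gradient live on a dense grid (2001 points) with linear
interpolation; the PMF grid default is 400 points. An empirical
landscape can also be built from the helicity values of a synthetic
ensemble (−kT log histogram), letting the machinery run on the CV
itself.

The package-wide default bias factor is γ = 10. The double-well
benchmark (minima at 0.2/0.8, barrier 3 kcal/mol, tilt 1 kcal/mol) uses
γ = 6, chosen by the standard rule of thumb k_B ΔT ≈ barrier height;
its protocol is 2×10⁶ steps, dt 1e-3, D = 0.05, hills h = 0.1, w = 0.05,
stride 400. Basin free-energy differences are measured by Boltzmann
integration of the PMF on either side of the barrier and compared with
numerical quadrature of the analytic landscape; because single-run WTM
estimates fluctuate (per-seed SD ≈ 0.2 k_BT under this protocol), the
recovery check averages over 5 seeds.

Convergence diagnostic: PMFs at fractions (0.25, 0.5, 0.75, 1.0) are
aligned by their mean over the low-free-energy window of the final PMF
(cutoff 3 k_BT above the minimum) and summarised by RMS deviation from
the final profile over that window. Non-convergence is flagged when the
last-quarter RMS (the largest fraction below 1) exceeds a threshold,
default 0.3 kcal/mol. The threshold was calibrated on control runs:
converged double-well runs sit at ≤ ~0.17 kcal/mol, while the
insufficient-CV counterexample sits at ≥ ~0.57.

The insufficient-CV counterexample adds a slow binary coordinate z the
bias cannot see: the landscape's tilt flips sign with z
(±2.5 kcal/mol·s). Stochastic hopping of z is supported, but a purely
stochastic demonstration is unreliable *for a physical reason*: if the
hops happen early, well-tempered damping freezes the PMF and the run
looks converged. The shipped counterexample therefore flips z once,
deterministically, at 70% of the run — a quasi-static slow mode — which
raises the flag for every seed tested.

Schedule comparison: at equal hill counts an independent fine-hill run
(h = 0.1, w = 0.01) deposits ~25× less bias volume per hill than a
coarse run (h = 0.5, w = 0.05) and cannot fill the landscape, so the
meaningful comparison is sequential — a coarse stage continued by a fine
refinement stage (`langevin_wtm(initial_trace=...)`), mirroring how
coarse-then-fine protocols are used in practice. On a rugged variant of
the double well (two barrier spikes of width 0.012–0.015, below the
coarse hill width), the refined schedule lowers the final convergence
RMS several-fold relative to coarse-only at equal total hill count; the
test asserts this as a mean over seeds.

## Problem sizes

Defaults were chosen so the entire pipeline runs comfortably on a single
CPU: the occupancy/PCA stages use the full study design (20 variants ×
16 replicas × 1000 frames — dihedral-level only, no coordinates needed);
coordinate-level compactness uses 16 × 25 frames with SASA on every 5th
frame; the end-to-end demo config uses 4 replicas × 200 frames. These
are package defaults, all configurable.

## Known limitations

- Frames are i.i.d.; kinetic or autocorrelation-dependent quantities are
  out of scope.
- No side chains, solvent, or force-field energetics; compactness values
  are backbone+pseudo-CB quantities, not comparable to all-atom data.
- Sequence effects enter only through per-residue default propensities;
  no neighbour coupling, cis-proline, or charge interactions.
- The WTM engine is 1-D (plus one hidden mode) and desk-scale; it
  illustrates estimator behaviour and diagnostics, not peptide
  thermodynamics.
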