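# glycopmf

Umbrella-sampling free-energy reconstruction and sugar-ring puckering
analysis for glycoside hydrolase reaction trajectories.

## The problem

Inverting glycoside hydrolases (e.g. processive cellobiohydrolases) cleave
the glycosidic C1–O4 bond through a single-displacement mechanism: a general
acid protonates the leaving-group oxygen while a water molecule, activated by
a general base, attacks the anomeric carbon through an oxocarbenium-like
transition state. Simulation studies of such reactions produce two
characteristic data streams:

1. **Biased samples of a reaction coordinate.** The cleavage distance
   RC2 = d(C1, O4) is restrained in a ladder of harmonic umbrella windows;
   the potential of mean force (PMF) G(ξ) is recovered by the weighted
   histogram analysis method (WHAM), which solves the self-consistency
   equations

       P(ξ) = Σⱼ nⱼ(ξ) / Σⱼ Nⱼ exp[(Fⱼ − wⱼ(ξ))/k_BT]
       Fⱼ   = −k_BT ln Σ_ξ P(ξ) exp(−wⱼ(ξ)/k_BT)

   with harmonic biases wⱼ(ξ) = ½ kⱼ (ξ − cⱼ)². The quantities of interest
   are the landmarks of G: the reactant and product minima, the position of
   the interior maximum, the barrier height and the reaction free energy.

2. **Ring geometries of the catalytic-centre sugar.** The distortion of the
   −1-subsite pyranose is quantified by Cremer–Pople puckering coordinates
   (Q, θ, φ) and their Stoddart projections q_x = Q sinθ sinφ,
   q_y = Q sinθ cosφ; conformers are named by the nearest canonical vertex
   (⁴C₁ chair, ¹S₃ skew-boat, ²,⁵B boat, envelopes, half-chairs) on the
   puckering sphere, tracing the conformational itinerary
   ¹S₃ → ²,⁵B → ⁴C₁ across the reaction.

`glycopmf` implements both analyses as a tested, reusable library, together
with the geometric monitors that accompany them (composite reaction
coordinates, hydrogen-bond criteria, bond-vs-ring-plane axiality angles,
Kabsch superposition RMSD) and a synthetic surrogate generator that stands in
for the expensive QM/MM engine: an analytic free-energy surface through
prescribed landmark values, sampled by overdamped Langevin dynamics, and an
idealized ring-geometry stream following the conformational itinerary.

## Worked example

`examples/umbrella_wham.py` samples 42 umbrella windows (k = 500 kcal/mol/Å²,
10,000 + 10,000 Langevin steps each, 300 K) on a surrogate surface
constructed through the landmarks (1.5 Å, 0), (2.17 Å, 19) and
(3.2 Å, 5 kcal/mol), then unbiases and extracts the landmarks:

```
sampled 42 windows x 10000 production steps
WHAM converged in 5250 iterations (420000 samples in 118 bins)
reactant minimum :  1.500 A   (constructed at 1.50)
transition state :  2.174 A   (constructed at 2.17)
product minimum  :  3.194 A   (constructed at 3.20)
barrier          :  18.78 kcal/mol (constructed 19.0)
reaction dG      :   4.88 kcal/mol (constructed  5.0)
```

The recovered landmarks agree with the construction values to a few
hundredths of an Å and a few tenths of a kcal/mol — the statistical accuracy
of the finite sampling — validating the window generation, WHAM unbiasing
and landmark extraction end-to-end. `examples/puckering_itinerary.py` runs
the ring analysis on a synthetic trajectory and prints the per-region
conformer populations (93% ¹S₃ in the reactant region, 68% ²,⁵B near the
transition state, 94% ⁴C₁ in the product region);
`examples/reaction_coordinates.py` and `examples/reproducibility.py` show
the geometric monitors and the replicate-to-replicate profile spread.

A thin CLI chains the same stages on files
(`glycopmf simulate | wham | pucker | rc | report`); every artifact is a
TSV/JSON file with a provenance header (version, seed, config hash).

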