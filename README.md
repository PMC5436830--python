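# mgatp

Trajectory analysis and free-energy estimation for Mg²⁺–ATP binding sites,
built around the question of why removing two arginines from the ε subunit
of bacterial F₁Fₒ-ATP synthase (the R103A/R115A double mutant of the
thermophilic *Bacillus* PS3 protein) *increases* ATP affinity by roughly two
orders of magnitude.  The package re-implements, as a tested and reusable
library, the analysis layer that sits on top of molecular-dynamics output:

* **Hydrogen-bond network analysis.**  A bond is a donor–H···acceptor triple
  with d(H···A) ≤ 2.7 Å and a deviation from D–H···A linearity ≤ 30°.
  Networks are scored per frame with the empirical exponential relation

      E_HB = −502·10³ · exp(−3.6 · d(H···A))  [kJ/mol]

  summed over all detected bonds and reported as a magnitude in kcal/mol.
  Two partitions are scored separately: protein↔ATP bonds, and bonds linking
  the second C-terminal α-helix (residues 112–133, the segment that swings
  from the down- to the up-state on ATP release) to the rest of the protein.
* **Mg²⁺ coordination classification.**  From the minimal distances of the
  ion to the non-bridging α/β/γ-phosphate oxygens (Oα = {O1A, O2A},
  Oβ = {O1B, O2B}, Oγ = {O1G, O2G, O3G}), each frame is labelled
  first-sphere Oα/Oβ, first-sphere Oβ/Oγ, second-sphere (water-bridged) or
  unbound.  Repulsive contacts count binding-site Arg/Lys cationic atoms
  within 4.5 Å of the cation.
* **Free-energy estimators.**  Bennett acceptance ratio (BAR) from
  forward/backward work samples, solved to machine precision with a
  bracketed root finder, with the asymptotic (inverse-Fisher) standard
  error; thermodynamic integration (TI) as trapezoidal quadrature of
  per-window mean ∂H/∂λ after a per-window equilibration discard; a
  time-slice convergence check that re-runs the estimator on early and late
  parts of each window.
* **Replica statistics.**  Independent runs are reduced to run means first;
  reported values are mean ± sample SD (n−1) across run means.
* **Synthetic data.**  Because no trajectories are deposited for this
  system, a generator plants hydrogen bonds at exact distances/angles, a
  Mg²⁺ ion in a chosen coordination state, cationic contacts at chosen
  ranges, and Gaussian positional jitter — plus Crooks-consistent Gaussian
  work samples and closed-form ∂H/∂λ profiles — so every analysis stage has
  inputs with known ground truth.

## Worked example

```python
from mgatp.energetics import frame_ehb
from mgatp.hbonds import protein_atp_hbonds, helix_rest_hbonds
from mgatp.synthetic import build_site_trajectory, default_site_config

trajectory, truth = build_site_trajectory(
    default_site_config("wild_type", n_frames=5, jitter_sigma=0.02, seed=1))
frame = trajectory.frames[0]
pa, hx = protein_atp_hbonds(frame), helix_rest_hbonds(frame)
print(len(pa), len(hx), round(frame_ehb(pa), 1))
```

prints `9 5 1026.5`: the nine planted protein–ATP bonds and five
helix-network bonds are recovered, and the protein–ATP network scores
1026.5 kcal/mol in this jittered frame (with this prefactor a
single 1.9 Å bond already contributes ≈ 130 kcal/mol).  The
`examples/` directory holds one short script per capability — bond
detection and scoring, coordination classification, BAR/TI estimation, and
the full wild-type vs mutant comparison with its table:

```
                                 wild_type (...)   mutant (...)
h-bonds (protein-ATP)              9.0 +/- 0.0     10.0 +/- 0.0
repulsive contacts                 2.0 +/- 0.0      1.0 +/- 0.0
E_HB                            1502.1 +/- 27.7  1601.1 +/- 27.3
```

The mutant gains a protein–ATP bond and loses a repulsive contact, so its
binding-energy penalty ΔE_HB = E_HB(mutant) − E_HB(wild type) is positive —
the qualitative signature the analysis is designed to expose.  A thin CLI
(`mgatp simulate|hbonds|helix|contacts|mgstate|ehb|bar|ti|compare`) wraps
the same calls for shell use.

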