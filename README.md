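# aquaperm

Single-channel water permeability analysis for molecular-dynamics
trajectories of membrane water channels (aquaporin-style single-file pores).

Given an equilibrium trajectory and a per-monomer channel definition (two
constriction-region boundary atoms, an axis, a lateral cutoff), the package
computes the two single-channel permeability constants and the descriptors
that usually accompany them:

- **p_d — diffusive permeability.** Complete permeation events (a water
  entering the constriction region through one axial boundary and leaving
  through the opposite one) are counted into N₊, N₋ and N± = N₊ + N₋; the
  unidirectional rate constant is k₀ = N± / (2 n_m t_sim) for n_m monomers
  and analyzed time t_sim, and p_d = v_w k₀, with v_w = V_w/N_A ≈
  2.99×10⁻²³ cm³ the volume of one water molecule.
- **p_f — osmotic permeability**, from the collective diffusion model: the
  collective coordinate n(t) accumulates dn = Σᵢ dzᵢ / L̄ over the waters in
  the constriction region of average length L̄; at equilibrium ⟨n²(t)⟩ =
  2 D_n t over multiple time origins, and p_f = v_w D_n.
- **p_f/p_d — "single-fileness".** For a perfect single file of N waters the
  continuous-time random-walk model gives p_f/p_d = N + 1; water–water
  interchange pushes the ratio toward 1.
- Channel **occupancy** histograms, HOLE-style **pore-radius profiles**
  (largest clearance sphere centered in each axial plane), z-resolved water
  **dipole order parameters** P₁(z) = ⟨cos θ⟩ and P₂(z) = ⟨(3cos²θ−1)/2⟩,
  and Cα-RMSD/RMSF/average-structure metrics.

Because production MD trajectories of channel proteins are rarely
redistributable, the package ships a Gillespie **single-file channel
simulator** with exact transport ground truth (event log, k₀ = k/(N+1),
D_n = (1−q)k + qk/N for interchange probability q), used to validate every
estimator end to end.

## Worked example

Synthesize a 4 ns single-file channel (5 sites, 2 ps frames) and run the
full pipeline:

```yaml
# cfg.yaml
synthetic:
  n_sites: 5
  n_frames: 2001
  rng_seed: 3
seed: 3
```

```bash
aquaperm report --config cfg.yaml --out-dir out
```

prints the summary table (permeabilities in 10⁻¹⁴ cm³ s⁻¹):

```
quantity	mean_sd	A
p_d (1e-14 cm3/s)	1.1 +/- nan	1.1
p_f (1e-14 cm3/s)	4.2 +/- nan	4.2
<N>	5.0 +/- nan	5.0
p_f/p_d	3.8 +/- nan	3.8
L (A)	14.0 +/- nan	14.0
```

The channel holds exactly ⟨N⟩ = 5 waters over a constriction region of
L̄ = 5 × 2.8 Å = 14 Å. The single-file model predicts p_f/p_d → N + 1 = 6;
a 4 ns run recovers 3.8 because only a handful of permeation events occur
(the SD column is `nan` with a single monomer — the aggregate needs at
least two). Longer runs and more monomers tighten both estimates; the
acceptance suite demonstrates recovery within 25 % on a 200 ns tetramer.
`out/` additionally contains the event table, cumulative N₊/N₋/N± series,
occupancy histograms and orientation profiles as TSV, and the full-precision
`report.json`.

The same pipeline runs on file-based input (`trajectory: {pdb: ..., xyz:
..., frame_interval: ...}` plus a `channels:` list with boundary-atom
selectors such as `"name=O and resnum=195 and chain=A"`). Subcommands
`simulate`, `permeability`, `occupancy`, `orientation`, `radius` and `rmsd`
expose individual stages; everything is also importable
(`import aquaperm`).

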