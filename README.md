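# tcrmsm

Kinetic characterisation of T-cell receptor CDR3 loop ensembles and their
coupling to the relative Vα-Vβ interdomain orientation.

## The problem

The CDR3 loops of a TCR — the hypervariable loops that contact the peptide —
do not hold a single canonical conformation in solution: they interconvert
between metastable states on micro-to-millisecond timescales, and which
loop state the receptor occupies shifts the packing angle between its two
variable domains (Vα and Vβ), and with it the geometry of the antigen
binding site. Characterising that ensemble takes a pipeline of enhanced
sampling, kinetic modelling, and state-conditioned geometry:

1. **Featurization** — backbone φ/ψ dihedrals of the CDR3α and CDR3β loops,
   embedded periodically as (sin θ, cos θ) pairs; a metadynamics collective
   variable s = Σᵢ aᵢ sin ψᵢ + Σᵢ bᵢ cos ψᵢ over the loop ψ angles.
2. **Well-tempered metadynamics** (toy engine) — hills of height
   h = h₀ exp(−V_bias/((γ−1)k_BT)) deposited every 1,000 steps (γ = 10,
   300 K), free energy recovered as F(s) = −γ/(γ−1)·V_bias(s).
3. **Seed clustering** — average-linkage hierarchical clustering of
   pairwise post-superposition RMSD with a 1.2 Å cutoff; medoids are the
   seed structures for production clones.
4. **tICA** — slowest linear collective motions from the generalized
   eigenproblem C(τ)v = λC(0)v at lag τ = 10 ns; free-energy landscapes by
   Boltzmann inversion, F = −k_BT ln ρ.
5. **Markov-state model** — k-means microstates (150 at production scale),
   reversible maximum-likelihood transition matrix on the largest connected
   set, implied timescales tᵢ = −τ/ln λᵢ, mean first-passage times, PCCA+
   macrostates, Chapman-Kolmogorov validation.
6. **State-conditioned geometry** — the interdomain orientation as the
   torsion over four centers of mass, COM(CDR loops, α) → COM(Vα) →
   COM(Vβ) → COM(CDR loops, β); one angle distribution per macrostate;
   two-sample Kolmogorov-Smirnov comparisons; per-residue RMSF.

Everything runs end to end on synthetic trajectories with known ground
truth (module `tcrmsm.synthetic`): hidden-Markov dihedral dynamics realised
as toy backbones, and rigid two-domain assemblies with prescribed
interdomain torsions. Real structures enter through standard PDB files and
user-supplied chain/residue-range selections.

## Worked example

```python
import numpy as np
from tcrmsm import clustering, featurize, msm, state_analysis, synthetic, tica

# a two-domain assembly whose loop state sets the interface angle
spec = synthetic.TwoDomainSpec(
    targets_deg=[40.0, 60.0],
    label_transition_matrix=[[0.98, 0.02], [0.02, 0.98]],
    angle_sigma_deg=5.0,
    loop_psi_means=np.array([[-60.0] * 5, [120.0] * 5]),
    loop_sigma_deg=10.0, n_frames=20_000, seed=2024,
)
traj, labels = synthetic.generate_two_domain_trajectory(spec)

fm = featurize.psi_phi_features(traj, spec.loop_selections(), angles=("psi", "phi"))
model = tica.fit_tica(fm, lag=10.0, n_components=2)
dtraj, centers, _ = clustering.kmeans(tica.project(model, fm), 100, seed=515)
mm = msm.estimate_msm(dtraj, 10, 1.0)
macro = msm.pcca_plus(mm, 2)
print(mm.timescales(1)[0], macro.macro_stationary)

r = spec.region_selections()
angles = featurize.interdomain_torsion(
    traj, r["cdr_alpha"], r["v_alpha"], r["v_beta"], r["cdr_beta"])
pos = {s: i for i, s in enumerate(mm.active_set)}
frame_macro = np.array([macro.crisp_assignment[pos[m]] for m in dtraj.states])
for d in state_analysis.macrostate_angle_distributions(angles, frame_macro):
    print(d.macro, d.n, round(d.mean, 1), round(d.variance, 1))
```

prints (numbers from this exact run):

```
22.58744754940419 [0.41851937 0.5814806 ]
0 9872 60.1 25.2
1 10128 40.0 24.1
```

The slowest implied timescale (≈22.6 ns) matches the hidden label chain's
relaxation time (−1/ln 0.96 ≈ 24.5 ns); the two PCCA+ macrostates carry
interface-angle distributions centred on the prescribed 60° and 40° targets
with the prescribed 5° spread, and a KS test between them rejects equality
at machine-zero p — the coupling between loop state and interdomain
orientation is recovered from the trajectory alone.

The same steps are laid out as a narrative analysis in `analysis/01…06`
(simulation, toy metadynamics, seed clustering, tICA landscape, MSM and
macrostates, interdomain angles), each writing its tables under `results/`.
A thin CLI mirrors the stages: `tcrmsm run-all config.json`, plus
`simulate`, `featurize`, `cluster-seeds`, `tica`, and `msm` subcommands.

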