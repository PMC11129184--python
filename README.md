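# memallo

Trajectory-analysis toolkit for studying how membrane lipids — cholesterol in
particular — modulate the gating of pentameric ligand-gated ion channels
(pLGICs) such as the glycine receptor. Starting from molecular-dynamics
trajectories (XTC/DCD + PDB/GRO) it answers four questions that recur in
lipid-modulation studies:

1. **Which residues are allosteric hotspots?** Perturbation response
   scanning (PRS) over a trajectory-derived covariance matrix.
2. **Where do lipids accumulate?** Time-averaged 3D occupancy grids at 1 Å
   resolution with a ≥50 %-of-frames reporting filter, exported as OpenDX.
3. **Where and how long do lipids bind?** Dual-cutoff contact events,
   survival-curve residence times, and co-occurrence clustering of residues
   into binding sites with representative poses.
4. **What holds the lipid in place?** Atomistic hydrogen-bond/hydrophobic
   interaction fingerprints, named atom-pair distance series, RMSD series,
   and a simple pore-radius profile.

A first-class synthetic-data module generates trajectories with *planted*
ground truth (prescribed covariances, exponential dwell-time kinetics,
exact hydrogen-bond geometries), so the whole pipeline is testable without
downloading microsecond simulations. It also hosts the mole-percent
calculator for the asymmetric neuronal membrane mimic used in such studies.

## The methods

**Perturbation response scanning.** Each Cα atom is a node; the 3N×3N
positional covariance C is estimated from superposed frames. Linear response
theory relates a constant external force **F** applied at one node to the
expected displacement **ΔR** = C·**F**. Each node is probed with many random
unit force directions (1000 directions × 5 repeats by default), and each
response is scored against a target conformational change **ΔS** (e.g. the
closed→open displacement between experimental structures) by the absolute
cosine overlap

    O_i = max over forces of |ΔR·ΔS| / (|ΔR|·|ΔS|)   ∈ [0, 1]

Residues with O_i ≥ 0.6 are reported as candidate hotspots. A closed-form
optimal-force solution (f\* ∝ (CᵢᵀCᵢ)⁻¹CᵢᵀΔS for the node's 3N×3 column
block Cᵢ) is provided and serves as the oracle for the random scan.

**Residence times.** A contact opens when the lipid–residue minimum
distance drops below r_on (4.75 Å) and closes only above r_off (7 Å) —
hysteresis that suppresses boundary flicker. Event durations feed an
empirical survival curve S(t); the residence time is 1/k from a log-linear
least-squares fit of S (mean duration below 5 events). Residues are
clustered into sites when the same lipid contacts both members in ≥50 % of
the frames where either is contacted.

**Occupancy.** A voxel's value is the fraction of frames in which ≥1
selected lipid particle falls inside it; the reporting filter keeps voxels
≥0.5, optionally restricted to within 6 Å of the protein.

## Worked example

Plant a soft collective mode on residue 8 of a 20-residue chain, sample
10 000 frames, and ask PRS to find it:

```python
import numpy as np
from memallo import prs, synthetic

n, planted = 20, 7                       # 0-based node -> residue 8
u = np.zeros(3 * n); u[3*planted:3*planted+3] = 1.0
u /= np.linalg.norm(u)
spec = synthetic.GaussianEnsembleSpec(
    n_residues=n,
    mean_coords=np.column_stack([np.arange(n)*3.8, np.zeros(n), np.zeros(n)]),
    covariance_builder=synthetic.Spiked(sigma2=0.01, lam=1.0, u=u),
    n_frames=10_000, seed=1,
)
traj, _ = synthetic.generate_gaussian_ensemble(spec)

C = prs.compute_covariance(traj, "name CA", align=False)
target = prs.DisplacementField(u, C.node_resids)
profile = prs.scan(C, target, n_directions=1000, n_repeats=5, seed=1)
for chain, resid, o in prs.rank_hotspots(profile, threshold=0.6):
    print(f"{chain}:{resid}  O_i = {o:.3f}")
```

prints

```
A:8  O_i = 1.000
```

— the planted residue is the only node whose best-force response overlaps
the target above the 0.6 hotspot threshold, with an overlap of 1.0 because
the soft mode is entirely localized there.

The same study end-to-end from a shell (`simulate → occupancy → sites →
prs` on synthetic data with planted truth):

```bash
memallo run --seed 11 --out run/
```

The emitted `run/report.json` compares every estimate to its planted value;
with seed 11 the sites stage reports the planted four-residue cluster
recovered exactly (`"top_site_residues": [1, 2, 3, 4]`) with a site
residence time of 77.5 ns against a realized planted segment mean of
75.8 ns, and the PRS stage ranks the planted residue 8 first with overlap
1.000. Individual stages are also available as `memallo occupancy`,
`memallo sites`, `memallo fingerprint`, `memallo distance`, `memallo rmsd`,
`memallo pore` and `memallo prs` on your own trajectories.

Membrane recipe arithmetic:

```python
from memallo.synthetic import (LeafletComposition, mole_percents,
                               NEURONAL_INNER_LEAFLET)
mole_percents(LeafletComposition(NEURONAL_INNER_LEAFLET))
# {'CHOL': 43.3, 'POPC': 13.4, 'POPE': 21.6, 'DOPS': 16.5, 'PIP2': 2.1, 'SM': 3.1}
```

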