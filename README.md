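# mdcoord

Comparative analysis of molecular-dynamics trajectories of multidomain
receptors, built around the question: *how does a bound ligand reshape a
protein's internal dynamics?*  The motivating system is the αvβ3 integrin
ectodomain head bound to the 10th type-III fibronectin repeat — wild-type
(agonist) versus a high-affinity tryptophan mutant (antagonist) — where the
functional difference shows up not as a large conformational transition but
as a redistribution of coordinated fluctuations, domain orientations and
local interaction networks.

`mdcoord` implements that analysis stack as a reusable, tested library:

- **Distance fluctuations (DF).** For residues *i, j* with Cα distance
  *r<sub>ij</sub>*, `DF_ij = ⟨(r_ij − ⟨r_ij⟩)²⟩` over trajectory frames.
  Low DF marks mechanically coordinated pairs; the matrix is invariant
  under rigid motion and vanishes on rigid subsets.  Replica matrices are
  averaged.  Per-residue RMSF with replica spread is included.
- **Essential dynamics (ED).** Covariance PCA of the 3N Cα coordinates:
  eigenvalues (Å²), orthonormal modes, per-frame projections, variance
  fractions, plus sampling diagnostics — split-half essential-subspace
  overlap (RMSIP) and per-mode cosine content.
- **Generalized correlations.** Kraskov–Stögbauer–Grassberger k-nearest-
  neighbour mutual information (variant 1, Chebyshev norm, k = 6) between
  3-D displacement series, mapped to `r_MI = √(1 − exp(−2I/3))`, which
  equals |ρ| for jointly Gaussian motions and is orientation-insensitive.
- **Geometric descriptors.** Radius of gyration, tagged pair distances
  (including HETATM metal particles such as Mn²⁺ at the MIDAS/ADMIDAS
  sites), domain principal axes and the inter-domain torsion angle,
  aromatic ring centroid distance and interplanar angle θ with
  pairing (< 12 Å) and stacking ([4.9, 10.4] Å, [1.2°, 89.9°]) windows,
  and H-bond / salt-bridge occupancies.
- **GROMOS clustering.** Greedy neighbour-count RMSD clustering with
  central structures and populations (0.2 / 0.3 nm cutoff presets).
- **Gaussian network model.** Kirchhoff slow modes, Bruschweiler
  collectivity `κ = (1/N)·exp(−Σ p_i ln p_i)`, per-domain mode
  contributions and a contact-cutoff sensitivity report.
- **Synthetic generators.** Gaussian ensembles with prescribed block
  covariance, rigid hinges with a known torsion sweep, ideal aromatic ring
  pairs, and two-state switches with known populations — every analysis is
  validated against ground truth known by construction.

I/O covers PDB (fixed-column, altloc policy, author numbering), DCD and XTC
(via MDAnalysis; XTC nanometres converted to the internal Å unit), and a
small selection language (`"chain B and resid 55-108 353-434 and name CA"`).

## Worked example

```python
import numpy as np
import mdcoord as m

# two-domain receptor; domain B hinges about the inter-centroid axis
structure = m.make_two_domain_structure()
hinge = m.HingeSpec(structure=structure, domain_b_indices=tuple(range(40, 80)),
                    axis_point=(0, 0, 0), axis_dir=(1, 0, 0),
                    amplitude_deg=30.0, n_frames=400, seed=0, noise_sigma=0.3)
traj = m.generate_hinge_trajectory(hinge)

ca = m.resolve_selection(structure, "name CA")
dom_a = m.resolve_selection(structure, "chain A")
dom_b = m.resolve_selection(structure, "chain B")

fitted = m.superpose_trajectory(traj, structure, dom_a)
dfm = m.df_matrix(fitted, ca)
print(f"intra-domain DF (median): {np.median(dfm.matrix[:40, :40]):.3f} A^2")
print(f"inter-domain DF (median): {np.median(dfm.matrix[:40, 40:]):.3f} A^2")

tor = m.interdomain_torsion_series(fitted, dom_a, dom_b)
print(f"torsion range: {np.ptp(tor.values):.1f} deg (imposed sweep: 60.0 deg)")

ed = m.fit_pca(fitted, ca)
print(f"variance in first two modes: {ed.variance_fractions[:2].sum():.1%}")
diag = m.split_half_diagnostics(fitted, ca)
print(f"cosine content of mode 1: {diag.cosine_contents[0]:.2f}")
```

prints

```
intra-domain DF (median): 0.181 A^2
inter-domain DF (median): 3.392 A^2
torsion range: 60.4 deg (imposed sweep: 60.0 deg)
variance in first two modes: 97.8%
cosine content of mode 1: 0.72
```

Read: residues within a rigid domain stay coordinated (DF ≈ 0.18 Å², pure
thermal jitter) while cross-domain pairs fluctuate an order of magnitude
more; the measured torsion range recovers the imposed ±30° sweep; almost
all variance sits in the two hinge modes; and the high cosine content
correctly flags the slow, sweep-like mode as unconverged sampling.

The same analyses run end-to-end from a YAML configuration over real
topology + trajectory files:

```sh
mdcoord all --config run.yaml --out results/ --seed 0 --log-level info
mdcoord df --config run.yaml        # a single stage
```

producing per-system DF/LMI matrices (TSV), RMSF and ED projections (CSV),
descriptor series and histograms, contact occupancy tables, cluster
assignments, GNM mode tables, cross-system DF difference matrices, and a
JSON manifest (parameters, seeds, input digests) that reconstructs the run.

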