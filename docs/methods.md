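# Methods

This note documents the models and procedures implemented in `mdcoord`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open.

## Units, numbering, structure model

Internal units are Ångström everywhere; nanometres appear only at format
boundaries (XTC stores nm and is converted on read) and in reports that
conventionally use nm (cluster cutoffs, cross-structure RMSDs).  Residues
are identified by author (PDB) numbering with the insertion code part of
the residue key, so labels like β3 Y122 or FN W1496 read exactly as in the
structural literature.  The PDB reader keeps altloc 'A' or blank and logs
the number of dropped alternate locations; malformed mandatory columns
raise an error naming the line.  HETATM records (e.g. Mn²⁺ at the
MIDAS/ADMIDAS/LIMBS sites) are first-class atoms and resolvable by the
same `chain:resid:name` labels as protein atoms.

## Superposition and RMSD

Rigid-body fits use the Kabsch algorithm with SVD sign correction, so the
rotation is always proper (det = +1): a mirror-image frame is never
matched by reflection.  Degenerate SVD spectra are resolved by the
ascending singular-value order of the backend; fits require at least three
non-collinear atoms.  Superposition is idempotent to < 1e-8 Å and never
increases the fit-set RMSD.  For cross-crystal comparisons Cα atoms are
paired by (chain role, author residue number) intersection and unpaired
residues are dropped; insertion-coded residues are excluded from pairing.
Published cross-crystal RMSD values rarely state their pairing convention,
so the corresponding checks carry a ±0.03 nm tolerance.

## Distance fluctuations

`DF_ij = ⟨(r_ij − ⟨r_ij⟩)²⟩` with the population convention (divide by F),
matching the time-average reading of the brackets.  Accumulation is
streaming (two moments per pair), O(N²) memory and O(F·N²) time; the
two-moment form costs ~1e-13 Å² of cancellation noise at protein scale,
which the tests treat as the numerical floor.  Multi-replica matrices are
the arithmetic mean of per-replica matrices rather than a concatenation:
independently equilibrated replicas can sit at offset mean geometries, and
concatenation would book that static offset as fluctuation.  (The choice
is switchable by analysing replicas individually.)
RMSF is √⟨|x − ⟨x⟩|²⟩ per atom on superposed frames, reported per residue
via the Cα, with mean and standard deviation across replicas.  A gross
(>10 Å) deviation of a replica's mean from the reference triggers an
unfitted-trajectory warning.

## Essential dynamics

Mass-unweighted covariance of the 3N Cα coordinates over pooled,
pre-superposed replica frames; exact symmetric eigen-decomposition (dense
`eigh`, adequate to N ≈ 1100 nodes); eigenvalues clamped at zero and
sorted descending; eigenvector sign fixed by making the largest-magnitude
component positive.  Projections are `(x − mean)·v_k`; on the fitting
ensemble their variance equals the eigenvalue exactly.  Sampling
diagnostics follow the standard practice: split-half RMSIP of the top-m
essential subspaces, and the discrete cosine content
`c_k = (2/T)(Σ_t cos(kπ(t+½)/T) p_t)² / Σ_t p_t²`.  The half-sample offset
makes the discrete cosine sum exactly zero over the window, so a constant
projection scores 0 and a pure k-half-period cosine scores 1 — the two
limit cases used as anchors.  Note that when leading eigenvalues are
degenerate (as in isotropic synthetic ensembles, where every atom-space
eigenvalue appears once per Cartesian axis) the individual eigenvectors
are arbitrary within the degenerate subspace; subspace overlap is the
meaningful convergence measure there, taken over the full degenerate set.

## Generalized correlations

Mutual information between per-atom 3-D displacement series (about each
atom's time mean, on superposed frames) is estimated with the KSG
variant-1 estimator: Chebyshev norm in the joint space, k = 6 neighbours
by default, natural log, marginal counts with the strict `< ε_i`
inequality, small negative estimates clamped to zero.  Exact duplicate
samples collapse the k-th neighbour distance to zero; the default policy
breaks them with a deterministic jitter of 1e-10 of the coordinate scale
(an error can be requested instead).  The correlation scale is
`r_MI = √(1 − exp(−2I/d))` with d = 3 for displacement vectors, which
equals |ρ| for jointly Gaussian data; identical series (infinite true MI,
finite-sample estimate saturating near ψ(N) − ψ(k)) are reported as
exactly 1.  Replica matrices are averaged.  Cost is O(pairs · F log F);
the default stride caps the frames per pair at 2000 and is logged.

## Geometric descriptors

Rg is unweighted.  Domain principal axes are gyration-tensor eigenvectors
in descending-extent order.  For the inter-domain torsion the axis sign is
set against body-internal reference vectors (last−first atom, falling back
to first-atom−centroid): a lab-frame sign rule would flip arbitrarily
under per-frame rigid motion, while the body-fixed rule makes the torsion
series exactly invariant under it and continuous across frames.  The
torsion itself is the dihedral (tip_a, centroid_a, centroid_b, tip_b) with
tip = centroid + first axis, reported as a magnitude in [0°, 180°] — a
declared operationalization of "the torsion angle between the domains'
principal axes", which visualization packages implement with unstated
conventions; absolute values are therefore trajectory-convention-dependent
and only ranges are compared against constructions.

Aromatic ring geometry: centroid = mean of ring heavy atoms (Trp uses all
9 bicyclic atoms by default; the 6-ring alone is an option — the
difference moves the centroid a few tenths of an Å, absorbed by the ±0.3 Å
tolerance on crystal comparisons); ring plane by total least squares
(smallest eigenvector of the ring-atom covariance); θ folded to [0°, 90°],
independent of atom order and normal sign.  Pairing: centroid distance
< 12 Å.  Stacking/T-shaped window: distance ∈ [4.9, 10.4] Å and
θ ∈ [1.2°, 89.9°], inclusive with a 1e-9 tolerance so exact window-edge
geometries classify inside.  Exactly parallel rings (θ = 0°) fall below
the angle window by definition.

Contacts: H-bond = donor–acceptor heavy-atom distance ≤ 3.5 Å plus
donor-H…acceptor angle ≥ 120° when hydrogens exist, distance-only
otherwise (typical for Cα/heavy-atom trajectories without force-field
hydrogens); salt bridge = any basic N (Arg NE/NH1/NH2, Lys NZ, His
ND1/NE2) within 4.0 Å of a carboxylate O (Asp OD1/OD2, Glu OE1/OE2),
scanned across a declared interface and reported per residue pair.  All
cutoffs are arguments; the defaults are the field-standard values.
Occupancy is the percentage of pooled
replica frames and is additive over frame sets by construction.

## GROMOS clustering

All-pairs RMSD with per-pair Kabsch fitting on a fit selection (default:
the analysis region itself; global-fit and no-fit variants are exposed,
since rotamer-region analyses differ between tools on whether the fit is
local or global).  Greedy partition: the frame with the most neighbours within the
cutoff seeds a cluster with all its neighbours; ties break to the lowest
frame index; repeat on the remainder.  Presets mirror the rotamer-region
use case: residues 124–131 of the β chain, cutoffs 0.2 and 0.3 nm.  The
matrix is O(F²); a hard cap (default 2000 frames) forces an explicit
stride for longer runs.  Note that a two-state fixture must switch
*internally* (e.g. a rotamer-like partial rotation): two conformers
related by a rigid motion are indistinguishable after superposition.

## Gaussian network model

Kirchhoff matrix with uniform spring constant 1 and contact cutoff 10 Å by
default (the usual GNM range; collectivity is cutoff-sensitive, so a
7–13 Å sensitivity table accompanies every single-cutoff result).  A
disconnected contact graph is an error naming the components.  "Slowest
modes" are the smallest non-zero eigenvalues after excluding the single
zero mode; their "cumulative contribution to overall mobility" is their
share of Σ_k 1/λ_k.  Collectivity is the Bruschweiler entropy measure.
Per-domain contributions are Σ u_i² over domain nodes of the normalized
mode; a full partition sums to 1.

## Synthetic data: what it emulates, what it does not

The generators stand in for microsecond multi-replica ensembles of a
two-subunit multidomain receptor (~1000 Cα, 3 replicas, thousands of
frames) that cannot be shipped or regenerated at desk scale:

- **Gaussian ensembles** prescribe the per-coordinate atom covariance
  (block variance/correlation structure, default 0.04 Å² diagonal — the
  jitter scale of a rigid core, RMSF ≈ 0.35 Å) and are sampled through the
  symmetric PSD square root; x, y, z are independent.  This reproduces
  second-moment structure (DF, PCA, MI targets) but has no time
  correlation, no anharmonicity and no actual dynamics.
- **Hinges** rotate a rigid domain about an explicit axis through a
  deterministic sinusoidal sweep `A·sin(2πt/F)` — with F a multiple of 4
  the sweep hits ±A exactly, making range recovery an exact construction
  test — with optional lab-frame noise.  Real inter-domain motion is
  neither rigid nor periodic; the fixture isolates the measurement.
- **Ring pairs** build ideal hexagons at exact (distance, θ); **switches**
  draw i.i.d. Bernoulli states, with true labels returned.

Passing these tests shows the estimators recover known ground truth under
the stated statistical model; it does not validate force fields, sampling
convergence, or any biological conclusion about real trajectories.

## Problem sizes in the shipped tests

The suite runs the estimators at the sizes where their error bounds are
meaningful and small: F = 10000 for the MI closed-form and PCA recovery
checks, F = 2000 × 50 atoms for the DF-vs-naive agreement (< 1e-10 Å²),
F = 5000 for RMSF/σ√3 recovery, 20-frame pools over 50 seeds for the
clustering oracle equality.  The acceptance script uses the same sizes.

## Known limitations

- The selection language covers chain/resid/name/resname/element
  conjunctions only; no boolean OR/NOT beyond multi-token arguments.
- The KSG estimator's O(N²) pair loop makes full-protein LMI matrices
  expensive in pure Python; stride and selection control the budget.
- H-bond detection without explicit topology relies on atom-name tables
  and cannot distinguish protonation states (His is treated as a possible
  donor/acceptor on both ring nitrogens).
- The crystal-structure checks (printed distances, ring geometry,
  cross-structure RMSDs, GNM collectivity averages) require the PDB
  entries 4MMX/4MMZ/1JV2 under `data/structures/`; the files are not
  redistributed with the package.
- DynDom-style dynamic-domain detection and trajectory-level published
  numbers (torsion ranges, variance fractions, occupancies, Mn–Mn
  distributions) depend on the original microsecond trajectories, which
  are not deposited; they are documented as context, not reproduced.
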