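# Methods

`tesgroup` implements group-level dose optimization for transcranial
electrical stimulation (tES): given lead-field models of one or more heads,
it finds electrode montages that shape the normal component of the cortical
electric field (En) toward a weighted target map, and quantifies how well
montages derived on one head (or a pool of heads) transfer to another.

## The fitness: NERNI

For a head with cortical-surface lead-field **K** (N_nodes x (N_electrodes -
1), V/m per mA; each column a bipolar injection against a fixed Cz
reference), target field t = En^trg, node weights w and electrode currents I
(mA, reference implicit), the fitness is the normalised error relative to no
intervention:

    NERNI(I) = ( ||w . t||^2 - ||w . (K I) - w . t||^2 ) / ||w . t||^2

where `.` is element-wise. NERNI = 1 for a perfect fit, 0 at I = 0, and is
unbounded below. The weights enter inside the squared norm and are therefore
effectively squared: the default target weight 10 versus off-target weight 2
is an effective 25:1 penalty ratio. The group objective is the arithmetic
mean of per-subject NERNI; it expands as NERNI_g(I) = 2 b.I - I.Q.I with Q
and b *averaged* over subjects, so group inner solves cost the same as
single-subject ones regardless of group size.

A secondary intensity metric, the area-weighted average of En over the
target region ⟨En⟩ = Σ En_i A_i / Σ A_i, uses node areas A_i equal to one
third of the summed adjacent-triangle areas. Node normals are area-weighted
averages of adjacent-triangle normals, oriented so that positive En points
into the cortex (the depolarising direction for radial pyramidal cells — an
anode above the cortex induces positive En).

## Optimization

The inner problem — optimal currents for a fixed electrode subset — is a
concave quadratic maximisation over a polytope:

- |I_e| <= 2.0 mA for every electrode, including the implicit reference
  (I_ref = -ΣI, so montages are balanced by construction);
- total injected (anodal) current, reference included, <= 4.0 mA.

The solver reformulates currents as positive/negative splits (I = p - m plus
an explicitly split reference) so all constraints become linear and SLSQP
sees a smooth concave program; the split polytope maps exactly onto the true
constraint set. The unconstrained stationary point is used directly when
feasible, otherwise SLSQP runs from a scaled warm start and from zero
(ftol 1e-12). On 2-electrode problems the solution matches a 0.001 mA grid
search to better than 1e-4 in NERNI.

The outer problem — which <= 8 electrodes to use out of the 10-10
candidates — is a genetic algorithm over binary masks with exactly
`max_electrodes` active genes: tournament selection (size 3), uniform
crossover (p = 0.5), per-gene mutation (2/n_candidates), cardinality repair
by random drop/add, elitism of 1, and termination when the best objective
improves by less than 1e-6 for 5 consecutive generations (population 3000 by
default; desk-scale runs use 100-200). Inner solutions are memoised by
subset, which makes late generations nearly free. Equal-objective subsets
tie-break to the lexicographically smallest label set, so runs are fully
reproducible from the seed. When the candidate set is no larger than the
cap, the GA degenerates to a single full-set solve (extra electrodes never
hurt a concave objective).

The electrode cap counts active non-reference electrodes; the implicit
reference obeys the 2 mA safety bound but not the cardinality budget (the
`count_reference_in_budget` option adds a zero-reference equality for the
stricter reading).

Group leave-one-out protocol: for every subject, the group objective is
optimized over the remaining subjects and the montage is evaluated on the
held-out subject. Every group montage is different because the pool varies.

## Synthetic cohort

Real MRI-derived head models are not redistributable, so cohorts are
emulated by 4-shell concentric spheres (brain/CSF/skull/scalp, outer radii
78/80/86/92 mm) with isotropic conductivities 0.40, 1.79, 0.008 and
0.33 S/m. White matter is merged into the brain shell for the forward
solution, but the volume mesh used for anatomical features keeps a distinct
WM sub-shell at 0.8 x brain radius. The forward solution is the classical
Legendre-series potential of a point current source on a layered sphere,
solved per degree by interface continuity with per-layer radius scaling for
conditioning; series order 300 keeps the relative series tail below 1e-8 at
the cortical evaluation radius across jittered geometries. Electrodes are
ideal points at 39 standard 10-10 positions constructed from spherical arcs
(midline and coronal chains in 10% steps, outer ring at 72 deg polar angle,
intermediate rows on circles through their ring and midline electrodes).

Inter-subject variability is a lognormal multiplicative factor per shell
radius (relative s.d. 0.03 by default, a realistic head-circumference
coefficient of variation), redrawn when a draw breaks the shell ordering.
Optional conductivity jitter produces repeated models of one subject that
differ only in the lead-field, for optimization under conductivity
uncertainty. The target is a circular cortical patch centred under F3
(angular radius 0.35 rad, about 23 cm^2 — the scale of the left DLPFC) with
target En 0.25 V/m and weight 10; elsewhere the target is 0 V/m with
weight 2.

What the sphere world does *not* emulate: cortical folding (all node
normals are radial, so targets are far easier to fit — synthetic NERNI
values around 0.9 rather than the ~0.2 of real cohorts), irregular target
shape, electrode-skin interfaces, and skull inhomogeneity. Passing tests
therefore validate the algorithms and their contracts, not field magnitudes
on real heads. One known consequence: on a noiseless smooth sphere the
unlimited-electrode solution keeps harvesting small off-target improvements
from arbitrarily many electrodes, so the 8-electrode optimum reaches about
98-99% of the unlimited objective rather than the >= 99% typical of folded
cortex, where the total-current bound rather than electrode count is the
limiting factor.

## Anatomical features and transfer prediction

Features per head: geodesic scalp perimeters between standard landmarks
(axial Nz-LPA-Iz-RPA, sagittal Nz-Cz-Iz, coronal LPA-Cz-RPA) and per-tissue
volumes (scalp, skull, CSF, GM, WM), plus normalised variants (distances
over the sum of the three; volumes over the total). Geodesics are edge-graph
Dijkstra paths shortened by multiscale elastic straightening (midpoint
smoothing with KD-tree-accelerated closest-point projection back onto the
surface), accurate to well under 0.5% of great-circle arcs on sphere
benchmarks. Tissue volumes sum |det|/6 over tetrahedra; the synthetic head
mesh builds nested shells from matched icosphere layers, splitting each
radial prism into three tetrahedra with minimum-vertex-rule diagonals so
neighbouring prisms conform.

Regression models relate template-minus-subject feature differences to
transferred NERNI/⟨En⟩: order-1 (linear) or order-2 designs (all squares and
pairwise products, i.e. every second-order term of every feature pair), fit
by OLS with the overall-model F test. Because spherical-head features are
exact functions of four shell radii, the full feature set is collinear;
PCA-before-regression (z-scored features, component count fixed or chosen by
leave-one-out cross-validation on prediction MSE) is the supported remedy
and the pipeline falls back to it automatically. Generalisation is measured
by leave-one-subject-out prediction; the reported R^2 is the coefficient of
determination of pooled held-out predictions.

## Statistics

Protocol conditions (personalized, group leave-one-out, template,
single-donor) are compared with pairwise paired t-tests on within-subject
differences, Bonferroni-adjusted over the number of pairs — the
repeated-measures analysis — alongside a Kruskal-Wallis omnibus test with
Dunn post-hoc z tests (rank sums, mid-rank tie correction, Bonferroni). The
pooled NERNI-versus-⟨En⟩ relationship is summarised by an OLS quadratic
(NERNI on 1, ⟨En⟩, ⟨En⟩^2): too little field underdoses, too much field
spreads beyond the target, so the fit is concave with an interior optimum.

## Problem sizes and numerical choices

Default surfaces are subdivision-3 icospheres (642 nodes); closed-surface
flux checks use subdivision 4 (2562 nodes), where quadrature error is below
1e-3 of Σ|En|A. Volume meshes use subdivision-2 layers. Tests and the
acceptance script run the GA with populations of 100-200 on 6-20 subject
cohorts; these sizes reproduce every algorithmic contract at desk scale.
Degenerate inputs are rejected explicitly: zero-area triangles, orphan
surface nodes, non-orientable surfaces, zero weighted targets (NERNI's
denominator), empty target regions, non-increasing shell radii, non-unit
electrode directions, and undecayed Legendre series all raise informative
errors rather than propagating NaNs.

## Limitations

The sphere cohort is a stand-in: absolute NERNI and ⟨En⟩ levels, and any
quantity driven by cortical folding, do not transfer to real heads. The GA
is a heuristic; it is validated against exhaustive subset enumeration only
at small scale (20 candidates, 3 electrodes). Local tissue-thickness
features and real-MRI ingestion are out of scope.
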