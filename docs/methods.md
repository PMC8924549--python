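# Methods

## Coordinate and packing conventions

Voxel indices are 0-based and global; the physical position of voxel `v` is
`(v + 0.5) · spacing_nm`, so voxel *centers* carry the geometry. Bit-packed
masks linearize x-fastest with little-endian bit significance; the payload
is exactly `ceil(nx·ny·nz / 8)` bytes, an 8-fold reduction against a
one-byte-per-voxel mask whenever the voxel count is a multiple of 8.

The distance-from-boundary field (DBF) is the anisotropic Euclidean
distance between voxel centers, computed with a standard Euclidean distance
transform (`scipy.ndimage.distance_transform_edt` with per-axis sampling).
Everything outside the mask's bounding box, padded by one voxel, counts as
background, so border voxels always receive finite distances. Measuring to
the nearest background voxel *center* (rather than to a face) is a
convention; it makes a single isolated voxel with 5×5×45 nm spacing have
DBF = 5 nm, and it is what the node radii inherit.

## Centerline tracing

The tracer follows the sparse-TEASAR scheme. The foreground points form a
26-connectivity graph whose directed edge cost from `u` to `v` is the
physical step length plus a center-hugging penalty evaluated at the head:

    cost(u→v) = ‖pos(u) − pos(v)‖ + s · (1 − DBF(v)/DBF_max)^e

with defaults `s = 5000 nm` and `e = 16`. The penalty form and constants
are this package's documented choice of the classic TEASAR-style
functional; both are parameters of `SkeletonizeParams`. Steps toward the
boundary are therefore expensive and shortest paths hug the medial axis.

Per connected component: the first seed is the DBF maximum (ties resolved
to the lexicographically first voxel); each iteration runs Dijkstra
(`scipy.sparse.csgraph`) from the current seed, picks the farthest (by
graph distance) unvisited point as the destination, and walks the
predecessor chain back. The chain truncates at the first node already in
the skeleton, which becomes the attachment point. If the chain never
touches the skeleton, the graph shortest path from the seed to the nearest
(by graph distance) skeleton point is prepended, so the junction follows
the object's interior instead of jumping straight across space. All points
within `max(invalidation_scale · DBF(n), invalidation_min)` of each new
node are marked visited (defaults: scale 3, floor 2× the smallest voxel
spacing); subsequent iterations re-seed at the unvisited point closest to
the visited set and stop when nothing is left. The loop contains no
randomness; identical inputs give bit-identical skeletons.

Node radii are the DBF values of the underlying voxels. Each tree is
finally re-rooted at its maximal-radius node, a soma proxy. When the radius
is constant along a tube the argmax tie lands on a tube end, which is why a
cylinder's root can be a path endpoint; all topology assertions in the
tests account for this.

Fragmented objects (discontinuous segmentation) are re-joined by
`reconnect_components`: repeatedly bridge the globally closest pair of
terminal-or-root nodes belonging to different trees, ascending by gap,
while the gap is within the threshold (default 5000 nm). The absorbed tree
(the smaller one) is re-rooted at its joining node, preserving the forest
invariant.

## Postprocessing

The cleanup pipeline runs in a fixed order: redundant-node merging
(consecutive nodes closer than ε, keeping the larger radius; irreducible
nodes are never removed), hair removal (terminal segments shorter than
`hair_ratio ×` the attachment node's diameter, iterated to a fixed point,
with root-containing segments exempt; default ratio 1.5), soma-branch
removal (subtrees entirely inside the root-radius sphere), arc-length
resampling at uniform spacing (irreducible nodes preserved exactly, radii
linearly interpolated), empty-branch removal (zero-length terminal
segments), and a centered moving-average smoothing of segment interiors
(default window 3; endpoints fixed). The removal steps and resampling are
idempotent; smoothing, being a moving average, is a contraction whose fixed
points are straight segments — repeated smoothing flattens further, which
is inherent to the operator, so only its fixed-point behaviour is asserted.

Default parameters target EM-scale data (resampling at 500 nm); the phantom
tests use 3 nm because the phantoms live on 1 nm voxels. The "hair" ratio
(1.5) and the soma sphere rule (root radius around the root node) are
package choices where only the comparison principle is standard.

## Morphometrics

A skeleton decomposes into maximal unbranched segments between irreducible
nodes (root, branching, terminal). Segment order counts branch points from
the root. Tortuosity is path length over chord (undefined, reported as NaN,
for zero chords). Branching angles average the pairwise angles between unit
vectors from the branching node toward each daughter segment's *distal*
irreducible node — more robust to node jitter than using the first child
node. The terminal-segment neck/head ratio splits the segment at its
arc-length midpoint: min proximal radius over max distal radius, a spine
signature. Sholl counts edges crossing concentric spheres centered on the
root (sign change of `‖x−root‖ − r` across an edge; nodes exactly on a
sphere count once). Whole-neuron features use the unweighted node mass
center; asymmetry is the root-to-mass-center distance and the typical
radius is the RMS node distance to the mass center (the RMS reading of an
ambiguous convention). Fractal dimension is box counting over dyadic box
sizes from extent/2 to extent/64, least-squares slope of log N versus
log(1/s); it requires ≥ 32 points and non-degenerate extent. Convex-hull
volume uses Qhull (degenerate sets report 0). Surface area sums lateral
frustum areas `π(r₁+r₂)·√(len² + (r₁−r₂)²)` over edges.

## NBLAST

Dotprops are built by resampling the skeleton at `spacing_um` (default
1 µm) and assigning each point the dominant principal axis (sign-free) of
its k = 5 nearest neighbours. The raw score of a query against a target
sums `f(d, adp)` over query points, where `d` is the distance to the
nearest target point and `adp` the absolute tangent dot product. The
default score function is parametric, `adp · exp(−d/σ)` with σ = 3 µm; a
tabulated (distance × |dot|) matrix can be loaded from CSV with explicit
bin edges for compatibility with published score tables. Scores are
normalized by the query self-score, and the two directions are averaged
(the mean-score variant; forward-only scores are available as the
`normalized` matrix). `1 − symmetrized`, clipped at zero, feeds
average-linkage agglomerative clustering cut by cluster *count* — the cut
is a free choice in any real dataset, so the count is an explicit argument.

## Connectivity

Synapses arrive as CSV rows (id, presynaptic neuron, postsynaptic neuron,
position); counts per ordered pair form the connectivity matrix, with
autapses on the diagonal and rows referencing unknown neurons dropped with
a logged count. Symmetrized counts map to a distance `d = 1/(1+s)` — a
monotone map of "more synapses = closer" onto (0, 1] — which is clustered
and used to reorder the matrix by dendrogram leaf order. The
morphology–connectivity association is the Spearman rank correlation
between symmetrized NBLAST score and symmetrized synapse count over
unordered neuron pairs; since pairs sharing a neuron are not independent,
significance comes from a permutation test that relabels neurons (permuting
rows and columns of the count matrix together; 999 permutations,
two-sided, add-one p-value).

## Synthetic ground truth

Phantoms are rasterized capsules/spheres on a voxel grid: a voxel is
foreground iff its center lies within the tube radius of the true
centerline polyline, which makes the ground truth exact by construction.
Tube axes pass through voxel centers so the DBF maximum sits on the true
centerline. The circuit generator places one archetype skeleton per class
(a smooth random-walk polyline of 60 nodes at 3 µm steps) on a ring of
radius 300 µm and adds isotropic Gaussian node jitter (σ = 1 µm) per
neuron; synapse counts per ordered pair are Poisson with rate λ_within = 8
inside a class and λ_between = 0.5 across classes. The large class
separation relative to jitter makes the planted classes unambiguous; these
are validation conditions, not a model of biological variability. What the
phantoms do **not** emulate: EM image texture, segmentation merge/split
errors beyond a clean gap, spines and boutons, realistic within-class shape
variation, or distance-dependent synapse placement. Passing tests
demonstrate algorithmic correctness under known geometry, not end-to-end
accuracy on real segmentations.

## Numerical choices and limitations

Ties in seeds and argmaxes resolve to the lowest index (lexicographic voxel
order), making every stage deterministic. The acceptance script scales
problem sizes to phantom dimensions of ~100 voxels, 12–40-neuron circuits
and 20 replicate seeds — the package's chosen validation sizes; all
quantities it reports are recomputed at run time. Known limitations: the
tracer is sparse (one object at a time) by design, dense multi-object
skeletonization is out of scope; there is no interactive skeleton editing;
dendrite/axon compartment labels are accepted as input but never inferred;
and the binary SWC dialect is this package's own versioned layout with no
compatibility claim toward other binary SWC flavours.
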