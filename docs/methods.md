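# Methods

## The shape model

Each conformer is modelled as a sum of spherical atom-centred Gaussians

    rho(r) = sum_i p exp(-alpha_i |r - c_i|^2),

with a shared amplitude `p = 2*sqrt(2)` and per-atom exponents calibrated so
that one atom's Gaussian integrates to its hard-sphere volume:

    p (pi/alpha_i)^{3/2} = (4/3) pi r_i^3
    =>  alpha_i = pi (3p / 4 pi)^{2/3} / r_i^2.

This amplitude is the standard choice for Gaussian shape overlays; it has the
convenient consequence that an isolated atom's self-overlap volume equals its
monopole volume exactly (`p / 2^{3/2} = 1`), which anchors several exact unit
tests. Van der Waals radii default to the Bondi set with 1.70 Å for unlisted
elements; hydrogens are excluded by default (heavy-atom shape model), both
overridable.

Three volumes are derived from the density:

* **monopole volume** `V_mp = ∫ rho` — the sum of calibrated atomic volumes,
  conformation-independent;
* **self-overlap volume** `V_so = ∫ rho²` — a closed-form double sum over
  atom pairs; the `V_AA`/`V_BB` of the shape Tanimoto. Because every atom
  pair contributes positively, it overestimates physical volume roughly
  threefold for bonded systems (the synthetic corpus shows a mean
  `V_so/V_an` ratio near 3.5);
* **analytic volume** `V_an` — an inclusion–exclusion estimate of the
  hard-sphere union volume using closed-form Gaussian product integrals,
  truncated at third order by default. Intersection subsets are restricted
  to cliques of atoms within 1.2× the pairwise radius sum; beyond that the
  Gaussian product is negligible. Order 3 with this pruning tracks a
  10⁷-point Monte-Carlo union-of-spheres reference within 3% on bonded
  chains; higher orders cost combinatorially more and change desk-scale
  results by less than the Monte-Carlo noise.

The **steric quadrupoles** `(Qx, Qy, Qz)` are the eigenvalues of the
monopole-normalised second-moment tensor of the density about its centroid,
sorted `Qx >= Qy >= Qz`; they behave as squared length/width/height proxies
and are rigid-motion invariant. Under this normalisation the trace identity
`Qx + Qy + Qz = R_g²` holds exactly, with `R_g` the density radius of
gyration, and a single atom has `Q = 1/(2 alpha)` on every axis (~0.45 Å² for
small-element radii), matching the smallest values seen in large public
descriptor tables. An un-normalised variant scaled by `V_mp` is available
behind a config flag for compatibility with tables quoted in Å⁵.

Degenerate eigenvalues are ordered descending and the eigenvector signs are
fixed (largest-magnitude component non-negative, then determinant forced to
+1) so the principal frame is deterministic.

## Superposition and shape Tanimoto

    ST = V_AB / (V_AA + V_BB - V_AB)

with `V_AB` the Gaussian cross overlap maximised over rigid placements of B.
The optimiser moves both conformers to their principal frames and refines
each of the four proper axis alignments (identity plus π flips about x, y,
z — the standard overlay start set) with L-BFGS on a rotation-vector +
translation chart. Gradients are analytic: the translation gradient is the
weighted sum of centre differences, and the rotation gradient is obtained
from the left-trivialised derivative mapped through the SO(3) left Jacobian.
Convergence tolerances (`ftol 1e-13`, `gtol 1e-9`, 200 iterations max)
recover ST = 1 for exact rigid copies to well below 1e-6. Optional random
restarts (seed required) exist for near-degenerate principal frames, where
four starts can in principle miss the global optimum; on randomly generated
conformers the four-start optimum matches or beats an exhaustive 15°
rotation-grid search.

A volume-only upper bound is used as the first screening stage: by
Cauchy–Schwarz, `V_AB <= sqrt(V_AA V_BB)` for any pose, hence
`ST <= s/(V_AA+V_BB-s)` with `s = sqrt(V_AA V_BB)`. The bound is provable
for Gaussian densities (unlike min-volume bounds, which assume hard
volumes), so the prefilter can never discard an achievable neighbour.

## Quadrupole filters

Volumes are binned with width 5.0 Å³ and quadrupoles with widths 2.5 / 0.5 /
0.1 Å² for Qx / Qy / Qz, by truncation (`floor(value/binsize)`); floor versus
round only shifts bin boundaries and is recorded in the filter-file metadata.
Pairs are ordered canonically — smaller volume bin first, ties cascading
through Qx, Qy, Qz bins, fully identical bins preserving input order — and
the signed difference `ΔQ_bin = Q_bin(mol2) - Q_bin(mol1)` is tallied per
ordered volume-bin key. The signed inclusive range per key is stored rather
than a symmetric |ΔQ| cap, honouring the observed asymmetry of the
difference distribution; the signed range subsumes the symmetric variant.

**Fringe fill.** Because the training corpus samples the descriptor space
finitely, sparsely populated border regions of the (V1, V2) maps would cause
false rejections of unseen but plausible pairs. The fill processes unique
difference magnitudes from the maximum downward, separately for the
non-negative and non-positive branches; at each level the cumulative
populated region is gap-closed along rows and columns (every bin between the
populated extremes becomes allowed). Closure is iterated to a fixed point,
and the final per-key range collapse is itself re-swept to a fixed point, so
the fill is idempotent and its output region always contains the raw region.
The construction guarantees **zero false negatives on the training corpus**
at every threshold — the method's core contract.

**Unknown-key policy.** Volume-bin keys never seen in training default to
PASS: filters only reject pairs the corpus holds evidence against. A strict
mode (reject unknown keys) exists for efficiency experiments. The threshold
sweep (efficiency as a function of ST threshold) is evaluated in strict
mode: under the pass policy the trained-key coverage shrinks as the
threshold rises, and at desk-scale corpus density that coverage loss
dominates the range tightening, inverting the expected trend. In strict
mode the allowed regions provably nest across thresholds (a filter built
from a sub-corpus admits a subset of what the super-corpus filter admits),
so the rejected fraction is monotonically non-decreasing in the threshold —
the property the sweep is meant to exhibit. At production corpus densities
(billions of pairs) essentially every key is trained and the two policies
coincide.

The cascade applies Qx, then Qy, then Qz, short-circuiting at the first
rejection; Qx is consistently the most efficient single filter. The cascade
rejection set equals the union of the single-filter rejection sets.

## Synthetic corpus

The generator emulates the inputs the filters are built from — conformer
descriptor tables and ST-labelled pair lists — without any external data:

* conformers are heavy-atom point clouds of 6–24 atoms grown by sequential
  bonded placement (1.3–1.6 Å steps). The anchor is the previously placed
  atom with probability 0.65, otherwise a uniformly chosen earlier atom.
  The chain bias produces elongated, branched scaffolds whose descriptor
  spread is strongly anisotropic (Qx varies far more than Qz, both
  right-skewed), as in real small-molecule corpora; purely uniform anchoring
  collapses everything into near-spherical blobs whose shapes are all alike.
  A hard core rejects placements closer than 0.8× the mean vdW radius of the
  pair (a core at 0.8× the radius *sum* would exceed the bond length itself
  and forbid every placement);
* element draws follow an organic drug-like mix (C 65%, N 12%, O 14%,
  S 4%, F 3%, Cl 2%);
* "similar" pairs are a conformer plus a jittered (σ = 0.05 Å default),
  randomly re-posed copy — ST typically ≥ 0.97; "dissimilar" pairs are two
  independent conformers, which at these sizes still neighbour each other
  (ST ≥ 0.8) a few percent of the time, so the corpus contains genuinely
  hard marginal cases;
* every pair is labelled by running the actual superposition optimiser, so
  ground truth and pipeline share one ST definition;
* the default corpus is 2,000 training and 5,000 held-out pairs with 30%
  similar pairs, train/test disjoint by conformer id, fully determined by a
  single seed.

What the generator does **not** emulate: bond topology, valence, torsional
flexibility, rings, aromaticity, or the empirical descriptor distributions
of any real compound database. Passing tests therefore demonstrate the
correctness and soundness of the machinery, not filter efficiency on real
chemistry.

## Known limitations

* **Held-out false negatives at desk scale.** Soundness is exact on the
  training corpus, but a corpus of ~700 neighbour pairs cannot cover the
  per-key difference ranges the way billions of pairs do; held-out pairs at
  trained keys with undersampled ranges are rejected — on the default
  corpus, roughly one in seven positives, concentrated at marginal
  similarities just above the threshold. A filtered neighbour search on
  such corpora therefore loses a corresponding fraction of marginal
  neighbours even though it never invents any and skips a large share of
  superpositions. This is a property of corpus density, not of the
  algorithm; at production densities (where essentially every key holds
  thousands of observations) the analogous loss is orders of magnitude
  smaller.
* The superposition optimiser uses four deterministic starts; highly
  symmetric shapes with near-degenerate principal frames may need the
  seeded random restarts.
* The analytic volume is a truncated series; it is accurate for bonded
  geometries, not for heavily interpenetrating pathological inputs.
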