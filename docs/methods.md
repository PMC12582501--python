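# Methods

## Scope and model

`polyads` detects in-plane extensions of tetrads in nucleic-acid tertiary
structures and classifies the resulting multiplets by residue count
(pentad … octad). It deliberately does *not* detect free-standing triads,
classify tetrad topology (ONZ classes, loop types), or judge
thermodynamic stability; it answers one geometric question: which
nucleotides participate, with a tetrad, in one planar hydrogen-bonded
ring?

The underlying structural model: a polyadic ring is planar, each member
typically bonds its two ring neighbours, and extensions of a tetrad sit
in the tetrad plane at roughly symmetric distances from their two
neighbouring members. The four filtering criteria operationalize exactly
these properties (connectivity, planarity, proximity/symmetry, plane
height), and the score measures how far inside every gate a candidate
sits.

## Base frames and measurements

Each analyzable nucleotide gets a least-squares base plane through its
ring atoms (9 for purines, 6 for pyrimidines), computed as the smallest-
variance eigenvector of the ring-atom covariance. Residues missing ring
atoms are flagged non-analyzable and skipped, never fatal. Modified
nucleotides are mapped to a parent base when their atom names contain the
full purine or pyrimidine ring set.

**Tilt** between two bases is arccos of the *absolute* dot product of
their unit normals, folded into [0°, 90°]. Folding matters: the sign of
a fitted normal is a bookkeeping convention, and anti-parallel frames
occur between syn- and anti-glycosidic bases of one coplanar multiplet.
Without folding, a perfectly coplanar candidate with a flipped frame
would read as 180° − θ and always fail the planarity gate.

**ΔH(C, A, X) = (C − A)·n̂ₓ** is the signed height of candidate atom A
over member X's base plane, measured from the tetrad centroid C. Two
probe atoms are used: A_in, the candidate's base heavy atom closest to C
(base atoms only — a sugar atom would make the measure depend on backbone
conformation), and A_out, the glycosidic nitrogen (N9 purine / N1
pyrimidine). The "atom involved in the glycosidic bond" admits C1' as an
alternative reading; the base-side nitrogen keeps both probes in the base
plane, so the two heights genuinely measure the *base*, not the sugar.
Criteria consume |ΔH|; the sign is kept for reporting.

## Thresholds

| knob | default | meaning |
|---|---|---|
| tilt_avg (TT_avg) | 40° | mean candidate–member tilt |
| tilt_max (TT_max) | 50° | tolerance for a single member comparison |
| height_avg (HT_avg) | 3.15 Å | mean abs plane height, per probe |
| height_max (HT_max) | 3.7 Å | single-plane tolerance, per probe |
| dist_in_max | 13 Å | A_in to tetrad centroid (also the search radius) |
| dist_out_max | 13 Å | A_out to tetrad centroid (search radius) |
| dist_spread_max | 2 Å | difference of the two nearest member distances |

All are user-adjustable (CLI flags / `Thresholds`). Loosening any knob
can only grow the passing candidate set; the test suite verifies this
monotonicity per knob.

### The proximity spread: which distances?

"Variation in the distances between the candidate and the individual
tetrad nucleotides" admits several readings. This package uses, per
member, the **minimum heavy-atom distance between the candidate's base
and the member's base**, and applies the 2 Å cap to the two *nearest*
members — the neighbours the candidate would bond in the ring. Rationale,
established on ideal fixture geometry:

* centroid-to-centroid distances are dominated by base size and ring
  position; for an ideal sheared-pair hexad extension the two nearest
  member distances differ by ≈3.4 Å, so that reading would reject
  textbook hexads outright;
* A_in-to-member-centroid distances sit at ≈2.1–2.5 Å spread for the same
  geometry — still at or past the gate, and noise-fragile because the
  identity of the innermost atom can switch between near-tied atoms;
* nearest-atom distances give ≈0.2–1.3 Å spread for valid geometry, are
  smooth under coordinate noise (0 failures in 200 perturbation trials at
  0.1 Å noise), and still reject candidates hanging far off one neighbour.

The max−min over all four members is *not* used: the far side of the
tetrad says nothing about ring symmetry. The Euclidean centroid-distance
gate itself uses A_in, consistent with the `--dist-in-max` naming.

### Scoring

Score = (Σᵢ wᵢ·(mᵢ·100)^pᵢ)/2 + PairCount over the six margins, with
negative margins clamped to zero. Two deliberate choices: the half-sum
(rather than squaring each term a second time, which would duplicate the
exponents already present) and the ×100 margin scaling, kept as printed
in the defining formula. The scaling makes geometric terms dominate
PairCount except very near the thresholds — which is precisely where a
discrete tie-breaker should take over. The score is *ordinal*: it ranks
hypotheses during conflict resolution and order standardization and has
no physical unit. Conflict ties break deterministically (higher
PairCount, smaller centroid distance, chain/sequence order), so repeated
runs are byte-identical.

### Order standardization

Within one stack, strict mode trims every extended tetrad to the minimum
extension count among the stack's *extended* tetrads (plain tetrads do
not force the minimum to zero), removing lowest scores first. Among
exact score ties, the removal that maximizes the minimum pairwise angular
separation of the survivors around the tetrad axis is preferred —
one concrete quantification of "preserve the overall symmetry".
`--lax-order` skips trimming entirely, and its output is always a
superset of the strict run.

## The built-in annotator

Pair detection is deliberately permissive: ≥2 polar (N/O) base-atom
contacts within 3.5 Å (donor–acceptor heavy-atom distance proxies the
hydrogen bond; deposited structures rarely resolve hydrogens), inter-base
tilt ≤ 60°, centroids ≤ 12 Å apart, and a vertical centroid offset
≤ 2.5 Å along the mean normal. The vertical gate separates pairing from
stacking: without it, two stacked tetrad layers 3.4 Å apart (parallel
normals, several polar contacts just under 3.5 Å) register as base pairs
and fabricate inter-layer 4-cycles. Sequential edges require an actual
covalent O3'(i)–P(i+1) linkage (≤ 2.5 Å) between chain neighbours, so
chain breaks never fabricate connectivity. Stacking edges need centroid
distance ≤ 5.5 Å, tilt ≤ 30°, in-plane offset ≤ 4 Å and a non-trivial
vertical offset. None of these constants comes from the multiplet
literature — they are module configuration with sane defaults, and
downstream criteria re-check candidate geometry much more strictly.
Leontis–Westhof edge labels (W/H/S) are best-effort metadata derived from
which atoms carry the contacts. Results on borderline real structures may
differ from a specialized annotator's; the JSON import path
(`--annotations`) exists for exactly that case.

Tetrads are chordless 4-cycles in the pair graph with pairwise member
tilts ≤ 50° and member centroids within 9 Å of their mean — gates chosen
to mirror the candidate thresholds. When accepted 4-cycles share
residues, the most planar (lowest mean pairwise tilt) wins, so each
residue belongs to at most one tetrad; the graph-walk enumeration is
verified against an exhaustive 4-subset oracle in the tests. Tetrad
members are never extension candidates for another tetrad.

## The synthetic-structure generator

Fixtures are built from standard planar base templates (ideal literature
bond geometry, heavy atoms plus C1'; hydrogens omitted to match
crystal-structure reality). Two small cached least-squares solves produce
(a) the C4-symmetric G-tetrad with neighbour N1–O6 / N2–N7 distances of
2.85 Å and the O6 carbonyls ringing the channel, and (b) per base type,
an extension pose whose Watson–Crick edge H-bonds (≈2.95 Å) the sugar
edge (N3/N2) of one tetrad member, balanced toward the middle of the gap
to the next member, with a 2.6 Å clash floor. Layers stack at 3.4 Å rise
and 30° twist; a K⁺ ion is placed in the channel between layers (kept in
the reader's ion side channel, unused by detection).

Connectivity of a planted extension is one base pair plus one covalent
O3'–P link to the next member around the ring (residue numbering makes
them chain neighbours). This mirrors how validated hexad adenines reach
ConCount = 2 in real structures, and it is forced by geometry: the gap
between two tetrad members is wider than any single base's edge, so a
rigid base cannot H-bond two members simultaneously — numerically
verified during design.

Planted **tilt** is a hinge rotation about the axis through the two
H-bonded edge atoms: bonds survive and the base normal tilts by exactly
the requested angle, so the planted value is the measured value. Planted
**height** is a vertical translation; beyond ≈1.8 Å it necessarily
stretches the H-bonds past 3.5 Å and the candidate fails connectivity
before the height gates can speak. That is real physics — a base cannot
hover 3 Å over the plane and keep in-plane hydrogen bonds — and it is why
the ±5% boundary checks of the height (and distance) gates plant
*measurements* at the criterion-evaluation level, while geometry-level
sweeps exercise the tilt gate and the overall accept/reject flip.

What the generator does *not* emulate: loop backbones connecting layers,
sugar puckers and realistic backbone torsions, syn/anti glycosidic
diversity, crystallographic disorder, solvent, or modified bases. Passing
the fixture grid therefore demonstrates the correctness of the geometric
logic under controlled conditions, not annotator parity on borderline
experimental structures.

Default planted conditions: extension tilt 10°, height 0.5 Å, Gaussian
coordinate noise 0–0.1 Å (crystallographic coordinate precision is of
this order), 20 seeds per grid cell, orders 5–8, 1–3 layers. Under these
conditions the ideal-geometry margins are large for most gates (tilt at
25% of its mean gate, heights at ≈6–16%); the A_out centroid distance is
the exception at ≈92% of its 13 Å radius, fixed by rigid-body geometry
of a paired base (glycosidic nitrogen ≈12 Å from the tetrad centre).

## Numerical choices and degenerate inputs

* Angles are degrees at every API boundary; arccos inputs are clamped to
  [−1, 1].
* Normal sign convention: positive dot product with (C1'→glyco) ×
  (glyco→centroid); any fixed convention works because tilt folds.
* Alternate locations: highest occupancy wins; multi-model files default
  to model 1 with explicit selection (`--model`).
* Gzip is detected from magic bytes, format (PDB vs mmCIF) from content,
  never from file extensions.
* No randomness anywhere in detection; all orderings are total, so
  identical inputs give byte-identical reports.
* Empty results are not errors: a structure without tetrads yields an
  empty report and exit status 0.

## Known limitations

* The built-in annotator trades specificity for recall by design;
  on experimental structures with marginal contacts it may pair bases a
  specialist tool would not (or miss sugar-edge O2' mediated pairs, since
  contacts are restricted to base atoms). Import external annotations
  when fidelity to a reference annotator matters.
* Detection quality is bounded by the tetrad layer: a tetrad the pair
  detector cannot see cannot be extended.
* Order standardization assumes stacks are linear chains; exotic branched
  stacking would be ordered by axis projection without warning.
* Scores are comparable only within one structure and threshold setting.
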