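# Methods

## The pathways decay model

Long-range electron transfer between a buried heme and a protein radical
site is treated as tunneling through a discrete network of interactions.
Each edge between atoms *i* and *j* carries a decay factor

    q_ij = A · exp(−B (r_ij − R)),   q_ij clamped to ≤ A

with per-kind parameters (defaults in parentheses):

| kind      | A    | B (Å⁻¹) | R (Å) | meaning |
|-----------|------|---------|-------|---------|
| covalent  | 0.60 | 0.0     | 0.0   | fixed attenuation per bond, length-independent |
| hbond     | 0.36 | 1.7     | 2.8   | referenced to a 2.8 Å donor–acceptor separation |
| space     | 0.60 | 1.7     | 1.4   | referenced to van-der-Waals contact |

These are the classic tunneling-pathways values; all are configurable
(`DecayParameters`). The clamp `q ≤ A` keeps −ln q ≥ 0 — the Dijkstra
nonnegativity precondition — and encodes that no jump can couple better
than its own contact limit. A pathway's coupling is ∏ q, reported as
ln(k) = Σ ln q ≤ 0; maximizing the product is identical to a shortest-path
problem under weights −ln q, which Dijkstra's algorithm solves exactly.
Ties on total weight are broken by fewer atoms, then lexicographically by
atom serials, so results are deterministic; the tie-break priority
`(weight, edge count, serial chain)` is preserved under path extension,
which keeps the greedy search exact for the full ordering. A brute-force
enumeration over all simple paths (guarded to ≤ 14 nodes) implements the
same ordering and serves as the oracle in tests; networkx's Dijkstra is a
second, independent check of the optimal weight.

This is a coupling-topology model only: no Marcus reorganization energies,
driving forces, or electronic-structure couplings are computed, and ln(k)
values are comparative scores, not absolute rates.

## Graph construction

**Covalent bonds.** Intra-residue connectivity comes from name-based
templates for the 20 standard amino acids, heme b (protoporphyrin IX with
methine bridges, vinyls, methyls and both propionates) and water. Atoms a
template does not cover — hydrogens, unknown residues, ligands — fall back
to a distance rule: bonded iff r ≤ r_cov(i) + r_cov(j) + 0.45 Å, with
covalent radii from gemmi. Peptide bonds join C(i)–N(i+1) of consecutive
residues within 2.0 Å; an inter-residue distance-rule pass picks up
disulfides and metal contacts. The heme iron is linked to the proximal
histidine NE2 when within 3.0 Å; that edge is flagged so the path search
can exclude it (the coordination bond is a modeling artifact as an
electron-transfer segment, and rankings report whether an optimal path
used it). Templates are applied by atom name irrespective of distance, so
covalent topology is robust to strained input geometry; edge distances are
always measured from the coordinates at hand.

**Hydrogen bonds.** In structures containing hydrogens, donors are N/O
atoms with an attached H; an edge requires H···A < 2.5 Å and a D–H···A
angle > 135°. In hydrogen-free structures (crystal coordinates;
united-atom topologies are *not* hydrogen-free for polar groups) any N/O
pair within 3.5 Å that is not covalently connected within two bonds is
taken as hydrogen-bonded. In both modes the edge carries the
donor–acceptor heavy-atom distance, since the hydrogen-bond decay term is
parameterized on heavy-atom separation (R = 2.8 Å). The hydrogen-based
detection thresholds mirror the occupancy-analysis criteria (0.25 nm,
135°) with Å used internally throughout; nm values appear only at
reporting boundaries.

**Space edges.** Every remaining atom pair within 6.0 Å (configurable)
gets one through-space edge. Beyond ~6 Å a space jump costs more than
e⁻⁷·⁸ relative to contact and cannot participate in an optimal path while
shorter alternatives exist; the cutoff keeps the graph sparse. Precedence
per pair is covalent > hbond > space, so the edge-kind sets partition the
edge set.

## Residue ranking and candidate selection

Scores are computed on the inverse route, from the heme iron to each
tyrosine hydroxyl oxygen (OH) and tryptophan indole nitrogen (NE1); the
graph is undirected, so the score equals the donor→acceptor value.
Residues missing their acceptor atom are skipped with a warning. Rows sort
by descending ln(k); `select_candidates` keeps rows at or above a caller
ln(k) cutoff, the operation used when scores of established radical sites
in homologous peroxidases set the selection threshold. The porphyrin-edge
donor variant (electron donated at the closest porphyrin atom rather than
Fe) is deliberately not implemented; Fe is the single donor convention.

## Ensemble analytics

Per-frame scoring holds the covalent topology fixed (perceived once from
the topology structure), re-measures covalent edge distances from each
frame, rebuilds hydrogen-bond and space edges from that frame's
coordinates, and reruns the search. Rebuilding per frame is the point:
sub-Å fluctuations toggle hydrogen bonds and space contacts and thereby
reroute the optimal path. A frame whose acceptor is unreachable yields a
sentinel (ln k = −∞) that is excluded from statistics but counted in
totals.

Participation is the fraction of valid frames whose optimal path contains
a given atom, binned left-open/right-closed into
>90%, 80–90%, 65–80%, 50–65%, 40–50%, 30–40%, 10–30%, <10%.
The ensemble score is the arithmetic mean of per-frame ln(k) — the
geometric mean of the per-frame couplings. The averaging convention is
genuinely open (mean of ln k vs ln of mean k differ under fluctuation);
mean-of-ln is chosen because ln(k) is the reported scale, and both
extremes are exposed (`best_frame`, `worst_frame`) so other conventions
can be formed from the same outputs.

## Hydrogen-bond occupancy

For a donor with attached polar hydrogen(s) and candidate acceptors, a
frame is bonded when any donor hydrogen satisfies both criteria
(H···A < 0.25 nm, angle at H > 135°); a frame counts once per pair even
with multiple hydrogens. Mean distance (H···A, nm) and mean angle are
computed over bonded frames only, so they are conditional geometries, as
in standard occupancy tables. Occupancy is invariant to frame order and
monotone under criterion tightening. A donor without polar hydrogen is an
error naming the atom — occupancy requires explicit hydrogen geometry.

## Water structure

The rdf histograms center–water-oxygen distances with 0.1 Å bins to
r_max = 10 Å (defaults), normalizes by exact shell volumes
(4/3)π(r₂³−r₁³) — the discrete form of 4πr²dr, which makes the shell
integral reproduce the mean in-range count identically — and divides by
the reference density: N/V when a periodic box is supplied (minimum-image
distances; r_max must not exceed half the shortest box edge), otherwise
the mean count inside r_max over the sphere volume. Raw per-bin counts are
exposed alongside g(r) since distance-distribution plots are sometimes
left unnormalized. The minimum-distance series is the per-frame minimum
center–water distance, unsmoothed.

## Synthetic data: what it emulates, what it does not

The generators produce the study conditions each stage needs with ground
truth known in closed form:

- **covalent chains / bridged pairs** — geometries whose optimal score is
  analytic (n·ln 0.6 plus the bridge term). With default parameters a
  straight-chain geometry admits no through-space shortcut cheaper than
  the covalent route, so the closed forms hold with all edge kinds
  present.
- **occupancy trajectories** — a water-like donor–H–acceptor triad
  toggling between a geometry inside the criteria (1.8 Å, 165°) and one
  outside (3.2 Å, 165°) via seeded Bernoulli draws at the prescribed rate;
  the bonded mask is returned, never recomputed by the consumer.
- **water boxes** — Poisson-count, uniformly placed oxygens at bulk water
  density (0.0334 Å⁻³) around a central probe: the ideal-gas limit in
  which g(r) = 1 at all r.
- **random graphs** — ≤ 14 nodes with random edge kinds/distances for the
  enumeration oracle; connectivity is not guaranteed, exercising the
  no-path sentinel.

Fixtures use legal PDB vocabulary and round-trip through the real reader.
They do not emulate physical conformational sampling, correlated
hydrogen-bond dynamics, or solvent structure beyond uniformity — passing
tests demonstrate algorithmic correctness and estimator calibration, not
force-field realism. Ranking real crystal structures further depends on
deposited coordinates and hydrogen placement: scores on un-minimized,
hydrogen-free structures use the heavy-atom hydrogen-bond fallback and can
shift by fractions of a ln-unit relative to minimized united-atom
coordinates.

## Numerical choices and problem sizes

- All coordinates in Å internally; nm only at reporting boundaries.
- Altloc resolution: highest occupancy, ties to conformer 'A'.
- q clamped at A per kind; ln(k) accumulated as a sum of per-edge logs
  (additivity holds to 1e-12 relative).
- Dijkstra tie-break: fewer atoms, then lexicographic serials.
- Degenerate inputs: empty structures, empty rankings, all-pathless
  ensembles and hydrogen-free occupancy donors raise; unreachable
  acceptors return sentinels.
- Test and acceptance problem sizes: 200 random graphs of ≤ 12 nodes for
  oracle equivalence; 2000-frame occupancy trajectories (binomial 3σ
  bound); 40 resampled frames of a ~900-water box for the rdf tail, which
  puts the statistical noise of the tail mean near 1.5% — comfortably
  inside the ±0.05 check it supports. The full suite runs in seconds.

## Known limitations

- No bond-order or aromaticity perception; π-stacking (e.g. a Tyr–Trp
  dyad) is visible only as space edges.
- Heavy-atom hydrogen-bond fallback over-generates donors (any N/O may
  donate), which is the intended permissive behavior for hydrogen-free
  crystal structures but can admit chemically implausible donor pairs.
- Single-donor convention (heme Fe); no porphyrin-edge entry points, no
  multi-acceptor flux networks.
- mmCIF and compressed trajectory formats (DCD/XTC) are out of scope;
  inputs are PDB or XYZ frame stacks.
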