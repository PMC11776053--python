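# Methods

This note documents the models and procedures `alchemap` implements, the
choices made where the design was genuinely open, and what the test suite
does and does not establish.

## Molecular representation and MCS

Molecules are hydrogen-suppressed RDKit graphs; every atom count in the
package is a heavy-atom count. Identity is canonical isomeric SMILES
(`canonical_key`), used to deduplicate generated candidates. Multi-fragment
inputs are rejected: a perturbation endpoint must be a single molecule.

The maximum common substructure is computed with RDKit's FMCS under an
*incomplete atom-type matching* flavor chosen for alchemical planning:

- atom compatibility is by connectivity only (elements may mismatch; the
  mismatching pairs are recorded), because an element mutation is a cheap
  single-topology perturbation;
- bond orders are ignored (a saturation change is likewise cheap);
- ring atoms/bonds may only map to ring atoms/bonds, keeping mappings
  chemically meaningful for ring-preserving transformations;
- the MCS is connected and maximizes atoms rather than bonds.

Where no bonded common substructure respects the ring rule (an acyclic
molecule against a fully cyclic one), the mapping degenerates to a single
shared atom: one atom carries no bonds, so the ring-bond rule is vacuous.
This keeps the "strict matching never finds more atoms than tolerant
matching" monotonicity intact, which a naive "retry without ring
constraints" fallback would violate.

RDKit may report several maximum mappings; for determinism the one with the
fewest element mismatches is taken, then the lexicographically smallest
pair list under canonical atom ranks (computed over up to 128 substructure
matches per side). The per-pair search budget defaults to 60 s; on timeout
the best mapping found is used and flagged. Because RDKit's emitted MCS
SMARTS can pin elements or bond orders of one input, the query is rebuilt
atom-by-atom into the declared flavor before re-matching — otherwise the
mapping extraction can spuriously fail on asymmetric pairs.

## Protonation states

Reference workflows use commercial ligand-preparation tools to set
protonation states before charge filtering. This package instead applies a
small deterministic rule table at a nominal pH 7.4: carboxylic, sulfonic
and phosphonic acids are deprotonated, aliphatic (non-aromatic, non-amide)
amines are protonated; atoms already carrying explicit formal charges are
never touched. Absolute charges may therefore differ from a full pKa
engine's output; what matters downstream is only that both endpoints agree,
which the generator enforces.

## Intermediate generation

Generation is a closure of single graph edits toward the common-core frame,
run in both directions (A toward B's core, B toward A's core), with a LIFO
compound pool and a global visited set keyed by canonical SMILES.

Decisions where the procedure definitions leave room:

- *Edit (b)* applies only to acyclic non-core atoms whose deletion keeps
  the graph connected; ring atoms are handled exclusively by (c)/(d)/(e),
  since removing a single ring atom produces invalid valences.
- *Edits (c)/(d)* delete an entire non-core branch hanging off a single
  non-ring bond, provided the branch contains a complete ring and no core
  atoms (substituents of the deleted ring go with it; they are separately
  reachable via (b) first, so no candidates are lost). (d) caps the
  attachment point with a methyl carbon; the cap is itself a non-core atom
  and can be deleted later by (b).
- *Edit (e)* removes the atoms of a fused ring that are neither core nor
  shared with another ring, then re-perceives aromaticity; edits whose
  product cannot be sanitized are discarded.
- *Edit (a)* transfers both the element and the formal charge of the mapped
  target atom.
- The core frame is tracked by projecting the A↔B atom mapping through
  each edit's survivor index map, rather than recomputing an MCS per
  intermediate.

Every edit strictly decreases (#non-core atoms + #mismatched core atoms),
so the pool empties after finitely many pops; safety caps (50,000 pops,
10,000 candidates per direction) guard against pathological inputs and
abort with a diagnostic rather than degrade silently. Candidates whose net
charge differs from the inputs' shared charge are excluded from results and
from further expansion. Identical inputs are required to carry identical
net charges up front.

## Scores

Link score: `S_e = exp(−β(N_A + N_B − 2N_MCS))` with β = 0.1 (Lomap's
default). The exponent counts inserted/deleted heavy atoms; tolerated
element swaps count zero, so two distinct compounds related by pure element
mutations share `S_e = 1`. Path score: `S_P = 1/Σ S_e⁻²`, the reduced form
of "harmonic mean of squared link scores divided by path length"; the
expanded form is kept in the test oracles. `S_P` strictly decreases when
any edge is appended, penalizing long paths.

The all-pairs score matrix is the dominant cost (quadratic in candidate
count, one MCS per pair); it is computed once and shared by path search and
map construction.

## Optimal path and map construction

Path search is an exhaustive depth-bounded enumeration of simple paths
(defaults MIN_SCORE = 0.5, MAX_DIST = 3 edges; distance 1 is a direct
link). Candidate graphs are small enough that heuristic search is
unnecessary. Ties are broken by shorter length, then higher worst link,
then lexicographic node ids — an invented but fixed order for determinism.
When no path qualifies, the error carries a flagged best-effort path
maximizing the worst link within MAX_DIST ignoring MIN_SCORE, so callers
can distinguish fallbacks from genuine optima.

Map construction prunes candidate links below a threshold (default 0.2,
exposed separately from MIN_SCORE), then attempts removals worst-first
(ties by node-id pair), keeping a removal only if every optimal link is
still present and lies on a cycle of ≤ MAX_CYCLE = 4 edges. Cycle
membership is decided by a bounded shortest-path query on the graph minus
the link. If some optimal link lies on no qualifying cycle even in the full
pruned graph, the constraint is waived for that link, the map carries a
per-link feasibility flag, and a warning is emitted — never a silent pass.
Corridor extraction (keep only nodes on simple A→B paths within
MAX_SUBGRAPH_DIST = 4) runs once at finalization by default; a
`subgraph_mode="each_removal"` switch re-extracts after every kept removal
instead, since the timing of this step is ambiguous in the underlying
procedure description and both readings are defensible. If the final
extraction would break a cycle constraint it is skipped (warned), and only
nodes unreachable from the endpoints are dropped.

## Series mode

The base map over series members is a Lomap-style constrained removal:
graph stays connected, every member within D_max = 6 edges of every other,
and each retained member–member edge on a cycle of ≤ MAX_CYCLE when one was
feasible in the full graph. These constraint settings are this package's
own defaults; Lomap implementations vary.

Member–member links scoring below the series threshold (default 0.6) are
repaired by pair-mode injection: generation + optimal path between the
link's endpoints with MIN_SCORE equal to the threshold, new intermediates
deduplicated by canonical key against everything already present. The
rebuild is incremental — new link scores are computed only between injected
intermediates and existing nodes — followed by a worst-first removal pass
whose constraints exempt intermediates (no connectivity, distance or cycle
requirements for them). The weak member link itself is not force-deleted;
it becomes removable by the ordinary pass once its replacement path exists.
Intermediates left disconnected from the members or dangling as acyclic
leaves are pruned to a fixpoint. The loop stops when no unattempted weak
member link remains or after 5 iterations; a link whose repair fails is
kept, flagged, and never retried, which makes progress monotone.

## Fixtures and what the tests show

The toy congeneric series grafts single substituents (methyl, hydroxyl,
chloro, amino, ethyl, methoxy) onto a benzene scaffold and adds one distant
anthracene member. With β = 0.1 the distant member's links to the 8-atom
members score exp(−1.0) ≈ 0.37 < 0.4, emulating the multi-ring
insertions that force intermediate injection in real lead-optimization
sets. These fixtures are deliberately small aromatic systems: they exercise
every edit procedure and the full pipeline within seconds, but they do not
probe stereochemistry, tautomers, macrocycles, charged series, or MCS
timeouts on large flexible molecules — conclusions from a green suite carry
to real drug-like series only insofar as those features are absent.
Abstract seeded scored graphs (random spanning tree plus extra edges)
bypass chemistry entirely to test the graph algorithms against brute-force
oracles.

Problem sizes in the test and acceptance runs — 50 path-search graphs of
8–12 nodes, 30 map-build graphs of 6–8 nodes, 4 generation pairs, an
8-member series — were chosen so each oracle comparison is exhaustive and
exact; the algorithms themselves carry no size assumptions beyond the
safety caps above.

## Known limitations

- Net-charge-changing intermediates are out of scope by design; inputs must
  share a net charge.
- Link scores are a similarity proxy: they do not necessarily track actual
  FEP sampling difficulty, so a map optimal under these scores is not
  guaranteed cheapest to simulate.
- The score of 1 for pure element swaps means chemically distinct compounds
  can be "free" to interconvert under the model; this mirrors the
  single-topology perturbation cost model, not chemical identity.
- No 3D information: conformers, binding poses, and alignment are outside
  the package; edits are purely topological.
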