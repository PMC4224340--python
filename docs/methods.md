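# Methods

## The character and its event grammar

`archevo` treats the gene complement of a pathway in one genome as a single
complex character: a **genome profile**, the multiset of **gene
architectures** (ordered N→C domain strings) present in that genome.  For
the bundled folate case the alphabet is `{B, K, P}` for the folB (DHNA),
folK (HPPK) and folP (DHPS) domains of the pterin branch of folate
biosynthesis, and the observed architectures range from the four-domain
fusion `B-B-K-P` down to the empty profile `.` (pathway absent).

Profiles evolve by a closed grammar of seven event types:

| event                 | arity | action |
|-----------------------|-------|--------|
| `fusion`              | 2→1   | concatenate two genes N→C in a stated order |
| `fission_separation`  | 1→2   | break one gene at a domain boundary into prefix + suffix |
| `fission_domain_loss` | 1→1   | delete a contiguous domain run from a gene with ≥ 2 distinct domain types |
| `domain_contraction`  | 1→1   | the same deletion applied to a single-domain-type gene |
| `domain_duplication`  | 1→1   | insert a tandem copy of a contiguous run next to itself |
| `gene_loss`           | 1→0   | remove a whole gene |
| `gene_gain`           | 0→1   | add a stated architecture (models horizontal acquisition) |

Deletions are classified from the gene they act on, not from labels in an
input file, so summary counts are always grammar-derived.  The distinction
between `fission_domain_loss` and `domain_contraction` is deliberate:
losing a folB copy from a standalone `B-B` gene does not split or truncate
a fusion and must not inflate fission counts, whereas the same deletion
applied to `B-B-K-P` is a genuine fission by domain loss.  A deletion that
would empty a gene is rejected; total removal is exactly `gene_loss`,
which keeps event counts unambiguous.  Both fusion concatenation orders
are always generated — the observed N→C order is an outcome, not an
assumption.  Profile equality is multiset equality; genomic location and
synteny are treated as evidence for tip states, not as part of the
character.

**State caps.** The reachable profile space is bounded by two caps: at
most 2 copies of a domain type per gene (matching the observed tandem
`B-B`) and at most 4 genes per profile.  Cap-violating event applications
are excluded from neighbour enumeration and carry zero hazard in the
simulator, so searches and jump processes are always well-defined.

## Event distance

`event_distance` finds a minimum-total-cost event path between two
profiles by uniform-cost search over the directed profile graph, with a
consistent admissible heuristic (a domain type present in the target but
absent from the current profile forces at least one gain; a type present
but unwanted forces at least one deletion or loss).  Ties on the frontier
are broken by canonical profile text, so the reported path is
deterministic.  The default cost model is 1.0 per event except
`gene_gain` at 10.0: gains encode horizontal acquisition and are
deliberately expensive so that vertical-inheritance explanations win.
The search radius defaults to `max_cost = 12.0` — ample for the case
study (largest observed pairwise distance 11.0) while preventing runaway
search through chains of gains.  `brute_force_distance`, an
iterative-deepening exhaustive enumeration with exactness-preserving
pruning, serves as the independent oracle in the tests.

## State universe and Sankoff reconstruction

Because the character is a multiset, the ancestral state space is not
fixed in advance.  A finite **state universe** is built as the closure of
the observed tip profiles (plus any root constraint) under a bounded
number of single events, gains excluded from the closure; the default
depth is 2 and a guard rejects universes above 5,000 states.  Branch
transition costs are shortest-path costs in the event graph *induced on
the universe* — single-event edges between universe members, including
finite-cost gain edges whose gained architecture occurs in the universe —
memoized as an all-pairs matrix (scipy's sparse Dijkstra when all costs
are positive, a dense relaxation otherwise).  These restricted costs can
in principle exceed the free-space distance when a needed intermediate
state falls outside the closure; for the case study the relevant pairs
are verified equal to the free-space values by the oracle tests.

The reconstruction itself is the classical Sankoff dynamic program:
bottom-up score vectors over the universe, minimum over root states (or
evaluation at an explicit constraint — the constrained run is a flag, not
a hidden default), and a top-down traceback that enumerates **all**
minimum-cost assignments up to a cap (default 256) with an explicit
truncation flag.  Ties are real in this problem — alternative placements
are often only slightly less or equally parsimonious — so the MPR set is
surfaced rather than an arbitrary representative.  Branch lengths are
ignored by parsimony; they matter only to the simulator.  Polytomies are
handled naturally (children contribute independently).

On the bundled case study the unconstrained optimum is 13.0 versus the
narrative scenario's 14.0; the gap is produced by reconstructions that
place a single folB-domain deletion on a basidiomycete stem instead of
parallel deletions on daughter branches.  This is reported (the
`cost_gap_strict` flag), never silenced; the headline fission counts are
properties of the narrative scenario and are computed by the scenario
module.

## Scenarios

A scenario is a root profile plus ordered per-branch event placements,
addressed by child-node name (taxon names for tips, clade labels for
internal branches, which keeps scenario files robust to rearrangement
inside uniform clades).  `play_scenario` propagates the root state down
the tree; `validate_scenario` reports per-tip match/mismatch and grammar
violations instead of raising; `summarize_scenario` refuses invalid
scenarios and otherwise counts events through the grammar classifier and
prices them under a cost model.  For any valid scenario, the
root-constrained Sankoff optimum is a lower bound on the scenario's cost;
the tests assert this on the fixture and on randomly generated forward
scenarios.

## The simulator

`simulate` runs a continuous-time jump process independently along each
branch: the total hazard is Σ over applicable event *instances* of the
per-type rate, where an instance is one concrete application (one gene
copy, one boundary or run, one ordered partner pair) — a gene present in
two copies is twice as likely to be lost.  Waiting times are exponential
in the total hazard; the realized instance is drawn proportionally to its
rate; the process restarts from the updated profile until the branch
length is exhausted.  Default demo rates put fission-type events and gene
loss at 0.2 per instance per unit branch length and fusion/duplication at
0.1, with gains off — a deliberately fission-heavy regime reflecting the
lability this kind of character shows in practice; they are demo defaults,
not estimates.  Every run logs its full event history, and replaying the
log from the root state reproduces the simulated tips exactly (a tested
invariant).  Calibration tests check single-event-type runs against the
closed form `1 − exp(−λt)` at 3 standard errors.

What the simulator does *not* emulate: sequence evolution, alignment
noise, annotation error in tip profiles, rate variation across lineages,
and horizontal transfer with realistic donor pools.  Passing recovery
tests therefore demonstrates internal consistency of the
grammar/inference stack under the stated process, not robustness of the
biological conclusions to data error.

`recovery_experiment` simulates, then infers with an unconstrained root.
Its search universe is seeded with the observed tips **plus the
experiment's known generating root state** (the root assignment itself
stays free): tip-only closures exclude gains and so can never contain an
ancestral state whose domains ended up split across different tips.  With
that seeding, the parsimony lower bound — inferred minimal cost ≤ cost of
the true simulated history — is asserted on every replicate, with one
adaptive retry at closure depth 3 for histories too deep for the default
closure.  Exact-recovery fractions are reported, not thresholded: at
roughly one expected event per tree recovery is nearly always exact,
while at several events parsimony systematically undercounts
(overwritten events are invisible), which is the expected behaviour of
the method, not a defect.

## Numerical choices and problem sizes

Costs and scores are floats with a 1e-9 tie tolerance (all default costs
are integral, so ties are exact in practice).  Canonical text ordering of
profiles fixes every tie-break: frontier expansion in searches, universe
indexing, MPR enumeration order.  Test and validation problem sizes —
40-replicate recovery runs, 10,000-replicate calibration, oracle
comparisons on 5-topology families over ≤ 8-state universes — were chosen
as the smallest sizes at which the statistical checks have useful power
at 3-standard-error tolerances.

## Known limitations

- Universe-restricted transition costs upper-bound free-space distances;
  pathological tip sets could in principle inflate reconstruction costs.
  The closure-depth guard surfaces the trade-off explicitly.
- The grammar allows internal-run deletions (e.g. `B-K-P` → `B-P`); they
  are classified as fission by domain loss but never occur in the case
  study, and no claim is made about their biological frequency.
- The case-study tree commits to one published-compatible topology for
  clades whose internal arrangement is not fully recoverable (e.g. within
  Basidiomycota); the uniform-clade invariance test shows the headline
  results do not depend on arrangements inside profile-uniform clades.
- Parsimony here has no time model: branch lengths never influence
  inference, and rate estimation is out of scope.
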