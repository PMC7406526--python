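# Methods

This note documents the models and procedures implemented in
`fluencynet`, the parameter choices that matter, and what the synthetic
data used in the test suite does and does not establish.

## Data model and cleaning pipeline

A dataset is a collection of fluency lists, each an ordered sequence of
response tokens for one subject and one probe. Cleaning is applied in a
fixed order at load time:

1. lowercasing and whitespace trimming (optionally stripping all
   non-alphabetic characters, including internal spaces);
2. spelling/canonicalization corrections from a two-column
   `correct,incorrect` dictionary;
3. optional removal of verbatim perseverations;
4. optional removal of intrusions (requires a category scheme or target
   letter).

Corrections precede deduplication deliberately: a dictionary that maps
synonyms or subspecies onto one canonical token (e.g. two elephant
subspecies onto *elephant*) turns near-repeats into verbatim repeats, so
correct-then-dedupe never removes fewer tokens than the reverse order.
Spell dictionaries with chains (a→b where b→c) are rejected at load
rather than resolved transitively; a chain usually indicates a coding
error, and silent resolution would hide it. All matching is
case-insensitive. When both perseveration and intrusion removal are
requested, perseverations are removed first; the choice is arbitrary for
disjoint token sets and documented here for the overlapping case.

Datasets carry a `hierarchical` flag. Flat datasets report one value per
list; hierarchical datasets report the unweighted mean of per-list values
per subject. The flag changes aggregation only, never the underlying
lists, so toggling twice is the identity.

## Cluster segmentation

Each token carries the set of category labels assigned by the scheme
(letter-prefix schemes label a word by its first *k* characters).
Cluster continuity requires a non-empty intersection of label sets, not
label equality, because schemes may assign several labels per word.

* **Fluid:** a new cluster begins at token *t* iff
  `labels(t) ∩ labels(t−1) = ∅`.
* **Static:** a running intersection of label sets is maintained over the
  current cluster; a new cluster begins at *t* iff
  `labels(t) ∩ running = ∅`, and *t* (the breaking token) starts the next
  cluster with `running = labels(t)`.

The static criterion is at least as strict as the fluid one, so static
switches ≥ fluid switches on every list — a property test enforces this
on random list/scheme pairs, and an independent oracle (recursive
longest-valid-prefix splitting) checks the segmentation itself.

Tokens absent from the scheme are given a unique per-occurrence label:
they break clusters on both sides and form singleton clusters, and a
warning lists them. The alternative — silently fusing unknown words into
neighbouring clusters — would make dictionary gaps invisible in the
scores.

Switch rate divides the switch count by the number of scored tokens in
the list (the natural "switches per item" denominator); the raw count and
the rate are both available because the count is confounded with list
length.

## Perseverations, intrusions, word norms

A perseveration is a token whose identical string occurred earlier in the
same list; every repeat beyond the first occurrence counts, so the count
equals list length minus the number of distinct tokens. Detection of
non-verbatim repeats (morphological variants, subspecies) is delegated
entirely to the canonicalization dictionary: the engine takes no stance
on whether e.g. a superordinate term is a repeat or an intrusion — that
is the experimenter's choice encoded in the spell and scheme files.

An intrusion is a token outside the allowed response set: not a member of
any scheme category (semantic fluency) or not starting with the target
letter (letter fluency). The count is order-invariant.

Word statistics average a `word → value` table over a list's tokens.
Missing words either contribute a fixed substitute value (0.5 is the
conventional default for frequency-per-million norms) or are ignored;
under the ignore policy a list with no covered tokens yields NaN with a
warning, never a silent zero.

## Network estimators

All estimators return an undirected, unweighted, self-loop-free network
over all distinct tokens; nodes appearing in only one list remain as
isolated or low-degree nodes rather than being pruned.

**Pathfinder.** The proximity between two items is the mean absolute
difference of their first-occurrence positions across the lists
containing both, infinite for pairs never co-listed. No single distance
definition is canonical for fluency data; this positional-lag choice is
isolated behind `pathfinder_distances` so alternatives can be swapped in.
The retained graph is the union of all minimum spanning trees of each
finite-distance component — the sparsest classical Pathfinder
parameterization. Membership in some MST is decided by the cycle
property (an edge of weight *w* is in some MST iff its endpoints are
disconnected using only edges of weight strictly below *w*), implemented
as Kruskal over tie groups with union–find: all edges of equal weight are
tested against the forest of strictly lighter edges before any is merged.
A brute-force enumeration of all spanning trees verifies this on random
weighted graphs with small integer (tie-heavy) weights.

**Correlation-based.** Each item's presence/absence profile across lists
is correlated (Pearson) with every other; pairs at or above the threshold
(default 0.5, required explicit) become edges. Zero-variance items
(present in all or no lists) have undefined correlations and are retained
as isolated nodes with a warning. More elaborate variants (planarity
filtering) are out of scope.

**Conceptual network.** Two items co-occur in a list when their first
occurrences lie within `window` positions (default 2, counted at most
once per list). Under the null that a list of length *m* is a uniformly
random ordering, the co-occurrence probability for one list is
`p = w(2m − w − 1) / (m(m − 1))` with `w = window` (clipped at list
length − 1; when the window spans the whole list p = 1 and the list is
uninformative). An edge is placed when the exact upper tail
`P(C ≥ observed)` of the Poisson-binomial co-occurrence count over the
lists containing both items falls below `alpha` (default 0.05). No
multiple-comparison correction is applied; the edge set is therefore
monotone (nested) in alpha, which a test enforces.

## The censored random walk and U-INVITE

The generative model: a walker starts at some node, repeatedly moves to a
uniformly chosen neighbor, and emits a node on first visit only. The
probability that, given visited set *V* and current position *u*, the
next emission is *x* is a first-passage probability of the absorbing
Markov chain with transient states *V* and absorbing states the unvisited
neighbors of *V*. With `Q` the transition sub-matrix among transient
states and `B` the transient→absorbing block, absorption probabilities
solve `(I − Q) H = B`; the transition probability is the row of `H` at
*u*. Transient states from which no absorbing state is reachable are
removed first (mass entering them is genuinely lost — the walk cycles
forever), which keeps the system nonsingular; an isolated current node
yields probability zero. The dense solve uses `numpy.linalg.solve` on
systems no larger than the visited set; solved probabilities are clipped
to [0, 1] against roundoff at a relative tolerance of 1e-10.

The list log-likelihood conditions on the first response (contribution
log 1 = 0) rather than modelling a start distribution: no start prior is
part of the model here, and conditioning keeps the objective comparable
across candidate networks. A transition with zero first-passage
probability makes the list impossible (−∞). Dataset log-likelihood sums
over lists, treated as independent. Within-list repeats are not
representable (each item is emitted once), so perseverations are a
precondition error; they should be removed at load time.

**U-INVITE search.** The estimator maximizes the data log-likelihood
plus an independent-Bernoulli(θ) edge prior (default θ = 0.5, i.e. flat:
pure maximum likelihood). Search is greedy coordinate ascent from the
naive-random-walk network — a representable start, since consecutive
observed responses are adjacent there, making every transition possible.
Node pairs are swept in seeded random order; an edge is toggled whenever
the toggle strictly increases the objective (first-improvement
acceptance); the search stops after a sweep with no accepted toggle or
after `max_passes` (default 20) sweeps. Toggling edge (u, v) can only
change the likelihood of lists containing u or v — transition
probabilities depend solely on edges incident to visited states — so only
those lists are re-evaluated per candidate. The result is a local
optimum, deterministic given (dataset, seed). The accepted-toggle score
trajectory is non-decreasing by construction and can be returned for
inspection. Hierarchical variants (per-participant networks sharing a
group prior) are out of scope.

## Synthetic data generator

`generate_synthetic_dataset` produces censored-walk lists from a given
network (the study conditions for the recovery experiments: 50 lists of
all 10 nodes from a random connected 10-node, 15-edge network for network
recovery; 4 subjects × 3 lists of 8 nodes for measure recovery), then
optionally plants errors: verbatim copies of earlier walk tokens
(perseverations) and out-of-lexicon insertions (intrusions), each at a
per-slot probability (0.12 and 0.08 in the measure-recovery experiment —
chosen as the high end of error rates seen in clinical fluency data, so
the planted counts are reliably non-zero at this problem size).
Intrusion words are drawn without replacement per list and must be
disjoint from the network's nodes; perseverations duplicate only walk
tokens. These two constraints keep the planted perseveration and
intrusion counts disjoint, so the measures must recover the ledger's
counts *exactly*, not approximately. Walks truncated by the step budget
before reaching their emission target are emitted as-is and flagged in
the ledger.

What the generator does not emulate: real start-node biases (responses
begin with high-frequency category exemplars), response-time structure,
weighted or priming-modulated transitions, and within-subject network
variation. Passing the recovery tests therefore shows the estimators are
correct under their own generative assumptions, not that those
assumptions hold of human data.

## Numerical and design choices

* Problem sizes in the validation suite: likelihood checks enumerate all
  labeled connected graphs on ≤ 4 nodes (the DP oracle over
  (position, emission-order) states converges below 1e-9 residual within
  600 steps); the simulator check uses 1e5 runs on the 3-node star, where
  the two completions have probability exactly 1/2; Pathfinder is checked
  on 100 random graphs of ≤ 6 nodes, the largest size where exhaustive
  spanning-tree enumeration is instant.
* Edge-list files are canonical text: a sorted node section (so isolated
  nodes survive round trips) then sorted `u,v` rows with endpoints
  alphabetically ordered; import(export(net)) is the identity.
* The summary JSON isolates the timestamp in a single field; everything
  else is byte-comparable across reruns of the same configuration, and
  every reported number is recomputable by calling the library with the
  serialized parameters.
* Inter-item response times are stored when present but no measure uses
  them; no current statistic is defined on them.

## Known limitations

* The Pathfinder distance and the correlation thresholding rule are
  reconstructions of common practice, configurable rather than claimed
  equivalences to any particular historical implementation.
* U-INVITE's greedy search finds a local optimum; different seeds can
  yield different networks on small or noisy datasets.
* The conceptual-network null assumes items appear at most once per list;
  lists with perseverations are handled by first-occurrence positions,
  which slightly misstates the null for heavily perseverative data.
* No statistical modelling of the measures (group comparisons, regression
  on age or clinical status) is included; the measures export to CSV for
  analysis in standard statistics packages.
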