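# fluencynet

Scoring and semantic network estimation for verbal fluency data.

The verbal fluency task — "name as many animals as you can in one minute",
or "words starting with F" — is one of the most widely used probes of
semantic memory, in aging and bilingualism research and in clinical
batteries for mild cognitive impairment and dementia. Scoring it by hand
is slow and subjective: raters must demarcate semantic clusters, count
cluster switches, and flag repetitions (perseverations) and
out-of-category responses (intrusions). `fluencynet` automates these
analyses against explicit, shareable coding files (category schemes,
canonicalization dictionaries, word-norm tables), and goes further:
it estimates *semantic networks* — graphs whose nodes are concepts and
whose edges link related concepts — directly from the order in which
people produce responses.

## What it computes

**Fluency measures.** Lists are segmented into clusters of responses
sharing category labels, under two criteria: *fluid* (a switch occurs when
a response shares no label with the immediately preceding one) and
*static* (a switch occurs when a response shares no label common to the
entire current cluster). From the segmentation come switch counts, switch
rate (switches per item), and mean cluster size. Perseverations are
verbatim within-list repeats, counted after canonicalization through a
user-supplied spelling/synonym dictionary; intrusions are responses
outside the allowed category scheme (or not starting with the target
letter). Word-level norms (frequency, age of acquisition, any
`word,value` CSV) are averaged per list with an explicit missing-value
policy.

**Network estimation.** Six methods produce an undirected, unweighted
network (a symmetric 0/1 adjacency matrix) from a set of fluency lists:

| method | edge rule |
|---|---|
| first-edge | the first two responses of each list are linked |
| naive-random-walk | all adjacent responses are linked |
| pathfinder | edges in at least one minimum spanning tree of the mean positional-lag distances |
| correlation | presence/absence profiles correlate above a threshold |
| conceptual | co-occurrence within a positional window is significant under an exact random-order null |
| uinvite | the network maximizing the exact censored-random-walk likelihood |

**The censored random walk.** U-INVITE models a fluency list as the
first-visit record of a random walk on the latent network G: from node
*u* the walker steps to a uniformly chosen neighbor, and a response is
emitted only on first visit. The probability that the next emission after
the visited set *V* (current position *u*) is item *x* is the absorption
probability of the chain whose transient states are *V* and whose
absorbing states are the unvisited neighbors of *V* — computed exactly by
solving the linear system *(I − Q) H = B* of the absorbing chain. The
list log-likelihood is the sum of these log transition probabilities (the
first response is conditioned on), and U-INVITE greedily toggles edges to
maximize it. The same model runs forward as a simulator, which doubles as
the package's synthetic-data generator with a ground-truth ledger of
planted perseverations and intrusions.

## Worked example

Data files are plain CSV. `demo.csv` holds two subjects (A101's list is
hamster, cat, dog, wolf, coyote, zebra; A102's is dog, cat, dog, zebru),
`scheme.csv` assigns category labels (`Pets,hamster` ... with *dog* in
both Pets and Canines), and `spell.csv` corrects `zebru` to `zebra`:

```bash
fluencynet stats demo.csv --scheme scheme.csv --spell spell.csv \
    --measures n_responses,cluster_switches,cluster_size,perseverations,intrusions
```

prints

```
n_responses: mean=5 (n=2)
cluster_switches: mean=1 (n=2)
cluster_size: mean=2.5 (n=2)
perseverations: mean=0.5 (n=2)
intrusions: mean=0 (n=2)
```

A101's six responses form two fluid clusters (hamster–coyote chain
through shared Pets/Canines labels, then zebra): 1 switch, mean cluster
size 3. A102 has one verbatim repeat of *dog* (1 perseveration; the mean
over two lists is 0.5) and no intrusions once *zebru* is corrected. The
same library calls are available in Python (`fluencynet.cluster_switches`,
`fluencynet.perseverations`, ...), returning pandas Series per list, or
per subject when the dataset is loaded hierarchically.

Estimating a network and exporting its edge list:

```bash
fluencynet network demo.csv --spell spell.csv --method naive-random-walk \
    --out-edges edges.csv
```

```
nodes=6 edges=6 components=1 clustering=0.000 mean_degree=2.00 mean_shortest_path=1.93
```

Both commands also write a summary JSON (`--out-json`) recording every
parameter plus itemized spelling corrections, perseverations, and
intrusions, so an analysis is reproducible from the file alone.

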