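# Methods

## Model and estimation

The package treats the data as N independent complete-case draws from a
discrete Bayesian network over V categorical variables and asks for the
Markov equivalence class (CPDAG) of that network.  All information
quantities are plug-in (maximum-likelihood) estimates on observed joint
counts, in **nats**; no logarithm base is prescribed by the decision rules
themselves, and a single base throughout avoids unit mistakes when
information terms and log-normalizers are mixed.  The CLI can convert to
bits on request (`--bits`).

Entropies are computed over sparse observed-state tables; unobserved joint
states contribute exactly zero.  Conditional mutual information is the
four-entropy combination `H(x,u)+H(y,u)−H(x,y,u)−H(u)`; values in
`(−10⁻⁹, 0)` arising from floating-point cancellation are clamped to zero
(plug-in CMI is mathematically nonnegative), and anything more negative is
treated as a bug and raised.  The per-variable level count `r_v` is the
number of *observed* distinct categories; theoretical categories never seen
in the sample do not enter the complexity terms.  Categories are
integer-coded in lexicographic label order so that results are invariant to
sample order and column order.  Missing data are rejected rather than
imputed.

## Complexity terms

Two penalties `k_{x;y|{u}}` are implemented:

* **MDL/BIC**: `½ (r_x−1)(r_y−1) Π_i r_{u_i} ln N` — exact closed form, the
  large-N (Laplace) limit of NML.  `ln` is the natural log, consistent with
  the nats convention.
* **NML**: the factorized normalized-maximum-likelihood penalty,
  xy-symmetrized, summing `log C^r_n` terms over the observed joint states
  of the conditioning set.  Since `C^r_0 = 1`, unobserved states contribute
  exactly zero and sparse iteration is lossless.

The universal multinomial constant `C^r_n` is always handled in log-space:
the exact binomial sum for `r = 2` (via log-sum-exp, which would otherwise
overflow for n in the thousands), the Szpankowski asymptotic expansion above
a switch-over sample size `n* = 1000` (configurable in
`LogMultinomialCache`; the expansion's relative error is well below 0.1 % in
that regime), and the linear-time recursion
`C^r_n = C^{r−1}_n + n/(r−2)·C^{r−2}_n` for `r ≥ 3`.  The recursion is never
applied at `r = 2`, where its denominator vanishes.  Values are memoized per
`(n, r)`.

The 3-point complexity is the difference
`k_{x;y;z|{u}} = k_{x;y|{u},z} − k_{x;y|{u}}`, positive whenever all
implicated variables have at least two levels.

## Scores, ranks and modes

`score_kind` selects MDL or NML; `rank_mode` selects whether the *shifted*
or the *raw* information terms feed the contributor probabilities
`P_nv` and `P_b` and the eligibility test.  The default `auto` resolves to
shifted with NML and raw with MDL: the MDL penalty over-charges edges
between many-level variables at finite N, and ranking with raw terms limits
the resulting false negatives, whereas NML is well calibrated with shifted
terms.  The mode is applied uniformly to both probabilities, since the two
enter a single min().  In either mode the test that actually deletes an
edge is the shifted criterion `I'(x;y|{u}) < 0`.

All exponentials of `±N·I` are evaluated in the log domain (`expit`,
max-subtracted softmax), so probabilities remain well-defined for
arbitrarily large `N·I`.

A contributor `z` is eligible only when its (mode-selected) 3-point term is
strictly positive: negative 3-point information signals a collider, not an
indirect path, and conditioning on a collider *opens* a dependence rather
than explaining it away.  Ties in the rank are broken by lexicographic
variable name, making runs deterministic and column-order independent.

## Skeleton search

The search keeps one state per edge (conditioning set, shifted information,
best contributor, rank) and a single max-priority queue over edges keyed by
rank.  Popping the top edge appends its best contributor, re-tests
independence, and either deletes the edge (recording the conditioning set
as its separation set) or re-queues it with a fresh best contributor.
Candidate contributors for edge `xy` are the current neighbors of `x` or
`y` in the shrinking graph — the same adjacency restriction constraint-based
algorithms use — which keeps the search polynomial on sparse graphs.  When
an edge is removed, only edges incident to its endpoints can see their
candidate sets change; their queue entries are invalidated and lazily
recomputed on pop.  Since candidate sets only ever shrink, a settled edge
(no eligible contributor left) can never become active again.  Variables
with a single observed level are disconnected at initialization: they carry
no information, and the trivial separation set is empty.

`max_cond_size` (default unbounded) caps the conditioning-set size for
speed on dense problems.

## Orientation

Unshielded triples `x−z−y` are scored once with the shifted 3-point
information, conditioning on the step-1 separation set of `(x, y)` with `z`
excluded — the sepset is the estimate of the upstream contributors, and `z`
inside its own conditioning set would zero its own 3-point term.  Scores
are static; the sweep is dynamic: triples are processed in decreasing
`|I'|`, colliders (`I' < 0`) orient both arrowheads unless either
contradicts an existing orientation (then the whole, less likely triple is
skipped), positive triples propagate a single existing arrowhead through
`z`, and passes repeat until nothing changes.  A triple with `I' = 0`
exactly expresses no likelihood preference and is never used.  An
arrowhead, once placed, is never reversed.  The alternative of re-scoring
triples against an updated contributor set after each orientation was
considered and rejected for determinism and simplicity.

Rules R2 and R3 are deliberately **not** applied to the inferred PDAG: they
enforce acyclicity rather than encode a likelihood preference, so the
output may contain directed cycles.  The full R1–R3 closure *is* used in
`cpdag_of_dag`, but only to convert a known reference DAG into the CPDAG it
is evaluated against.

## Evaluation metrics

Skeleton precision/recall/F compare unordered adjacencies.  CPDAG metrics
reclassify every skeleton-true edge whose orientation status differs from
the reference (undirected vs directed, or oppositely directed) as a false
positive: `TP′ = TP − TP_mis`, `FP′ = FP + TP_mis`,
`Prec′ = TP′/(TP′+FP′)`.  The recall denominator keeps the skeleton count,
`Rec′ = TP′/(TP+FN)`, so misorientation penalizes the numerator only; the
alternative denominator `TP′+FN′` would double-count the penalty.  Ratios
0/0 are reported as 0 with an `undefined_precision` flag, so empty
predictions score zero rather than crashing.

## Synthetic data

`simulate` provides ancestral sampling from explicit CPTs, random DAGs, and
named fixtures.  The fixtures use hand-set CPTs so the analytic
independencies hold exactly:

* chain `x→z→y` and fork `x←z→y`: binary copy gates with fidelity 0.85 and
  uniform roots, giving `I(x;y) ≈ 0.13` nats and `I(x;y|z) = 0` in the
  population;
* v-structure `x→z←y` (and its variant with a child `z→w`): a *tilted*
  near-XOR gate, `P(z=1|x,y) = (0.05, 0.75, 0.85, 0.50)`.  A perfectly
  symmetric XOR gate would make every pairwise information vanish and the
  graph unidentifiable from pairwise signal; the tilt leaves each parent a
  clear marginal footprint (`I(x;z) ≈ 0.039`, `I(y;z) ≈ 0.016` nats) while
  keeping the explaining-away signal strong (`I(x;y|z) ≈ 0.167` nats);
* an 8-node mini-benchmark (10 edges, average degree 2.5, maximum in-degree
  2, all binary) mixing four colliders with chain segments; its CPDAG is
  fully compelled, which makes exact-recovery checks sharp.

`random_dag` draws a uniform topological order and places
`round(avg_degree·V/2)` edges under an in-degree cap.  Two CPT styles are
offered: `dirichlet` rows (faithful to published benchmark tables, but a
sparse Dirichlet can produce near-degenerate rows and hence edges that
carry no signal at any sample size) and `logistic` rows, a
multinomial-logistic model whose per-parent weight magnitudes are bounded
into `[1, 2.5]` so that every edge shifts the child's log-odds by at least
1 — the "strong dependence" regime used in the large-N recovery tests.

What the synthetic generator does *not* emulate: sampling noise models of
real assays (dropout, batch effects), continuous or mixed-type variables,
latent confounders, and selection bias.  Passing the recovery tests
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to the ways real single-cell or
clinical data violate them.

## Problem sizes and known limitations

The bundled studies use fixtures of 3–8 nodes with N up to 50,000 and
10–20 sampling seeds per condition; these sizes make every result
reproducible on a laptop in minutes while still exercising the asymptotic
regime (`N·I ≫ k`).

The take-off search is greedy and can be locally trapped: on denser graphs
(average degree ≳ 2) a collider's child occasionally *looks* like an
indirect contributor at the first step, after which the true separator's
3-point term turns negative and the edge can no longer be removed.  This is
a property of the scheme, not of the implementation — a stochastic
resampling variant is the natural remedy and is out of scope here.  The
exact-skeleton recovery test therefore uses sparse random DAGs (average
degree 1.5); on the denser mini-benchmark the same effect merely costs a
few F-score points at small N.

Other non-goals: latent variables and bidirected edges, continuous or
hybrid networks, missing-data handling, third-party network interchange
formats (BIF/DSC/NET), and alternative skeleton scores (BDe, G²-test PC).
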