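# Methods

## The model

`symbionet` treats an organism's metabolism as a purely qualitative reaction
network. A *reaction universe* catalogues compounds and directed reactions
indexed by EC number; an organism's network is the subset of universe
reactions whose EC annotations intersect the organism's genome-derived EC
list. Three modeling assumptions are built in:

1. **One well-mixed pool.** The bacteriocyte is a single compartment with
   free metabolite flux between host and symbionts and among symbionts.
   Compound identity is a flat namespace with no compartment suffixes.
2. **Qualitative reachability.** A compound is either producible or not; no
   stoichiometric balancing, flux values or quantities. Consequently a
   metabolite flagged as a shared resource is not necessarily limiting, and
   a predicted co-production may occur in negligible amounts — the outputs
   are testable hypotheses, not rates.
3. **Annotation-driven reconstruction.** One EC may map to many reactions
   and all are included; no pathway-context filtering. Reversible catalogue
   records are split into two directed reactions at load time, so
   feasibility is always "all substrates available".

### Network expansion (scope)

Given source metabolites S and reaction set R, the scope σ(S, R) is the
least fixed point of "if all substrates of a reaction are in the set, add
its products". The implementation is a worklist keyed by per-reaction
unmet-substrate counts (each compound arrival decrements the counters of
the reactions consuming it), which is near-linear in the number of
substrate occurrences. The contract, however, is the order-free fixed
point: a deliberately naive sweep-until-no-change oracle
(`expansion.expand_bruteforce`) is kept in the package and the two are
checked for equality under random reaction orderings in the tests and the
acceptance script. Autocatalytic reactions (a product that is also a
substrate) need no special handling under fixed-point semantics.

Growth capacity in an environment is proxied by target-panel coverage:
|σ ∩ T| for a fixed panel T of essential metabolites (amino acids,
nucleotides, cofactors).

### Environments

The host is represented only by the metabolites it provides. The packaged
host-only medium (`data/bacteriocyte_sources_synthetic.txt`) is a
**synthetic reconstruction**: the authoritative 49-compound list lives in
supplementary material that is not machine-readable here, so the packaged
file carries the described composition — ATP, NAD(P)+, heme, thiamine and
other cofactors, six non-essential amino acids, sugars and polyols,
central-carbon precursors (including D-ribose 5-phosphate, D-erythrose
4-phosphate, phosphoenolpyruvate, L-homocysteine), nucleosides and
inorganics — padded with phloem-plausible compounds to exactly 49 entries.
Analyses that depend on the *identity* of every compound (absolute per-pair
complementary counts) are therefore catalogue-dependent and are not treated
as reproducible; analyses that depend on the *structure* of the medium are.

The enriched host+obligate environment is the obligate symbiont's full
scope in the host-only medium (equivalently: host sources plus everything
the obligate can make — identical sets, since seeds are part of scope).
Environment names propagate into every downstream result so the two media
cannot be silently mixed.

### Complementation and masking

A metabolite is complementary for combination C in environment S when
σ(S, ∪C) contains it but no proper non-empty sub-combination's scope does
(singletons included). For pairs this is the classic pool–simulate–compare
procedure. The k-wise generalisation subtracts *all* proper
sub-combinations, so a triple is credited only with metabolites no pair and
no singleton can reach; the search defaults to k ≤ 3 and k is configurable.
Complementary sets are reported over all compounds (a pathway-classified
filter can be applied downstream via compound `pathway_class` tags).

Masking labels compare one pair across the two media: `both_envs`,
`host_only` (complementary only before obligate enrichment — an
alternative obligate route exists) and `host_portiera_only`. Scopes are
monotone in the environment, but complementary sets are not — enrichment
can delete a complementation by making one member self-sufficient; the
lysine fixture in the tests is exactly such a counterexample.

Profiles are binary combination × metabolite incidence matrices (rows
labelled `members@environment`, columns lexicographic). PCA runs on the
centered raw binary incidence without scaling; each component's sign is
fixed so its largest-magnitude loading is positive, making coordinates
deterministic. Hierarchical clustering uses Euclidean distance with
average linkage and a user-set flat cluster count. Distance and linkage
were genuinely open choices; Euclidean/average is the common default for
small binary profiles and is recorded here as this package's convention.

### Seed sets and competition

The seed set is the topological prediction of an organism's required
external resources: all compounds in source strongly connected components
(no incoming edge from outside the component) of the substrate→product
compound graph, computed via graph condensation (networkx). Seed SCCs of
size > 1 contribute all members, unweighted — the simplest reading of "all
predicted resource metabolites available". The original competition tool's
internal seed weighting is unpublished; scores here reproduce the described
procedure (binary seeds, count-ratio score), not that tool bit-for-bit.

The score of ordered pair (row, col) is (T_opt − T_red)/T_opt with T_opt
evaluated in the row's own seed set and T_red after removing seeds shared
with the column. T_opt = 0 yields 0 rather than NaN: an organism producing
nothing cannot be outcompeted in this metric. Scores are asymmetric and lie
in [0, 1] by expansion monotonicity.

Dependency scans operate in the explicit bacteriocyte medium instead of the
seed-set "optimal" environment: one source metabolite is removed at a time
and the loss of producible targets recorded. Sources consumed by no
reaction of the network short-circuit to 0. Only single removals are
scanned; combinatorial removals are out of scope.

### Summary statistics

The community-level mean competition score averages all ordered pairs whose
members belong to different genera; same-genus cells (duplicate genome
reconstructions of one genus) and the diagonal are excluded. Under that
definition the packaged published table (38 cross-genus ordered cells)
reproduces the printed community mean of 0.18 at two-decimal display
rounding. The occurrence association test is a two-sided Welch two-sample
t-test (Welch–Satterthwaite df) of cross-genus scores grouped by whether
the unordered pair co-occurs in field surveys; a closed-form Welch
implementation is kept alongside the scipy route as an oracle. The packaged
occurrence flags are reconstructed from the published table's typography
and are ambiguous for a few cells, so the package asserts only the
qualitative conclusion (no significant difference), never the printed
t statistic.

## Synthetic data

Generators are pure functions of their parameters and RNG seed:

- `make_linear_pathway` / `plant_split_pathway` — an unbranched chain
  partitioned across genomes, with the exact combination-specific
  complementary sets derivable in closed form (non-empty only for prefix
  runs of segments). Planted-structure recovery is exact
  (precision = recall = 1) by construction and is verified, not assumed.
- `plant_shared_seeds` — genomes whose targets hang off a known mix of
  shared and private seeds; expected pairwise scores are
  n_shared_dependent / n_targets in closed form.
- `make_random_universe` — uniform substrate/product sets of size 1–3 with
  a configurable reversible fraction; the substrate for oracle-equality
  testing.
- Toy communities (`lysine_toy`, `tryptophan_toy`, `thiamine_toy`,
  `bacteriocyte_demo`) — hand-built networks whose structure mirrors
  documented symbiont biology: the terminal lysine decarboxylase
  (EC 4.1.1.20) separated from the M-DAP producer, tryptophan hanging off
  ribose-5-P/erythrose-4-P/PEP, thiamine activation confined to the
  diphosphokinase carrier, branched-chain amino acids completed by an
  aminotransferase (EC 2.6.1.42) the obligate lacks, and ATP regeneration
  (pyruvate kinase) present only in the glycolytic genomes.

What the generators do **not** emulate: realistic reaction-network degree
distributions, currency-metabolite hubs spanning hundreds of reactions,
annotation noise (missing or spurious ECs), and the size of real catalogues
(thousands of reactions). Passing the planted-recovery and oracle tests
therefore demonstrates algorithmic correctness, not that predictions on a
real genome set are right — those inherit the uncertainty of the EC
annotations and of whichever reaction catalogue the user supplies.

## Numerical and interface choices

- Problem sizes: oracle agreement uses 100 random universes (≤ 30
  compounds, ≤ 40 reactions) × 10 orderings; planted-complementation
  recovery uses 50 random split configurations; these sizes give full
  coverage of the combinatorics this model exercises while keeping the
  suite fast.
- Determinism: all report emission is sorted; re-running on identical
  inputs is byte-identical (the run sidecar carries checksums and seed, no
  timestamps).
- Partial ECs (`1.1.1.-`) prefix-match the catalogue by default
  (annotation pipelines emit them routinely); `--strict-ec` disables this.
  Unmapped ECs are logged, never fatal. An empty reconstructed network is a
  warning, distinct from a parse failure.
- Degenerate inputs: empty environments are errors; empty networks yield
  empty seed sets (warning); all-identical profile rows yield zero PCA
  coordinates with a zero-variance warning; an environment reduced to the
  empty set during a dependency scan produces zero targets by definition.

## Known limitations

- Absolute complementary-metabolite counts and absolute competition values
  for real genomes depend on the reaction-catalogue release backing the
  EC→reaction mapping; no specific release is bundled, so those absolute
  values are reproducible only relative to a user-supplied catalogue.
- The qualitative model cannot distinguish mutualistic provisioning from
  parasitic scavenging, nor detect competition over non-limiting resources.
- Host enzymes are not modeled; host contribution enters only as source
  metabolites.
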