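# Methods

## Model

Each fibril template — one chain of one layer of a solved light-chain
amyloid structure — defines a consensus sequence (its structurally resolved
residues in author-numbering order) and a set of annotations: jumps in
author numbering open *missing segments*, and CDR intervals are supplied
explicitly per template in consensus coordinates. CDRs are never inferred
from the sequence, because no single numbering scheme (Kabat/IMGT/Chothia)
can be assumed for arbitrary templates; the annotation config is the single
source of truth.

The template HMM has one match state per consensus position. Its topology
encodes the structural prior that framework regions of light chains almost
never carry indels:

- **Constant regions:** match states chain directly, `M_i -> M_{i+1}`; no
  insert or delete neighbours exist, so no internal gap can open there.
- **Missing segments:** a single emitting deletion state bridges the two
  flanking matches, with self-transition 0.9 and exit 0.1 — a geometric
  length distribution (mean 10) over the residues spanning the unresolved
  stretch. Deletion states *emit* (uniform 0.05 per residue): they absorb
  the query residues that the template simply cannot see, rather than
  silently skipping them.
- **CDRs:** full match/insert/delete profile wiring. From a CDR match, gap
  opening costs 0.1 total (0.05 to the insert, 0.05 to the delete chain);
  insert self-loops and delete chains extend with 0.9. CDR deletion states
  are emitting as well, mirroring the missing-segment convention. A CDR
  interval that crosses a missing-segment boundary is rejected as ambiguous.
- **Termini:** uniform-emission flank states with self-transition 0.9 absorb
  unaligned leading/trailing query residues.

### Semi-global entry and exit

Alignment is semi-global ("glocal"): terminal gaps on either side are
allowed, internal constant-region gaps are not. Entry probability is split
0.5/0.5 between the N-flank and the match chain, and the match-chain share
is spread uniformly over all positions; every non-final match state carries
a small terminal-exit probability (`TERMINAL_EXIT_PROB = 0.01`, split
between the C-flank and the end state). This is what lets a query leave the
template's own termini unmatched — the situation the coverage rule exists
to detect — while keeping interior matches at 0.99 pass-through. The two
entry/exit constants are package choices (uniform entry, 1% exit): the
underlying method fixes only the interior transition probabilities, and any
small exit value behaves identically after quantile calibration because the
calibration is monotone.

A *global* variant (entry pinned to position 1, no interior exits) is used
by the fixture generator when sampling, so that synthetic corpora consist of
full-length chains rather than fragments, matching what a curated LC corpus
looks like after the 211-residue full-length filter.

### Initial parameterization

Match states emit their template residue with probability 0.8 and each
other residue with 0.2/19. All indel and flank states emit uniformly at
0.05. These are deliberate "dummy" values to be refined by training.

## Inference and training

All dynamic programming runs in natural-log space with log-sum-exp; an
impossible event is a `-inf` sentinel that propagates without exceptions.
Transitions are stored as sparse edge lists and reduced segment-wise, so a
250-position template against a 300-residue query stays well away from
underflow. Viterbi ties are broken deterministically — match over emitting
delete over insert over flank, then lower state index — which favors
maximal template coverage.

Baum–Welch updates every emission and transition row as
`new = inertia * old + (1 - inertia) * estimate`, where the estimate is the
normalized expected count, floored at 1e-10 and renormalized over the
events the topology allows (structural zeros stay zero; a state with zero
expected visits keeps its old row). Because the EM objective is concave in
each probability row and the feasible set is convex, the inertia-damped
update never decreases the corpus likelihood; the suite checks this to
1e-6. Iteration stops when the *absolute* corpus log-likelihood improvement
falls below the stop threshold (default 50) or after `max_iterations`
(default 500). The per-sequence interpretation of the stop threshold is a
plausible alternative reading; the absolute convention is exposed as a
plain argument, so callers can rescale.

Training proceeds in rounds over shrinking corpus fractions (0.30, 0.20,
0.10). Each round scores the full corpus with the current model using raw
(uncalibrated) scores, keeps the top `ceil(f * N)` finite scorers — ties at
the boundary broken by input order — and refines on them with inertia 0.9.
Degenerate (`-inf`) sequences never enter a training pool. The quantile
calibrator is fitted once, on the final model's scores over the whole
corpus.

## Scoring and calibration

The raw score is `log P(x) − log mean_i P(shuffle_i(x))` with the mean over
100 uniform residue shuffles taken in probability space via log-sum-exp
(the log-space mean is a config-level alternative; probability-space is the
literal reading of a ratio of averaged probabilities). Per-shuffle RNG
streams are spawned from one master seed, so scores are reproducible and
independent of evaluation order; in corpus scoring each sequence gets its
own child stream, making results independent of corpus order too. For a
model that is indifferent to residue order the score is exactly 0, and for
i.i.d. background queries its expectation is 0 — both are tested.

Calibration maps a raw score to its empirical quantile in the reference
corpus: sorted reference scores against a uniform grid with linear
interpolation, clamped to [0, 1]. This reproduces the uniform-output
quantile transformer of scikit-learn (cross-checked in the tests) without a
runtime dependency on it. Degenerate queries calibrate to 0 and keep their
flag.

## Selection

`select_template` scores a query against every registered template and
applies the two-part rule: modelable iff the best calibrated score strictly
exceeds 0.5 ("exceeds" — a score equal to the median fails) and the best
alignment covers at least 80% of the template consensus through match
states (non-strict). Coverage uses the template-consensus denominator by
default — the quantity backbone transfer actually needs — with the
query-length convention available as `coverage_denominator="sequence"`; the
two readings coexist in the method's own description, and the
template-length reading was chosen as the structurally meaningful one. CDR
indel events are tabulated separately and do not break constant-segment
pairs. Ties in the best-template argmax go to the lexicographically
smaller template id.

## Structure job

Pruning removes whole residues whose consensus positions are not in the
alignment, symmetrically on every chain of the fibril stack (layers share
author numbering); retained coordinates are preserved bit-for-bit at the
PDB field level. The side-chain job writes the pruned PDB, a mutation list
(`<wt><chain><number><mut>` comma-joined, semicolon-terminated, identity
positions omitted, mutations applied to every chain), and a JSON manifest.
Execution of any external force-field binary is out of scope; the package
emits the job inputs only.

## Synthetic data

The fixture generator emulates the study conditions end to end: a random
consensus (default 60 positions) with declared CDR intervals (default one,
positions 25–34) and missing segments (default one of length 6 after
position 45), a backbone-only multi-chain PDB consistent with the segment
numbering, and a corpus sampled from the template's own global-form HMM at
a 10% per-position mutation rate and 0.1 CDR gap-open rate (matching the
intended noise level of the recovery experiments), with ground-truth
alignments recorded at sampling time. The default recovery experiment uses
200 sequences — small enough to run in about a minute, large enough for
emission counts to dominate the inertia damping.

What the generator does **not** emulate: germline structure (real LC
corpora are mixtures of κ/λ families with correlated substitutions, not
i.i.d. mutations), somatic insertion/deletion hotspots, fragmentary
database entries, and any relationship between sequence and actual fibril
geometry. Passing tests therefore demonstrate the correctness of the
machinery — inference, training dynamics, calibration, rule application,
structural bookkeeping — not the biological accuracy of template
assignments on real patient sequences.

## Numerical choices and edge cases

- Probability-sum invariants are enforced to 1e-9 at validation.
- Forward/backward agreement is asserted to 1e-6 everywhere it is checked.
- `-inf` likelihoods arise only when a query contains a residue no
  reachable emitting state can produce (e.g. under a noise-free model);
  such queries are flagged degenerate, excluded from calibrator fitting and
  training pools, calibrated to 0, and marked for exclusion in score-matrix
  exports.
- An empty alignment (degenerate query) yields coverage 0 and refuses
  backbone pruning.
- Fasta parsing is permissive about residue letters; validation happens
  when a model consumes the sequence, naming the offending character and
  position.

## Known limitations

- Only the 20 canonical residues are supported; nonstandard residues in
  templates are a hard error rather than being remapped.
- The registry of real templates is user-populated: the package ships no
  curated template structures or corpora, only the generator.
- Multi-layer fibril symmetry is collapsed to a single chain for alignment;
  all chains are treated identically when pruning and mutating.
- Posterior decoding and pair HMMs are out of scope.
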