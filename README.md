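# fibrilhmm

Profile hidden Markov models with a segment-constrained topology for
matching antibody **light-chain (LC) amyloid** sequences to experimentally
solved fibril structure templates.

In AL amyloidosis, misfolded antibody light chains deposit as amyloid
fibrils. Only a handful of LC fibril structures have been solved, so for a
new patient-derived LC sequence the practical question is: *is any known
fibril structure close enough to model this sequence by homology — and if
so, which one?* `fibrilhmm` answers it with one HMM per template:

- **Constrained topology.** Each structurally resolved template position is a
  match state. In the conserved framework regions, match states chain
  directly — insertions and deletions are forbidden there, which sharply
  limits misalignment. Gaps are permitted only inside the
  complementarity-determining regions (CDRs, wired as a standard M/I/D
  profile), across structurally unresolved template segments (a self-looping
  emitting deletion state with geometric length), and at the termini
  (uniform-emission flank states).
- **Shuffle-normalized scoring.** The similarity of sequence *x* to template
  *T* is the log-ratio
  `score(x, T) = log P(x | HMM_T) − log( mean_i P(shuffle_i(x) | HMM_T) )`
  over 100 random residue shuffles, which cancels length and composition
  effects. Raw scores are mapped to [0, 1] by an empirical quantile
  transform fitted on a reference corpus.
- **Training.** Starting from the printed initial parameterization (match
  0.8, mismatch 0.2 over the 19 other residues, indel emissions 0.05, CDR
  gap open 0.1 split evenly, gap extension 0.9), each model is refined by
  Baum–Welch with inertia 0.9 and stop threshold 50 on the top 30%, then
  20%, then 10% of corpus sequences ranked by the current model.
- **Selection rule.** A query is *modelable* only if its best calibrated
  template score exceeds 0.5 **and** at least 80% of the template consensus
  aligns through match states without gaps.
- **Structure job.** For a modelable query, the template backbone is pruned
  to the aligned region (all fibril chains symmetrically, coordinates
  untouched) and a mutation list in the individual-list dialect of external
  side-chain force fields (`<wt><chain><number><mut>` tokens) is emitted.

## Worked example

Everything runs offline from generated fixtures:

```bash
fibrilhmm --seed 5 fixtures --out-dir fx --corpus-size 50
fibrilhmm build-template fx/template.json --out fx/model.json
fibrilhmm --seed 5 train fx/model.json fx/corpus.fasta --out-dir fx/trained --min-length 1
fibrilhmm --seed 5 score fx/corpus.fasta --model fx/trained/model.json --out fx/scores.tsv
```

`fx/scores.tsv` then holds one row per query, e.g.

```
query_id  score_SYN5  degenerate_SYN5  excluded  best_template  modelable
seq0000   0.7755      False            False     SYN5           True
seq0001   0.4286      False            False     SYN5           False
seq0002   0.0204      False            False     SYN5           False
```

`score_SYN5` is the calibrated quantile score against the (only) registered
template: `seq0000` exceeds 0.5 and aligns gap-free over at least 80% of the
template, so it is declared modelable; `seq0001` scores below the 0.5
quantile of the training corpus and is not. With several `--model` options
the score columns form the per-sequence feature vector used for landscape
analyses, and `fibrilhmm model-structure` turns a modelable query's
alignment into a pruned-backbone PDB plus mutation list.

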