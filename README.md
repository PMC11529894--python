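# pooldyn

Pool-seq population genomics and transposable-element (TE) dynamics toolkit.

`pooldyn` reimplements, as a tested and reusable pipeline, a pool-seq
analysis stack for bottlenecked insect populations:

* **formats** — mpileup decoding, PoPoolation2-style sync I/O, indel-region
  masking, GFF3/BED features, FASTA, TE hierarchy tables.
* **popgen** — pooling-corrected nucleotide diversity (π), Watterson's θ and
  Tajima's *D* in nonoverlapping windows, synonymous/nonsynonymous π, and the
  bottleneck statistic ΔΘ = 1 − π/Θ. Min-count detection bias is corrected by
  exact expectations over the neutral site-frequency spectrum, memoized per
  (min-count, coverage, pool size).
* **divergence** — windowed pairwise FST (classical pooled estimator with
  small-sample factors) and major-allele absolute divergence dXY with seeded
  tie-breaking.
* **mobilome** — TE insertion calling from paired-end physical-pileup
  signatures (identify → frequency → filter → pair-up), cross-population
  unique-insertion sets, insertion frequency spectra, read-vs-library
  divergence landscapes (1% bins), genome-architecture windows, and
  telomere-motif scans.
* **synthio** — synthetic data generator with ground truth: coalescent
  (msprime-backed) pool-seq under equilibrium or founder-event demographies,
  two-stage pooled read sampling with sequencing error, TE pair evidence at
  known insertion frequencies, and mutated TE copies for landscape tests.
* **stats / pipeline / cli** — Kruskal–Wallis + Holm-adjusted pairwise
  rank-sum tests with compact letter displays, a YAML-config driven
  orchestrator with manifest/checksums, and a `pooldyn` command-line tool.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the desk-scale acceptance criteria
(estimator oracle equivalence, equilibrium recovery, bottleneck signature,
TE caller recovery, landscape recovery, letter-display axioms, …); the whole
suite runs in about two minutes.

## CLI

```bash
# synthetic four-pool input with truth twin
pooldyn simulate --length 500000 --theta 0.005 --pool-sizes 40,21,33,40 \
    --seed 1 --output sim

# windowed diversity for one pool (NAME:COLUMN:POOL_SIZE:MAX_COV)
pooldyn diversity sim.sync --pool BH:0:40:112 --pool KP:1:21:105 \
    --window-size 100000 --output diversity.tsv

# pairwise FST / dXY
pooldyn differentiation sim.sync --pool BH:0:40:112 --pool KP:1:21:105 \
    --seed 1 --output pairs.tsv

# TE insertion calling from a pair-evidence table
pooldyn te-call evidence.tsv --seed 1 --output insertions.tsv

# everything from one config
pooldyn run-all --config run.yaml --output report/
```

Other subcommands: `te-spectrum`, `landscape`, `composition`, `telomere`,
`compare`. Exit codes: 0 ok, 1 validation error, 2 runtime failure.

A minimal `run.yaml`:

```yaml
output_dir: report
seed: 1
window: {size: 100000, min_covered_fraction: 0.6}
populations:
  - {name: BH, column: 0, pool_size: 40, max_coverage: 112}
  - {name: KP, column: 1, pool_size: 21, max_coverage: 105}
simulate:
  theta: 0.005
  length: 500000
  mean_coverage: 60
  error_rate: 0.001
```

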