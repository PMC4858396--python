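# toxprofiler

A tested, reusable pipeline for profiling the mechanisms of oxidative-stress
hepatotoxicity from high-throughput screening data. It covers:

- **qHTS curve processing** — range scaling of 15-point concentration–response
  series, a noise filter with monotone repair producing a curve fingerprint
  summarised by a single scalar (`curvep`), four-level activity calls
  (active / potential active / inconclusive / inactive with scores
  1 / 0.75 / 0.25 / 0), and replicate averaging per compound.
- **Structure curation** — desalting to the largest covalent component,
  neutralisation by proton transfer, rejection of metalorganics and very
  large molecules (MW > 2000), stereo stripping and canonical deduplication
  with majority label resolution.
- **Bioassay profile mining** — per-assay confusion counts against a binary
  endpoint, sensitivity/specificity, CCR = (sens + spec)/2, the likelihood
  parameter L = sens·(FP+TP)/(FP+1), Pearson χ² (no continuity correction),
  the four assay selection criteria (present in both endpoint profiles,
  > 10 matching active responses, CCR > 0.5 and L ≥ 1, in vitro), and the
  per-compound rate of actives RA = A/(A+I) with missing/inconclusive
  responses excluded and a strict RA > 0.25 toxicity call.
- **Consensus QSAR** — two descriptor sets × three algorithms
  (random forest, SVM, k-NN) averaged into a consensus score in [0,1],
  similarity-guided down-sampling of inactives for class balance,
  stratified 5-fold external cross-validation with per-fold re-fitting,
  dual consensus prediction thresholds (split at 0.5; ≥0.8/≤0.3 with an
  inconclusive band) and a k-NN distance applicability domain with
  coverage reporting.
- **Toxicophore evaluation** — substructure matching of candidate fragments,
  fragment-level in vitro/in vivo 2×2 tables with χ², and a transparent
  (openly simplified) circular-fragment enrichment ranking.
- **Synthetic data** — a generator that emulates all required inputs with
  known ground truth: valid structures decorated with planted fragments,
  a logistic latent model for activity/toxicity, Hill-shaped curves with
  Gaussian noise, and a sparse assay matrix with a planted associated
  assay subset. Ground truth is used only by tests.

## Test

```
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end recovery and trend
criteria (seed sweeps); the rest are per-module unit and property tests.
The full suite takes a few minutes (dominated by the QSAR seed sweep).

## CLI

Each pipeline stage is a subcommand; `run-all` executes the whole workflow
from one YAML config:

```
toxprofiler simulate  --config examples/simulate.yaml --out out/sim
toxprofiler curves    --curves out/sim/curves.csv --out out/calls.csv
toxprofiler curate    --smiles out/sim/library.smi --out out/curated
toxprofiler profile   --matrix out/sim/assay_matrix.csv \
                      --labels-a out/are.csv --labels-b out/sim/labels.csv \
                      --metadata out/sim/assay_metadata.csv --out out/profile
toxprofiler run-all   --config examples/run.yaml --out out/full
```

`run-all` writes every stage's outputs (library, curve calls, assay stats,
RA table, QSAR predictions, fragment IVIVC) plus `run_report.json`; reports
are byte-reproducible for a fixed config and seed.

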