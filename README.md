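# ecbs-screen

Ligand-based virtual screening with **evolutionary chemical binding
similarity (ECBS)**. A pairwise compound-similarity model is trained so
that *evolutionarily related chemical pairs* (ERCPs) — compounds whose
binding targets are identical or homologous — score high. A
target-specific ensemble of probabilistic classifiers then scores a
chemical library against known reference ligands; each library compound's
final target-binding score is the maximum pairwise score over all
references (in [0, 1], higher = more likely binder). A staged funnel
(score cutoffs, top-k, external keep-lists) narrows the ranked hits.

## What's inside

| Module | Purpose |
| --- | --- |
| `ecbscreen.chem` | SMILES/SDF ingestion, canonicalization, Morgan fingerprints, Tanimoto |
| `ecbscreen.targets` | Target records, pairwise identity, homology graph, activity tables |
| `ecbscreen.pairs` | ERCP enumeration and labeling, symmetric pair features, ensemble training, ECBS scoring |
| `ecbscreen.screening` | Max-score library screening, ranking, funnel stages, TSV/CSV results |
| `ecbscreen.synthworld` | Synthetic compound/target worlds with planted actives; enrichment metrics (AUROC, EF@f, recall@k) |
| `ecbscreen.cli` / `ecbscreen.config` | `ecbs-screen` CLI, strict run configs, JSON run manifests |

## CLI

Simulate a synthetic world, train, score, funnel, evaluate:

```bash
# world.yaml: smiles_mode must be true so files round-trip through SMILES
cat > world.yaml <<'EOF'
n_target_families: 2
targets_per_family: 2
actives_per_target: 5
n_decoys: 100
motif_strength: 1.0
fingerprint_length: 512
smiles_mode: true
seed: 7
EOF
ecbs-screen simulate --config world.yaml --out-dir data/

cat data/references.smi data/library.smi > data/all.smi
ecbs-screen train \
    --compounds data/all.smi --activities data/activities.tsv \
    --identity data/identity.tsv --focal-target F0_T0 \
    --out model.joblib

ecbs-screen score --model model.joblib \
    --references data/references.smi --library data/library.smi \
    --out results.tsv

cat > stages.yaml <<'EOF'
stages:
  - {kind: score_cutoff, score_cutoff: 0.5}
  - {kind: top_k, top_k: 25}
EOF
ecbs-screen funnel --results results.tsv --stages stages.yaml --out hits.tsv

ecbs-screen evaluate --results results.tsv --truth data/truth.txt \
    --out metrics.json
```

`ecbs-screen pipeline --config run.yaml --out-dir out/` runs
train → score → funnel from a single config (see `tests/test_cli.py` for a
complete example). Every command accepts `--seed` and `--log-level` and
writes a `*.manifest.json` recording input hashes, the config hash, and
library versions; identical config + seed reproduce byte-identical result
files. Unknown config keys are hard errors.

Real-data screens use the same commands: pass your own `.smi`/SDF library,
reference ligands, an activity TSV (`compound_id  target_id  active`), and
either target FASTA sequences (`--targets`) or a precomputed identity TSV
(`--identity`).

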