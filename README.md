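# combonet

Signed directed regulatory-network scoring of drug-combination efficacy.

`combonet` builds a signed directed network of drug targets (activation /
expression edges are positive, inhibition / repression negative), propagates
each drug's effect outward from its immediate targets with per-hop
attenuation and negative-regulation blocking, partitions targets into
positive and negative effect sets by their summed intensity of action, and
classifies a drug pair from the relative network distances between those
sets: both same-sign set distances closer than the nearest cross-sign pair
means **synergism**, either one farther means **antagonism**.

## Modules

| Module | Purpose |
| --- | --- |
| `combonet.regnet_model` | Network/edge/profile data model, edge-list TSV I/O, centrality screen for key targets |
| `combonet.kgml_io` | KGML (KEGG pathway XML) parsing, drug-target and pair-label TSV readers/writers |
| `combonet.propagation` | Action-path enumeration, intensity-of-action computation, node-set partition |
| `combonet.set_distance` | Node-set distances, relative distances, classification and ranking score |
| `combonet.optimizer` | DE/rand/1/bin and grid search for the attenuation coefficients |
| `combonet.evaluation` | Confusion counts, accuracy, ROC-AUC |
| `combonet.synthetic` | Random signed networks and planted synergy/antagonism benchmarks |
| `combonet.cli` | `combonet` command-line entry point |
| `combonet.datasets` | Bundled 11-pair reference distance table |

## CLI

```bash
# KGML pathway files -> signed edge list
combonet build --kgml pathway1.xml --kgml pathway2.xml --out edges.tsv

# generate a synthetic labelled benchmark
combonet simulate --n-pairs 10 --synergy-frac 0.5 --seed 1 --out-dir sim/

# score drug pairs (defaults delta_pos=1.5, delta_neg=1.1, hop_max=2)
combonet score --edges sim/edges.tsv --targets sim/targets.tsv \
    --pairs sim/pairs.tsv --out assessments.tsv

# fit the attenuation coefficients
combonet optimize --pairs sim/pairs.tsv --edges sim/edges.tsv \
    --targets sim/targets.tsv --method de --seed 1 --out de_trace.tsv

# metrics against true labels
combonet evaluate --assessments assessments.tsv --pairs sim/pairs.tsv --out report.tsv

# metrics on the bundled reference distance table
combonet evaluate --reference --out reference_report.tsv
```

All runs write a `manifest.json` next to their outputs and are
byte-reproducible given the same inputs and seed. `score` and `optimize`
accept `--config config.json` whose keys override built-in defaults
(explicit flags win over the config file).

### File formats

All tabular I/O is TSV with a header row; `#` lines are comments;
undefined values serialize as `NA`.

- edge list: `source destination relation sign pathway_id`
- drug targets: `drug_id target action` with action in
  activation/upregulation/inhibition/downregulation
- pair labels: `drug_a drug_b label [condition]` with label
  synergism/antagonism
- distance tables: `d_pp d_mm d_pm d_mp label` (same-sign and cross-sign
  set distances)

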