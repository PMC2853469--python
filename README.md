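# cbpot

Residue-level, orientation-dependent statistical potentials for protein model
quality assessment, built on a **shuffled reference state**, together with the
decoy-ranking benchmark machinery used to compare scoring functions.

Each residue is reduced to its Cβ atom (a virtual Cβ is constructed for
glycine from the N–CA–C frame). Ordered residue pairs are counted by residue
type, by Cβ–Cβ distance bin (0–4 Å, then 1 Å increments) and, for the
orientation-dependent variants, by one of three discrete side-chain
orientation classes (parallel; antiparallel facing; antiparallel pointing
away). Energies are obtained by Boltzmann inversion of observed against
reference frequencies with Sippl-style sparse-count smoothing.

Four potential variants are derivable from the same machinery:

| variant        | reference state | orientation classes |
|----------------|-----------------|---------------------|
| `RF_CB`        | classic (all-type average) | 1 |
| `RF_CB_OD`     | classic         | 3 |
| `RF_CB_SRS`    | shuffled        | 1 |
| `RF_CB_SRS_OD` | shuffled        | 3 |

The shuffled reference permutes residue identities within each chain while
keeping every interaction-centre coordinate fixed. It is available as a
Monte-Carlo average over repeated shuffles (`shuffled_reference_mc`, default
1000 shuffles) and as the exact closed-form expectation of the same
randomisation (`shuffled_reference_exact`, the recommended production path).

## Package layout

- `cbpot.structure_io` — PDB chain ingestion, virtual Cβ construction,
  training-set selection filters (X-ray, resolution < 2.1 Å, R-value < 0.2,
  ≥ 50 residues, completeness, no ions) and greedy sequence-identity culling.
- `cbpot.geometry` — distance binning and the three-class orientation rule.
- `cbpot.counts` — ordered-pair count tables (no sequence-separation cutoff).
- `cbpot.reference` — classic and shuffled reference states.
- `cbpot.potential` — smoothing, energy tables, model scoring, table text I/O.
- `cbpot.benchmark` — GDT_TS combination, 2.5-unit binned ranking with the
  native-present rank-2 rule, decoy-set selection filters, rank summaries and
  pairwise one-tailed Wilcoxon signed-rank comparison.
- `cbpot.synthetic` — synthetic chains, interacting ensembles with known
  ground-truth pair energies (composition-preserving label-swap Metropolis
  sampling), and synthetic decoy benchmarks.
- `cbpot.cli` — `train` / `score` / `benchmark` / `simulate` subcommands.

## CLI

```sh
# synthetic training data
cbpot simulate chains --n-chains 20 --length 60 --seed 1 --out-dir chains/

# derive a potential (text energy table)
cbpot train --chain-list chains/chains.list --variant RF_CB_SRS_OD \
    --out rf_cb_srs_od.tsv

# score model PDB files
cbpot score --table rf_cb_srs_od.tsv --out scores.tsv model1.pdb model2.pdb

# benchmark scoring functions on a decoy manifest
cbpot simulate decoys --n-targets 20 --rho 0.7 --seed 2 --out decoys.tsv
cbpot benchmark --manifest decoys.tsv --out-prefix bench
```

Decoy manifests are tab-separated
(`target_id  model_id  gdt_ts  is_native  [energy]`); score files are
tab-separated (`model_id  energy  n_pairs_scored`). Exit codes: 0 success,
1 user error, 2 data error.

Real training data (PDB chains passing the selection filters) can be supplied
through the same `--chain-list` mechanism with `--apply-filters`; the package
never fetches from remote archives.

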