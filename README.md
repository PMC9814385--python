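# rxngen

Generate novel, stoichiometrically balanced chemical reactions by sampling
the latent space of a character-level sequence variational autoencoder (VAE)
trained on reaction equations written in a SMILES dialect, then score the
survivors with a per-species thermodynamic combination layer.

Reactions look like:

```
O=C=O + 2[H][H] >> C=O + O
```

i.e. ` + `-separated species per side, optional integer coefficients glued to
the SMILES, and `>>` (or `→`) between reactants and products.

## What is in the box

| module | purpose |
| --- | --- |
| `rxngen.reaction` | parse/serialize the reaction dialect, elemental composition (implicit H resolved via RDKit), balance check (elements + net charge), direction-sensitive canonical duplicate keys |
| `rxngen.corpus` | cleaning cascade (valid → balanced → ≤3 species/side → unique), character vocabulary, fixed-length integer coding, seeded 70/20/10 split |
| `rxngen.nn` | NumPy layers (embedding, dense, LSTM with variational recurrent dropout, Adam) with exact hand-derived backprop; the LSTM time loops are numba-jitted |
| `rxngen.vae` | embedding → BiLSTM encoder → Gaussian latent (mean/log-variance) → repeat-vector LSTM decoder → per-position softmax; reconstruction + KL-weighted loss |
| `rxngen.generator` | standard-normal prior sampling, greedy decoding, validation cascade (parse → species validity → dedup → balance), novelty reporting, species search |
| `rxngen.thermo` | ΔG°/ΔS°/Δμ aggregation over a pluggable per-species property table, dipole-from-point-charges, ±5 eV stability filter |
| `rxngen.synthetic` | seeded balanced-by-construction gas-phase toy corpora with controllable corruption, plus planted-value property tables |
| `rxngen.cli` | `rxngen` command wiring the stages together |

There is intentionally no deep-learning framework dependency: the VAE is
implemented in NumPy with finite-difference-verified gradients, so the whole
pipeline runs on a single CPU.

## CLI walk-through

```bash
rxngen synth  --seed 11 --out run                       # toy corpus + property table
rxngen clean  --corpus run/corpus.txt --out run         # filtering cascade + rejection log
rxngen train  --corpus run/clean_corpus.txt --out run   # VAE -> run/checkpoint.npz
rxngen generate --checkpoint run/checkpoint.npz \
                --corpus run/clean_corpus.txt \
                --count 100 --mode survivors --out run  # sample latent prior + validate
rxngen validate --equations run/generated.txt --out run # independent cascade audit
rxngen thermo --equations run/generated.txt \
              --properties run/species_thermo.csv \
              --augment-missing --out run   # synthesize props for novel species
rxngen filter --thermo-csv run/thermo_generated.csv --out run
rxngen report --training-csv run/thermo_clean_corpus.csv \
              --generated-csv run/thermo_generated.csv --out run
```

Every command accepts `--config config.yaml` (blocks: `synthetic`, `model`,
`generate`, `thermo`, `filter`, plus a master `seed`) and writes a
`manifest_<stage>.json` recording the config snapshot, seed, input checksums
and versions; a rerun from the same manifest reproduces artifacts
byte-for-byte.

Model hyperparameter defaults (embedding 500, latent 350, recurrent dropout
0.2, KL weight 0.1, Adam at 1e-5, 500 epochs, batch 25) are full-scale
reference settings; pass a reduced `model:` block for desk-scale runs, e.g.

```yaml
model: {embedding_dim: 64, latent_dim: 32, hidden_dim: 96,
        learning_rate: 5.0e-3, epochs: 200, batch_size: 8}
```

## File formats

- reaction text: UTF-8, one equation per line, `#` comments ignored
- property table CSV: `canonical_smiles,H_eV,S_eV_per_K,dipole_debye`
  (column names carry the unit contract and are checked)
- checkpoint: single `.npz` containing weights plus the embedded vocabulary
  and config, so generation cannot run against a mismatched alphabet
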