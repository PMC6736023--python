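# allercat

Tiered protein-allergenicity screening from sequence. Given query
proteins (FASTA) and a reference set of known allergens (sequences, plus
optional 3D structures with pre-built surface-epitope tables), each
query receives a **strong / weak / no evidence** call from a fixed
decision cascade:

1. **Gluten-like Q-repeat** — a compositional log-odds fingerprint
   trained on Celiac-associated peptides; any 9-mer window scoring
   within one SD of the training mean is strong evidence, evaluated
   first and independent of everything else.
2. **3D surface-epitope similarity** — the query is matched against
   structure representatives (internal Smith–Waterman with
   Karlin–Altschul E-values, cutoff 0.001); the best allergen hit is
   compared over all epitope-sized surface patches (surface residues at
   < 2.55 Å from the solvent-accessible surface; 12 Å patch radius;
   ≥ 13 residues). Epitope identity ≥ 93% ⇒ strong, below ⇒ weak.
3. **Linear-window rule** — the classical criterion of ≥ 35% identity
   over an 80-column window of a global alignment ⇒ strong.
4. **Triple-hexamer rule** — ≥ 3 distinct shared 6-mers after removing
   ambiguous (BJOUXZ) and low-complexity (entropy < 0.34 bits) hexamers
   ⇒ weak.

If nothing triggers, the call is *no evidence*.

## Layout

| module | contents |
|---|---|
| `allercat.seqdb` | FASTA I/O, 100%-identity merge/dedup, greedy identity clustering |
| `allercat.kmer` | hexamer entropy filter, inverted index, triple-hit rule |
| `allercat.qrepeat` | Q-repeat fingerprint training/scoring |
| `allercat.structure` | PDB parsing, surface detection, epitope-patch tables |
| `allercat.align` | global/local alignment, E-values, window rule, epitope identity |
| `allercat.workflow` | the cascade, batch CSV runs, self-screening |
| `allercat.fixtures` | seed-deterministic synthetic data (sequences, helices, peptides) |

## CLI

```bash
# generate a complete synthetic demo bundle
allercat make-fixtures --seed 1 --out demo/

# train the Q-repeat model and assess queries
allercat train-qrepeat --peptides demo/celiac_peptides.txt --out model.json
allercat assess --query demo/queries.fasta --allergens demo/allergens.fasta \
    --structures demo/structures --epitopes demo/epitopes.json \
    --qrepeat-model model.json --out calls.csv
```

Output CSV columns: `query_id, evidence, basis, best_allergen,
best_structure, epitope_identity, window_identity, hexamer_hits, notes`.

Other subcommands: `build-index` (hexamer index TSV), `build-epitopes`
(surface + epitope tables from a PDB directory), `self-screen`
(sensitivity of a bundle against itself, with `--jackknife`). Every
threshold can be overridden via `--config config.yaml` (keys mirror
`allercat.workflow.WorkflowConfig`).

## Notes and caveats

- E-values come from internal Smith–Waterman + Karlin–Altschul constants
  (λ = 0.267, K = 0.041 for gapped BLOSUM62), not from BLASTP with its
  database-size correction; hit sets near the 0.001 boundary may differ
  from an external BLASTP run.
- The hexamer entropy threshold (0.34 bits) is applied to the raw base-2
  Shannon entropy of the k-mer's residue composition; at k = 6 this
  removes exactly the homopolymeric hexamers.
- The linear-window rule slides over global-alignment columns; shorter
  alignments are evaluated as a single full-width window, which lets very
  short reference entries self-match.
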