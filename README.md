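# mirsig

Consensus-based inference of disease-specific miRNA–miRNA interaction
networks, and mining of interaction signatures conserved across related
diseases.

## The problem

Curated databases of miRNA differential expression (PhenomiR-style) record,
per study, the fold-change of individual miRNAs in individual diseases.
Direct miRNA–miRNA interactions are almost never measured, yet miRNAs are
known to act in co-regulated groups. `mirsig` infers candidate miRNA–miRNA
interactions from such fold-change records and asks which interactions are
*conserved* across all diseases of a class (e.g. gastrointestinal cancers) —
a putative signature component with diagnostic potential.

It is aimed at computational biologists who have tabular
`(study, PMID, disease, miRNA, fold-change)` records and want ranked
interaction networks plus class-level signatures, reproducibly, from a
library or a CLI.

## Method

1. **Expression matrices.** Each (miRNA, disease) pair is one *MD* node;
   the records become a studies × MD-nodes matrix under one of three scoring
   schemes for dual-valued (min/max) fold-changes: `average`
   (cell = (fc_min + fc_max)/2), `maxmin` (both values kept as separate
   sample rows), `missingmax` (absent maxima imputed from the node's other
   studies, then averaged).
2. **Six inference algorithms** score every ordered MD–MD pair: absolute
   Pearson and Spearman correlation, distance correlation (dCor), CLR
   (mutual information with per-node background z-scoring, combined as
   √(z_i² + z_j²)), MRNETB (max-relevance min-redundancy backward predictor
   selection on the MI matrix), and a GENIE3-style randomized tree ensemble
   whose per-target importances become directed scores.
3. **Borda consensus.** Each algorithm's scores are ranked descending; rank
   r among n edges earns (n − r)/(n − 1) normalized Borda points, and an
   edge's final confidence is the mean over the K algorithms:
   `final(e) = (1/K) Σ_k borda_k(e) ∈ [0, 1]`.
4. **Validation.** A co-citation truth network labels a same-disease pair
   (M_a, M_b, D_x) as validated when one PubMed ID associates both miRNAs
   with that disease; precision/recall and ROC curves sweep the confidence
   threshold.
5. **Signatures.** Per disease, the same-disease (type-3) edges with
   confidence ≥ 0.9 (or the top fraction) form the disease-specific miRNA
   interaction network (DMIN); intersecting the DMINs of every disease in a
   class leaves the conserved signature edges.

See `docs/methods.md` for assumptions, estimator details and limitations.

## Worked example

A synthetic record set with a planted 3-miRNA co-expression module shared by
3 diseases (12 miRNAs, 40 studies per disease):

```python
import mirsig as m
from mirsig.records import write_records

cfg = m.SynthConfig(n_mirnas=12, n_diseases=3, n_studies_per_disease=40, seed=42)
dataset, truth = m.generate_dataset(cfg)
write_records(dataset, "records.csv")

manifest = m.run_pipeline(m.RunConfig(input="records.csv", outdir="out", seed=42))
```

The manifest reports 1297 records over 36 MD nodes and 120 studies (1296
potential ordered interactions), six score matrices fused with K = 6. The
top of the consensus table (`out/consensus.csv`):

```
 rank                              interaction    score
    1 disease-01:mir-003 => disease-01:mir-001 0.997021
    2 disease-01:mir-001 => disease-01:mir-003 0.994771
    3 disease-01:mir-001 => disease-01:mir-002 0.991197
```

and the class signature (`out/signature_class-1.csv`) is exactly the planted
module triangle — every edge above confidence 0.9 in all three diseases:

```
mirna_a,mirna_b,disease_or_class,confidence
mir-001,mir-002,class-1,0.96604447974583
mir-001,mir-003,class-1,0.9261980407731003
mir-002,mir-003,class-1,0.9164019062748213
```

Scores are consensus confidences in [0, 1]: the mean normalized Borda rank
of the edge across the six algorithms; a signature edge's confidence is its
weakest value over the member diseases.

The same run from the shell:

```sh
mirsig synth --seed 42 --out records.csv
printf 'input = records.csv\noutdir = out\n' > run.cfg
mirsig run --config run.cfg --seed 42
```

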