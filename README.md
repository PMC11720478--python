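# freeassoc

Analysis of **free-association data** — the words that come to mind when
people are shown a cue — for researchers studying mental representations:
how laypeople think about a construct like *intelligence* or *risk*, and
how those representations differ between demographic groups.

The package implements a complete analysis engine for cue–response
tables, with first-class support for the two-level **mini-snowball**
design (first-level responses to a top cue become cues for second-level
responses):

1. **Import** a long-format table into three linked tables
   (participants, cues, responses) with referential-integrity checks.
2. **Preprocess**: normalize word forms (case / punctuation /
   whitespace) and run a manual spelling-correction round trip via
   exportable wordlists.
3. **Set targets** — the unit of analysis (cues, responses, or both) —
   once; every later stage is restricted to this set.
4. **Embed targets** from their response distributions: for targets
   *t* and responses *r*, counts *n<sub>tr</sub>* are reweighted with
   positive pointwise mutual information,

   PPMI(t, r) = max(0, ln [ n<sub>tr</sub> · n<sub>··</sub> /
   (n<sub>t·</sub> · n<sub>·r</sub>) ]),

   and compressed with a truncated SVD, embedding rows as
   U<sub>k</sub>Σ<sub>k</sub>. A pluggable provider interface supports
   external text-embedding models instead.
5. **Characterize targets**: response frequencies, psycholinguistic
   norms (valence, arousal, …) via user-supplied lookup tables, response
   summaries (e.g. mean position), and phi / point-biserial correlations
   between target retrieval and participant covariates.
6. **Cluster and map**: Louvain community detection on the
   positive-part cosine-similarity graph (or k-means / hierarchical),
   bootstrap **cluster-stability** co-assignment analysis, 2-D
   projection (PCA / classical MDS / UMAP), semantic maps and word
   clouds.
7. **Compare groups** at three levels: cluster cross-tables,
   frequency-weighted characteristic summaries, and **representational
   similarity analysis** (Spearman correlation of group-specific
   cosine-similarity matrices).

A synthetic-data module generates mini-snowball studies with known
latent topic structure and injected group effects, so the full pipeline
can be validated end-to-end against ground truth.

## Worked example

```python
import freeassoc as fa

# a 3-topic mini-snowball study: 60 participants x 30 responses each
config = fa.default_config(n_participants=60, n_topics=3, vocab_size=30, seed=11)
study = fa.generate_study(config)
study = fa.normalize(study)                 # lower-case, strip punctuation
study = fa.set_targets(study, "cues")       # top cue + first-level responses
study = fa.count_targets(study)             # first-level frequencies
study = fa.embed_targets(study, method="ppmi-svd", n_dim=20)
study = fa.cluster_targets(study, method="louvain", seed=5)

print(study.targets["cluster"].value_counts().sort_index())
# cluster
# 1    26
# 2    25
# 3    22        <- three clusters matching the three latent topics

stability = fa.cluster_stability(study, n_bootstrap=50, seed=5)
print(stability.cluster_level.round(2))
#       1     2     3
# 1  0.99  0.00  0.02
# 2  0.00  0.99  0.02
# 3  0.02  0.02  0.93
# diagonal ~1: targets stay with their cluster across bootstrap reruns
# (chance level for 3 clusters would be 1/3)

rsa = fa.compare_embeddings(study, ["gender"], n_dim=15)
print(fa.rsa_frame(rsa).round(3))
#   variable group_a group_b    rho            type  shared_targets
# 0   gender  female    male  0.422  lower_triangle              45
# moderate similarity: the groups share topics but retrieve them at
# different rates (the generator injects gender effects)
```

The same workflow is available from the shell:

```bash
freeassoc simulate --n-participants 60 --seed 11 study/
freeassoc normalize study/
freeassoc targets study/ --source cues
freeassoc count study/
freeassoc embed study/ --n-dim 20
freeassoc cluster study/ --seed 5
freeassoc project study/ --method umap --seed 5
freeassoc plot study/ map.svg
```

or as a single configured run (`freeassoc run config.json out/`), which
writes every intermediate table, the effective configuration, and a JSON
summary.

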