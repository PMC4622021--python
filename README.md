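# eqminer

Phenotype candidate extraction from pre-parsed sentences, and mining of
ranked phenotype–disorder association rules from literature co-occurrence.

The pipeline:

1. **Select** — keep sentences containing one of eleven abnormality trigger
   stems (prefix match: `abnormal*`, `aberra*`, `defect*`, `atypical*`,
   `unusual*`, `irregular*`, `anomal*`, `unhealthy*`, `inactiv*`, `inadeq*`,
   `characteristic*`).
2. **Annotate** — dictionary-based concept recognition (greedy
   leftmost-longest, per ontology namespace) over the sentence tokens using
   quality (PATO), anatomy (FMA/MA), chemical (RxNORM/ChEBI), phenotype
   (HP/MP) and disease (DOID/ORDO/OMIM) lexicons; concept hits are attached
   to the parse tree as `SEM` children of the covering preterminals.
3. **Match** — run nine built-in tree patterns (a small Tregex-style dialect
   with child `<`, following-sister `++` and coordination `+ CC` relations)
   over the semantically typed trees. Every pattern requires a PATO-linked
   adjective and an entity-linked noun (the entity–quality decomposition).
4. **Extract** — matched noun phrases become phenotype candidates,
   deduplicated on their normalized surface form, filtered by document
   frequency (default df ≥ 10) against a term → PMID index, and exported as
   XML (schema in `src/eqminer/schema/records.xsd`) or JSON lines.
5. **Mine** — phenotype and disorder PMID lists (disorder synonyms unified
   to MEDIC-style canonical names) become PMID-keyed transactions of `p/`
   and `d/` items; Apriori (defaults `sup=2.5e-7`, `conf=0.1`,
   `minlen=maxlen=2`) yields `{phenotype} → {disorder}` rules ranked by
   one-sided Fisher's exact p-value.

A synthetic-fixtures module generates every input with gold labels (pattern
templates and distractors, toy lexicons, seeded document indexes with
planted phenotype–disorder pairs), so the whole pipeline is testable
offline.

## CLI

```bash
pm fixtures --out-dir fixtures/                      # synthetic inputs + gold.json
pm select   --in fixtures/sentences.tsv --out selected.tsv
pm annotate --lexicons fixtures/pato.tsv,fixtures/fma.tsv,... \
            --in selected.tsv --out annotated.tsv
pm match    --in annotated.tsv --out matches.jsonl   # uses the 9 built-in patterns
pm extract  --in annotated.tsv --index fixtures/idx.tsv --min-df 10 \
            --out candidates.xml
pm mine     --phenotypes candidates.xml --pheno-index fixtures/idx.tsv \
            --disorders fixtures/medic.tsv --disorder-index fixtures/didx.tsv \
            --out rules.tsv
```

File formats: sentence TSV (`pmid`, `sent_index`, `text`, `ptb_tree` in
Penn-Treebank bracket notation), lexicon TSV (`term`, `concept_id`,
`namespace`) or OBO 1.2, document index TSV (term, comma-separated PMIDs),
MEDIC-style disease TSV (`DiseaseName`, `DiseaseID`, `AltDiseaseIDs`,
`Synonyms` pipe-separated; rows without an OMIM id are dropped).

## Layout

- `src/eqminer/corpus_model.py` — parse trees, bracket I/O, trigger selection
- `src/eqminer/concept_annotator.py` — lexicons, dictionary matching, SEM trees
- `src/eqminer/tregex_engine.py` — pattern language, matcher + brute-force oracle
- `src/eqminer/phenotype_extraction.py` — candidates, df filtering, export
- `src/eqminer/association_miner.py` — transactions, Apriori, Fisher ranking
- `src/eqminer/synthetic_fixtures.py` — seeded generators with gold labels
- `src/eqminer/patterns/builtin9.tgx` — the nine extraction patterns
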