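# genoprio

Phenotype-driven variant prioritization for annotated VCFs, with no network
access: every evidence source is a local, diffable TSV table.

The pipeline has four stages:

1. **Gene discovery** — turn phenotype/disease identifiers into gene lists:
   ontology superclass expansion (configurable walk depth), a known-gene
   query over four disease-gene sources (omim/orphanet/medgen/clinvar), and
   candidate generators from animal-model orthologs, paralogues, interaction
   neighborhoods, and tissue expression.
2. **Validity scoring** — consolidate the lists into a genes × sources count
   matrix and score each gene as `sum(weight[source] * count)`, classifying
   it known / candidate / novel.
3. **Variant classification** — evaluate ACMG-style evidence criteria per
   variant (13 built-in evaluators: PVS1, PS1, PS2, PM1, PM2, PM4, PM5, PP5,
   BA1, BS1, BP3, BP6, BP7; the remaining criteria can be supplied
   externally), detect trio de novo variants from a PED file, combine flags
   into the five-tier call, and write three VCFs: de novo subset, P/LP
   subset, and all variants.
4. **Causality ranking** — sort variants into four review bins (P/LP in a
   known / candidate / novel gene, VUS in a known gene), rank within bins by
   validity score, export the validity-vs-pathogenicity scatter, and filter
   points with a file-supplied lasso polygon.

A seeded synthetic generator (`genoprio.evidence_store.generate_store` /
`generate_trio_vcf`) produces evidence stores and trio VCF fixtures with
planted criteria profiles, so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic evidence store + trio fixture
genoprio --seed 1 --out-dir fix simulate --store-dir store

# full pipeline on the fixture
genoprio --out-dir out run \
    --vcf fix/trio.vcf --ped fix/trio.ped --store store \
    --phenotype MONDO:7000000

# or stage by stage
genoprio --out-dir lists discover --store store --phenotype MONDO:7000000 --tissue heart
genoprio --out-dir val validity --vcf fix/trio.vcf --genelists lists --weights king=3,ppi=1
genoprio --out-dir vip vip --vcf fix/trio.vcf --ped fix/trio.ped --store store
genoprio --out-dir caus causality --assessments vip/trio.assessments.tsv \
    --validity val/validity.tsv --lasso polygon.json
```

Global flags: `--config run.yaml` (see `genoprio.io_formats.config.RunConfig`
for every knob: frequency cutoffs, pLI cutoff, expansion/PPI levels, module
weights, INFO key remapping), `--seed`, `--out-dir`, `--log-level`.

Input VCFs use ANNOVAR-style INFO keys (defaults: `Gene.refGene`,
`Func.refGene`, `ExonicFunc.refGene`, `AAChange.refGene`,
`gnomAD_genome_ALL`), remappable via `info_key_map`.

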