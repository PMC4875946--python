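# domseln

Evolutionary contrasts between Pfam-domain and unassigned regions of
protein-coding sequences: a tested, reusable pipeline for

* mapping population SNVs onto spliced coding sequences and classifying them
  as synonymous / non-synonymous, by region (domain vs unassigned) and by
  minor-allele-frequency class (rare <0.5%, low 0.5–5%, common >5%);
* calling fixed divergences against a high-confidence ancestral sequence;
* fractional synonymous/non-synonymous site counting (unweighted
  Nei–Gojobori) and density odds-ratio tests (Fisher's exact);
* Direction of Selection, `Dn/(Dn+Ds) − Pn/(Pn+Ps)`;
* gamma-DFE inference from paired neutral/selected site-frequency spectra
  with per-class demographic distortion multipliers;
* amino-acid-composition chi-square and ENC (effective number of codons)
  confounder filters;
* SNP-free domain surveys with a uniform-placement randomization null,
  domain-length rank tests, and length–SNP-count Spearman correlations;
* a synthetic-data module generating genomes, gene models, domain hits,
  variants, and ancestral sequences with full ground truth.

## Package layout

| module | contents |
| --- | --- |
| `domseln.data_model_io` | core types (GeneModel, CodingSequence, DomainHit, RegionPartition, Variant) and FASTA/GFF3-GTF/VCF/domain-TSV readers and writers |
| `domseln.variant_classify` | effect/region/MAF classification, fixed-divergence calling, the region × effect × class counts table |
| `domseln.sites_density` | fractional site counting and density odds-ratio tests |
| `domseln.selection_dfe` | DoS, expected SFS under selection, gamma-DFE likelihood and fitting, |S|-category proportions |
| `domseln.composition_codon` | composition chi-square tests, Wright's ENC, gene filters |
| `domseln.domain_survey` | SNP-free domains, randomization test, length comparisons and correlations |
| `domseln.synthetic_data` | proteome/variant/ancestor simulators and the direct SFS-pair simulator |
| `domseln.cli_report` | `domseln` CLI and the end-to-end `run_pipeline` report |

## CLI

```bash
# generate a synthetic input bundle with ground truth
domseln simulate --seed 3 --out inputs/ --n-genes 100 --domain-fraction 0.44

# full pipeline from a YAML config (see below)
domseln run-all --config run.yaml --seed 17 --out out/

# single analyses
domseln dos 10153 18988 104956 81593
domseln density 5 10 1000 1000
domseln dfe --sfs sfs.tsv --n 20 --out fit.json
domseln enc --genome genome.fa --genes genes.gff3 --out enc.tsv
```

A config file lists either input paths or a `simulate:` block:

```yaml
# run.yaml — analysis of existing files
genome: inputs/genome.fa
gene_models: inputs/genes.gff3
variants: inputs/variants.vcf
domain_hits: inputs/domains.tsv
ancestral: inputs/ancestral.fa
out_dir: out
seed: 17
e_value_threshold: 1.0e-3
n_reps: 1000
```

```yaml
# run.yaml — synthetic end-to-end run
simulate: {n_genes: 100, theta: 0.03, divergence_rate: 0.01}
seed: 17
out_dir: out
```

`run-all` writes classified-variant and divergence TSVs, the counts table
(TSV + JSON), DoS, density, DFE, composition/ENC, and survey outputs, plus a
`manifest.json` recording the seed, input hashes, and per-stage record counts.

## Conventions

* Genomic and amino-acid coordinates are 1-based inclusive everywhere
  (GFF/VCF convention); internal CDS offsets are 0-based only inside
  `CodingSequence`.
* The amino-acid interval (s, e) projects to CDS nucleotides
  `3(s−1)+1 .. 3e`; a codon is wholly inside or outside a domain.
* The terminal stop codon is kept in the CDS but excluded from site counting
  and classification.
* Low-confidence ancestral calls are lower-case in the ancestral FASTA.
* Folded spectra are the default for DFE fitting; nonsense changes are pooled
  with non-synonymous (flagged per record so the alternative is recomputable).
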