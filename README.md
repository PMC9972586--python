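# intronq

Toolkit for **intronic genomic qPCR**: designing species-discriminating
primer pairs that sit entirely within the introns flanking a short exon
(so they amplify genomic DNA but never spliced cDNA), validating them by
in-silico PCR against the sibling species' genome, and quantifying the
human/murine composition of mixed samples (cell lines, PDX tumors) from
Ct values under the twofold-per-cycle model. A built-in simulator
generates Ct plates from known copy numbers and a designable synthetic
two-species genome pair, so the whole pipeline is testable offline.

## Modules

| module | what it does |
|---|---|
| `intronq.genome_io` | FASTA/GFF3 reading, gene models, intron derivation, strand-aware sequence extraction (0-based half-open internally) |
| `intronq.assay_design` | candidate-site enumeration, exhaustive intronic primer scan with nearest-neighbor Tm / GC / homopolymer filters, in-silico PCR, cross-species specificity (mismatch + 3' seed model), probe placement |
| `intronq.quantify` | replicate aggregation with Ct-40 censoring, ΔCt → fold → percentages, detection floors, mass↔copies conversion, RQ = 2^(−ΔΔCt), doubling time, tumor volume |
| `intronq.simulate` | seeded Ct generator (`ct = intercept − log_{1+E}(copies) + noise`), mixture/sensitivity plate series, synthetic genome pair with conserved exons and divergent introns |
| `intronq.assays` | the published human/mouse GAPDH intronic oligo sets |
| `intronq.cli` | `intronq design / ispcr / quantify / simulate` |

## CLI

```bash
# synthetic two-species fixture
intronq simulate --scenario genome_pair --seed 7 --out pair/

# design one discriminating assay per species, cross-validated
intronq design \
  --genome-a pair/genome_a.fasta --gff-a pair/genome_a.gff3 --gene-a geneA \
  --genome-b pair/genome_b.fasta --gff-b pair/genome_b.gff3 --gene-b geneA \
  --out design/

# simulate mixture plates (5,000 copies at 100/75/50/25/0 % human) and quantify
intronq simulate --scenario mixture_series --seed 7 --out mix/
intronq quantify --ct-table mix/plate_h0.5.csv --out report.tsv

# in-silico PCR of any primer pair against a FASTA template
intronq ispcr --primer-f CTGACTCAGCCCTGCAAAG --primer-r CCTGCCTTCCTCACCTGAT \
  --template genome.fasta
```

Exit codes: 0 success, 1 usage/I-O error, 2 validation failure (no
discriminating assay, no template detected). Every command writes its
resolved configuration (`run_config.yaml`) next to its outputs.

Ct tables are CSV/TSV with columns `sample_id, assay, replicate, ct`;
`Undetermined` / `N/A` / empty Ct values are treated as censored and
enter replicate means at the censor cycle (default 40), with an
additional detection-floor bound reported for fully censored assays.

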