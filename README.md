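# microexon

A toolkit for genome-wide analysis of micro-exons (exons of 3–51 nt) in
annotated genomes:

- **Extraction** — parse GFF3 + FASTA into gene models and pull out every
  annotated micro-exon with positional class (first/internal/last/single),
  coding status (CDS/UTR/mixed) and frame class (in-frame vs frame-shifting).
- **Detection** — scan spliced short-read alignments (SAM) for internal
  aligned blocks of micro-exon size flanked by ≥6-nt anchors; intervals
  supported by more than 10 reads across samples become candidates,
  labelled annotated / novel-in-gene / novel-intergenic.
- **PSI quantification** — build inclusion/exclusion junction references
  (100-nt mature-transcript flanks), count junction-spanning reads (≥3-nt
  overhang), and compute percent-spliced-in as
  `PSI = R_tot / (R_tot + R_skipped)` with `R_tot = 2·min(R_L, R_R)`;
  replicates merge to the mean when they differ by <0.10, and merged values
  classify as CS (PSI ≥ 0.9), AS (0.1 ≤ PSI < 0.9) or low.
- **Gene age** — filter 12-column tabular homology hits
  (e ≤ 1e-5, identity ≥ 0.3, query coverage ≥ 0.8) over 13 nested taxonomic
  databases and assign each gene the oldest qualifying phylostratum
  (no hit ⇒ PS13); PS1–3 are "old", PS11–13 "young".
- **Conservation** — map each coding micro-exon through a pairwise protein
  alignment into its collinear partner gene; same CDS phase and length ⇒
  conserved (substitutions counted by Hamming distance), homologs absorbed
  into longer exons are flagged as exon-merged; domain tables
  (InterProScan-style TSV) yield a domain-consistency category.
- **Synthetic data** — a deterministic simulator producing toy genomes with
  planted micro-exons, GFF3, spliced reads at controlled inclusion levels
  (pre-aligned SAM against genome and junction library), homology-hit
  tables with planted ages, and edited partner genomes — the ground truth
  for the whole test suite.

## CLI

All functionality sits behind the `mex` command:

```bash
mex annot-extract --gff ann.gff3 --fasta genome.fa --out-prefix mexons
mex detect --sam s1.sam --sam s2.sam --gff ann.gff3 --fasta genome.fa --out-prefix cand
mex psi --library junctions.fa --sam lib_s1.sam --design design.tsv --out-prefix psi
mex phylostrata --hits-dir hits/ --query-lengths hits/query_lengths.tsv --out ps.tsv
mex conserve --pairs pairs.collinearity --gff-a a.gff3 --fasta-a a.fa \
             --gff-b b.gff3 --fasta-b b.fa --out-prefix consv
mex simulate --config sim.yaml --out-dir fixture/
mex run --config run.yaml          # full pipeline + manifest
```

`mex run` takes a YAML config naming inputs and threshold overrides
(defaults: length 3–51 nt, 6-nt anchors, >10 supporting reads, 100-nt
flanks, 3-nt overhangs, coverage floor 10, PSI classes at 0.1/0.9, merge
delta 0.10, homology filters 1e-5/0.3/0.8) and writes per-stage TSVs, a
plain-text report and a JSON manifest with SHA-256 checksums; identical
configs reproduce identical runs.

A complete worked fixture + config can be produced in one call:

```python
from microexon.synthetic_data import SimConfig, write_run_fixture
config = write_run_fixture(SimConfig(seed=1, n_genes=20), "fixture/")
```

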