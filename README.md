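# replitax

Comparative-genomics toolkit for multipartite bacterial genomes:

* **Replicon architecture** — per-replicon GC, strand-symmetric dinucleotide
  relative-abundance (DRA) signatures, chromosome / putative chromid /
  ambiguous / megaplasmid classification, cumulative GC-skew profiles and
  replication-origin-count inference.
* **Alignment & orthology** — exact and k-mer-seeded Smith–Waterman with
  Karlin–Altschul e-values, bidirectional-best-hit (BBH) orthology with
  coverage/e-value gates, circos-style synteny links, cointegration mapping
  and translocated-block detection, global-alignment SNP counting.
* **Relatedness indices** — fragment-based ANI (ANIb-style, 1020-bp
  fragments), raw GBDP-d4 identity fraction, core-proteome AAI (cpAAI) from
  marker tables, whole-proteome AAI (wpAAI) from BBH orthologs.
* **Pan-genome & demarcation** — BBH-graph ortholog clustering,
  presence/absence matrices, strictly-quantified species-specific gene
  reports with compensation checks, CD-HIT-style greedy identity clustering,
  and threshold-based species (ANI ~95–96%) / genus (cpAAI ~86%) calls.
* **Synthetic genomes** — Markov-chain replicons with controlled GC and
  dinucleotide signatures, mutated strain pairs with exact identity ground
  truth, cointegrants, translocated gene blocks, and group-structured
  pan-genomes, all with machine-readable truth tables.

## CLI

```bash
replitax --seed 1 --out-dir out simulate --preset tumorigenes-like
replitax --out-dir out classify genome.fasta --gc-tol 1.0 --dra-tol 0.4
replitax --out-dir out synteny strainA/ strainB/ --evalue 1e-100 --min-cov 0.5
replitax --out-dir out relatedness --index anib strainA/ strainB/ strainC/
replitax --out-dir out pangenome strain*/ --groups groups.tsv
replitax --out-dir out demarcate --ani-matrix ani.tsv --cpaai-matrix cpaai.tsv
```

Strain directories contain a genome FASTA plus optional features
(`*.gff3` or 5-column `*.tsv`: gene_id, replicon_id, start, end, strand)
and protein FASTA (`*.faa`). Every flag has a config-file twin
(`--config file` with `key = value` lines); command-line flags win.

## DRA scale

DRA distances are reported as `(100/16) * sum |rho1 - rho2|` so that the
chromid screening threshold sits at 0.4. At this scale pure sampling noise
between same-signature replicons is roughly `0.5 / sqrt(L_eff / 250 kb)`
(with `1/L_eff = 1/L1 + 1/L2`), so sub-megabase replicons sit close to the
screening threshold even when their underlying signatures are identical.

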