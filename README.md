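# stwinscan

Detection and evolutionary analysis of donor-disrupted spliceosomal twin
introns — (D1,2) stwintrons — and their proliferated relatives in fungal
genomic DNA.

A (D1,2) stwintron is a complex intervening sequence in which an internal
U2 intron splits the 6-nt donor of an external U2 intron between its first
nucleotide (G1) and the second, so the feature begins `GGT` (rarely `GGC`)
and is excised by two consecutive splicing reactions, inside out. The
package implements:

- **seqcore** — sequence/feature model, IUPAC degenerate matching, reverse
  complement, FASTA/GFF3/TSV/JSON I/O (`stwinscan.seqcore`)
- **scanner** — canonical-intron and (D1,2) stwintron detection by a
  configurable nested motif grammar with intron-definition (smallest
  intron) pairing (`stwinscan.scanner`)
- **splice** — two-step excision simulation, the splinter intermediate,
  the one-step alternative product with exonised G1, and 60-nt junction
  verification queries (`stwinscan.splice`)
- **family** — affine-gap global alignment, seed-centric sister-family
  collection, and classification of relatives (full sister, sheared,
  cropped type-1/type-2, long intron, unrelated) (`stwinscan.family`)
- **symmetry** — terminal-inverted-repeat detection by aligning a sequence
  with its own reverse complement, degenerate 10-nt palindrome
  (`WTTCTAGAAA`) scanning, and a simplified two-molecule duplex score
  (`stwinscan.symmetry`)
- **crop** — the three stwintron→canonical-intron derivation paths
  (external-intron loss, microhomology-mediated central deletion between
  the palindrome copies, one-step long intron) and breakpoint inference
  for observed parent/derivative pairs (`stwinscan.crop`)
- **context** — intron phase, tandem-site-duplication scan,
  seamless-integration check against intron-less orthologue windows, and
  the junction position-frequency matrix (`stwinscan.context`)
- **synth** — synthetic genomes with planted element families and
  machine-readable ground truth for end-to-end testing (`stwinscan.synth`)
- **pipeline** — orchestration of scan → family → symmetry → crop →
  context with a single YAML configuration (`stwinscan.pipeline`)

## CLI

Every stage is a subcommand of `stwinscan`:

```sh
# generate a synthetic genome with planted elements and ground truth
stwinscan simulate --params sim.yaml --out-prefix sim/

# scan genomic DNA for stwintron candidates
stwinscan scan --fasta sim/genome.fasta --gff3 out.gff3 --tsv out.tsv

# splice simulation and junction queries for detected features
stwinscan splice --fasta elements.fasta --queries q.fasta --products p.tsv

# sister-family collection and classification against a seed element
stwinscan family --candidates c.fasta --seed seed.fasta --min-identity 55 --out fam.tsv

# terminal inverted repeats, palindrome copies, duplex score
stwinscan symmetry --fasta introns.fasta --out symmetry.tsv

# crop-path products and breakpoint inference
stwinscan crop --parents parents.fasta --derivatives d.fasta --out crops.tsv

# full pipeline from one YAML config
stwinscan run --config run.yaml
```

A minimal `run.yaml`:

```yaml
fasta: sim/genome.fasta
gff3: sim/genes.gff3        # optional, enables intron-phase calls
seed_fasta: seed.fasta      # optional, defaults to the most template-like hit
out_dir: results/run1
min_identity: 55.0
seed: 1
```

The pipeline writes `stwintrons.gff3/tsv`, `family.tsv`, `symmetry.tsv`,
`crops.tsv`, `context.tsv`, `pfm.tsv` and `summary.json` into `out_dir`.
Runs are deterministic: the same configuration produces byte-identical
outputs.

## Tests

```sh
python -m pytest tests/
```

The suite validates the scanner against brute-force enumeration oracles,
exercises every module, and runs the acceptance criteria in
`tests/test_acceptance.py`. Three acceptance tests (worked examples on the
published HCOc096A/HCOc066A element sequences) require sequence data from
a journal supplementary appendix that is not redistributable here; they
fail with an explanatory message unless `data/appendix_a.fasta` is
provided.

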