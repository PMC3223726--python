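# regulonkit

Comparative-genomics reconstruction of bacterial transcriptional regulons.

Given a set of related bacterial genomes (nucleotide FASTA + GFF3 with
protein translations), `regulonkit` rebuilds the regulons — the sets of
operons directly co-regulated by one transcription factor (TF) — the way
comparative regulatory genomics does it for a genus-scale pangenome:

1. **Orthology.** Proteins are clustered into orthologous groups as
   connected components of reciprocal best Smith–Waterman hits (BLOSUM62,
   affine gaps 11/1, identity ≥ 30% over the local alignment). Groups are
   classed *core* (all genomes), *variable* (several) or *strain-specific*
   (one).
2. **Motif discovery.** TF-binding sites are modelled as palindromic
   position weight matrices (PWMs). Weak palindromes — windows in which at
   most *m* of the L/2 complementary position pairs mismatch — seed an
   iterative profile refinement over the upstream intergenic regions (≤ 350
   bp) of a training set of operons; the converged profile with the largest
   information content is the recognition rule.
3. **Scanning.** Every genome encoding the TF is scanned with the PWM; the
   detection threshold is the lowest score observed in the training set, so
   all training sites are re-detected by construction.
4. **Consistency check.** A candidate target operon is kept only if
   orthologs of its lead gene in at least two *other* genomes also carry a
   candidate site (or if it is explicitly functionally linked to
   established members).
5. **Regulon assembly and analytics.** Known regulons are propagated from a
   model genome (ortholog projection → motif re-derivation → scan →
   filter, repeated once when the repertoire grows); novel regulons are
   inferred ab initio from pathway- or gene-cluster-derived training sets
   and attributed to a TF by genomic context (positional clustering,
   autoregulation, phylogenetic-pattern match). Cross-genome presence
   matrices, regulon overlap degrees, regulatory cascades and
   expression-correlation subregulons summarize the resulting network.

A fully seeded pangenome **simulator** (`regulonkit.synthetic_data`)
generates genomes with known orthology, implanted palindromic sites with
bounded mutational noise, single-genome decoy sites, and block-structured
expression, so every stage is testable against ground truth without any
external data.

## The model

With site counts `c(b, j)` over `N` aligned sites of width `L`, the PWM uses
pseudocounted log-odds weights against a uniform background:

    f(b, j) = (c(b, j) + 0.5) / (N + 2)
    w(b, j) = log2( f(b, j) / 0.25 )

A candidate site `s` scores `S(s) = Σ_j w(s_j, j)`, and a profile's
information content is `IC = Σ_j Σ_b f(b, j) · log2( f(b, j) / 0.25 )` bits.
Palindromic profiles are symmetrized (`c'(b, j) = c(b, j) + c(b̄, L−1−j)`),
which makes a window and its reverse complement score identically.

## Worked example

Simulate a 4-genome pangenome with an implanted 18-bp palindromic regulon
and rediscover its motif from one genome's upstream regions:

```bash
$ regulonkit simulate --out demo --seed 5 --genomes 4 --expression
wrote 4 genomes and truth tables to demo

$ regulonkit discover --fasta demo/G01.fna --gff3 demo/G01.gff3 --len 18 \
      --out demo/motif.meme
consensus TTGACAATATATTGTCAA  IC 15.82 bits
```

The discovered consensus is exactly the implanted palindrome
(`TTGACAATATATTGTCAA` equals its own reverse complement); 15.82 bits over
18 columns reflects the ≤ 2 mutations the simulator scatters over each
implanted site. Scanning a genome with a site model reports BED-like hits
(genome, 0-based interval, target operon, score, strand, sequence):

```bash
$ regulonkit scan --fasta demo/G01.fna --gff3 demo/G01.gff3 --sites sites.txt \
      --threshold auto | head -2
G01     1968    1986    opn_G01_0004    23.7947 +       TTGACAATATATTGTCAA
G01     3614    3632    opn_G01_0007    23.7947 +       TTGACAATATATTGTCAA
```

and the expression matrix splits into its two simulated co-expression
blocks at the default Pearson threshold r ≥ 0.5:

```bash
$ regulonkit analyze --expression demo/expression.tsv
subregulon_0    G01_0001,G01_0002,G01_0003,G01_0004,G01_0005,G01_0006
subregulon_1    G01_0007,G01_0008,G01_0009,G01_0010,G01_0011,G01_0012
```

The heavier workflows — BBH ortholog clustering, regulon propagation, ab
initio inference, TF attribution — are library calls; see
`regulonkit.orthology`, `regulonkit.regulon_reconstruction` and
`regulonkit.validation` for end-to-end examples.

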