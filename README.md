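# novitax

Metagenome-guided discovery of novel bacterial taxa.

Whole-metagenome shotgun (WMGS) assemblies of host-associated microbiomes
routinely contain *dark matter*: contigs from organisms no reference
database can name. `novitax` implements a discovery workflow that turns
such dark matter into cultivation targets and then confirms the novelty of
the resulting isolates. It was built around the bifidobacterial gut
community use case (the default target genus is *Bifidobacterium*) but
every stage is genus-agnostic.

The workflow:

1. **Genus binning** — each assembled contig is classified by its
   proteome: six-frame ORF calls are searched against a labeled reference
   panel and the contig's genus is decided by score-weighted best-hit
   voting. Abundance profiles are base-pair weighted.
2. **Novelty screening** — genus-assigned contigs longer than 5 kb are
   compared to every panel genome at three levels (nucleotide fragments,
   deduced proteins, chained chromosomal alignment). Contigs claimed by no
   known species — and not flagged as phage/plasmid by mobile-marker
   genes — are the *novel candidates*.
3. **Glycobiome profiling** — genes on novel candidates are assigned to
   glycosyl-hydrolase (GH) families; an editable rule table converts the GH
   repertoire into ranked carbon sources for selective cultivation (e.g. a
   GH13 pullulanase supports pullulan as the sole carbon source).
4. **Confirmation** — isolates obtained on those substrates are triaged by
   ITS identity, placed against the panel by fragment-based average
   nucleotide identity (reciprocal ANI; two genomes with ANI < 95% are
   distinct species), and positioned on a core-genome neighbor-joining
   phylogeny with gene-resampling bootstrap supports.

A deterministic synthetic-community simulator (`novitax.simulate`)
generates reference panels, divergent "novel species" genomes at controlled
substitution rates, GH/mobile-gene implants, assembly-like contig
fragmentation and spike-in titrations, with truth logs that score every
stage — the package's entire test suite runs on it.

## Worked example

Simulate a community in which a novel *Bifidobacterium* diverged 12% from
a panel species, then run the discovery workflow:

```bash
novitax simulate --spec community.yaml --out sim/
novitax panel build --genomes panel_genomes/ --metadata panel_meta.tsv --out panel/
novitax discover --contigs sim/contigs.fasta --panel panel/ --seed 1 --out run/
```

with `community.yaml`:

```yaml
seed: 3
n50: 8000
genome_length: 40000
members:
  - {id: A, abundance: 0.7}
  - {id: B, abundance: 0.3, divergence_from: A, sub_rate: 0.1}
```

where `panel_genomes/` holds genome `A` (the known species) and
`panel_meta.tsv` labels it `Bifidobacterium adolescentis`. `discover`
prints:

```json
{
 "target_fraction": 1.0,
 "screen_counts": {
  "known_species": 4,
  "novel_candidate": 3,
  "mobile_element": 0,
  "too_short": 1
 },
 "substrates": []
}
```

All assembled bp binned to the target genus (both community members are
bifidobacteria); four contigs matched the known panel species at the
species level (nucleotide identity ≥ 95% over ≥ 75% of the contig), one
was below the 5 kb screening floor, and the three contigs from the 10%
divergent genome `B` did not match — the dark-matter candidates written to
`run/novel_candidates.fasta`. The substrate list is empty because this toy
community carries no GH genes; implant a pullulanase (see
`novitax.simulate.implant_genes`) and `"pullulan"` appears with its
supporting gene ids.

Pairwise species checks run the same way; for an isolate simulated at 8%
divergence from the type strain:

```bash
novitax ani --query isolate.fasta --subject nearest_type_strain.fasta
# {"reciprocal_ani": 91.77, "boundary": "distinct_species", ...}
```

`novitax confirm` bundles ITS triage, nearest-genome ANI and the
bootstrapped core-genome NJ tree into one JSON report.

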