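# tandemkit

Discovery and characterization of tandem-repeat (satellite DNA) families
from noisy single-molecule long reads, with conserved-window FISH oligo
design — for plant cytogenomics groups (and anyone hunting satellites)
who have an uncorrected long-read archive (~10% error, CLR-style) and no
genome assembly.

Tandem repeats — arrays of a repeating unit (monomer) of tens to hundreds
of bp — dominate centromeric and subtelomeric heterochromatin, collapse in
assemblies, and make the best FISH probes. tandemkit finds them one read at
a time, without assembly:

1. **k-mer screen.** For each read ≥ 5 kb, all 12-mers are counted on the
   read's strand; a read is retained iff its 5th-most-abundant 12-mer occurs
   ≥ 8 times. An array of a unit ≥ 12 bp with *m* copies lifts ~every unit
   12-mer to count *m*, while random sequence stays near 1, so the rule
   passes arrays of ≥ 8 copies and yields orders-of-magnitude enrichment on
   a library.
2. **Self-alignment dot plots.** Maximal exact word matches (word 10, both
   strands) of a read against itself; tandem repeats appear as parallel
   diagonals whose perpendicular offsets are multiples of the unit length.
3. **Region calling & pattern classes.** The offset histogram of
   off-diagonal matches gives the period (the smallest strong offset whose
   harmonic series explains ≥ 50% of match support); repeat-dense intervals
   become regions with period, copy number, and a continuity index in
   [0, 1]. Each read is classified as one of five patterns: no-TR /
   low-complexity, full-read TR, partial, interspersed, or combo (two
   families in one read).
4. **polySeq family catalog.** Every family is a 1-kb block (2 kb for units
   > 500 bp) of its tiled consensus; blocks concatenate, append-only, into a
   single reference whose kilobase offsets identify families. Reads are
   assigned by block matching; unmatched repeat reads found new families.
5. **Consensus & summary.** Per-region consensus by iterative
   majority over monomer copies (alignment scores match = 2, mismatch = 2,
   indel = 7; arrays scoring < 50 are not reported; unit lengths rounded to
   the nearest 5 bp), with copy number, AT%, and reads-per-million
   abundance in a summary table.
6. **Divergence & probes.** Eleven consecutive internal monomers per read
   give within/between-read percent-identity matrices (black→yellow heat
   map, 40→70). Per-read consensi of a family are rotation-normalized,
   multiple-aligned (center-star), and the most conserved 22-column window
   becomes the FISH oligo candidate.

A seeded synthetic-read generator (units 50–600 bp, AT fraction 0.42–0.79,
five arrangement patterns, configurable substitution/insertion/deletion
noise totalling ~10%) makes every stage testable with known ground truth.

## Worked example

Simulate a library of 206 reads — three reads each from a 120-bp and a
225-bp family plus 200 random background reads — and run the pipeline:

```python
from tandemkit import SynthSpec, build_library, random_monomer
from tandemkit import ReadPattern, PipelineConfig, run_pipeline

fam = {120: random_monomer(120, 0.67, 71), 225: random_monomer(225, 0.64, 72)}
specs = [SynthSpec(seed=300 + i, monomer=fam[[120, 225][i % 2]], copies=10,
                   pattern=ReadPattern.FULL, read_len_target=6000,
                   read_id=f"t{i}")
         for i in range(6)]
build_library(specs, n_background=200, seed=4,
              fasta_path="library.fasta", truth_path="truth.tsv")
run_pipeline(PipelineConfig(input_fasta="library.fasta", output_dir="out", seed=1))
```

`out/family_summary.tsv`:

```
   family  unit_length  n_reads  reads_per_million  at_percent representative_read
HuluTR225          225        3              14563          63                  t1
HuluTR120          120        3              14563          68                  t0
```

The screen kept 6 of 206 reads (enrichment 34×, the inverse of the repeat
prevalence); both families were discovered de novo from the noisy reads,
named after their rounded consensus unit length, and counted at
3 reads × 10⁶ / 206 ≈ 14563 reads per million. `out/probes.tsv` holds one
conserved-window oligo per family, e.g.
`HuluTR120_oligo  5'-F-GATGTTATAGTCTGAATGTCTT` (conservation 1.0 across the
three per-read consensi). The same stages are available as CLI
subcommands: `tandemkit screen|dotplot|detect|assign|consensus|divergence|
probes|simulate|run`.

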