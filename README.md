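# circkit

A toolkit for circRNA degradome analysis: weighted 5′-end pileups and
cleavage-peak calling from degradome/PARE alignments, miRNA slice-site
prediction at peaks via a duplex minimum-energy model, back-splice-junction
references and junction-spanning decay-read detection, rolling-circle ORF
prediction, circRNA typing/quantification/differential expression, and
random-segment permutation enrichment — plus a deterministic synthetic-data
generator that plants ground truth for every stage.

## Tests

```
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests (hypothesis), and
`tests/test_acceptance.py`, which checks the headline guarantees: exact
equivalence of the peak caller with a per-position brute-force oracle, exact
binomial tails, duplex dynamic programming against an enumeration oracle,
end-to-end planted-cleavage recovery (recall/precision ≥ 0.95, zero calls
for shuffled miRNAs), junction-read recovery, rolling-circle ORF equivalence
with a periodic-sequence oracle, permutation calibration under a uniform
null, and byte-identical determinism.

## Command-line interface

All subcommands accept `--log-level` (logs go to stderr). Coordinates are
0-based half-open internally; GFF3/GTF and SAM are converted at the
boundary.

| command | purpose |
| --- | --- |
| `circkit simulate all --seed N --out DIR` | synthetic genome, gene models, circRNAs, degradome SAM, junction reads, peptides, with truth TSVs |
| `circkit pileup SAM -o TSV` | weighted 5′-end pileup (each alignment contributes 1/NH at its 5′ end; strands kept separate) |
| `circkit peaks PILEUP --lengths TSV -o TSV` | cleavage peaks: position weight ≥ 50% of the 21-nt window and exact binomial p ≤ 0.05 (null: uniform over the transcript by default, `--null-mode window` for 1/21) |
| `circkit cleave PEAKS TX_FASTA MIR_FASTA -o TSV` | miRNA cleavage calls: 51-nt context, duplex MFE ratio ≥ 0.7 (`--ratio-sense le` flips), predicted slice (opposite miRNA base 10) within ±1 of the peak |
| `circkit junction-ref BED FASTA -o FA` | back-splice junction references: last f + first f nt of the spliced circle, f = min(50, L/2), offset in the header |
| `circkit junction-reads READS JREF_FA -o TSV` | ungapped junction mapping (≤ 1 mismatch, ≥ 5 nt overhang on each side) |
| `circkit classify BED GFF3 -o TSV` | ecircRNA / ciRNA / intergenic typing; `--alt-bs-out` adds per-pair A5BS/A3BS/MIC labels |
| `circkit quant COUNTS TOTALS -o TSV` | RPM normalization of junction counts |
| `circkit de COUNTS ... -o TSV` | differential circRNAs: RPM fold change, exact two-proportion binomial p, BH FDR, cutoffs FC ≥ 2, p < 0.01, FDR ≤ 0.01 |
| `circkit corr X Y -o TSV` | Pearson correlation between expression profiles with a high-PCC flag at \|r\| ≥ 0.5 |
| `circkit corf CIRC_FASTA -o TSV` | rolling-circle ORFs from the 4×-concatenated circle (strict > 10 aa; rolling ORFs flagged) |
| `circkit uorf TX_FASTA CDS_BED -o TSV` | uORF/dORF/pORF annotation around a transcript CDS |
| `circkit peptide-filter PEPTIDES ORF_FASTA -o TSV` | drop peptides matching ≠ 1 ORF; keep ORFs with ≥ 1 unique peptide |
| `circkit enrich FEATURES TARGETS GFF3 -o TSV` | permutation enrichment versus equal-count, length-matched random transcript segments (add-one empirical p, z-score) |
| `circkit mirna-classify READS KNOWN -o TSV` | conserved (exact) / variant (≤ 3 edits) small-RNA matching |

### File-format notes

- circRNA tables are BED6/BED12; **column 5 (score) carries the back-splice
  junction read count**. 12-column rows define the exon chain through
  blockSizes/blockStarts; 6-column rows get a single-exon chain.
- Degradome alignments are consumed as SAM (reads are assumed already
  aligned; this toolkit is not an aligner). `NH` tags set the multi-mapping
  weight 1/n; without the tag, n defaults to the number of records sharing
  the read id. Soft-clipped bases are excluded when locating 5′ ends.
- All sequence input is normalized to uppercase DNA with U → T.
- Junction-reference FASTA headers carry `offset=N`, the index of the first
  base after the back-splice point.

### Duplex energy model

The `cleave` engine uses a deliberately simple, exactly testable pairing
model rather than a full thermodynamic parameter set: pair energies
G:C = −3, A:T = −2, G:T (wobble) = −1; +2 per bulged base inside the
duplex; +1 per opposed mismatch; dangling ends free. The decision statistic
is the ratio of the duplex minimum energy to the energy of the miRNA bound
to its exact complement, so a ratio of 1.0 means a perfect target. Energies
and penalties are configurable via `--config` (YAML keys `gc`, `at`, `gt`,
`bulge`, `mismatch`).
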