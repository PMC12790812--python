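# hifisim

A multi-sample PacBio HiFi (CCS) amplicon sequencing simulator for
microbiome benchmarking.

Benchmarking long-read amplicon workflows (ASV calling, taxonomic
assignment, demultiplexing) requires synthetic datasets with known ground
truth that still look like real sequencing output. `hifisim` generates such
datasets end to end from reference genomes:

1. **Genome-aware abundance simulation** — genome molarities are drawn from
   uniform, lognormal, power-law, or user-supplied (empirical)
   distributions; between-replicate biological variability is modeled as a
   squared coefficient of variation (CV²) that declines log-linearly with
   intensity, with negative-binomial-style dispersion and an explicit
   "predicted CV² ≤ 0 → 0" rule (replicates then share identical abundances
   before technical sampling). Counts are realized per sample by a
   Gamma (biological) + multinomial (technical) two-stage draw.
2. **In-silico PCR** — degenerate primers (IUPAC codes) are scanned against
   both strands of each genome; every primer-to-primer product is extracted.
   Genomes with multiple, non-identical rRNA operon copies yield multiple
   ASVs whose copy multiplicities (the *amplitype*, e.g. `3+2+1`) weight
   their expected abundances.
3. **Dual-barcoded template construction** — each sample × ASV molecule is
   `A + FwdBC + FwdPrimer + insert + rc(RevPrimer) + rc(RevBC) + A`,
   so downstream errors hit barcodes and insert alike (realistic
   demultiplexing evaluations).
4. **Pass-number-aware subread simulation** — the number of CCS passes per
   molecule (np) is drawn from an empirical histogram or a truncated
   lognormal (default range 2–59). Each pass walks the template with
   per-step accuracy 0.65 (default) and error-type ratio
   substitution:insertion:deletion = 6:55:39, alternating strands.
5. **Consensus calling** — a hierarchical plurality-vote consensus over the
   subreads produces the final read with per-base Phred qualities; reads
   are consolidated into one FASTQ with PacBio-style names
   (`<movie>/<zmw>/ccs`) plus a ground-truth sidecar TSV.

Evaluation utilities mirror how simulated datasets are judged against real
ones: nearest-reference edit-distance distributions, expected-vs-observed
abundance R², positional error profiles, and a KL-divergence grid search
that calibrates subread accuracy against a target edit-distance histogram.

## Worked example

Generate a synthetic mock community and simulate a run:

```sh
hifisim make-fixtures --out fx --n-genomes 3 --copies 3,2,1 \
    --core-length 250 --seed 4
hifisim simulate --genomes fx/genomes.fasta --barcodes fx/barcodes.tsv \
    --out run --n-samples 2 --reads-per-sample 10 \
    --max-primer-mismatch 0 --max-product-len 400 --seed 3
```

which prints

```
simulated 20 reads from 20 ZMWs (6 ASVs, 3 genomes) -> run
```

i.e. each of the 2 samples received its configured depth of 10 reads, one
consensus read per simulated molecule (ZMW), drawn from the 6 ASVs that
in-silico PCR extracted from the 3 genomes (the diverged operon copies of
genome 1 and 2 yield distinct ASVs). `run/` then contains `reads.fastq`
(Phred+33 CCS reads with provenance in the header comments), `truth.tsv`
(read → sample/genome/ASV/np), `asvs.fasta`, the ground-truth
`counts.tsv`, and `manifest.json` with per-stage counts and timings.

The same functionality is available as a library:

```python
from hifisim import RunConfig, extract_amplicons
from hifisim.pipeline import run_pipeline
```

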