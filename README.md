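# methylsense

Cytosine methylation can silence transcription-factor binding sites
directly, by changing the chemistry of the base a protein reads.  For
plant WRKY transcription factors this happens at the W-box element
(core TTGAC(C/T); written here in the displayed orientation
**G1 G2 T3 C4 A5 A6**): 5-methylcytosine at position 4 on the forward
strand (CHH context) strongly represses binding of the Arabidopsis
factor AtWRKY40, while methylation of the reverse-strand cytosines at
positions 1 and 2 barely matters.

`methylsense` packages the three quantitative layers of that analysis
for epigenomics and biophysics workflows:

1. **DAP/ampDAP ratio analysis** (`methylsense.dap_methyl`).  DAP-seq
   assays TF binding on native (methylated) genomic DNA; ampDAP-seq on
   PCR-amplified (methylation-free) DNA.  Per bound region the statistic
   is the normalized log-ratio

   `log10[ ((DAP + pc)/N_DAP) / ((ampDAP + pc)/N_ampDAP) ]`

   with pseudocount `pc = 1` read.  The module scans each region for its
   best PWM site (both strands, log-odds scoring), computes methylation
   density (fraction of cytosines with methylation probability > 0.5),
   counts methylated cytosines in the best site, and — per motif position
   and strand — the Pearson correlation *r* between methylation
   probability and the log-ratio, with Benjamini–Hochberg FDR control.
   Positions with fewer than 10 cytosines are masked `insufficient_n`;
   tested positions with q > 5% are blanked.

2. **BLI kinetics** (`methylsense.bli_kinetics`).  1:1 Langmuir model of
   Bio-Layer Interferometry sensorgrams:
   association `R(t) = R_eq (1 − e^{−(k_on C + k_off) t})` with
   `R_eq = R_max C/(C + K_D)`, dissociation `R(t) = R0 e^{−k_off t}`,
   `K_D = k_off/k_on`.  Global kinetic fits across concentrations and
   steady-state hyperbola fits of `R_eq(C)` are both provided, with
   identifiability flags for linear-regime and saturated data.

3. **Contact geometry** (`methylsense.struct_contacts`).  Multi-model
   PDB I/O, Kabsch superposition, in-silico C5 methylation of a cytosine
   (1.50 Å in-plane bond along the external bisector of C4–C5–C6), and
   exhaustive van der Waals contact (distance ≤ Σr + 0.5 Å, Bondi radii)
   and steric clash (overlap > 0.4 Å) enumeration.  This is the
   computational form of the structural claim: the W-box C4 base touches
   the conserved WRKY-domain tyrosine (Y154 in AtWRKY40), and a C5-methyl
   group occupies exactly that spot.

4. **Synthetic data** (`methylsense.synthetic_data`).  First-class
   generators for every input: peak sets with planted per-position
   methylation effects, sensorgram sets from a registry of ground-truth
   affinities (630 nM unmethylated, ~630 nM for 5mC1/5mC2, 12 µM for
   5mC4, 9.2 µM for the triple state), and an idealized C·G base-pair +
   tyrosine geometry fixture.

## Worked example

```python
from methylsense import synthetic_data as sd, bli_kinetics as bk

spec = sd.SCENARIOS["5mC4"]                       # K_D = 12 µM ground truth
sgs = sd.generate_sensorgram_set(spec, noise_sd=0.02 * spec.R_max, seed=1)
pairs = [(sg.concentration_nM * 1e-9, bk.extract_req(sg)) for sg in sgs]
print(bk.fit_steady_state(pairs).K_D_nM)
```

prints `11765.2…` — the steady-state K_D (nM) recovered from five noisy
sensorgrams at 0.2–5× K_D, within 2% of the 12 000 nM ground truth.  The
same pipeline on the unmethylated scenario returns ≈ 630 nM, a ~19-fold
affinity difference caused by the single methyl group.

On the genomics side:

```python
from methylsense import synthetic_data as sd, dap_methyl as dm

bundle = sd.generate_methylome_peakset(500, seed=1)
regions = bundle.to_regions()
hits = [dm.scan_best_site(r.sequence(bundle.genome), bundle.pwm, r.region_id)
        for r in regions]
table = dm.per_position_correlation(hits, regions, bundle.genome, bundle.track)
print(table[table.strand != "both"].round(3))
```

yields the per-position effect table; the three W-box cytosines come out

```
 position strand      r      q  n_cytosines  status
        1      - -0.288  0.000          414  tested
        2      - -0.455  0.000          491  tested
        4      + -0.595  0.000          490  tested
```

negative at all three positions, strongest at C4 — the planted effect
ordering (β₄ > β₂ > β₁) recovered from counts alone.  Non-cytosine
positions are masked `insufficient_n` or blanked by FDR.

The same functionality is exposed on the command line:

```sh
methylsense simulate peakset --n-regions 500 --seed 1 --out-dir data/
methylsense dap-analyze --peaks data/peaks.bed --genome data/genome.fa \
    --counts data/counts.tsv --methylome data/methylation.tsv \
    --pwm data/motif.meme --out-dir out/
methylsense simulate bli --scenario 5mC4 --noise-sd 0.02 --out-dir bli/
methylsense bli-fit --input bli/sensorgrams_5mC4.csv --mode both --out fit.yaml
methylsense simulate geometry --methylated --out-dir struct/
methylsense struct clashes --pdb struct/fixture_methylated.pdb --sel-a B --sel-b A
```

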