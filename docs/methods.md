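# Methods

## Coordinate and motif conventions

All genomic intervals are 0-based half-open (BED).  The W-box core is
stored in the displayed orientation **G1 G2 T3 C4 A5 A6** (the reverse
complement of TTGACC).  Under this convention the three W-box cytosines
are: C4 on the motif forward strand (CHH context in the synthetic
genomes), and C1/C2 on the reverse strand (paired under G1/G2).  Best-site
hits on the genomic minus strand are strand-normalized: motif position
indices always refer to the motif, and the genomic strand of each
cytosine is translated accordingly, so "position 4" denotes the same
base-pair contact in either orientation.

## DAP/ampDAP signal ratio

Per-region binding change is `log10(((d+pc)/N_d) / ((a+pc)/N_a))` with
read counts `d`, `a`, library sizes `N`, and pseudocount `pc = 1` read
added before normalization so the ratio is always finite.  Normalization
is counts-per-total-mapped-reads; no input-chromatin correction is
attempted.  The statistic is antisymmetric under swapping the two
experiments.

Two region-level methylation summaries exist in the field's usage and
both are provided: the *proportion* of cytosines (both strands) with
methylation probability strictly > 0.5 (`methylation_density`, the
default), and the absolute *count* (`methylated_cytosine_number`).  At
the TFBS level the count definition is used.  Methylation probability
enters the per-position correlations as a continuous covariate; the 0.5
threshold applies only to density/counting.  Cytosines absent from the
methylome track are treated as confidently unmethylated (probability 0)
rather than missing — bisulfite-style tracks routinely omit such sites —
and the run log records this policy.

## PWM scanning

PWMs hold per-position probabilities over ACGT with a pseudocount split
uniformly across bases: `(count + pc/4)/(n + pc)`.  Scanning maximizes
the log2-odds sum against the background over all windows on both
strands; `N` bases contribute 0 (background).  Ties (within float
round-off) resolve to the smallest forward-strand offset, then the
forward strand.  MEME minimal text is read and written for interchange;
motif discovery itself is out of scope — PWMs come from aligned sites or
files.

## Per-position correlation and masking

For each (motif position, strand), regions whose best-site base at that
position is a cytosine contribute one `(log-ratio, methylation
probability)` pair.  Pearson r with a two-sided p-value is computed when
at least 3 pairs exist and both variables vary; zero-variance cases are
reported with a distinct `zero_variance` status, never raised.
Benjamini–Hochberg adjustment (step-up with monotonicity enforcement) is
applied across all per-strand tests of one run — the narrowest
defensible family; pooled both-strand rows, reported for convenience,
form their own second family so they cannot dilute the primary one.
Masking then follows the heatmap convention: `insufficient_n` below 10
cytosines (regardless of significance), `blank_fdr` for q > 5%; masking
relabels rows and never alters r/p/q.

## Synthetic peaksets

`generate_methylome_peakset` plants one PWM-sampled site per region
(random orientation) in otherwise uniform-random sequence (200 bp
regions, 50 bp spacers, one chromosome).  Methylation probabilities:
planted-site cytosines draw from the bimodal mixture
`0.5·Beta(0.5, 5) + 0.5·Beta(5, 0.5)` so both unmethylated and strongly
methylated sites are common (necessary for correlation power);
background cytosines draw from `Beta(1, 10)`.  The generative law is

    log10(DAP/ampDAP) = baseline − Σ_pos β_pos · m_pos + ε,
    ε ~ Normal(0, noise_sd),

with `m_pos` the planted-site methylation probability at each effect
position.  ampDAP counts follow a region-specific log-normal baseline
(mean 200 reads, σ = 0.3 on the log scale; library sizes 10⁶); DAP
expected counts realize the ratio, and by default both are
Poisson-realized (`count_noise=True`) to mimic sequencing.  Setting
`count_noise=False` keeps exact expected counts so that, at
`noise_sd = 0` and pseudocount 0, the per-region log-ratio equals the
planted predictor to machine precision — the property the recovery tests
pin down.  Default effects β = {C4⁺: 0.6, C2⁻: 0.45, C1⁻: 0.25},
`noise_sd = 0.1`, 500 regions: a regime in which the planted ordering is
reliably recovered while single positions remain noisy enough that FDR
control matters.  Effects are constrained non-negative (methylation only
represses in this model) and may only sit on consensus cytosines.

What the generator does *not* emulate: read-level sampling, mappability
and GC bias, peak-calling uncertainty, correlated methylation along a
region, or sequence composition of a real genome.  Passing recovery
tests therefore demonstrates correctness of the inference chain under
the stated generative model, not performance on any particular organism.

## BLI simulation and fitting

Phases follow the standard schedule baseline 120 s / loading 300 s /
baseline 120 s / association 300 s / dissociation 900 s, sampled at 1 s.
Loading is treated as an immobilization offset removed by reference
subtraction and is not modelled mechanistically; drift, mass-transport
limitation and nonspecific binding are likewise not modelled — noise is
i.i.d. Gaussian in response units.

The scenario registry fixes ground truth per duplex methylation state
(K_D in nM; k_on = k_off/K_D exactly, so the kinetic identity is an
identity, not an estimate):

| scenario     | K_D (nM) | k_off (s⁻¹) | R_max (nm) |
|--------------|---------:|------------:|-----------:|
| unmethylated |      630 |       0.126 |        1.2 |
| 5mC1         |      630 |       0.126 |        1.2 |
| 5mC2         |      630 |       0.126 |        1.2 |
| 5mC4         |   12 000 |        0.60 |        1.1 |
| 5mC1+2+4     |    9 200 |        0.55 |        1.1 |
| C4T_mutant   |   20 000 |        0.80 |        1.0 |

The C4T_mutant entry is illustrative (flagged in code): it encodes
"binding loss comparable to a C→T substitution", not a measured
affinity.  The default concentration ladder is K_D × {0.2, 0.5, 1, 2, 5}
per scenario — five concentrations spanning the informative range of
both the kinetic and the equilibrium fit.  The shipped 16-mer duplex
sequence (`WBOX_DUPLEX_16MER`) is a synthetic stand-in containing the
core in the stated orientation.

Kinetic fitting shares k_on/k_off/R_max across concentrations
(log-parameterized Levenberg–Marquardt least squares).  Initialization:
k_off from a log-linear regression on early dissociation, per-curve
k_obs from single-exponential association fits, k_on from the slope of
k_obs versus C.  Equilibrium responses default to the mean of the final
5% of association samples; a single-exponential plateau estimate is
available and is preferred automatically for associations shorter than
20 samples (and advisable whenever k_obs·t_end ≲ 1, where the tail mean
is biased low).  The steady-state fit `R_eq = R_max·C/(C + K_D)` is
log-parameterized for positivity, initialized at R_max = 1.1·max(R_eq),
K_D = median(C); fits with K_D > 5× the largest tested concentration are
flagged `lower_bound_only`, and K_D < ⅕ the smallest `saturated`.
Steady-state and kinetic K_D can differ under noise; reports label both.

## Contact geometry

PDB I/O is fixed-width v3 with MODEL/ENDMDL multi-model support, 'A' or
blank altlocs kept, elements inferred from atom names when absent, and
coordinates round-tripping to the format's 10⁻³ Å precision; malformed
lines fail with their line number.  Superposition is the Kabsch SVD
solution (proper rotation enforced), defaulting to protein backbone
atoms N/CA/C, and is validated against an independent quaternion
(Horn) implementation.

Van der Waals criteria (no numeric convention is universal, so both
knobs are exposed): contact at distance ≤ Bondi-radii sum + 0.5 Å; clash
at overlap > 0.4 Å (the conventional severe-overlap threshold).
Hydrogens are not modelled; the C5-methyl carbon therefore uses a
united-atom radius of 2.00 Å approximating CH₃ bulk (configurable to
1.70 Å for explicit-carbon work).  `methylate_cytosine` places the C5M
carbon in the base plane at 1.50 Å along the external bisector of the
C4–C5–C6 angle — ideal thymine-like pyrimidine geometry — and refuses to
run twice on the same residue.

The geometry fixture is an idealized C·G base pair (standard base-frame
coordinates, exactly coplanar) plus a tyrosine phenol fragment whose
nearest ring carbon sits at the C···C radii sum + 0.2 Å from the
cytosine C5, along the direction the 5-methyl substituent occupies.  By
construction the unmethylated pair is a contact but not a clash, and
methylation converts it into a clash — the fixture encodes the
qualitative structural mechanism, not refined coordinates.  Ensemble
models differ only by deterministic rigid transforms (distances are
exactly preserved), which makes persistence trivially 1.0 on the fixture
while still exercising multi-model bookkeeping and superposition.
Ensemble refinement itself (homology modelling, simulated annealing) is
out of scope; users supply their own refined ensembles for real systems.

## Problem sizes and numerical choices

Analyses in the test-suite and the acceptance script run at 500 regions
per peakset, 50 noisy sensorgram replicates per scenario (2% of R_max
Gaussian noise), and 100 null-model seeds for the type-I calibration —
sizes at which the planted effects are comfortably identifiable and the
whole battery completes in about a minute.  Under the global null, BH at
the 5% level leaves no significant position in ≈ 95–97% of seeds, as
expected for a procedure whose family-wise error under the complete null
equals the nominal level.  Optimizer tolerances are set to 10⁻¹⁴–10⁻¹⁵
(xtol/ftol/gtol) so noiseless round-trips recover parameters to ~10⁻⁶
relative or better; scan tie-breaking uses a relative 10⁻¹² score
tolerance so float round-off cannot reorder genuinely tied windows.

## Known limitations

- The correlation analysis assumes one best site per region and ignores
  secondary sites; regions where the best site is ambiguous contribute
  noise.
- Pearson r on probability-vs-log-ratio pairs is a linear summary;
  saturating or threshold-like repression would be attenuated.
- The 1:1 BLI model cannot represent heterogeneous ligand densities or
  avidity; such data will show systematic residuals that the convergence
  flag does not capture.
- Contact analysis is distance-only: no angular terms, no energetics,
  and united-atom hydrogens only via the inflated methyl radius.
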