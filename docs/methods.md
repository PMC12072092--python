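# Methods

## Model structure

The presynapse is modelled as a well-mixed compartment system with eight
species (µM): serum tryptophan (Trp_serum), tryptophan available for
serotonin synthesis (Trp), a sequestered tryptophan pool (Trp_pool), the
intermediate 5-HTP, free cellular serotonin (fc5-HT), vesicular serotonin
(v5-HT), extracellular serotonin (e5-HT) and the degradation product
5-HIAA. Six steps are saturable (Michaelis–Menten): tryptophan transport
into the terminal, TPH2 hydroxylation, AADC decarboxylation, VMAT vesicle
loading, SERT reuptake and MAOA degradation. Five are first-order mass
action: pool filling and leakage, vesicular leakage (k_out = 40 h⁻¹),
exocytosis (k_release = 20 h⁻¹ acting on v5-HT) and the removal sinks
(Trp and Trp_pool at 0.2 h⁻¹, synaptic-cleft clearance at 400 h⁻¹, 5-HIAA
clearance at 1 h⁻¹). The simulation starts from a single 100 µM
Trp_serum bolus with every other species at zero and runs for three hours.

Assumptions inherited from the model family this design follows: no
autoreceptor or glial feedback, no postsynaptic receptors, no
electrically-patterned release, no dietary tryptophan input; genotype
affects protein *amount* (hence Vmax), never Km.

### Ambiguities resolved in the rate table

Two printed conventions are internally ambiguous; both readings are
implemented and switchable on `ModelParameters`:

* **Exocytosis** (`release_order`): first-order in v5-HT by default (the
  rate-table form); a zeroth-order constant-flux alternative exists because
  the accompanying prose quotes a flux in µM/h.
* **Pool leakage** (`pool_reverse_substrate`): proportional to [Trp] by
  default — the literal table form, which also reproduces the observed slow
  late-time decline of Trp_pool (its only remaining drain after Trp
  depletion is the 0.2 h⁻¹ removal) — with a [Trp_pool] alternative.
* The pool-exchange constants are printed with µM/h units but enter
  first-order rate laws; they are treated as 1/h (dimensional consistency).
* 5-HIAA removal is first-order with k = 1 h⁻¹, consistent with the
  measured first-order disappearance constant (~0.8 h⁻¹) it approximates.

## Genotype model

Each locus carries normalized allelic expression effects (reference
allele = 1): rs11178998 A=1/G=3, rs4290270 T=1/A=0.7, rs7305115 G=1/A=1.7,
5-HTTLPR L=1/S=0.3, uVNTR 3R=5R=0.2 (Low) and 3.5R=4R=1 (High — the
reference is the *high* expressor to avoid inflating MAOA Vmax). The
per-gene correction is a sum of two allelic effects: dominant for SERT
(S carriers get 0.3+0.3=0.6, L/L gets 2), additive averaged over the three
TPH2 loci, additive for MAOA with hemizygous males counted as homozygotes.
The reference genotype therefore has C = 2 everywhere, and
Vmax = E_NX · C · kcat · scale with E_NX = NX/1000 µM (TPH2 0.0462, SLC6A4
0.0112, MAOA 0.0186) and kcat in h⁻¹ (3600 × 5.03, 198.4, 18.6 s⁻¹
respectively). The uVNTR 2R allele exists in populations but has no
published expression effect; it is rejected unless the user supplies one.
Variant definitions ship as `serosim/data/variant_effects.yaml` and are
overridable.

### Vmax scale calibration (frozen)

The literal products E_NX·C·kcat use in-vitro turnover numbers of purified
protein, which ignore in-situ constraints (membrane insertion, substrate
channeling, regulatory inhibition); for SERT and MAOA they are orders of
magnitude away from rates consistent with the published baseline
concentrations, while for TPH2 the literal product is nearly exact. The
package therefore carries one dimensionless multiplier per gene,
calibrated once by `serosim.calibrate.calibrate_scales` and frozen as
`serosim.genotype.CALIBRATED_SCALE`:

| gene   | scale     | calibration role |
|--------|-----------|------------------|
| TPH2   | 1.011028  | solved exactly for the 13.62 µM baseline 5-HTP mean |
| SLC6A4 | 0.014295  | joint SD-weighted least squares over the five      |
| MAOA   | 0.036905  | downstream baseline quantities (see below)          |

The calibration evaluates *expected* cohort means over the exact
Hardy–Weinberg genotype lattice (genotype probability × per-genotype
simulation; 150 genotype classes), i.e. the infinite-cohort limit — no
sampling noise, no seed. 5-HTP is upstream of SERT/MAOA, so the TPH2 scale
separates into a 1-D root solve. The SERT/MAOA pair minimizes the
SD-weighted squared error over fc5-HT (0.88 ± 0.26 µM), v5-HT (2.47 ±
0.67 µM), e5-HT (70 ± 1.3 nM), 5-HIAA (0.60 ± 0.25 µM) and the
5-HIAA/fc5-HT ratio (0.67 ± 0.05); an exact two-target solve on (e5-HT,
5-HIAA) is nearly degenerate along a curve on which fc5-HT escapes its
published spread, so every published number participates, weighted by its
own precision. At the frozen scales the expected-lattice means are 5-HTP
13.620 µM, fc5-HT 0.898 µM, v5-HT 2.522 µM, e5-HT 70.46 nM, 5-HIAA
0.603 µM, ratio 0.672 — all within one published SD, most within 2%.
The scales were fixed once against these published numbers and are not
adjusted thereafter; `scale = 1` recovers the literal products.

## Simulation and summaries

LSODA integrates the balance equations (rtol 1e-8, atol 1e-12; the means
are tolerance-independent to at least six digits, which the suite checks).
"Step size 0.01" is the *output* grid (301 points on [0, 3] h); the
adaptive solver picks internal steps, as it must for a stiff system whose
fastest mode (~1300 h⁻¹ on e5-HT) is ~400× faster than the slowest.
Species within −1e-9 µM of zero are clipped to zero at output (solver
undershoot); anything more negative raises an error. The per-individual
statistic is the arithmetic mean of each species over all 301 grid rows,
t = 0 included (excluding it changes the mean by < 1/301 of the range).
Cohort simulation caches on the Vmax triple, since the trajectory is a
pure function of it.

## Synthetic cohorts

Cohorts are drawn under Hardy–Weinberg equilibrium at the published
unaffected-cohort allele frequencies (rs11178998 A 0.95; rs4290270 T 0.63;
rs7305115 G 0.60; 5-HTTLPR L 0.58; uVNTR 3R 0.302 / 3.5R 0.004 / 4R 0.685 /
5R 0.009), sex drawn at the published female fraction 0.657, X-linked
uVNTR with one draw for males and two for females. Loci are sampled
independently: the three TPH2 SNVs are physically linked in reality, but
no haplotype frequencies were published; a `haplotype_freqs` hook exists
for users who have them. The uVNTR frequencies are applied to both sexes.
What the generator deliberately does *not* emulate: linkage
disequilibrium, family structure, genotyping error, or any case/control
frequency differences (none were established per-variant) — so passing
baseline tests shows the model reproduces the published *unaffected*
cohort under HWE, not that it can re-identify the patient cohorts.

## Statistics

Two-sided throughout, tie corrections always applied. Mann-Whitney U uses
the exact null distribution when both groups have n ≤ 8 and the pooled
data are tie-free, otherwise the tie-corrected normal approximation
without continuity correction (so identical samples give p = 1 exactly).
Kruskal-Wallis takes its p from chi-square with k−1 df. Dunn's post hoc z
uses pooled midranks with the tie term Σ(t³−t)/(12(N−1)) and a Bonferroni
multiplier equal to the number of pairs. Cohen's d is the pooled-SD
variant with n−1 weights on raw species means; post hoc power uses the
noncentral-t two-sample approximation. For two groups Dunn's z satisfies
z² = H exactly, an identity the tests exploit as an independent oracle.

## Numerical and design notes

* The mass-balance identity (Σ derivatives = −total removal) holds
  analytically; tests verify it to 1e-10 on random states and audit the
  time-integrated removal against the 100 µM input to 0.1%.
* A fixed-step RK4 oracle at dt = 1e-4 h, written independently of the
  solver path, agrees with LSODA species means to 1e-4 relative.
* Genotype TSV is the canonical exchange format ("/"-separated unordered
  pairs; "3.5R" a literal token); concentrations are stored in µM, with nM
  companion columns on cohort output. Output files carry package version,
  seed and config hash as comment headers.
* Default problem sizes (n = 140 cohorts, 301-point grids, 150-class
  lattices) match the published study design and keep a full cohort run
  under ten seconds on one core.

## Known limitations

* The absolute Vmax scale for SERT and MAOA is under-determined by the
  published material (the per-genotype Vmax tables live in an appendix not
  available here); the calibrated multipliers absorb that uncertainty and
  are only as good as the baseline means they were fitted to.
* At the three-hour endpoint the species have not literally reached zero:
  the 5-HTP tail drains through AADC at ~Vmax/Km = 2.5 h⁻¹, leaving
  ~0.15–0.2 µM, and 5-HIAA (cleared at 1 h⁻¹) is still at ~30–70% of its
  peak. "Depletion by three hours" is qualitative — every non-pool species
  is past its peak and declining — and the package tests it as such.
* Group comparisons on synthetic cohorts characterize the *method*, not
  the patient populations; patient-level findings cannot be reproduced
  without the original genotypes.
* No post-transcriptional or post-translational regulation (TPH2 RNA
  editing, SERT trafficking): genotype acts on expression only.
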