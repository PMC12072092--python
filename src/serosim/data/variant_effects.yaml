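# Allelic effects on mRNA expression and population allele frequencies for
# the five modelled loci. Effects are normalized to the reference allele
# (= 1); frequencies are the published unaffected-cohort values used by the
# synthetic-cohort sampler. User configs may override any entry.
variants:
  rs11178998:
    gene: TPH2
    chromosome_mode: autosomal
    inheritance_model: additive
    alleles:
      A: {effect: 1.0, frequency: 0.95}
      G: {effect: 3.0, frequency: 0.05}
  rs4290270:
    gene: TPH2
    chromosome_mode: autosomal
    inheritance_model: additive
    alleles:
      T: {effect: 1.0, frequency: 0.63}
      A: {effect: 0.7, frequency: 0.37}
  rs7305115:
    gene: TPH2
    chromosome_mode: autosomal
    inheritance_model: additive
    alleles:
      G: {effect: 1.0, frequency: 0.60}
      A: {effect: 1.7, frequency: 0.40}
  5-HTTLPR:
    gene: SLC6A4
    chromosome_mode: autosomal
    inheritance_model: dominant
    dominant_allele: S
    alleles:
      L: {effect: 1.0, frequency: 0.58}
      S: {effect: 0.3, frequency: 0.42}
  uVNTR:
    gene: MAOA
    chromosome_mode: X-linked
    inheritance_model: additive
    alleles:
      3R: {effect: 0.2, frequency: 0.302, group: Low}
      3.5R: {effect: 1.0, frequency: 0.004, group: High}
      4R: {effect: 1.0, frequency: 0.685, group: High}
      5R: {effect: 0.2, frequency: 0.009, group: Low}
# Brain-stem expression (NX units) and turnover numbers (1/s) used to build
# the genotype-dependent maximal rates. E = NX/1000 (µM); kcat_h = 3600*kcat_s.
expression:
  TPH2: {nx: 46.2, kcat_per_s: 5.03}
  SLC6A4: {nx: 11.2, kcat_per_s: 198.4}
  MAOA: {nx: 18.6, kcat_per_s: 18.6}
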