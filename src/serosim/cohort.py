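"""Synthetic genotype cohorts under Hardy-Weinberg equilibrium.

The original study's genotypes are not public, so cohorts are emulated by
independent allele draws at the published unaffected-cohort allele
frequencies (autosomal loci: two draws per individual; the X-linked MAOA
uVNTR: one draw for males, two for females), with sex drawn from the
published female fraction.  Loci are sampled independently -- no linkage
disequilibrium, since no haplotype frequencies were published; a
``haplotype_freqs`` hook exists for callers who have them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .genotype import GenotypeRecord, VariantDef, default_variant_defs

__all__ = ["CohortSpec", "sample_cohort", "hwe_chi2", "genotype_counts"]

#: share of females among the unaffected reference group (92/140)
DEFAULT_FEMALE_FRACTION = 0.657


@dataclass(frozen=True)
class CohortSpec:
    """Size, sex ratio, allele frequencies and seed of a synthetic cohort."""

    n: int = 140
    female_fraction: float = DEFAULT_FEMALE_FRACTION
    allele_freqs: Mapping[str, Mapping[str, float]] | None = None  # None = packaged defaults
    seed: int = 0
    group_label: str = "unaffected"
    haplotype_freqs: Mapping[tuple, float] | None = None  # LD hook, unused by default

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.allele_freqs is not None:
            for locus, freqs in self.allele_freqs.items():
                total = sum(freqs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"{locus}: allele frequencies sum to {total}, expected 1"
                    )
                if any(f < 0 for f in freqs.values()):
                    raise ValueError(f"{locus}: negative allele frequency")

    def resolved_freqs(
        self, defs: Mapping[str, VariantDef] | None = None
    ) -> dict[str, dict[str, float]]:
        if self.allele_freqs is not None:
            return {k: dict(v) for k, v in self.allele_freqs.items()}
        defs = defs if defs is not None else default_variant_defs()
        return {loc: dict(vd.allele_frequency) for loc, vd in defs.items()}


def sample_cohort(
    spec: CohortSpec, defs: Mapping[str, VariantDef] | None = None
) -> list[GenotypeRecord]:
    """Draw a reproducible HWE cohort from ``spec``.

    Returns one :class:`GenotypeRecord` per individual, ids ``<group>_0001``
    onward; identical specs (including seed) give identical cohorts.
    """
    defs = defs if defs is not None else default_variant_defs()
    freqs = spec.resolved_freqs(defs)
    rng = np.random.default_rng(spec.seed)
    sexes = np.where(rng.random(spec.n) < spec.female_fraction, "female", "male")
    records = []
    width = max(4, len(str(spec.n)))
    for i in range(spec.n):
        genotype: dict[str, tuple[str, ...]] = {}
        for locus, vd in defs.items():
            alleles = list(freqs[locus])
            probs = np.array([freqs[locus][a] for a in alleles])
            n_draws = 1 if (vd.chromosome_mode == "X-linked" and sexes[i] == "male") else 2
            draws = rng.choice(alleles, size=n_draws, p=probs)
            genotype[locus] = tuple(str(a) for a in draws)
        records.append(
            GenotypeRecord(
                sample_id=f"{spec.group_label}_{i + 1:0{width}d}",
                sex=str(sexes[i]),
                group=spec.group_label,
                genotype=genotype,
            )
        )
    return records


def genotype_counts(
    records: Sequence[GenotypeRecord],
    locus: str,
    allele_a: str,
    grouping: Mapping[str, str] | None = None,
) -> tuple[int, int, int]:
    """Count (AA, Aa, aa) genotypes at a biallelic locus.

    ``grouping`` optionally collapses raw alleles to two classes first
    (e.g. uVNTR repeats to Low/High); only two-allele genotypes are counted,
    so hemizygous males are excluded at X-linked loci.
    """
    n_aa = n_ab = n_bb = 0
    for rec in records:
        alleles = rec.genotype.get(locus)
        if alleles is None or len(alleles) != 2:
            continue
        mapped = [grouping.get(a, a) if grouping else a for a in alleles]
        k = sum(1 for a in mapped if a == allele_a)
        if k == 2:
            n_aa += 1
        elif k == 1:
            n_ab += 1
        else:
            n_bb += 1
    return n_aa, n_ab, n_bb


def hwe_chi2(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg proportions, 1 df.

    ``counts`` are observed (AA, Aa, aa) genotype counts; expectations use
    the allele frequency estimated from the same counts.  Returns
    (statistic, p-value).
    """
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes to test")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    if p in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic: trivially in HWE
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))
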