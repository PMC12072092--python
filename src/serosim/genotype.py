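"""Genotype-to-Vmax mapping for TPH2, SERT and MAOA.

Five regulatory variants modulate mRNA expression of the three genes:
three *TPH2* SNVs (rs11178998, rs4290270, rs7305115), the *SLC6A4*
promoter length polymorphism 5-HTTLPR (L/S) and the X-linked *MAOA*
promoter uVNTR (repeat alleles grouped into low/high expressors).  Each
allele carries a normalized expression effect (reference allele = 1); a
per-locus genotype correction C_genotype combines the two allelic effects
(males count their single X allele twice), and the maximal rate becomes

    Vmax_gene = E_NX * C_genotype * kcat * scale_gene      (µM/h)

with E_NX the NX-derived protein concentration (NX/1000, µM), kcat the
turnover number in 1/h, and ``scale_gene`` an explicit dimensionless
calibration multiplier (1 = the literal product).

*SLC6A4* uses a dominant model (the low-expressing S allele dominates:
SS and LS both give C = 0.6, LL gives 2); *TPH2* averages the additive
C values of its three loci; *MAOA* is additive with the male-as-homozygote
rule.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "VariantDef",
    "GenotypeRecord",
    "ProteinExpression",
    "VmaxSet",
    "default_variant_defs",
    "default_expression",
    "group_uvntr_allele",
    "c_genotype",
    "kcat_to_per_hour",
    "enzyme_conc_from_vmax",
    "nx_to_concentration",
    "vmax_from_genotype",
    "CALIBRATED_SCALE",
    "UVNTR_GROUPS",
    "GENES",
    "LOCI",
]

GENES = ("TPH2", "SLC6A4", "MAOA")
LOCI = ("rs11178998", "rs4290270", "rs7305115", "5-HTTLPR", "uVNTR")

UVNTR_GROUPS = {"3R": "Low", "5R": "Low", "3.5R": "High", "4R": "High"}

#: Frozen per-gene calibration multipliers for the maximal rates, fixed once
#: against the published baseline (unaffected-cohort) concentration means and
#: never revisited; see serosim.calibrate for the procedure that produced
#: them.  scale=1 would be the literal E*C*kcat product.
CALIBRATED_SCALE: dict[str, float] = {
    "TPH2": 1.011028,
    "SLC6A4": 0.014295,
    "MAOA": 0.036905,
}


class GenotypeError(ValueError):
    """Invalid allele, genotype or locus."""


@dataclass(frozen=True)
class VariantDef:
    """One modelled locus: its gene, alleles and normalized allelic effects."""

    locus_id: str
    gene: str
    chromosome_mode: str  # 'autosomal' | 'X-linked'
    normalized_effect: Mapping[str, float]
    inheritance_model: str = "additive"  # 'additive' | 'dominant'
    dominant_allele: str | None = None
    allele_frequency: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.chromosome_mode not in ("autosomal", "X-linked"):
            raise GenotypeError(f"bad chromosome_mode {self.chromosome_mode!r}")
        if self.inheritance_model not in ("additive", "dominant"):
            raise GenotypeError(f"bad inheritance_model {self.inheritance_model!r}")
        if not any(abs(e - 1.0) < 1e-12 for e in self.normalized_effect.values()):
            raise GenotypeError(
                f"{self.locus_id}: no reference allele (normalized effect 1)"
            )
        if self.inheritance_model == "dominant" and (
            self.dominant_allele not in self.normalized_effect
        ):
            raise GenotypeError(f"{self.locus_id}: dominant allele not among alleles")

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(self.normalized_effect)

    def effect(self, allele: str) -> float:
        try:
            return self.normalized_effect[allele]
        except KeyError:
            raise GenotypeError(
                f"allele {allele!r} not defined for locus {self.locus_id}"
            ) from None


@dataclass(frozen=True)
class GenotypeRecord:
    """One individual: sex, group label and alleles at the five loci.

    ``genotype`` maps locus id to a tuple of alleles -- two for autosomal
    loci (order irrelevant) and for females at X-linked loci, one for males
    at X-linked loci.
    """

    sample_id: str
    sex: str  # 'male' | 'female'
    group: str
    genotype: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise GenotypeError(f"{self.sample_id}: sex must be male/female, got {self.sex!r}")

    def validate(self, defs: Mapping[str, VariantDef]) -> None:
        for locus, vd in defs.items():
            if locus not in self.genotype:
                raise GenotypeError(f"{self.sample_id}: missing genotype at {locus}")
            alleles = self.genotype[locus]
            expected = 1 if (vd.chromosome_mode == "X-linked" and self.sex == "male") else 2
            if len(alleles) != expected:
                raise GenotypeError(
                    f"{self.sample_id}: {locus} needs {expected} allele(s) for "
                    f"{self.sex}, got {len(alleles)}"
                )
            for a in alleles:
                if a not in vd.normalized_effect:
                    raise GenotypeError(
                        f"{self.sample_id}: unknown allele {a!r} at {locus}"
                    )


@dataclass(frozen=True)
class ProteinExpression:
    """Brain-stem expression level and turnover number of one gene."""

    gene: str
    nx: float
    kcat_per_s: float

    @property
    def kcat_per_h(self) -> float:
        return kcat_to_per_hour(self.kcat_per_s)

    @property
    def e_nx_uM(self) -> float:
        return nx_to_concentration(self.nx)


@dataclass(frozen=True)
class VmaxSet:
    """The three genotype-dependent maximal rates (µM/h) of one individual."""

    tph2: float
    sert: float
    maoa: float
    scale: Mapping[str, float] = field(default_factory=lambda: {g: 1.0 for g in GENES})

    def __post_init__(self):
        for name in ("tph2", "sert", "maoa"):
            if getattr(self, name) < 0:
                raise GenotypeError(f"Vmax {name} must be >= 0")


def _load_packaged_table() -> dict:
    text = (
        importlib.resources.files("serosim").joinpath("data/variant_effects.yaml")
    ).read_text()
    return yaml.safe_load(text)


def default_variant_defs() -> dict[str, VariantDef]:
    """The five packaged locus definitions with published allelic effects."""
    raw = _load_packaged_table()["variants"]
    defs = {}
    for locus, entry in raw.items():
        defs[str(locus)] = VariantDef(
            locus_id=str(locus),
            gene=entry["gene"],
            chromosome_mode=entry["chromosome_mode"],
            inheritance_model=entry["inheritance_model"],
            dominant_allele=entry.get("dominant_allele"),
            normalized_effect={str(a): float(v["effect"]) for a, v in entry["alleles"].items()},
            allele_frequency={str(a): float(v["frequency"]) for a, v in entry["alleles"].items()},
        )
    return defs


def default_expression() -> dict[str, ProteinExpression]:
    """Packaged NX expression levels and kcat values per gene."""
    raw = _load_packaged_table()["expression"]
    return {
        g: ProteinExpression(gene=g, nx=float(e["nx"]), kcat_per_s=float(e["kcat_per_s"]))
        for g, e in raw.items()
    }


def group_uvntr_allele(allele: str, extra_effects: Mapping[str, str] | None = None) -> str:
    """Classify a MAOA uVNTR repeat allele as 'Low' or 'High' expression.

    3R and 5R are low expressors; 3.5R and 4R high.  2R exists in
    populations but has no published expression effect, so it is rejected
    unless the caller supplies a grouping via ``extra_effects``.
    """
    if extra_effects and allele in extra_effects:
        return extra_effects[allele]
    if allele == "2R":
        raise GenotypeError(
            "uVNTR allele 2R has no published expression effect; "
            "supply one explicitly to include it"
        )
    try:
        return UVNTR_GROUPS[allele]
    except KeyError:
        raise GenotypeError(f"unknown uVNTR allele {allele!r}") from None


def kcat_to_per_hour(kcat_per_s: float) -> float:
    """Convert a turnover number from 1/s to 1/h."""
    if kcat_per_s <= 0:
        raise ValueError(f"kcat must be > 0, got {kcat_per_s}")
    return 3600.0 * kcat_per_s


def enzyme_conc_from_vmax(vmax: float, kcat_per_h: float) -> float:
    """Protein concentration E = Vmax/kcat (µM)."""
    if vmax <= 0:
        raise ValueError(f"vmax must be > 0, got {vmax}")
    if kcat_per_h <= 0:
        raise ValueError(f"kcat must be > 0, got {kcat_per_h}")
    return vmax / kcat_per_h


def nx_to_concentration(nx: float) -> float:
    """Map an NX expression unit to a protein concentration: E = NX/1000 µM."""
    if nx < 0:
        raise ValueError(f"NX must be >= 0, got {nx}")
    return nx / 1000.0


def _locus_allele_sum(record: GenotypeRecord, vd: VariantDef) -> float:
    """Combined allelic effect a1+a2 at one locus (males: 2*a on the X)."""
    alleles = record.genotype[vd.locus_id]
    if vd.chromosome_mode == "X-linked" and record.sex == "male":
        (a,) = alleles
        return 2.0 * vd.effect(a)
    if vd.inheritance_model == "dominant":
        # heterozygotes behave as homozygous for the dominant allele
        if vd.dominant_allele in alleles:
            return 2.0 * vd.effect(vd.dominant_allele)
        return sum(vd.effect(a) for a in alleles)
    return sum(vd.effect(a) for a in alleles)


def c_genotype(
    record: GenotypeRecord, defs: Mapping[str, VariantDef] | None = None
) -> dict[str, float]:
    """Per-gene genotype correction factors C_genotype.

    TPH2 averages the (a1+a2) sums of its three loci so that three SNVs do
    not triple-count relative to the single-locus genes; SLC6A4 and MAOA
    use their single locus directly.  The all-reference genotype gives
    C = 2 for every gene.
    """
    defs = defs if defs is not None else default_variant_defs()
    record.validate(defs)
    per_gene_sums: dict[str, list[float]] = {}
    for vd in defs.values():
        per_gene_sums.setdefault(vd.gene, []).append(_locus_allele_sum(record, vd))
    return {g: sum(v) / len(v) for g, v in per_gene_sums.items()}


def vmax_from_genotype(
    record: GenotypeRecord,
    expr: Mapping[str, ProteinExpression] | None = None,
    defs: Mapping[str, VariantDef] | None = None,
    scale: Mapping[str, float] | None = None,
) -> VmaxSet:
    """Build an individual's VmaxSet: Vmax = E_NX * C_genotype * kcat * scale."""
    expr = expr if expr is not None else default_expression()
    scale = dict(scale) if scale is not None else {g: 1.0 for g in GENES}
    cg = c_genotype(record, defs)

    def one(gene: str) -> float:
        e = expr[gene]
        return e.e_nx_uM * cg[gene] * e.kcat_per_h * scale.get(gene, 1.0)

    return VmaxSet(tph2=one("TPH2"), sert=one("SLC6A4"), maoa=one("MAOA"), scale=scale)
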