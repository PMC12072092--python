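"""How SERT and MAOA genotypes reshape the 5-HIAA time course.

Simulates six individuals sharing the same TPH2 genotype but differing at
5-HTTLPR (L/L, L/S, S/S) and the MAOA uVNTR (High/High vs Low/Low), and
prints the peak and time-mean of the degradation product 5-HIAA for each.
Low-expression MAOA alleles slow serotonin degradation, lowering 5-HIAA.
"""

from serosim import (
    CALIBRATED_SCALE,
    GenotypeRecord,
    simulate_individual,
    summarize_trajectory,
    vmax_from_genotype,
)


def person(httlpr, uvntr):
    return GenotypeRecord(
        sample_id=f"{'/'.join(httlpr)}+{'/'.join(uvntr)}",
        sex="female",
        group="demo",
        genotype={
            "rs11178998": ("A", "A"),
            "rs4290270": ("T", "T"),
            "rs7305115": ("G", "G"),
            "5-HTTLPR": httlpr,
            "uVNTR": uvntr,
        },
    )


print(f"{'genotype':<16}{'peak 5-HIAA (µM)':>18}{'mean 5-HIAA (µM)':>18}")
for httlpr in [("L", "L"), ("L", "S"), ("S", "S")]:
    for uvntr in [("4R", "4R"), ("3R", "3R")]:
        rec = person(httlpr, uvntr)
        vm = vmax_from_genotype(rec, scale=CALIBRATED_SCALE)
        traj = simulate_individual(vm)
        mean = summarize_trajectory(traj).means["hiaa5_mean"]
        peak = traj.species("hiaa5").max()
        print(f"{rec.sample_id:<16}{peak:>18.3f}{mean:>18.3f}")
print(
    "\nHomozygous high-expression uVNTR (4R/4R) yields ~5x the 5-HIAA of the\n"
    "low expressor (3R/3R), mirroring their 5x expression-effect ratio; the\n"
    "SERT genotype modulates it further by controlling how much serotonin is\n"
    "recycled into the degradable pool (S carriers recycle less)."
)
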