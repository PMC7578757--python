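"""Cross tables of the WZ/ZZ system and the 3:1 progeny sex ratio.

Builds the offspring genotype distribution for each admissible cross and
partitions the WZ x WZ (intersex male x female) progeny into functional
classes. The headline numbers: 25% of that progeny are WW females, and with
no intersex emergence the phenotypic female:male ratio is 3:1.
"""

from wzpop import (
    Genotype,
    PhenotypeClass,
    offspring_genotype_distribution,
    phenotype_partition,
)

for sire, dam in [(Genotype.ZZ, Genotype.WZ), (Genotype.WZ, Genotype.WZ),
                  (Genotype.ZZ, Genotype.WW), (Genotype.WZ, Genotype.WW)]:
    g = offspring_genotype_distribution(sire, dam)
    print(f"{sire.value} male x {dam.value} female -> "
          + ", ".join(f"{k.value}: {v:.2f}" for k, v in g.items() if v > 0))

print()
g = offspring_genotype_distribution(Genotype.WZ, Genotype.WZ)
c = phenotype_partition(g, alpha=0.0)
females = c[PhenotypeClass.WZ_FEMALE] + c[PhenotypeClass.WW_FEMALE]
males = c[PhenotypeClass.ZZ_MALE] + c[PhenotypeClass.IS]
print(f"WZ x WZ at alpha=0: {100*g[Genotype.WW]:.0f}% WW females, "
      f"female:male = {females/males:.0f}:1")
# A quarter of the progeny lack the Z chromosome entirely (WW females);
# because WZ and WW offspring are all female, only the ZZ quarter is male.
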