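"""Exact Mendelian genetics of a WZ/ZZ sex-determination system with intersex males.

In the system modelled here females are heterogametic (WZ) or, unusually,
homogametic (WW); males are ZZ. A fraction ``alpha`` of WZ-genotype progeny
emerge as *intersex* individuals (IS): animals bearing the female WZ genotype
that function as males. Crossing such a WZ male with a WZ female yields WW
females (25% of the progeny) and, at ``alpha = 0``, a 3:1 phenotypic
female:male ratio.

This module provides the gamete-segregation and cross tables, the
``alpha``-partition of genotypes into the four functional classes, and the
band-pattern -> genotype calling used with the W- and Z-specific PCR markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Genotype(str, Enum):
    """Sex-chromosome genotype. WZ is the only heterogametic genotype."""

    ZZ = "ZZ"
    WZ = "WZ"
    WW = "WW"


class PhenotypeClass(str, Enum):
    """The four functional classes of the population.

    IS (intersex) individuals carry the WZ genotype but reproduce as males;
    functional males are {ZZ_MALE, IS}, functional females {WZ_FEMALE,
    WW_FEMALE}.
    """

    ZZ_MALE = "ZZ_male"
    IS = "IS"
    WZ_FEMALE = "WZ_female"
    WW_FEMALE = "WW_female"


#: Canonical ordering of the four classes used by arrays throughout.
CLASS_ORDER: tuple[PhenotypeClass, ...] = (
    PhenotypeClass.ZZ_MALE,
    PhenotypeClass.IS,
    PhenotypeClass.WZ_FEMALE,
    PhenotypeClass.WW_FEMALE,
)

MALE_CLASSES = frozenset({PhenotypeClass.ZZ_MALE, PhenotypeClass.IS})
FEMALE_CLASSES = frozenset({PhenotypeClass.WZ_FEMALE, PhenotypeClass.WW_FEMALE})

#: Genotype underlying each functional class.
CLASS_GENOTYPE = {
    PhenotypeClass.ZZ_MALE: Genotype.ZZ,
    PhenotypeClass.IS: Genotype.WZ,
    PhenotypeClass.WZ_FEMALE: Genotype.WZ,
    PhenotypeClass.WW_FEMALE: Genotype.WW,
}

_VALID_SIRES = frozenset({Genotype.ZZ, Genotype.WZ})
_VALID_DAMS = frozenset({Genotype.WZ, Genotype.WW})


class UndeterminedCallError(ValueError):
    """Raised when a marker call has neither band: a genotyping failure."""


class InadmissiblePairError(ValueError):
    """Raised for a genotype/phenotype combination the system cannot produce."""


@dataclass(frozen=True)
class MarkerCall:
    """Presence/absence of the W- and Z-specific PCR bands for one animal."""

    w_band: bool
    z_band: bool


def gamete_distribution(parent: Genotype) -> dict[str, float]:
    """Probability of transmitting each sex chromosome.

    Each of the parent's two sex chromosomes is transmitted with
    probability 1/2, so heterogametic WZ parents give {W: 0.5, Z: 0.5} and
    homogametic parents transmit their single chromosome type with certainty.
    """
    parent = Genotype(parent)
    if parent is Genotype.WZ:
        return {"W": 0.5, "Z": 0.5}
    if parent is Genotype.ZZ:
        return {"W": 0.0, "Z": 1.0}
    return {"W": 1.0, "Z": 0.0}


def offspring_genotype_distribution(
    sire: Genotype, dam: Genotype
) -> dict[Genotype, float]:
    """Offspring genotype probabilities for a sire x dam cross.

    The distribution is the outer product of the two parents' gamete
    distributions. Sires must be functional males ({ZZ, WZ}: ZZ males or
    WZ intersex males); dams must be females ({WZ, WW}). The canonical
    WZ x WZ (intersex x female) cross gives {ZZ: 1/4, WZ: 1/2, WW: 1/4}.

    Raises
    ------
    ValueError
        If the sire or dam genotype is not admissible for its role.
    """
    sire, dam = Genotype(sire), Genotype(dam)
    if sire not in _VALID_SIRES:
        raise ValueError(f"invalid sire genotype {sire.value!r}: sires must be ZZ or WZ")
    if dam not in _VALID_DAMS:
        raise ValueError(f"invalid dam genotype {dam.value!r}: dams must be WZ or WW")
    pw_s = gamete_distribution(sire)["W"]
    pw_d = gamete_distribution(dam)["W"]
    dist = {
        Genotype.WW: pw_s * pw_d,
        Genotype.WZ: pw_s * (1.0 - pw_d) + (1.0 - pw_s) * pw_d,
        Genotype.ZZ: (1.0 - pw_s) * (1.0 - pw_d),
    }
    return dist


def phenotype_partition(
    genotype_dist: dict[Genotype, float], alpha: float
) -> dict[PhenotypeClass, float]:
    """Partition a genotype distribution into the four functional classes.

    ZZ offspring are males, WW offspring are females, and WZ offspring split:
    a fraction ``alpha`` emerge as intersex (functional males), the remaining
    ``1 - alpha`` as WZ females. ``alpha`` is treated as a constant of the
    population, not an environmental response.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    p_zz = genotype_dist.get(Genotype.ZZ, 0.0)
    p_wz = genotype_dist.get(Genotype.WZ, 0.0)
    p_ww = genotype_dist.get(Genotype.WW, 0.0)
    return {
        PhenotypeClass.ZZ_MALE: p_zz,
        PhenotypeClass.IS: alpha * p_wz,
        PhenotypeClass.WZ_FEMALE: (1.0 - alpha) * p_wz,
        PhenotypeClass.WW_FEMALE: p_ww,
    }


def genotype_from_markers(call: MarkerCall) -> Genotype:
    """Call a genotype from the W/Z band pattern.

    Both bands -> WZ; Z only -> ZZ; W only -> WW. A call with neither band
    signals failed amplification, not a genotype, and raises
    :class:`UndeterminedCallError`.
    """
    if call.w_band and call.z_band:
        return Genotype.WZ
    if call.z_band:
        return Genotype.ZZ
    if call.w_band:
        return Genotype.WW
    raise UndeterminedCallError(
        "no band amplified: marker call is undetermined (genotyping failure)"
    )


_ADMISSIBLE: dict[tuple[Genotype, str], PhenotypeClass] = {
    (Genotype.ZZ, "male"): PhenotypeClass.ZZ_MALE,
    # ZZ animals with an intersex gonopore configuration are functionally
    # ordinary males bearing the masculine genotype.
    (Genotype.ZZ, "intersex"): PhenotypeClass.ZZ_MALE,
    (Genotype.WZ, "intersex"): PhenotypeClass.IS,
    (Genotype.WZ, "female"): PhenotypeClass.WZ_FEMALE,
    (Genotype.WW, "female"): PhenotypeClass.WW_FEMALE,
}


def classify_individual(genotype: Genotype, phenotype: str) -> PhenotypeClass:
    """Map a (genotype, gonopore phenotype) pair to its functional class.

    Admissible pairs: ZZ+male, ZZ+intersex (-> ZZ_MALE), WZ+intersex (-> IS),
    WZ+female, WW+female. Anything else (e.g. a WW male) is biologically
    inadmissible in this system and raises :class:`InadmissiblePairError`.
    """
    genotype = Genotype(genotype)
    phenotype = str(phenotype).strip().lower()
    if phenotype not in {"male", "female", "intersex"}:
        raise InadmissiblePairError(f"unknown phenotype label {phenotype!r}")
    try:
        return _ADMISSIBLE[(genotype, phenotype)]
    except KeyError:
        raise InadmissiblePairError(
            f"inadmissible genotype/phenotype pair: {genotype.value} + {phenotype}"
        ) from None
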