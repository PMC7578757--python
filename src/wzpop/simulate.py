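"""Seeded generators for every input the analysis consumes.

The generators emulate the study designs the statistics are meant for:
laboratory crosses with genotyped progenies, earthen ponds stocked with
chosen phenotype compositions, native populations sampled at the long-term
stable structure, and RAD-tag presence/absence matrices with planted
W-linked tags subject to dropout and false-presence noise. Everything is
driven by an explicit seed (or ``numpy.random.Generator``) and emits tables
consumable by the cohort, marker and population modules with no edits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohorts import IndividualRecord
from .genetics import (
    CLASS_ORDER,
    CLASS_GENOTYPE,
    FEMALE_CLASSES,
    Genotype,
    PhenotypeClass,
    offspring_genotype_distribution,
    phenotype_partition,
)
from .markers import TagMatrix
from .popdyn import PopulationState, newborn_class_distribution, stable_distribution

_PHENOTYPE_OF = {
    PhenotypeClass.ZZ_MALE: "male",
    PhenotypeClass.IS: "intersex",
    PhenotypeClass.WZ_FEMALE: "female",
    PhenotypeClass.WW_FEMALE: "female",
}

_BANDS_OF = {
    Genotype.ZZ: (False, True),
    Genotype.WZ: (True, True),
    Genotype.WW: (True, False),
}


@dataclass
class RadDesign:
    """Design of a synthetic RAD-tag matrix.

    Defaults mirror a 12-male (ZZ) / 12-female (8 WZ + 4 WW) sequencing
    cohort with a few thousand background tags and a handful of planted
    W-linked tags.
    """

    n_males: int = 12
    n_wz_females: int = 8
    n_ww_females: int = 4
    n_tags: int = 2000
    n_w_linked: int = 5
    dropout: float = 0.0
    false_presence: float = 0.0


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _make_record(
    idx: int,
    cls: PhenotypeClass,
    site: str,
    rng: np.random.Generator,
    genotyping_error: float,
    progeny: str | None = None,
    id_prefix: str = "ind",
) -> IndividualRecord:
    g = CLASS_GENOTYPE[cls]
    w, z = _BANDS_OF[g]
    if genotyping_error > 0.0:
        # independent per-band flips; can produce (F, F) undetermined calls
        if rng.random() < genotyping_error:
            w = not w
        if rng.random() < genotyping_error:
            z = not z
    observed = None
    if (w, z) == _BANDS_OF[g]:
        observed = g
    return IndividualRecord(
        id=f"{id_prefix}{idx:06d}",
        site=site,
        phenotype=_PHENOTYPE_OF[cls],
        w_band=w,
        z_band=z,
        genotype=observed,
        progeny=progeny,
    )


def _draw_cohort(
    class_probs: dict[PhenotypeClass, float],
    n: int,
    rng: np.random.Generator,
    site: str,
    genotyping_error: float,
    progeny: str | None = None,
) -> list[IndividualRecord]:
    p = np.array([class_probs.get(c, 0.0) for c in CLASS_ORDER])
    counts = rng.multinomial(n, p / p.sum())
    records: list[IndividualRecord] = []
    idx = 0
    for cls, k in zip(CLASS_ORDER, counts):
        for _ in range(int(k)):
            records.append(
                _make_record(idx, cls, site, rng, genotyping_error, progeny)
            )
            idx += 1
    return records


def simulate_cross(
    sire: Genotype,
    dam: Genotype,
    n: int,
    alpha: float = 0.0,
    genotyping_error: float = 0.0,
    seed: int | np.random.Generator | None = None,
    progeny: str | None = None,
) -> list[IndividualRecord]:
    """Multinomial progeny of a single sire x dam cross.

    Offspring classes follow ``phenotype_partition(offspring_genotype_
    distribution(sire, dam), alpha)``; marker bands are derived from the
    true genotype with optional independent per-band error flips.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    dist = phenotype_partition(offspring_genotype_distribution(sire, dam), alpha)
    return _draw_cohort(dist, n, rng, site="cross", genotyping_error=genotyping_error,
                        progeny=progeny)


def simulate_pond_experiment(
    stocking: dict[PhenotypeClass, int],
    n_offspring_sampled: int,
    alpha: float = 0.04,
    brood_size: int = 100,
    brood_dispersion: float = 0.0,
    genotyping_error: float = 0.0,
    seed: int | np.random.Generator | None = None,
    site: str = "pond",
) -> list[IndividualRecord]:
    """Progeny sample from a pond stocked with chosen phenotype classes.

    Each stocked female mates with one sire drawn proportional to the
    stocked male-class counts and produces a brood (``brood_size`` offspring;
    with ``brood_dispersion > 0`` brood sizes are negative-binomially
    overdispersed). The returned cohort is sampled without replacement from
    the pooled progeny.
    """
    rng = _as_rng(seed)
    stocked = {c: int(stocking.get(c, 0)) for c in CLASS_ORDER}
    if any(v < 0 for v in stocked.values()):
        raise ValueError("stocked counts must be nonnegative")
    state = PopulationState(
        zz=stocked[PhenotypeClass.ZZ_MALE],
        is_=stocked[PhenotypeClass.IS],
        wz=stocked[PhenotypeClass.WZ_FEMALE],
        ww=stocked[PhenotypeClass.WW_FEMALE],
    )
    if state.males <= 0 or state.females <= 0:
        raise ValueError("stocking must include at least one male-class "
                         "and one female-class animal")
    male_p = np.array([state.zz, state.is_]) / state.males
    pool_counts = np.zeros(len(CLASS_ORDER), dtype=np.int64)
    for dam_cls in (PhenotypeClass.WZ_FEMALE, PhenotypeClass.WW_FEMALE):
        for _ in range(stocked[dam_cls]):
            sire_cls = (PhenotypeClass.ZZ_MALE, PhenotypeClass.IS)[
                rng.choice(2, p=male_p)
            ]
            dist = phenotype_partition(
                offspring_genotype_distribution(
                    CLASS_GENOTYPE[sire_cls], CLASS_GENOTYPE[dam_cls]
                ),
                alpha,
            )
            if brood_dispersion > 0.0:
                # NB with mean brood_size, variance brood_size*(1+dispersion)
                r = brood_size / brood_dispersion
                b = rng.negative_binomial(r, r / (r + brood_size))
            else:
                b = brood_size
            p = np.array([dist[c] for c in CLASS_ORDER])
            pool_counts += rng.multinomial(b, p)
    pool_total = int(pool_counts.sum())
    if n_offspring_sampled > pool_total:
        raise ValueError(
            f"cannot sample {n_offspring_sampled} offspring from a pooled "
            f"progeny of {pool_total}"
        )
    # multivariate hypergeometric = sampling without replacement from the pool
    sampled = rng.multivariate_hypergeometric(pool_counts, n_offspring_sampled)
    records: list[IndividualRecord] = []
    idx = 0
    for cls, k in zip(CLASS_ORDER, sampled):
        for _ in range(int(k)):
            records.append(_make_record(idx, cls, site, rng, genotyping_error))
            idx += 1
    return records


def simulate_native_population(
    n: int,
    alpha: float = 0.04,
    genotyping_error: float = 0.0,
    seed: int | np.random.Generator | None = None,
    site: str = "native",
) -> list[IndividualRecord]:
    """Random sample from a native population at the long-term stable structure.

    Individuals are drawn multinomially from the alpha-LTSD, with genotypes
    and marker bands attached. Use this for populations old enough to have
    converged; transient populations should be simulated with
    :func:`wzpop.popdyn.simulate_trajectory` instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    ltsd = stable_distribution(alpha).fractions
    return _draw_cohort(ltsd, n, rng, site=site, genotyping_error=genotyping_error)


def simulate_rad_matrix(
    design: RadDesign | None = None,
    seed: int | np.random.Generator | None = None,
) -> TagMatrix:
    """Synthetic RAD-tag presence/absence matrix with planted W-linked tags.

    W-linked tags are present in each W-carrying sample (WZ and WW females)
    with probability ``1 - dropout`` and in ZZ males with probability
    ``false_presence``. Background tags are present i.i.d. across all
    samples at a per-tag frequency drawn uniformly on (0, 1). Planted tags
    are named ``Wtag...``; background tags ``tag...``.
    """
    d = design or RadDesign()
    if d.n_w_linked > d.n_tags:
        raise ValueError("n_w_linked cannot exceed n_tags")
    if d.n_males < 1 or (d.n_wz_females + d.n_ww_females) < 1:
        raise ValueError("need at least one sample of each sex")
    rng = _as_rng(seed)
    genotypes = (
        [Genotype.ZZ] * d.n_males
        + [Genotype.WZ] * d.n_wz_females
        + [Genotype.WW] * d.n_ww_females
    )
    sexes = ["male"] * d.n_males + ["female"] * (d.n_wz_females + d.n_ww_females)
    samples = [f"{s}{i:03d}" for i, s in enumerate(sexes)]
    n_samples = len(samples)
    w_carrier = np.array([g is not Genotype.ZZ for g in genotypes])

    presence = np.zeros((d.n_tags, n_samples), dtype=np.int8)
    for i in range(d.n_w_linked):
        row = np.where(
            w_carrier,
            rng.random(n_samples) < (1.0 - d.dropout),
            rng.random(n_samples) < d.false_presence,
        )
        presence[i] = row.astype(np.int8)
    n_bg = d.n_tags - d.n_w_linked
    if n_bg:
        freqs = rng.uniform(size=(n_bg, 1))
        presence[d.n_w_linked:] = (rng.random((n_bg, n_samples)) < freqs).astype(np.int8)
    tags = [f"Wtag{i:04d}" for i in range(d.n_w_linked)] + [
        f"tag{i:06d}" for i in range(n_bg)
    ]
    return TagMatrix(
        tags=tags,
        samples=samples,
        presence=presence,
        sample_sex=sexes,
        sample_genotype=genotypes,
    )
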