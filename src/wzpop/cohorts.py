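"""Progeny-ratio goodness-of-fit tests and cohort tally reports.

Progeny testing: genotyping the offspring of a WZ male x WZ female cross and
testing the observed (WZ/ZZ pooled) : WW counts against the Mendelian 3:1
expectation with an uncorrected chi-square goodness-of-fit test. Cohort
tallies summarise field samples: phenotype counts, female:male ratio, and
among genotyped females the WZ:WW ratio and WW percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import (
    Genotype,
    MarkerCall,
    PhenotypeClass,
    UndeterminedCallError,
    classify_individual,
    genotype_from_markers,
)

logger = logging.getLogger(__name__)

#: Default null for progeny tests: WZ and ZZ pooled vs WW at 3:1.
DEFAULT_NULL_RATIO: tuple[float, ...] = (3.0, 1.0)


@dataclass
class IndividualRecord:
    """One sampled animal: phenotype mandatory, genotype optional.

    When the genotype is absent but marker bands are recorded, it can be
    back-filled from the band pattern via :meth:`resolve_genotype`.
    """

    id: str
    site: str = ""
    phenotype: str = "female"
    gonopore_config: str | None = None
    w_band: bool | None = None
    z_band: bool | None = None
    genotype: Genotype | None = None
    progeny: str | None = None

    def resolve_genotype(self) -> Genotype | None:
        """Genotype as recorded, or called from bands; None if undetermined."""
        if self.genotype is not None:
            return Genotype(self.genotype)
        if self.w_band is None or self.z_band is None:
            return None
        try:
            return genotype_from_markers(MarkerCall(self.w_band, self.z_band))
        except UndeterminedCallError:
            return None

    def functional_class(self) -> PhenotypeClass | None:
        g = self.resolve_genotype()
        if g is None:
            return None
        return classify_individual(g, self.phenotype)


@dataclass(frozen=True)
class GofResult:
    """A chi-square goodness-of-fit result for one set of counts."""

    observed: tuple[float, ...]
    expected: tuple[float, ...]
    ratio: tuple[float, ...]
    chi2: float
    df: int
    p: float


@dataclass
class CohortSummary:
    """Phenotype and genotype tallies for one cohort/site."""

    site: str | None
    n: int
    n_female: int
    n_male: int
    n_intersex: int
    fm_ratio: float | None            # exact F/M quotient, None if M == 0
    fm_ratio_label: str               # "k:1" display style, "—" if undefined
    n_genotyped_females: int
    n_wz_females: int
    n_ww_females: int
    n_genotype_excluded: int
    wz_ww_ratio: float | None
    wz_ww_ratio_label: str
    ww_percent: float | None          # 100 * WW / (WZ + WW), 2-dp rounded


def expected_counts(n_total: float, ratio: Sequence[float]) -> np.ndarray:
    """Expected category counts for ``n_total`` trials at the given ratio."""
    w = np.asarray(ratio, dtype=float)
    if w.size == 0 or np.any(w <= 0):
        raise ValueError("ratio weights must be nonempty and positive")
    if n_total < 0:
        raise ValueError("n_total must be nonnegative")
    return n_total * w / w.sum()


def chi_square_gof(
    observed: Sequence[float], ratio: Sequence[float] = DEFAULT_NULL_RATIO
) -> GofResult:
    """Uncorrected chi-square goodness-of-fit test against a ratio null.

    chi2 = sum (O - E)^2 / E with df = k - 1 and no continuity correction;
    p is the upper tail of the chi-square distribution.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two categories")
    if obs.sum() <= 0:
        raise ValueError("total count must be positive")
    exp = expected_counts(obs.sum(), ratio)
    if obs.size != exp.size:
        raise ValueError("observed and ratio lengths differ")
    if np.any(exp == 0):
        raise ValueError("an expected count is zero; the statistic is undefined")
    chi2, p = stats.chisquare(obs, f_exp=exp)
    return GofResult(
        observed=tuple(obs),
        expected=tuple(exp),
        ratio=tuple(float(r) for r in ratio),
        chi2=float(chi2),
        df=obs.size - 1,
        p=float(p),
    )


def _ratio_label(num: float, den: float) -> tuple[float | None, str]:
    if den == 0:
        return None, "—"
    q = num / den
    return q, f"{round(q):d}:1"


def tally_cohort(
    records: Iterable[IndividualRecord], site_filter: str | None = None
) -> CohortSummary:
    """Tally phenotypes and genotyped-female genotypes for a cohort.

    Records with undetermined genotype stay in the phenotype counts but are
    excluded (and counted as exclusions) from the genotype tallies. The F:M
    and WZ:WW ratios are reported both as exact quotients and in the rounded
    "k:1" display style.
    """
    recs = [r for r in records if site_filter is None or r.site == site_filter]
    if not recs:
        raise ValueError(
            f"empty cohort{f' for site {site_filter!r}' if site_filter else ''}"
        )
    pheno = {"female": 0, "male": 0, "intersex": 0}
    wz = ww = excluded = 0
    for r in recs:
        p = str(r.phenotype).strip().lower()
        if p not in pheno:
            raise ValueError(f"record {r.id!r}: unknown phenotype {r.phenotype!r}")
        pheno[p] += 1
        if p == "female":
            g = r.resolve_genotype()
            if g is Genotype.WZ:
                wz += 1
            elif g is Genotype.WW:
                ww += 1
            elif g is Genotype.ZZ:
                raise ValueError(f"record {r.id!r}: female phenotype with ZZ genotype")
            else:
                excluded += 1
    if excluded:
        logger.info("tally_cohort: %d female(s) without a determined genotype", excluded)
    fm_q, fm_label = _ratio_label(pheno["female"], pheno["male"])
    wzww_q, wzww_label = _ratio_label(wz, ww)
    ww_pct = round(100.0 * ww / (wz + ww), 2) if (wz + ww) > 0 else None
    return CohortSummary(
        site=site_filter,
        n=len(recs),
        n_female=pheno["female"],
        n_male=pheno["male"],
        n_intersex=pheno["intersex"],
        fm_ratio=fm_q,
        fm_ratio_label=fm_label,
        n_genotyped_females=wz + ww,
        n_wz_females=wz,
        n_ww_females=ww,
        n_genotype_excluded=excluded,
        wz_ww_ratio=wzww_q,
        wz_ww_ratio_label=wzww_label,
        ww_percent=ww_pct,
    )


def progeny_ratio_report(
    progenies: Mapping[str, Iterable[IndividualRecord]],
    null_ratio: Sequence[float] = DEFAULT_NULL_RATIO,
    pool_wz_zz: bool = True,
) -> pd.DataFrame:
    """Goodness-of-fit report for genotyped progenies of WZ x WZ crosses.

    By default WZ and ZZ offspring are pooled into one category (the W
    marker distinguishes WW from not-WW) and tested against 3:1 with df = 1.
    With ``pool_wz_zz=False`` a 3-category 1:2:1 test is run instead (then
    ``null_ratio`` must have three weights, ordered ZZ, WZ, WW).

    Progenies with zero genotyped offspring are skipped with a warning.
    Returns one row per progeny with observed/expected counts, percentage
    columns, the chi-square statistic, df and p.
    """
    rows = []
    for name, recs in progenies.items():
        genos = [g for g in (r.resolve_genotype() for r in recs) if g is not None]
        if not genos:
            logger.warning("progeny %r has no genotyped offspring; skipped", name)
            continue
        n = len(genos)
        n_ww = sum(g is Genotype.WW for g in genos)
        if pool_wz_zz:
            obs = [n - n_ww, n_ww]
        else:
            obs = [
                sum(g is Genotype.ZZ for g in genos),
                sum(g is Genotype.WZ for g in genos),
                n_ww,
            ]
        res = chi_square_gof(obs, null_ratio)
        row: dict[str, object] = {"progeny": name, "n": n}
        labels = ["WZ/ZZ", "WW"] if pool_wz_zz else ["ZZ", "WZ", "WW"]
        for lab, o, e in zip(labels, res.observed, res.expected):
            row[f"obs_{lab}"] = o
            row[f"obs_{lab}_pct"] = round(100.0 * o / n)
            row[f"exp_{lab}"] = e
            row[f"exp_{lab}_pct"] = round(100.0 * e / n)
        row.update(chi2=res.chi2, df=res.df, p=res.p)
        rows.append(row)
    return pd.DataFrame(rows)
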