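"""Sex-linked marker screening from RAD-tag presence/absence matrices.

Downstream of read clustering, each RAD tag is scored present/absent in
every sequenced sample. A tag is a candidate W-linked marker when it is
present in most (strictly more than a threshold fraction, default 60%) of
the female samples and absent in every male sample — W-bearing genotypes
(WZ, WW) occur only in females, so a W-derived tag can never legitimately
appear in a ZZ male. Dropout (a W-linked tag missing from some females) is
expected; the female-fraction threshold absorbs it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import Genotype

logger = logging.getLogger(__name__)


@dataclass
class TagMatrix:
    """Binary tag-presence matrix over sexed samples.

    ``presence`` is tags x samples with values in {0, 1}. ``sample_sex``
    labels each column 'male' or 'female'; ``sample_genotype`` optionally
    records ZZ/WZ/WW per sample (needed only for Z-linked screening).
    """

    tags: list[str]
    samples: list[str]
    presence: np.ndarray
    sample_sex: list[str]
    sample_genotype: list[Genotype] | None = None
    #: optional boolean mask of missing calls (same shape as presence);
    #: missing entries must be coded 0 in `presence`
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if self.presence.shape != (len(self.tags), len(self.samples)):
            raise ValueError(
                f"presence matrix shape {self.presence.shape} does not match "
                f"{len(self.tags)} tags x {len(self.samples)} samples"
            )
        if len(self.sample_sex) != len(self.samples):
            raise ValueError("every sample needs a sex label")
        bad = set(self.sample_sex) - {"male", "female"}
        if bad:
            raise ValueError(f"unknown sex labels: {sorted(bad)}")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence values must be 0/1 (binarize counts first)")
        if self.sample_genotype is not None and len(self.sample_genotype) != len(
            self.samples
        ):
            raise ValueError("sample_genotype length does not match samples")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.presence.shape:
                raise ValueError("missing mask shape does not match presence matrix")
            if self.presence[self.missing].any():
                raise ValueError("missing calls must be coded 0 in the presence matrix")
            n_miss = int(self.missing.sum())
            if n_miss:
                logger.info("TagMatrix: %d missing presence call(s)", n_miss)

    @classmethod
    def from_counts(
        cls,
        tags: list[str],
        samples: list[str],
        counts: np.ndarray,
        sample_sex: list[str],
        binarize_min: int = 1,
        sample_genotype: list[Genotype] | None = None,
    ) -> "TagMatrix":
        """Binarize a read-count matrix: present iff count >= ``binarize_min``."""
        presence = (np.asarray(counts) >= binarize_min).astype(np.int8)
        return cls(tags, samples, presence, sample_sex, sample_genotype)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.tags, columns=self.samples)


@dataclass
class ScreenResult:
    """Per-tag screening statistics and the selected candidate set."""

    table: pd.DataFrame          # columns: tag, female_fraction, male_fraction, selected
    threshold: float
    n_female: int
    n_male: int

    @property
    def selected_tags(self) -> list[str]:
        return self.table.loc[self.table["selected"], "tag"].tolist()


def _sex_masks(m: TagMatrix) -> tuple[np.ndarray, np.ndarray]:
    sex = np.asarray(m.sample_sex)
    f_mask, m_mask = sex == "female", sex == "male"
    if not f_mask.any() or not m_mask.any():
        raise ValueError("matrix must contain at least one sample of each sex")
    return f_mask, m_mask


def screen_sex_markers(
    m: TagMatrix,
    female_fraction_threshold: float = 0.6,
    exclude_missing: bool = False,
) -> ScreenResult:
    """Screen for candidate W-linked tags.

    A tag is selected iff it is present in strictly more than
    ``female_fraction_threshold`` of the female samples AND present in zero
    male samples. The comparison is strict: with 12 females and a 0.6
    threshold, 7/12 (~0.583) fails and 8/12 passes.

    Missing calls count as absences by default (conservative for the
    zero-males criterion); with ``exclude_missing=True`` and a missing mask
    on the matrix, missing female calls are dropped from the per-tag
    denominator instead.
    """
    if not 0.0 <= female_fraction_threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    f_mask, m_mask = _sex_masks(m)
    if exclude_missing and m.missing is not None:
        denom = (~m.missing[:, f_mask]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            fem_frac = np.where(
                denom > 0, m.presence[:, f_mask].sum(axis=1) / np.maximum(denom, 1), 0.0
            )
    else:
        fem_frac = m.presence[:, f_mask].mean(axis=1)
    male_frac = m.presence[:, m_mask].mean(axis=1)
    selected = (fem_frac > female_fraction_threshold) & (male_frac == 0.0)
    table = pd.DataFrame(
        {
            "tag": m.tags,
            "female_fraction": fem_frac,
            "male_fraction": male_frac,
            "selected": selected,
        }
    )
    return ScreenResult(
        table=table,
        threshold=female_fraction_threshold,
        n_female=int(f_mask.sum()),
        n_male=int(m_mask.sum()),
    )


def screen_z_markers(
    m: TagMatrix, presence_threshold: float = 0.6
) -> ScreenResult:
    """Symmetric Z-linked screen (off by default in pipelines).

    Requires per-sample genotypes: a candidate Z-linked tag is present in
    more than ``presence_threshold`` of males and of WZ females, and absent
    in all WW females (which carry no Z chromosome).
    """
    if m.sample_genotype is None:
        raise ValueError("Z-linked screening requires sample genotypes")
    geno = np.asarray([g.value for g in m.sample_genotype])
    sex = np.asarray(m.sample_sex)
    zz = geno == "ZZ"
    wz_f = (geno == "WZ") & (sex == "female")
    ww = geno == "WW"
    if not zz.any() or not wz_f.any() or not ww.any():
        raise ValueError("Z-linked screening needs ZZ, WZ-female and WW samples")
    male_frac = m.presence[:, zz].mean(axis=1)
    wzf_frac = m.presence[:, wz_f].mean(axis=1)
    ww_frac = m.presence[:, ww].mean(axis=1)
    selected = (
        (male_frac > presence_threshold)
        & (wzf_frac > presence_threshold)
        & (ww_frac == 0.0)
    )
    table = pd.DataFrame(
        {
            "tag": m.tags,
            "female_fraction": wzf_frac,
            "male_fraction": male_frac,
            "ww_fraction": ww_frac,
            "selected": selected,
        }
    )
    return ScreenResult(
        table=table,
        threshold=presence_threshold,
        n_female=int(wz_f.sum() + ww.sum()),
        n_male=int(zz.sum()),
    )


def tag_association_stats(m: TagMatrix) -> pd.DataFrame:
    """Per-tag 2x2 contingency counts (present/absent x female/male).

    Diagnostic companion to the screen: returns counts and presence
    fractions per sex for every tag, for reporting or plotting.
    """
    f_mask, m_mask = _sex_masks(m)
    nf, nm = int(f_mask.sum()), int(m_mask.sum())
    fp = m.presence[:, f_mask].sum(axis=1)
    mp = m.presence[:, m_mask].sum(axis=1)
    return pd.DataFrame(
        {
            "tag": m.tags,
            "female_present": fp,
            "female_absent": nf - fp,
            "male_present": mp,
            "male_absent": nm - mp,
            "female_fraction": fp / nf,
            "male_fraction": mp / nm,
        }
    )
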