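"""Proliferation comparators: genomic grade index, KI67 class, IHC3 score.

The genomic grade index (GGI) contrasts the summed expression of probe sets
up-regulated in histologic grade-3 tumors against those up-regulated in
grade-1 tumors, then rescales the raw difference so that the training
cohort's grade-1 mean sits at -1 and its grade-3 mean at +1; the genomic
grade call dichotomizes at 0.  KI67 immunostaining is dichotomized at the
14% cut-off.  The IHC3 score is the published IHC4 prognostic combination
of ER, PR, HER2 and KI67 immunostaining restricted to HER2-negative tumors,
i.e. with the HER2 term removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical panel sizes of the genomic grade index.
GGI_PANEL_SIZES = (112, 16)

#: IHC4 linear-combination coefficients (Cuzick et al., J Clin Oncol 2011):
#: IHC4 = 94.7 x (-0.100 ER10 - 0.079 PR10 + 0.586 HER2 + 0.240 ln(1 + 10 Ki67)).
#: IHC3 drops the HER2 term for HER2-negative tumors.  ER10/PR10 are the
#: semi-quantitative 0-10 immunostaining scores; Ki67 is the stained-cell
#: fraction in [0, 1].  Kept as data so users can audit the source.
IHC_COEFFICIENTS = {
    "outer_scale": 94.7,
    "er10": -0.100,
    "pr10": -0.079,
    "ki67_log": 0.240,  # multiplies ln(1 + 10 * ki67_fraction)
}

KI67_CUTOFF = 0.14


@dataclass(frozen=True)
class GgiPanel:
    """Probe-set lists defining the genomic grade index contrast."""

    up_in_grade3: frozenset
    up_in_grade1: frozenset

    def __post_init__(self):
        g3 = frozenset(self.up_in_grade3)
        g1 = frozenset(self.up_in_grade1)
        if g3 & g1:
            raise ValueError(f"panels overlap: {sorted(g3 & g1)[:5]} ...")
        object.__setattr__(self, "up_in_grade3", g3)
        object.__setattr__(self, "up_in_grade1", g1)
        logger.info("GGI panel sizes: %d up-in-G3, %d up-in-G1", len(g3), len(g1))
        if (len(g3), len(g1)) != GGI_PANEL_SIZES:
            logger.warning(
                "GGI panel sizes %d/%d differ from the canonical %d/%d",
                len(g3),
                len(g1),
                *GGI_PANEL_SIZES,
            )

    @classmethod
    def from_files(cls, path_g3, path_g1) -> "GgiPanel":
        """Load the two panels from plain-text files, one probe-set ID per line."""

        def read_ids(path):
            with open(path) as fh:
                return [line.strip() for line in fh if line.strip()]

        return cls(frozenset(read_ids(path_g3)), frozenset(read_ids(path_g1)))


@dataclass(frozen=True)
class GgiModel:
    """Affine standardization of the raw GGI; genomic-grade cut-off at 0."""

    scale: float
    offset: float
    cutoff: float = 0.0

    def transform(self, raw):
        return self.scale * (np.asarray(raw, dtype=float) - self.offset)


def ggi_raw(expression: pd.DataFrame, panel: GgiPanel) -> pd.Series:
    """Raw genomic grade index per sample.

    ``expression`` is a samples x probe-sets matrix (e.g. RMA-normalized
    log2 intensities).  The raw index is the sum over the up-in-grade-3
    probe sets minus the sum over the up-in-grade-1 probe sets.
    """
    missing = sorted((panel.up_in_grade3 | panel.up_in_grade1) - set(expression.columns))
    if missing:
        raise KeyError(f"expression matrix is missing {len(missing)} panel probe set(s): {missing}")
    sub = expression[sorted(panel.up_in_grade3 | panel.up_in_grade1)]
    if not np.all(np.isfinite(sub.to_numpy())):
        raise ValueError("expression values for panel probe sets must be finite")
    up3 = expression[sorted(panel.up_in_grade3)].sum(axis=1)
    up1 = expression[sorted(panel.up_in_grade1)].sum(axis=1)
    return (up3 - up1).rename("ggi_raw")


def fit_ggi_standardization(raw: pd.Series, grade: pd.Series) -> GgiModel:
    """Fit scale/offset so grade-1 and grade-3 cohort means map to -1 and +1.

    Only samples with histologic grade 1 or 3 anchor the fit; grade-2
    tumors are standardized with the fitted model afterwards.  With
    ``m1, m3`` the raw grade means, scale = 2 / (m3 - m1) and
    offset = (m3 + m1) / 2, so standardized = scale * (raw - offset).
    """
    raw = pd.Series(raw, dtype=float)
    grade = pd.Series(grade)
    m1 = raw[grade == 1].mean()
    m3 = raw[grade == 3].mean()
    if pd.isna(m1) or pd.isna(m3):
        raise ValueError("need at least one grade-1 and one grade-3 sample")
    if m3 == m1:
        raise ValueError("degenerate standardization: grade means are equal")
    return GgiModel(scale=2.0 / (m3 - m1), offset=(m3 + m1) / 2.0)


def genomic_grade(ggi: float) -> str:
    """Genomic grade call: GG3 iff standardized GGI > 0, else GG1.

    A value of exactly 0 is called GG1 (conservative lower-risk tie rule).
    """
    if not np.isfinite(ggi):
        raise ValueError("GGI must be finite")
    return "GG3" if ggi > 0 else "GG1"


def ki67_class(fraction: float) -> str:
    """KI67 dichotomization: 'high' iff the stained fraction is >= 14%.

    The boundary value 0.14 itself is 'high' (the cut-off *defines* the
    high-proliferation group).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"ki67 fraction must be in [0, 1], got {fraction}")
    return "high" if fraction >= KI67_CUTOFF else "low"


def ihc3_score(er10, pr10, ki67_fraction, ki67_rescale: float = 1.0):
    """IHC3 prognostic score: the IHC4 combination without the HER2 term.

    Parameters are the 0-10 semi-quantitative ER and PR scores and the
    KI67 stained-cell fraction in [0, 1].  Manual KI67 reads may be divided
    by ``ki67_rescale`` to calibrate against automated counts; the factor
    defaults to 1 and is logged.  Accepts scalars or equally shaped arrays.
    """
    er10 = np.asarray(er10, dtype=float)
    pr10 = np.asarray(pr10, dtype=float)
    ki67 = np.asarray(ki67_fraction, dtype=float)
    if np.any((er10 < 0) | (er10 > 10)) or np.any((pr10 < 0) | (pr10 > 10)):
        raise ValueError("er10 and pr10 must lie in 0-10")
    if np.any((ki67 < 0) | (ki67 > 1)):
        raise ValueError("ki67 fraction must lie in [0, 1]")
    if ki67_rescale <= 0:
        raise ValueError("ki67_rescale must be positive")
    logger.info("IHC3: KI67 rescaling factor %g", ki67_rescale)
    c = IHC_COEFFICIENTS
    score = c["outer_scale"] * (
        c["er10"] * er10
        + c["pr10"] * pr10
        + c["ki67_log"] * np.log1p(10.0 * ki67 / ki67_rescale)
    )
    return float(score) if score.ndim == 0 else score
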