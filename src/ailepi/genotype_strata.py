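"""Genotype discretization, fixed-effect correction, and conditioning strata.

Contrasts in [-1, 1] are discretized into hard HH/HL/LL calls with
conservative thresholds (boundary values become heterozygotes), phenotypes
are residualized against sex-by-generation class means, and per-locus
homozygote strata are extracted for conditional analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CALLS = ("HH", "HL", "LL")

#: Default minimum stratum size accepted by downstream scans.
DEFAULT_MIN_STRATUM = 30


@dataclass(frozen=True)
class Stratum:
    """Individuals homozygous for one class at a conditioning locus."""

    locus: str
    genotype_class: str  # "HH" or "LL"
    ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def label(self) -> str:
        return f"{self.genotype_class}-{self.locus}"


def discretize_contrasts(contrasts: pd.DataFrame, hi: float = 0.4,
                         lo: float = -0.4) -> pd.DataFrame:
    """Discretize line-origin contrasts into HH/HL/LL/NA calls.

    ``contrast > hi`` -> HH, ``contrast < lo`` -> LL, everything else
    (including the boundary values themselves) -> HL; missing values
    become "NA".  The default +-0.4 thresholds are deliberately
    conservative: the heterozygote interval is wider than either
    homozygote interval to avoid false homozygote calls.
    """
    if not (-1.0 <= lo < hi <= 1.0):
        raise ValueError(f"thresholds must satisfy -1 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    arr = contrasts.to_numpy(dtype=float)
    if np.nanmin(arr, initial=0.0) < -1.0 or np.nanmax(arr, initial=0.0) > 1.0:
        raise ValueError("contrast values outside [-1, 1]")
    out = np.where(arr > hi, "HH", np.where(arr < lo, "LL", "HL"))
    out[np.isnan(arr)] = "NA"
    return pd.DataFrame(out, index=contrasts.index, columns=contrasts.columns)


def correct_phenotypes(phenotypes: pd.DataFrame) -> pd.Series:
    """Residualize weights against sex-by-generation class means.

    ``phenotypes`` is indexed by individual id with columns
    ``weight56, sex, generation``.  Returns the residual (deviation of each
    individual from its class mean, grams) as a Series; every class is
    exactly centered at zero.
    """
    for col in ("weight56", "sex", "generation"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    if phenotypes[["sex", "generation"]].isna().any().any():
        raise ValueError("every individual must have sex and generation")
    sizes = phenotypes.groupby(["sex", "generation"], observed=True)["weight56"].size()
    singletons = sizes[sizes == 1]
    if len(singletons):
        warnings.warn(
            f"{len(singletons)} sex-by-generation class(es) of size 1; "
            "their residuals are 0 by construction", stacklevel=2)
    mean = phenotypes.groupby(["sex", "generation"], observed=True)["weight56"].transform("mean")
    resid = phenotypes["weight56"] - mean
    resid.name = "residual"
    return resid


def make_strata(calls: pd.DataFrame, locus: str) -> tuple[Stratum, Stratum]:
    """Return the (HH, LL) strata for a conditioning locus.

    Heterozygous and NA individuals belong to neither stratum.  An empty
    stratum is returned (with a warning); downstream operations enforce
    their own minimum sizes.
    """
    if locus not in calls.columns:
        raise KeyError(f"locus {locus!r} not present in genotype matrix")
    col = calls[locus]
    out = []
    for cls in ("HH", "LL"):
        ids = tuple(col.index[col == cls])
        if not ids:
            warnings.warn(f"empty {cls} stratum at {locus}", stacklevel=2)
        out.append(Stratum(locus=locus, genotype_class=cls, ids=ids))
    return out[0], out[1]


def make_all_strata(calls: pd.DataFrame, loci) -> list[Stratum]:
    """HH and LL strata for each conditioning locus (2 per locus)."""
    strata: list[Stratum] = []
    for locus in loci:
        strata.extend(make_strata(calls, locus))
    return strata
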