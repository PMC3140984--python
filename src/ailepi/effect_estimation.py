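"""Stratified additive-effect estimation and multi-locus effect arithmetic.

Covers: additive effects (with standard errors) of a marker inside a
conditioning-locus stratum, one-sided comparison of effects between HH and
LL strata, network-level summaries (stratum sums, their ratio, percent of
the founder-line difference), and the k-level decomposition that attributes
pair and triplet spans back to individual loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_strata import DEFAULT_MIN_STRATUM, Stratum
from .scan_engine import additive_code

#: Founder-line 56-day body-weight means (grams): high line, low line.
DEFAULT_LINE_MEANS = (1522.0, 181.0)


@dataclass(frozen=True)
class EffectEstimate:
    locus: str
    stratum: str
    a: float      # additive effect, grams
    se: float
    n: int

    def __str__(self) -> str:  # Table-2-style "a +- SE"
        return f"{self.a:.1f}±{self.se:.1f}"


@dataclass(frozen=True)
class StrataComparison:
    a_hh: float
    a_ll: float
    se_hh: float
    se_ll: float
    direction: str  # "HH>LL" or "HH<LL"
    one_sided_p: float


@dataclass(frozen=True)
class NetworkSummary:
    sum_a_hh: float
    sum_a_ll: float
    ratio: float | None
    pct_hh: float
    pct_ll: float
    sigma_hh: float | None = None
    sigma_ll: float | None = None


@dataclass(frozen=True)
class KDecomposition:
    k: int
    attributions: dict[str, float]
    total: float


def stratified_additive_effect(stratum: Stratum, marker: str, y: pd.Series,
                               calls: pd.DataFrame,
                               min_n: int = DEFAULT_MIN_STRATUM) -> EffectEstimate:
    """Additive effect of ``marker`` within a conditioning stratum.

    Least-squares slope of the residual phenotype on the additive coding
    (HH=+1, HL=0, LL=-1) over stratum members with a called genotype.
    """
    ids = [i for i in stratum.ids if i in y.index and calls.at[i, marker] != "NA"]
    n = len(ids)
    if n < min_n:
        raise ValueError(f"stratum {stratum.label} has {n} usable members "
                         f"at {marker} (minimum {min_n})")
    x = additive_code(calls.loc[ids, marker])
    yv = y.loc[ids].to_numpy(dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError(f"no contrast: {marker} is monomorphic in stratum {stratum.label}")
    a = float(np.sum((x - x.mean()) * (yv - yv.mean())) / sxx)
    resid = yv - yv.mean() - a * (x - x.mean())
    rss = float(resid @ resid)
    se = float(np.sqrt(max(rss, 0.0) / (n - 2) / sxx)) if n > 2 else np.nan
    return EffectEstimate(locus=marker, stratum=stratum.label, a=a, se=se, n=n)


def compare_strata_effects(e_hh: EffectEstimate, e_ll: EffectEstimate,
                           direction: str = "HH>LL") -> StrataComparison:
    """One-sided normal (Wald) test on the difference of two stratum effects.

    The estimates are treated as independent; SE of the difference is
    sqrt(SE_HH^2 + SE_LL^2).  ``direction`` states the alternative.
    """
    if direction not in ("HH>LL", "HH<LL"):
        raise ValueError(f"direction must be 'HH>LL' or 'HH<LL', got {direction!r}")
    if not (np.isfinite(e_hh.se) and np.isfinite(e_ll.se)):
        raise ValueError("both estimates need standard errors")
    diff = e_hh.a - e_ll.a
    se = float(np.hypot(e_hh.se, e_ll.se))
    if se == 0.0:
        if diff == 0.0:
            p = 0.5
        else:
            favoured = diff > 0 if direction == "HH>LL" else diff < 0
            p = 0.0 if favoured else 1.0
    else:
        z = diff / se
        p = float(stats.norm.sf(z)) if direction == "HH>LL" else float(stats.norm.cdf(z))
    return StrataComparison(a_hh=e_hh.a, a_ll=e_ll.a, se_hh=e_hh.se, se_ll=e_ll.se,
                            direction=direction, one_sided_p=p)


def network_summary(effect_pairs, line_means=DEFAULT_LINE_MEANS,
                    sd_ref: float | None = None) -> NetworkSummary:
    """Stratum-wise sums of additive effects and their contrast.

    ``effect_pairs`` is a sequence of (HH-stratum estimate, LL-stratum
    estimate) tuples, typically the non-transgressive rows of the network.
    Percentages are relative to the founder-line difference; an empty input
    yields zero sums and an undefined ratio.
    """
    hi, lo = line_means
    if hi == lo:
        raise ValueError("line means must differ")
    sum_hh = float(sum(e.a for e, _ in effect_pairs))
    sum_ll = float(sum(e.a for _, e in effect_pairs))
    ratio = sum_hh / sum_ll if sum_ll != 0.0 else None
    pct_hh = 100.0 * sum_hh / (hi - lo)
    pct_ll = 100.0 * sum_ll / (hi - lo)
    sig_hh = sum_hh / sd_ref if sd_ref else None
    sig_ll = sum_ll / sd_ref if sd_ref else None
    return NetworkSummary(sum_a_hh=sum_hh, sum_a_ll=sum_ll, ratio=ratio,
                          pct_hh=pct_hh, pct_ll=pct_ll,
                          sigma_hh=sig_hh, sigma_ll=sig_ll)


def k_level_decomposition(marginals: dict[str, float],
                          pair_spans: dict[tuple[str, str], float],
                          triplet_span: float) -> list[KDecomposition]:
    """Attribute multi-locus effects to individual loci at k = 1, 2, 3.

    * k=1: each locus keeps its marginal effect.
    * k=2: half of each pair span goes to each member locus; a locus's
      attribution is the average over the two pairs it belongs to.
    * k=3: the triplet span is split equally among the three loci.

    Totals are exact sums of attributions (no rounding internally).
    """
    loci = list(marginals)
    if len(loci) != 3:
        raise ValueError(f"exactly 3 loci required, got {len(loci)}")
    spans = {frozenset(k): float(v) for k, v in pair_spans.items()}
    for pair in itertools.combinations(loci, 2):
        if frozenset(pair) not in spans:
            raise ValueError(f"missing pair span for {pair[0]}-{pair[1]}")

    k1 = {l: float(marginals[l]) for l in loci}
    k2 = {}
    for l in loci:
        halves = [spans[frozenset((l, o))] / 2.0 for o in loci if o != l]
        k2[l] = sum(halves) / len(halves)
    k3 = {l: float(triplet_span) / 3.0 for l in loci}
    return [KDecomposition(k=k, attributions=att, total=sum(att.values()))
            for k, att in ((1, k1), (2, k2), (3, k3))]
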