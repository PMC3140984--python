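"""Genotype-phenotype maps: model-free class means and orthogonal parametric fits.

The model-free map summarizes corrected phenotypes over ten classes defined
by the hub genotype (HH/LL) and the number of high-homozygous radial loci
(0-4).  The parametric counterpart fits marginal and pairwise orthogonal
genetic effects under the observed genotype frequencies (statistical
scaling) and transforms them linearly into expected values for all 3^L
multi-locus genotypes; observed-minus-expected differences indicate
higher-order interactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Genotype ordering used for frequencies and design rows.
GENO_ORDER = ("LL", "HL", "HH")

_GIDX = {g: i for i, g in enumerate(GENO_ORDER)}

DEFAULT_MIN_CLASS = 3


@dataclass(frozen=True)
class NOIAEffects:
    loci: tuple[str, ...]
    terms: tuple[str, ...]
    estimates: pd.Series          # indexed by term name
    frequencies: dict[str, np.ndarray]  # per-locus (pLL, pHL, pHH)
    model: str                    # "marginal" or "pairwise"


@dataclass(frozen=True)
class GPMapParametric:
    loci: tuple[str, ...]
    values: pd.Series             # indexed by genotype tuples, grams
    effects: NOIAEffects


def scaling_matrix(freqs) -> np.ndarray:
    """Single-locus statistical-scaling basis under genotype frequencies.

    ``freqs`` = (pLL, pHL, pHH).  Rows follow :data:`GENO_ORDER`; columns
    are (reference, additive, dominance).  The additive and dominance
    columns have zero mean and zero covariance under the given
    frequencies; at the ideal intercross frequencies (1/4, 1/2, 1/4) the
    basis reduces to the classical orthogonal coding a = (-1, 0, 1),
    d = (-1/2, 1/2, -1/2).
    """
    p1, p2, p3 = (float(p) for p in freqs)
    if min(p1, p2, p3) <= 0.0:
        raise ValueError("all three genotype frequencies must be > 0")
    denom = p1 + p3 - (p1 - p3) ** 2
    a = np.array([-p2 - 2 * p3, 1 - p2 - 2 * p3, 2 - p2 - 2 * p3])
    d = np.array([-2 * p2 * p3, 4 * p1 * p3, -2 * p1 * p2]) / denom
    return np.column_stack([np.ones(3), a, d])


def _term_names(loci, model: str) -> tuple[str, ...]:
    names = ["r"]
    for l in loci:
        names += [f"a_{l}", f"d_{l}"]
    if model == "pairwise":
        for l1, l2 in itertools.combinations(loci, 2):
            names += [f"aa_{l1}:{l2}", f"ad_{l1}:{l2}",
                      f"da_{l1}:{l2}", f"dd_{l1}:{l2}"]
    return tuple(names)


def _design(geno_idx: np.ndarray, loci, freqs: dict[str, np.ndarray],
            model: str) -> np.ndarray:
    """Design matrix rows for genotype-index array of shape (n, L)."""
    n = geno_idx.shape[0]
    ad = {}
    for j, l in enumerate(loci):
        S = scaling_matrix(freqs[l])
        ad[l] = (S[geno_idx[:, j], 1], S[geno_idx[:, j], 2])
    cols = [np.ones(n)]
    for l in loci:
        cols += [ad[l][0], ad[l][1]]
    if model == "pairwise":
        for l1, l2 in itertools.combinations(loci, 2):
            a1, d1 = ad[l1]
            a2, d2 = ad[l2]
            cols += [a1 * a2, a1 * d2, d1 * a2, d1 * d2]
    return np.column_stack(cols)


def _complete_cases(calls: pd.DataFrame, loci) -> pd.DataFrame:
    sub = calls[list(loci)]
    return sub[(sub != "NA").all(axis=1)]


def noia_fit(calls: pd.DataFrame, y: pd.Series, loci,
             model: str = "pairwise") -> NOIAEffects:
    """Fit orthogonal genetic effects by least squares.

    Genotype frequencies are taken from the analyzed sample itself, so the
    single-locus additive/dominance columns are exactly orthogonal to the
    intercept within the sample.  A locus with an unobserved genotype class
    is rejected (the statistical scaling is undefined there).
    """
    if model not in ("marginal", "pairwise"):
        raise ValueError(f"model must be 'marginal' or 'pairwise', got {model!r}")
    loci = tuple(loci)
    sub = _complete_cases(calls, loci)
    sub = sub.loc[sub.index.intersection(y.index)]
    geno_idx = np.column_stack([sub[l].map(_GIDX).to_numpy() for l in loci])
    freqs = {}
    for j, l in enumerate(loci):
        counts = np.bincount(geno_idx[:, j], minlength=3)
        if (counts == 0).any():
            missing = [GENO_ORDER[k] for k in np.flatnonzero(counts == 0)]
            raise ValueError(f"locus {l} has zero-frequency genotype class(es) "
                             f"{missing}; orthogonal scaling undefined")
        freqs[l] = counts / counts.sum()
    X = _design(geno_idx, loci, freqs, model)
    yv = y.loc[sub.index].to_numpy(dtype=float)
    beta = np.linalg.lstsq(X, yv, rcond=None)[0]
    terms = _term_names(loci, model)
    return NOIAEffects(loci=loci, terms=terms,
                       estimates=pd.Series(beta, index=list(terms)),
                       frequencies=freqs, model=model)


def noia_to_gp_map(effects: NOIAEffects) -> GPMapParametric:
    """Transform fitted effects into values for all 3^L genotypes."""
    loci = effects.loci
    combos = list(itertools.product(GENO_ORDER, repeat=len(loci)))
    geno_idx = np.array([[_GIDX[g] for g in c] for c in combos])
    X = _design(geno_idx, loci, effects.frequencies, effects.model)
    expected_terms = _term_names(loci, effects.model)
    if tuple(effects.estimates.index) != expected_terms:
        raise ValueError("effect vector does not match the declared model order")
    values = X @ effects.estimates.to_numpy(dtype=float)
    idx = pd.MultiIndex.from_tuples(combos, names=list(loci))
    return GPMapParametric(loci=loci, values=pd.Series(values, index=idx, name="value"),
                           effects=effects)


def effects_from_gp_map(gp: GPMapParametric) -> NOIAEffects:
    """Invert the transformation: recover effects from genotype values."""
    loci = gp.loci
    combos = list(itertools.product(GENO_ORDER, repeat=len(loci)))
    geno_idx = np.array([[_GIDX[g] for g in c] for c in combos])
    X = _design(geno_idx, loci, gp.effects.frequencies, gp.effects.model)
    vals = gp.values.loc[combos].to_numpy(dtype=float)
    beta = np.linalg.lstsq(X, vals, rcond=None)[0]
    return NOIAEffects(loci=loci, terms=gp.effects.terms,
                       estimates=pd.Series(beta, index=list(gp.effects.terms)),
                       frequencies=gp.effects.frequencies, model=gp.effects.model)


def _hub_radial_classes(calls: pd.DataFrame, radial_loci, hub: str) -> pd.DataFrame:
    loci = list(radial_loci) + [hub]
    if len(radial_loci) != 4:
        raise ValueError("exactly 4 radial loci required")
    sub = _complete_cases(calls, loci)
    sub = sub[sub[hub].isin(["HH", "LL"])]
    n_hh = (sub[list(radial_loci)] == "HH").sum(axis=1)
    return pd.DataFrame({"hub": sub[hub], "n_hh": n_hh}, index=sub.index)


def model_free_gp_map(calls: pd.DataFrame, y: pd.Series, radial_loci, hub: str,
                      min_class_n: int = DEFAULT_MIN_CLASS) -> pd.DataFrame:
    """Model-free GP map over hub genotype x radial HH-count classes.

    Individuals heterozygous at the hub, or with any missing call at the
    five loci, are excluded.  Heterozygous radial calls count toward the
    "not HH" side.  Returns a 10-row DataFrame (hub in {HH, LL} x HH-count
    0..4) with columns ``mean, sem, n``; classes smaller than
    ``min_class_n`` report a missing (NaN) mean.
    """
    cls = _hub_radial_classes(calls, radial_loci, hub)
    cls = cls.loc[cls.index.intersection(y.index)]
    yv = y.loc[cls.index]
    rows = []
    for hubg in ("HH", "LL"):
        for k in range(5):
            vals = yv[(cls["hub"] == hubg) & (cls["n_hh"] == k)]
            n = len(vals)
            if n >= max(min_class_n, 1):
                mean = float(vals.mean())
                sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            else:
                mean, sem = np.nan, np.nan
            rows.append({"hub": hubg, "n_hh": k, "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)


def higher_order_indicator(calls: pd.DataFrame, y: pd.Series, radial_loci,
                           hub: str, effects: NOIAEffects,
                           min_class_n: int = DEFAULT_MIN_CLASS) -> pd.DataFrame:
    """Observed-minus-expected class means.

    Expected values come from the parametric (second-order) GP map
    evaluated at each individual's own multi-locus genotype, then averaged
    within the same ten classes as the model-free map.  Differences beyond
    the observed sem point at interactions above the fitted order.
    """
    gp = noia_to_gp_map(effects)
    observed = model_free_gp_map(calls, y, radial_loci, hub, min_class_n=min_class_n)
    loci = list(effects.loci)
    sub = _complete_cases(calls, loci)
    sub = sub.loc[sub.index.intersection(y.index)]
    keys = list(map(tuple, sub[loci].to_numpy()))
    predicted = pd.Series(gp.values.loc[keys].to_numpy(), index=sub.index)
    cls = _hub_radial_classes(calls, radial_loci, hub)
    cls = cls.loc[cls.index.intersection(predicted.index)]
    expected = []
    for _, row in observed.iterrows():
        member = cls[(cls["hub"] == row["hub"]) & (cls["n_hh"] == row["n_hh"])].index
        expected.append(float(predicted.loc[member].mean()) if len(member) else np.nan)
    out = observed.copy()
    out = out.rename(columns={"mean": "observed"})
    out["expected"] = expected
    out["difference"] = out["observed"] - out["expected"]
    return out
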