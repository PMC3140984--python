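"""Pair/triplet genotype-class means, plane variances, and the R_p statistic.

A triplet's 27 corrected genotype-class means partition, for any choice of
conditioning locus, into three "planes" of nine cells (one per conditioning
genotype).  The ratio of the largest to the smallest within-plane variance
(R_p) quantifies how strongly the conditioning locus capacitates the other
two.  Scans enumerate every triplet x conditioning choice among a candidate
set and rank the resulting values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

GENO_ORDER = ("LL", "HL", "HH")

DEFAULT_MIN_CELL_N = 3
DEFAULT_MIN_CELLS_PER_PLANE = 5


@dataclass(frozen=True)
class GenotypeClassMap:
    loci: tuple[str, ...]
    table: pd.DataFrame  # indexed by genotype tuples; columns mean, n


@dataclass(frozen=True)
class PlaneSet:
    loci: tuple[str, ...]
    conditioning_locus: str
    planes: dict[str, pd.Series]      # conditioning genotype -> 9 cell means
    variances: dict[str, float]       # NaN when too few populated cells
    weighted: bool = False


@dataclass(frozen=True)
class RpResult:
    loci: tuple[str, ...]
    conditioning_locus: str
    variances: dict[str, float]
    rp: float
    defined: bool
    infinite: bool = False


def genotype_class_means(calls: pd.DataFrame, y: pd.Series, loci,
                         min_cell_n: int = DEFAULT_MIN_CELL_N) -> GenotypeClassMap:
    """Corrected phenotype mean and count per multi-locus genotype class.

    Accepts 2 or 3 loci; individuals with an NA call at any locus are
    excluded.  All 3^L classes appear in the output; classes with fewer
    than ``min_cell_n`` members are flagged missing (NaN mean).
    """
    loci = tuple(loci)
    if len(loci) not in (2, 3):
        raise ValueError(f"2 or 3 loci required, got {len(loci)}")
    sub = calls[list(loci)]
    sub = sub[(sub != "NA").all(axis=1)]
    sub = sub.loc[sub.index.intersection(y.index)]
    yv = y.loc[sub.index]

    combos = list(itertools.product(GENO_ORDER, repeat=len(loci)))
    keys = pd.Series(list(map(tuple, sub.to_numpy())), index=sub.index)
    grouped = yv.groupby(keys)
    means = grouped.mean().to_dict()
    counts = grouped.size().to_dict()

    rows = []
    for c in combos:
        n = int(counts.get(c, 0))
        mean = float(means.get(c, np.nan)) if n >= min_cell_n else np.nan
        rows.append({"mean": mean, "n": n})
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(combos, names=list(loci)))
    if int((table["n"] > 0).sum()) < 2:
        raise ValueError("fewer than 2 populated genotype classes")
    return GenotypeClassMap(loci=loci, table=table)


def extract_planes(class_map: GenotypeClassMap, conditioning_locus: str,
                   min_cells_per_plane: int = DEFAULT_MIN_CELLS_PER_PLANE,
                   weighted: bool = False) -> PlaneSet:
    """Partition a triplet map into the conditioning locus's three planes.

    Each plane holds the 9 cell means sharing one conditioning genotype;
    its variance is the sample variance (divisor n-1) over populated cells,
    or, with ``weighted=True``, the count-weighted variance.  Planes with
    fewer than ``min_cells_per_plane`` populated cells get a missing (NaN)
    variance.
    """
    loci = class_map.loci
    if len(loci) != 3:
        raise ValueError("plane extraction requires a triplet map")
    if conditioning_locus not in loci:
        raise ValueError(f"{conditioning_locus!r} is not one of {loci}")
    axis = loci.index(conditioning_locus)
    planes: dict[str, pd.Series] = {}
    variances: dict[str, float] = {}
    for g in GENO_ORDER:
        plane = class_map.table.xs(g, level=axis)
        cells = plane["mean"]
        ok = cells.notna()
        if int(ok.sum()) < min_cells_per_plane:
            var = np.nan
        elif weighted:
            w = plane.loc[ok, "n"].to_numpy(dtype=float)
            m = cells[ok].to_numpy(dtype=float)
            mu = np.average(m, weights=w)
            var = float(np.average((m - mu) ** 2, weights=w))
        else:
            var = float(cells[ok].var(ddof=1))
        planes[g] = cells
        variances[g] = var
    return PlaneSet(loci=loci, conditioning_locus=conditioning_locus,
                    planes=planes, variances=variances, weighted=weighted)


def rp_ratio(plane_set: PlaneSet) -> RpResult:
    """Max/min within-plane variance ratio for one conditioning choice.

    Requires at least two planes with a defined variance.  A zero minimum
    variance yields an undefined-infinite result (flagged, rp = inf)
    rather than a pseudo-number.
    """
    defined = {g: v for g, v in plane_set.variances.items() if np.isfinite(v)}
    if len(defined) == 0:
        raise ValueError("all plane variances are missing")
    if len(defined) < 2:
        return RpResult(loci=plane_set.loci,
                        conditioning_locus=plane_set.conditioning_locus,
                        variances=plane_set.variances, rp=np.nan, defined=False)
    vmax, vmin = max(defined.values()), min(defined.values())
    if vmin <= 0.0:
        return RpResult(loci=plane_set.loci,
                        conditioning_locus=plane_set.conditioning_locus,
                        variances=plane_set.variances, rp=np.inf,
                        defined=False, infinite=True)
    return RpResult(loci=plane_set.loci,
                    conditioning_locus=plane_set.conditioning_locus,
                    variances=plane_set.variances, rp=float(vmax / vmin),
                    defined=True)


def rp_scan(calls: pd.DataFrame, y: pd.Series, candidate_loci,
            min_cell_n: int = DEFAULT_MIN_CELL_N,
            min_cells_per_plane: int = DEFAULT_MIN_CELLS_PER_PLANE,
            weighted: bool = False, null_perms: int = 0,
            seed: int = 0) -> pd.DataFrame:
    """Exhaustive triplet scan over a candidate locus set.

    Enumerates all C(L, 3) triplets and, for each, the three conditioning
    choices; returns every R_p value sorted in decreasing order (undefined
    entries flagged and sorted last).  With ``null_perms`` > 0 a permutation
    null (phenotypes shuffled against genotypes) adds an empirical
    exceedance probability per defined value — an add-on, since no formal
    test accompanies the statistic.
    """
    candidate_loci = list(candidate_loci)
    if len(candidate_loci) < 3:
        raise ValueError("at least 3 candidate loci required")

    def one_scan(yy: pd.Series) -> list[dict]:
        entries = []
        for triplet in itertools.combinations(candidate_loci, 3):
            try:
                cmap = genotype_class_means(calls, yy, triplet, min_cell_n=min_cell_n)
            except ValueError:
                for cond in triplet:
                    entries.append({"triplet": triplet, "conditioning": cond,
                                    "rp": np.nan, "defined": False, "infinite": False,
                                    "var_LL": np.nan, "var_HL": np.nan, "var_HH": np.nan})
                continue
            for cond in triplet:
                ps = extract_planes(cmap, cond, min_cells_per_plane=min_cells_per_plane,
                                    weighted=weighted)
                try:
                    res = rp_ratio(ps)
                except ValueError:
                    entries.append({"triplet": triplet, "conditioning": cond,
                                    "rp": np.nan, "defined": False, "infinite": False,
                                    "var_LL": np.nan, "var_HL": np.nan, "var_HH": np.nan})
                    continue
                entries.append({"triplet": triplet, "conditioning": cond,
                                "rp": res.rp, "defined": res.defined,
                                "infinite": res.infinite,
                                **{f"var_{g}": res.variances[g] for g in GENO_ORDER}})
        return entries

    rows = one_scan(y)
    out = pd.DataFrame(rows)

    if null_perms > 0:
        rng = np.random.default_rng(seed)
        yv = y.to_numpy(dtype=float)
        null_rps = np.full((null_perms, len(rows)), np.nan)
        for p in range(null_perms):
            yp = pd.Series(yv[rng.permutation(len(yv))], index=y.index)
            null_rows = one_scan(yp)
            null_rps[p] = [r["rp"] for r in null_rows]
        exceed = []
        for j, row in out.iterrows():
            if np.isfinite(row["rp"]):
                col = null_rps[:, j]
                col = col[np.isfinite(col)]
                exceed.append(float((col >= row["rp"]).mean()) if len(col) else np.nan)
            else:
                exceed.append(np.nan)
        out["null_exceedance"] = exceed

    out["triplet"] = out["triplet"].map(lambda t: "|".join(t))
    out = out.sort_values("rp", ascending=False, na_position="last",
                          kind="stable").reset_index(drop=True)
    return out
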