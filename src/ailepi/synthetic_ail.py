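"""Synthetic advanced intercross line (AIL) generator.

Produces pedigrees, line-origin genotypes (by gene dropping through the
pedigree with Haldane recombination), and phenotypes driven by configurable
multi-locus genotype-phenotype architectures.  Every downstream analysis
stage of the package can be exercised on this module's output without any
external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_strata import discretize_contrasts

GENOTYPES = ("LL", "HL", "HH")
ADDITIVE_CODE = {"HH": 1.0, "HL": 0.0, "LL": -1.0}

#: Default chromosomal segments: (name, start Mb, stop Mb).
DEFAULT_SEGMENTS = (
    ("Growth1", 169.6, 181.1),
    ("Growth2", 47.9, 65.5),
    ("Growth3", 124.3, 133.6),
    ("Growth4", 24.0, 68.0),
    ("Growth6", 1.3, 13.5),
    ("Growth7", 85.5, 88.8),
    ("Growth8", 33.7, 39.1),
    ("Growth9", 10.9, 35.5),
    ("Growth12", 7.1, 13.9),
)


@dataclass(frozen=True)
class PedigreeSpec:
    """Founder counts and per-generation offspring counts for an AIL.

    Defaults follow the reference design: reciprocal founder matings
    (high-line males x low-line females and vice versa), ~100 offspring in
    most generations, 300 in F3 and 400 in F8.
    """

    hws_males: int = 10
    lws_females: int = 22
    lws_males: int = 8
    hws_females: int = 19
    generation_sizes: tuple[int, ...] = (100, 100, 300, 100, 100, 100, 100, 400)

    def __post_init__(self) -> None:
        for name in ("hws_males", "lws_females", "lws_males", "hws_females"):
            if getattr(self, name) <= 0:
                raise ValueError(f"founder count {name} must be > 0")
        # an empty tuple is the founders-only identity case
        if any(n <= 0 for n in self.generation_sizes):
            raise ValueError("generation sizes must be > 0")

    @property
    def n_founders(self) -> int:
        return self.hws_males + self.lws_females + self.lws_males + self.hws_females

    @property
    def generations(self) -> tuple[str, ...]:
        return tuple(f"F{i}" for i in range(1, len(self.generation_sizes) + 1))


@dataclass(frozen=True)
class GPArchitecture:
    """Map from multi-locus genotype to genotypic value (grams)."""

    loci: tuple[str, ...]
    value_map: dict[tuple[str, ...], float]
    preset_name: str

    def __post_init__(self) -> None:
        expected = 3 ** len(self.loci)
        if len(self.value_map) != expected:
            raise ValueError(
                f"value_map must cover all {expected} genotypes, got {len(self.value_map)}"
            )
        if not all(np.isfinite(v) for v in self.value_map.values()):
            raise ValueError("value_map contains non-finite values")

    def with_loci(self, loci) -> "GPArchitecture":
        """Rebind the architecture to concrete marker ids."""
        loci = tuple(loci)
        if len(loci) != len(self.loci):
            raise ValueError(f"expected {len(self.loci)} loci, got {len(loci)}")
        return replace(self, loci=loci)

    def values_array(self) -> np.ndarray:
        """Genotype values as a flat array indexed base-3 (LL=0, HL=1, HH=2)."""
        arr = np.empty(3 ** len(self.loci))
        for combo, value in self.value_map.items():
            idx = 0
            for call in combo:
                idx = idx * 3 + GENOTYPES.index(call)
            arr[idx] = value
        return arr


def default_marker_map(markers_per_segment: int = 5,
                       segments=DEFAULT_SEGMENTS) -> pd.DataFrame:
    """Build the default 9-segment marker map.

    Genetic positions default to 1 cM per Mb; markers are evenly spaced
    within each segment's physical bounds.
    """
    rows = []
    for seg, start, stop in segments:
        mb = np.linspace(start, stop, markers_per_segment)
        for i, pos in enumerate(mb, start=1):
            rows.append(
                {"segment": seg, "marker": i, "marker_id": f"{seg}_m{i}",
                 "mb": round(float(pos), 4), "cm": round(float(pos), 4)}
            )
    return pd.DataFrame(rows)


def build_pedigree(spec: PedigreeSpec, seed: int = 0) -> pd.DataFrame:
    """Generate a pedigree table from a :class:`PedigreeSpec`.

    Founders (generation F0) come from the two lines; F1 matings are
    cross-line; later generations mate randomly within the previous
    generation with sex balance enforced.

    Returns a DataFrame with columns ``id, sire, dam, generation, sex, line``
    in which parents always precede their offspring.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add_founders(n, line, sex):
        start = len(rows) + 1
        for k in range(n):
            rows.append({"id": f"F0_{start + k:04d}", "sire": "", "dam": "",
                         "generation": "F0", "sex": sex, "line": line})

    add_founders(spec.hws_males, "HWS", "M")
    add_founders(spec.hws_females, "HWS", "F")
    add_founders(spec.lws_males, "LWS", "M")
    add_founders(spec.lws_females, "LWS", "F")
    founders = pd.DataFrame(rows)

    prev = founders
    for gen, size in zip(spec.generations, spec.generation_sizes):
        males = prev[prev["sex"] == "M"]
        females = prev[prev["sex"] == "F"]
        if len(males) == 0 or len(females) == 0:
            missing = "males" if len(males) == 0 else "females"
            raise ValueError(f"no {missing} available to parent generation {gen}")
        # balanced sexes, order shuffled
        sexes = np.array(["M"] * ((size + 1) // 2) + ["F"] * (size // 2))
        rng.shuffle(sexes)
        male_ids = males["id"].to_numpy()
        sires = male_ids[rng.integers(len(males), size=size)]
        if gen == "F1":
            # cross-line founder matings: dam from the line opposite the sire
            sire_line = males.set_index("id")["line"].loc[sires].to_numpy()
            dams = np.empty(size, dtype=object)
            for line in ("HWS", "LWS"):
                opp = females.loc[females["line"] != line, "id"].to_numpy()
                pick = sire_line == line
                if pick.any():
                    if len(opp) == 0:
                        raise ValueError("no cross-line females available for F1")
                    dams[pick] = opp[rng.integers(len(opp), size=int(pick.sum()))]
        else:
            female_ids = females["id"].to_numpy()
            dams = female_ids[rng.integers(len(females), size=size)]
        new = pd.DataFrame({"id": [f"{gen}_{k + 1:04d}" for k in range(size)],
                            "sire": sires, "dam": dams, "generation": gen,
                            "sex": sexes, "line": ""})
        prev = new
        rows.extend(new.to_dict("records"))

    return pd.DataFrame(rows)


def haldane(d_cm) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def sample_gametes(hap: np.ndarray, parent_rows: np.ndarray, rec: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample one gamete per parent from a haplotype array.

    ``hap`` has shape (n_individuals, 2, n_markers); ``rec`` holds the
    recombination fractions between adjacent markers (length n_markers-1).
    Returns an array of shape (len(parent_rows), n_markers).
    """
    k = len(parent_rows)
    m = hap.shape[2]
    start = rng.integers(0, 2, size=k)
    if m == 1:
        hap_idx = start[:, None]
    else:
        switches = rng.random((k, m - 1)) < rec[None, :]
        hap_idx = (start[:, None] + np.concatenate(
            [np.zeros((k, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1)) % 2
    return hap[parent_rows[:, None], hap_idx, np.arange(m)[None, :]]


def simulate_genotypes(ped: pd.DataFrame, marker_map: pd.DataFrame,
                       seed: int = 0, blur: float = 0.0) -> pd.DataFrame:
    """Gene-drop line origins through the pedigree and return contrasts.

    Each individual carries two haplotypes per segment; founders are fixed
    for their line's allele.  Meiosis recombines between adjacent markers
    with Haldane fractions from the cM distances; segments segregate
    independently.  The contrast at a marker is (high-line allele count
    minus low-line allele count) / 2, i.e. -1, 0 or +1; ``blur`` adds
    Gaussian noise truncated to [-1, 1] to emulate estimated contrasts.
    """
    if marker_map["cm"].isna().any():
        bad = marker_map.loc[marker_map["cm"].isna(), "marker_id"].tolist()
        raise ValueError(f"markers with undefined genetic position: {bad}")

    rng = np.random.default_rng(seed)
    ids = ped["id"].to_numpy()
    row_of = {i: k for k, i in enumerate(ids)}
    n = len(ped)

    segments = []
    for seg, sub in marker_map.groupby("segment", sort=False):
        sub = sub.sort_values("marker")
        cm = sub["cm"].to_numpy(float)
        if np.any(np.diff(cm) <= 0) and len(cm) > 1:
            raise ValueError(f"genetic positions not strictly increasing in {seg}")
        segments.append((seg, sub["marker_id"].tolist(), haldane(np.diff(cm))))

    is_founder = (ped["generation"] == "F0").to_numpy()
    founder_allele = (ped["line"] == "HWS").to_numpy().astype(np.int8)

    contrast_cols = {}
    for seg, mids, rec in segments:
        m = len(mids)
        hap = np.zeros((n, 2, m), dtype=np.int8)
        hap[is_founder, :, :] = founder_allele[is_founder, None, None]
        for gen in ped.loc[~is_founder, "generation"].unique():
            mask = (ped["generation"] == gen).to_numpy()
            idx = np.flatnonzero(mask)
            sires = np.array([row_of[s] for s in ped.loc[mask, "sire"]])
            dams = np.array([row_of[d] for d in ped.loc[mask, "dam"]])
            hap[idx, 0, :] = sample_gametes(hap, sires, rec, rng)
            hap[idx, 1, :] = sample_gametes(hap, dams, rec, rng)
        contrast = hap.sum(axis=1).astype(float) - 1.0
        for j, mid in enumerate(mids):
            contrast_cols[mid] = contrast[:, j]

    out = pd.DataFrame(contrast_cols, index=pd.Index(ids, name="id"))
    if blur > 0:
        out = out + rng.normal(0.0, blur, size=out.shape)
        out = out.clip(-1.0, 1.0)
    return out


def _enumerate(loci):
    return itertools.product(GENOTYPES, repeat=len(loci))


def make_architecture(preset: str, loci=None, **params) -> GPArchitecture:
    """Build a fully-enumerated genotype-phenotype architecture.

    Presets
    -------
    flat
        no genetic effect at any locus.
    hub_only
        additive effect ``a_hub`` at the first (hub) locus only.
    additive3
        independent additive effects ``a`` (3-tuple) at three loci.
    pairwise_no_hub
        additive hub plus an additive-by-additive interaction ``i23``
        between the two non-hub loci; the hub's genotype planes are exact
        translates of each other.
    capacitating
        the non-hub loci (and their interaction) act only when the hub is
        HH; their effects are fully suppressed otherwise.
    radial_network
        one hub and ``n_radial`` peripheral loci; the phenotype increases
        by ``slope`` per HH radial genotype, but only in the hub-HH
        background.
    """
    if loci is not None:
        loci = tuple(loci)

    def finish(names, fn):
        nonlocal loci
        if loci is None:
            loci = names
        vm = {g: float(fn(g)) for g in _enumerate(loci)}
        return GPArchitecture(loci=loci, value_map=vm, preset_name=preset)

    ac = ADDITIVE_CODE
    if preset == "flat":
        n = int(params.pop("n_loci", 3))
        return finish(tuple(f"locus{i+1}" for i in range(n)), lambda g: 0.0)
    if preset == "hub_only":
        a_hub = float(params.pop("a_hub", 40.0))
        return finish(("hub", "locus2", "locus3"), lambda g: a_hub * ac[g[0]])
    if preset == "additive3":
        a = tuple(params.pop("a", (40.0, 35.0, 30.0)))
        return finish(("locus1", "locus2", "locus3"),
                      lambda g: sum(ai * ac[gi] for ai, gi in zip(a, g)))
    if preset == "pairwise_no_hub":
        a_hub = float(params.pop("a_hub", 40.0))
        a2 = float(params.pop("a2", 35.0))
        a3 = float(params.pop("a3", 35.0))
        i23 = float(params.pop("i23", 25.0))
        return finish(("hub", "locus2", "locus3"),
                      lambda g: a_hub * ac[g[0]] + a2 * ac[g[1]] + a3 * ac[g[2]]
                      + i23 * ac[g[1]] * ac[g[2]])
    if preset == "capacitating":
        a_hub = float(params.pop("a_hub", 40.0))
        a2 = float(params.pop("a2", 35.0))
        a3 = float(params.pop("a3", 35.0))
        i23 = float(params.pop("i23", 25.0))
        return finish(("hub", "locus2", "locus3"),
                      lambda g: a_hub * ac[g[0]] + (g[0] == "HH")
                      * (a2 * ac[g[1]] + a3 * ac[g[2]] + i23 * ac[g[1]] * ac[g[2]]))
    if preset == "radial_network":
        a_hub = float(params.pop("a_hub", 40.0))
        slope = float(params.pop("slope", 35.0))
        n_radial = int(params.pop("n_radial", 4))
        names = ("hub",) + tuple(f"radial{i+1}" for i in range(n_radial))
        return finish(names, lambda g: a_hub * ac[g[0]] + (g[0] == "HH")
                      * slope * sum(gi == "HH" for gi in g[1:]))
    raise ValueError(f"unknown architecture preset: {preset!r}")


def genotypic_values(contrasts: pd.DataFrame, arch: GPArchitecture,
                     hi: float = 0.4, lo: float = -0.4) -> pd.Series:
    """Evaluate the architecture's genotypic value for every individual."""
    missing = [m for m in arch.loci if m not in contrasts.columns]
    if missing:
        raise ValueError(f"architecture references markers absent from the matrix: {missing}")
    calls = discretize_contrasts(contrasts[list(arch.loci)], hi=hi, lo=lo)
    if (calls.to_numpy() == "NA").any():
        raise ValueError("cannot evaluate architecture on NA genotype calls")
    code = np.column_stack(
        [calls[c].map({"LL": 0, "HL": 1, "HH": 2}).to_numpy(dtype=np.int64)
         for c in calls.columns])
    idx = np.zeros(len(calls), dtype=np.int64)
    for j in range(code.shape[1]):
        idx = idx * 3 + code[:, j]
    return pd.Series(arch.values_array()[idx], index=contrasts.index, name="value")


def simulate_phenotypes(contrasts: pd.DataFrame, ped: pd.DataFrame,
                        arch: GPArchitecture, baseline: float = 850.0,
                        sex_effect: float = 150.0,
                        generation_effects: dict[str, float] | None = None,
                        noise_sd: float = 127.0, seed: int = 0) -> pd.DataFrame:
    """Simulate 56-day body weights (grams).

    weight = baseline + genotypic value + sex effect (males) + generation
    effect + Gaussian(0, noise_sd).  Returns a DataFrame indexed by id with
    columns ``weight56, sex, generation``.
    """
    rng = np.random.default_rng(seed)
    ped = ped.set_index("id").loc[contrasts.index]
    value = genotypic_values(contrasts, arch)
    gen_eff = ped["generation"].map(generation_effects or {}).fillna(0.0).astype(float)
    weight = (baseline + value + (ped["sex"] == "M") * sex_effect + gen_eff
              + rng.normal(0.0, noise_sd, size=len(ped)))
    return pd.DataFrame({"weight56": weight, "sex": ped["sex"],
                         "generation": ped["generation"]},
                        index=contrasts.index)


def simulate_dataset(preset: str = "radial_network", spec: PedigreeSpec | None = None,
                     marker_map: pd.DataFrame | None = None, noise_sd: float = 127.0,
                     seed: int = 0, blur: float = 0.0, arch_loci=None, **arch_params):
    """Convenience wrapper: pedigree + genotypes + phenotypes in one call.

    Architecture loci default to the first marker of the first L segments
    (hub bound to the segment named ``Growth9`` when present).  Returns
    ``(ped, marker_map, contrasts, phenotypes, architecture)``.
    """
    spec = spec or PedigreeSpec()
    marker_map = marker_map if marker_map is not None else default_marker_map()
    ss = np.random.SeedSequence(seed).spawn(3)
    ped = build_pedigree(spec, seed=ss[0])
    contrasts = simulate_genotypes(ped, marker_map, seed=ss[1], blur=blur)
    arch = make_architecture(preset, loci=arch_loci, **arch_params)
    if arch_loci is None:
        segs = list(dict.fromkeys(marker_map["segment"]))
        hub_seg = "Growth9" if "Growth9" in segs else segs[0]
        others = [s for s in segs if s != hub_seg]
        chosen = [hub_seg] + others[: len(arch.loci) - 1]
        first_marker = {s: marker_map[marker_map["segment"] == s].iloc[0]["marker_id"]
                        for s in segs}
        arch = arch.with_loci([first_marker[s] for s in chosen])
    pheno = simulate_phenotypes(contrasts, ped, arch, noise_sd=noise_sd, seed=ss[2])
    return ped, marker_map, contrasts, pheno, arch
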