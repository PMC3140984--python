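import itertools

import numpy as np
import pandas as pd
import pytest

import ailepi as ai
from ailepi.gp_map import GENO_ORDER, _design, _term_names

from conftest import enumerated_calls

ACODE = {"HH": 1.0, "HL": 0.0, "LL": -1.0}


def balanced_sample(loci, counts_per_locus):
    """Sample whose joint genotype counts factorize over loci.

    ``counts_per_locus`` maps locus -> (nLL, nHL, nHH) as relative weights;
    the joint design enumerates all combinations with product multiplicity,
    which guarantees empirical linkage equilibrium.
    """
    combos = []
    for combo in itertools.product(*[range(3)] * len(loci)):
        mult = 1
        for j, g in enumerate(combo):
            mult *= counts_per_locus[loci[j]][g]
        combos += [combo] * mult
    idx = [f"i{k}" for k in range(len(combos))]
    data = {l: [GENO_ORDER[c[j]] for c in combos] for j, l in enumerate(loci)}
    return pd.DataFrame(data, index=idx)


class TestScalingMatrix:
    def test_f2_frequencies_classical_coding(self):
        S = ai.scaling_matrix((0.25, 0.5, 0.25))
        assert np.allclose(S[:, 1], [-1.0, 0.0, 1.0])
        assert np.allclose(S[:, 2], [-0.5, 0.5, -0.5])

    def test_columns_orthogonal_under_frequencies(self):
        for freqs in [(0.3, 0.5, 0.2), (0.1, 0.6, 0.3), (0.25, 0.5, 0.25)]:
            S = ai.scaling_matrix(freqs)
            w = np.asarray(freqs)
            G = S.T @ np.diag(w) @ S
            off = G - np.diag(np.diag(G))
            assert np.abs(off).max() < 1e-12

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            ai.scaling_matrix((0.5, 0.5, 0.0))


class TestNoiaFit:
    def test_design_gram_diagonal_on_balanced_sample(self):
        calls = balanced_sample(["A", "B"], {"A": (1, 2, 1), "B": (2, 3, 1)})
        y = pd.Series(np.random.default_rng(0).normal(size=len(calls)), index=calls.index)
        eff = ai.noia_fit(calls, y, ["A", "B"])
        geno_idx = np.column_stack([calls[l].map({g: i for i, g in enumerate(GENO_ORDER)})
                                    for l in ("A", "B")])
        X = _design(geno_idx, ("A", "B"), eff.frequencies, "pairwise")
        G = X.T @ X / len(calls)
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6

    def test_zero_class_rejected_naming_locus(self):
        calls = enumerated_calls(["A", "B"], reps=2)
        calls.loc[calls["A"] == "LL", "A"] = "HL"
        y = pd.Series(np.zeros(len(calls)), index=calls.index)
        with pytest.raises(ValueError, match="locus A"):
            ai.noia_fit(calls, y, ["A", "B"])

    def test_additive_y_no_interactions(self):
        rng = np.random.default_rng(1)
        calls = pd.DataFrame({l: rng.choice(GENO_ORDER, p=[0.25, 0.5, 0.25], size=1000)
                              for l in ("A", "B", "C")},
                             index=[f"i{k}" for k in range(1000)])
        y = pd.Series(sum(30.0 * calls[l].map(ACODE) for l in ("A", "B", "C"))
                      + rng.normal(0, 20.0, size=1000), index=calls.index)
        eff = ai.noia_fit(calls, y, ["A", "B", "C"])
        inter = [t for t in eff.terms if t[:2] in ("aa", "ad", "da", "dd")]
        # joint F2-like frequencies: interaction estimates ~ N(0, small)
        assert np.abs(eff.estimates[inter]).max() < 10.0

    def test_planted_aa_recovered(self):
        rng = np.random.default_rng(2)
        calls = pd.DataFrame({l: rng.choice(GENO_ORDER, p=[0.25, 0.5, 0.25], size=1000)
                              for l in ("A", "B")}, index=[f"i{k}" for k in range(1000)])
        a = calls["A"].map(ACODE)
        b = calls["B"].map(ACODE)
        y = pd.Series(20.0 * a * b + rng.normal(0, 50.0, size=1000), index=calls.index)
        eff = ai.noia_fit(calls, y, ["A", "B"])
        # SE of the aa estimate ~ sigma/sqrt(n*var(a*a-col)) ~ 2.4; 2 SE window
        assert eff.estimates["aa_A:B"] == pytest.approx(20.0, abs=5.0)


class TestGPMapTransformation:
    def fitted_effects(self, seed=3):
        rng = np.random.default_rng(seed)
        calls = pd.DataFrame({l: rng.choice(GENO_ORDER, p=[0.3, 0.5, 0.2], size=400)
                              for l in ("A", "B")}, index=[f"i{k}" for k in range(400)])
        y = pd.Series(rng.normal(size=400), index=calls.index)
        return ai.noia_fit(calls, y, ["A", "B"])

    def test_zero_effects_constant_map(self):
        eff = self.fitted_effects()
        zero = ai.NOIAEffects(loci=eff.loci, terms=eff.terms,
                              estimates=pd.Series(0.0, index=list(eff.terms)),
                              frequencies=eff.frequencies, model=eff.model)
        zero.estimates["r"] = 7.5
        gp = ai.noia_to_gp_map(zero)
        assert np.allclose(gp.values.to_numpy(), 7.5)

    def test_pure_additive_plane(self):
        eff = self.fitted_effects()
        est = pd.Series(0.0, index=list(eff.terms))
        est["a_A"], est["a_B"] = 12.0, 5.0
        # use ideal frequencies so the additive coding is -1/0/1 exactly
        freqs = {"A": np.array([0.25, 0.5, 0.25]), "B": np.array([0.25, 0.5, 0.25])}
        add = ai.NOIAEffects(loci=eff.loci, terms=eff.terms, estimates=est,
                             frequencies=freqs, model=eff.model)
        gp = ai.noia_to_gp_map(add)
        span = gp.values[("HH", "HH")] - gp.values[("LL", "LL")]
        assert span == pytest.approx(2 * 12.0 + 2 * 5.0)

    def test_round_trip_identity(self):
        eff = self.fitted_effects()
        rng = np.random.default_rng(4)
        randomized = ai.NOIAEffects(
            loci=eff.loci, terms=eff.terms,
            estimates=pd.Series(rng.normal(size=len(eff.terms)), index=list(eff.terms)),
            frequencies=eff.frequencies, model=eff.model)
        gp = ai.noia_to_gp_map(randomized)
        back = ai.effects_from_gp_map(gp)
        assert np.abs(back.estimates - randomized.estimates).max() < 1e-8
        gp2 = ai.noia_to_gp_map(back)
        assert np.abs(gp2.values - gp.values).max() < 1e-8

    def test_mismatched_effects_rejected(self):
        eff = self.fitted_effects()
        wrong = ai.NOIAEffects(loci=eff.loci, terms=eff.terms,
                               estimates=eff.estimates.iloc[:-1],
                               frequencies=eff.frequencies, model=eff.model)
        with pytest.raises(ValueError):
            ai.noia_to_gp_map(wrong)


def radial_sim(seed, preset="radial_network", noise_sd=0.0, residualize=None,
               **params):
    """Simulated dataset without sex/generation effects.

    For noiseless runs the phenotype is used directly (class means then
    reflect the architecture exactly); noisy runs are residualized.
    """
    mm = ai.default_marker_map(markers_per_segment=1)
    spec = ai.PedigreeSpec()
    ss = np.random.SeedSequence(seed).spawn(3)
    ped = ai.build_pedigree(spec, seed=ss[0])
    con = ai.simulate_genotypes(ped, mm, seed=ss[1])
    arch = ai.make_architecture(preset, **params)
    segs = list(dict.fromkeys(mm["segment"]))
    hub_seg = "Growth9"
    first = {s: mm[mm.segment == s].marker_id.iloc[0] for s in segs}
    chosen = [hub_seg] + [s for s in segs if s != hub_seg][: len(arch.loci) - 1]
    arch = arch.with_loci([first[s] for s in chosen])
    ph = ai.simulate_phenotypes(con, ped, arch, sex_effect=0.0, noise_sd=noise_sd,
                                seed=ss[2])
    if residualize is None:
        residualize = noise_sd > 0
    y = ai.correct_phenotypes(ph) if residualize else ph["weight56"]
    calls = ai.discretize_contrasts(con)
    return arch, y, calls


class TestModelFreeGPMap:
    def test_ten_classes(self):
        arch, resid, calls = radial_sim(0, noise_sd=50.0)
        table = ai.model_free_gp_map(calls, resid, list(arch.loci[1:]), arch.loci[0],
                                     min_class_n=1)
        assert len(table) == 10
        assert set(table["hub"]) == {"HH", "LL"}
        assert set(table["n_hh"]) == {0, 1, 2, 3, 4}

    def test_radial_pattern_noiseless(self):
        arch, resid, calls = radial_sim(1, noise_sd=0.0)
        table = ai.model_free_gp_map(calls, resid, list(arch.loci[1:]), arch.loci[0],
                                     min_class_n=1)
        hh = table[table["hub"] == "HH"].set_index("n_hh")["mean"].dropna()
        ll = table[table["hub"] == "LL"].set_index("n_hh")["mean"].dropna()
        assert (np.diff(hh.to_numpy()) > 0).all()      # increases with HH-count
        assert np.ptp(ll.to_numpy()) < 1e-9            # flat in LL background

    def test_flat_architecture_equal_means(self):
        arch, resid, calls = radial_sim(2, preset="flat", noise_sd=0.0,
                                        n_loci=5)
        table = ai.model_free_gp_map(calls, resid, list(arch.loci[1:]), arch.loci[0],
                                     min_class_n=1)
        means = table["mean"].dropna()
        assert np.ptp(means.to_numpy()) < 1e-9

    def test_class_counts_sum(self):
        arch, resid, calls = radial_sim(3, noise_sd=30.0)
        radial, hub = list(arch.loci[1:]), arch.loci[0]
        table = ai.model_free_gp_map(calls, resid, radial, hub, min_class_n=1)
        complete = calls[(calls[[hub] + radial] != "NA").all(axis=1)]
        expected = int(complete[hub].isin(["HH", "LL"]).sum())
        assert int(table["n"].sum()) == expected

    def test_small_class_reported_missing(self):
        arch, resid, calls = radial_sim(4, noise_sd=30.0)
        table = ai.model_free_gp_map(calls, resid, list(arch.loci[1:]), arch.loci[0],
                                     min_class_n=10 ** 6)
        assert table["mean"].isna().all()
        assert (table["n"] >= 0).all()


class TestHigherOrderIndicator:
    def test_second_order_architecture_small_differences(self):
        # pairwise model is correctly specified for pairwise_no_hub + padding
        rng = np.random.default_rng(5)
        calls = pd.DataFrame({l: rng.choice(GENO_ORDER, p=[0.25, 0.5, 0.25], size=2000)
                              for l in ("H", "R1", "R2", "R3", "R4")},
                             index=[f"i{k}" for k in range(2000)])
        a = {l: calls[l].map(ACODE) for l in calls}
        y = pd.Series(40.0 * a["H"] + 25.0 * a["R1"] + 20.0 * a["H"] * a["R2"]
                      + rng.normal(0, 60.0, size=2000), index=calls.index)
        eff = ai.noia_fit(calls, y, ["H", "R1", "R2", "R3", "R4"])
        out = ai.higher_order_indicator(calls, y, ["R1", "R2", "R3", "R4"], "H", eff)
        ok = out.dropna(subset=["difference", "sem"])
        assert (np.abs(ok["difference"]) < 3 * ok["sem"] + 1e-9).mean() > 0.8

    def test_three_way_interaction_detected(self):
        rng = np.random.default_rng(6)
        calls = pd.DataFrame({l: rng.choice(GENO_ORDER, p=[0.25, 0.5, 0.25], size=4000)
                              for l in ("H", "R1", "R2", "R3", "R4")},
                             index=[f"i{k}" for k in range(4000)])
        a = {l: calls[l].map(ACODE) for l in calls}
        y = pd.Series(80.0 * a["H"] * a["R1"] * a["R2"] + rng.normal(0, 30.0, size=4000),
                      index=calls.index)
        eff = ai.noia_fit(calls, y, ["H", "R1", "R2", "R3", "R4"])
        out = ai.higher_order_indicator(calls, y, ["R1", "R2", "R3", "R4"], "H", eff)
        ok = out.dropna(subset=["difference", "sem"])
        assert (np.abs(ok["difference"]) > 2 * ok["sem"]).any()

    def test_shift_invariance(self):
        arch, resid, calls = radial_sim(7, noise_sd=40.0)
        radial, hub = list(arch.loci[1:]), arch.loci[0]
        eff = ai.noia_fit(calls, resid, [hub] + radial)
        out1 = ai.higher_order_indicator(calls, resid, radial, hub, eff)
        eff2 = ai.noia_fit(calls, resid + 500.0, [hub] + radial)
        out2 = ai.higher_order_indicator(calls, resid + 500.0, radial, hub, eff2)
        d1 = out1["difference"].dropna().to_numpy()
        d2 = out2["difference"].dropna().to_numpy()
        assert np.allclose(d1, d2, atol=1e-8)
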