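"""Generator contracts: closed-form count moments, determinism, linkage."""

import numpy as np
import pytest

import mzlspatial as mz
from mzlspatial import synthetic
from mzlspatial.synthetic import (
    DEFAULT_INTENSITY_MODELS,
    IntensityModel,
    SimulationError,
)


def _csr_cfg(window, seed, lam=1e-3):
    return mz.SimulationConfig(window=window, seed=seed, intensity=lam)


def _thomas_cfg(window, seed, kappa=5e-5, mu=50.0, sd=20.0):
    return mz.SimulationConfig(
        window=window,
        seed=seed,
        process_kind="thomas",
        thomas=mz.ThomasParams(kappa, mu, sd),
    )


class TestCSR:
    def test_mean_count_matches_poisson_intensity(self, window):
        counts = [
            len(mz.simulate_csr(_csr_cfg(window, s))) for s in range(200)
        ]
        expected = 1e-3 * window.area
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_count_variance_matches_poisson_mean(self, window):
        counts = np.array(
            [len(mz.simulate_csr(_csr_cfg(window, 1000 + s))) for s in range(500)]
        )
        lam = 1e-3 * window.area
        # Var(S²) ≈ (μ4 − σ⁴)/n with Poisson μ4 = λ + 3λ²
        se_var = np.sqrt((lam + 2 * lam**2) / len(counts))
        assert abs(counts.var(ddof=1) - lam) < 3 * se_var

    def test_coordinates_inside_window(self, csr_pattern, window):
        assert window.contains(csr_pattern.x, csr_pattern.y).all()

    def test_seeded_determinism(self, window):
        a = mz.simulate_csr(_csr_cfg(window, 7))
        b = mz.simulate_csr(_csr_cfg(window, 7))
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.labels, b.labels)

    def test_rejects_nonpositive_intensity(self, window):
        with pytest.raises(SimulationError):
            mz.simulate_csr(mz.SimulationConfig(window=window, seed=0, intensity=0.0))


class TestThomas:
    def test_mean_retained_count_matches_neyman_scott(self, window):
        # stationary intensity κ·μ_c restricted to the window
        counts = [len(mz.simulate_thomas(_thomas_cfg(window, s))) for s in range(100)]
        expected = 5e-5 * 50.0 * window.area
        # Var(N) = κ|A|(μ + μ²) for a stationary Thomas count
        se = np.sqrt(5e-5 * window.area * (50.0 + 50.0**2) / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_parent_ids_recorded(self, thomas_pattern):
        assert thomas_pattern.parent_ids is not None
        assert (thomas_pattern.parent_ids >= 0).all()

    def test_window_scale_sigma_approaches_csr(self, window):
        scores = []
        with pytest.warns(UserWarning, match="unresolvable"):
            for s in range(5):
                pat = mz.simulate_thomas(
                    _thomas_cfg(window, s, kappa=1e-4, mu=30.0, sd=600.0)
                )
                scores.append(mz.ripley_k(pat.x, pat.y, window).cluster_score)
        assert abs(np.mean(scores)) < 0.1

    def test_seeded_determinism(self, window):
        a = mz.simulate_thomas(_thomas_cfg(window, 3))
        b = mz.simulate_thomas(_thomas_cfg(window, 3))
        assert np.array_equal(a.x, b.x) and np.array_equal(a.parent_ids, b.parent_ids)


class TestBivariate:
    def _pair(self, window, seed, kind, mu_b=30.0):
        cfg = mz.SimulationConfig(
            window=window,
            seed=seed,
            process_kind=kind,
            thomas=mz.ThomasParams(5e-5, 30.0, 20.0),
            label_a="A",
            label_b="B",
            mean_offspring_b=mu_b,
        )
        return mz.simulate_bivariate(cfg)

    def test_linked_closer_than_independent(self, window):
        wins = 0
        for s in range(10):
            med = {}
            for kind in ("linked_bivariate", "independent_bivariate"):
                pat = self._pair(window, s, kind)
                a, b = pat.subset("A"), pat.subset("B")
                med[kind] = mz.cross_nn_distances(a.x, a.y, b.x, b.y).median
            wins += med["linked_bivariate"] < med["independent_bivariate"]
        assert wins >= 9

    def test_linked_higher_morisita_horn(self, window):
        wins = 0
        for s in range(10):
            mh = {}
            for kind in ("linked_bivariate", "independent_bivariate"):
                pat = self._pair(window, s, kind)
                a, b = pat.subset("A"), pat.subset("B")
                g = mz.tessellate(a.x, a.y, b.x, b.y, window, 200.0)
                mh[kind] = mz.morisita_horn(g.counts_a, g.counts_b)
            wins += mh["linked_bivariate"] > mh["independent_bivariate"]
        assert wins >= 9

    def test_zero_offspring_class_b_is_empty_and_propagates(self, window):
        pat = self._pair(window, 0, "linked_bivariate", mu_b=0.0)
        b = pat.subset("B")
        assert len(b) == 0
        a = pat.subset("A")
        with pytest.raises(mz.NeighborError):
            mz.cross_nn_distances(a.x, a.y, b.x, b.y)
        with pytest.raises(mz.QuadratError):
            mz.morisita_horn([1, 2], [0, 0])

    def test_non_bivariate_kind_rejected(self, window):
        cfg = mz.SimulationConfig(
            window=window, seed=0, process_kind="csr",
            thomas=mz.ThomasParams(5e-5, 30.0, 20.0),
        )
        with pytest.raises(SimulationError):
            mz.simulate_bivariate(cfg)


class TestIntensities:
    def test_missing_channel_model_rejected(self, window):
        pat = mz.simulate_csr(_csr_cfg(window, 1))
        cfg = mz.SimulationConfig(
            window=window, seed=1, intensity_models={"cell": {"CD4": synthetic.HIGH}}
        )
        with pytest.raises(SimulationError, match="channel"):
            mz.attach_intensities(pat, cfg)

    def test_unknown_phenotype_rejected(self, window):
        pat = mz.simulate_csr(_csr_cfg(window, 1))
        cfg = mz.SimulationConfig(window=window, seed=1, intensity_models={})
        with pytest.raises(SimulationError, match="intensity model"):
            mz.attach_intensities(pat, cfg)

    def test_seeded_determinism(self, window):
        _, t1 = mz.simulate_full_tissue(seed=5)
        _, t2 = mz.simulate_full_tissue(seed=5)
        assert t1.equals(t2)

    def test_identical_models_are_indistinguishable(self, window):
        # two phenotypes with the same channel models: gating cannot beat chance
        models = {
            "A": DEFAULT_INTENSITY_MODELS["Tfh"],
            "B": DEFAULT_INTENSITY_MODELS["Tfh"],
        }
        rng = np.random.default_rng(0)
        n = 2000
        labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2), dtype=object)
        pat = mz.LabeledPattern(
            rng.uniform(0, 1000, n), rng.uniform(0, 1000, n), labels, window
        )
        cfg = mz.SimulationConfig(window=window, seed=2, intensity_models=models)
        table = mz.attach_intensities(pat, cfg)
        # both classes produce identical (Tfh-like) calls: zero discrimination
        gcfg = mz.GatingConfig(
            thresholds={c: 12.0 for c in ("CD4", "PD1", "FOXP3", "Ki67")}
        )
        calls = mz.gate_cells(table, gcfg)
        frac_a = (calls[calls["true_label"] == "A"]["phenotype"] == "Tfh").mean()
        frac_b = (calls[calls["true_label"] == "B"]["phenotype"] == "Tfh").mean()
        assert abs(frac_a - frac_b) < 0.05

    def test_pd1_channel_bimodal_in_full_tissue(self):
        _, table = mz.simulate_full_tissue(seed=9)
        logpd1 = np.log(table["PD1"])
        lo = (logpd1 < 2.5).mean()
        assert 0.05 < lo < 0.995 and (logpd1 > 2.5).any()


class TestFullTissue:
    def test_labels_and_window(self):
        pattern, table = mz.simulate_full_tissue(seed=3)
        assert set(np.unique(pattern.labels)) == {"Tfh", "Treg", "Bprolif", "background"}
        assert pattern.window.contains(table["x"], table["y"]).all()

    def test_composition_near_declared_mixture(self):
        # Tfh and Treg analogues have equal expected counts; subset share of
        # CD4-positive phenotypes is about 16%
        _, table = mz.simulate_full_tissue(seed=21)
        counts = table["true_label"].value_counts()
        assert 0.7 < counts["Tfh"] / counts["Treg"] < 1.4
        cd4 = counts["Tfh"] + counts["Treg"] + counts["background"]
        assert 0.10 < (counts["Tfh"] + counts["Treg"]) / cd4 < 0.25
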