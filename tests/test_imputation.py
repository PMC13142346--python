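import dataclasses

import numpy as np
import pandas as pd
import pytest

from strainrec.errors import EmptyResourceError, NoCisVariantError
from strainrec.genomes import Window, window_distances
from strainrec.imputation import (GeneLocus, _ridge_path, donor_feature_matrix,
                                  fit_gene_model, impute_f1, impute_panel,
                                  impute_strain, load_models, map_cis_eqtl,
                                  read_expression, save_models, train_resource,
                                  write_expression)
from strainrec.pipeline import simulate_study
from strainrec.synthesizer import (SimulationConfig, simulate_donors,
                                   simulate_founders)
from .conftest import make_gm


def _random_instance(rng, n_donors, n_variants=12):
    """A random genotype panel + expression with every variant in one window."""
    dosage = rng.integers(0, 3, size=(n_variants, n_donors)).astype(float)
    gm = make_gm(dosage, pos=np.arange(1, n_variants + 1) * 100,
                 samples=[f"D{i}" for i in range(n_donors)])
    y = rng.normal(0, 1, n_donors)
    window = Window("1", 600, 100_000)
    return gm, y, window


def _closed_form_ridge(F, y, lam):
    """Normal-equations oracle for centered ridge with intercept."""
    Fc = F - F.mean(axis=0)
    yc = y - y.mean()
    beta = np.linalg.solve(Fc.T @ Fc + lam * np.eye(F.shape[1]), Fc.T @ yc)
    return beta, y.mean() - F.mean(axis=0) @ beta


class TestMapCisEqtl:
    def test_single_candidate_is_forced(self):
        gm = make_gm([[0, 1, 2, 0, 1]], pos=[1000])
        y = np.array([0.1, 0.9, 2.2, -0.1, 1.1])
        eq = map_cis_eqtl(y, gm, GeneLocus("g", "1", 1500), gm.sample_ids)
        assert eq.variant_id == "v0"

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            gm, y, _ = _random_instance(rng, n_donors=30, n_variants=20)
            eq = map_cis_eqtl(y, gm, GeneLocus("g", "1", 1000), gm.sample_ids,
                              cis_span=10_000)
            best = max(range(gm.n_variants), key=lambda k: (
                abs(np.corrcoef(gm.dosage[k], y)[0, 1])
                if gm.dosage[k].std() > 0 else -1.0))
            r_best = abs(np.corrcoef(gm.dosage[best], y)[0, 1])
            assert abs(eq.r - r_best) < 1e-12

    def test_no_candidate_raises(self):
        gm = make_gm([[0, 1, 2]], pos=[10_000_000])
        with pytest.raises(NoCisVariantError):
            map_cis_eqtl(np.array([1.0, 2.0, 3.0]), gm,
                         GeneLocus("g", "1", 1000), gm.sample_ids,
                         cis_span=1000)

    def test_planted_eqtl_recovered_in_95_of_100(self):
        """A planted cis effect (beta=1, noise sd 0.2, 185 donors) is found."""
        cfg = SimulationConfig(n_donors=185, n_variants=600,
                               chrom_length=6_000_000,
                               block_length=1_000_000, seed=0)
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(100):
            founders = simulate_founders(cfg, rng)
            donors = simulate_donors(founders, cfg, rng)
            poly = np.flatnonzero(donors.dosage.std(axis=1) > 0)
            vi = int(rng.choice(poly))
            y = donors.dosage[vi] + rng.normal(0, 0.2, donors.n_samples)
            eq = map_cis_eqtl(y, donors, GeneLocus("g", "1", int(donors.pos[vi])),
                              donors.sample_ids)
            hits += int(eq.index == vi)
        assert hits >= 95


class TestRidgeFit:
    def test_huge_penalty_shrinks_to_donor_mean(self):
        rng = np.random.default_rng(1)
        gm, y, window = _random_instance(rng, n_donors=10)
        eq = map_cis_eqtl(y, gm, GeneLocus("g", "1", 600), gm.sample_ids,
                          cis_span=10_000)
        model = fit_gene_model(y, gm, eq, gm.sample_ids, lambda_grid=[1e9])
        assert np.abs(model.beta).max() < 1e-6
        assert model.intercept == pytest.approx(y.mean(), abs=1e-3)

    def test_beta_matches_closed_form_oracle(self):
        rng = np.random.default_rng(2)
        lam = 0.7
        for _ in range(5):
            gm, y, window = _random_instance(rng, n_donors=6)
            eq = map_cis_eqtl(y, gm, GeneLocus("g", "1", 600), gm.sample_ids,
                              cis_span=10_000)
            model = fit_gene_model(y, gm, eq, gm.sample_ids, lambda_grid=[lam])
            F = donor_feature_matrix(gm, gm.sample_ids, y, model.window)
            beta, intercept = _closed_form_ridge(F, y, lam)
            np.testing.assert_allclose(model.beta, beta, atol=1e-6)
            assert model.intercept == pytest.approx(intercept, abs=1e-6)

    def test_beta_matches_sklearn_ridge(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(3)
        gm, y, _ = _random_instance(rng, n_donors=15)
        eq = map_cis_eqtl(y, gm, GeneLocus("g", "1", 600), gm.sample_ids,
                          cis_span=10_000)
        model = fit_gene_model(y, gm, eq, gm.sample_ids, lambda_grid=[2.5])
        F = donor_feature_matrix(gm, gm.sample_ids, y, model.window)
        sk = Ridge(alpha=2.5, fit_intercept=True).fit(F, y)
        np.testing.assert_allclose(model.beta, sk.coef_, atol=1e-8)
        assert model.intercept == pytest.approx(sk.intercept_, abs=1e-8)

    def test_lambda_selection_equals_brute_force_cv_scan(self):
        rng = np.random.default_rng(4)
        gm, y, _ = _random_instance(rng, n_donors=20)
        eq = map_cis_eqtl(y, gm, GeneLocus("g", "1", 600), gm.sample_ids,
                          cis_span=10_000)
        grid = np.logspace(-2, 2, 9)
        seed = 5
        model = fit_gene_model(y, gm, eq, gm.sample_ids, lambda_grid=grid,
                               seed=seed)
        F = donor_feature_matrix(gm, gm.sample_ids, y, model.window)
        # independent fold-by-fold scan with normal-equations solves
        perm = np.random.default_rng(seed).permutation(len(y))
        sse = np.zeros(len(grid))
        for test in np.array_split(perm, 5):
            mask = np.ones(len(y), dtype=bool)
            mask[test] = False
            for li, lam in enumerate(grid):
                beta, b0 = _closed_form_ridge(F[mask], y[mask], lam)
                sse[li] += ((F[test] @ beta + b0 - y[test]) ** 2).sum()
        assert model.lambda_ == grid[int(np.argmin(sse))]

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(6)
        F = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        lams = np.logspace(-3, 3, 20)
        betas, _ = _ridge_path(F, y, lams)
        norms = np.linalg.norm(betas, axis=0)
        assert np.all(np.diff(norms) <= 1e-12)


class TestImputation:
    @staticmethod
    def _one_hot_setup():
        """Strain T matches donor D0 exactly and is maximally distant from
        the five other (mutually identical) donors."""
        rng = np.random.default_rng(8)
        pattern = rng.choice([0.0, 2.0], size=10)
        dosage = np.column_stack([pattern] + [2 - pattern] * 5 + [pattern])
        samples = [f"D{i}" for i in range(6)] + ["T"]
        gm = make_gm(dosage, pos=np.arange(1, 11) * 100, samples=samples)
        y = rng.normal(0, 1, 6)
        donors = samples[:6]
        eq = map_cis_eqtl(y, gm, GeneLocus("g", "1", 500), donors,
                          cis_span=10_000)
        model = fit_gene_model(y, gm, eq, donors, lambda_grid=[0.5],
                               gene_id="g")
        return gm, model, y

    def test_one_hot_strain_prediction(self):
        gm, model, y = self._one_hot_setup()
        pred = impute_strain(model, gm, "T")
        assert pred == pytest.approx(model.intercept + model.beta[0] * y[0])

    def test_panel_shape_ids_and_determinism(self, small_study):
        assert list(small_study.resource.columns) == small_study.strain_ids
        assert len(small_study.resource) == len(small_study.models)
        again = impute_panel(small_study.models, small_study.genotypes,
                             small_study.strain_ids)
        pd.testing.assert_frame_equal(again, small_study.resource)

    def test_training_reproducible_bit_identical(self, small_config):
        a = simulate_study(small_config)
        b = simulate_study(small_config)
        for ma, mb in zip(a.models, b.models):
            assert ma.to_dict() == mb.to_dict()
        pd.testing.assert_frame_equal(a.resource, b.resource)

    def test_empty_model_list_raises(self, small_study):
        with pytest.raises(EmptyResourceError):
            impute_panel([], small_study.genotypes, ["STR001"])

    def test_imputed_tracks_noise_free_truth(self, default_study):
        """Per-gene correlation between imputed strain expression and the
        planted noise-free genetic expression, across the inbred panel."""
        nf = default_study.truth.noise_free(default_study.strains)
        rs = []
        for g in default_study.resource.index:
            t = nf.loc[g].to_numpy()
            if t.std() == 0:
                continue
            rs.append(np.corrcoef(default_study.resource.loc[g], t)[0, 1])
        assert len(rs) >= 200
        assert np.nanmean(rs) > 0.8

    def test_cv_r2_improves_as_noise_falls(self, small_config):
        means = []
        for sd in (1.0, 0.5, 0.2):
            cfg = dataclasses.replace(small_config, noise_sd=sd)
            study = simulate_study(cfg)
            means.append(np.mean([m.cv_r2 for m in study.models]))
        assert means[0] < means[1] < means[2]


class TestVirtualF1:
    def test_self_cross_equals_strain_imputation(self, small_study):
        s = small_study.strain_ids[0]
        f1 = impute_f1(small_study.models, small_study.genotypes, s, s)
        direct = small_study.resource[s]
        np.testing.assert_allclose(f1.to_numpy(), direct.to_numpy(),
                                   atol=1e-12)

    def test_symmetry(self, small_study):
        a, b = small_study.strain_ids[:2]
        ab = impute_f1(small_study.models, small_study.genotypes, a, b)
        ba = impute_f1(small_study.models, small_study.genotypes, b, a)
        np.testing.assert_array_equal(ab.to_numpy(), ba.to_numpy())

    def test_f1_distance_bounded_by_parents(self, small_study):
        """d(F1, donor) lies within the triangle bounds
        [|d_a - d_b| / 2, (d_a + d_b) / 2] of the parents' distances."""
        gm = small_study.genotypes
        rng = np.random.default_rng(10)
        window = small_study.models[0].window
        donors = small_study.donor_ids
        for _ in range(50):
            a, b = rng.choice(small_study.strain_ids, 2, replace=False)
            ia, ib = gm.sample_index(a), gm.sample_index(b)
            f1 = (gm.dosage[:, ia] + gm.dosage[:, ib]) / 2
            from strainrec.genomes import vector_window_distances
            dF = vector_window_distances(gm, f1, donors, window)
            da = window_distances(gm, [a], donors, window)[0]
            db = window_distances(gm, [b], donors, window)[0]
            assert np.all(dF <= (da + db) / 2 + 1e-12)
            assert np.all(dF >= np.abs(da - db) / 2 - 1e-12)


class TestModelStore:
    def test_round_trip_bit_exact(self, small_study, tmp_path):
        path = tmp_path / "models.json"
        save_models(small_study.models, path)
        back = load_models(path)
        for ma, mb in zip(small_study.models, back):
            da, db = ma.to_dict(), mb.to_dict()
            assert da == db  # exact float equality via repr round-trip

    def test_expression_tsv_round_trip_bit_exact(self, small_study, tmp_path):
        path = tmp_path / "resource.tsv"
        write_expression(small_study.resource, path)
        back = read_expression(path)
        assert (back.to_numpy() == small_study.resource.to_numpy()).all()
        assert list(back.index) == list(small_study.resource.index)
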