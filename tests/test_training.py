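import numpy as np
import pytest

from scmformer import (GenerationTask, IntegrationTask, LatentRepresentation,
                       PreprocessConfig, ScmModelConfig, SimConfig,
                       extract_latents, generate, loss_comb, loss_integration,
                       loss_rec, pair, preprocess_dataset, simulate_paired,
                       train_generation, train_integration)


class TestLosses:
    def test_rec_identical(self, rng):
        X = rng.normal(size=(3, 4))
        assert loss_rec(X, X) == 0.0

    def test_rec_unit_residual(self):
        assert loss_rec(np.ones((3, 4)), np.zeros((3, 4))) == 1.0

    def test_rec_matches_loop_oracle(self, rng):
        a, b = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        acc = 0.0
        for i in range(3):
            for j in range(4):
                acc += (a[i, j] - b[i, j]) ** 2
        np.testing.assert_allclose(loss_rec(a, b), acc / 12, atol=1e-12)

    def test_rec_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            loss_rec(rng.normal(size=(2, 3)), rng.normal(size=(3, 2)))

    def test_comb_identical(self, rng):
        L = LatentRepresentation(rng.normal(size=(4, 3)), "rna")
        assert loss_comb([L, L]) == 0.0

    def test_comb_three_identical(self, rng):
        L = rng.normal(size=(4, 3))
        assert loss_comb([L, L, L]) == 0.0

    def test_comb_constant_offset(self, rng):
        A = rng.normal(size=(4, 3))
        assert loss_comb([A, A + 2.0]) == pytest.approx(4.0)

    def test_comb_pairwise_mean_for_three(self, rng):
        A = rng.normal(size=(4, 3))
        B, C = A + 1.0, A - 1.0
        # pairs: (A,B)=1, (A,C)=1, (B,C)=4 -> mean 2
        assert loss_comb([A, B, C]) == pytest.approx(2.0)

    def test_integration_limits(self):
        assert loss_integration([0.3, 0.4], 0.5, 0.0) == pytest.approx(0.5)
        assert loss_integration([0.3, 0.4], 0.0, 2.0) == pytest.approx(1.4)
        assert loss_integration([0.1], 0.5, 70.0) == pytest.approx(7.5)

    def test_integration_negative_lambda(self):
        with pytest.raises(ValueError):
            loss_integration([0.1], 0.5, -1.0)

    def test_pairing_invariance(self, rng):
        A, B = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        assert loss_comb([A, B]) == pytest.approx(loss_comb([A[perm], B[perm]]))
        assert loss_rec(A, B) == pytest.approx(loss_rec(A[perm], B[perm]))


@pytest.fixture(scope="module")
def trained_small():
    ds, _ = simulate_paired(SimConfig(n_cells=200, n_genes=120,
                                      n_proteins=24, seed=7))
    red = preprocess_dataset(ds, PreprocessConfig(aligned_dim=32))
    cfg = ScmModelConfig(s=8, H=2, aligned_dim=32, epochs=5, batch_size=16,
                         drop_rate=0.0, lr=2e-3, seed=0)
    model, trace = train_integration(IntegrationTask(dataset=red, config=cfg))
    return ds, red, cfg, model, trace


class TestTrainIntegration:
    def test_loss_decreases(self, trained_small):
        *_, trace = trained_small
        assert trace.total[-1] < trace.total[0]

    def test_default_lambda_in_printed_range(self):
        assert 40.0 <= ScmModelConfig().lambda_rec <= 100.0

    def test_deterministic_traces(self, trained_small):
        ds, red, cfg, _, trace = trained_small
        _, trace2 = train_integration(IntegrationTask(dataset=red, config=cfg))
        assert trace.total == trace2.total

    def test_d_not_divisible_by_s(self, trained_small):
        ds, red, *_ = trained_small
        with pytest.raises(ValueError, match="divisible"):
            IntegrationTask(dataset=red,
                            config=ScmModelConfig(s=5, H=1, aligned_dim=35))

    def test_raw_layer_rejected(self, trained_small):
        ds, *_ = trained_small
        with pytest.raises(ValueError, match="reduced"):
            IntegrationTask(dataset=ds, config=ScmModelConfig())


class TestExtractLatents:
    def test_shape_and_repeatability(self, trained_small):
        _, red, cfg, model, _ = trained_small
        lat1 = extract_latents(model, red)
        lat2 = extract_latents(model, red)
        for name in ("rna", "protein"):
            assert lat1[name].values.shape == (200, cfg.s)
            assert np.array_equal(lat1[name].values, lat2[name].values)

    def test_duplicated_cells_identical_latents(self, trained_small):
        _, red, cfg, model, _ = trained_small
        dup = pair([m.replace(values=np.vstack([m.values[:1], m.values[:1]]),
                              cell_ids=["a", "b"])
                    for m in red.modalities])
        lat = extract_latents(model, dup)
        for name in lat:
            np.testing.assert_array_equal(lat[name].values[0],
                                          lat[name].values[1])


@pytest.fixture(scope="module")
def gen_setup():
    from scmformer import normalize_protein
    ds, _ = simulate_paired(SimConfig(n_cells=200, n_genes=120,
                                      n_proteins=24, seed=7))
    red = preprocess_dataset(ds, PreprocessConfig(aligned_dim=32))
    rna = red.modality("rna")
    prot = normalize_protein(ds.modality("protein"))
    cfg = ScmModelConfig(s=8, H=2, aligned_dim=32, epochs=8, batch_size=16,
                         drop_rate=0.0, lr=2e-3, seed=0)
    task = GenerationTask(dataset=pair([rna]), config=cfg,
                          source_modality="rna", target_modality="protein",
                          target_values=prot.values)
    model, trace = train_generation(task)
    return rna, prot, model, trace


class TestGeneration:

    def test_loss_decreases(self, gen_setup):
        *_, trace = gen_setup
        assert trace.total[-1] < trace.total[0]

    def test_prediction_width(self, gen_setup):
        rna, prot, model, _ = gen_setup
        pred = generate(model, rna)
        assert pred.shape == (200, prot.values.shape[1])

    def test_beats_column_mean_baseline(self, gen_setup):
        from scmformer import generation_scores
        rna, prot, model, _ = gen_setup
        pred = generate(model, rna)
        r = generation_scores(pred, prot.values).pearson_per_feature.mean()
        assert r > 0.0  # column-mean baseline has correlation 0 by definition

    def test_row_order_follows_input(self, gen_setup):
        rna, _, model, _ = gen_setup
        rev = rna.replace(values=rna.values[::-1].copy(),
                          cell_ids=list(reversed(rna.cell_ids)))
        np.testing.assert_allclose(generate(model, rev),
                                   generate(model, rna)[::-1], atol=1e-12)

    def test_zero_cell_finite(self, gen_setup):
        rna, _, model, _ = gen_setup
        zero = rna.replace(values=np.zeros((1, rna.n_features)),
                           cell_ids=["z"])
        out = generate(model, zero)
        assert np.all(np.isfinite(out))

    def test_feature_space_mismatch(self, gen_setup):
        rna, _, model, _ = gen_setup
        bad = rna.replace(values=rna.values[:, :8],
                          feature_ids=rna.feature_ids[:8])
        with pytest.raises(ValueError, match="incompatible"):
            generate(model, bad)


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_nan_guard():
    ds, _ = simulate_paired(SimConfig(n_cells=60, n_genes=60, n_proteins=16,
                                      seed=3))
    red = preprocess_dataset(ds, PreprocessConfig(aligned_dim=16))
    red.modalities[0].values[0, 0] = np.inf  # poison one entry
    cfg = ScmModelConfig(s=8, H=2, aligned_dim=16, epochs=1, batch_size=60,
                         drop_rate=0.0, seed=0)
    with pytest.raises(FloatingPointError, match="non-finite"):
        train_integration(IntegrationTask(dataset=red, config=cfg))
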