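import numpy as np
import pytest

from barcodenet import BarcodeMemory, ModelConfig, RecurrentWeights, hebbian_update

from conftest import reduced_config


# --------------------------------------------------------------------------
# Hebbian update rule
# --------------------------------------------------------------------------

class TestHebbianUpdate:
    def test_basis_vector_entries_at_printed_scale(self):
        """dJ on a unit basis vector, evaluated at the printed eta, beta, N."""
        cfg = ModelConfig(dtype="float64")  # N_x = 5000, eta = 40, beta = -0.35
        w = RecurrentWeights(B=np.zeros((cfg.N_x, cfg.N_x)))
        x = np.zeros(cfg.N_x)
        x[0] = 1.0
        hebbian_update(w, x, cfg)
        assert w.H[0, 0] == pytest.approx((40 / 5000) * (1 - 0.35), abs=1e-12)
        assert w.H[0, 0] == pytest.approx(0.0052, abs=1e-12)
        assert w.H[0, 1] == pytest.approx(-(40 / 5000) * 0.35, abs=1e-12)
        assert w.H[0, 1] == pytest.approx(-0.0028, abs=1e-12)
        # all rows with x_i = 0 stay exactly zero (postsynaptic gating)
        assert np.all(w.H[1:] == 0.0)

    def test_zero_activity_no_change(self, cfg_tiny):
        w = RecurrentWeights(B=np.zeros((cfg_tiny.N_x, cfg_tiny.N_x)))
        hebbian_update(w, np.zeros(cfg_tiny.N_x), cfg_tiny)
        assert np.all(w.H == 0.0)

    def test_negative_activity_rejected(self, cfg_tiny):
        w = RecurrentWeights(B=np.zeros((cfg_tiny.N_x, cfg_tiny.N_x)))
        x = np.zeros(cfg_tiny.N_x)
        x[3] = -0.1
        with pytest.raises(ValueError, match="nonnegative"):
            hebbian_update(w, x, cfg_tiny)

    def test_matches_outer_product_form(self, cfg_tiny):
        rng = np.random.default_rng(0)
        x = np.abs(rng.standard_normal(cfg_tiny.N_x))
        w = RecurrentWeights(B=np.zeros((cfg_tiny.N_x, cfg_tiny.N_x)))
        hebbian_update(w, x, cfg_tiny)
        scale = cfg_tiny.eta / cfg_tiny.N_x
        expected = scale * (np.outer(x, x) + cfg_tiny.beta * np.outer(x, np.ones_like(x)))
        assert np.allclose(w.H, expected, atol=1e-6)

    def test_accumulation_is_additive(self, cfg_tiny):
        """H after two updates equals the sum of the two increments."""
        rng = np.random.default_rng(1)
        xs = [np.abs(rng.standard_normal(cfg_tiny.N_x)) for _ in range(2)]
        w_seq = RecurrentWeights(B=np.zeros((cfg_tiny.N_x, cfg_tiny.N_x)))
        for x in xs:
            hebbian_update(w_seq, x, cfg_tiny)
        parts = []
        for x in xs:
            w = RecurrentWeights(B=np.zeros((cfg_tiny.N_x, cfg_tiny.N_x)))
            hebbian_update(w, x, cfg_tiny)
            parts.append(w.H)
        assert np.allclose(w_seq.H, parts[0] + parts[1], atol=1e-6)


# --------------------------------------------------------------------------
# storage
# --------------------------------------------------------------------------

class TestStorage:
    def test_first_cache_readouts(self, cfg_tiny):
        model = BarcodeMemory(cfg_tiny, seed=5)
        assert np.all(model.readout.w_seed == 0.0)
        assert np.all(model.readout.J_place == 0.0)
        trace = model.store_cache(7)
        scale = cfg_tiny.eta / cfg_tiny.N_x
        assert np.allclose(model.readout.w_seed, scale * trace.x_stored, atol=1e-7)
        assert np.allclose(
            model.readout.J_place,
            scale * np.outer(trace.p_stored, trace.x_stored),
            atol=1e-7,
        )

    def test_readout_additivity(self, cfg_tiny):
        """Readouts after several caches equal the sums of per-cache terms."""
        model = BarcodeMemory(cfg_tiny, seed=5)
        traces = [model.store_cache(loc) for loc in (3, 11, 17)]
        scale = cfg_tiny.eta / cfg_tiny.N_x
        w_expect = scale * np.sum([t.x_stored for t in traces], axis=0)
        J_expect = scale * np.sum(
            [np.outer(t.p_stored, t.x_stored) for t in traces], axis=0
        )
        assert np.allclose(model.readout.w_seed, w_expect, atol=1e-6)
        assert np.allclose(model.readout.J_place, J_expect, atol=1e-6)

    def test_trace_recorded_before_update(self, cfg_small):
        model = BarcodeMemory(cfg_small, seed=1)
        trace = model.store_cache(50)
        assert np.all(trace.x_stored >= 0)
        # the stored snapshot reflects pre-update weights: re-running the same
        # caching dynamics on a fresh model reproduces it exactly
        model2 = BarcodeMemory(cfg_small, seed=1)
        trace2 = model2.store_cache(50)
        assert np.array_equal(trace.x_stored, trace2.x_stored)

    def test_same_seed_same_barcode_different_seed_uncorrelated(self, cfg_small):
        m = BarcodeMemory(cfg_small, seed=7)
        a = m.store_cache(30).x_stored
        b = BarcodeMemory(cfg_small, seed=7).store_cache(30).x_stored
        c = BarcodeMemory(cfg_small, seed=8).store_cache(30).x_stored
        assert np.array_equal(a, b)
        # the shared place drive confines both patterns to the same local
        # neighborhood; which units win within it is seed-specific, so the
        # patterns decorrelate once the local place subspace is removed
        B = m.bank.vectors[[26, 28, 30, 32, 34]].T
        Q, _ = np.linalg.qr(B.astype(np.float64))
        ra = a - Q @ (Q.T @ a)
        rc = c - Q @ (Q.T @ c)
        assert abs(np.corrcoef(ra, rc)[0, 1]) < 0.25

    def test_separated_caches_store_uncorrelated_patterns(self, stored_model):
        """Barcodes at well-separated sites: near-zero residual correlation."""
        t1, t2 = stored_model.traces
        def residual(t):
            p = t.p_stored / np.linalg.norm(t.p_stored)
            return t.x_stored - (t.x_stored @ p) * p
        r = np.corrcoef(residual(t1), residual(t2))[0, 1]
        assert abs(r) < 0.15


# --------------------------------------------------------------------------
# recall
# --------------------------------------------------------------------------

class TestRecall:
    def test_no_caches_zero_readouts(self, cfg_tiny):
        model = BarcodeMemory(cfg_tiny, seed=0)
        _, y_seed, y_place = model.recall_event([0, 5], 0.0)
        assert np.all(y_seed == 0.0)
        assert np.all(y_place == 0.0)

    def test_same_site_recall_reinstates_stored_pattern(self, cfg_small):
        """Pattern completion: place cue alone converges onto the attractor."""
        coses, ys_vals = [], []
        for seed in (2, 3, 4):
            model = BarcodeMemory(cfg_small, seed=seed)
            t = model.store_cache(20)
            model.store_cache(70)
            x, y_seed, _ = model.recall_event([20], 0.0)
            coses.append(
                t.x_stored @ x[:, 0]
                / (np.linalg.norm(t.x_stored) * np.linalg.norm(x[:, 0]))
            )
            ys_vals.append(float(y_seed[0]))
        assert np.mean(coses) > 0.85
        assert min(coses) > 0.75
        assert all(v > cfg_small.kappa for v in ys_vals)

    def test_seed_output_above_threshold_only_near_caches(self, three_cache_model):
        m = three_cache_model
        _, y_seed, _ = m.recall_event(np.array([20, 35, 70, 27, 52, 95]), 0.0)
        assert all(y_seed[i] > m.config.kappa for i in range(3))
        assert all(y_seed[i] <= m.config.kappa for i in (3, 4, 5))

    def test_remote_recall_requires_search_strength(self, three_cache_model):
        """Seed output at a remote state grows with the search strength."""
        m = three_cache_model
        remote = np.array([62])  # 8 states from the nearest cache
        vals = []
        for s in (0.0, 1.5):
            _, y_seed, _ = m.recall_event(remote, s)
            vals.append(float(y_seed[0]))
        assert vals[1] > vals[0]

    def test_place_output_peaks_at_recalled_cache(self, three_cache_model):
        m = three_cache_model
        _, y_seed, y_place = m.recall_event(np.array([35]), 0.0)
        assert y_seed[0] > m.config.kappa
        peak = m.place_peak_states(y_place)[0]
        d = min(abs(peak - 35), m.config.N_s - abs(peak - 35))
        assert d <= 2


class TestBetaBias:
    def test_beta_prevents_spurious_recall_between_caches(self, cfg_small):
        """Removing the inhibitory bias floods the midpoint with false recall."""
        mids = {}
        for beta in (-0.35, -1e-9):
            vals = []
            for seed in (1, 2, 3):
                m = BarcodeMemory(cfg_small.replace(beta=beta), seed=seed)
                m.store_cache(20)
                m.store_cache(28)
                _, ys, _ = m.recall_event(np.array([24]), 0.0)
                vals.append(float(ys[0]))
            mids[beta] = np.mean(vals)
        assert mids[-0.35] < cfg_small.kappa
        assert mids[-1e-9] > 4 * mids[-0.35]
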