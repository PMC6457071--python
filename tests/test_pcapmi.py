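import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metanet import (
    AbundanceError,
    CommunitySpec,
    ParameterError,
    PmiParams,
    generate_community,
    mutual_information,
    part_mutual_information,
    pca_pmi_network,
    pmi_from_joint,
)

BINNED = PmiParams(estimator="binned")
GAUSSIAN = PmiParams(estimator="gaussian")


def reference_pmi(p):
    """Literal triple sum over the discrete joint: an oracle kept deliberately
    dumb (python loops, explicit conditionals)."""
    nx_, ny_, nz_ = p.shape
    px = [sum(p[x, y, z] for y in range(ny_) for z in range(nz_)) for x in range(nx_)]
    py = [sum(p[x, y, z] for x in range(nx_) for z in range(nz_)) for y in range(ny_)]
    pz = [sum(p[x, y, z] for x in range(nx_) for y in range(ny_)) for z in range(nz_)]
    pxz = [[sum(p[x, y, z] for y in range(ny_)) for z in range(nz_)] for x in range(nx_)]
    pyz = [[sum(p[x, y, z] for x in range(nx_)) for z in range(nz_)] for y in range(ny_)]
    total = 0.0
    for x in range(nx_):
        for y in range(ny_):
            for z in range(nz_):
                if p[x, y, z] <= 0:
                    continue
                p_xy_given_z = p[x, y, z] / pz[z]
                p_star_y = sum(
                    (p[xp, y, z] / pxz[xp][z]) * px[xp]
                    for xp in range(nx_)
                    if pxz[xp][z] > 0
                )
                p_star_x = sum(
                    (p[x, yp, z] / pyz[yp][z]) * py[yp]
                    for yp in range(ny_)
                    if pyz[yp][z] > 0
                )
                total += p[x, y, z] * math.log(p_xy_given_z / (p_star_x * p_star_y))
    return max(total, 0.0)


def random_joint(rng, shape):
    flat = rng.dirichlet(np.ones(shape[0] * shape[1] * shape[2]))
    return flat.reshape(shape)


class TestMutualInformation:
    def test_identical_vectors_hit_bin_entropy(self):
        # 100 samples, 10 equal-frequency bins -> MI = log(10)
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        mi = mutual_information(x, x, PmiParams(estimator="binned", n_bins=10))
        assert mi == pytest.approx(math.log(10), abs=1e-12)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        mi = mutual_information(x, y, PmiParams(estimator="binned", n_bins=4))
        assert mi < 0.02  # estimator bias bound at this bin count

    def test_gaussian_zero_correlation_is_exact_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # r = 0
        assert mutual_information(x, y, GAUSSIAN) == 0.0

    def test_constant_vector_has_zero_information(self):
        x = np.ones(10)
        y = np.arange(10.0)
        assert mutual_information(x, y, BINNED) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            mutual_information(np.ones(5), np.ones(6))

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_binned_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        base = mutual_information(x, y, BINNED)
        assert mutual_information(np.exp(x), y, BINNED) == base
        assert mutual_information(x, 3 * y + 7, BINNED) == base


class TestPartMutualInformation:
    def test_matches_reference_on_toy_distribution(self):
        rng = np.random.default_rng(2)
        joint = random_joint(rng, (2, 2, 2))
        assert pmi_from_joint(joint) == pytest.approx(reference_pmi(joint), abs=1e-12)

    def test_independent_triple_is_zero(self):
        px = np.array([0.3, 0.7])
        py = np.array([0.6, 0.4])
        pz = np.array([0.25, 0.75])
        joint = np.einsum("x,y,z->xyz", px, py, pz)
        assert pmi_from_joint(joint) == pytest.approx(0.0, abs=1e-9)

    def test_empty_conditioning_reduces_to_mutual_information(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=50)
            y = x + rng.normal(size=50)
            assert part_mutual_information(x, y, None, BINNED) == pytest.approx(
                mutual_information(x, y, BINNED), abs=1e-12
            )
            assert part_mutual_information(x, y, None, GAUSSIAN) == pytest.approx(
                mutual_information(x, y, GAUSSIAN), abs=1e-12
            )

    def test_invalid_joint_rejected(self):
        with pytest.raises(ParameterError):
            pmi_from_joint(np.ones((2, 2, 2)))  # does not sum to 1

    def test_sparse_support_warns(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        z = rng.normal(size=(3, 30))
        with pytest.warns(UserWarning, match="low-confidence"):
            part_mutual_information(x, y, z, PmiParams(estimator="binned", n_bins=5))


class TestNetwork:
    def test_huge_threshold_gives_empty_network(self):
        spec = CommunitySpec(n_taxa=8, n_samples=100, seed=0)
        df, _ = generate_community(spec)
        net = pca_pmi_network(df, PmiParams(threshold=50.0))
        assert net.number_of_edges() == 0

    def test_non_finite_values_rejected(self):
        df = pd.DataFrame(np.full((3, 10), np.nan))
        with pytest.raises(AbundanceError):
            pca_pmi_network(df)

    def test_proportional_pair_survives_all_orders(self):
        hits = 0
        for seed in range(5):
            spec = CommunitySpec(
                n_taxa=8, n_samples=300, direct_edges=((0, 1, 1.0),),
                noise_sigma=0.2, seed=seed,
            )
            df, _ = generate_community(spec)
            net = pca_pmi_network(df)
            hits += net.has_edge("T000", "T001")
        assert hits == 5

    def test_chain_shortcut_removed_with_separating_set_logged(self):
        spec = CommunitySpec(n_taxa=10, n_samples=500, chains=((0, 1, 2),), seed=1)
        df, _ = generate_community(spec)
        net = pca_pmi_network(df)
        assert not net.has_edge("T000", "T002")
        assert net.has_edge("T000", "T001") and net.has_edge("T001", "T002")
        sep = [r for r in net.graph["removals"] if {r[0], r[1]} == {"T000", "T002"}]
        assert sep and "T001" in sep[0][3]

    def test_binned_network_runs_and_prunes(self):
        spec = CommunitySpec(n_taxa=6, n_samples=400, chains=((0, 1, 2),), seed=2)
        df, _ = generate_community(spec)
        net = pca_pmi_network(df, PmiParams(estimator="binned", threshold=0.35, n_bins=4))
        assert net.graph["estimator"] == "binned"

    def test_weights_are_minimum_observed_statistic(self):
        spec = CommunitySpec(
            n_taxa=6, n_samples=400, direct_edges=((0, 1, 0.9), (1, 2, 0.9)), seed=3
        )
        df, _ = generate_community(spec)
        net = pca_pmi_network(df)
        for u, v, attrs in net.edges(data=True):
            assert attrs["weight"] > net.graph["pmi_threshold"]
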