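import numpy as np
import pandas as pd
import pytest

from hemibrain import metrics as met
from hemibrain.io_core import Partition

from conftest import random_symmetric


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately loop-based)
# ---------------------------------------------------------------------------


def oracle_within(z, labels, network, hemi_mask, double=False):
    n = len(labels)
    total = 0.0
    for i in range(n):
        if labels[i] != network or not hemi_mask[i]:
            continue
        for j in range(n):
            if j == i or not hemi_mask[j]:
                continue
            if labels[j] == network:
                total += z[i, j] if double else z[i, j] / 2.0
            else:
                total += z[i, j]
    return total


def oracle_homotopic(z, labels, network, hemi_mask):
    total = 0.0
    for i in range(len(labels)):
        if labels[i] != network or not hemi_mask[i]:
            continue
        for j in range(len(labels)):
            if labels[j] == network and not hemi_mask[j]:
                total += z[i, j]
    return total


def oracle_contra(z, labels, network, hemi_mask):
    total = 0.0
    for i in range(len(labels)):
        if labels[i] != network or not hemi_mask[i]:
            continue
        for j in range(len(labels)):
            if not hemi_mask[j]:
                total += z[i, j]
    return total


def oracle_participation(w, labels):
    n = len(labels)
    p = np.zeros(n)
    for i in range(n):
        k = sum(w[i, j] for j in range(n) if j != i)
        if k == 0:
            continue
        acc = 0.0
        for s in set(labels):
            kappa = sum(w[i, j] for j in range(n) if labels[j] == s and j != i)
            acc += (kappa / k) ** 2
        p[i] = 1.0 - acc
    return p


def full_case(rng, pairs=6, nets=3):
    half_labels = rng.integers(0, nets, size=pairs)
    while len(np.unique(half_labels)) < nets:
        half_labels = rng.integers(0, nets, size=pairs)
    labels = np.concatenate([half_labels, half_labels])
    z = random_symmetric(2 * pairs, rng, scale=0.4)
    return z, labels


class TestSumOracles:
    def test_within_sum_matches_bruteforce(self, rng):
        for _ in range(5):
            z, labels = full_case(rng)
            hemi_mask = np.arange(len(labels)) < len(labels) // 2
            for net in np.unique(labels):
                got = met.within_hemisphere_sum(z, labels, net, "L")
                assert got == pytest.approx(
                    oracle_within(z, labels, net, hemi_mask), abs=1e-12
                )
                got_d = met.within_hemisphere_sum(
                    z, labels, net, "L", double_count_within=True
                )
                assert got_d == pytest.approx(
                    oracle_within(z, labels, net, hemi_mask, double=True), abs=1e-12
                )

    def test_homotopic_and_contra_match_bruteforce(self, rng):
        for _ in range(5):
            z, labels = full_case(rng)
            half = len(labels) // 2
            for hemi, mask in (("L", np.arange(2 * half) < half), ("R", np.arange(2 * half) >= half)):
                for net in np.unique(labels):
                    assert met.homotopic_sum(z, labels, net, hemi) == pytest.approx(
                        oracle_homotopic(z, labels, net, mask), abs=1e-12
                    )
                    assert met.whole_contralateral_sum(
                        z, labels, net, hemi
                    ) == pytest.approx(oracle_contra(z, labels, net, mask), abs=1e-12)

    def test_hand_sum_two_node_network(self):
        # 3 nodes per hemisphere; network 0 = first two nodes of L, all z=0.5
        labels = np.array([0, 0, 1, 0, 0, 1])
        z = np.full((6, 6), 0.5)
        np.fill_diagonal(z, 0.0)
        got = met.within_hemisphere_sum(z, labels, 0, "L")
        assert got == pytest.approx(1.5)  # one inner pair + two outward links

    def test_isolated_network_zero(self):
        labels = np.array([0, 1, 0, 1])
        z = np.zeros((4, 4))
        assert met.within_hemisphere_sum(z, labels, 0, "L") == 0.0

    def test_linearity_in_z(self, rng):
        z, labels = full_case(rng)
        a = met.within_hemisphere_sum(z, labels, 0, "L")
        b = met.within_hemisphere_sum(2 * z, labels, 0, "L")
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_single_pair_homotopic(self):
        labels = np.array([0, 1, 0, 1])
        z = np.zeros((4, 4))
        z[0, 2] = z[2, 0] = 0.8
        assert met.homotopic_sum(z, labels, 0, "L") == pytest.approx(0.8)

    def test_mirror_symmetric_z_gives_equal_sums(self, rng):
        half_labels = np.array([0, 0, 1, 1, 2])
        labels = np.concatenate([half_labels, half_labels])
        b = random_symmetric(5, rng, scale=0.3)
        x = random_symmetric(5, rng, scale=0.2)  # symmetric cross block
        z = np.block([[b, x], [x, b]])
        for net in (0, 1, 2):
            assert met.homotopic_sum(z, labels, net, "L") == pytest.approx(
                met.homotopic_sum(z, labels, net, "R"), abs=1e-12
            )
            assert met.within_hemisphere_sum(z, labels, net, "L") == pytest.approx(
                met.within_hemisphere_sum(z, labels, net, "R"), abs=1e-12
            )

    def test_empty_network_in_hemisphere_raises(self):
        labels = np.array([0, 0, 0, 0])
        with pytest.raises(ValueError):
            met.within_hemisphere_sum(np.zeros((4, 4)), labels, 7, "L")

    def test_contra_equals_homotopic_for_single_network(self, rng):
        labels = np.zeros(8, dtype=int)
        z = random_symmetric(8, rng)
        assert met.whole_contralateral_sum(z, labels, 0, "L") == pytest.approx(
            met.homotopic_sum(z, labels, 0, "L")
        )


class TestSegregation:
    def test_fully_segregated(self):
        assert met.hemispheric_segregation(2.0, 0.0) == 1.0

    def test_equal_sums_give_zero(self):
        assert met.hemispheric_segregation(1.7, 1.7) == 0.0

    def test_arithmetic(self):
        assert met.hemispheric_segregation(2.0, 0.5) == pytest.approx(0.75)

    def test_zero_denominator_warns_nan(self):
        with pytest.warns(UserWarning):
            out = met.hemispheric_segregation(0.0, 0.5)
        assert np.isnan(out)

    def test_scale_invariance(self, rng):
        z, labels = full_case(rng)
        zll = met.within_hemisphere_sum(z, labels, 0, "L")
        zlr = met.homotopic_sum(z, labels, 0, "L")
        s1 = met.hemispheric_segregation(zll, zlr)
        s2 = met.hemispheric_segregation(3.7 * zll, 3.7 * zlr)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_lr_block_monotonicity(self, rng):
        """Shrinking the cross-hemisphere block raises segregation and
        lowers inter-hemispheric integration."""
        half_labels = np.array([0, 0, 1, 1])
        labels = np.concatenate([half_labels, half_labels])
        b = np.abs(random_symmetric(4, rng)) + 0.1
        np.fill_diagonal(b, 0)
        x = np.abs(random_symmetric(4, rng)) + 0.1
        z1 = np.block([[b, x], [x.T, b]])
        z2 = np.block([[b, 0.5 * x], [0.5 * x.T, b]])
        for net in (0, 1):
            zll = met.within_hemisphere_sum(z1, labels, net, "L")
            lr1 = met.homotopic_sum(z1, labels, net, "L")
            lr2 = met.homotopic_sum(z2, labels, net, "L")
            assert lr2 <= lr1
            assert met.hemispheric_segregation(zll, lr2) >= met.hemispheric_segregation(zll, lr1)


class TestParticipation:
    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(5):
            labels_half = rng.integers(0, 4, size=20)
            labels = np.concatenate([labels_half, labels_half])
            w = random_symmetric(40, rng, nonneg=True)
            for hemi, sl in (("L", slice(0, 20)), ("R", slice(20, 40))):
                got = met.participation_coefficients(w, labels, hemi)
                want = oracle_participation(w[sl, sl], labels[sl])
                np.testing.assert_allclose(got, want, atol=1e-12)

    def test_all_weight_in_own_community(self):
        labels = np.array([0, 0, 1, 0, 0, 1])
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 1.0  # both in community 0
        p = met.participation_coefficients(w, labels, "L")
        assert p[0] == 0.0

    def test_even_split_two_communities(self):
        labels = np.array([0, 0, 1, 0, 0, 1])
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        p = met.participation_coefficients(w, labels, "L")
        assert p[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("s", [2, 3, 5])
    def test_even_split_s_communities(self, s):
        half = s + 1
        labels_half = np.concatenate([[0], np.arange(s)])
        labels = np.concatenate([labels_half, labels_half])
        w = np.zeros((2 * half, 2 * half))
        for j in range(1, half):
            w[0, j] = w[j, 0] = 1.0
        p = met.participation_coefficients(w, labels, "L")
        assert p[0] == pytest.approx(1 - 1 / s)

    def test_isolated_node_zero(self):
        labels = np.array([0, 1, 0, 1])
        p = met.participation_coefficients(np.zeros((4, 4)), labels, "L")
        np.testing.assert_array_equal(p, 0.0)

    def test_negative_weights_rejected(self):
        labels = np.array([0, 1, 0, 1])
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = -0.1
        with pytest.raises(ValueError):
            met.participation_coefficients(w, labels, "L")


class TestIntraIntegration:
    def test_zero_participation(self):
        assert met.intra_hemispheric_integration(np.zeros(4), np.zeros(4, int), 0) == 0.0

    def test_mean(self):
        pc = np.array([0.2, 0.4, 0.9])
        labels = np.array([0, 0, 1])
        assert met.intra_hemispheric_integration(pc, labels, 0) == pytest.approx(0.3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            met.intra_hemispheric_integration(np.zeros(3), np.zeros(3, int), 9)

    def test_mirror_symmetry(self, rng):
        labels_half = np.array([0, 0, 1, 1])
        labels = np.concatenate([labels_half, labels_half])
        b = np.abs(random_symmetric(4, rng))
        w = np.block([[b, np.zeros((4, 4))], [np.zeros((4, 4)), b]])
        pl = met.participation_coefficients(w, labels, "L")
        pr = met.participation_coefficients(w, labels, "R")
        np.testing.assert_allclose(pl, pr, atol=1e-12)


class TestMetricsTable:
    def test_eleven_network_fixture_has_22_rows(self, rng):
        labels_half = np.repeat(np.arange(11), 2)
        labels = np.concatenate([labels_half, labels_half])
        z = random_symmetric(44, rng, scale=0.3)
        zt = np.where(z > 0.2, z, 0)
        tab = met.metrics_table(z, zt, Partition(labels, symmetric=True))
        assert len(tab) == 22
        assert set(tab["hemisphere"]) == {"L", "R"}

    def test_toy_matrix_matches_hand_enumeration(self, rng):
        z, labels = full_case(rng, pairs=4, nets=2)
        zt = np.where(z > 0.1, z, 0)
        tab = met.metrics_table(z, zt, Partition(labels, symmetric=True))
        hemi_mask = np.arange(8) < 4
        row = tab[(tab["network"] == "0") & (tab["hemisphere"] == "L")].iloc[0]
        assert row["sum_z_within"] == pytest.approx(
            oracle_within(z, labels, 0, hemi_mask), abs=1e-12
        )
        assert row["inter_integration"] == pytest.approx(
            oracle_homotopic(z, labels, 0, hemi_mask), abs=1e-12
        )
        pc = oracle_participation(zt[:4, :4], labels[:4])
        assert row["intra_integration"] == pytest.approx(
            pc[labels[:4] == 0].mean(), abs=1e-12
        )

    def test_node_permutation_invariance(self, rng):
        z, labels = full_case(rng, pairs=5, nets=2)
        zt = np.where(z > 0.1, z, 0)
        tab1 = met.metrics_table(z, zt, Partition(labels, symmetric=True))
        # permute pairs consistently in both hemispheres
        perm_half = rng.permutation(5)
        perm = np.concatenate([perm_half, perm_half + 5])
        z2 = z[np.ix_(perm, perm)]
        zt2 = zt[np.ix_(perm, perm)]
        tab2 = met.metrics_table(z2, zt2, Partition(labels[perm], symmetric=True))
        key = ["network", "hemisphere"]
        pd.testing.assert_frame_equal(
            tab1.sort_values(key).reset_index(drop=True),
            tab2.sort_values(key).reset_index(drop=True),
            atol=1e-12,
        )

    def test_network_names_used(self, rng):
        z, labels = full_case(rng, pairs=4, nets=2)
        p = Partition(labels, symmetric=True, network_names={0: "FPN", 1: "DMN"})
        tab = met.metrics_table(z, np.abs(z), p)
        assert set(tab["network"]) == {"FPN", "DMN"}
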