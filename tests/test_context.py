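"""Context statistics and mean-force potentials."""

import numpy as np
import pytest
from oracles import brute_force_counts, random_micro_corpus

from ss8pred.alphabets import AA_INDEX, SS8_INDEX, SS8_ORDER
from ss8pred.context import (
    ContextScaler,
    OffsetConfig,
    accumulate_counts,
    build_potentials,
    context_score_profile,
    load_tables,
    observed_probability,
    potential,
    reference_probability,
    save_tables,
)
from ss8pred.io import ChainRecord, ProfileMatrix
from conftest import one_hot_profile

SMALL_OFFSETS = OffsetConfig(
    doublet_offsets=(-2, -1, 1, 2), triplet_offset_pairs=((-1, 1), (1, 2))
)


# ------------------------------------------------------------- counting


class TestAccumulateCounts:
    def test_aa_hh_hand_counts(self, aa_hh_corpus):
        tables = accumulate_counts(aa_hh_corpus, SMALL_OFFSETS)
        A, H = AA_INDEX["A"], SS8_INDEX["H"]
        assert tables.n_singlet[A] == pytest.approx(2.0)
        assert tables.singlet_state[H, A] == pytest.approx(2.0)
        # only j=0 has j+1 in range
        assert tables.doublet_state[1][H, A, A] == pytest.approx(1.0)
        assert tables.n_doublet(1)[A, A] == pytest.approx(1.0)
        assert tables.doublet_state[-1][H, A, A] == pytest.approx(1.0)
        assert tables.total_weight == 2.0

    def test_uniform_profiles_symmetry(self):
        L = 30
        chain = ChainRecord("u", "A" * L, "H" * L)
        prof = ProfileMatrix("u", np.full((L, 20), 1 / 20))
        tables = accumulate_counts([(chain, prof)], SMALL_OFFSETS)
        np.testing.assert_allclose(tables.n_singlet, L / 20, atol=1e-12)

    def test_empty_corpus(self):
        tables = accumulate_counts([], SMALL_OFFSETS)
        assert tables.total_weight == 0.0
        assert not tables.singlet_state.any()
        assert not any(v.any() for v in tables.triplet_state.values())

    def test_length_mismatch_names_chain(self):
        chain = ChainRecord("bad", "AAA", "HHH")
        prof = ProfileMatrix("bad", np.full((2, 20), 1 / 20))
        with pytest.raises(ValueError, match="bad"):
            accumulate_counts([(chain, prof)], SMALL_OFFSETS)

    @pytest.mark.parametrize("one_hot", [True, False])
    def test_matches_brute_force_oracle(self, one_hot):
        rng = np.random.default_rng(7 if one_hot else 8)
        for _ in range(10):
            corpus = random_micro_corpus(rng, one_hot)
            tables = accumulate_counts(corpus, SMALL_OFFSETS)
            singlet, doublet, triplet, total = brute_force_counts(corpus, SMALL_OFFSETS)
            np.testing.assert_allclose(tables.singlet_state, singlet, atol=1e-10)
            for k in SMALL_OFFSETS.doublet_offsets:
                np.testing.assert_allclose(tables.doublet_state[k], doublet[k], atol=1e-10)
            for p in SMALL_OFFSETS.triplet_offset_pairs:
                np.testing.assert_allclose(tables.triplet_state[p], triplet[p], atol=1e-10)
            assert tables.total_weight == pytest.approx(total)

    def test_doublet_marginal_consistency(self):
        """Summing the doublet table over the neighbor axis reproduces the
        singlet table restricted to positions whose offset partner exists."""
        rng = np.random.default_rng(11)
        corpus = random_micro_corpus(rng, one_hot=True)
        offsets = OffsetConfig(doublet_offsets=(1,), triplet_offset_pairs=())
        tables = accumulate_counts(corpus, offsets)
        # restricted singlet: drop each chain's last position (and respect
        # the determined mask of both partners)
        restricted = [
            (
                ChainRecord(
                    c.chain_id,
                    c.sequence[:-1],
                    c.ss8[:-1],
                    c.determined_mask[:-1] & c.determined_mask[1:],
                ),
                ProfileMatrix(c.chain_id, p.freqs[:-1]),
            )
            for c, p in corpus
            if len(c) > 1
        ]
        expected = accumulate_counts(restricted, offsets).singlet_state
        np.testing.assert_allclose(
            tables.doublet_state[1].sum(axis=2), expected, atol=1e-10
        )

    def test_deterministic(self, small_bundle):
        corpus = [(c, small_bundle.profiles[c.chain_id]) for c in small_bundle.chains]
        t1 = accumulate_counts(corpus, SMALL_OFFSETS)
        t2 = accumulate_counts(corpus, SMALL_OFFSETS)
        assert np.array_equal(t1.singlet_state, t2.singlet_state)
        for k in SMALL_OFFSETS.doublet_offsets:
            assert np.array_equal(t1.doublet_state[k], t2.doublet_state[k])

    def test_state_marginal_equals_context_totals(self, small_bundle):
        corpus = [(c, small_bundle.profiles[c.chain_id]) for c in small_bundle.chains]
        tables = accumulate_counts(corpus, SMALL_OFFSETS)
        np.testing.assert_allclose(
            tables.singlet_state.sum(axis=0), tables.n_singlet, atol=1e-8
        )
        for p in SMALL_OFFSETS.triplet_offset_pairs:
            np.testing.assert_allclose(
                tables.triplet_state[p].sum(axis=0), tables.n_triplet(p), atol=1e-8
            )


# ------------------------------------------------------------- probabilities


class TestProbabilities:
    def test_unobserved_context_is_uniform(self):
        tables = accumulate_counts([], SMALL_OFFSETS)
        for s in SS8_ORDER:
            assert observed_probability(tables, s, ("singlet", "A")) == pytest.approx(1 / 8)
            assert observed_probability(
                tables, s, ("triplet", (1, 2), "A", "C", "D")
            ) == pytest.approx(1 / 8)

    def test_observed_alpha_limit(self, aa_hh_corpus):
        tables = accumulate_counts(aa_hh_corpus, SMALL_OFFSETS)
        p = observed_probability(tables, "H", ("singlet", "A"), alpha=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_states_sum_to_one(self, small_bundle):
        corpus = [(c, small_bundle.profiles[c.chain_id]) for c in small_bundle.chains]
        tables = accumulate_counts(corpus, SMALL_OFFSETS)
        for ctx in [("singlet", "G"), ("doublet", 2, "A", "W"), ("triplet", (1, 2), "C", "C", "C")]:
            tot_obs = sum(observed_probability(tables, s, ctx) for s in SS8_ORDER)
            tot_ref = sum(reference_probability(tables, s, ctx) for s in SS8_ORDER)
            assert tot_obs == pytest.approx(1.0, abs=1e-9)
            assert tot_ref == pytest.approx(1.0, abs=1e-9)

    def test_singlet_reference_residue_independent(self, small_bundle):
        corpus = [(c, small_bundle.profiles[c.chain_id]) for c in small_bundle.chains]
        tables = accumulate_counts(corpus, SMALL_OFFSETS)
        a = reference_probability(tables, "H", ("singlet", "A"))
        b = reference_probability(tables, "H", ("singlet", "W"))
        assert a == b

    def test_reference_is_state_frequency(self):
        # states H and E in ratio 3:1 over a 4-residue chain
        chain = ChainRecord("r", "ACDF", "HHHE")
        tables = accumulate_counts([(chain, one_hot_profile(chain))], SMALL_OFFSETS)
        p = reference_probability(tables, "H", ("singlet", "W"), alpha=1e-12)
        assert p == pytest.approx(0.75, abs=1e-9)


# ------------------------------------------------------------- potentials


class TestPotentials:
    def test_zero_when_obs_equals_ref(self):
        """Uniform profiles make every conditional equal its reference, so
        potentials vanish (alpha -> 0 to remove pseudocount scale effects)."""
        L = 40
        chain = ChainRecord("u", "A" * L, "HHEECCTT" * 5)
        prof = ProfileMatrix("u", np.full((L, 20), 1 / 20))
        tables = accumulate_counts([(chain, prof)], SMALL_OFFSETS)
        for ctx in [("singlet", "C"), ("doublet", 1, "A", "D"), ("triplet", (1, 2), "A", "C", "D")]:
            assert potential(tables, "H", ctx, alpha=1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_biased_fixture_is_favorable(self):
        # A residues always helix, C residues always strand: helix is
        # enriched on A relative to the corpus state frequency (50%)
        chains = [ChainRecord("a", "AAAA", "HHHH"), ChainRecord("c", "CCCC", "EEEE")]
        corpus = [(c, one_hot_profile(c)) for c in chains]
        tables = accumulate_counts(corpus, SMALL_OFFSETS)
        assert potential(tables, "H", ("singlet", "A"), alpha=0.01) < 0
        assert potential(tables, "H", ("singlet", "C"), alpha=0.01) > 0

    def test_independence_limit_shrinks_with_corpus(self):
        """With labels independent of sequence, mean |U| decreases in N."""
        from ss8pred.synthetic import GeneratorConfig, generate_corpus

        emission = np.full((8, 20), 1 / 20)
        means = []
        for n_chains in (4, 40):
            cfg = GeneratorConfig(
                n_chains=n_chains,
                length_range=(500, 500),
                emission=emission,
                pssm_noise=100.0,
                profile_query_blend=0.1,
                seed=13,
            )
            bundle = generate_corpus(cfg)
            corpus = [(c, bundle.profiles[c.chain_id]) for c in bundle.chains]
            offsets = OffsetConfig(doublet_offsets=(-1, 1), triplet_offset_pairs=())
            pots = build_potentials(accumulate_counts(corpus, offsets))
            entries = np.concatenate(
                [np.abs(pots.u_singlet[:, :20]).ravel()]
                + [np.abs(U[:, :20, :20]).ravel() for U in pots.u_doublet.values()]
            )
            means.append(entries.mean())
        assert means[1] < means[0]
        assert means[1] < 0.1

    def test_vectorized_tables_match_scalar_formulas(self, small_bundle):
        """Dual route: dense table build vs the scalar probability chain."""
        corpus = [(c, small_bundle.profiles[c.chain_id]) for c in small_bundle.chains]
        tables = accumulate_counts(corpus, SMALL_OFFSETS)
        pots = build_potentials(tables, pseudocount="uniform")
        rng = np.random.default_rng(5)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            c = SS8_ORDER[rng.integers(8)]
            a, b1, b2 = (aas[i] for i in rng.integers(0, 20, size=3))
            ci, ai, b1i, b2i = SS8_INDEX[c], AA_INDEX[a], AA_INDEX[b1], AA_INDEX[b2]
            assert pots.u_singlet[ci, ai] == pytest.approx(
                potential(tables, c, ("singlet", a)), abs=1e-10
            )
            assert pots.u_doublet[2][ci, ai, b1i] == pytest.approx(
                potential(tables, c, ("doublet", 2, a, b1)), abs=1e-10
            )
            assert pots.u_triplet[(1, 2)][ci, ai, b1i, b2i] == pytest.approx(
                potential(tables, c, ("triplet", (1, 2), a, b1, b2)), abs=1e-10
            )

    def test_finite_everywhere(self, small_bundle):
        corpus = [(c, small_bundle.profiles[c.chain_id]) for c in small_bundle.chains]
        pots = build_potentials(accumulate_counts(corpus, SMALL_OFFSETS))
        assert np.isfinite(pots.u_singlet).all()
        assert all(np.isfinite(U).all() for U in pots.u_doublet.values())
        assert all(np.isfinite(U).all() for U in pots.u_triplet.values())


# ------------------------------------------------------------- scoring


class TestContextScoreProfile:
    def _tables(self, small_bundle):
        corpus = [(c, small_bundle.profiles[c.chain_id]) for c in small_bundle.chains]
        return accumulate_counts(corpus, SMALL_OFFSETS)

    def test_single_residue_chain_is_singlet_column(self, small_bundle):
        pots = build_potentials(self._tables(small_bundle))
        chain = ChainRecord("one", "W")
        scores = context_score_profile(chain, pots)
        np.testing.assert_allclose(scores[0], pots.u_singlet[:, AA_INDEX["W"]])

    def test_terms_match_manual_sum(self, small_bundle):
        """Term-count audit on a 3-residue chain with offsets +/-1, (-1,1)."""
        offsets = OffsetConfig(doublet_offsets=(-1, 1), triplet_offset_pairs=((-1, 1),))
        corpus = [(c, small_bundle.profiles[c.chain_id]) for c in small_bundle.chains]
        pots = build_potentials(accumulate_counts(corpus, offsets))
        chain = ChainRecord("tri", "AWC")
        a = [AA_INDEX[x] for x in chain.sequence]
        scores = context_score_profile(chain, pots)
        # end residue 0: singlet + one doublet (k=+1)
        exp0 = pots.u_singlet[:, a[0]] + pots.u_doublet[1][:, a[0], a[1]]
        np.testing.assert_allclose(scores[0], exp0, atol=1e-12)
        # middle residue: singlet + two doublets + the triplet
        exp1 = (
            pots.u_singlet[:, a[1]]
            + pots.u_doublet[-1][:, a[1], a[0]]
            + pots.u_doublet[1][:, a[1], a[2]]
            + pots.u_triplet[(-1, 1)][:, a[1], a[0], a[2]]
        )
        np.testing.assert_allclose(scores[1], exp1, atol=1e-12)

    def test_unknown_residues_use_averaged_slot(self, small_bundle):
        pots = build_potentials(self._tables(small_bundle))
        chain = ChainRecord("xxx", "XXXXX")
        scores = context_score_profile(chain, pots)
        assert np.isfinite(scores).all()
        expected0 = (
            pots.u_singlet[:, 20]
            + pots.u_doublet[1][:, 20, 20]
            + pots.u_doublet[2][:, 20, 20]
            + pots.u_triplet[(1, 2)][:, 20, 20, 20]
        )
        np.testing.assert_allclose(scores[0], expected0, atol=1e-12)


class TestScalerAndPersistence:
    def test_scaler_bounds_and_center(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(size=(500, 8)) * 3 + 1
        scaler = ContextScaler().fit(rows)
        out = scaler.transform(rows)
        assert out.min() >= 0.0 and out.max() <= 1.0
        np.testing.assert_allclose(
            scaler.transform(scaler.mean[None, :]), 0.5, atol=1e-12
        )

    def test_tables_round_trip(self, small_bundle, tmp_path):
        corpus = [(c, small_bundle.profiles[c.chain_id]) for c in small_bundle.chains]
        tables = accumulate_counts(corpus, SMALL_OFFSETS)
        path = tmp_path / "tables.npz"
        save_tables(tables, path)
        back = load_tables(path)
        assert back.offsets == SMALL_OFFSETS
        assert np.array_equal(back.singlet_state, tables.singlet_state)
        for p in SMALL_OFFSETS.triplet_offset_pairs:
            assert np.array_equal(back.triplet_state[p], tables.triplet_state[p])
        assert back.total_weight == tables.total_weight

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"doublet_offsets": (0, 1)},
            {"doublet_offsets": (1, 1)},
            {"doublet_offsets": (1, 2), "triplet_offset_pairs": ((2, 1),)},
            {"doublet_offsets": (1, 2), "triplet_offset_pairs": ((1, 3),)},
        ],
    )
    def test_offset_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            OffsetConfig(**kwargs)
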