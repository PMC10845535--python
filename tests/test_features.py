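import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rumensemble as r
from rumensemble.features import (DIVERSITY_INDICES, core_taxon_mask,
                                  fisher_alpha)
import oracles


def test_collapse_to_phylum_matches_hand_sums(toy_counts):
    phylum = r.collapse_taxonomy(toy_counts, "phylum")
    expected = pd.DataFrame(
        [[5, 8, 14, 7],       # P1 = g1+g2+g3
         [13, 5, 3, 8]],      # P2 = g4+g5+g6
        index=pd.Index(["P1", "P2"], name="taxon"),
        columns=["s1", "s2", "s3", "s4"])
    pd.testing.assert_frame_equal(phylum.counts, expected,
                                  check_dtype=False)
    assert (phylum.counts.sum(axis=0) == toy_counts.counts.sum(axis=0)).all()


def test_collapse_preserves_totals_at_every_rank(toy_counts):
    totals = toy_counts.counts.sum(axis=0)
    for rank in ("phylum", "class", "order", "family", "genus"):
        collapsed = r.collapse_taxonomy(toy_counts, rank)
        assert (collapsed.counts.sum(axis=0) == totals).all()


def test_collapse_at_genus_is_identity(toy_counts):
    out = r.collapse_taxonomy(toy_counts, "genus")
    pd.testing.assert_frame_equal(out.counts, toy_counts.counts)


def test_collapse_unknown_rank(toy_counts):
    with pytest.raises(ValueError):
        r.collapse_taxonomy(toy_counts, "kingdom")


def test_relative_abundance_percent(toy_counts):
    ra = r.relative_abundance(toy_counts)
    np.testing.assert_allclose(ra.sum(axis=0), 100.0, atol=1e-9)
    single = pd.DataFrame({"s": [7]}, index=["t"])
    assert r.relative_abundance(single).iloc[0, 0] == 100.0
    simple = r.relative_abundance(pd.DataFrame({"s": [2, 3, 5]}))
    np.testing.assert_allclose(simple["s"], [20.0, 30.0, 50.0])


def test_clr_hand_example_and_closure():
    mat = pd.DataFrame({"s": [1, 2, 4, 8]})
    out = r.clr_transform(mat, pseudocount=0.0)["s"].to_numpy()
    np.testing.assert_allclose(out, [-1.0397, -0.3466, 0.3466, 1.0397],
                               atol=2e-4)
    equal = r.clr_transform(pd.DataFrame({"s": [1, 1, 1, 1]}), 0.0)
    np.testing.assert_allclose(equal["s"], 0.0, atol=1e-12)


@settings(max_examples=40, derandomize=True)
@given(st.lists(st.integers(1, 1000), min_size=2, max_size=20),
       st.floats(0.1, 100))
def test_clr_scale_invariance(counts, k):
    mat = pd.DataFrame({"s": counts}, dtype=float)
    a = r.clr_transform(mat, 0.0)
    b = r.clr_transform(mat * k, 0.0)
    assert np.max(np.abs(a.values - b.values)) < 1e-9
    assert abs(a["s"].sum()) < 1e-9


def test_clr_zero_counts_need_pseudocount():
    with pytest.raises(ValueError):
        r.clr_transform(pd.DataFrame({"s": [0, 1]}), 0.0)


def test_uniform_and_single_taxon_diversity_closed_forms():
    uniform = pd.DataFrame({"s": [5] * 8})
    div = r.alpha_diversity(uniform)
    assert div.loc["s", "diversity_shannon"] == pytest.approx(np.log(8))
    assert div.loc["s", "evenness_pielou"] == pytest.approx(1.0)
    assert div.loc["s", "diversity_gini_simpson"] == pytest.approx(0.875)
    assert div.loc["s", "dominance_dbp"] == pytest.approx(0.125)
    single = pd.DataFrame({"s": [42]})
    div1 = r.alpha_diversity(single)
    assert div1.loc["s", "diversity_shannon"] == 0.0
    assert div1.loc["s", "diversity_inverse_simpson"] == pytest.approx(1.0)
    assert div1.loc["s", "dominance_dbp"] == 1.0


def test_chao1_bias_corrected_fixture():
    # 10 observed, 4 singletons, 2 doubletons -> 10 + 4*3/(2*3) = 12
    x = pd.DataFrame({"s": [1, 1, 1, 1, 2, 2, 5, 7, 9, 11]})
    div = r.alpha_diversity(x)
    assert div.loc["s", "chao1"] == pytest.approx(12.0)


def test_twenty_two_indices_emitted(small_cohort):
    _, counts, _ = small_cohort
    div = r.alpha_diversity(counts)
    assert list(div.columns) == list(DIVERSITY_INDICES)
    assert len(div.columns) == 22
    assert div.notna().values.all()
    # dbp and relative dominance coincide under these definitions
    np.testing.assert_allclose(div["dominance_dbp"], div["dominance_relative"])


def test_every_index_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    mat = pd.DataFrame(rng.integers(0, 60, size=(30, 50)))
    mat.iloc[:, 0] = np.arange(1, 31)          # deterministic mixed sample
    div = r.alpha_diversity(mat)
    core = core_taxon_mask(mat)
    pairs = {
        "observed": lambda x: float((x > 0).sum()),
        "chao1": oracles.chao1_oracle,
        "diversity_inverse_simpson": oracles.inverse_simpson_oracle,
        "diversity_gini_simpson": oracles.gini_simpson_oracle,
        "diversity_shannon": oracles.shannon_oracle,
        "diversity_coverage": oracles.coverage_oracle,
        "evenness_camargo": oracles.camargo_oracle,
        "evenness_pielou": oracles.pielou_oracle,
        "evenness_simpson": oracles.simpson_evenness_oracle,
        "evenness_evar": oracles.evar_oracle,
        "evenness_bulla": oracles.bulla_oracle,
        "dominance_dbp": oracles.berger_parker_oracle,
        "dominance_dmn": oracles.dmn_oracle,
        "dominance_absolute": lambda x: float(x.max()),
        "dominance_relative": oracles.berger_parker_oracle,
        "dominance_simpson": lambda x: 1.0 / oracles.inverse_simpson_oracle(x),
        "dominance_gini": oracles.gini_oracle,
        "rarity_log_modulo_skewness": oracles.log_modulo_skewness_oracle,
        "rarity_low_abundance": oracles.low_abundance_oracle,
    }
    for j, sample in enumerate(mat.columns):
        x = mat.iloc[:, j].to_numpy(float)
        for name, oracle in pairs.items():
            assert div.loc[sample, name] == pytest.approx(oracle(x), abs=1e-8), name
        assert div.loc[sample, "dominance_core_abundance"] == pytest.approx(
            oracles.core_abundance_oracle(x, core), abs=1e-8)
        assert div.loc[sample, "rarity_rare_abundance"] == pytest.approx(
            1 - oracles.core_abundance_oracle(x, core), abs=1e-8)
        assert div.loc[sample, "diversity_fisher"] == pytest.approx(
            oracles.fisher_oracle(x), abs=1e-6)


def test_fisher_alpha_solves_its_defining_equation():
    x = np.array([5, 1, 1, 2, 9, 30, 1, 0, 0, 4])
    alpha = fisher_alpha(x)
    s, n = (x > 0).sum(), x.sum()
    assert alpha * np.log(1 + n / alpha) == pytest.approx(s, abs=1e-9)


def test_feature_matrix_counting_formula(toy_counts):
    # toy taxonomy: 2 phyla, 3 classes, 4 orders, 5 families, 6 genera
    fm = r.build_feature_matrix(toy_counts)
    assert fm.values.shape == (4, 3 * (2 + 3 + 4 + 5 + 6) + 22)
    no_div = r.build_feature_matrix(toy_counts, include_diversity=False)
    assert fm.values.shape[1] - no_div.values.shape[1] == 22
    assert list(fm.values.index) == list(toy_counts.counts.columns)
    assert not fm.values.isna().values.any()


def test_feature_matrix_invariants(small_cohort):
    _, counts, _ = small_cohort
    fm = r.build_feature_matrix(counts)
    relabund = [c for c, (rank, t, rep) in fm.provenance.items()
                if rep == "relabund"]
    block = fm.values[relabund].to_numpy()
    assert block.min() >= 0 and block.max() <= 100
    clr_genus = [c for c, (rank, t, rep) in fm.provenance.items()
                 if rep == "clr" and rank == "genus"]
    sums = fm.values[clr_genus].sum(axis=1)
    assert np.abs(sums).max() < 1e-9
    assert all(fm.provenance[c][0] == "diversity"
               for c in fm.feature_ids if c.startswith("diversity|"))
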