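import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import rumensemble as r
from rumensemble import daa
from rumensemble.daa import coefficient_mode
import oracles

SHAPE = {"phylum": 4, "class": 6, "order": 8, "family": 12, "genus": 80}
GROUPS = np.r_[["A"] * 30, ["B"] * 30]


def _null_counts(seed, n=60, genera=80):
    shape = dict(SHAPE, genus=genera)
    cfg = r.SimConfig(n_cows=n, taxonomy_shape=shape, seed=seed,
                      n_planted_taxa={"RFI": 0, "residual_MFE": 0,
                                      "residual_MPE": 0})
    return r.generate_counts(cfg, rng=np.random.default_rng(seed))


def _planted_counts(seed, effect=2.0, n=60, genera=80, taxon=5):
    shape = dict(SHAPE, genus=genera)
    cfg = r.SimConfig(n_cows=n, taxonomy_shape=shape, seed=seed)
    signal = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    table = r.generate_counts(cfg, cow_signal=signal, planted_taxa=[taxon],
                              effect_sizes=np.array([effect]),
                              rng=np.random.default_rng(seed))
    return table, table.taxon_ids[taxon]


def test_prevalence_filter_strict_threshold():
    counts = pd.DataFrame(0, index=[f"t{i}" for i in range(3)],
                          columns=[f"s{i}" for i in range(100)], dtype=np.int64)
    counts.iloc[0, :5] = 1     # 5% -> removed
    counts.iloc[1, :11] = 1    # 11% -> kept ("more than 10%")
    counts.iloc[2, :10] = 1    # exactly 10% -> removed
    lineages = pd.DataFrame({rank: list("xyz") for rank in
                             ("phylum", "class", "order", "family", "genus")},
                            index=counts.index)
    table = r.CountTable(counts, lineages)
    kept = daa.prevalence_filter(table, 0.10)
    assert kept.taxon_ids == ["t1"]
    assert daa.prevalence_filter(table, 0.0).taxon_ids == ["t0", "t1", "t2"]
    with pytest.raises(ValueError):
        daa.prevalence_filter(table, 0.99)


def test_bh_adjust_hand_cases():
    np.testing.assert_allclose(r.bh_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])
    np.testing.assert_allclose(r.bh_adjust([0.2]), [0.2])
    np.testing.assert_allclose(r.bh_adjust([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])
    with pytest.raises(ValueError):
        r.bh_adjust([0.5, 1.5])


def test_bh_adjust_matches_independent_oracles():
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = rng.random(rng.integers(1, 40))
        ours = r.bh_adjust(p)
        np.testing.assert_allclose(ours, oracles.bh_oracle(p), atol=0)
        np.testing.assert_allclose(
            ours, multipletests(p, method="fdr_bh")[1], atol=1e-12)


def test_group_design_validation():
    table = _null_counts(0)
    with pytest.raises(ValueError):
        daa.maaslin_like(table, np.r_[["A"] * 58, ["B"] * 2])
    with pytest.raises(ValueError):
        daa.maaslin_like(table, ["A"] * 60)


def test_aldex_fixed_seed_is_deterministic():
    table = _null_counts(1)
    a = daa.aldex_like(table, GROUPS, seed=5)
    b = daa.aldex_like(table, GROUPS, seed=5)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_aldex_identical_relabeling_yields_high_adjusted_p():
    """Both groups holding the very same samples cannot look different."""
    for seed in range(3):
        table = _null_counts(seed, n=30)
        doubled = pd.concat(
            [table.counts,
             table.counts.rename(columns=lambda s: s + "_copy")], axis=1)
        relabeled = r.CountTable(doubled, table.lineages)
        groups = np.r_[["A"] * 30, ["B"] * 30]
        res = daa.aldex_like(relabeled, groups, seed=seed)
        assert res.table["qvalue"].min() > 0.5


@pytest.mark.parametrize("method", ["aldex_like", "ancombc_like",
                                    "maaslin_like", "linda_like"])
def test_each_method_detects_a_planted_shift(method):
    table, planted = _planted_counts(3)
    fn = getattr(daa, method)
    kwargs = {"seed": 3} if method == "aldex_like" else {}
    res = fn(table, GROUPS, **kwargs)
    assert planted in res.significant_taxa
    assert res.table.loc[planted, "effect"] > 0   # more abundant in group B
    assert (res.table["qvalue"] >= res.table["pvalue"] - 1e-12).all()


def test_ancombc_absorbs_pure_depth_variation():
    """Per-sample depth multipliers with no group effect: no discoveries."""
    for seed in range(3):
        rng = np.random.default_rng(seed)
        n_taxa, n = 80, 60
        mu = rng.normal(0, 2, n_taxa)
        la = mu[:, None] + rng.normal(0, 1, (n_taxa, n))
        p = np.exp(la - la.max(axis=0))
        p /= p.sum(axis=0)
        depths = np.maximum(3000, rng.lognormal(np.log(15_000), 1.0, n))
        counts = rng.multinomial(depths.astype(int), p.T).T
        mat = pd.DataFrame(counts, index=[f"t{i}" for i in range(n_taxa)],
                           columns=[f"s{i}" for i in range(n)])
        lineages = pd.DataFrame(
            {k: "x" for k in ("phylum", "class", "order", "family")},
            index=mat.index)
        lineages["genus"] = mat.index
        res = daa.ancombc_like(r.CountTable(mat, lineages), GROUPS)
        assert not res.table["significant"].any()


def test_coefficient_mode_finds_the_bulk():
    rng = np.random.default_rng(0)
    coefs = np.r_[rng.normal(0.7, 0.05, 150), rng.normal(4.0, 0.1, 5)]
    assert coefficient_mode(coefs) == pytest.approx(0.7, abs=0.1)


def test_linda_mode_correction_recovers_global_shift():
    """A constant added to every coefficient is removed by the mode."""
    table = _null_counts(11, genera=120)
    res = daa.linda_like(table, GROUPS)
    # corrected coefficients are centered near zero under the null
    assert abs(np.median(res.table["effect"])) < 0.05


def test_linda_warns_with_few_taxa():
    table = _null_counts(2)
    few = r.CountTable(table.counts.iloc[:6], table.lineages.iloc[:6])
    with pytest.warns(UserWarning):
        daa.linda_like(few, GROUPS)


def test_maaslin_null_discovery_rate_is_controlled():
    rng = np.random.default_rng(13)
    table = _null_counts(13)
    rates = []
    for _ in range(20):
        perm = rng.permutation(GROUPS)
        res = daa.maaslin_like(table, perm)
        rates.append(res.table["significant"].mean())
    assert np.mean(rates) <= 0.05


def test_run_all_shares_one_filtered_universe():
    table = _null_counts(4)
    results = daa.run_all(table, GROUPS, seed=0)
    assert set(results) == set(daa.METHODS)
    universes = {m: tuple(res.table.index) for m, res in results.items()}
    assert len(set(universes.values())) == 1
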