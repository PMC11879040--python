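"""Descriptor pruning, PCA reduction, embedding, chemotype frequencies,
and stratified chemical selection."""

import itertools

import numpy as np
import pytest
from scipy import stats

from toxtoolbox import (
    ChemotypeMatrix,
    DescriptorMatrix,
    PruneConfig,
    chemotype_frequencies,
    embed_2d,
    prune_descriptors,
    reduce_pca,
    stratified_select,
)
from toxtoolbox.chemspace import diversity_fraction_nonmodal
from toxtoolbox.errors import DataError, InsufficientDataError, ParameterError


def _dm(values, names=None, items=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"d{j}" for j in range(values.shape[1])]
    items = items or [f"i{k}" for k in range(values.shape[0])]
    return DescriptorMatrix(items=items, descriptors=names, values=values)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def test_constant_column_removed_for_diversity():
    m = _dm(np.column_stack([np.arange(6.0), np.full(6, 3.0)]))
    pruned, log = prune_descriptors(m)
    assert pruned.descriptors == ["d0"]
    assert log == [{"descriptor": "d1", "reason": "diversity", "score": 0.0}]


def test_duplicated_column_removed_for_correlation():
    x = np.arange(8.0)
    m = _dm(np.column_stack([x, x]))
    pruned, log = prune_descriptors(m)
    assert pruned.descriptors == ["d0"]
    (entry,) = log
    assert entry["reason"] == "correlation"
    assert entry["retained_partner"] == "d0"
    assert entry["r2"] == pytest.approx(1.0)


def _oracle_prune(values, cfg):
    """Independent application of both rules: diversity filter, then greedy
    keep-first-seen correlation filter using a full r² matrix."""
    n_cols = values.shape[1]
    alive = []
    for j in range(n_cols):
        col = values[:, j]
        if diversity_fraction_nonmodal(col) >= cfg.diversity_min:
            alive.append(j)
    r2 = np.zeros((n_cols, n_cols))
    for a, b in itertools.combinations(range(n_cols), 2):
        sa, sb = values[:, a].std(), values[:, b].std()
        r = 0.0 if (sa == 0 or sb == 0) else np.corrcoef(values[:, a], values[:, b])[0, 1]
        r2[a, b] = r2[b, a] = r * r
    kept = []
    for j in alive:
        if all(r2[j, k] <= cfg.r2_max for k in kept):
            kept.append(j)
    return kept


def test_prune_matches_exhaustive_oracle_on_crafted_matrix():
    rng = np.random.default_rng(3)
    base = rng.standard_normal(6)
    values = np.column_stack([
        base,                       # kept
        2 * base + 1,               # r² = 1 with column 0 -> removed
        rng.standard_normal(6),     # independent -> kept
        np.full(6, 2.0),            # constant -> diversity removal
    ])
    cfg = PruneConfig()
    pruned, _ = prune_descriptors(_dm(values), cfg)
    expected = _oracle_prune(values, cfg)
    assert pruned.descriptors == [f"d{j}" for j in expected]


def test_prune_matches_oracle_on_random_matrices():
    rng = np.random.default_rng(17)
    for trial in range(10):
        values = rng.standard_normal((12, 6))
        # plant correlation and low-diversity structure
        values[:, 3] = values[:, 1] * rng.uniform(0.5, 2) + rng.normal(0, 0.01, 12)
        values[:, 5] = np.round(values[:, 5])  # few distinct levels
        cfg = PruneConfig(r2_max=0.8, diversity_min=0.3)
        pruned, _ = prune_descriptors(_dm(values), cfg)
        assert pruned.descriptors == [f"d{j}" for j in _oracle_prune(values, cfg)]


def test_prune_is_idempotent():
    rng = np.random.default_rng(23)
    values = rng.standard_normal((10, 5))
    values[:, 2] = values[:, 0] * 3 - 1
    values[:, 4] = 0.5
    pruned, _ = prune_descriptors(_dm(values))
    again, log = prune_descriptors(pruned)
    assert log == []
    assert again.descriptors == pruned.descriptors


def test_retained_pairs_satisfy_r2_ceiling():
    rng = np.random.default_rng(29)
    values = rng.standard_normal((20, 8))
    values[:, 4] = values[:, 2] + rng.normal(0, 0.1, 20)
    cfg = PruneConfig()
    pruned, _ = prune_descriptors(_dm(values), cfg)
    for a, b in itertools.combinations(range(len(pruned.descriptors)), 2):
        r = np.corrcoef(pruned.values[:, a], pruned.values[:, b])[0, 1]
        assert r * r <= cfg.r2_max + 1e-12


def test_prune_needs_two_items():
    with pytest.raises(InsufficientDataError):
        prune_descriptors(_dm([[1.0, 2.0]]))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_full_variance_target():
    rng = np.random.default_rng(31)
    m = _dm(rng.standard_normal((9, 4)))
    result = reduce_pca(m, variance_target=1.0)
    assert result.n_components == min(9 - 1, 4)
    assert result.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
    # non-increasing spectrum and centered scores
    assert np.all(np.diff(result.explained_variance_ratio) <= 1e-12)
    assert np.allclose(result.scores.mean(axis=0), 0.0, atol=1e-10)


def test_pca_perfectly_correlated_pair_needs_one_component():
    x = np.arange(10.0)
    m = _dm(np.column_stack([x, 2 * x + 5]))
    result = reduce_pca(m, variance_target=0.95)
    assert result.n_components == 1


def test_pca_rejects_zero_variance_column():
    m = _dm(np.column_stack([np.arange(5.0), np.full(5, 1.0)]))
    with pytest.raises(DataError):
        reduce_pca(m)


# ---------------------------------------------------------------------------
# t-SNE embedding
# ---------------------------------------------------------------------------

def test_embedding_shape_and_determinism():
    rng = np.random.default_rng(37)
    scores = rng.standard_normal((100, 5))
    a = embed_2d(scores, seed=7, perplexity=10)
    b = embed_2d(scores, seed=7, perplexity=10)
    assert a.shape == (100, 2)
    np.testing.assert_array_equal(a, b)


def test_embedding_preserves_separated_clusters():
    rng = np.random.default_rng(41)
    c1 = rng.normal(0.0, 0.1, size=(40, 4))
    c2 = rng.normal(8.0, 0.1, size=(40, 4))
    coords = embed_2d(np.vstack([c1, c2]), seed=3, perplexity=10)
    a, b = coords[:40], coords[40:]

    def mean_pairwise(x, y):
        return np.linalg.norm(x[:, None, :] - y[None, :, :], axis=-1).mean()

    within = (mean_pairwise(a, a) + mean_pairwise(b, b)) / 2
    between = mean_pairwise(a, b)
    assert within < between


def test_embedding_perplexity_guard():
    with pytest.raises(ParameterError):
        embed_2d(np.zeros((10, 3)), perplexity=30)


# ---------------------------------------------------------------------------
# chemotype frequencies
# ---------------------------------------------------------------------------

def test_chemotype_frequency_simple_cases():
    cm = ChemotypeMatrix(
        items=["a", "b", "c"],
        chemotypes=["benzene", "carbonyl"],
        values=[[1, 0], [1, 0], [1, 0]],
        set_label={"a": "test", "b": "test", "c": "ref"},
    )
    table, distinct = chemotype_frequencies(cm, top_k=2)
    benzene = table[table.chemotype == "benzene"].iloc[0]
    assert benzene["test"] == 100.0 and benzene["ref"] == 100.0
    carbonyl = table[table.chemotype == "carbonyl"].iloc[0]
    assert carbonyl["test"] == 0.0  # absent but still listed in union top-k
    assert distinct == {"ref": 1, "test": 1}


def test_chemotype_frequencies_match_bruteforce():
    rng = np.random.default_rng(43)
    values = (rng.random((30, 50)) < 0.3).astype(int)
    items = [f"i{k}" for k in range(30)]
    labels = {it: ("test" if k % 3 == 0 else "ref") for k, it in enumerate(items)}
    cm = ChemotypeMatrix(items=items, chemotypes=[f"ct{j:02d}" for j in range(50)],
                         values=values, set_label=labels)
    table, distinct = chemotype_frequencies(cm, top_k=50)
    for _, row in table.iterrows():
        j = int(row["chemotype"][2:])
        for s in ("test", "ref"):
            members = [k for k, it in enumerate(items) if labels[it] == s]
            expected = 100.0 * sum(values[k, j] for k in members) / len(members)
            assert row[s] == pytest.approx(expected)
    for s in ("test", "ref"):
        members = [k for k, it in enumerate(items) if labels[it] == s]
        assert distinct[s] == sum(values[members, :].sum(axis=0) > 0)


def test_chemotype_matrix_rejects_nonbinary():
    with pytest.raises(DataError):
        ChemotypeMatrix(items=["a"], chemotypes=["x"], values=[[2]],
                        set_label={"a": "test"})


# ---------------------------------------------------------------------------
# stratified selection
# ---------------------------------------------------------------------------

def _pool(sizes):
    pool = {}
    for cat, n in sizes.items():
        for i in range(n):
            pool[f"{cat}_{i}"] = cat
    return pool


def test_stratified_shortlist_of_196():
    """Five use categories capped at 40 each; a 36-member category
    contributes all of its members, giving 196 in total — for any seed."""
    sizes = {"Agricultural": 200, "Drug": 300, "Homecare": 150,
             "Food": 120, "Cosmetic": 36}
    for seed in (0, 1, 7, 123):
        shortlist = stratified_select(_pool(sizes), sorted(sizes), 40, seed)
        assert len(shortlist) == 196
        assert sum(1 for s in shortlist if s.startswith("Cosmetic")) == 36


def test_stratified_select_deterministic_and_exhaustive_category():
    pool = _pool({"A": 50, "B": 40})
    one = stratified_select(pool, ["A", "B"], 40, seed=9)
    two = stratified_select(pool, ["A", "B"], 40, seed=9)
    assert one == two
    assert {s for s in one if s.startswith("B")} == {f"B_{i}" for i in range(40)}


def test_stratified_select_missing_category():
    with pytest.raises(DataError):
        stratified_select({"x": "A"}, ["A", "B"], 5, seed=0)


def test_stratified_select_uniform_over_seeds():
    """Chi-square sanity: item selection frequencies over 1,000 draws of
    5-from-20 are consistent with uniformity."""
    pool = {f"item{i}": "A" for i in range(20)}
    counts = {item: 0 for item in pool}
    for seed in range(1000):
        for item in stratified_select(pool, ["A"], 5, seed):
            counts[item] += 1
    observed = np.array(list(counts.values()))
    expected = np.full(20, 1000 * 5 / 20)
    chi2 = ((observed - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, df=19)
    assert p > 1e-3
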