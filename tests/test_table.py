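import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apexdiff.table import (
    OtuTable,
    ParseError,
    TaxLevel,
    aggregate_taxa,
    parse_lineage,
    prevalence_filter,
    rarefy,
    read_otu_table,
    relative_abundance,
    write_otu_table,
)

# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_round_trip_identity(small_table, tmp_path):
    path = tmp_path / "t.tsv"
    write_otu_table(small_table, path)
    assert read_otu_table(path) == small_table


def test_round_trip_without_taxonomy(tmp_path):
    t = OtuTable(["a", "b"], [(), ()], ["S1", "S2"], np.array([[1, 2], [3, 4]]))
    path = tmp_path / "t.tsv"
    write_otu_table(t, path)
    # taxonomy column omitted entirely
    assert "taxonomy" not in path.read_text().splitlines()[0]
    assert read_otu_table(path) == t


def test_zero_feature_table_round_trip(tmp_path):
    t = OtuTable([], [], ["S1", "S2"], np.zeros((0, 2), dtype=int))
    path = tmp_path / "t.tsv"
    write_otu_table(t, path)
    back = read_otu_table(path)
    assert back.n_features == 0 and back.sample_ids == ["S1", "S2"]


def test_greengenes_prefixes_are_stripped(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text(
        "#OTU ID\tS1\tS2\ttaxonomy\n"
        "otu1\t3\t4\tk__Bacteria; p__Firmicutes\n"
    )
    t = read_otu_table(path)
    assert t.taxonomy[0] == ("Bacteria", "Firmicutes")
    assert t.taxonomy[0][TaxLevel.PHYLUM.rank_index] == "Firmicutes"


@pytest.mark.parametrize(
    "row", ["otu1\t-3\t1", "otu1\tx\t1", "otu1\t1.5\t1", "otu1\t1"]
)
def test_malformed_rows_raise_parse_error_with_line(tmp_path, row):
    path = tmp_path / "t.tsv"
    path.write_text("#OTU ID\tS1\tS2\n" + row + "\n")
    with pytest.raises(ParseError, match=r":2"):
        read_otu_table(path)


def test_duplicate_ids_rejected(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("#OTU ID\tS1\notu1\t1\notu1\t2\n")
    with pytest.raises(ParseError):
        read_otu_table(path)


@st.composite
def otu_tables(draw):
    nf = draw(st.integers(0, 6))
    ns = draw(st.integers(1, 4))
    counts = draw(
        st.lists(
            st.lists(st.integers(0, 50), min_size=ns, max_size=ns),
            min_size=nf, max_size=nf,
        )
    )
    depth = draw(st.integers(0, 4))
    names = ["Bacteria", "Firmicutes", "Bacilli", "Lactobacillales"]
    taxonomy = [tuple(names[:depth]) for _ in range(nf)]
    return OtuTable(
        [f"f{i}" for i in range(nf)],
        taxonomy,
        [f"S{j}" for j in range(ns)],
        np.array(counts, dtype=int).reshape(nf, ns),
    )


@settings(max_examples=40, derandomize=True)
@given(otu_tables())
def test_round_trip_property(tmp_path_factory, table):
    path = tmp_path_factory.mktemp("io") / "t.tsv"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-depth samples are legal here
        write_otu_table(table, path)
        assert read_otu_table(path) == table


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def test_aggregate_sums_same_genus(small_table):
    genus = aggregate_taxa(small_table, TaxLevel.GENUS)
    strep = [i for i, t in enumerate(genus.taxonomy) if t and t[-1] == "Streptococcus"]
    assert len(strep) == 1
    assert list(genus.counts[strep[0]]) == [7, 2, 1]  # f1 + f2 summed


def test_aggregate_pools_unassigned(small_table):
    genus = aggregate_taxa(small_table, TaxLevel.GENUS)
    assert "unassigned" in genus.feature_ids
    i = genus.feature_ids.index("unassigned")
    # f3 (family-truncated) and f4 (phylum-only) pool together; their common
    # lineage prefix stops at the kingdom
    assert list(genus.counts[i]) == [5, 8, 3]
    assert genus.taxonomy[i] == ("Bacteria",)


@pytest.mark.parametrize("level", list(TaxLevel))
def test_aggregate_conserves_depths(small_table, level):
    agg = aggregate_taxa(small_table, level)
    assert np.array_equal(agg.sample_depths(), small_table.sample_depths())


def test_homonymous_genera_not_merged():
    t = OtuTable(
        ["a", "b"],
        [("Bacteria", "P1", "c", "o", "f1", "Gen"),
         ("Bacteria", "P2", "c", "o", "f2", "Gen")],
        ["S1"],
        np.array([[1], [1]]),
    )
    assert aggregate_taxa(t, "genus").n_features == 2


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def test_rarefy_identity_at_full_depth():
    t = OtuTable(["a", "b"], [(), ()], ["S1"], np.array([[2], [3]]))
    out = rarefy(t, 5, seed=0)
    assert np.array_equal(out.counts, t.counts)


def test_rarefy_depths_exact(default_cohort):
    table, _, _ = default_cohort
    depth = int(table.sample_depths().min())
    out = rarefy(table, depth, seed=3)
    assert np.all(out.sample_depths() == depth)
    assert out.sample_ids == table.sample_ids


def test_rarefy_drops_shallow_samples_with_warning():
    t = OtuTable(["a"], [()], ["S1", "S2"], np.array([[10, 3]]))
    with pytest.warns(UserWarning, match="S2"):
        out = rarefy(t, 5, seed=0)
    assert out.sample_ids == ["S1"]


def test_rarefy_rejects_nonpositive_depth():
    t = OtuTable(["a"], [()], ["S1"], np.array([[10]]))
    with pytest.raises(ValueError):
        rarefy(t, 0, seed=0)


def test_rarefy_reproducible_and_seed_sensitive(default_cohort):
    table, _, _ = default_cohort
    sub = table.select_samples(table.sample_ids[:4])
    a = rarefy(sub, 5000, seed=11)
    b = rarefy(sub, 5000, seed=11)
    c = rarefy(sub, 5000, seed=12)
    assert np.array_equal(a.counts, b.counts)
    assert not np.array_equal(a.counts, c.counts)


def test_rarefy_matches_hypergeometric_distribution():
    """Counts [2, 3] subsampled to depth 3: the first feature's draw must
    follow the hypergeometric pmf (1/10, 6/10, 3/10 for k = 0, 1, 2)."""
    t = OtuTable(["a", "b"], [(), ()], ["S1"], np.array([[2], [3]]))
    n = 2000
    draws = np.array([rarefy(t, 3, seed=s).counts[0, 0] for s in range(n)])
    pmf = {0: 0.1, 1: 0.6, 2: 0.3}
    for k, p in pmf.items():
        freq = np.mean(draws == k)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(freq - p) < 4 * se


# ---------------------------------------------------------------------------
# Relative abundance & prevalence filter
# ---------------------------------------------------------------------------


def test_relative_abundance_fractions():
    t = OtuTable(["a", "b"], [(), ()], ["S1"], np.array([[1], [3]]))
    frac = relative_abundance(t)
    assert np.allclose(frac[:, 0], [0.25, 0.75])


def test_relative_abundance_columns_sum_to_one(default_cohort):
    table, _, _ = default_cohort
    frac = relative_abundance(table)
    assert np.allclose(frac.sum(axis=0), 1.0, atol=1e-12)


def test_relative_abundance_scale_invariance(small_table):
    scaled = OtuTable(
        small_table.feature_ids, small_table.taxonomy,
        small_table.sample_ids, small_table.counts * 10,
    )
    assert np.allclose(relative_abundance(small_table), relative_abundance(scaled))


def test_prevalence_threshold_arithmetic():
    # 50 samples at 10%: present in 4 -> removed, present in 5 -> retained
    counts = np.zeros((2, 50), dtype=int)
    counts[0, :4] = 1
    counts[1, :5] = 1
    t = OtuTable(["four", "five"], [(), ()], [f"S{i}" for i in range(50)], counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept = prevalence_filter(t, 0.10)
    assert kept.feature_ids == ["five"]


def test_prevalence_filter_epsilon_keeps_singletons(small_table):
    kept = prevalence_filter(small_table, 1e-9)
    assert kept.n_features == small_table.n_features


def test_prevalence_filter_idempotent(default_cohort):
    table, _, _ = default_cohort
    once = prevalence_filter(table, 0.10)
    twice = prevalence_filter(once, 0.10)
    assert once == twice
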