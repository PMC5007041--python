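"""Relatedness path counting, dyad classification, and the count summary."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cookin.pedigree import (
    GM_LEVELS,
    Pedigree,
    PedigreeError,
    classify_dyads,
    relatedness,
    summarize_counts,
    table1_summary,
)

from conftest import make_pedigree


# ---------------------------------------------------------------------------
# an independent oracle: additive relationship by the recursive tabular
# method on the pedigree truncated at the grandparents of the two focals
# ---------------------------------------------------------------------------


def truncated_links(ped: Pedigree, a: str, b: str, depth: int = 2) -> dict:
    """Parent links restricted to ancestors within `depth` of a or b."""
    keep = {}
    for focal in (a, b):
        frontier = {focal: 0}
        while frontier:
            nxt = {}
            for ind, d in frontier.items():
                if d >= depth:
                    continue
                dam, sire = ped.parents(ind)
                if dam or sire:
                    keep.setdefault(ind, (dam, sire))
                for par in (dam, sire):
                    if par:
                        nxt[par] = d + 1
            frontier = nxt
    return keep


def tabular_relationship(links: dict, a: str, b: str) -> float:
    """Additive relationship A(a, b) = 2 * kinship, by memoized recursion."""
    depth_memo: dict[str, int] = {}

    def gen(x: str) -> int:
        if x in depth_memo:
            return depth_memo[x]
        dam, sire = links.get(x, ("", ""))
        d = 0 if not (dam or sire) else 1 + max(gen(p) for p in (dam, sire) if p)
        depth_memo[x] = d
        return d

    memo: dict[tuple[str, str], float] = {}

    def kin(x: str, y: str) -> float:
        if not x or not y:
            return 0.0
        key = (min(x, y), max(x, y))
        if key in memo:
            return memo[key]
        if x == y:
            dam, sire = links.get(x, ("", ""))
            val = 0.5 * (1.0 + kin(dam, sire))
        else:
            # recurse on the individual further from the founders
            if gen(x) < gen(y):
                x, y = y, x
            dam, sire = links.get(x, ("", ""))
            val = 0.5 * (kin(dam, y) + kin(sire, y))
        memo[key] = val
        return val

    return 2.0 * kin(a, b)


def random_pedigree(rng: np.random.Generator, n_founders: int, n_per_gen: int,
                    n_gens: int, p_unknown: float = 0.15):
    """Layered random pedigree: parents come from the previous generation.

    (With cross-generation matings a node can be a parent of one focal and
    a grandparent of the other, and the tabular method on a jointly
    truncated pedigree would count chains the per-side grandparent rule
    excludes; layering keeps the two formulations equivalent.)
    """
    rows = [(f"P0_{i}", "", "") for i in range(n_founders)]
    prev = [r[0] for r in rows]
    for g in range(1, n_gens + 1):
        cur = []
        for i in range(n_per_gen):
            ind = f"P{g}_{i}"
            if rng.random() < p_unknown or len(prev) < 2:
                dam = sire = ""
            else:
                dam, sire = rng.choice(prev, size=2, replace=False)
            rows.append((ind, dam, sire))
            cur.append(ind)
        prev = cur
    return make_pedigree(rows), [r[0] for r in rows[-n_per_gen:]]


# ---------------------------------------------------------------------------
# exact hand cases
# ---------------------------------------------------------------------------

FULL_SIB_ROWS = [
    ("D", "", ""), ("S", "", ""),
    ("A", "D", "S"), ("B", "D", "S"),
]

SHARED_GP_ROWS = [
    ("G", "", ""), ("GA2", "", ""), ("GB2", "", ""),
    ("DA2", "", ""), ("DB2", "", ""),
    ("PA", "DA2", "G"), ("PB", "DB2", "G"),
    ("MA", "", ""), ("MB", "", ""),
    ("A", "MA", "PA"), ("B", "MB", "PB"),
]


@pytest.mark.parametrize(
    "rows, a, b, expected",
    [
        # full siblings: two paths of two steps
        (FULL_SIB_ROWS, "A", "B", 0.5),
        # maternal half siblings
        ([("D", "", ""), ("S1", "", ""), ("S2", "", ""),
          ("A", "D", "S1"), ("B", "D", "S2")], "A", "B", 0.25),
        # paternal half siblings
        ([("S", "", ""), ("D1", "", ""), ("D2", "", ""),
          ("A", "D1", "S"), ("B", "D2", "S")], "A", "B", 0.25),
        # exactly one shared grandparent
        (SHARED_GP_ROWS, "A", "B", 0.0625),
        # mother-daughter
        ([("D", "", ""), ("S", "", ""), ("A", "D", "S")], "A", "D", 0.5),
        # grandmother-granddaughter
        ([("G", "", ""), ("GS", "", ""), ("D", "G", "GS"), ("S", "", ""),
          ("A", "D", "S")], "A", "G", 0.25),
        # aunt (dam's full sister)
        ([("G", "", ""), ("GS", "", ""), ("D", "G", "GS"), ("B", "G", "GS"),
          ("S", "", ""), ("A", "D", "S")], "A", "B", 0.25),
    ],
)
def test_relatedness_exact_cases(rows, a, b, expected):
    ped = make_pedigree(rows)
    assert relatedness(ped, a, b) == pytest.approx(expected, abs=1e-12)
    assert relatedness(ped, b, a) == pytest.approx(expected, abs=1e-12)


def test_related_grandparent_increment():
    """Two otherwise-unlinked grandparents related at 0.5 add 0.5 * (1/2)^4."""
    rows = [
        ("GA", "", ""), ("GB", "", ""),
        ("DA2", "", ""), ("DB2", "", ""),
        ("PA", "DA2", "GA"), ("PB", "DB2", "GB"),
        ("MA", "", ""), ("MB", "", ""),
        ("A", "MA", "PA"), ("B", "MB", "PB"),
    ]
    ped = make_pedigree(rows)
    assert relatedness(ped, "A", "B") == 0.0
    r = relatedness(ped, "A", "B", founder_kinship={("GA", "GB"): 0.5})
    assert r == pytest.approx(0.03125, abs=1e-12)


def test_depth_truncation_ignores_great_grandparents():
    # shared great-grandparent only: invisible at depth 2
    rows = [
        ("GG", "", ""), ("X1", "", ""), ("X2", "", ""),
        ("GA", "GG", "X1"), ("GB", "GG", "X2"),
        ("DA", "", ""), ("DB", "", ""),
        ("PA", "DA", "GA"), ("PB", "DB", "GB"),
        ("MA", "", ""), ("MB", "", ""),
        ("A", "MA", "PA"), ("B", "MB", "PB"),
    ]
    ped = make_pedigree(rows)
    assert relatedness(ped, "A", "B", max_depth=2) == 0.0
    # one path of 3+3 steps through the great-grandparent
    assert relatedness(ped, "A", "B", max_depth=3) == pytest.approx(0.5**6, abs=1e-12)


def test_relatedness_errors():
    ped = make_pedigree(FULL_SIB_ROWS)
    with pytest.raises(PedigreeError):
        relatedness(ped, "A", "A")
    with pytest.raises(PedigreeError):
        make_pedigree([("A", "B", ""), ("B", "A", "")])  # cycle
    with pytest.raises(PedigreeError):
        make_pedigree([("A", "A", "")])  # own parent


def test_path_counting_matches_tabular_oracle():
    """Truncated path counting equals the tabular additive relationship."""
    rng = np.random.default_rng(2024)
    n_checked = 0
    for rep in range(100):
        ped, bottom = random_pedigree(
            rng, n_founders=int(rng.integers(4, 8)),
            n_per_gen=int(rng.integers(4, 8)), n_gens=int(rng.integers(2, 4)))
        for a, b in itertools.combinations(bottom, 2):
            links = truncated_links(ped, a, b)
            expected = tabular_relationship(links, a, b)
            got = relatedness(ped, a, b)
            assert got == pytest.approx(expected, abs=1e-12), (a, b)
            n_checked += 1
    assert n_checked > 500


# ---------------------------------------------------------------------------
# dyad classification
# ---------------------------------------------------------------------------


def meta_pedigree(rows, meta):
    df = pd.DataFrame(rows, columns=["id", "dam_id", "sire_id"])
    df["sex"] = "F"
    df["birth_year"] = [meta.get(i, (2000, "G0", "M0"))[0] for i in df["id"]]
    df["group"] = [meta.get(i, (2000, "G0", "M0"))[1] for i in df["id"]]
    df["matriline"] = [meta.get(i, (2000, "G0", "M0"))[2] for i in df["id"]]
    return Pedigree(df)


def test_classify_dyads_rules():
    # A, B share a dam; C has one unknown grandparent and shares nothing
    rows = [
        ("D", "GD1", "GS1"), ("S1", "GD2", "GS2"), ("S2", "GD3", "GS3"),
        ("GD1", "", ""), ("GS1", "", ""), ("GD2", "", ""), ("GS2", "", ""),
        ("GD3", "", ""), ("GS3", "", ""),
        ("DC", "GD4", ""), ("SC", "GD5", "GS5"),
        ("GD4", "", ""), ("GD5", "", ""), ("GS5", "", ""),
        ("A", "D", "S1"), ("B", "D", "S2"), ("C", "DC", "SC"),
    ]
    meta = {
        "A": (2001, "G0", "M0"), "B": (2004, "G0", "M0"), "C": (2010, "G1", "M1"),
    }
    ped = meta_pedigree(rows, meta)
    dy = classify_dyads(ped, ["A", "B", "C"]).set_index(["id_a", "id_b"])

    ab = dy.loc[("A", "B")]
    assert ab["kin_class"] == "kin"           # shared dam, 12 of 12 known
    assert ab["r"] == pytest.approx(0.25)
    assert ab["n_known_ancestors"] == 12
    assert ab["gm_level"] == "same_group_same_matriline"
    assert ab["age_diff"] == 3.0

    ac = dy.loc[("A", "C")]
    assert ac["kin_class"] == "excluded"      # unknown grandparent, r = 0 uncertifiable
    assert ac["n_known_ancestors"] == 11


def test_classify_dyads_other_level_excluded():
    rows = [("A", "", ""), ("B", "", "")]
    meta = {"A": (2000, "G0", "M0"), "B": (2000, "G1", "M0")}  # same matriline, diff group
    ped = meta_pedigree(rows, meta)
    dy = classify_dyads(ped, ["A", "B"])
    assert dy.iloc[0]["gm_level"] == "other"
    assert dy.iloc[0]["kin_class"] == "excluded"


def test_dyad_partition_and_symmetry(small_dataset):
    ped = small_dataset.pedigree
    ids = list(small_dataset.membership["id"])
    dy = classify_dyads(ped, ids)
    n = len(ids)
    assert len(dy) == n * (n - 1) // 2
    assert set(dy["kin_class"]) <= {"kin", "nonkin", "excluded"}
    assert (dy["id_a"] < dy["id_b"]).all()
    assert dy["gm_level"].isin(GM_LEVELS).all()
    # kin invariants
    kin = dy[dy["kin_class"] == "kin"]
    assert (kin["r"] >= 0.0625 - 1e-12).all()
    assert (kin["n_known_ancestors"] >= 10).all()
    nonkin = dy[dy["kin_class"] == "nonkin"]
    assert (nonkin["r"] == 0).all()
    assert (nonkin["n_known_ancestors"] == 12).all()
    # attainable r values under depth-2 truncation are multiples of 1/32
    assert np.allclose(np.mod(dy["r"] * 32, 1.0), 0.0)


def test_table1_summary_and_totals(small_dataset):
    dy = classify_dyads(small_dataset.pedigree, list(small_dataset.membership["id"]))
    tab = table1_summary(dy)
    counts = summarize_counts(tab)
    analysed = (dy["kin_class"] != "excluded").sum()
    assert counts["analysed"] == analysed
    assert counts["kin"] == (dy["kin_class"] == "kin").sum()
    assert counts["nonkin"] == (dy["kin_class"] == "nonkin").sum()


def test_table1_empty():
    empty = table1_summary(pd.DataFrame(columns=["kin_class", "r", "gm_level", "id_a"]))
    assert len(empty) == 0
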