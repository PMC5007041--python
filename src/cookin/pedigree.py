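"""Pedigree relatedness and dyad classification.

Relatedness between two individuals is computed by Wright's path counting,
deliberately truncated at the grandparental generation: every chain of
descent runs through a common ancestor that is at most two meiotic steps
above each member of the dyad.  Each path contributes ``(1/2) ** (steps_a +
steps_b)`` and no individual may appear twice within a path, so r-values are
*minimum* estimates — kinship through great-grandparents or beyond is
ignored by design.  Common ancestors are assumed non-inbred.

Dyads of focal females are then classified with the ancestor-knowledge
rules used in dyadic kinship studies of provisioned macaque colonies:

* ``kin``     — at least 10 of the 12 possible ancestors (2 pairs of parents
  plus 4 pairs of grandparents) identified, and at least one ancestor
  shared (hence r >= 0.0625);
* ``nonkin``  — all 12 ancestors identified and none shared (r = 0
  certified);
* ``excluded``— anything else (r = 0 cannot be certified, or the dyad falls
  in the unused same-matriline/different-group cell of the familiarity
  factor).

The familiarity covariates derived per dyad are the three-level
group-matrilineal membership factor and the absolute birth-year difference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "relatedness",
    "classify_dyads",
    "table1_summary",
    "summarize_counts",
    "GM_LEVELS",
]

#: Levels of the group-matrilineal membership familiarity factor.
#: "other" collects same-matriline/different-group dyads, which the
#: three-level design does not model; they are excluded from analysis.
GM_LEVELS = (
    "same_group_same_matriline",
    "same_group_diff_matriline",
    "diff_group_diff_matriline",
    "other",
)

UNKNOWN = ""


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, self-parenting, bad ids)."""


@dataclass
class Pedigree:
    """A table of parent links plus per-individual metadata.

    Parameters
    ----------
    table
        DataFrame with columns ``id``, ``dam_id``, ``sire_id`` and optionally
        ``sex``, ``birth_year``, ``group``, ``matriline``.  Unknown parents
        are empty strings or NaN.
    """

    table: pd.DataFrame
    _dam: dict = field(init=False, repr=False)
    _sire: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("dam_id", "sire_id"):
            if col not in t.columns:
                raise PedigreeError(f"pedigree table lacks column {col!r}")
            t[col] = t[col].fillna(UNKNOWN).astype(str)
        t["id"] = t["id"].astype(str)
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicate individual id {dup!r}")
        self.table = t
        self._dam = dict(zip(t["id"], t["dam_id"]))
        self._sire = dict(zip(t["id"], t["sire_id"]))
        for ind in t["id"]:
            if self._dam[ind] == ind or self._sire[ind] == ind:
                raise PedigreeError(f"{ind!r} is its own parent")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        color: dict[str, int] = {}

        def visit(node: str) -> None:
            color[node] = 1
            for par in (self._dam.get(node, UNKNOWN), self._sire.get(node, UNKNOWN)):
                if par == UNKNOWN or par not in self._dam:
                    continue
                c = color.get(par, 0)
                if c == 1:
                    raise PedigreeError(f"cycle through {par!r}")
                if c == 0:
                    visit(par)
            color[node] = 2

        for ind in self._dam:
            if color.get(ind, 0) == 0:
                visit(ind)

    # -- basic accessors ---------------------------------------------------

    def parents(self, ind: str) -> tuple[str, str]:
        return self._dam.get(ind, UNKNOWN), self._sire.get(ind, UNKNOWN)

    def ancestors(self, ind: str, max_depth: int = 2) -> dict[str, int]:
        """Known ancestors of ``ind`` with their minimal depth (1 = parent).

        Only depths ``1..max_depth`` are returned; ``ind`` itself is not
        included.
        """
        out: dict[str, int] = {}
        frontier = [ind]
        for depth in range(1, max_depth + 1):
            nxt: list[str] = []
            for node in frontier:
                for par in self.parents(node):
                    if par != UNKNOWN:
                        if par not in out:
                            out[par] = depth
                        nxt.append(par)
            frontier = nxt
        return out

    def ancestor_slots(self, ind: str) -> list[str]:
        """The six ancestor slots (dam, sire, 4 grandparents), '' if unknown.

        Slots are positional: a grandparent slot is unknown both when the
        grandparent link is missing and when the parent itself is unknown.
        """
        dam, sire = self.parents(ind)
        slots = [dam, sire]
        for par in (dam, sire):
            if par == UNKNOWN:
                slots += [UNKNOWN, UNKNOWN]
            else:
                slots += list(self.parents(par))
        return slots

    def meta(self, ind: str, col: str):
        row = self.table.loc[self.table["id"] == ind]
        if row.empty or col not in row.columns:
            raise PedigreeError(f"no metadata {col!r} for {ind!r}")
        return row.iloc[0][col]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _paths_up(ped: Pedigree, ind: str, max_depth: int) -> list[tuple[str, ...]]:
    """All ascending paths (ind, ..., ancestor) of 1..max_depth steps."""
    paths: list[tuple[str, ...]] = []
    stack: list[tuple[str, ...]] = [(ind,)]
    while stack:
        path = stack.pop()
        if len(path) - 1 >= max_depth:
            continue
        for par in ped.parents(path[-1]):
            if par != UNKNOWN and par not in path:
                new = path + (par,)
                paths.append(new)
                stack.append(new)
    return paths


def relatedness(
    ped: Pedigree,
    id_a: str,
    id_b: str,
    max_depth: int = 2,
    founder_kinship: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Coefficient of relatedness r(a, b) by truncated path counting.

    Sums ``(1/2) ** (steps_a + steps_b)`` over all pairs of ascending paths
    from ``id_a`` and ``id_b`` that meet in a common ancestor and share no
    other individual (standard Wright path counting with non-inbred
    ancestors).  A path of zero steps is allowed, so direct
    ancestor–descendant kinship within ``max_depth`` is covered.

    ``founder_kinship`` optionally declares relatedness between pairs of
    individuals that the truncated pedigree treats as unrelated (e.g. two
    grandparents known to be sibs from deeper records).  Each declared pair
    (c1, c2) with relatedness r0 adds ``r0 * (1/2) ** (steps_a + steps_b)``
    for every pair of non-overlapping paths from a up to c1 and from b up to
    c2.  This quantifies how much the truncation can understate kinship: two
    grandparents related at r = 0.5 raise the dyad's r by
    ``0.5 * (1/2)**4 = 0.03125``.
    """
    id_a, id_b = str(id_a), str(id_b)
    if id_a == id_b:
        raise PedigreeError("self-dyad: relatedness(a, a) is not defined here")

    paths_a = [(id_a,)] + _paths_up(ped, id_a, max_depth)
    paths_b = [(id_b,)] + _paths_up(ped, id_b, max_depth)

    r = 0.0
    for pa in paths_a:
        for pb in paths_b:
            if pa[-1] != pb[-1]:
                continue
            # the two path halves may share only the common ancestor
            if set(pa[:-1]) & set(pb):
                continue
            if set(pb[:-1]) & set(pa):
                continue
            r += 0.5 ** (len(pa) - 1 + len(pb) - 1)

    if founder_kinship:
        fk: dict[tuple[str, str], float] = {}
        for (c1, c2), r0 in founder_kinship.items():
            fk[(str(c1), str(c2))] = r0
            fk[(str(c2), str(c1))] = r0
        for pa in paths_a:
            for pb in paths_b:
                r0 = fk.get((pa[-1], pb[-1]))
                if r0 is None:
                    continue
                if set(pa) & set(pb):
                    continue
                r += r0 * 0.5 ** (len(pa) - 1 + len(pb) - 1)
    return r


def _gm_level(same_group: bool, same_matriline: bool) -> str:
    if same_group and same_matriline:
        return "same_group_same_matriline"
    if same_group:
        return "same_group_diff_matriline"
    if not same_matriline:
        return "diff_group_diff_matriline"
    return "other"  # same matriline, different group: outside the 3-level factor


def classify_dyads(
    ped: Pedigree,
    focal_ids: Iterable[str],
    max_depth: int = 2,
    min_known_kin: int = 10,
) -> pd.DataFrame:
    """Enumerate all unordered focal dyads and apply the kin/non-kin rules.

    Returns one row per dyad (``id_a < id_b`` lexicographically) with
    columns ``r``, ``n_known_ancestors``, ``n_shared_ancestors``,
    ``kin_class``, ``gm_level`` and ``age_diff``.
    """
    ids = sorted(str(i) for i in focal_ids)
    if len(ids) < 2:
        raise PedigreeError("need at least two focal individuals")
    meta = ped.table.set_index("id")
    for col in ("group", "matriline", "birth_year"):
        if col not in meta.columns:
            raise PedigreeError(f"focal metadata column {col!r} missing")

    rows = []
    for id_a, id_b in itertools.combinations(ids, 2):
        slots_a = ped.ancestor_slots(id_a)
        slots_b = ped.ancestor_slots(id_b)
        known_a = [s for s in slots_a if s != UNKNOWN]
        known_b = [s for s in slots_b if s != UNKNOWN]
        n_known = len(known_a) + len(known_b)
        # a member that is itself an ancestor of the other also counts as shared
        n_shared = (
            len(set(known_a) & set(known_b)) + int(id_a in known_b) + int(id_b in known_a)
        )

        r = relatedness(ped, id_a, id_b, max_depth=max_depth)

        ga, gb = meta.loc[id_a, "group"], meta.loc[id_b, "group"]
        ma, mb = meta.loc[id_a, "matriline"], meta.loc[id_b, "matriline"]
        gm = _gm_level(ga == gb, ma == mb)
        age_diff = abs(float(meta.loc[id_a, "birth_year"]) - float(meta.loc[id_b, "birth_year"]))

        if gm == "other":
            kin_class = "excluded"
        elif n_shared >= 1 and n_known >= min_known_kin:
            kin_class = "kin"
        elif n_shared == 0 and n_known == 12:
            kin_class = "nonkin"
        else:
            kin_class = "excluded"
        rows.append(
            dict(
                id_a=id_a,
                id_b=id_b,
                r=r,
                n_known_ancestors=n_known,
                n_shared_ancestors=n_shared,
                kin_class=kin_class,
                gm_level=gm,
                age_diff=age_diff,
            )
        )
    return pd.DataFrame(rows)


def table1_summary(dyads: pd.DataFrame) -> pd.DataFrame:
    """Contingency of discrete r values by group-matrilineal level.

    Only analysed dyads (kin or nonkin) are tabulated, one row per distinct
    r value, one column per gm level, plus a ``total`` column.
    """
    analysed = dyads[dyads["kin_class"].isin(["kin", "nonkin"])]
    levels = [lv for lv in GM_LEVELS if lv != "other"]
    if analysed.empty:
        return pd.DataFrame(columns=["r"] + levels + ["total"])
    tab = (
        analysed.assign(r=analysed["r"].round(6))
        .pivot_table(index="r", columns="gm_level", values="id_a", aggfunc="count", fill_value=0)
        .reindex(columns=levels, fill_value=0)
        .reset_index()
    )
    tab.columns.name = None
    tab["total"] = tab[levels].sum(axis=1)
    return tab


def summarize_counts(table: pd.DataFrame) -> dict[str, int]:
    """Totals from an r-by-gm-level count table (as built by table1_summary).

    Returns analysed / nonkin / kin dyad counts, where the nonkin count is
    the r = 0 row and kin are all non-zero-r cells.
    """
    levels = [c for c in table.columns if c in GM_LEVELS]
    cells = table[levels].to_numpy(dtype=float)
    r = table["r"].to_numpy(dtype=float)
    total = int(cells.sum())
    nonkin = int(cells[np.isclose(r, 0.0)].sum())
    return {"analysed": total, "nonkin": nonkin, "kin": total - nonkin}
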