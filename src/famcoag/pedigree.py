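"""Pedigree construction, relationship classification and exposure building.

A pedigree is a directed acyclic parent->child graph over individuals. Families
are the connected components of the undirected version of that graph; they are
the clustering unit for the robust variance estimation downstream. Relative
pairs are classified into first degree (parent, full sibling, child; coefficient
of relationship 0.5), second degree (half-sibling, grandparent, grandchild,
aunt/uncle, niece/nephew; 0.25), "other" (more remote or unresolvable) and
"unrelated" (different families). Classification is driven by the recursive
kinship coefficient phi, mapped through 2*phi, assuming no inbreeding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MALE, FEMALE, UNKNOWN_SEX = "male", "female", "unknown"
_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN_SEX}
_SEX_TO_CODE = {MALE: "1", FEMALE: "2", UNKNOWN_SEX: "0"}

FIRST, SECOND, OTHER, UNRELATED = "first", "second", "other", "unrelated"

#: coefficient of relationship a_R for the two degree classes used in analyses
RELATIONSHIP_COEFFICIENT = {FIRST: 0.5, SECOND: 0.25}


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree row. Parent ids of ``None`` mean unknown parent."""

    iid: str
    father_iid: str | None = None
    mother_iid: str | None = None
    sex: str = UNKNOWN_SEX

    def __post_init__(self):
        if not self.iid:
            raise PedigreeError("empty individual id")
        if self.sex not in (MALE, FEMALE, UNKNOWN_SEX):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.iid}")


@dataclass(frozen=True)
class RelativeDegree:
    """Degree class plus, for first/second degree, the coefficient a_R."""

    degree: str

    @property
    def a_R(self) -> float:
        try:
            return RELATIONSHIP_COEFFICIENT[self.degree]
        except KeyError:
            raise ValueError(f"a_R undefined for degree {self.degree!r}") from None


class Pedigree:
    """Validated pedigree with family labels and cached pair classifications.

    Build with :func:`build_pedigree` or :meth:`Pedigree.from_ped_file`.
    Individuals referenced as parents but absent from the input are
    materialized as placeholder founders: they shape relationships (e.g. two
    children naming the same absent father are half or full siblings) but can
    never carry phenotype data.
    """

    def __init__(self, records: Sequence[IndividualRecord]):
        seen: dict[str, IndividualRecord] = {}
        for rec in records:
            if rec.iid in seen:
                raise PedigreeError(f"duplicate individual id {rec.iid!r}")
            seen[rec.iid] = rec

        # materialize dangling parent references as placeholder founders
        placeholders = set()
        for rec in list(seen.values()):
            for parent in (rec.father_iid, rec.mother_iid):
                if parent is not None and parent not in seen:
                    placeholders.add(parent)
        for pid in sorted(placeholders):
            seen[pid] = IndividualRecord(iid=pid)
        if placeholders:
            logger.info("materialized %d placeholder founders", len(placeholders))

        self.iids: list[str] = list(seen.keys())
        self._index: dict[str, int] = {iid: k for k, iid in enumerate(self.iids)}
        self.placeholders: frozenset[str] = frozenset(placeholders)

        n = len(self.iids)
        self.father = np.full(n, -1, dtype=np.int64)
        self.mother = np.full(n, -1, dtype=np.int64)
        self.sex = np.array([seen[iid].sex for iid in self.iids], dtype=object)
        for k, iid in enumerate(self.iids):
            rec = seen[iid]
            if rec.father_iid is not None:
                self.father[k] = self._index[rec.father_iid]
            if rec.mother_iid is not None:
                self.mother[k] = self._index[rec.mother_iid]

        self._check_acyclic()
        self._depth = self._compute_depths()
        self.family_id = self._assign_families()
        self._pair_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._relmat_cache: dict | None = None

    # -- construction helpers ------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.iids)))
        for child in range(len(self.iids)):
            for par in (self.father[child], self.mother[child]):
                if par >= 0:
                    g.add_edge(par, child)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            self._digraph = g
            return
        names = [self.iids[u] for u, _ in cycle]
        raise PedigreeError(f"pedigree cycle (individual is its own ancestor): {' -> '.join(names)}")

    def _compute_depths(self) -> np.ndarray:
        depth = np.zeros(len(self.iids), dtype=np.int64)
        for node in nx.topological_sort(self._digraph):
            for par in (self.father[node], self.mother[node]):
                if par >= 0:
                    depth[node] = max(depth[node], depth[par] + 1)
        return depth

    def _assign_families(self) -> np.ndarray:
        fam = np.full(len(self.iids), -1, dtype=np.int64)
        for label, comp in enumerate(nx.connected_components(self._digraph.to_undirected(as_view=True))):
            for node in comp:
                fam[node] = label
        return fam

    # -- basic queries -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.iids)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def index_of(self, iid: str) -> int:
        try:
            return self._index[iid]
        except KeyError:
            raise PedigreeError(f"unknown individual id {iid!r}") from None

    @property
    def n_families(self) -> int:
        return int(self.family_id.max()) + 1 if len(self.iids) else 0

    def sex_series(self) -> pd.Series:
        return pd.Series(self.sex, index=self.iids, name="sex")

    def family_series(self) -> pd.Series:
        return pd.Series(self.family_id, index=self.iids, name="family_id")

    # -- kinship -------------------------------------------------------------

    def kinship(self, i: int, j: int) -> float:
        """Kinship coefficient phi between positional indices, no inbreeding."""
        return self._kinship_cached(i, j, {})

    def _kinship_cached(self, i: int, j: int, memo: dict) -> float:
        if i > j:
            i, j = j, i
        key = (i, j)
        val = memo.get(key)
        if val is not None:
            return val
        if i == j:
            val = 0.5
        elif self.family_id[i] != self.family_id[j]:
            val = 0.0
        else:
            # recurse through the parents of the deeper individual; a deeper
            # individual can never be an ancestor of a shallower one
            a, b = (i, j) if self._depth[i] >= self._depth[j] else (j, i)
            val = 0.0
            for par in (self.father[a], self.mother[a]):
                if par >= 0:
                    val += 0.5 * self._kinship_cached(par, b, memo)
        memo[key] = val
        return val

    def relationship_degree(self, i: str, j: str) -> RelativeDegree:
        """Classify the pair (i, j) into first/second/other/unrelated.

        Sibling-like pairs (sharing at least one recorded parent) where either
        member has an unrecorded parent are unresolvable between full and half
        siblings and are conservatively classified as "other".
        """
        a, b = self.index_of(i), self.index_of(j)
        if a == b:
            raise PedigreeError("relationship_degree requires two distinct individuals")
        return RelativeDegree(self._degree_idx(a, b, {}, warn=True))

    def _degree_idx(self, a: int, b: int, memo: dict, warn: bool = False) -> str:
        if self.family_id[a] != self.family_id[b]:
            return UNRELATED
        pa = {p for p in (self.father[a], self.mother[a]) if p >= 0}
        pb = {p for p in (self.father[b], self.mother[b]) if p >= 0}
        if pa & pb and b not in pa and a not in pb:
            # sibling-like pair: resolve by shared-parent count when complete
            if len(pa) == 2 and len(pb) == 2:
                return FIRST if len(pa & pb) == 2 else SECOND
            if warn:
                warnings.warn(
                    f"siblings {self.iids[a]!r}/{self.iids[b]!r} with an unrecorded "
                    "parent: full/half sibship unresolvable, classified as 'other'",
                    stacklevel=2,
                )
            return OTHER
        two_phi = 2.0 * self._kinship_cached(a, b, memo)
        if abs(two_phi - 0.5) < 1e-9:
            return FIRST
        if abs(two_phi - 0.25) < 1e-9:
            return SECOND
        return OTHER

    # -- bulk pair machinery -------------------------------------------------

    def degree_pair_indices(self, degree: str) -> tuple[np.ndarray, np.ndarray]:
        """All ordered within-family pairs (i, j) of the given degree.

        Returns positional index arrays; both orientations are included so a
        scatter over ``i`` visits every individual's relatives ``j``. Cached.
        """
        if degree not in (FIRST, SECOND):
            raise PedigreeError(f"pair enumeration supports first/second degree, not {degree!r}")
        cached = self._pair_cache.get(degree)
        if cached is not None:
            return cached
        self._enumerate_pairs()
        return self._pair_cache[degree]

    def _enumerate_pairs(self) -> None:
        fam_members: dict[int, list[int]] = {}
        for idx, fam in enumerate(self.family_id):
            fam_members.setdefault(int(fam), []).append(idx)
        firsts_i, firsts_j, seconds_i, seconds_j = [], [], [], []
        memo: dict = {}
        for members in fam_members.values():
            m = len(members)
            for u in range(m):
                for v in range(u + 1, m):
                    a, b = members[u], members[v]
                    deg = self._degree_idx(a, b, memo)
                    if deg == FIRST:
                        firsts_i += (a, b)
                        firsts_j += (b, a)
                    elif deg == SECOND:
                        seconds_i += (a, b)
                        seconds_j += (b, a)
        self._pair_cache[FIRST] = (
            np.asarray(firsts_i, dtype=np.int64),
            np.asarray(firsts_j, dtype=np.int64),
        )
        self._pair_cache[SECOND] = (
            np.asarray(seconds_i, dtype=np.int64),
            np.asarray(seconds_j, dtype=np.int64),
        )

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_ped_file(cls, path: str | Path) -> "Pedigree":
        """Read a whitespace/tab-delimited PED-like file.

        Columns: optional FID, then IID PAT MAT SEX; "0" or empty marks a
        missing parent; SEX is 1=male, 2=female, 0=unknown.
        """
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                if not fields or fields[0].startswith("#"):
                    continue
                if len(fields) == 5:
                    fields = fields[1:]
                if len(fields) != 4:
                    raise PedigreeError(f"{path}:{lineno}: expected 4 or 5 columns, got {len(fields)}")
                iid, pat, mat, sex = fields
                records.append(
                    IndividualRecord(
                        iid=iid,
                        father_iid=None if pat in ("0", "") else pat,
                        mother_iid=None if mat in ("0", "") else mat,
                        sex=_SEX_CODES.get(sex, UNKNOWN_SEX),
                    )
                )
        return cls(records)

    def to_ped_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, iid in enumerate(self.iids):
                pat = self.iids[self.father[k]] if self.father[k] >= 0 else "0"
                mat = self.iids[self.mother[k]] if self.mother[k] >= 0 else "0"
                fh.write(
                    f"F{self.family_id[k]}\t{iid}\t{pat}\t{mat}\t{_SEX_TO_CODE[self.sex[k]]}\n"
                )


def build_pedigree(records: Iterable[IndividualRecord]) -> Pedigree:
    """Validate records and return a :class:`Pedigree` with family labels."""
    records = list(records)
    if not records:
        raise PedigreeError("no pedigree records")
    return Pedigree(records)


# -- relative counting / exposure --------------------------------------------


def _aligned_status(ped: Pedigree, panel, phenotype: str) -> np.ndarray:
    """Lifetime status codes aligned to pedigree order; absent iids -> missing."""
    codes = panel.status_codes(phenotype)  # pd.Series of {1, 0, -1} by iid
    aligned = codes.reindex(ped.iids, fill_value=-1)
    return aligned.to_numpy(dtype=np.int8)


def count_relatives_with_data(ped: Pedigree, panel, degree: RelativeDegree, phenotype: str) -> pd.Series:
    """Per individual: relatives of exactly ``degree`` with non-missing status."""
    status = _aligned_status(ped, panel, phenotype)
    i_idx, j_idx = ped.degree_pair_indices(degree.degree)
    out = np.zeros(len(ped), dtype=np.int64)
    if len(i_idx):
        np.add.at(out, i_idx, (status[j_idx] >= 0).astype(np.int64))
    return pd.Series(out, index=ped.iids, name=f"n_{degree.degree}_{phenotype}")


def exposure_status(ped: Pedigree, panel, degree: RelativeDegree, phenotype: str) -> pd.Series:
    """1 iff at least one relative of ``degree`` is a lifetime case, else 0.

    Individuals without relatives in the dataset get 0: they stay in the
    general-population denominator.
    """
    status = _aligned_status(ped, panel, phenotype)
    i_idx, j_idx = ped.degree_pair_indices(degree.degree)
    acc = np.zeros(len(ped), dtype=np.int64)
    if len(i_idx):
        np.add.at(acc, i_idx, (status[j_idx] == 1).astype(np.int64))
    return pd.Series((acc > 0).astype(np.int8), index=ped.iids, name=f"exposed_{degree.degree}_{phenotype}")


def relationship_matrix(ped: Pedigree) -> dict[int, tuple[list[int], np.ndarray]]:
    """Per-family additive relationship matrices A (A_uv = 2*kinship).

    Returns {family_id: (member positional indices, A)}. Cached on the
    pedigree: repeated phenotype simulations on the same pedigree reuse it.
    """
    if ped._relmat_cache is not None:
        return ped._relmat_cache
    fam_members: dict[int, list[int]] = {}
    for idx, fam in enumerate(ped.family_id):
        fam_members.setdefault(int(fam), []).append(idx)
    out = {}
    memo: dict = {}
    for fam, members in fam_members.items():
        m = len(members)
        A = np.eye(m)
        for u in range(m):
            for v in range(u + 1, m):
                A[u, v] = A[v, u] = 2.0 * ped._kinship_cached(members[u], members[v], memo)
        out[fam] = (members, A)
    ped._relmat_cache = out
    return out
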