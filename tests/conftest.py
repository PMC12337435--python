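import numpy as np
import pandas as pd
import pytest

from famcoag.pedigree import IndividualRecord, build_pedigree


@pytest.fixture
def trio_records():
    return [
        IndividualRecord("F", sex="male"),
        IndividualRecord("M", sex="female"),
        IndividualRecord("C", father_iid="F", mother_iid="M", sex="female"),
    ]


@pytest.fixture
def three_gen_records():
    """Three generations: founder couple, two children, a married-in spouse,
    two grandchildren, and a half-sib branch via a second partner."""
    return [
        IndividualRecord("gf", sex="male"),
        IndividualRecord("gm", sex="female"),
        IndividualRecord("c0", "gf", "gm", sex="male"),
        IndividualRecord("c1", "gf", "gm", sex="female"),
        IndividualRecord("sp", sex="female"),
        IndividualRecord("g0", "c0", "sp", sex="male"),
        IndividualRecord("g1", "c0", "sp", sex="female"),
        IndividualRecord("gm2", sex="female"),
        IndividualRecord("h0", "gf", "gm2", sex="male"),
    ]


@pytest.fixture
def three_gen_ped(three_gen_records):
    return build_pedigree(three_gen_records)


def kinship_by_path_counting(ped, i, j):
    """Independent oracle: Wright's path counting on the parent DAG.

    The coefficient of relationship 2*phi between non-inbred i and j is the
    sum over all connecting paths i ... a ... j through a common ancestor a
    (the two legs sharing only a) of (1/2)^(number of edges).
    """
    import networkx as nx

    g = nx.DiGraph()
    for child in range(len(ped)):
        for par in (ped.father[child], ped.mother[child]):
            if par >= 0:
                g.add_edge(par, child)
    g.add_nodes_from(range(len(ped)))
    a_idx, b_idx = ped.index_of(i), ped.index_of(j)
    anc_a = nx.ancestors(g, a_idx) | {a_idx}
    anc_b = nx.ancestors(g, b_idx) | {b_idx}
    total = 0.0
    for anc in anc_a & anc_b:
        paths_a = (
            [[anc]] if anc == a_idx else list(nx.all_simple_paths(g, anc, a_idx))
        )
        paths_b = (
            [[anc]] if anc == b_idx else list(nx.all_simple_paths(g, anc, b_idx))
        )
        for pa in paths_a:
            for pb in paths_b:
                if set(pa) & set(pb) == {anc}:
                    total += 0.5 ** (len(pa) - 1 + len(pb) - 1)
    return total


@pytest.fixture
def wave_order():
    return ["1A", "2A", "3A"]


def make_records(rows):
    """rows: (iid, phenotype, wave, status(1/0/None), age)"""
    return pd.DataFrame(
        [
            {"iid": i, "phenotype": p, "wave": w, "status": s, "age": a}
            for i, p, w, s, a in rows
        ]
    )
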