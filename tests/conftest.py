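"""Shared fixtures: built once per session, reused across the suite."""

import numpy as np
import pytest

from crossbeta import (
    HEWL_PEPTIDE,
    build_monomer,
    enumerate_assembly_series,
    pair_sheets,
    stack_strands,
)


@pytest.fixture(scope="session")
def monomer_b():
    return build_monomer(HEWL_PEPTIDE, "B")


@pytest.fixture(scope="session")
def monomer_h():
    return build_monomer(HEWL_PEPTIDE, "H")


@pytest.fixture(scope="session")
def ba2_sheet(monomer_b):
    return stack_strands(monomer_b, 4, "antiparallel", "BA2")


@pytest.fixture(scope="session")
def ba2_series(monomer_b):
    return enumerate_assembly_series(monomer_b, 5, "antiparallel", "BA2")


@pytest.fixture(scope="session")
def core(ba2_sheet):
    cores = pair_sheets(ba2_sheet, ba2_sheet, n_poses=3, seed=11)
    assert cores, "pose search must yield at least one clash-free core"
    return cores[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
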