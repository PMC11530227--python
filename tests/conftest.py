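"""Shared fixtures: deterministic synthetic databases and query sets.

Everything is generated at test time by the package's own fixture module;
the expensive pieces (calibrated profile databases, the end-to-end default
fixture) are session-scoped so they are built once.
"""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from annopipe import fixtures, refdb


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The desk-scale planted fixture: (seq_db, profile_db, query_path, truth)."""
    root = tmp_path_factory.mktemp("default_fixture")
    return fixtures.make_default_fixture(root, seed=1)


@pytest.fixture(scope="session")
def sequence_db(default_fixture):
    seq_db, _, _, _ = default_fixture
    return refdb.build_sequence_db(
        seq_db.fasta_path, seq_db.metadata_path, "seqdb")


@pytest.fixture(scope="session")
def profile_db(default_fixture):
    _, prof_db, _, _ = default_fixture
    return refdb.load_profile_db(
        prof_db.msa_dir, prof_db.metadata_path, "profdb",
        refdb.CalibrationParams(seed=1))


@pytest.fixture(scope="session")
def compiled_dbs(tmp_path_factory, default_fixture):
    """Both fixture databases compiled once: (seq_db_dir, profile_db_dir, query_path)."""
    seq_fx, prof_fx, qpath, _truth = default_fixture
    root = tmp_path_factory.mktemp("compiled")
    sdb = refdb.compile_sequence_db(
        seq_fx.fasta_path, seq_fx.metadata_path, "sdb", root / "sdb")
    pdb = refdb.compile_profile_db(
        prof_fx.msa_dir, prof_fx.metadata_path, "pdb", root / "pdb",
        refdb.CalibrationParams(n_shuffles=100, shuffle_len=60, seed=1))
    return sdb, pdb, qpath


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
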