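import numpy as np
import pytest

from ervkit.simdata import SimParams, make_ancestor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ancestor():
    """One default genotype-1 ancestral provirus, shared across tests."""
    return make_ancestor(SimParams(seed=7))


@pytest.fixture(scope="session")
def ancestor2():
    """Genotype-2 profile ancestor (lys1,2 PBS, 144 CpG target)."""
    return make_ancestor(SimParams.genotype2(seed=11))


def write_fasta_text(path, entries):
    path.write_text("".join(f">{h}\n{s}\n" for h, s in entries))
    return path


@pytest.fixture
def fasta_writer(tmp_path):
    def _write(entries, name="test.fasta"):
        return write_fasta_text(tmp_path / name, entries)

    return _write
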