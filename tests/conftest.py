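import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from disprof.proteomes import Proteome, ProteinRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_random_record(rng: np.random.Generator, rid: str, length: int) -> ProteinRecord:
    seq = "".join(np.array(list(AA))[rng.integers(0, 20, size=length)])
    return ProteinRecord(id=rid, seq=seq)


def make_random_proteome(
    rng: np.random.Generator, n: int, lmin: int = 20, lmax: int = 120
) -> Proteome:
    recs = [
        make_random_record(rng, f"p{i}", int(rng.integers(lmin, lmax + 1)))
        for i in range(n)
    ]
    return Proteome(recs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_proteome(rng) -> Proteome:
    return make_random_proteome(rng, 12, lmin=30, lmax=80)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(records: dict, name: str = "input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
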