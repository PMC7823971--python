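import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracle` importable

from cytocomp import MaskedSequenceRecord

ALPHABET_FULL = "ACGTacgt" + "NnRYSWKMrywskm" + "ACGTacgt"  # biased to bases


def random_sequence(rng: random.Random, length: int, alphabet: str = ALPHABET_FULL) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260928)


@pytest.fixture
def small_record() -> MaskedSequenceRecord:
    return MaskedSequenceRecord(id="toy", description="toy chromosome", residues="ACGTacgt")


@pytest.fixture
def two_record_fasta(tmp_path: Path) -> Path:
    path = tmp_path / "two.fa"
    path.write_text(
        ">chrA first chromosome\n"
        "ACGTACGTacgtacgt\n"
        "GGGGcccc\n"
        ">chrB second chromosome\n"
        "NNNNacgtACGT\n"
    )
    return path
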