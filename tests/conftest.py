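import numpy as np
import pytest

from tcrisk import (
    Peptide,
    PSSMMatrix,
    ProteinRecord,
    parse_pattern,
)
from tcrisk.motif_engine import AMINO_ACIDS

ADRB3_PEPTIDE = "GLIMGTFTL"
FLU_PEPTIDE = "GILGFVFTL"
CHM1_LIKE_ORIGINAL = "QQQQQSWWV"  # consistent with the published CHM1 motif
ADRB3_MOTIF = "X-L-X-X-X-X-F-X-[LA]"
CHM1_MOTIF = "X-X-X-X-X-[ST]-W-W-[VT]"


@pytest.fixture
def adrb3():
    return Peptide(name="ADRB3_295", sequence=ADRB3_PEPTIDE)


@pytest.fixture
def adrb3_pattern():
    return parse_pattern(ADRB3_MOTIF)


@pytest.fixture
def chm1_pattern():
    return parse_pattern(CHM1_MOTIF)


@pytest.fixture
def zero_matrix():
    return PSSMMatrix(allele="ZERO", length=9, scores={})


@pytest.fixture
def self_matrix():
    """1 on each residue of GLIMGTFTL at its own position, 0 elsewhere."""
    scores = {
        (pos, res): 1 for pos, res in enumerate(ADRB3_PEPTIDE, start=1)
    }
    return PSSMMatrix(allele="SELF", length=9, scores=scores)


def random_pattern(rng: np.random.Generator, length: int):
    """Random dialect pattern (wildcards biased up so matches actually occur)."""
    from tcrisk.motif_engine import (
        MotifPattern, exclude, fixed, include, wildcard,
    )
    classes = []
    for _ in range(length):
        kind = rng.choice(["wildcard", "fixed", "include", "exclude"],
                          p=[0.55, 0.15, 0.15, 0.15])
        if kind == "wildcard":
            classes.append(wildcard())
        elif kind == "fixed":
            classes.append(fixed(AMINO_ACIDS[rng.integers(20)]))
        else:
            k = int(rng.integers(2, 5))
            residues = rng.choice(list(AMINO_ACIDS), size=k, replace=False)
            classes.append(include(residues) if kind == "include"
                           else exclude(residues))
    return MotifPattern(tuple(classes))


def random_database(rng: np.random.Generator, n_records: int, max_len: int,
                    nonstandard_rate: float = 0.0):
    alphabet = list(AMINO_ACIDS)
    odd = list("BJOUXZ*")
    records = []
    for i in range(n_records):
        length = int(rng.integers(1, max_len + 1))
        chars = [alphabet[rng.integers(20)] for _ in range(length)]
        if nonstandard_rate > 0:
            for j in range(length):
                if rng.random() < nonstandard_rate:
                    chars[j] = odd[rng.integers(len(odd))]
        records.append(ProteinRecord(identifier=f"r{i}", sequence="".join(chars)))
    return records
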