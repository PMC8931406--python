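import logging
import math

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hedratio import (
    DistanceParams,
    build_grantham_matrix,
    load_residue_properties,
)

logging.getLogger("hedratio").setLevel(logging.ERROR)
logging.getLogger("lifelines").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def props():
    return load_residue_properties()


@pytest.fixture(scope="session")
def params():
    return DistanceParams()


@pytest.fixture(scope="session")
def matrix():
    return build_grantham_matrix()


def naive_pairwise_hed(seq_a, seq_b, props, params):
    """Independent brute-force oracle: per-position formula evaluation."""
    assert len(seq_a) == len(seq_b)
    total, n = 0.0, 0
    for x, y in zip(seq_a, seq_b):
        if x in "-X" or y in "-X":
            continue
        px, py = props[x], props[y]
        d = params.scale * math.sqrt(
            params.alpha * (px.composition - py.composition) ** 2
            + params.beta * (px.polarity - py.polarity) ** 2
            + params.gamma * (px.volume - py.volume) ** 2
        )
        total += d
        n += 1
    return total / n


@pytest.fixture(scope="session")
def toy_store_fasta(tmp_path_factory):
    """Six-locus store with hand-sized alignments for scoring tests."""
    entries = {
        "A*01:01": "ACDEFGHIKL",
        "A*02:01": "ACDEFGHIKV",   # differs from A*01:01 at 1 position
        "A*02:05": "ACDEFGHIRV",
        "B*01:01": "MNPQRSTVWY",
        "B*02:01": "MNPQRSTVWC",
        "C*01:01": "AAAAAAAAAA",
        "C*02:01": "AAAAAAAAAC",
        "DRB1*01:01": "DEDEDEDEDE",
        "DRB1*02:01": "DEDEDEDEDD",
        "DQB1*01:01": "KLKLKLKLKL",
        "DQB1*02:01": "KLKLKLKLKK",
        "DPB1*01:01": "WYWYWYWYWY",
        "DPB1*02:01": "WYWYWYWYWW",
    }
    path = tmp_path_factory.mktemp("store") / "toy.fasta"
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n{seq}\n")
    return path
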