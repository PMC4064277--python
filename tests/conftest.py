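import random

import pytest
from hypothesis import settings

from runalign import make_preset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

PRESET_NAMES = ("sw", "swga", "sw_plus", "swga_plus")


@pytest.fixture(params=PRESET_NAMES)
def preset(request):
    return make_preset(request.param)


@pytest.fixture
def swga_plus():
    return make_preset("swga_plus")


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutated_copy(rng: random.Random, seq: str, sub=0.15, indel=0.05) -> str:
    """A diverged copy of ``seq`` (substitutions plus short indels)."""
    out = []
    for ch in seq:
        r = rng.random()
        if r < sub:
            out.append(rng.choice("ACGT"))
        elif r < sub + indel / 2:
            continue
        elif r < sub + indel:
            out.append(ch)
            out.append(rng.choice("ACGT"))
        else:
            out.append(ch)
    return "".join(out) or "A"
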