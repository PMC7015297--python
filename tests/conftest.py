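import pytest

from fxpode.fixedpoint import FixedFormat
from fxpode.prng import GeneratorState


def tiny_formats(max_w: int = 8):
    """Every format with word length <= max_w (the exhaustive-test surface)."""
    fmts = []
    for signed in (False, True):
        sign_bit = 1 if signed else 0
        for i in range(0, max_w + 1):
            for p in range(0, max_w + 1):
                w = i + p + sign_bit
                if 1 <= w <= max_w:
                    fmts.append(FixedFormat(signed, i, p))
    return fmts


@pytest.fixture
def kiss():
    return GeneratorState("KISS99", 12345)


@pytest.fixture(params=["KISS99", "LFSR33", "RANQD1"])
def any_rng(request):
    return GeneratorState(request.param, 2024)
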