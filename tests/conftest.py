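import numpy as np
import pytest

from crcbias import CaptureTable, EffectStudy, hbv_review_table


@pytest.fixture(scope="session")
def review_table() -> CaptureTable:
    """The reconstructed worked-example capture table (hepatitis-B review)."""
    return hbv_review_table()


@pytest.fixture(scope="session")
def independence_table() -> CaptureTable:
    """All 8 cells of a 2x2x2 equal 10; the 7 observed cells satisfy the
    independence model exactly, so the missing cell is also 10."""
    return CaptureTable(10, 10, 10, 10, 10, 10, 10)


@pytest.fixture()
def symmetric_studies() -> list[EffectStudy]:
    """15 studies exactly mirrored about 0 (one at the centre)."""
    rng = np.random.default_rng(42)
    ses = rng.uniform(0.2, 0.6, size=7)
    studies = [EffectStudy("centre", 0.0, 0.3)]
    for i, (d, se) in enumerate(zip(np.linspace(0.1, 1.2, 7), ses)):
        studies.append(EffectStudy(f"r{i}", float(d), float(se)))
        studies.append(EffectStudy(f"l{i}", float(-d), float(se)))
    return studies
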