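import numpy as np
import pytest

from psmkit.types import PlexDesign, PSMRecord


def make_psm(**overrides) -> PSMRecord:
    """A valid PSM with innocuous defaults; override any field."""
    fields = dict(
        spectrum_id="S000001",
        run_id="run0",
        plex_id="plex0",
        fraction_id="frac0",
        charge=2,
        precursor_mh=1500.0,
        mass_error_ppm=0.5,
        score=12.0,
        delta_rank_score=2.0,
        delta_fr_score=5.0,
        bcs=8.0,
        spi_pct=75.0,
        sequence="ACDEFGHIK",
        is_decoy=False,
        class_label="canonical",
        purity_pct=90.0,
        tmt_labeled=True,
        tag_length=4,
    )
    fields.update(overrides)
    return PSMRecord(**fields)


@pytest.fixture
def psm_factory():
    counter = [0]

    def factory(**overrides):
        counter[0] += 1
        overrides.setdefault("spectrum_id", f"S{counter[0]:06d}")
        return make_psm(**overrides)

    return factory


@pytest.fixture
def tmt10_design():
    channels = ("126", "127N", "127C", "128N", "128C",
                "129N", "129C", "130N", "130C", "131")
    return PlexDesign("plex0", channels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
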