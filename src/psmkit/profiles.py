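"""Built-in filter profiles for the four data types ('omes).

Each profile bundles the fixed record-level thresholds used by the
subset-FDR stage and the spectral/charge constraints of its acquisition
mode.  HLA profiles use the immunopeptidome spectral-quality settings
(precursor MH+ 600-4000, sequence tag length > 1); tryptic 'omes use the
global settings (MH+ 800-6000, tag length > 0).

``max_abs_ppm`` is strict (|ppm| < 5); every other bound is inclusive.
"""

from __future__ import annotations

import yaml

from .types import FilterProfile

HLA_I = FilterProfile(
    name="HLA-I",
    min_score=7.0,
    min_spi_pct=50.0,
    max_abs_ppm=5.0,
    min_bcs=5.0,
    length_range=(8, 12),
    charge_range=(1, 4),
    mh_range=(600.0, 4000.0),
    min_tag_length=2,
)

HLA_II = FilterProfile(
    name="HLA-II",
    min_score=7.0,
    min_spi_pct=50.0,
    max_abs_ppm=5.0,
    min_bcs=5.0,
    length_range=(9, 50),
    charge_range=(2, 6),
    mh_range=(600.0, 4000.0),
    min_tag_length=2,
)

PTM_OME = FilterProfile(
    name="PTM-ome",
    min_score=7.0,
    min_spi_pct=50.0,
    max_abs_ppm=5.0,
    min_bcs=4.0,
    length_range=(7, 50),
    charge_range=(2, 6),
    mh_range=(800.0, 6000.0),
    min_tag_length=1,
)

PROTEOME = FilterProfile(
    name="proteome",
    min_score=7.0,
    min_spi_pct=50.0,
    max_abs_ppm=5.0,
    min_bcs=0.0,
    length_range=(7, 50),
    charge_range=(2, 6),
    mh_range=(800.0, 6000.0),
    min_tag_length=1,
)

BUILTIN_PROFILES = {p.name: p for p in (HLA_I, HLA_II, PTM_OME, PROTEOME)}


def get_profile(name: str) -> FilterProfile:
    try:
        return BUILTIN_PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {sorted(BUILTIN_PROFILES)}"
        ) from None


def load_profiles(path) -> dict:
    """Load custom profiles from a YAML mapping name -> field dict."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    profiles = {}
    for name, fields in raw.items():
        fields = dict(fields)
        for key in ("length_range", "charge_range", "mh_range"):
            fields[key] = tuple(fields[key])
        profiles[name] = FilterProfile(name=name, **fields)
    return profiles
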