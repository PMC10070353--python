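"""Domain types for PSM-level proteomics data.

The atomic unit throughout the package is the :class:`PSMRecord` — one
peptide-spectrum match carrying identification scores, target/decoy
provenance, modification annotations and (optionally) TMT reporter-ion
intensities.  Higher-level containers (:class:`VMSiteRecord`,
:class:`ProteinSubgroup`, :class:`QuantMatrix`) are assembled from PSMs by
the site, grouping and quantitation modules.

Conventions
-----------
* Peptide and protein positions are 1-based inclusive.
* A modified (acetylated / ubiquitylated) lysine is rendered as lowercase
  ``"k"`` in sequence strings; all other residues are upper-case.
* ``class_label`` is ``canonical``, ``variant``, ``contaminant`` or
  ``nuORF:<category>`` (e.g. ``nuORF:lncRNA``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MOD_TYPES = ("phospho", "acetyl", "diGly", "other")

#: residues a modification of each type can sit on (used to expand the
#: candidate position set of an ambiguously localized observation)
MOD_ACCEPTOR_RESIDUES = {
    "phospho": "STY",
    "acetyl": "K",
    "diGly": "K",
    "other": None,  # no expansion: candidate set == stated positions
}

_BASE_CLASS_LABELS = {"canonical", "variant", "contaminant"}


def is_valid_class_label(label: str) -> bool:
    return label in _BASE_CLASS_LABELS or (
        label.startswith("nuORF:") and len(label) > len("nuORF:")
    )


@dataclass
class PSMRecord:
    """One peptide-spectrum match with all scores, flags and intensities."""

    spectrum_id: str
    run_id: str
    plex_id: str
    fraction_id: str
    charge: int
    precursor_mh: float
    mass_error_ppm: float
    score: float
    delta_rank_score: float
    delta_fr_score: float
    bcs: float
    spi_pct: float
    sequence: str
    modifications: list = field(default_factory=list)  # [(pos, mod_type)]
    localization: Optional[tuple] = None  # (top_score, second_score)
    is_decoy: bool = False
    class_label: str = "canonical"
    purity_pct: float = 100.0
    tmt_labeled: bool = True
    reporter_intensities: Optional[np.ndarray] = None
    candidate_proteins: list = field(default_factory=list)
    tag_length: Optional[int] = None  # sequence tag length; None = unknown
    extras: dict = field(default_factory=dict)  # opaque pass-through columns

    def validate(self, n_channels: Optional[int] = None) -> list:
        """Return a list of invariant-violation messages (empty if valid)."""
        errors = []
        if not (1 <= self.charge <= 6):
            errors.append(f"charge {self.charge} outside [1, 6]")
        if not (0.0 <= self.spi_pct <= 100.0):
            errors.append(f"spi_pct {self.spi_pct} outside [0, 100]")
        if not (0.0 <= self.purity_pct <= 100.0):
            errors.append(f"purity_pct {self.purity_pct} outside [0, 100]")
        if self.delta_rank_score < 0:
            errors.append(f"delta_rank_score {self.delta_rank_score} < 0")
        if self.bcs < 0:
            errors.append(f"bcs {self.bcs} < 0")
        if self.localization is not None:
            top, second = self.localization
            if second is not None and top < second:
                errors.append(
                    f"localization pair ({top}, {second}) not ordered"
                )
        if self.reporter_intensities is not None:
            if np.any(np.asarray(self.reporter_intensities) < 0):
                errors.append("negative reporter intensity")
            if n_channels is not None and len(self.reporter_intensities) != n_channels:
                errors.append(
                    f"reporter vector length {len(self.reporter_intensities)}"
                    f" != plex channel count {n_channels}"
                )
        for pos, mod_type in self.modifications:
            if not (1 <= pos <= len(self.sequence)):
                errors.append(
                    f"modification position {pos} outside peptide"
                    f" (length {len(self.sequence)})"
                )
            if mod_type not in MOD_TYPES:
                errors.append(f"unknown mod_type {mod_type!r}")
        if not is_valid_class_label(self.class_label):
            errors.append(f"invalid class_label {self.class_label!r}")
        return errors

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlexDesign:
    """A TMT plex: ordered reporter channels and their sample assignments."""

    plex_id: str
    channels: tuple
    sample_map: Optional[dict] = None
    reference_channel: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if (
            self.reference_channel is not None
            and self.reference_channel not in self.channels
        ):
            raise ValueError(
                f"reference_channel {self.reference_channel!r} not in channels"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class FilterProfile:
    """Fixed record-level thresholds for one 'ome.

    ``max_abs_ppm`` is a strict bound (|ppm| < max_abs_ppm); all other
    comparisons are inclusive.
    """

    name: str
    min_score: float
    min_spi_pct: float
    max_abs_ppm: float
    min_bcs: float
    length_range: tuple  # inclusive (min, max)
    charge_range: tuple  # inclusive (min, max)
    mh_range: tuple  # inclusive (min, max) Da
    min_tag_length: int

    def __post_init__(self):
        for name in ("length_range", "charge_range", "mh_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} minimum {lo} exceeds maximum {hi}")
            object.__setattr__(self, name, (lo, hi))


@dataclass
class ImpurityMatrix:
    """Channel x channel reporter-ion cross-contamination matrix.

    Entry ``(i, j)`` is the fraction of reagent *j*'s signal observed in
    channel *i*.  Columns may sum to < 1 when part of a reagent's isotopic
    envelope falls outside the plex (lost mass).
    """

    channels: tuple
    matrix: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.channels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != ({n}, {n})"
            )
        if np.any(self.matrix < 0):
            raise ValueError("impurity matrix entries must be >= 0")
        colsums = self.matrix.sum(axis=0)
        if np.any(colsums > 1 + 1e-9):
            raise ValueError("impurity matrix column sums exceed 1")
        diag = np.diag(self.matrix)
        if np.any(self.matrix > diag[np.newaxis, :] + 1e-12):
            raise ValueError(
                "diagonal must dominate every off-diagonal in its column"
            )
        if abs(np.linalg.det(self.matrix)) < 1e-300:
            raise ValueError("impurity matrix is singular")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class VMSiteRecord:
    """An aggregated variable-modification site on a protein.

    ``positions`` is the confident site set for localized rows, or the
    candidate position set for ambiguous-only rows.  ``n_mods`` is the
    number of modifications of this type on the member peptides (all
    members agree on it by construction).
    """

    protein: str
    positions: tuple  # sorted 1-based protein coordinates
    mod_type: str
    n_mods: int
    confident_localized: bool
    best_score: float
    representative: str  # spectrum_id
    member_ids: tuple  # spectrum_ids
    plexes: frozenset
    channel_ratios: Optional[dict] = None  # filled by tmt_quant

    @property
    def site_key(self):
        return (self.protein, self.mod_type, self.n_mods, self.positions,
                self.confident_localized)


@dataclass
class ProteinSubgroup:
    """A set of co-grouped protein accessions with allocated peptides.

    ``peptides`` maps each allocated distinct peptide sequence to its best
    PSM; the protein score is the sum of those best-PSM scores.
    """

    members: tuple  # sorted accessions
    peptides: dict  # sequence -> best PSMRecord
    score: float
    plexes: frozenset
    all_false: bool  # every allocated PSM has delta_fr_score < 0
    group_id: int = -1

    @property
    def n_distinct_peptides(self) -> int:
        return len(self.peptides)


@dataclass
class QuantMatrix:
    """Feature x channel matrix of log2 ratios with explicit missingness.

    ``values`` uses NaN for missing entries (never zero-filled);
    ``ratio_counts`` records the number of contributing PSM-level ratios
    per cell.  ``feature_meta`` carries per-feature annotations such as
    unique-peptide counts.
    """

    feature_ids: tuple
    channels: tuple
    values: np.ndarray
    ratio_counts: np.ndarray
    feature_meta: Optional[dict] = None

    def __post_init__(self):
        self.feature_ids = tuple(self.feature_ids)
        self.channels = tuple(self.channels)
        self.values = np.asarray(self.values, dtype=float)
        self.ratio_counts = np.asarray(self.ratio_counts, dtype=int)
        shape = (len(self.feature_ids), len(self.channels))
        if self.values.shape != shape or self.ratio_counts.shape != shape:
            raise ValueError(
                f"matrix shapes {self.values.shape}/{self.ratio_counts.shape}"
                f" do not match ({shape})"
            )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.channels)
        )

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            self.feature_ids,
            self.channels,
            self.values.copy(),
            self.ratio_counts.copy(),
            dict(self.feature_meta) if self.feature_meta else None,
        )
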