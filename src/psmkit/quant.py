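"""TMT reporter-ion quantitation.

Pipeline: reporter intensities are corrected for reagent isotopic
impurities by solving ``M x = observed`` with Cramer's rule (M built from
the manufacturer certificate-of-analysis -2/-1/+1/+2 percentages); PSMs
lacking a TMT label, with precursor isolation purity < 50% or with a
negative delta forward-reverse score are excluded; per-PSM log2 ratios
(against the per-PSM median channel or a reference channel) are
aggregated to protein subgroups / VM sites as medians; each channel is
then median/MAD normalized so the aggregate log-ratio distribution is
centered at zero with equal spread.

MAD here is the raw median absolute deviation (no 1.4826 Gaussian
consistency factor): only relative channel scaling matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import ImpurityMatrix, PlexDesign, QuantMatrix

MIN_PURITY_PCT = 50.0
CONDITION_NUMBER_CAP = 1e8

#: relative isotope offsets reported on a TMT certificate of analysis
COA_OFFSETS = (-2, -1, 1, 2)


def build_impurity_matrix(coa_rows, design: PlexDesign,
                          provenance: str = "") -> ImpurityMatrix:
    """Build the channel x channel impurity matrix from CoA percentages.

    ``coa_rows`` maps each channel label to its (-2, -1, +1, +2)
    impurity percentages.  Column *j* gets ``1 - sum(impurities)/100`` on
    the diagonal and the stated fractions at the neighboring rows in
    reagent-series order; spill beyond the plex is lost mass, so those
    columns sum to < 1.
    """
    n = design.n_channels
    matrix = np.zeros((n, n))
    for j, channel in enumerate(design.channels):
        percentages = coa_rows[channel]
        if len(percentages) != len(COA_OFFSETS):
            raise ValueError(
                f"channel {channel!r}: expected {len(COA_OFFSETS)}"
                f" impurity percentages, got {len(percentages)}"
            )
        if any(p < 0 or p > 100 for p in percentages):
            raise ValueError(f"channel {channel!r}: percentages outside [0, 100]")
        total = sum(percentages)
        if total >= 100:
            raise ValueError(
                f"channel {channel!r}: impurities sum to {total}% >= 100%"
            )
        matrix[j, j] = 1.0 - total / 100.0
        for offset, pct in zip(COA_OFFSETS, percentages):
            i = j + offset
            if 0 <= i < n:
                matrix[i, j] = pct / 100.0
    return ImpurityMatrix(design.channels, matrix, provenance)


def correct_reporters(observed, impurity: ImpurityMatrix):
    """Undo isotopic cross-contamination by Cramer's rule.

    Solves ``M x = observed`` as ratios of determinants.  Negative
    components (possible with noisy data) are clamped to zero and
    flagged.  Returns ``(corrected, clamped: bool)``.
    """
    observed = np.asarray(observed, dtype=float)
    m = impurity.matrix
    if observed.shape != (impurity.n_channels,):
        raise ValueError("observed vector length != channel count")
    if np.any(observed < 0):
        raise ValueError("observed intensities must be non-negative")
    if np.linalg.cond(m) > CONDITION_NUMBER_CAP:
        raise ValueError(
            f"impurity matrix condition number exceeds {CONDITION_NUMBER_CAP:g}"
        )
    det_m = np.linalg.det(m)
    x = np.empty_like(observed)
    for i in range(len(observed)):
        m_i = m.copy()
        m_i[:, i] = observed
        x[i] = np.linalg.det(m_i) / det_m
    clamped = bool(np.any(x < 0))
    return np.maximum(x, 0.0), clamped


def psm_quant_filter(psm) -> bool:
    """Usable for quantitation: TMT-labeled, purity >= 50%, delta FR >= 0."""
    return (
        psm.tmt_labeled
        and psm.purity_pct >= MIN_PURITY_PCT
        and psm.delta_fr_score >= 0
    )


def psm_log_ratios(corrected, policy: str = "per-psm-median",
                   reference_index: Optional[int] = None):
    """Per-PSM log2 ratios against the chosen denominator.

    ``per-psm-median``: denominator is the median of the PSM's positive
    channel intensities; ``reference-channel``: the intensity at
    ``reference_index``.  Channels with zero intensity yield NaN (missing,
    never -inf).  An all-zero vector returns all-NaN and ``flagged=True``.
    Returns ``(ratios, flagged)``.
    """
    corrected = np.asarray(corrected, dtype=float)
    positive = corrected > 0
    if not positive.any():
        return np.full(corrected.shape, np.nan), True
    if policy == "per-psm-median":
        denom = float(np.median(corrected[positive]))
    elif policy == "reference-channel":
        if reference_index is None:
            raise ValueError("reference-channel policy needs reference_index")
        denom = float(corrected[reference_index])
        if denom <= 0:
            return np.full(corrected.shape, np.nan), True
    else:
        raise ValueError(f"unknown ratio policy {policy!r}")
    ratios = np.full(corrected.shape, np.nan)
    ratios[positive] = np.log2(corrected[positive] / denom)
    return ratios, False


def aggregate_feature_ratios(ratios_by_feature, channels) -> QuantMatrix:
    """Median-aggregate PSM-level ratios per feature and channel.

    ``ratios_by_feature`` maps feature id -> list of per-PSM ratio
    vectors (NaN = missing).  Per cell: median over non-missing
    contributing ratios, with the contributing count recorded; features
    with no usable PSM ratios in a channel stay missing.
    """
    feature_ids = tuple(sorted(ratios_by_feature))
    n_ch = len(channels)
    values = np.full((len(feature_ids), n_ch), np.nan)
    counts = np.zeros((len(feature_ids), n_ch), dtype=int)
    for i, fid in enumerate(feature_ids):
        vectors = np.asarray(ratios_by_feature[fid], dtype=float)
        if vectors.size == 0:
            continue
        vectors = vectors.reshape(-1, n_ch)
        present = ~np.isnan(vectors)
        counts[i] = present.sum(axis=0)
        for c in range(n_ch):
            if counts[i, c]:
                values[i, c] = np.median(vectors[present[:, c], c])
    return QuantMatrix(feature_ids, tuple(channels), values, counts)


def quant_reporting_filter(matrix: QuantMatrix,
                           peptide_support: Optional[dict] = None,
                           min_unique_peptides: int = 2,
                           min_ratio_count: int = 2) -> QuantMatrix:
    """Reporting filter for protein-level matrices.

    A protein is reported only with at least ``min_unique_peptides``
    fully quantified unique peptides, each supported by at least
    ``min_ratio_count`` PSM-level ratios, and a protein-level ratio count
    of ``min_ratio_count`` or more in every quantified channel.

    ``peptide_support`` maps feature id -> {peptide sequence ->
    (fully_quantified: bool, ratio_count: int)}; when omitted it is
    taken from ``matrix.feature_meta["peptide_support"]``.
    """
    if peptide_support is None:
        peptide_support = (matrix.feature_meta or {}).get("peptide_support", {})
    keep = []
    for i, fid in enumerate(matrix.feature_ids):
        support = peptide_support.get(fid, {})
        n_good = sum(
            1
            for fully, count in support.values()
            if fully and count >= min_ratio_count
        )
        quantified = ~np.isnan(matrix.values[i])
        counts_ok = bool(quantified.any()) and bool(
            (matrix.ratio_counts[i][quantified] >= min_ratio_count).all()
        )
        if n_good >= min_unique_peptides and counts_ok:
            keep.append(i)
    meta = dict(matrix.feature_meta) if matrix.feature_meta else None
    return QuantMatrix(
        tuple(matrix.feature_ids[i] for i in keep),
        matrix.channels,
        matrix.values[keep] if keep else np.empty((0, len(matrix.channels))),
        matrix.ratio_counts[keep] if keep else np.empty(
            (0, len(matrix.channels)), dtype=int
        ),
        meta,
    )


def median_mad_normalize(matrix: QuantMatrix):
    """Center each channel at zero median and equalize channel MADs.

    Every channel is shifted by its median; channels are then scaled so
    each MAD equals the pre-normalization median of per-channel MADs
    (computed over channels with at least 3 non-missing values and
    non-zero MAD).  Missing entries are untouched.  Channels with fewer
    than 3 non-missing values, or zero MAD, are centered only and
    flagged.  Idempotent.  Returns ``(normalized, flagged_channels)``.
    """
    values = matrix.values.copy()
    n_ch = len(matrix.channels)
    medians = np.full(n_ch, np.nan)
    mads = np.full(n_ch, np.nan)
    for c in range(n_ch):
        col = values[:, c]
        present = ~np.isnan(col)
        if present.sum() == 0:
            continue
        medians[c] = np.median(col[present])
        mads[c] = np.median(np.abs(col[present] - medians[c]))
    scalable = np.array(
        [
            (~np.isnan(values[:, c])).sum() >= 3 and mads[c] > 0
            for c in range(n_ch)
        ]
    )
    flagged = [matrix.channels[c] for c in range(n_ch) if not scalable[c]]
    target_mad = (
        float(np.median(mads[scalable])) if scalable.any() else float("nan")
    )
    for c in range(n_ch):
        if np.isnan(medians[c]):
            continue
        values[:, c] -= medians[c]
        if scalable[c]:
            values[:, c] *= target_mad / mads[c]
    out = QuantMatrix(
        matrix.feature_ids, matrix.channels, values,
        matrix.ratio_counts.copy(),
        dict(matrix.feature_meta) if matrix.feature_meta else None,
    )
    return out, flagged


def saav_patient_consistency(row, carrier_mask, z_hi: float = 2.0) -> bool:
    """Variant-peptide consistency with the patient carrying the variant.

    Keep a single-amino-acid-variant feature iff its TMT ratio is
    extremely high (robust z >= ``z_hi`` against the row's own
    median/MAD) for every carrier channel and below ``z_hi`` for every
    non-carrier channel.  A carrier with a missing ratio fails the check;
    missing non-carriers are ignored.
    """
    row = np.asarray(row, dtype=float)
    carrier_mask = np.asarray(carrier_mask, dtype=bool)
    if row.shape != carrier_mask.shape:
        raise ValueError("row and carrier mask lengths differ")
    if not carrier_mask.any():
        raise ValueError("no carrier channels in design")
    present = ~np.isnan(row)
    if not present.any():
        return False
    med = np.median(row[present])
    mad = np.median(np.abs(row[present] - med))
    if mad == 0:
        return False
    z = (row - med) / mad
    carriers = carrier_mask & present
    if carriers.sum() < carrier_mask.sum():
        return False  # carrier with missing quantitation
    non_carriers = ~carrier_mask & present
    return bool(np.all(z[carriers] >= z_hi) and np.all(z[non_carriers] < z_hi))
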