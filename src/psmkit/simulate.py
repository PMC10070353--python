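"""Seeded generators for PSM tables, quant inputs and HLA peptide sets.

The generators emulate the statistical structure that target-decoy FDR
control assumes: correct matches drawn from a shifted (normal) score
distribution, incorrect matches and decoys drawn from one shared
right-skewed (Gumbel) distribution, quality metrics (BCS, SPI, mass
error, sequence tag length) correlated with correctness, and
non-canonical classes (nuORFs, variants) carrying lower correct-match
priors — the situation motivating subset-specific thresholds.  Reporter
intensities are known channel abundances passed through a known isotopic
impurity matrix with co-isolation contamination tied to precursor
purity.

Everything is deterministic under ``(config, seed)``, and the
:class:`SyntheticTruth` sidecar carries per-PSM correct/incorrect labels
and per-feature true abundance profiles so every headline property can
be recomputed without regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .quant import build_impurity_matrix
from .types import ImpurityMatrix, PlexDesign, PSMRecord

TMT10_CHANNELS = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131",
)

_AA = "ACDEFGHILMNPQRSTVWY"  # K handled separately for tryptic termini


def _default_class_probs():
    return {
        "canonical": 0.90,
        "nuORF:lncRNA": 0.04,
        "nuORF:uORF": 0.03,
        "variant": 0.02,
        "contaminant": 0.01,
    }


def _default_correct_priors():
    # P(correct | target) per class; nuORF classes are noisier
    return {
        "canonical": 0.92,
        "nuORF:lncRNA": 0.65,
        "nuORF:uORF": 0.60,
        "variant": 0.80,
        "contaminant": 0.85,
    }


def _default_charge_probs():
    return {2: 0.50, 3: 0.30, 4: 0.12, 5: 0.05, 6: 0.03}


def _default_coa_rows():
    # plausible certificate-of-analysis (-2, -1, +1, +2) percentages
    return {
        "126": (0.0, 0.0, 5.0, 0.1),
        "127N": (0.0, 0.2, 5.4, 0.1),
        "127C": (0.0, 0.3, 5.1, 0.1),
        "128N": (0.0, 0.4, 4.9, 0.1),
        "128C": (0.1, 0.5, 4.6, 0.1),
        "129N": (0.1, 0.7, 4.2, 0.1),
        "129C": (0.1, 1.0, 3.9, 0.1),
        "130N": (0.1, 1.2, 3.5, 0.0),
        "130C": (0.1, 1.4, 3.1, 0.0),
        "131": (0.1, 1.6, 2.8, 0.0),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic generators (defaults = study conditions)."""

    n_psms: int = 20_000
    runs: int = 4
    plexes: int = 2
    fractions: int = 3
    channels: tuple = TMT10_CHANNELS
    charge_probs: dict = field(default_factory=_default_charge_probs)
    class_probs: dict = field(default_factory=_default_class_probs)
    correct_priors: dict = field(default_factory=_default_correct_priors)
    #: "matched" splits incorrect matches 50/50 target/decoy so the decoy
    #: count mirrors the incorrect-target count; a float fixes P(decoy)
    decoy_fraction: object = "matched"
    # score families: shifted normal (correct) vs Gumbel (incorrect/decoy)
    correct_score_loc: float = 13.0
    correct_score_scale: float = 2.2
    incorrect_score_loc: float = 4.5
    incorrect_score_scale: float = 1.3
    score_decimals: int = 2  # scores reported at fixed precision
    length_range: tuple = (7, 30)
    tryptic_termini: bool = True
    mod_fraction: float = 0.0  # fraction of PSMs carrying one phospho
    ambiguity_rate: float = 0.3  # P(localization gap <= 1.1 | modified)
    # quant generator
    n_features: int = 500
    n_signal_features: int = 200
    psms_per_feature: int = 50
    log2_fc: float = 1.0
    noise_sigma: float = 0.3  # stdev of per-channel log2 intensity noise
    base_intensity: float = 1.0e6
    reference_channel: object = None  # channel label of a pooled reference
    coa_rows: dict = field(default_factory=_default_coa_rows)
    unlabeled_fraction: float = 0.02
    coisolation_fraction: float = 1.0  # scales (1 - purity) contamination
    purity_beta: tuple = (6.0, 1.5)  # purity/100 ~ Beta(a, b)
    # HLA peptide generator
    hla_length_probs: dict = field(
        default_factory=lambda: {8: 0.08, 9: 0.55, 10: 0.22, 11: 0.10, 12: 0.05}
    )
    hla_anchors: dict = field(
        default_factory=lambda: {2: ("L", 0.9), -1: ("V", 0.7)}
    )
    hla2_n_sets: int = 40
    hla2_core_length: int = 9
    hla2_set_size_range: tuple = (2, 6)
    hla2_length_range: tuple = (12, 20)

    def validate(self):
        for name, probs in (("class_probs", self.class_probs),
                            ("charge_probs", self.charge_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for label, prior in self.correct_priors.items():
            if not 0 <= prior <= 1:
                raise ValueError(f"correct prior for {label} outside [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_signal_features > self.n_features:
            raise ValueError("n_signal_features exceeds n_features")
        if isinstance(self.decoy_fraction, float) and not (
            0 <= self.decoy_fraction < 1
        ):
            raise ValueError("decoy_fraction outside [0, 1)")

    @classmethod
    def hla(cls, **overrides) -> "SyntheticConfig":
        """Immunopeptidome preset: charges 1-4, short unmodified peptides."""
        base = cls(
            charge_probs={1: 0.15, 2: 0.50, 3: 0.25, 4: 0.10},
            length_range=(8, 12),
            tryptic_termini=False,
            runs=1,
            fractions=3,
        )
        return replace(base, **overrides)


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside each synthetic dataset."""

    psm_correct: dict = field(default_factory=dict)  # spectrum_id -> bool
    feature_log2: dict = field(default_factory=dict)  # feature -> channel vec
    impurity: Optional[ImpurityMatrix] = None
    carrier_masks: dict = field(default_factory=dict)
    nested_sets: dict = field(default_factory=dict)  # set id -> peptides


def _random_peptide(rng, length: int, tryptic: bool) -> str:
    body = "".join(rng.choice(list(_AA), size=length - 1 if tryptic else length))
    if tryptic:
        return body + rng.choice(["K", "R"], p=[0.5, 0.5])
    return body


def _draw_scores(rng, n, correct_mask, cfg: SyntheticConfig):
    scores = np.where(
        correct_mask,
        rng.normal(cfg.correct_score_loc, cfg.correct_score_scale, n),
        rng.gumbel(cfg.incorrect_score_loc, cfg.incorrect_score_scale, n),
    )
    return np.round(np.clip(scores, 0, None), cfg.score_decimals)


def generate_psm_dataset(config: SyntheticConfig, seed: int):
    """Generate a PSM table with known correct/incorrect labels.

    Incorrect targets and decoys share one score distribution (the
    target-decoy assumption); correct matches come from a shifted
    distribution; BCS/SPI/mass error/tag length correlate with
    correctness.  Returns ``(records, SyntheticTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_psms

    labels = list(config.class_probs)
    class_label = rng.choice(
        labels, size=n, p=[config.class_probs[c] for c in labels]
    )
    priors = np.array(
        [config.correct_priors[c] for c in class_label]
    )
    if config.decoy_fraction == "matched":
        # q = P(correct): correct prior among targets p => q = p / (2 - p)
        q = priors / (2.0 - priors)
        correct = rng.random(n) < q
        is_decoy = ~correct & (rng.random(n) < 0.5)
    else:
        is_decoy = rng.random(n) < float(config.decoy_fraction)
        correct = ~is_decoy & (rng.random(n) < priors)
    correct &= ~is_decoy

    charges = rng.choice(
        list(config.charge_probs),
        size=n,
        p=list(config.charge_probs.values()),
    )
    scores = _draw_scores(rng, n, correct, config)
    delta_rank = np.where(
        correct,
        np.abs(rng.normal(2.5, 1.2, n)),
        rng.exponential(0.6, n),
    )
    delta_rank = np.round(delta_rank, config.score_decimals)
    delta_fr = np.where(correct, rng.normal(5.0, 2.0, n), rng.normal(0.0, 2.0, n))
    bcs = np.clip(
        np.where(correct, rng.normal(8, 2, n), rng.normal(3, 1.5, n)), 0, None
    )
    spi = np.clip(
        np.where(correct, rng.normal(75, 10, n), rng.normal(45, 12, n)), 0, 100
    )
    ppm = np.where(
        correct,
        np.clip(rng.normal(0, 1.5, n), -10, 10),
        rng.uniform(-10, 10, n),
    )
    purity = 100.0 * rng.beta(*config.purity_beta, size=n)
    tag = np.where(
        correct, 2 + rng.poisson(3.0, n), 1 + rng.poisson(0.8, n)
    ).astype(int)
    mh = np.clip(rng.normal(1800, 600, n), 820, 5800)

    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    run_ids = rng.integers(0, config.runs, size=n)
    plex_ids = rng.integers(0, config.plexes, size=n)
    fraction_ids = rng.integers(0, config.fractions, size=n)
    modified = rng.random(n) < config.mod_fraction
    ambiguous = rng.random(n) < config.ambiguity_rate

    records = []
    truth = SyntheticTruth()
    n_proteins = max(10, n // 20)
    for i in range(n):
        seq = _random_peptide(rng, int(lengths[i]), config.tryptic_termini)
        mods = []
        localization = None
        if modified[i]:
            sty = [j for j, aa in enumerate(seq) if aa in "STY"]
            if sty:
                pos = int(rng.choice(sty)) + 1
                mods = [(pos, "phospho")]
                gap = (
                    float(rng.uniform(0.0, 1.1))
                    if ambiguous[i]
                    else 1.1 + float(rng.exponential(1.5))
                )
                localization = (float(scores[i]), float(scores[i]) - gap)
        sid = f"S{i:06d}"
        records.append(
            PSMRecord(
                spectrum_id=sid,
                run_id=f"run{run_ids[i]}",
                plex_id=f"plex{plex_ids[i]}",
                fraction_id=f"frac{fraction_ids[i]}",
                charge=int(charges[i]),
                precursor_mh=float(np.round(mh[i], 4)),
                mass_error_ppm=float(np.round(ppm[i], 3)),
                score=float(scores[i]),
                delta_rank_score=float(delta_rank[i]),
                delta_fr_score=float(np.round(delta_fr[i], 3)),
                bcs=float(np.round(bcs[i], 2)),
                spi_pct=float(np.round(spi[i], 2)),
                sequence=seq,
                modifications=mods,
                localization=localization,
                is_decoy=bool(is_decoy[i]),
                class_label=str(class_label[i]),
                purity_pct=float(np.round(purity[i], 2)),
                tmt_labeled=True,
                candidate_proteins=[f"PROT{int(rng.integers(n_proteins)):05d}"],
                tag_length=int(tag[i]),
            )
        )
        truth.psm_correct[sid] = bool(correct[i])
    return records, truth


def quant_channel_groups(config: SyntheticConfig):
    """Channel index groups of the quant design.

    Returns ``(group_a, group_b, reference_index)``: signal features are
    shifted on ``group_a`` (the first half of the non-reference
    channels); ``group_b`` is the remaining non-reference channels;
    ``reference_index`` is None without a pooled reference channel.
    """
    channels = list(config.channels)
    ref = (
        channels.index(config.reference_channel)
        if config.reference_channel is not None
        else None
    )
    non_ref = [i for i in range(len(channels)) if i != ref]
    half = len(non_ref) // 2
    return non_ref[:half], non_ref[half:], ref


def generate_quant_dataset(config: SyntheticConfig, seed: int):
    """Generate reporter-level PSMs with known channel abundance profiles.

    ``n_signal_features`` features carry a true log2 fold change of
    ``log2_fc`` (sign randomized per feature) between two channel groups
    (see :func:`quant_channel_groups`); the remainder are null, anchoring
    the median/MAD normalization.  A pooled reference channel, when
    configured, stays at the baseline abundance.  Reporters are
    impurity-matrix-mixed true intensities with multiplicative lognormal
    noise and co-isolation contamination proportional to (1 - purity).

    Returns ``(records, design, SyntheticTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    design = PlexDesign(
        "plex0", config.channels, reference_channel=config.reference_channel
    )
    n_ch = len(config.channels)
    impurity = build_impurity_matrix(
        config.coa_rows, design, provenance="synthetic CoA"
    )

    group_a, group_b, _ = quant_channel_groups(config)
    truth = SyntheticTruth(impurity=impurity)
    profiles = {}
    for f in range(config.n_features):
        fid = f"FEAT{f:05d}"
        mu = np.zeros(n_ch)
        if f < config.n_signal_features:
            # symmetric +/- fc/2 profile: every sample channel carries the
            # same signal spread, so channel-wise median/MAD normalization
            # stays valid; a pooled reference channel sits at baseline
            sign = 1.0 if rng.random() < 0.5 else -1.0
            mu[group_a] = sign * config.log2_fc / 2
            mu[group_b] = -sign * config.log2_fc / 2
        profiles[fid] = mu
        truth.feature_log2[fid] = mu
    background = config.base_intensity * np.ones(n_ch)

    records = []
    i = 0
    for fid, mu in profiles.items():
        x_true = config.base_intensity * np.power(2.0, mu)
        for _ in range(config.psms_per_feature):
            noise = np.power(2.0, rng.normal(0.0, config.noise_sigma, n_ch))
            intensity = x_true * noise
            purity = 100.0 * rng.beta(*config.purity_beta)
            contam = config.coisolation_fraction * (1.0 - purity / 100.0)
            mixed = impurity.matrix @ (
                (1.0 - contam) * intensity + contam * background
            )
            unlabeled = rng.random() < config.unlabeled_fraction
            delta_fr = float(rng.normal(5.0, 2.0)) if rng.random() > 0.05 else -1.0
            records.append(
                PSMRecord(
                    spectrum_id=f"Q{i:06d}",
                    run_id="run0",
                    plex_id="plex0",
                    fraction_id="frac0",
                    charge=2,
                    precursor_mh=1500.0,
                    mass_error_ppm=0.0,
                    score=float(np.round(rng.normal(13, 2), 2)),
                    delta_rank_score=2.0,
                    delta_fr_score=delta_fr,
                    bcs=8.0,
                    spi_pct=75.0,
                    sequence=_random_peptide(rng, 12, True),
                    is_decoy=False,
                    purity_pct=float(np.round(purity, 2)),
                    tmt_labeled=not unlabeled,
                    reporter_intensities=np.round(mixed, 6),
                    candidate_proteins=[fid],
                )
            )
            i += 1
    return records, design, truth


def generate_hla_peptides(config: SyntheticConfig, seed: int):
    """Generate class-I peptides with anchors and class-II nested sets.

    Class I: lengths drawn from ``hla_length_probs`` (mode 9), anchor
    residues placed with the configured probabilities.  Class II: each
    nested set extends one seeded 9-mer binding core with ragged random
    flanks.  Returns ``(class1_peptides, class2_peptides, SyntheticTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    lengths = list(config.hla_length_probs)
    probs = [config.hla_length_probs[k] for k in lengths]

    class1 = []
    n_class1 = 5000
    for _ in range(n_class1):
        length = int(rng.choice(lengths, p=probs))
        pep = list("".join(rng.choice(list(_AA + "K"), size=length)))
        for pos, (residue, prob) in config.hla_anchors.items():
            if rng.random() < prob:
                pep[pos if pos < 0 else pos - 1] = residue
        class1.append("".join(pep))

    truth = SyntheticTruth()
    class2 = []
    lo, hi = config.hla2_length_range
    for s in range(config.hla2_n_sets):
        core = "".join(rng.choice(list(_AA + "K"), size=config.hla2_core_length))
        size = int(rng.integers(*config.hla2_set_size_range, endpoint=True))
        members = []
        for _ in range(size):
            total = int(rng.integers(lo, hi + 1))
            n_flank = total - config.hla2_core_length
            n_left = int(rng.integers(0, n_flank + 1))
            left = "".join(rng.choice(list(_AA + "K"), size=n_left))
            right = "".join(
                rng.choice(list(_AA + "K"), size=n_flank - n_left)
            )
            members.append(left + core + right)
        members = list(dict.fromkeys(members))
        truth.nested_sets[f"set{s:03d}"] = members
        class2.extend(members)
    return class1, class2, truth
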