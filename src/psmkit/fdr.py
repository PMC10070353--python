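"""Target-decoy FDR estimation and threshold autovalidation.

The estimator is the plain concatenated target-decoy ratio
``FDR = n_decoy / n_target`` (isolated in :func:`estimate_fdr` so that
alternatives such as ``(D+1)/T`` are one-line swaps).

Autovalidation searches, independently within each scope (one LC-MS/MS run
or one TMT plex, per precursor-charge bucket), for the
``(min_score, min_delta_rank)`` pair on the empirical candidate grid of
observed values that maximizes the number of accepted target PSMs subject
to the scope's FDR budget.  Rarely observed peptide classes (nuORFs,
variants) additionally pass through fixed record-level thresholds and a
BCS x score grid search that tightens each class to a subset-specific
FDR < 1%.

Threshold semantics: score/delta/BCS/SPI/length bounds are inclusive;
the precursor mass-error bound is strict; run/plex FDR budgets are
inclusive (FDR <= target) while the subset grid search is strict
(FDR < target).

Selection-bias correction.  Maximizing accepted targets subject to
``D/T <= target`` stops just short of the next decoy event along each
threshold axis, so the decoy count at the selected pair underestimates
the incorrect-match rate there and the realized false-discovery
proportion overshoots the budget by roughly one decoy event per axis
and scope.  Autovalidation therefore tests candidate pairs with a
next-decoy-corrected count, ``(D + k)/T <= target`` with ``k = 2`` by
default (one per threshold dimension — the two-dimensional analogue of
the standard "+1 decoy" convention); the reported FDR estimate remains
the plain ``D/T``.  Set ``decoy_correction=0`` for the uncorrected
rule.  The subset grid search keeps the plain estimator: its classes
are small enough that a +k rule would make them categorically
infeasible, and its budgets are already strict.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import FilterProfile

# above this many empirical grid cells, fall back to a column-wise sweep
_MAX_DENSE_CELLS = 25_000_000


def estimate_fdr(psms) -> float:
    """Concatenated target-decoy FDR estimate ``n_decoy / n_target``."""
    if len(psms) == 0:
        raise ValueError("no accepted PSMs")
    n_decoy = sum(1 for p in psms if p.is_decoy)
    n_target = len(psms) - n_decoy
    if n_decoy == 0:
        return 0.0
    if n_target == 0:
        raise ValueError("FDR undefined: decoys accepted but no targets")
    return n_decoy / n_target


@dataclass(frozen=True)
class BucketSpec:
    """One charge bucket: which charges, how scoped, and its FDR budget."""

    charges: tuple
    scope: str  # "run" | "plex" | "pooled"
    target: float

    def __post_init__(self):
        if self.scope not in ("run", "plex", "pooled"):
            raise ValueError(f"unknown scope {self.scope!r}")
        object.__setattr__(self, "charges", tuple(self.charges))


#: per-run <0.8% for charges 2-4, per-plex <0.4% pooled charges 5-6
DEFAULT_TMT_BUCKETS = (
    BucketSpec((2,), "run", 0.008),
    BucketSpec((3,), "run", 0.008),
    BucketSpec((4,), "run", 0.008),
    BucketSpec((5, 6), "plex", 0.004),
)


def hla_buckets(charge_range=(1, 4), target=0.01):
    """Single pooled bucket across all fractions at 1% FDR (HLA mode)."""
    lo, hi = charge_range
    return (BucketSpec(tuple(range(lo, hi + 1)), "pooled", target),)


@dataclass
class ThresholdSet:
    """Optimized thresholds and achieved statistics for one scope."""

    charges: tuple
    scope: str
    scope_id: str
    target: float
    min_score: float
    min_delta_rank: float
    achieved_fdr_estimate: float
    n_accepted_targets: int
    n_accepted_decoys: int
    feasible: bool
    note: str = ""


def _optimize_pair_thresholds(scores, deltas, is_decoy, target,
                              decoy_correction: int = 0):
    """Exhaustive search over the empirical (score, delta) candidate grid.

    A pair is feasible when ``(D + decoy_correction)/T <= target``.
    Returns ``(min_score, min_delta, fdr, n_targets, n_decoys)`` for the
    feasible pair maximizing accepted targets, or ``None`` when no pair
    with at least one accepted target meets the budget.  Ties are broken
    by fewer decoys, then lower score threshold, then lower delta
    threshold.  The returned ``fdr`` is the uncorrected ``D/T``.
    """
    scores = np.asarray(scores, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    us = np.unique(scores)
    ud = np.unique(deltas)
    si = np.searchsorted(us, scores)
    di = np.searchsorted(ud, deltas)

    if us.size * ud.size <= _MAX_DENSE_CELLS:
        t_hist = np.zeros((us.size, ud.size), dtype=np.int64)
        d_hist = np.zeros_like(t_hist)
        np.add.at(t_hist, (si[~is_decoy], di[~is_decoy]), 1)
        np.add.at(d_hist, (si[is_decoy], di[is_decoy]), 1)
        T = t_hist[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)[::-1, ::-1]
        D = d_hist[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)[::-1, ::-1]
        ok = (T > 0) & ((D + decoy_correction) / np.maximum(T, 1) <= target)
        if not ok.any():
            return None
        t_max = T[ok].max()
        cand = ok & (T == t_max)
        d_min = D[cand].min()
        cand &= D == d_min
        i, j = np.argwhere(cand)[0]  # argwhere is row-major: min i, then j
        return (
            float(us[i]),
            float(ud[j]),
            d_min / t_max,
            int(t_max),
            int(d_min),
        )

    # column-wise sweep: one pass per unique delta threshold
    best = None  # key: (-T, D, i, j)
    for j in range(ud.size):
        m = di >= j
        t_col = np.bincount(si[m & ~is_decoy], minlength=us.size)
        d_col = np.bincount(si[m & is_decoy], minlength=us.size)
        T = t_col[::-1].cumsum()[::-1]
        D = d_col[::-1].cumsum()[::-1]
        ok = (T > 0) & ((D + decoy_correction) / np.maximum(T, 1) <= target)
        if not ok.any():
            continue
        idx = np.nonzero(ok)[0]
        t_max = T[idx].max()
        idx = idx[T[idx] == t_max]
        d_min = D[idx].min()
        i = int(idx[D[idx] == d_min][0])
        key = (-int(t_max), int(d_min), i, j)
        if best is None or key < best[0]:
            best = (key, (float(us[i]), float(ud[j]), d_min / t_max,
                          int(t_max), int(d_min)))
    return None if best is None else best[1]


def autovalidate(psms, buckets=DEFAULT_TMT_BUCKETS, decoy_correction: int = 2):
    """Per-scope threshold optimization at the configured FDR budgets.

    ``decoy_correction`` is the next-decoy count added when testing a
    candidate threshold pair against the budget (see module docstring);
    the default of 2 (one per threshold dimension) keeps the realized
    false-discovery proportion calibrated to the budget.

    Returns ``(threshold_sets, accepted)``: one :class:`ThresholdSet` per
    (bucket, scope) combination present in the input, and the union of
    accepted PSMs (targets and decoys) across scopes, in input order.
    PSMs whose charge falls in no bucket are never accepted.  Scopes with
    zero targets or with no feasible threshold pair accept nothing and are
    flagged, never silently relaxed.
    """
    charge_to_bucket = {}
    for bucket in buckets:
        for z in bucket.charges:
            if z in charge_to_bucket:
                raise ValueError(f"charge {z} assigned to multiple buckets")
            charge_to_bucket[z] = bucket

    scopes = {}
    for idx, psm in enumerate(psms):
        bucket = charge_to_bucket.get(psm.charge)
        if bucket is None:
            continue
        if bucket.scope == "run":
            sid = f"run={psm.run_id}/charge={psm.charge}"
        elif bucket.scope == "plex":
            sid = f"plex={psm.plex_id}"
        else:
            sid = "pooled"
        key = (bucket, sid)
        scopes.setdefault(key, []).append(idx)

    threshold_sets = []
    accepted_idx = set()
    for (bucket, sid) in sorted(scopes, key=lambda k: (k[0].charges, k[1])):
        members = scopes[(bucket, sid)]
        sub = [psms[i] for i in members]
        charges = (
            bucket.charges
            if bucket.scope != "run"
            else (sub[0].charge,)
        )
        n_targets = sum(1 for p in sub if not p.is_decoy)
        if n_targets == 0:
            threshold_sets.append(
                ThresholdSet(charges, bucket.scope, sid, bucket.target,
                             float("inf"), float("inf"), 0.0, 0, 0,
                             feasible=False, note="no target PSMs in scope")
            )
            continue
        result = _optimize_pair_thresholds(
            [p.score for p in sub],
            [p.delta_rank_score for p in sub],
            [p.is_decoy for p in sub],
            bucket.target,
            decoy_correction,
        )
        if result is None:
            threshold_sets.append(
                ThresholdSet(charges, bucket.scope, sid, bucket.target,
                             float("inf"), float("inf"), float("nan"), 0, 0,
                             feasible=False,
                             note="no threshold pair meets FDR budget")
            )
            continue
        min_score, min_delta, fdr, n_t, n_d = result
        threshold_sets.append(
            ThresholdSet(charges, bucket.scope, sid, bucket.target,
                         min_score, min_delta, fdr, n_t, n_d, feasible=True)
        )
        for i in members:
            p = psms[i]
            if p.score >= min_score and p.delta_rank_score >= min_delta:
                accepted_idx.add(i)

    accepted = [psms[i] for i in sorted(accepted_idx)]
    return threshold_sets, accepted


def apply_fixed_subset_thresholds(psms, profile: FilterProfile):
    """Fixed record-level thresholds for rarely observed peptide classes.

    Inclusive on score, SPI, BCS and length; strict on |mass error| (the
    bound is "< 5 ppm").
    """
    lo, hi = profile.length_range
    return [
        p
        for p in psms
        if p.score >= profile.min_score
        and p.spi_pct >= profile.min_spi_pct
        and abs(p.mass_error_ppm) < profile.max_abs_ppm
        and p.bcs >= profile.min_bcs
        and lo <= len(p.sequence) <= hi
    ]


@dataclass
class SubsetThresholds:
    """Grid-search outcome for one rarely observed peptide class."""

    class_label: str
    profile_name: str
    min_bcs: float
    min_score: float
    achieved_fdr: float
    n_retained_targets: int
    feasible: bool


def subset_grid_search(
    psms,
    bcs_grid: Sequence[float],
    score_grid: Sequence[float],
    fdr_target: float = 0.01,
    class_label: str = "",
    profile_name: str = "",
):
    """Lowest (BCS, score) grid pair bringing a class below the FDR target.

    Among all grid pairs achieving ``estimate_fdr < fdr_target`` (strict)
    on the surviving subset, returns the pair maximizing retained target
    count, ties broken by smaller BCS then smaller score.  Classes already
    below the target therefore keep the grid minima; infeasible classes
    (including empty and all-decoy ones) return ``feasible=False`` and
    retain nothing.

    Returns ``(SubsetThresholds, retained_psms)``.
    """
    bcs_grid = list(bcs_grid)
    score_grid = list(score_grid)
    if bcs_grid != sorted(bcs_grid) or score_grid != sorted(score_grid):
        raise ValueError("grids must be ascending")
    if not psms:
        return (
            SubsetThresholds(class_label, profile_name, float("nan"),
                             float("nan"), float("nan"), 0, False),
            [],
        )
    bcs = np.array([p.bcs for p in psms])
    scores = np.array([p.score for p in psms])
    decoy = np.array([p.is_decoy for p in psms])

    best = None  # key: (-T, bi, si)
    for bi, si in itertools.product(range(len(bcs_grid)), range(len(score_grid))):
        mask = (bcs >= bcs_grid[bi]) & (scores >= score_grid[si])
        n_t = int((mask & ~decoy).sum())
        n_d = int((mask & decoy).sum())
        if n_t == 0 or not (n_d / n_t < fdr_target):
            continue
        key = (-n_t, bi, si)
        if best is None or key < best[0]:
            best = (key, (bi, si, n_d / n_t, n_t))
    if best is None:
        return (
            SubsetThresholds(class_label, profile_name, float("nan"),
                             float("nan"), float("nan"), 0, False),
            [],
        )
    bi, si, fdr, n_t = best[1]
    retained = [
        p for p in psms if p.bcs >= bcs_grid[bi] and p.score >= score_grid[si]
    ]
    return (
        SubsetThresholds(class_label, profile_name, float(bcs_grid[bi]),
                         float(score_grid[si]), fdr, n_t, True),
        retained,
    )


def default_grids(profile: FilterProfile, n_bcs=11, n_score=17, score_step=0.5):
    """Default BCS x score grids starting at the profile's fixed minima."""
    bcs_grid = [profile.min_bcs + i for i in range(n_bcs)]
    score_grid = [profile.min_score + i * score_step for i in range(n_score)]
    return bcs_grid, score_grid


def run_subset_fdr(
    psms,
    profiles: dict,
    fdr_target: float = 0.01,
    grids: Optional[dict] = None,
):
    """Two-step subset-specific FDR control for non-canonical classes.

    ``profiles`` maps each non-canonical ``class_label`` to its
    :class:`FilterProfile`.  Canonical PSMs bypass both steps (they are
    controlled by :func:`autovalidate` alone).  Each other class passes
    through the fixed thresholds, then the BCS x score grid search.
    Returns ``(accepted, per_class_thresholds)`` with ``accepted`` the
    disjoint union across classes in input order.
    """
    by_class = {}
    for psm in psms:
        by_class.setdefault(psm.class_label, []).append(psm)
    unknown = [
        c for c in by_class if c != "canonical" and c not in profiles
    ]
    if unknown:
        raise ValueError(f"no profile for class label(s): {sorted(unknown)}")

    accepted_ids = set()
    per_class = {}
    for label in sorted(by_class):
        members = by_class[label]
        if label == "canonical":
            accepted_ids.update(id(p) for p in members)
            continue
        profile = profiles[label]
        survivors = apply_fixed_subset_thresholds(members, profile)
        if grids is not None and label in grids:
            bcs_grid, score_grid = grids[label]
        else:
            bcs_grid, score_grid = default_grids(profile)
        thresholds, retained = subset_grid_search(
            survivors, bcs_grid, score_grid, fdr_target,
            class_label=label, profile_name=profile.name,
        )
        per_class[label] = thresholds
        accepted_ids.update(id(p) for p in retained)

    accepted = [p for p in psms if id(p) in accepted_ids]
    return accepted, per_class
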