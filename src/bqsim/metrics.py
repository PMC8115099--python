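"""Spatial and compositional statistics of simulated communities.

Includes the genotype census and Shannon alpha-diversity, the partner
association degree/index (PAD/PAI) that quantify how tightly the two
members of an asymmetric functional complementation pair (AFCP) are mixed
in space, region sizes of pairs, the t1/t2/TIMEGAP/t3 timing of pair
emergence during spatial competition, and the rule cascade that labels a
final community structure.

PAD of a TFLG is the mean, over its cells, of the distance-weighted count
of complementary-partner cells in the Moore 8-neighborhood (weight 1 for
edge neighbors, 1/sqrt(2) for diagonal); PAI is the ratio of the PADs of
two competing pairs.  Undefined statistics (empty community, no focal
cells, zero denominator) are returned as ``nan``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import genotypes as gt
from .engine import LatticeState

__all__ = [
    "CommunitySnapshot",
    "PatternCall",
    "MOORE_WEIGHTS",
    "genotype_abundances",
    "alpha_diversity",
    "pad",
    "pai",
    "region_size",
    "classify_pattern",
    "competition_timing",
    "steady_state_reached",
]

#: Default neighborhood weighting: Moore radius 1, inverse-distance weights.
MOORE_WEIGHTS: dict[tuple[int, int], float] = {
    (-1, 0): 1.0, (1, 0): 1.0, (0, -1): 1.0, (0, 1): 1.0,
    (-1, -1): 1.0 / math.sqrt(2), (-1, 1): 1.0 / math.sqrt(2),
    (1, -1): 1.0 / math.sqrt(2), (1, 1): 1.0 / math.sqrt(2),
}


@dataclass
class CommunitySnapshot:
    """Genotype occupancy grid at one time point plus its census."""

    step: int
    genotype_grid: np.ndarray
    counts: np.ndarray

    @classmethod
    def from_state(cls, state: LatticeState) -> "CommunitySnapshot":
        return cls(state.step, state.genotype.copy(), state.counts())


@dataclass
class PatternCall:
    """Result of the final-pattern rule cascade."""

    label: str
    dominant_fraction: float
    cheater_fraction: float = 0.0


def _grid(snapshot) -> np.ndarray:
    if isinstance(snapshot, CommunitySnapshot):
        return snapshot.genotype_grid
    if isinstance(snapshot, LatticeState):
        return snapshot.genotype
    return np.asarray(snapshot)


def genotype_abundances(snapshot) -> tuple[np.ndarray, np.ndarray]:
    """Exact census: (counts, fractions) over the 8 genotypes.

    Fractions are all-nan for an empty community.
    """
    counts = gt.census(_grid(snapshot))
    total = counts.sum()
    if total == 0:
        return counts, np.full(8, np.nan)
    return counts, counts / total


def alpha_diversity(counts: np.ndarray) -> float:
    """Shannon index H = -sum p ln p over genotypes present; nan if empty."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    total = counts.sum()
    if total == 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def _weighted_partner_field(partner_mask: np.ndarray,
                            weights: dict[tuple[int, int], float]) -> np.ndarray:
    out = np.zeros(partner_mask.shape)
    for (dr, dc), w in weights.items():
        out += w * np.roll(np.roll(partner_mask, dr, axis=0), dc, axis=1)
    return out


def pad(snapshot, focal_tfg: int,
        weights: dict[tuple[int, int], float] | None = None) -> float:
    """Partner association degree of a TFLG towards its complement OFLG.

    Mean over focal TFLG cells of the weighted number of partner cells in
    the (periodic) neighborhood defined by ``weights``.  ``nan`` when no
    focal cell exists.
    """
    if focal_tfg not in gt.TFLGS:
        raise ValueError(f"focal genotype {focal_tfg} is not a TFLG")
    grid = _grid(snapshot)
    weights = MOORE_WEIGHTS if weights is None else weights
    focal = grid == focal_tfg
    if not focal.any():
        return float("nan")
    partner = (grid == gt.complement(focal_tfg)).astype(float)
    return float(_weighted_partner_field(partner, weights)[focal].mean())


def pai(snapshot, pair_a: int, pair_b: int,
        weights: dict[tuple[int, int], float] | None = None) -> float:
    """Partner association index PAD(pair_a) / PAD(pair_b).

    Pairs are named by their TFLG member.  > 1 means pair_a is more
    spatially associated.  ``nan`` when either PAD is undefined or the
    denominator is zero.
    """
    pa = pad(snapshot, pair_a, weights)
    pb = pad(snapshot, pair_b, weights)
    if math.isnan(pa) or math.isnan(pb) or pb == 0.0:
        return float("nan")
    return pa / pb


def region_size(snapshot, pair) -> int:
    """Number of boxes occupied by members of ``pair`` (iterable of codes)."""
    grid = _grid(snapshot)
    return int(sum(np.count_nonzero(grid == g) for g in pair))


def classify_pattern(snapshot, theta: float = 0.95) -> PatternCall:
    """Label the community structure with the dominance threshold ``theta``.

    Cascade: collapsed (no cells) -> ancestor_dominated -> one of the three
    AFC pair labels -> complete_functional_division -> one_way_dependency
    -> unresolved.  For the AFC and complete-division rules accompanying
    cheaters are tolerated: pair dominance is evaluated among non-cheater
    cells and the cheater fraction is reported on the call.
    """
    counts, frac = genotype_abundances(snapshot)
    total = counts.sum()
    if total == 0:
        return PatternCall("collapsed", 0.0)
    cheater_frac = float(frac[gt.CHEATER])
    if frac[gt.ANCESTOR] >= theta:
        return PatternCall("ancestor_dominated", float(frac[gt.ANCESTOR]),
                           cheater_frac)
    non_cheater = total - counts[gt.CHEATER]
    if non_cheater > 0:
        for tfg, ofg in gt.AFC_PAIRS:
            pair_frac = (counts[tfg] + counts[ofg]) / non_cheater
            if pair_frac >= theta and counts[tfg] > 0 and counts[ofg] > 0:
                return PatternCall(
                    f"AFC_{gt.compact_label(tfg)}_{gt.compact_label(ofg)}",
                    float(pair_frac), cheater_frac)
        tf_counts = counts[list(gt.TFLGS)]
        if tf_counts.sum() / non_cheater >= theta and np.all(tf_counts > 0):
            return PatternCall("complete_functional_division",
                               float(tf_counts.sum() / non_cheater),
                               cheater_frac)
    dep = frac[gt.ANCESTOR] + frac[gt.CHEATER]
    if dep >= theta and counts[gt.ANCESTOR] > 0 and counts[gt.CHEATER] > 0:
        return PatternCall("one_way_dependency", float(dep), cheater_frac)
    return PatternCall("unresolved",
                       float(np.nanmax(frac)) if total else 0.0, cheater_frac)


def competition_timing(snapshots: list[CommunitySnapshot],
                       colonizations: list[tuple],
                       joint_threshold: float = 0.95):
    """Timing of the spatial competition between the first two AFCPs.

    Parameters
    ----------
    snapshots
        Chronological snapshots of one run.
    colonizations
        ``(step, genotype)`` colonization records (see
        :func:`bqsim.lineage.colonization_events`); the first two TFLG
        entries define the competing pairs.
    joint_threshold
        Joint abundance fraction of the two pairs defining t3.

    Returns
    -------
    dict with keys ``t1``, ``t2``, ``timegap``, ``t3``,
    ``prior_space_at_t2``, ``first_pair``, ``second_pair`` (pairs named by
    TFLG code).  ``t2``-dependent values are ``nan``/``None`` when no
    second pair ever colonizes.
    """
    tfg_steps = [(step, g) for step, g in colonizations if g in gt.TFLGS]
    if not tfg_steps:
        raise ValueError("no TFLG ever colonized; timing undefined")
    t1, first = tfg_steps[0]
    second_entries = [(s, g) for s, g in tfg_steps[1:] if g != first]
    out = {"t1": t1, "first_pair": first, "t2": None, "second_pair": None,
           "timegap": float("nan"), "t3": None,
           "prior_space_at_t2": float("nan")}
    if not second_entries:
        return out
    t2, second = second_entries[0]
    out.update(t2=t2, second_pair=second, timegap=t2 - t1)
    pair1 = (first, gt.complement(first))
    pair2 = (second, gt.complement(second))
    snap_at_t2 = min((s for s in snapshots if s.step >= t2),
                     key=lambda s: s.step, default=snapshots[-1])
    out["prior_space_at_t2"] = region_size(snap_at_t2, pair1)
    for snap in snapshots:
        if snap.step < t2:
            continue
        total = snap.counts.sum()
        if total == 0:
            continue
        joint = sum(snap.counts[g] for g in pair1 + pair2) / total
        if joint >= joint_threshold:
            out["t3"] = snap.step
            break
    return out


def steady_state_reached(fractions: np.ndarray, window: int = 10_000,
                         tol: float = 0.01) -> bool:
    """Whether every genotype fraction varies < ``tol`` over the last window.

    ``fractions`` has one row per recorded step (the row index spacing is
    up to the caller; ``window`` counts rows).
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 2:
        raise ValueError("fractions must be (n_steps, n_genotypes)")
    if len(fractions) < window:
        raise ValueError("series shorter than the window")
    tail = fractions[-window:]
    span = np.nanmax(tail, axis=0) - np.nanmin(tail, axis=0)
    return bool(np.all(span < tol))
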