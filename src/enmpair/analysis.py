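"""Derived conformer analyses over elastic-network results.

Covers the comparisons made between an open (ligand-free) and closed
(ligand-bound) conformer of a two-domain protein: scaling predicted
B-factors to experiment, locating slow-mode hinge residues and fast-mode
kinetically hot residues, difference-distance and slow-mode
fluctuation-difference maps, and the rigid rotation angle between the two
domains estimated by two-stage least-squares superposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .enm import BFACTOR_PER_MSF, FluctuationProfile, GnmModel
from .structures import CalphaStructure, ResiduePairing, select_residues


@dataclass
class ScaleFitResult:
    """Least-squares k_BT/γ scale and Pearson correlation with experiment."""

    scale_kbt_over_gamma: float  # Å²
    pearson_r: float
    n_residues: int


def fit_scale(raw_msf: np.ndarray, exp_b: np.ndarray) -> ScaleFitResult:
    """Fit the k_BT/γ scale of an unscaled fluctuation profile to experiment.

    ``raw_msf`` is the model's mean-square fluctuation at scale 1.  The fit
    minimizes Σ (B_exp − c·B_raw)² over c ≥ 0 through the origin (closed
    form c = Σ B_exp·B_raw / Σ B_raw²); since predicted B is linear in
    k_BT/γ, c IS the fitted scale.  The Pearson correlation between
    predicted and experimental B is scale-invariant and reported alongside.
    """
    raw_msf = np.asarray(raw_msf, dtype=float)
    exp_b = np.asarray(exp_b, dtype=float)
    if raw_msf.shape != exp_b.shape or raw_msf.ndim != 1:
        raise ValueError("raw_msf and exp_b must be 1-D of equal length")
    if raw_msf.size < 3:
        raise ValueError("need at least 3 residues to fit a scale")
    if np.ptp(exp_b) == 0:
        raise ValueError("experimental B-factors are constant; correlation undefined")
    raw_b = BFACTOR_PER_MSF * raw_msf
    denom = float(np.dot(raw_b, raw_b))
    if denom == 0:
        raise ValueError("raw fluctuations are identically zero")
    c = max(0.0, float(np.dot(exp_b, raw_b)) / denom)
    r = float(stats.pearsonr(raw_b, exp_b).statistic)
    return ScaleFitResult(scale_kbt_over_gamma=c, pearson_r=r, n_residues=raw_msf.size)


@dataclass
class DifferenceDistanceMap:
    """Inter-residue distance changes ΔR_ij = R_ij(A) − R_ij(B), Å.

    ``classes`` codes each pair as +1 (increase, ΔR ≥ +threshold),
    −1 (decrease, ΔR ≤ −threshold) or 0 (unchanged).
    """

    delta: np.ndarray
    threshold: float
    classes: np.ndarray


def difference_distance(
    a: CalphaStructure,
    b: CalphaStructure,
    pairing: ResiduePairing,
    threshold: float = 1.5,
) -> DifferenceDistanceMap:
    """Difference-distance map over paired residues.

    Rigid regions (domains that move as a block) show |ΔR_ij| near zero
    within themselves; pairs crossing a hinge change by more than the
    threshold (default 1.5 Å).
    """
    if len(pairing) < 2:
        raise ValueError("need at least 2 paired residues")
    ra = squareform(pdist(a.coords[pairing.a_indices]))
    rb = squareform(pdist(b.coords[pairing.b_indices]))
    delta = ra - rb
    classes = np.zeros_like(delta, dtype=int)
    classes[delta >= threshold] = 1
    classes[delta <= -threshold] = -1
    return DifferenceDistanceMap(delta=delta, threshold=threshold, classes=classes)


def fluctuation_difference(
    profile_a: FluctuationProfile,
    profile_b: FluctuationProfile,
    pairing: ResiduePairing,
) -> np.ndarray:
    """Per-residue difference of normalized fluctuation profiles (A − B).

    Each profile is normalized to unit sum over its own structure before
    subtraction, because the two conformers' fitted k_BT/γ scales differ;
    the result compares mode *shapes*, not absolute amplitudes.
    """
    if profile_a.mode_subset != profile_b.mode_subset:
        raise ValueError(
            f"mode selections differ: {profile_a.mode_subset} vs {profile_b.mode_subset}"
        )
    if profile_a.model_kind != profile_b.model_kind:
        raise ValueError("profiles come from different model kinds")
    na = profile_a.msf / profile_a.msf.sum()
    nb = profile_b.msf / profile_b.msf.sum()
    return na[pairing.a_indices] - nb[pairing.b_indices]


@dataclass
class HingeReport:
    """Hinge residues: near-zero local minima of the slowest-mode profile."""

    hinge_residues: list
    hinge_indices: np.ndarray
    profile: np.ndarray
    minima_threshold_fraction: float


def find_hinges(
    profile: np.ndarray,
    threshold_fraction: float = 0.05,
    window: int = 2,
    residue_ids: Sequence | None = None,
) -> HingeReport:
    """Locate hinge residues in a slowest-mode fluctuation profile.

    A residue qualifies when its value lies below
    ``threshold_fraction · max(profile)`` and is a minimum within ±window.
    Consecutive qualifying residues are merged into one hinge region,
    reported by the region's minimum.
    """
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    if n < 2 * window + 1:
        raise ValueError("profile too short for the requested window")
    if np.ptp(profile) == 0:
        warnings.warn("flat fluctuation profile; no hinges detectable", stacklevel=2)
        return HingeReport([], np.array([], dtype=int), profile, threshold_fraction)
    floor = threshold_fraction * profile.max()
    qualifying = profile < floor
    hinge_idx: list[int] = []
    i = 0
    while i < n:
        if not qualifying[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qualifying[j + 1]:
            j += 1
        region = np.arange(i, j + 1)
        best = int(region[np.argmin(profile[region])])
        lo, hi = max(0, best - window), min(n, best + window + 1)
        if profile[best] <= profile[lo:hi].min():
            hinge_idx.append(best)
        i = j + 1
    idx = np.array(hinge_idx, dtype=int)
    ids = [residue_ids[k] if residue_ids is not None else int(k) for k in idx]
    return HingeReport(ids, idx, profile, threshold_fraction)


def fast_mode_profile(
    g: GnmModel, n_modes: int = 10, weighted: bool = False
) -> np.ndarray:
    """Average shape of the fastest GNM modes.

    Mean over the ``n_modes`` largest-eigenvalue modes of the squared
    eigenvector components (unweighted by default; ``weighted=True`` uses
    eigenvalue weights).  Either way the profile sums to 1, so peaks mark
    residues on which high-frequency motion localizes — the kinetically hot,
    tightly packed residues.
    """
    dec = g.decompose()
    if n_modes < 1 or n_modes > dec.n_nonzero:
        raise ValueError(
            f"n_modes must be in 1..{dec.n_nonzero} (available nonzero modes)"
        )
    u = dec.eigenvectors[:, -n_modes:]
    sq = u**2
    if weighted:
        lam = dec.eigenvalues[-n_modes:]
        profile = (sq * lam).sum(axis=1) / lam.sum()
    else:
        profile = sq.mean(axis=1)
    return profile


@dataclass
class HotResidueReport:
    """Peak residues of the fast-mode profile (kinetically hot residues)."""

    peak_residues: list
    peak_indices: np.ndarray
    profile: np.ndarray
    cutoff_used: float | None = None


def find_hot_residues(
    profile: np.ndarray,
    floor_sd: float = 1.0,
    window: int = 2,
    residue_ids: Sequence | None = None,
    cutoff_used: float | None = None,
) -> HotResidueReport:
    """Strict local maxima of a fast-mode profile above mean + floor_sd·sd."""
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    floor = profile.mean() + floor_sd * profile.std()
    peaks: list[int] = []
    for i in range(n):
        if profile[i] <= floor:
            continue
        lo, hi = max(0, i - window), min(n, i + window + 1)
        others = np.delete(profile[lo:hi], i - lo)
        if others.size and np.all(profile[i] > others):
            peaks.append(i)
    idx = np.array(peaks, dtype=int)
    ids = [residue_ids[k] if residue_ids is not None else int(k) for k in idx]
    return HotResidueReport(ids, idx, profile, cutoff_used)


@dataclass
class RotationResult:
    """Rigid inter-domain rotation angle between two conformers."""

    angle_deg: float
    fixed_domain: np.ndarray  # positional indices into structure A
    moving_domain: np.ndarray
    rmsd_fixed: float  # Å, over the fixed domain after stage-1 superposition
    rotation: np.ndarray  # 3×3 proper rotation aligning B's moving domain onto A's
    reflection_corrected: bool = False


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, bool]:
    """Optimal proper rotation R minimizing |p − (q − q̄)R ... | in the
    least-squares sense: returns R with det +1 such that R @ (q_i − q̄)
    best matches (p_i − p̄), plus a flag when the unconstrained optimum was
    a reflection."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = qc.T @ pc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corrected = d < 0
    s = np.diag([1.0, 1.0, d])
    r = vt.T @ s @ u.T
    return r, bool(corrected)


def _superpose(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Rigid transform (R, t) superposing q onto p; x ↦ R x + t."""
    r, corrected = _kabsch(p, q)
    t = p.mean(axis=0) - r @ q.mean(axis=0)
    return r, t, corrected


def rotation_angle(
    a: CalphaStructure,
    b: CalphaStructure,
    pairing: ResiduePairing,
    fixed_domain: Iterable,
    moving_domain: Iterable,
) -> RotationResult:
    """Rigid rotation of one domain relative to the other between conformers.

    Two-stage least-squares procedure: (1) superpose B onto A over the
    fixed-domain Cα (optimal rigid fit); (2) find the optimal rotation
    aligning the superposed moving domain of B onto A's.  The angle is
    arccos((trace R − 1)/2) of the stage-2 rotation, in [0°, 180°].  Domain
    selections are residue-number ranges or index arrays over structure A.

    This is a simplified superposition estimate of the inter-domain screw
    rotation, not a domain-finding algorithm: the domain memberships are an
    input, not an output.
    """
    fixed_idx = select_residues(a, fixed_domain)
    moving_idx = select_residues(a, moving_domain)
    a_pos = {int(i): k for k, i in enumerate(pairing.a_indices)}
    fixed_rows = np.array([a_pos[i] for i in fixed_idx if i in a_pos], dtype=int)
    moving_rows = np.array([a_pos[i] for i in moving_idx if i in a_pos], dtype=int)
    for name, rows in (("fixed", fixed_rows), ("moving", moving_rows)):
        if rows.size < 3:
            raise ValueError(f"{name} domain has fewer than 3 paired residues")
    pa = a.coords[pairing.a_indices]
    pb = b.coords[pairing.b_indices]
    for name, rows in (("fixed", fixed_rows), ("moving", moving_rows)):
        centered = pa[rows] - pa[rows].mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError(f"{name} domain selection is collinear or degenerate")

    # Stage 1: global superposition on the fixed domain.
    r1, t1, corr1 = _superpose(pa[fixed_rows], pb[fixed_rows])
    pb_sup = pb @ r1.T + t1
    diff = pa[fixed_rows] - pb_sup[fixed_rows]
    rmsd_fixed = float(np.sqrt((diff**2).sum() / fixed_rows.size))
    # Stage 2: residual rotation of the moving domain.
    r2, corr2 = _kabsch(pa[moving_rows], pb_sup[moving_rows])
    # equivalent to arccos((trace R − 1)/2) but numerically stable near 0°
    from scipy.spatial.transform import Rotation

    angle = float(np.degrees(Rotation.from_matrix(r2).magnitude()))
    if corr1 or corr2:
        warnings.warn(
            "optimal alignment was a reflection; corrected to a proper rotation",
            stacklevel=2,
        )
    return RotationResult(
        angle_deg=angle,
        fixed_domain=fixed_idx,
        moving_domain=moving_idx,
        rmsd_fixed=rmsd_fixed,
        rotation=r2,
        reflection_corrected=bool(corr1 or corr2),
    )
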