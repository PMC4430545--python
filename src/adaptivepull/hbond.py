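"""Geometric hydrogen-bond detection and pathway profiling.

A bond is emitted when the donor and acceptor heavy atoms lie within
``d_cut`` (default 4 A) and the donor-hydrogen-acceptor angle (vertex at
the hydrogen) is at least ``angle_cut`` (default 140 degrees).  The
angle vertex is configurable; choosing a non-default vertex is flagged
via a warning since it changes the meaning of the threshold.

Intrapeptide bonds are classed by the unsigned donor/acceptor residue
offset (3 -> 3_10-like, 4 -> alpha-like, 5 -> pi-like); bonds with
exactly one solvent partner are peptide-solvent, and solvent-solvent
bonds are kept in their own class so profile counts are unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import KB
from .errors import ConfigurationError, LabelingError
from .structures import StructureFrame

__all__ = [
    "HBClass",
    "HBond",
    "HBondProfile",
    "detect_hbonds",
    "classify_contacts",
    "classify_counts",
    "work_weighted_profile",
    "hbond_histogram_2d",
    "effective_solvent_hbonds",
]


class HBClass(Enum):
    I3 = "i3"
    I4 = "i4"
    I5 = "i5"
    OTHER_INTRA = "other_intrapeptide"
    PEPTIDE_SOLVENT = "peptide_solvent"
    SOLVENT_SOLVENT = "solvent_solvent"


#: classes reported in helical-contact profiles
PROFILE_CLASSES = (HBClass.I3, HBClass.I4, HBClass.I5)


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float
    hb_class: HBClass


def _classify(frame: StructureFrame, donor: int, acceptor: int) -> HBClass:
    d_solv = bool(frame.is_solvent[donor])
    a_solv = bool(frame.is_solvent[acceptor])
    if d_solv and a_solv:
        return HBClass.SOLVENT_SOLVENT
    if d_solv or a_solv:
        return HBClass.PEPTIDE_SOLVENT
    off = abs(int(frame.resids[acceptor]) - int(frame.resids[donor]))
    return {3: HBClass.I3, 4: HBClass.I4, 5: HBClass.I5}.get(off, HBClass.OTHER_INTRA)


def detect_hbonds(
    frame: StructureFrame,
    d_cut: float = 4.0,
    angle_cut: float = 140.0,
    angle_vertex: str = "hydrogen",
) -> list:
    """All (donor, hydrogen, acceptor) triples passing the geometric gate.

    Distance is measured between the donor and acceptor heavy atoms;
    pairs within one residue, and donor == acceptor, are excluded.
    """
    if angle_vertex not in ("hydrogen", "donor"):
        raise ConfigurationError(f"unknown angle vertex {angle_vertex!r}")
    if angle_vertex != "hydrogen":
        warnings.warn(
            "non-default angle vertex 'donor': the threshold now gates the "
            "hydrogen-donor-acceptor angle",
            stacklevel=2,
        )
    hydrogens = np.flatnonzero(frame.h_donor >= 0)
    for h in np.flatnonzero(np.array([e == "H" for e in frame.elements])):
        if frame.h_donor[h] < 0 and (frame.is_donor[h] or frame.is_acceptor[h]):
            raise LabelingError(f"hydrogen atom {h} carries a role but no donor link")
    acceptors = np.flatnonzero(frame.is_acceptor)
    if hydrogens.size == 0 or acceptors.size == 0:
        return []
    acc_xyz = frame.coords[acceptors]
    bonds = []
    for h in hydrogens:
        d = int(frame.h_donor[h])
        d_xyz = frame.coords[d]
        h_xyz = frame.coords[h]
        dist = np.linalg.norm(acc_xyz - d_xyz, axis=1)
        ok = (dist <= d_cut) & (acceptors != d) & (frame.resids[acceptors] != frame.resids[d])
        for ai in np.flatnonzero(ok):
            a = int(acceptors[ai])
            a_xyz = frame.coords[a]
            if angle_vertex == "hydrogen":
                v1, v2 = d_xyz - h_xyz, a_xyz - h_xyz
            else:
                v1, v2 = h_xyz - d_xyz, a_xyz - d_xyz
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang >= angle_cut:
                bonds.append(
                    HBond(d, int(h), a, float(dist[ai]), ang, _classify(frame, d, a))
                )
    return bonds


def classify_contacts(bonds: Sequence[HBond], frame: StructureFrame) -> dict:
    """Per-class bond counts (every class present in the result)."""
    counts = {c: 0 for c in HBClass}
    for b in bonds:
        counts[_classify(frame, b.donor, b.acceptor)] += 1
    return counts


# alias used internally where the name reads better
classify_counts = classify_contacts


@dataclass
class HBondProfile:
    """Mean contact count per class along the extension grid, with the raw
    per-trajectory counts retained for scatter plots."""

    extension_grid: np.ndarray
    mean_counts: Mapping[HBClass, np.ndarray]
    raw_counts: Mapping[HBClass, np.ndarray]  # (n_traj, n_grid) per class
    weighted: bool


def work_weighted_profile(
    extension_grid: np.ndarray,
    counts_by_class: Mapping[HBClass, np.ndarray],
    works: np.ndarray,
    temperature: float,
    mode: str = "work",
) -> HBondProfile:
    """Ensemble-average contact counts with Jarzynski weights.

    ``works`` is either one value per trajectory (applied at every
    extension) or a full (n_traj, n_grid) matrix of accumulated works;
    weights are exp(-W/kT) normalized per grid point, computed in
    log-space so arbitrarily large works cannot underflow to a zero
    weight sum.  ``mode='plain'`` gives the unweighted mean.
    """
    grid = np.asarray(extension_grid, dtype=float)
    if mode not in ("work", "plain"):
        raise ConfigurationError(f"unknown weighting mode {mode!r}")
    any_counts = next(iter(counts_by_class.values()))
    counts_arr = {c: np.asarray(v, dtype=float) for c, v in counts_by_class.items()}
    n_traj, n_grid = np.asarray(any_counts).shape
    if n_grid != grid.size:
        raise ConfigurationError("counts and extension grid are misaligned")
    for c, v in counts_arr.items():
        if v.shape != (n_traj, n_grid):
            raise ConfigurationError(f"counts for class {c} have inconsistent shape")
        if np.any(v < 0):
            raise ConfigurationError("contact counts must be >= 0")

    W = np.asarray(works, dtype=float)
    if W.ndim == 1:
        if W.size != n_traj:
            raise ConfigurationError("one work value per trajectory required")
        W = np.repeat(W[:, None], n_grid, axis=1)
    if W.shape != (n_traj, n_grid):
        raise ConfigurationError("work matrix and counts are misaligned")
    if not np.all(np.isfinite(W)):
        raise ConfigurationError("non-finite works")

    if mode == "plain":
        log_w = np.zeros((n_traj, n_grid))
    else:
        log_w = -W / (KB * temperature)
    log_norm = logsumexp(log_w, axis=0)  # (n_grid,)
    weights = np.exp(log_w - log_norm)  # rows sum to 1 per grid point

    means = {c: np.sum(weights * v, axis=0) for c, v in counts_arr.items()}
    return HBondProfile(grid, means, counts_arr, weighted=(mode == "work"))


def hbond_histogram_2d(pairs: Sequence[tuple]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer-binned density over (intrapeptide, peptide-solvent) counts.

    Returns (H, pp_values, ps_values) where H[i, j] is the number of
    frames with pp_values[i] intrapeptide and ps_values[j]
    peptide-solvent bonds; the total mass equals the frame count.
    """
    arr = np.asarray(pairs, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ConfigurationError("pairs must be (n_frames, 2)")
    if np.any(arr < 0):
        raise ConfigurationError("counts must be >= 0")
    pp_vals = np.arange(arr[:, 0].max() + 1) if arr.size else np.arange(1)
    ps_vals = np.arange(arr[:, 1].max() + 1) if arr.size else np.arange(1)
    H = np.zeros((pp_vals.size, ps_vals.size), dtype=int)
    for p, s in arr:
        H[p, s] += 1
    return H, pp_vals, ps_vals


def effective_solvent_hbonds(
    fixed_frame: StructureFrame,
    ensemble: Sequence[StructureFrame],
    d_cut: float = 4.0,
    angle_cut: float = 140.0,
) -> float:
    """Mean peptide-solvent bond count over solvent realizations around a
    fixed peptide structure.

    Every ensemble member must carry the fixed frame's peptide
    coordinates unchanged; intrapeptide counts are asserted invariant.
    """
    if not ensemble:
        raise ConfigurationError("effective_solvent_hbonds requires >= 1 ensemble member")
    ref = fixed_frame.coords[fixed_frame.peptide_mask]
    intra_ref = None
    total = 0.0
    for member in ensemble:
        mem_pep = member.coords[member.peptide_mask]
        if mem_pep.shape != ref.shape or not np.allclose(mem_pep, ref, atol=1e-9):
            raise ConfigurationError(
                "ensemble member peptide coordinates differ from the fixed frame"
            )
        counts = classify_counts(detect_hbonds(member, d_cut, angle_cut), member)
        intra = tuple(counts[c] for c in (HBClass.I3, HBClass.I4, HBClass.I5, HBClass.OTHER_INTRA))
        if intra_ref is None:
            intra_ref = intra
        elif intra != intra_ref:
            raise ConfigurationError(
                "intrapeptide bond counts vary across the ensemble despite a fixed peptide"
            )
        total += counts[HBClass.PEPTIDE_SOLVENT]
    return total / len(ensemble)
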