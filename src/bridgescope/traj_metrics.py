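"""Rigid superposition and per-residue fluctuation statistics.

Implements the frame-averaged per-residue RMSD procedure used to contrast
frame populations (e.g. wild-type frames with the salt bridge in a given
geometry vs a matched random subsample of mutant frames):

1. select frames in each independent simulation (by interaction state, or a
   seeded uniform subsample of the same fraction);
2. superpose every frame on a common reference using only anchor atoms
   (e.g. the backbone of a binding-site segment);
3. compute per-residue RMSD against the reference and average over the
   selected frames, giving one profile per simulation;
4. compare the per-simulation profiles between groups with independent
   two-tailed t-tests per residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sstats
from scipy.spatial.transform import Rotation

from .errors import SelectionError, SuperpositionError
from .structure_io import FrameEnsemble, AtomMeta, is_hydrogen, select_atoms

__all__ = [
    "SuperpositionSpec",
    "ResidueSeries",
    "GroupComparison",
    "superpose",
    "rmsd_per_residue",
    "frame_averaged_rmsd",
    "per_residue_ttest",
    "rmsf",
    "select_alignment_residues",
    "state_selector",
    "random_selector",
]


@dataclass
class ResidueSeries:
    """One number per residue, keyed by author residue numbers."""

    residue_numbers: np.ndarray
    values: np.ndarray
    units: str = ""
    n_samples: int = 0

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_numbers) != len(self.values):
            raise ValueError("residue_numbers and values differ in length")


@dataclass
class SuperpositionSpec:
    """Anchor-atom predicate and reference frame index for rigid fits."""

    anchor_selection: Callable[[AtomMeta], bool]
    reference_frame: int = 0


@dataclass
class GroupComparison:
    """Two groups of per-simulation residue profiles to be compared."""

    group_a: list[ResidueSeries]
    group_b: list[ResidueSeries]
    significance_threshold: float = 2e-5
    equal_var: bool = False  # Welch by default


# -- superposition -----------------------------------------------------------


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation + translation mapping mobile onto ref."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.as_matrix(), mc, rc


def superpose(ens: FrameEnsemble, spec: SuperpositionSpec,
              reference: FrameEnsemble | None = None) -> FrameEnsemble:
    """Rigidly fit every frame onto the reference frame using anchor atoms.

    The least-squares (Kabsch) rotation is proper (det = +1); non-anchor
    atoms are carried along by the fitted transform.  The reference is
    ``reference`` (same topology) or the ensemble itself, at
    ``spec.reference_frame``.
    """
    try:
        anchor = select_atoms(ens, spec.anchor_selection)
    except SelectionError as exc:
        raise SuperpositionError(str(exc)) from exc
    mask = np.fromiter(
        (bool(spec.anchor_selection(m)) for m in ens.topology),
        dtype=bool, count=ens.n_atoms,
    )
    if anchor.n_atoms < 3:
        raise SuperpositionError(f"need ≥3 anchor atoms, got {anchor.n_atoms}")
    ref_ens = ens if reference is None else reference
    ref = ref_ens.coords[spec.reference_frame][mask]
    # collinearity check on the reference anchors
    sv = np.linalg.svd(ref - ref.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise SuperpositionError("anchor atoms are (near-)collinear")
    out = np.empty_like(ens.coords)
    for i in range(ens.n_frames):
        R, mc, rc = _kabsch(ens.coords[i][mask], ref)
        out[i] = (ens.coords[i] - mc) @ R.T + rc
    return ens.with_coords(out)


# -- per-residue deviations --------------------------------------------------


def _residue_atom_masks(ens: FrameEnsemble, residues: Sequence[int],
                        include_hydrogens: bool) -> dict[int, np.ndarray]:
    h_mask = np.fromiter((is_hydrogen(str(a)) for a in ens.atom_name),
                         dtype=bool, count=ens.n_atoms)
    masks = {}
    for r in residues:
        m = ens.residue_number == r
        if not include_hydrogens:
            m = m & ~h_mask
        if not m.any():
            raise SelectionError(f"residue {r} has no (heavy) atoms in topology")
        masks[int(r)] = m
    return masks


def rmsd_per_residue(
    ens: FrameEnsemble,
    frame: int,
    reference: FrameEnsemble,
    residues: Sequence[int] | None = None,
    reference_frame: int = 0,
    include_hydrogens: bool = False,
) -> ResidueSeries:
    """Per-residue RMSD of one (pre-superposed) frame against a reference.

    No re-fitting happens here; superpose first.  For each residue the RMSD
    is the root of the mean squared displacement over its atoms.
    """
    if residues is None:
        residues = ens.residue_numbers()
    masks = _residue_atom_masks(ens, residues, include_hydrogens)
    vals = []
    for r in residues:
        d = ens.coords[frame][masks[r]] - reference.coords[reference_frame][masks[r]]
        vals.append(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    return ResidueSeries(np.asarray(residues), np.array(vals), units="Å", n_samples=1)


def state_selector(labels_per_sim: Sequence[Sequence], state) -> Callable[[int, int], np.ndarray]:
    """Frame selector keeping frames whose per-frame label equals *state*."""

    def select(sim_index: int, n_frames: int) -> np.ndarray:
        labels = labels_per_sim[sim_index]
        return np.flatnonzero(np.array([l == state for l in labels]))

    return select


def random_selector(fraction: float, seed: int) -> Callable[[int, int], np.ndarray]:
    """Seeded uniform random subsample of a fixed fraction of frames.

    Each simulation uses an independent child stream of the same seed, so
    results do not depend on call order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")

    def select(sim_index: int, n_frames: int) -> np.ndarray:
        if fraction == 1.0:
            return np.arange(n_frames)
        rng = np.random.default_rng([seed, sim_index])
        k = max(1, int(round(fraction * n_frames)))
        return np.sort(rng.choice(n_frames, size=k, replace=False))

    return select


def frame_averaged_rmsd(
    sims: Sequence[FrameEnsemble],
    spec: SuperpositionSpec,
    reference: FrameEnsemble,
    selector: Callable[[int, int], np.ndarray] | None = None,
    residues: Sequence[int] | None = None,
    include_hydrogens: bool = False,
) -> list[ResidueSeries]:
    """Frame-averaged per-residue RMSD, one profile per simulation.

    Frames are selected by *selector* (state filter or matched random
    subsample; all frames when None), superposed on the anchor atoms of the
    common reference, and the per-residue RMSD against the reference is
    averaged over the selected frames.
    """
    if len(sims) == 0:
        raise ValueError("need at least one simulation")
    out = []
    for i, sim in enumerate(sims):
        idx = (np.arange(sim.n_frames) if selector is None
               else np.asarray(selector(i, sim.n_frames), dtype=int))
        if len(idx) == 0:
            raise SelectionError(f"frame filter selected zero frames in simulation {i}")
        sub = sim.take_frames(idx)
        fitted = superpose(sub, spec, reference=reference)
        res = (reference.residue_numbers() if residues is None
               else np.asarray(residues, dtype=int))
        masks = _residue_atom_masks(fitted, res, include_hydrogens)
        vals = np.empty(len(res))
        ref_xyz = reference.coords[spec.reference_frame]
        for j, r in enumerate(res):
            d = fitted.coords[:, masks[r]] - ref_xyz[masks[r]]
            # RMSD per frame, then averaged over frames
            vals[j] = np.mean(np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1)))
        out.append(ResidueSeries(res, vals, units="Å", n_samples=len(idx)))
    return out


def per_residue_ttest(cmp: GroupComparison) -> ResidueSeries:
    """Two-tailed independent t-test per residue on per-simulation averages.

    Welch's test by default (``equal_var=False``); residues where both
    groups have zero variance and equal means get p = 1 by convention.
    """
    if len(cmp.group_a) < 2 or len(cmp.group_b) < 2:
        raise ValueError("need at least two simulations per group")
    res = cmp.group_a[0].residue_numbers
    for s in cmp.group_a + cmp.group_b:
        if not np.array_equal(s.residue_numbers, res):
            raise ValueError("groups must cover the same residue set")
    a = np.stack([s.values for s in cmp.group_a])
    b = np.stack([s.values for s in cmp.group_b])
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = sstats.ttest_ind(a, b, axis=0, equal_var=cmp.equal_var)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        same_mean = np.isclose(a.mean(axis=0), b.mean(axis=0))
        p[degenerate & same_mean] = 1.0
        p[degenerate & ~same_mean] = 0.0
    return ResidueSeries(res, p, units="p-value",
                         n_samples=len(cmp.group_a) + len(cmp.group_b))


# -- fluctuations ------------------------------------------------------------


def rmsf(ens: FrameEnsemble, residues: Sequence[int] | None = None,
         include_hydrogens: bool = False) -> ResidueSeries:
    """Per-residue RMSF about the time-mean position (pre-superposed frames).

    Per atom: sqrt(mean_t |r(t) − r̄|²); per residue: mean over its atoms.
    """
    if ens.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    if residues is None:
        residues = ens.residue_numbers()
    masks = _residue_atom_masks(ens, residues, include_hydrogens)
    mean_xyz = ens.coords.mean(axis=0)
    dev = ens.coords - mean_xyz
    atom_rmsf = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
    vals = np.array([atom_rmsf[masks[r]].mean() for r in residues])
    return ResidueSeries(np.asarray(residues), vals, units="Å",
                         n_samples=ens.n_frames)


def select_alignment_residues(
    series: ResidueSeries, percentile: float = 75.0
) -> tuple[np.ndarray, float]:
    """Residues with RMSF strictly below the given percentile of the profile.

    The percentile uses linear interpolation between order statistics
    (numpy's default); the cutoff value is returned alongside the residue
    set.  With an all-equal profile every residue is retained.
    """
    if len(series.values) == 0:
        raise ValueError("empty RMSF series")
    cutoff = float(np.percentile(series.values, percentile))
    keep = series.residue_numbers[series.values < cutoff]
    if len(keep) == 0:  # degenerate all-equal profile
        keep = series.residue_numbers.copy()
    return keep, cutoff
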