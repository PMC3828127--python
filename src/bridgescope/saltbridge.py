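"""Per-frame classification of an Arg–Glu ion pair and population summaries.

A frame is called a *salt bridge* when (i) the centroids of the two
side-chain charged groups (guanidinium and carboxylate) are within a cutoff
(default 4.0 Å) of each other, and (ii) at least one side-chain
nitrogen–oxygen pair is within the cutoff.  Frames meeting only (ii) form an
*N–O bridge*; frames meeting neither are *long range*.

Salt-bridge frames are sub-classified by which guanidinium nitrogens pair
with which carboxylate oxygens:

* ``GEOMETRY_A`` — NH1 and NH2 are each within the cutoff of two *distinct*
  Glu side-chain oxygens (bidentate, injective assignment);
* ``GEOMETRY_B`` — otherwise, NE and NH2 are each within the cutoff of
  distinct oxygens;
* ``OTHER_SALT_BRIDGE`` — any remaining salt-bridge arrangement.

A frame satisfying both patterns is GEOMETRY_A (the tighter arrangement);
"within" is inclusive (≤ cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import StructuralCompletenessError
from .structure_io import FrameEnsemble

__all__ = [
    "BridgeCriteria",
    "BridgeState",
    "BridgeSummary",
    "classify_frame",
    "classify_ensemble",
    "centroid_distance",
    "summarize",
]


class BridgeState(Enum):
    """Five mutually exclusive interaction states of the ion pair."""

    GEOMETRY_A = "GEOMETRY_A"
    GEOMETRY_B = "GEOMETRY_B"
    OTHER_SALT_BRIDGE = "OTHER_SALT_BRIDGE"
    N_O_BRIDGE = "N_O_BRIDGE"
    LONG_RANGE = "LONG_RANGE"


@dataclass(frozen=True)
class BridgeCriteria:
    """Geometric cutoffs and atom-set definitions for the classification.

    The defaults follow charged-group definitions in the Kumar–Nussinov
    tradition: guanidinium group {CZ, NE, NH1, NH2}, carboxylate
    {CD, OE1, OE2}; criterion (ii) uses side-chain nitrogens {NE, NH1, NH2}
    against carboxylate oxygens {OE1, OE2}.
    """

    centroid_cutoff: float = 4.0
    no_pair_cutoff: float = 4.0
    arg_centroid_atoms: tuple[str, ...] = ("CZ", "NE", "NH1", "NH2")
    glu_centroid_atoms: tuple[str, ...] = ("CD", "OE1", "OE2")
    arg_nitrogens: tuple[str, ...] = ("NE", "NH1", "NH2")
    glu_oxygens: tuple[str, ...] = ("OE1", "OE2")

    def __post_init__(self):
        if self.centroid_cutoff <= 0 or self.no_pair_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        for s in (self.arg_centroid_atoms, self.glu_centroid_atoms,
                  self.arg_nitrogens, self.glu_oxygens):
            if not s:
                raise ValueError("atom sets must be non-empty")


@dataclass
class BridgeSummary:
    """State populations and per-state Cα-distance statistics."""

    fractions: dict[BridgeState, float]
    n_frames: int
    ca_distance_stats: dict[BridgeState, dict] = field(default_factory=dict)
    labels: list[BridgeState] = field(default_factory=list)


def _atom_xyz(ens: FrameEnsemble, frame: int, residue: int, name: str) -> np.ndarray:
    hits = np.flatnonzero((ens.residue_number == residue) & (ens.atom_name == name))
    if len(hits) == 0:
        raise StructuralCompletenessError(
            f"residue {residue} is missing atom {name} required by the bridge criteria"
        )
    return ens.coords[frame, hits[0]]


def _group(ens, frame, residue, names) -> np.ndarray:
    return np.array([_atom_xyz(ens, frame, residue, n) for n in names])


def centroid_distance(
    ens: FrameEnsemble,
    frame: int,
    pair: tuple[int, int],
    criteria: BridgeCriteria = BridgeCriteria(),
) -> float:
    """Distance (Å) between unweighted centroids of the two charged groups."""
    arg_res, glu_res = pair
    arg = _group(ens, frame, arg_res, criteria.arg_centroid_atoms).mean(axis=0)
    glu = _group(ens, frame, glu_res, criteria.glu_centroid_atoms).mean(axis=0)
    return float(np.linalg.norm(arg - glu))


def _injective_pairing(dist: np.ndarray, cutoff: float, rows: list[int]) -> bool:
    """True if the nitrogens indexed by *rows* can be matched to distinct
    oxygens with every matched distance ≤ cutoff (injective assignment)."""
    n_ox = dist.shape[1]
    if len(rows) > n_ox:
        return False
    # small fixed sizes (≤3 nitrogens, 2 oxygens): brute-force permutations
    from itertools import permutations

    for perm in permutations(range(n_ox), len(rows)):
        if all(dist[r, o] <= cutoff for r, o in zip(rows, perm)):
            return True
    return False


def classify_frame(
    ens: FrameEnsemble,
    frame: int,
    pair: tuple[int, int],
    criteria: BridgeCriteria = BridgeCriteria(),
) -> BridgeState:
    """Classify one frame of the ensemble into one of the five states."""
    arg_res, glu_res = pair
    nitro = _group(ens, frame, arg_res, criteria.arg_nitrogens)
    oxy = _group(ens, frame, glu_res, criteria.glu_oxygens)
    # pairwise N–O distance matrix
    dist = np.linalg.norm(nitro[:, None, :] - oxy[None, :, :], axis=-1)
    pair_contact = bool((dist <= criteria.no_pair_cutoff).any())
    cent_contact = (
        centroid_distance(ens, frame, pair, criteria) <= criteria.centroid_cutoff
    )
    if not pair_contact:
        return BridgeState.LONG_RANGE
    if not cent_contact:
        return BridgeState.N_O_BRIDGE
    names = list(criteria.arg_nitrogens)
    cutoff = criteria.no_pair_cutoff

    def rows_for(wanted: tuple[str, str]) -> list[int] | None:
        try:
            return [names.index(w) for w in wanted]
        except ValueError:
            return None

    rows_a = rows_for(("NH1", "NH2"))
    if rows_a is not None and _injective_pairing(dist, cutoff, rows_a):
        return BridgeState.GEOMETRY_A
    rows_b = rows_for(("NE", "NH2"))
    if rows_b is not None and _injective_pairing(dist, cutoff, rows_b):
        return BridgeState.GEOMETRY_B
    return BridgeState.OTHER_SALT_BRIDGE


def classify_ensemble(
    ens: FrameEnsemble,
    pair: tuple[int, int],
    criteria: BridgeCriteria = BridgeCriteria(),
) -> list[BridgeState]:
    """Classify every frame; one label per frame."""
    return [classify_frame(ens, i, pair, criteria) for i in range(ens.n_frames)]


def summarize(
    ens: FrameEnsemble,
    pair: tuple[int, int],
    criteria: BridgeCriteria = BridgeCriteria(),
    histogram_bins: int = 40,
) -> BridgeSummary:
    """State fractions plus per-state Cα–Cα distance statistics.

    The Cα distance is measured between the CA atoms of the two residues of
    *pair* in every frame; mean, standard deviation and a histogram are
    reported per populated state.
    """
    labels = classify_ensemble(ens, pair, criteria)
    n = ens.n_frames
    fractions = {s: labels.count(s) / n for s in BridgeState}
    arg_res, glu_res = pair
    ca = np.array(
        [
            np.linalg.norm(
                _atom_xyz(ens, i, arg_res, "CA") - _atom_xyz(ens, i, glu_res, "CA")
            )
            for i in range(n)
        ]
    )
    stats: dict[BridgeState, dict] = {}
    lab_arr = np.array([l.value for l in labels], dtype=object)
    for s in BridgeState:
        sel = ca[lab_arr == s.value]
        if len(sel) == 0:
            continue
        counts, edges = np.histogram(sel, bins=histogram_bins)
        stats[s] = {
            "mean": float(sel.mean()),
            "sd": float(sel.std(ddof=0)),
            "n": int(len(sel)),
            "histogram": (counts.tolist(), edges.tolist()),
        }
    return BridgeSummary(fractions=fractions, n_frames=n, ca_distance_stats=stats,
                         labels=labels)
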