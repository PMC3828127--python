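"""Synthetic inputs with known ground truth for every analysis stage.

These generators are statistical emulators, not physical simulators: they
reproduce the *structure* of each input class (state populations and
geometry margins, cone-restricted bond vectors, exponential decays,
fast-exchange dispersion profiles, two-state unfolding curves, alignments
with prescribed column conservation) so that each fitting or classification
stage can be tested against its generating truth.  Every generator is
deterministic under (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .cd_unfold import UnfoldingFit, model_signal
from .conservation import Alignment
from .nmr_relax import (
    ModelFreeParams,
    NmrConstants,
    RelaxationRecord,
    predict_relaxation,
    rex_fast_exchange,
)
from .order_parameter import VectorSeries, cone_model_s2
from .saltbridge import BridgeCriteria, BridgeState
from .structure_io import CdTable, FrameEnsemble, IntensityTable

__all__ = [
    "GeneratorSpec",
    "BRIDGE_TEMPLATES",
    "bridge_template_ensemble",
    "gen_bridge_ensemble",
    "gen_cone_vectors",
    "gen_fluctuating_chain",
    "chain_template",
    "gen_relax_decay",
    "gen_relax_record",
    "gen_dispersion",
    "gen_unfolding",
    "gen_msa",
    "R1_DELAYS_S",
    "R2_DELAYS_S",
    "CPMG_TAU_CP_S",
]

#: Inversion-recovery delays (s) of the reference R1 experiment.
R1_DELAYS_S = np.array([11, 55, 110, 220, 330, 440, 660, 880, 1210]) * 1e-3
#: CPMG-train delays (s) of the reference R2 experiment.
R2_DELAYS_S = np.array([16.5, 33, 49.5, 66, 82.6, 99.1, 115.6, 132.1, 148.6]) * 1e-3
#: Nine τcp values spanning 1–20 ms for relaxation dispersion.
CPMG_TAU_CP_S = np.linspace(1.0, 20.0, 9) * 1e-3


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic data set."""

    kind: str
    parameters: dict = dc_field(default_factory=dict)
    n: int = 0
    seed: int = 0

    _KINDS = ("bridge_ensemble", "cone_vectors", "relax_decay", "dispersion",
              "unfolding", "msa", "fluctuating_chain")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


# -- ion-pair frame ensembles ------------------------------------------------

# Idealised planar guanidinium: CZ at the origin, the three nitrogens at
# 1.33 Å spaced 120 deg in the z=0 plane.
_ARG_SIDE = {
    "CZ": (0.0, 0.0, 0.0),
    "NE": (1.33, 0.0, 0.0),
    "NH1": (-0.665, 1.152, 0.0),
    "NH2": (-0.665, -1.152, 0.0),
}

# Carboxylate placements realising each interaction state, built from ideal
# internal geometry (C–O 1.25 Å, O–C–O 126 deg) and positioned so that every
# defining inequality holds with a comfortable margin (see
# ``classification_margin``).  CA atoms sit off-plane and fix the per-state
# Cα–Cα distance; they play no part in classification.
_CA_SPLIT = {
    BridgeState.GEOMETRY_A: 12.3,
    BridgeState.GEOMETRY_B: 11.6,
    BridgeState.OTHER_SALT_BRIDGE: 11.9,
    BridgeState.N_O_BRIDGE: 13.0,
    BridgeState.LONG_RANGE: 14.5,
}


def _carboxylate(cd_xy: tuple[float, float], angle1_deg: float) -> dict:
    """CD plus two oxygens at 1.25 Å, 126 deg apart, in the z=0 plane."""
    cd = np.array([cd_xy[0], cd_xy[1], 0.0])
    a1 = np.deg2rad(angle1_deg)
    a2 = np.deg2rad(angle1_deg + 126.0)
    oe1 = cd + 1.25 * np.array([np.cos(a1), np.sin(a1), 0.0])
    oe2 = cd + 1.25 * np.array([np.cos(a2), np.sin(a2), 0.0])
    return {"CD": tuple(cd), "OE1": tuple(oe1), "OE2": tuple(oe2)}


def _glu_template(state: BridgeState) -> dict:
    if state is BridgeState.GEOMETRY_A:
        # symmetric bidentate: the two oxygens face NH1/NH2
        return _carboxylate((-3.9, 0.0), -63.0)
    if state is BridgeState.GEOMETRY_B:
        # OE1 toward NE, OE2 toward NH2; NH1 left without a partner
        return _carboxylate((0.35, -4.0), 70.0)
    if state is BridgeState.OTHER_SALT_BRIDGE:
        # only NH2 engages the carboxylate; still centroid-close
        return _carboxylate((-2.065, -3.577), -6.0)
    if state is BridgeState.N_O_BRIDGE:
        # one N–O contact but centroids pulled past the cutoff
        return _carboxylate((-5.2, 0.0), 20.0)
    # LONG_RANGE: far away on the -x side
    return _carboxylate((-8.0, 0.0), 40.0)


def _template_coords(state: BridgeState) -> tuple[np.ndarray, list, list, list]:
    """Coordinates + topology arrays of the 9-atom two-residue template."""
    split = _CA_SPLIT[state]
    glu = _glu_template(state)
    atoms = [
        ("CA", 38, "GLU", (0.0, 0.0, -split / 2)),
        ("CD", 38, "GLU", glu["CD"]),
        ("OE1", 38, "GLU", glu["OE1"]),
        ("OE2", 38, "GLU", glu["OE2"]),
        ("CA", 62, "ARG", (0.0, 0.0, split / 2)),
        ("CZ", 62, "ARG", _ARG_SIDE["CZ"]),
        ("NE", 62, "ARG", _ARG_SIDE["NE"]),
        ("NH1", 62, "ARG", _ARG_SIDE["NH1"]),
        ("NH2", 62, "ARG", _ARG_SIDE["NH2"]),
    ]
    xyz = np.array([a[3] for a in atoms])
    return (xyz, [a[0] for a in atoms], [a[1] for a in atoms], [a[2] for a in atoms])


BRIDGE_TEMPLATES = {s: _template_coords(s) for s in BridgeState}


def bridge_template_ensemble(state: BridgeState) -> FrameEnsemble:
    """One-frame ensemble holding the noiseless template of a state."""
    xyz, names, resnum, resname = BRIDGE_TEMPLATES[state]
    return FrameEnsemble(xyz[None], names, resnum, resname, ["A"] * len(names))


def classification_margin(state: BridgeState,
                          criteria: BridgeCriteria = BridgeCriteria()) -> float:
    """Smallest |distance − cutoff| over every comparison the classifier makes.

    As long as coordinate jitter cannot move any compared distance across
    its cutoff, the generated label is correct by construction.
    """
    xyz, names, resnum, _ = BRIDGE_TEMPLATES[state]
    pos = {(r, n): xyz[i] for i, (n, r) in enumerate(zip(names, resnum))}
    dists = []
    for nn in criteria.arg_nitrogens:
        for on in criteria.glu_oxygens:
            dists.append(np.linalg.norm(pos[(62, nn)] - pos[(38, on)]))
    arg_c = np.mean([pos[(62, n)] for n in criteria.arg_centroid_atoms], axis=0)
    glu_c = np.mean([pos[(38, n)] for n in criteria.glu_centroid_atoms], axis=0)
    margins = [abs(d - criteria.no_pair_cutoff) for d in dists]
    margins.append(abs(np.linalg.norm(arg_c - glu_c) - criteria.centroid_cutoff))
    return float(min(margins))


def gen_bridge_ensemble(
    populations: dict[BridgeState, float],
    n_frames: int,
    seed: int,
    jitter_sigma: float = 0.05,
    rigid_motion: bool = False,
) -> tuple[FrameEnsemble, list[BridgeState]]:
    """Frame ensemble with prescribed interaction-state populations.

    Each frame is a state template plus isotropic Gaussian jitter of
    ``jitter_sigma`` Å per coordinate; optionally a random rigid rotation +
    translation of the whole frame.  The true per-frame labels are returned
    alongside.  A jitter too large for the template margins (2σ criterion)
    is refused.
    """
    states = list(populations.keys())
    probs = np.array([populations[s] for s in states], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("populations must be non-negative and sum to 1")
    for s, p in populations.items():
        if p > 0 and 2 * jitter_sigma >= classification_margin(s):
            raise ValueError(
                f"jitter σ={jitter_sigma} too large for state {s.value} "
                f"(margin {classification_margin(s):.3f} Å)"
            )
    rng = np.random.default_rng(seed)
    labels_idx = rng.choice(len(states), size=n_frames, p=probs)
    _, names, resnum, resname = BRIDGE_TEMPLATES[states[0]]
    frames = np.empty((n_frames, len(names), 3))
    for i, li in enumerate(labels_idx):
        xyz = BRIDGE_TEMPLATES[states[li]][0].copy()
        xyz += rng.normal(0.0, jitter_sigma, size=xyz.shape)
        if rigid_motion:
            from scipy.spatial.transform import Rotation

            rot = Rotation.random(rng=rng).as_matrix()
            xyz = xyz @ rot.T + rng.uniform(-20, 20, size=3)
        frames[i] = xyz
    ens = FrameEnsemble(frames, names, resnum, resname, ["A"] * len(names))
    return ens, [states[i] for i in labels_idx]


# -- bond-vector series ------------------------------------------------------


def gen_cone_vectors(theta0_rad: float, n: int, seed: int) -> tuple[VectorSeries, float]:
    """Unit vectors uniform (per solid angle) inside a cone about z.

    Returns the series and the closed-form S² = [cosθ₀(1+cosθ₀)/2]².
    """
    if not 0 <= theta0_rad < np.pi:
        raise ValueError("cone semi-angle must lie in [0, π)")
    if n < 2:
        raise ValueError("need at least two vectors")
    rng = np.random.default_rng(seed)
    cos_t = rng.uniform(np.cos(theta0_rad), 1.0, size=n)
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    v = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
    return VectorSeries(residue_number=0, vectors=v), cone_model_s2(theta0_rad)


# -- fluctuating toy chain ---------------------------------------------------


def chain_template(n_residues: int = 100) -> FrameEnsemble:
    """Static toy chain: helical Cα trace plus one side atom per residue.

    Helix-like geometry (1.5 Å rise, 100° twist, 2.3 Å radius) keeps any
    contiguous anchor block non-collinear, as rigid superposition requires.
    Residues are numbered 1..n; the template doubles as the common
    reference ("initial") frame for RMSD analyses.
    """
    names, resnum, resname, xyz = [], [], [], []
    for i in range(1, n_residues + 1):
        phi = np.deg2rad(100.0 * i)
        ca = (1.5 * i, 2.3 * np.cos(phi), 2.3 * np.sin(phi))
        xyz.append(ca)
        names.append("CA")
        resnum.append(i)
        resname.append("ALA")
        xyz.append((ca[0], ca[1] + 1.5 * np.cos(phi), ca[2] + 1.5 * np.sin(phi)))
        names.append("CB")
        resnum.append(i)
        resname.append("ALA")
    return FrameEnsemble(np.array(xyz)[None], names, resnum, resname,
                         ["A"] * len(names))


def gen_fluctuating_chain(
    amplitudes: np.ndarray,
    n_frames: int,
    seed: int,
    anchor: tuple[int, int] = (55, 68),
    anchor_amplitude: float = 0.02,
) -> FrameEnsemble:
    """Toy-chain trajectory with per-residue isotropic Gaussian displacements.

    ``amplitudes[r-1]`` is the displacement σ (Å per axis) of residue r;
    residues inside the ``anchor`` range are overridden with a near-static
    σ, emulating a rigid binding-site block used for frame alignment.
    """
    template = chain_template(len(amplitudes))
    amps = np.asarray(amplitudes, dtype=float)
    if np.any(amps <= 0):
        raise ValueError("amplitudes must be positive")
    per_atom = amps[template.residue_number - 1].copy()
    in_anchor = (template.residue_number >= anchor[0]) & (template.residue_number <= anchor[1])
    per_atom[in_anchor] = anchor_amplitude
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=(n_frames, template.n_atoms, 3))
    frames = template.coords[0][None] + noise * per_atom[None, :, None]
    return FrameEnsemble(frames, template.atom_name, template.residue_number,
                         template.residue_name, template.chain_id)


# -- NMR tables --------------------------------------------------------------


def gen_relax_decay(
    rate: float,
    n: int = 0,
    seed: int = 0,
    i0: float = 100.0,
    delays: np.ndarray | None = None,
    noise_frac: float = 0.0,
    modality: str = "R1",
    residue_number: int = 1,
) -> IntensityTable:
    """Mono-exponential decay sampled on a delay grid (default: R1 grid)."""
    t = np.asarray(delays if delays is not None else
                   (R1_DELAYS_S if modality == "R1" else R2_DELAYS_S))
    y = i0 * np.exp(-rate * t)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        y = y * (1 + rng.normal(0.0, noise_frac, size=len(t)))
        y = np.clip(y, 1e-9, None)
    return IntensityTable(residue_number, list(zip(t, y)), modality=modality)


def gen_relax_record(
    params: ModelFreeParams,
    seed: int = 0,
    noise_frac: float = 0.0,
    field_mhz: float = 600.0,
    residue_number: int = 1,
    constants: NmrConstants = NmrConstants(),
) -> RelaxationRecord:
    """(R₁, R₂, NOE) from the forward model, optionally with relative noise."""
    r1, r2, noe = predict_relaxation(params, field_mhz, constants)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        r1 *= 1 + rng.normal(0, noise_frac)
        r2 *= 1 + rng.normal(0, noise_frac)
        noe *= 1 + rng.normal(0, noise_frac)
    return RelaxationRecord(
        residue_number, r1=r1, r2=r2, noe=min(noe, 1.1),
        r1_err=noise_frac * abs(r1), r2_err=noise_frac * abs(r2),
        noe_err=noise_frac * abs(noe), field_mhz=field_mhz,
    )


def gen_dispersion(
    phi_ex: float,
    tau_ex: float,
    seed: int = 0,
    tau_cp: np.ndarray | None = None,
    total_period: float = 0.080,
    r2_base: float = 10.0,
    i0: float = 100.0,
    noise_frac: float = 0.0,
    residue_number: int = 1,
) -> IntensityTable:
    """CPMG intensity series from a fast-exchange R_ex(τcp) profile.

    I(τcp) = I₀ exp(−[R₂₀ + R_ex(τcp)]·T) with the constant total period T.
    """
    t = np.asarray(tau_cp if tau_cp is not None else CPMG_TAU_CP_S)
    rex = rex_fast_exchange(phi_ex, tau_ex, t)
    y = i0 * np.exp(-(r2_base + rex) * total_period)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y * (1 + rng.normal(0, noise_frac, size=len(t))), 1e-9, None)
    return IntensityTable(residue_number, list(zip(t, y)), modality="CPMG")


# -- CD ----------------------------------------------------------------------


def gen_unfolding(
    fit: UnfoldingFit,
    seed: int = 0,
    urea: np.ndarray | None = None,
    noise_sigma: float = 0.0,
) -> CdTable:
    """Unfolding curve from six two-state parameters on a urea grid."""
    u = np.asarray(urea if urea is not None else np.linspace(0.0, 9.0, 50))
    y = model_signal(fit, u)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=len(u))
    return CdTable(points=list(zip(u, y)), temperature_K=fit.temperature_K)


# -- alignments --------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def gen_msa(
    column_frequencies: np.ndarray,
    n_rows: int,
    seed: int,
    class_label: str = "F7",
) -> tuple[Alignment, list[str]]:
    """Alignment whose column c has the consensus residue at the given
    expected frequency (remaining mass spread over the other residues).

    Returns the alignment and the consensus residue per column.
    """
    freqs = np.asarray(column_frequencies, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    consensus = [_AA[rng.integers(len(_AA))] for _ in freqs]
    rows = []
    for i in range(n_rows):
        chars = []
        for c, f in enumerate(freqs):
            if rng.random() < f:
                chars.append(consensus[c])
            else:
                others = [a for a in _AA if a != consensus[c]]
                chars.append(others[rng.integers(len(others))])
        rows.append((f"seq{i:04d}", "".join(chars)))
    return Alignment(records=rows, class_label=class_label), consensus
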