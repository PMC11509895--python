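"""Synthetic conformational ensembles with known statistical structure.

Two independent generators stand in for molecular-dynamics trajectories:

* a dihedral-space generator (:func:`sample_dihedral_ensemble`) that draws,
  per frame, a Protein Block label for each conformational segment, places
  the prototype's central (phi, psi) at every segment position and adds
  wrapped Gaussian angular noise.  Segments switch conformers collectively
  by default, emulating a loop hopping between discrete local-conformer
  states (the regime in which the 5-residue assignment window recovers the
  sampled label); per-position independent sampling is available for tests
  that only need marginal statistics.
* a coordinate-space generator (:func:`perturb_coordinates`) that adds
  isotropic per-residue Gaussian displacement plus a random global
  rigid-body motion per frame to a single reference conformation — the
  harmonic test-bed for RMSD/RMSF.

:func:`build_ideal_conformation` constructs ideal helix/strand backbones
from internal coordinates so the dihedral extraction and PB assignment can
be validated against known targets; :func:`analytic_neq` gives the exact
Neq of a generating distribution for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .protein_blocks import (
    PB_LABELS,
    DihedralSeries,
    PBReferenceTable,
    load_reference_table,
    wrap_degrees,
)
from .structure_io import ConformationalEnsemble

# Standard backbone internal coordinates (A, degrees).
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
         "CA-CB": 1.530, "CB-SG": 1.808}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.5, "C-CA-CB": 110.1, "CA-CB-SG": 114.0}
_OMEGA = 180.0  # trans peptide bond

IDEAL_PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-120.0, 135.0)}

_THREE = {"A": "ALA", "G": "GLY", "C": "CYS"}


@dataclass
class Segment:
    """A run of residues sharing one conformer distribution.

    ``start``/``end`` are inclusive 0-based residue indices; ``distribution``
    maps PB labels to probabilities (must sum to 1).
    """

    start: int
    end: int
    distribution: dict[str, float]

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"inverted segment {self.start}-{self.end}")
        unknown = set(self.distribution) - set(PB_LABELS)
        if unknown:
            raise ValueError(f"unknown PB label(s) in distribution: {unknown}")
        total = sum(self.distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment distribution sums to {total}, not 1")
        if any(p < 0 for p in self.distribution.values()):
            raise ValueError("negative probability in segment distribution")


@dataclass
class SyntheticEnsembleConfig:
    """Study-condition knobs of the dihedral-space generator.

    Residues not covered by any segment sit in the rigid background
    conformer ``background_pb`` (default ``m``, the helix prototype).
    ``sigma_deg`` is the wrapped-Gaussian angular noise applied to every
    dihedral independently; 10 degrees keeps well-separated prototype
    basins (e.g. m vs d) essentially non-overlapping while exercising the
    angle wrap.  ``coupled=True`` draws one conformer per segment per frame
    (collective switching); ``False`` draws independently per position.
    """

    n_residues: int
    n_frames: int
    seed: int
    segments: list[Segment] = field(default_factory=list)
    background_pb: str = "m"
    sigma_deg: float = 10.0
    coupled: bool = True

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues for PB analysis")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.sigma_deg < 0:
            raise ValueError("sigma_deg must be non-negative")
        spans = sorted((s.start, s.end) for s in self.segments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("overlapping segments")
        for s in self.segments:
            if s.start < 0 or s.end >= self.n_residues:
                raise ValueError(f"segment {s.start}-{s.end} out of range")


def sample_dihedral_ensemble(
    config: SyntheticEnsembleConfig,
    table: PBReferenceTable | None = None,
    return_labels: bool = False,
):
    """Draw a dihedral ensemble from per-segment conformer distributions.

    Per frame, each segment draws a PB label from its distribution (one
    draw for the whole segment when ``config.coupled``, else one per
    position); each position takes the drawn prototype's central
    (phi, psi) plus independent wrapped Gaussian noise of width
    ``sigma_deg``.  Bit-reproducible for a fixed seed.

    Returns a :class:`DihedralSeries`; with ``return_labels=True`` also the
    (F, R) matrix of sampled ground-truth labels.
    """
    if table is None:
        table = load_reference_table()
    rng = np.random.default_rng(config.seed)
    F, R = config.n_frames, config.n_residues

    label_idx = np.full(
        (F, R), PB_LABELS.index(config.background_pb), dtype=np.int64
    )
    for seg in config.segments:
        labels = sorted(seg.distribution)
        probs = np.array([seg.distribution[l] for l in labels])
        codes = np.array([PB_LABELS.index(l) for l in labels])
        width = seg.end - seg.start + 1
        if config.coupled:
            draws = rng.choice(codes, size=F, p=probs)
            label_idx[:, seg.start:seg.end + 1] = draws[:, None]
        else:
            draws = rng.choice(codes, size=(F, width), p=probs)
            label_idx[:, seg.start:seg.end + 1] = draws

    central = table.central_phi_psi  # (16, 2)
    phi = central[label_idx, 0]
    psi = central[label_idx, 1]
    if config.sigma_deg > 0:
        phi = phi + rng.normal(0.0, config.sigma_deg, size=phi.shape)
        psi = psi + rng.normal(0.0, config.sigma_deg, size=psi.shape)
    phi = np.asarray(wrap_degrees(phi))
    psi = np.asarray(wrap_degrees(psi))
    phi[:, 0] = np.nan   # no preceding residue
    psi[:, -1] = np.nan  # no following residue

    series = DihedralSeries(phi=phi, psi=psi, positions=list(range(1, R + 1)))
    if return_labels:
        symbols = np.array(PB_LABELS, dtype="<U1")[label_idx]
        return series, symbols
    return series


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d at the given internal coordinates from frame a-b-c."""
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(tau),
        bond * math.sin(theta) * math.sin(tau),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_conformation(
    kind: str,
    n_residues: int,
    sequence: str | None = None,
    system_label: str | None = None,
) -> ConformationalEnsemble:
    """Single-frame ideal backbone with uniform (phi, psi).

    ``kind`` is ``"helix"`` ((-57, -47)) or ``"strand"`` ((-120, +135)).
    ``sequence`` is an optional one-letter string over {A, G, C} (default
    poly-alanine): non-glycine residues get a CB atom, cysteines also an SG,
    so side-chain truncation mutants can be exercised.  Backbone geometry
    uses standard bond lengths/angles with trans peptide bonds; extracted
    phi/psi reproduce the targets to well under 0.5 degrees.
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    try:
        phi0, psi0 = IDEAL_PHI_PSI[kind]
    except KeyError:
        raise ValueError(f"kind must be 'helix' or 'strand', got {kind!r}")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length does not match n_residues")
    if set(sequence) - set(_THREE):
        raise ValueError("sequence may only contain A, G, C")

    # chain of N, CA, C atoms placed by successive torsions psi/omega/phi
    n_at = [np.array([0.0, 0.0, 0.0])]
    ca_at = [np.array([_BOND["N-CA"], 0.0, 0.0])]
    theta = math.radians(_ANGLE["N-CA-C"])
    c_at = [ca_at[0] + _BOND["CA-C"] * np.array(
        [-math.cos(theta), math.sin(theta), 0.0]
    )]
    for i in range(1, n_residues):
        n_next = _nerf(n_at[-1], ca_at[-1], c_at[-1],
                       _BOND["C-N"], _ANGLE["CA-C-N"], psi0)
        ca_next = _nerf(ca_at[-1], c_at[-1], n_next,
                        _BOND["N-CA"], _ANGLE["C-N-CA"], _OMEGA)
        c_next = _nerf(c_at[-1], n_next, ca_next,
                       _BOND["CA-C"], _ANGLE["N-CA-C"], phi0)
        n_at.append(n_next)
        ca_at.append(ca_next)
        c_at.append(c_next)

    residues: list[tuple[int, str]] = []
    atom_names: list[list[str]] = []
    coords: list[np.ndarray] = []
    for i, one in enumerate(sequence):
        resname = _THREE[one]
        names = ["N", "CA", "C", "O"]
        # carbonyl O opposite the next N: torsion psi + 180 about N-CA-C
        psi_here = psi0 if i < n_residues - 1 else psi0  # uniform by design
        o = _nerf(n_at[i], ca_at[i], c_at[i],
                  _BOND["C-O"], _ANGLE["CA-C-O"], psi_here + 180.0)
        res_coords = [n_at[i], ca_at[i], c_at[i], o]
        if resname != "GLY":
            cb = _nerf(c_at[i], n_at[i], ca_at[i],
                       _BOND["CA-CB"], _ANGLE["C-CA-CB"], 122.6)
            names.append("CB")
            res_coords.append(cb)
        if resname == "CYS":
            cb = res_coords[-1]
            sg = _nerf(n_at[i], ca_at[i], cb,
                       _BOND["CB-SG"], _ANGLE["CA-CB-SG"], -60.0)
            names.append("SG")
            res_coords.append(sg)
        residues.append((i + 1, resname))
        atom_names.append(names)
        coords.extend(res_coords)

    frame = np.asarray(coords)[None, :, :]
    return ConformationalEnsemble(
        system_label=system_label or f"ideal-{kind}",
        residues=residues,
        atom_names=atom_names,
        coords=frame,
    )


def perturb_coordinates(
    reference: ConformationalEnsemble,
    amplitudes,
    n_frames: int,
    seed: int,
    rigid_motion: bool = True,
) -> ConformationalEnsemble:
    """Harmonic ensemble: reference + per-residue Gaussian displacement.

    Each frame displaces every residue rigidly by an isotropic Gaussian
    vector with that residue's amplitude (standard deviation per Cartesian
    component, in A), then applies a random global rotation and translation.
    The expected RMSF of residue i is amplitudes[i] * sqrt(3).
    Deterministic for a fixed seed.
    """
    if reference.n_frames != 1:
        raise ValueError("reference must be a single-frame ensemble")
    amplitudes = np.asarray(amplitudes, float)
    if amplitudes.shape != (reference.n_residues,):
        raise ValueError(
            f"need one amplitude per residue "
            f"({reference.n_residues}), got {amplitudes.shape}"
        )
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be non-negative")

    rng = np.random.default_rng(seed)
    base = reference.coords[0]
    atoms_per_res = [len(names) for names in reference.atom_names]
    res_of_atom = np.repeat(np.arange(reference.n_residues), atoms_per_res)

    disp = rng.normal(
        0.0, 1.0, size=(n_frames, reference.n_residues, 3)
    ) * amplitudes[None, :, None]
    frames = base[None, :, :] + disp[:, res_of_atom, :]

    if rigid_motion:
        rots = Rotation.random(n_frames, rng=rng).as_matrix()
        trans = rng.uniform(-20.0, 20.0, size=(n_frames, 3))
        center = base.mean(axis=0)
        frames = np.einsum(
            "bij,bnj->bni", rots, frames - center
        ) + center + trans[:, None, :]

    return ConformationalEnsemble(
        system_label=reference.system_label + "+harmonic",
        residues=list(reference.residues),
        atom_names=[list(a) for a in reference.atom_names],
        coords=frames,
        chain_id=reference.chain_id,
    )


def analytic_neq(distribution: dict[str, float]) -> float:
    """Exact Neq of a generating conformer distribution."""
    unknown = set(distribution) - set(PB_LABELS)
    if unknown:
        raise ValueError(f"unknown PB label(s): {unknown}")
    p = np.array([v for v in distribution.values() if v > 0], float)
    if np.any(p < 0) or abs(p.sum() - sum(distribution.values())) > 1e-12:
        raise ValueError("negative probabilities")
    if abs(sum(distribution.values()) - 1.0) > 1e-9:
        raise ValueError("distribution not normalised")
    return float(np.exp(-np.sum(p * np.log(p))))


def analytic_delta_pb(
    dist1: dict[str, float], dist2: dict[str, float]
) -> float:
    """Exact L1 distance between two generating conformer distributions."""
    for d in (dist1, dist2):
        if abs(sum(d.values()) - 1.0) > 1e-9:
            raise ValueError("distribution not normalised")
    labels = set(dist1) | set(dist2)
    return float(sum(abs(dist1.get(l, 0.0) - dist2.get(l, 0.0)) for l in labels))
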