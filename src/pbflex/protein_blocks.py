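"""Protein Blocks (PB) assignment from backbone dihedrals.

Protein Blocks are a structural alphabet of 16 prototype local backbone
conformations, labelled ``a`` through ``p``.  Each prototype is defined by
eight reference dihedral angles over a five-residue window centred on the
assigned residue:

    psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1), phi(i+2)

A residue is assigned the label of the prototype minimising the angular
dissimilarity (RMSDA: sum of squared differences, each wrapped to
(-180, 180]) between its window and the prototype's reference angles.
Prototypes ``m`` and ``d`` approximate the core alpha-helix and the central
beta-strand.  Positions whose window contains an undefined dihedral — always
the two first and two last residues of a chain, plus anything adjacent to a
chain break or a missing backbone atom — carry the out-of-alphabet symbol
``Z`` and are excluded from all frequency denominators.

The 16x8 reference-angle table ships as package data
(``data/pb_reference_angles.csv``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 16 PB labels, in alphabetical (tie-break) order.
PB_LABELS = tuple("abcdefghijklmnop")

#: Symbol for unassignable positions.
UNASSIGNED = "Z"

#: Column order of the 8-angle window.
WINDOW_ANGLES = (
    "psi_m2", "phi_m1", "psi_m1", "phi", "psi", "phi_p1", "psi_p1", "phi_p2",
)

#: CA(i)-CA(i+1) distance above which the chain is considered broken (A).
CHAIN_BREAK_CUTOFF = 4.5


def wrap_degrees(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    wrapped = np.remainder(np.asarray(angle, float) + 180.0, 360.0) - 180.0
    # remainder maps -180 -> -180; move it to +180 to close the interval
    return np.where(wrapped == -180.0, 180.0, wrapped)


def torsion_angle(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    Returns a value in (-180, 180]; ``nan`` when three consecutive points
    are (numerically) collinear or two consecutive points coincide, which
    leaves the angle undefined.
    """
    out = _torsion_batch(
        np.asarray(p1, float)[None],
        np.asarray(p2, float)[None],
        np.asarray(p3, float)[None],
        np.asarray(p4, float)[None],
    )
    return float(out[0])


def _torsion_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorised torsion over leading axes; inputs (..., 3), output (...)."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.einsum("...i,...i->...", n1, n2)
    y = b2n * np.einsum("...i,...i->...", b1, n2)
    angle = np.degrees(np.arctan2(y, x))
    degenerate = (np.linalg.norm(n1, axis=-1) < 1e-9) | (
        np.linalg.norm(n2, axis=-1) < 1e-9
    )
    angle = np.where(degenerate, np.nan, angle)
    return np.asarray(wrap_degrees(angle))


@dataclass
class DihedralSeries:
    """Per-frame, per-residue phi/psi backbone dihedrals in degrees.

    ``phi`` and ``psi`` have shape (F, R); undefined angles are ``nan``
    (phi of the first residue and psi of the last are always undefined).
    ``positions`` carries the author sequence numbers of the R residues.
    """

    phi: np.ndarray
    psi: np.ndarray
    positions: list[int]

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, float))
        self.psi = np.atleast_2d(np.asarray(self.psi, float))
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi shape mismatch")
        if self.phi.shape[1] != len(self.positions):
            raise ValueError("positions length does not match angle arrays")
        for name, arr in (("phi", self.phi), ("psi", self.psi)):
            defined = arr[np.isfinite(arr)]
            if defined.size and (
                defined.min() <= -180.0 or defined.max() > 180.0
            ):
                raise ValueError(f"{name} contains values outside (-180, 180]")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]

    def defined(self) -> np.ndarray:
        """Boolean (F, R, 2) mask of defined (phi, psi)."""
        return np.stack([np.isfinite(self.phi), np.isfinite(self.psi)], axis=-1)


@dataclass
class PBReferenceTable:
    """The 16 PB prototypes: label -> 8 reference angles (degrees)."""

    labels: tuple[str, ...]
    angles: np.ndarray  # (16, 8)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, float)
        if tuple(self.labels) != PB_LABELS:
            raise ValueError("reference table must cover labels a..p in order")
        if self.angles.shape != (16, 8):
            raise ValueError(f"expected (16, 8) angles, got {self.angles.shape}")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.angles[PB_LABELS.index(label)]

    @property
    def central_phi_psi(self) -> np.ndarray:
        """(16, 2) array of each prototype's central (phi, psi)."""
        return self.angles[:, [3, 4]]


def load_reference_table() -> PBReferenceTable:
    """Load the packaged canonical 16x8 PB reference-angle table."""
    with resources.files("pbflex.data").joinpath(
        "pb_reference_angles.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index("pb").loc[list(PB_LABELS), list(WINDOW_ANGLES)]
    return PBReferenceTable(PB_LABELS, df.to_numpy(float))


def extract_phi_psi(ensemble) -> DihedralSeries:
    """Compute phi/psi for every frame and residue of an ensemble.

    phi(i) is the torsion C(i-1)-N(i)-CA(i)-C(i); psi(i) is
    N(i)-CA(i)-C(i)-N(i+1).  Dihedrals spanning a chain break (consecutive
    CA-CA distance above :data:`CHAIN_BREAK_CUTOFF`) are undefined.
    """
    n = ensemble.atom_coords("N")
    ca = ensemble.atom_coords("CA")
    c = ensemble.atom_coords("C")
    F, R, _ = ca.shape

    phi = np.full((F, R), np.nan)
    psi = np.full((F, R), np.nan)
    if R >= 2:
        phi[:, 1:] = _torsion_batch(c[:, :-1], n[:, 1:], ca[:, 1:], c[:, 1:])
        psi[:, :-1] = _torsion_batch(n[:, :-1], ca[:, :-1], c[:, :-1], n[:, 1:])
        gap = np.linalg.norm(ca[:, 1:] - ca[:, :-1], axis=-1) > CHAIN_BREAK_CUTOFF
        if gap.any():
            logger.warning(
                "chain break(s) detected in %s at %d frame/bond pairs",
                getattr(ensemble, "system_label", "<ensemble>"),
                int(gap.sum()),
            )
            phi[:, 1:][gap] = np.nan
            psi[:, :-1][gap] = np.nan
    return DihedralSeries(phi=phi, psi=psi, positions=list(ensemble.positions))


def rmsda(window, prototype) -> float:
    """Angular dissimilarity: sum of squared wrapped angle differences.

    Both arguments are 8-vectors in degrees.  The result is >= 0, equals 0
    iff all angles agree modulo 360 degrees, and is ``nan`` when the window
    contains an undefined (``nan``) angle.
    """
    window = np.asarray(window, float)
    prototype = np.asarray(prototype, float)
    if window.shape != (8,) or prototype.shape != (8,):
        raise ValueError("rmsda expects two 8-angle vectors")
    diff = wrap_degrees(window - prototype)
    return float(np.sum(diff * diff))


def assign_pb(window, table: PBReferenceTable) -> str:
    """Assign one 8-angle window to its nearest PB prototype.

    Ties are broken alphabetically; any undefined angle yields ``Z``.
    """
    window = np.asarray(window, float)
    if not np.all(np.isfinite(window)):
        return UNASSIGNED
    diff = wrap_degrees(window[None, :] - table.angles)
    dist = np.sum(diff * diff, axis=1)
    return table.labels[int(np.argmin(dist))]


@dataclass
class PBSequenceSet:
    """F x R matrix of PB symbols over {a..p} plus ``Z`` for unassignable."""

    labels: np.ndarray  # (F, R) of single characters
    positions: list[int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D frame x residue matrix")
        if self.labels.shape[1] != len(self.positions):
            raise ValueError("positions length mismatch")
        allowed = set(PB_LABELS) | {UNASSIGNED}
        seen = set(np.unique(self.labels))
        if not seen <= allowed:
            raise ValueError(f"invalid PB symbols: {sorted(seen - allowed)}")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]

    def frame_strings(self) -> list[str]:
        return ["".join(row) for row in self.labels]

    def to_fasta(self, path, name: str = "frame") -> None:
        """Write one FASTA-like record of PB symbols per frame."""
        with open(path, "w") as fh:
            for i, s in enumerate(self.frame_strings()):
                fh.write(f">{name}_{i}\n{s}\n")


def assign_ensemble(
    dihedrals: DihedralSeries, table: PBReferenceTable
) -> PBSequenceSet:
    """Assign a PB label to every residue of every frame.

    The first two and last two residues are always ``Z`` (their window is
    incomplete); interior residues are ``Z`` exactly when a window dihedral
    is undefined.
    """
    F, R = dihedrals.phi.shape
    out = np.full((F, R), UNASSIGNED, dtype="<U1")
    if R < 5:
        return PBSequenceSet(out, list(dihedrals.positions))

    # windows[f, i] = (psi[i-2], phi[i-1], psi[i-1], phi[i], psi[i],
    #                  phi[i+1], psi[i+1], phi[i+2]) for i in 2..R-3
    phi, psi = dihedrals.phi, dihedrals.psi
    windows = np.stack(
        [
            psi[:, 0:R - 4], phi[:, 1:R - 3], psi[:, 1:R - 3],
            phi[:, 2:R - 2], psi[:, 2:R - 2],
            phi[:, 3:R - 1], psi[:, 3:R - 1], phi[:, 4:R],
        ],
        axis=-1,
    )  # (F, R-4, 8)
    valid = np.all(np.isfinite(windows), axis=-1)

    best = np.zeros(windows.shape[:2], dtype=np.int64)
    best_dist = np.full(windows.shape[:2], np.inf)
    for k in range(16):  # one prototype at a time keeps memory flat
        diff = wrap_degrees(windows - table.angles[k])
        dist = np.einsum("fri,fri->fr", diff, diff)
        better = dist < best_dist  # strict: earlier (alphabetical) label wins ties
        best = np.where(better, k, best)
        best_dist = np.where(better, dist, best_dist)

    symbols = np.array(table.labels, dtype="<U1")[best]
    out[:, 2:R - 2] = np.where(valid, symbols, UNASSIGNED)
    z_rate = float(np.mean(out == UNASSIGNED))
    logger.info("assigned %d frames x %d residues; Z rate %.3f", F, R, z_rate)
    return PBSequenceSet(out, list(dihedrals.positions))


@dataclass
class PBFrequencyProfile:
    """Per-position PB occurrence counts and frequencies.

    ``counts`` is (R, 16) over labels a..p; ``observed`` is the per-position
    number of non-Z frames.  Frequencies are counts / observed; positions
    with no observed frame are flagged unobserved and carry ``nan``
    frequencies.
    """

    positions: list[int]
    counts: np.ndarray  # (R, 16) ints
    observed: np.ndarray = field(default=None)  # (R,) ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 16:
            raise ValueError(f"counts must be (R, 16), got {self.counts.shape}")
        if self.counts.shape[0] != len(self.positions):
            raise ValueError("positions length mismatch")
        if self.observed is None:
            self.observed = self.counts.sum(axis=1)
        self.observed = np.asarray(self.observed, dtype=np.int64)

    @property
    def n_positions(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """(R, 16) frequency matrix; ``nan`` rows at unobserved positions."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.counts / self.observed[:, None]
        return np.where(self.observed[:, None] > 0, f, np.nan)

    @property
    def unobserved(self) -> np.ndarray:
        """(R,) boolean mask of positions with no assignable frame."""
        return self.observed == 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.frequencies, index=self.positions, columns=list(PB_LABELS)
        )
        df.index.name = "position"
        df["observed_frames"] = self.observed
        return df

    @classmethod
    def pool(cls, profiles: list["PBFrequencyProfile"]) -> "PBFrequencyProfile":
        """Pool counts across replicates before normalisation."""
        first = profiles[0]
        for p in profiles[1:]:
            if p.positions != first.positions:
                raise ValueError("cannot pool profiles over different positions")
        counts = np.sum([p.counts for p in profiles], axis=0)
        return cls(list(first.positions), counts)


def pb_frequency_profile(pbs: PBSequenceSet) -> PBFrequencyProfile:
    """Count PB occurrences per position across frames.

    f_x(i) = count of label x at position i / number of non-Z frames at i.
    """
    counts = np.zeros((pbs.n_residues, 16), dtype=np.int64)
    for k, label in enumerate(PB_LABELS):
        counts[:, k] = np.sum(pbs.labels == label, axis=0)
    return PBFrequencyProfile(list(pbs.positions), counts)
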