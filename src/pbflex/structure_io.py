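"""Multi-model PDB I/O, side-chain-truncation mutants and region annotation.

The central container is :class:`ConformationalEnsemble`: the conformations of
one system (e.g. frames saved from a trajectory, or the models of an NMR-style
multi-model file) for a single chain, with a fixed residue/atom composition
across frames.  Residues are identified by the author sequence numbering of
the source PDB file throughout; internal array indices are 0-based.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import zip_longest

import numpy as np
import yaml
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

#: Backbone atoms that must be present in every frame of every residue.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class StructureError(ValueError):
    """Raised on malformed or inconsistent structural input."""


@dataclass
class ConformationalEnsemble:
    """Per-frame, per-residue coordinates of one system.

    Parameters
    ----------
    system_label : str
        Free-text name of the system (e.g. ``"wild-type"`` or ``"32G-99G"``).
    residues : list of (int, str)
        Ordered ``(author_seq_number, three_letter_name)`` pairs.
    atom_names : list of list of str
        Per-residue ordered atom labels; identical across frames.
    coords : ndarray, shape (F, A_total, 3)
        Coordinates in Angstrom for every frame, atoms flattened in residue
        order.
    chain_id : str
        Chain identifier used when writing PDB output.
    frame_spacing_ps : float or None
        Time between consecutive frames in picoseconds (metadata only).
    """

    system_label: str
    residues: list[tuple[int, str]]
    atom_names: list[list[str]]
    coords: np.ndarray
    chain_id: str = "A"
    frame_spacing_ps: float | None = None
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(
                f"coords must have shape (F, A, 3), got {self.coords.shape}"
            )
        counts = [len(names) for names in self.atom_names]
        if len(counts) != len(self.residues):
            raise StructureError("atom_names and residues length mismatch")
        if sum(counts) != self.coords.shape[1]:
            raise StructureError(
                f"coords second axis ({self.coords.shape[1]}) does not match "
                f"total atom count ({sum(counts)})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in ensemble")
        self._offsets = np.concatenate([[0], np.cumsum(counts)])

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> list[int]:
        """Author sequence numbers, in order."""
        return [seq for seq, _ in self.residues]

    def atom_coords(self, atom_name: str) -> np.ndarray:
        """Coordinates of one named atom per residue, shape (F, R, 3).

        Raises :class:`StructureError` if any residue lacks the atom.
        """
        idx = []
        for i, names in enumerate(self.atom_names):
            try:
                idx.append(self._offsets[i] + names.index(atom_name))
            except ValueError:
                seq, resname = self.residues[i]
                raise StructureError(
                    f"residue {resname} {seq} has no atom {atom_name!r}"
                ) from None
        return self.coords[:, idx, :]

    def ca_coords(self) -> np.ndarray:
        """C-alpha coordinates, shape (F, R, 3)."""
        return self.atom_coords("CA")

    def residue_index(self, position: int) -> int:
        """0-based index of the residue with the given author number."""
        for i, (seq, _) in enumerate(self.residues):
            if seq == position:
                return i
        raise StructureError(f"no residue at position {position}")

    def copy(self) -> "ConformationalEnsemble":
        return replace(
            self,
            residues=list(self.residues),
            atom_names=[list(a) for a in self.atom_names],
            coords=self.coords.copy(),
        )


@dataclass(frozen=True)
class MutationSpec:
    """A single side-chain truncation: ``from_residue`` -> ALA or GLY."""

    position: int
    from_residue: str
    to_residue: str

    def __post_init__(self) -> None:
        if self.to_residue not in ("ALA", "GLY"):
            raise StructureError(
                f"truncation target must be ALA or GLY, got {self.to_residue!r}"
            )

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse a compact string such as ``"C32A"`` or ``"C99G"``."""
        text = text.strip()
        if len(text) < 3:
            raise StructureError(f"cannot parse mutation spec {text!r}")
        frm, pos, to = text[0].upper(), text[1:-1], text[-1].upper()
        if frm not in _ONE_TO_THREE or to not in _ONE_TO_THREE:
            raise StructureError(f"unknown residue code in {text!r}")
        return cls(int(pos), _ONE_TO_THREE[frm], _ONE_TO_THREE[to])


# Atoms retained by each truncation target.
_KEEP_ATOMS = {
    "ALA": frozenset({"N", "CA", "C", "O", "CB"}),
    "GLY": frozenset({"N", "CA", "C", "O"}),
}


def read_multimodel_pdb(
    path, chain: str = "A", system_label: str | None = None
) -> ConformationalEnsemble:
    """Read one chain of a multi-model PDB file into an ensemble.

    Models become frames, ordered by MODEL number (a single-structure file
    yields one frame).  Hydrogen/deuterium atoms are skipped; for alternate
    locations the highest-occupancy conformer is kept.  Heavy atoms that are
    not present in every model are dropped with a warning, except backbone
    atoms (N, CA, C, O), whose absence from any model is an error.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("ens", str(path))
    models = sorted(structure.get_models(), key=lambda m: m.serial_num)
    if not models:
        raise StructureError(f"no MODEL found in {path}")

    chains_seen = sorted({c.id for m in models for c in m})
    if chain not in chains_seen:
        raise StructureError(
            f"chain {chain!r} not found in {path}; available chains: "
            f"{', '.join(repr(c) for c in chains_seen)}"
        )

    def chain_residues(model):
        out = []
        for res in model[chain]:
            het, seq, icode = res.id
            if het.strip():  # skip waters / heteroatoms
                continue
            atoms = {}
            for atom in res.get_atoms():  # DisorderedAtom -> selected altloc
                if atom.element in ("H", "D"):
                    continue
                name = atom.get_name()
                if name not in atoms:
                    atoms[name] = atom.get_coord()
            out.append(((seq, res.get_resname()), atoms))
        return out

    per_model = [chain_residues(m) for m in models]
    keys0 = [key for key, _ in per_model[0]]
    for mi, reslist in enumerate(per_model[1:], start=2):
        keys = [key for key, _ in reslist]
        if keys != keys0:
            bad = next(
                a or b for a, b in zip_longest(keys0, keys) if a != b
            )
            raise StructureError(
                f"inconsistent residue composition: model {mi} disagrees at "
                f"residue {bad}"
            )

    residues: list[tuple[int, str]] = []
    atom_names: list[list[str]] = []
    for ri, ((seq, resname), atoms0) in enumerate(per_model[0]):
        common = [
            n for n in atoms0
            if all(n in reslist[ri][1] for reslist in per_model)
        ]
        missing_bb = [
            bb for bb in BACKBONE_ATOMS
            if any(bb not in reslist[ri][1] for reslist in per_model)
        ]
        if missing_bb:
            raise StructureError(
                f"residue {resname} {seq} lacks backbone atom(s) "
                f"{missing_bb} in at least one model"
            )
        dropped = set(atoms0) - set(common)
        if dropped:
            logger.warning(
                "residue %s %d: dropping atoms %s not present in all models",
                resname, seq, sorted(dropped),
            )
        ordered = [n for n in BACKBONE_ATOMS if n in common]
        ordered += [n for n in common if n not in BACKBONE_ATOMS]
        residues.append((seq, resname))
        atom_names.append(ordered)

    frames = np.empty((len(per_model), sum(map(len, atom_names)), 3))
    for fi, reslist in enumerate(per_model):
        cursor = 0
        for ri, names in enumerate(atom_names):
            for name in names:
                frames[fi, cursor] = reslist[ri][1][name]
                cursor += 1

    label = system_label if system_label is not None else str(path)
    return ConformationalEnsemble(
        system_label=label,
        residues=residues,
        atom_names=atom_names,
        coords=frames,
        chain_id=chain,
    )


_ELEMENT_GUESS = {"SG": "S", "SD": "S", "SE": "SE"}


def _element_of(atom_name: str) -> str:
    if atom_name in _ELEMENT_GUESS:
        return _ELEMENT_GUESS[atom_name]
    stripped = atom_name.lstrip("0123456789")
    return stripped[:1] or "C"


def write_multimodel_pdb(ensemble: ConformationalEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB file (one MODEL per frame).

    Coordinates round-trip through :func:`read_multimodel_pdb` to the PDB
    format's 3-decimal precision.
    """
    lines: list[str] = []
    for fi in range(ensemble.n_frames):
        lines.append(f"MODEL     {fi + 1:4d}")
        serial = 0
        cursor = 0
        for (seq, resname), names in zip(ensemble.residues, ensemble.atom_names):
            for name in names:
                serial += 1
                x, y, z = ensemble.coords[fi, cursor]
                cursor += 1
                pdb_name = name if len(name) >= 4 else f" {name:<3s}"
                lines.append(
                    f"ATOM  {serial % 100000:5d} {pdb_name}{'':1s}{resname:>3s} "
                    f"{ensemble.chain_id:1s}{seq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {_element_of(name):>2s}"
                )
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def mutate_side_chain_truncation(
    ensemble: ConformationalEnsemble, specs: list[MutationSpec]
) -> ConformationalEnsemble:
    """Build a truncation mutant (e.g. CYS->ALA or CYS->GLY) of an ensemble.

    The side chain is cut back to the truncation target's atom set in every
    frame: ALA keeps {N, CA, C, O, CB}, GLY keeps {N, CA, C, O}.  Retained
    atoms keep their coordinates bit-for-bit, so backbone dihedrals, Protein
    Blocks assignments and C-alpha metrics are unchanged by construction.
    No rotamer rebuilding or energy minimisation is attempted.
    """
    targets: dict[int, MutationSpec] = {}
    for spec in specs:
        idx = ensemble.residue_index(spec.position)
        seq, resname = ensemble.residues[idx]
        if resname != spec.from_residue:
            raise StructureError(
                f"mutation {spec} does not match structure: position "
                f"{spec.position} is {resname}, not {spec.from_residue}"
            )
        targets[idx] = spec

    residues = list(ensemble.residues)
    atom_names: list[list[str]] = []
    keep_flat: list[bool] = []
    for i, names in enumerate(ensemble.atom_names):
        if i in targets:
            spec = targets[i]
            keep = _KEEP_ATOMS[spec.to_residue]
            missing = {"N", "CA", "C", "O"} - set(names)
            if missing:
                raise StructureError(
                    f"cannot mutate residue at {spec.position}: missing "
                    f"backbone atoms {sorted(missing)}"
                )
            kept = [n for n in names if n in keep]
            atom_names.append(kept)
            keep_flat += [n in keep for n in names]
            residues[i] = (residues[i][0], spec.to_residue)
        else:
            atom_names.append(list(names))
            keep_flat += [True] * len(names)

    mask = np.asarray(keep_flat, bool)
    label = ensemble.system_label + "+" + ",".join(
        f"{s.from_residue}{s.position}{s.to_residue}" for s in specs
    )
    return ConformationalEnsemble(
        system_label=label,
        residues=residues,
        atom_names=atom_names,
        coords=ensemble.coords[:, mask, :].copy(),
        chain_id=ensemble.chain_id,
        frame_spacing_ps=ensemble.frame_spacing_ps,
    )


@dataclass
class RegionMap:
    """Named residue regions (FR1-FR4, CDR1-CDR3) as inclusive author ranges."""

    regions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.regions.items(), key=lambda kv: kv[1][0])
        for (na, (sa, ea)), (nb, (sb, eb)) in zip(spans, spans[1:]):
            if ea < sa or eb < sb:
                raise StructureError(f"inverted range in region map: {na} or {nb}")
            if sb <= ea:
                raise StructureError(f"overlapping regions {na} and {nb}")

    def annotate(self, position: int) -> str:
        """Region name containing ``position``, or ``"unassigned"``."""
        for name, (start, end) in self.regions.items():
            if start <= position <= end:
                return name
        return "unassigned"

    def labels(self, positions) -> list[str]:
        return [self.annotate(p) for p in positions]

    @classmethod
    def default_vhh(cls) -> "RegionMap":
        """Default nanobody (VHH) annotation.

        CDR bounds follow the commonly used approximate author-numbering
        ranges CDR1 23-37, CDR2 50-63 and CDR3 99-105; framework regions
        fill the complement.  Override via a config file when a different
        numbering scheme (e.g. IMGT) is in use.
        """
        return cls({
            "FR1": (1, 22),
            "CDR1": (23, 37),
            "FR2": (38, 49),
            "CDR2": (50, 63),
            "FR3": (64, 98),
            "CDR3": (99, 105),
            "FR4": (106, 150),
        })

    @classmethod
    def from_file(cls, path) -> "RegionMap":
        """Load ``{region_name: [start, end]}`` from a YAML or JSON file."""
        with open(path) as fh:
            text = fh.read()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise StructureError(f"region config {path} is not a mapping")
        return cls({
            str(name): (int(span[0]), int(span[1])) for name, span in raw.items()
        })

    def validate_against(self, ensemble: ConformationalEnsemble) -> None:
        """Check that every annotated residue exists in the ensemble."""
        present = set(ensemble.positions)
        for name, (start, end) in self.regions.items():
            covered = [p for p in range(start, end + 1) if p in present]
            if not covered:
                raise StructureError(
                    f"region {name} ({start}-{end}) matches no residue of "
                    f"{ensemble.system_label}"
                )


def annotate_regions(region_map: RegionMap, position: int) -> str:
    """Functional alias for :meth:`RegionMap.annotate`."""
    return region_map.annotate(position)
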