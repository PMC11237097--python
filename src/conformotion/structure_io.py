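"""Reading and writing protein structures for ensemble construction.

Chains are reduced to their backbone (N, CA, C, O). Missing data is made
explicit in the sequence string: residues declared in the entity's polymer
sequence but without coordinates appear as lowercase letters, unknown or
unmappable residue types as 'X'. Only the first model of a multi-model
file is read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3

from ._substitution import AMINO_ACIDS

if TYPE_CHECKING:  # pragma: no cover
    from .ensemble import ConformationalEnsemble

#: Canonical carbonyl C=O bond length in Angstrom.
CARBONYL_BOND_LENGTH = 1.23

_ONE_TO_THREE = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}
_ONE_TO_THREE["X"] = "UNK"

MIN_RESOLVED_RESIDUES = 5


class StructureFormatError(ValueError):
    """Raised when an input file cannot be parsed as mmCIF/PDB."""


@dataclass
class BackboneResidue:
    """One residue of a chain, with backbone coordinates if resolved.

    ``aa`` is the one-letter code: uppercase for resolved residues,
    lowercase for residues declared in the polymer sequence but lacking
    coordinates, and 'X' for unknown types.
    """

    label_seq_id: int
    aa: str
    n: Optional[np.ndarray] = None
    ca: Optional[np.ndarray] = None
    c: Optional[np.ndarray] = None
    o: Optional[np.ndarray] = None
    o_reconstructed: bool = False

    @property
    def resolved(self) -> bool:
        return self.n is not None and self.ca is not None and self.c is not None

    def transformed(self, rotation: np.ndarray, shift_pre: np.ndarray,
                    shift_post: np.ndarray) -> "BackboneResidue":
        """Apply ``x -> R (x - shift_pre) + shift_post`` to all atoms."""
        def tx(v):
            return None if v is None else (rotation @ (v - shift_pre)) + shift_post
        return BackboneResidue(self.label_seq_id, self.aa, tx(self.n), tx(self.ca),
                               tx(self.c), tx(self.o), self.o_reconstructed)


@dataclass
class ChainRecord:
    """A polypeptide chain: sequence with missing-data encoding + backbone."""

    structure_id: str
    chain_id: str
    residues: list[BackboneResidue] = field(default_factory=list)

    @property
    def record_id(self) -> str:
        return f"{self.structure_id}_{self.chain_id}"

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def n_resolved(self) -> int:
        return sum(r.resolved for r in self.residues)


def three_to_one(name: str) -> str:
    """Map a residue name to a one-letter code; unmapped types give 'X'.

    Modified residues with a tabulated natural parent (e.g. MSE) map to the
    parent's letter via gemmi's residue table.
    """
    info = gemmi.find_tabulated_residue(name.split(",")[0].strip())
    if info is not None and info.is_amino_acid():
        letter = info.one_letter_code.upper()
        if letter in AMINO_ACIDS:
            return letter
    return "X"


def reconstruct_carbonyl_oxygen(residue: BackboneResidue,
                                next_n: Optional[np.ndarray] = None) -> np.ndarray:
    """Place a missing carbonyl O at 1.23 A from C in the peptide plane.

    The O direction opposes the bisector of the CA->C and N(i+1)->C
    directions, which puts it trans to CA(i+1) in an ideal trans peptide.
    Chain-terminal residues (no following N) fall back to extending the
    CA->C direction; the caller should flag these via ``o_reconstructed``.
    If the residue already has an O, it is returned unchanged.
    """
    if residue.o is not None and not residue.o_reconstructed:
        return residue.o
    if residue.ca is None or residue.c is None:
        raise ValueError("cannot reconstruct O without CA and C coordinates")
    c, ca = residue.c, residue.ca
    if next_n is not None:
        u1 = _unit(ca - c)
        u2 = _unit(next_n - c)
        direction = -_unit(u1 + u2)
    else:
        direction = _unit(c - ca)
    return c + CARBONYL_BOND_LENGTH * direction


def _unit(v: np.ndarray) -> np.ndarray:
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValueError("zero-length vector in O reconstruction")
    return v / norm


def _atom_pos(res: gemmi.Residue, name: str) -> Optional[np.ndarray]:
    for atom in res:
        if atom.name == name:
            return np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
    return None


def _is_monomeric(structure: gemmi.Structure) -> bool:
    """First listed biological assembly contains exactly one polymer chain.

    Entries without assembly annotations fall back to counting the polymer
    chains of the asymmetric unit.
    """
    if len(structure.assemblies) > 0:
        asm = structure.assemblies[0]
        n = 0
        polymer_subchains = set()
        for ent in structure.entities:
            if ent.entity_type == gemmi.EntityType.Polymer:
                polymer_subchains.update(ent.subchains)
        for gen in asm.generators:
            n_ops = max(1, len(gen.operators))
            chains = set(gen.chains) | (set(gen.subchains) & polymer_subchains)
            if gen.chains:
                polymer_names = {ch.name for ch in structure[0]
                                 if len(ch.get_polymer()) > 0}
                chains = set(gen.chains) & polymer_names | (
                    set(gen.subchains) & polymer_subchains)
            n += len(chains) * n_ops
        return n <= 1
    n_polymers = sum(1 for ch in structure[0] if len(ch.get_polymer()) > 0)
    return n_polymers <= 1


def extract_chain_records(path: str | Path,
                          monomer_only: bool = False) -> list[ChainRecord]:
    """Read one structure file into per-chain backbone records.

    Only model 1 is used. Residues present in ``_entity_poly_seq`` but
    without coordinates become lowercase letters; residues with a missing
    backbone atom other than O are treated as unresolved as well (a missing
    O is reconstructed from standard peptide geometry). Chains with fewer
    than 5 resolved residues or fewer than 5 non-'X' sequence characters
    are dropped. With ``monomer_only``, chains from entries whose first
    biological assembly contains more than one polypeptide are excluded.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse structure file {path}: {exc}") from exc
    structure.setup_entities()
    if len(structure) == 0:
        return []
    if monomer_only and not _is_monomeric(structure):
        return []

    structure_id = (structure.name.strip() or path.stem)[:4] or path.stem[:4]
    records = []
    model = structure[0]
    for chain in model:
        polymer = chain.get_polymer()
        if len(polymer) == 0:
            continue
        entity = structure.get_entity_of(polymer)
        full_seq = list(entity.full_sequence) if entity is not None else []
        record = _build_chain_record(structure_id, chain.name, polymer, full_seq)
        if record is not None:
            records.append(record)
    return records


def _build_chain_record(structure_id: str, chain_id: str,
                        polymer: gemmi.ResidueSpan,
                        full_seq: list[str]) -> Optional[ChainRecord]:
    if full_seq:
        residues = [BackboneResidue(i + 1, three_to_one(mon).lower()
                                    if three_to_one(mon) != "X" else "X")
                    for i, mon in enumerate(full_seq)]
        for i, res in enumerate(polymer):
            idx = res.label_seq - 1 if res.label_seq is not None else i
            if not 0 <= idx < len(residues):
                continue
            _fill_coordinates(residues[idx], res)
    else:
        # only observed residues known: no lowercase encoding possible
        residues = []
        for i, res in enumerate(polymer):
            letter = three_to_one(res.name)
            br = BackboneResidue(i + 1, letter if letter != "X" else "X")
            _fill_coordinates(br, res)
            if br.resolved:
                residues.append(br)

    _finalize_oxygens(residues)
    record = ChainRecord(structure_id, chain_id, residues)
    n_informative = sum(1 for r in record.residues if r.aa.upper() != "X")
    if record.n_resolved < MIN_RESOLVED_RESIDUES or n_informative < MIN_RESOLVED_RESIDUES:
        return None
    return record


def _fill_coordinates(target: BackboneResidue, res: gemmi.Residue) -> None:
    n, ca, c, o = (_atom_pos(res, a) for a in ("N", "CA", "C", "O"))
    if n is None or ca is None or c is None:
        return  # missing backbone atom other than O: residue stays unresolved
    target.n, target.ca, target.c, target.o = n, ca, c, o
    if target.aa.upper() != "X":
        target.aa = target.aa.upper()


def _finalize_oxygens(residues: list[BackboneResidue]) -> None:
    resolved = [r for r in residues if r.resolved]
    for i, res in enumerate(resolved):
        if res.o is not None:
            continue
        nxt = resolved[i + 1] if i + 1 < len(resolved) else None
        sequential = nxt is not None and nxt.label_seq_id == res.label_seq_id + 1
        res.o = reconstruct_carbonyl_oxygen(res, nxt.n if sequential else None)
        res.o_reconstructed = True


# ---------------------------------------------------------------------------
# ensemble output
# ---------------------------------------------------------------------------

def write_ensemble_files(ensemble: "ConformationalEnsemble", out_dir: str | Path,
                         fmt: str = "cif", name: str = "ensemble") -> dict[str, Path]:
    """Write an ensemble as multi-model structure + FASTA MSA + RMSD matrix.

    Returns a dict with keys ``structure``, ``msa``, ``rmsd``, ``meta``
    mapping to the written paths. Models may carry different sequences.
    """
    from .ensemble import rmsd_matrix

    if fmt not in ("cif", "pdb"):
        raise ValueError(f"unsupported format: {fmt!r}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    structure = gemmi.Structure()
    structure.name = name[:8]
    for model_no, member in enumerate(ensemble.member_ids, start=1):
        model = gemmi.Model(str(model_no))
        chain = gemmi.Chain("A")
        store = ensemble.backbone_store[model_no - 1]
        for col in sorted(store):
            br = store[col]
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE.get(br.aa.upper(), "UNK")
            res.seqid = gemmi.SeqId(col + 1, " ")
            res.label_seq = col + 1
            for atom_name, element, pos in (("N", "N", br.n), ("CA", "C", br.ca),
                                            ("C", "C", br.c), ("O", "O", br.o)):
                if pos is None:
                    continue
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*map(float, pos))
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()

    structure_path = out_dir / f"{name}.{fmt}"
    if fmt == "pdb":
        structure.write_pdb(str(structure_path))
    else:
        structure.make_mmcif_document().write_file(str(structure_path))

    msa_path = out_dir / f"{name}.fasta"
    with open(msa_path, "w") as handle:
        for row_id, aligned in ensemble.msa.rows:
            handle.write(f">{row_id}\n{aligned}\n")

    rmsd = rmsd_matrix(ensemble)
    rmsd_path = out_dir / f"{name}_rmsd.tsv"
    _write_matrix_tsv(rmsd_path, rmsd.values, ensemble.member_ids)

    meta_path = out_dir / f"{name}_meta.json"
    meta = dict(ensemble.meta)
    meta.setdefault("n_conformations", len(ensemble.member_ids))
    meta.setdefault("reference_id", ensemble.member_ids[ensemble.reference_index])
    with open(meta_path, "w") as handle:
        json.dump(meta, handle, indent=1, sort_keys=True)

    return {"structure": structure_path, "msa": msa_path,
            "rmsd": rmsd_path, "meta": meta_path}


def _write_matrix_tsv(path: Path, values: np.ndarray, ids: Iterable[str]) -> None:
    import pandas as pd

    ids = list(ids)
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t",
                                                        float_format="%.6f")


def read_multimodel_ca(path: str | Path) -> list[tuple[str, dict[int, np.ndarray]]]:
    """Read every model of a multi-model file as (sequence, {column: CA}).

    Columns are the 0-based ``label_seq_id - 1`` values, i.e. the alignment
    positions used when the file was written by :func:`write_ensemble_files`.
    """
    structure = gemmi.read_structure(str(Path(path)))
    out = []
    for model in structure:
        for chain in model:
            seq = []
            coords: dict[int, np.ndarray] = {}
            for i, res in enumerate(chain):
                seq.append(three_to_one(res.name))
                ca = _atom_pos(res, "CA")
                label = res.label_seq if res.label_seq is not None else res.seqid.num
                if ca is not None:
                    coords[int(label) - 1] = ca
            out.append(("".join(seq), coords))
    return out


def read_fasta_rows(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as ordered (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
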