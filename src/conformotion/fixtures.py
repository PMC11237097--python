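"""Synthetic conformational ensembles with controlled motion structure.

Every generator is seed-deterministic and returns ground truth (modes,
amplitudes, angles) alongside the data, so parameter-recovery tests can
run without any downloaded structure. Backbone geometry is idealized: a
self-avoiding Calpha walk with 3.8 A steps, expanded to N/CA/C/O by
standard internal coordinates — valid for file formats and
superposition, not stereochemically scored.

Amplitudes are calibrated in Angstrom of per-atom RMS displacement: a
conformation at amplitude a deviates from the base trace by an RMSD of
a, so an ensemble spanning +/-a has endpoint-to-endpoint RMSD ~2a.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from ._substitution import AMINO_ACIDS
from .ensemble import ConformationalEnsemble, select_reference
from .grouping import Msa
from .structure_io import (BackboneResidue, _ONE_TO_THREE,
                           reconstruct_carbonyl_oxygen)

CA_STEP = 3.8           # A, consecutive Calpha distance
MIN_SEPARATION = 3.4    # A, self-avoidance cutoff


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic ensemble.

    ``amplitude`` is the half-span of the motion in Angstrom of per-atom
    RMS displacement; ``noise_sd`` is the isotropic per-coordinate noise
    standard deviation in Angstrom. Defaults give a clearly
    one-dimensional motion with 10% noise.
    """

    m: int = 50
    n: int = 30
    motion: str = "linear"
    amplitude: float = 2.0
    noise_sd: float = 0.2
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def self_avoiding_walk(m: int, rng: np.random.Generator) -> np.ndarray:
    """A Calpha trace: 3.8 A steps, rejecting points closer than 3.4 A."""
    points = [np.zeros(3)]
    while len(points) < m:
        for _ in range(200):
            step = rng.normal(size=3)
            step *= CA_STEP / np.linalg.norm(step)
            candidate = points[-1] + step
            dists = np.linalg.norm(np.asarray(points[:-1]) - candidate, axis=1) \
                if len(points) > 1 else np.array([np.inf])
            if (dists > MIN_SEPARATION).all():
                points.append(candidate)
                break
        else:  # extremely unlikely: restart the tail
            points = points[: max(1, len(points) // 2)]
    return np.asarray(points)


def random_sequence(m: int, rng: np.random.Generator,
                    template: Optional[str] = None,
                    mutation_rate: float = 0.0) -> str:
    """Uniform random sequence, optionally a mutated copy of a template."""
    if template is None:
        return "".join(rng.choice(list(AMINO_ACIDS), size=m))
    out = list(template)
    for i in range(len(out)):
        if rng.random() < mutation_rate:
            out[i] = rng.choice(list(AMINO_ACIDS))
    return "".join(out)


def _motion_directions(m: int, rng: np.random.Generator, k: int = 1,
                       base: Optional[np.ndarray] = None) -> np.ndarray:
    """k orthonormal 3m-directions orthogonal to the rigid-body modes.

    Net translation and (when the base trace is given) linearized rotation
    about its centroid are projected out, so superposition onto a
    reference leaves the motion essentially unchanged.
    """
    rigid = []
    for axis in range(3):
        t = np.zeros(3 * m)
        t[axis::3] = 1.0
        rigid.append(t / np.linalg.norm(t))
    if base is not None:
        centered = base.reshape(m, 3) - base.reshape(m, 3).mean(axis=0)
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = 1.0
            r = np.cross(np.broadcast_to(e, (m, 3)), centered).reshape(-1)
            for prev in rigid:
                r = r - (r @ prev) * prev
            norm = np.linalg.norm(r)
            if norm > 1e-8:
                rigid.append(r / norm)
    basis = []
    while len(basis) < k:
        v = rng.normal(size=3 * m)
        for prev in rigid + basis:
            v -= (v @ prev) * prev
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    return np.asarray(basis)


def expand_backbone(ca: np.ndarray) -> list[BackboneResidue]:
    """Idealized N/CA/C/O placement around a Calpha trace."""
    m = len(ca)
    residues = []
    for i in range(m):
        t = ca[min(i + 1, m - 1)] - ca[min(i + 1, m - 1) - 1]
        t = t / np.linalg.norm(t)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(t @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        side = np.cross(t, ref)
        side /= np.linalg.norm(side)
        d_n = -t + 0.5 * side
        d_c = t + 0.5 * side
        n = ca[i] + 1.46 * d_n / np.linalg.norm(d_n)
        c = ca[i] + 1.52 * d_c / np.linalg.norm(d_c)
        residues.append(BackboneResidue(i + 1, "A", n=n, ca=ca[i].copy(), c=c))
    for i, res in enumerate(residues):
        next_n = residues[i + 1].n if i + 1 < m else None
        res.o = reconstruct_carbonyl_oxygen(res, next_n)
        res.o_reconstructed = next_n is None
    return residues


def _member_id(i: int) -> str:
    return f"s{i:03d}_A"


def _ensemble_from_coords(coords: np.ndarray, sequence: str,
                          rng: np.random.Generator,
                          missing_fraction: float = 0.0) -> ConformationalEnsemble:
    """Wrap n x m x 3 coordinates as a fully-aligned ensemble.

    With ``missing_fraction`` > 0, random positions are marked unresolved
    (lowercase in the MSA, NaN in R) while keeping every column resolved
    in at least one member and every member >= 5 resolved positions.
    """
    n, m, _ = coords.shape
    mask = np.ones((n, m), dtype=bool)
    if missing_fraction > 0:
        for i in range(n):
            candidates = rng.permutation(m)
            quota = int(round(missing_fraction * m))
            for j in candidates:
                if quota == 0:
                    break
                if mask[:, j].sum() > 1 and mask[i].sum() > 5:
                    mask[i, j] = False
                    quota -= 1
    rows = []
    R = np.full((n, 3 * m), np.nan)
    store = []
    for i in range(n):
        chars = [sequence[j] if mask[i, j] else sequence[j].lower()
                 for j in range(m)]
        rows.append((_member_id(i), "".join(chars)))
        residues = expand_backbone(coords[i])
        for j, res in enumerate(residues):
            res.aa = chars[j]
        store.append({j: residues[j] for j in range(m) if mask[i, j]})
        flat = coords[i].reshape(-1).copy()
        dead = np.repeat(~mask[i], 3)
        flat[dead] = np.nan
        R[i] = flat
    msa = Msa(rows)
    ens = ConformationalEnsemble(msa=msa, member_ids=msa.ids, R=R,
                                 resolved_mask=mask, backbone_store=store)
    ens.reference_index = select_reference(msa)
    return ens


def make_linear_motion_ensemble(spec: SyntheticSpec
                                ) -> tuple[ConformationalEnsemble, dict]:
    """Ensemble deformed along one fixed direction.

    Conformation i sits at amplitude a_i (evenly spaced on
    [-amplitude, +amplitude]) along a fixed orthonormal direction scaled
    so that a_i is its RMSD from the base trace, plus isotropic noise.
    Ground truth: the unit 3m-mode, per-conformation amplitudes, base.
    """
    if spec.motion != "linear":
        raise ValueError("spec.motion must be 'linear'")
    rng = np.random.default_rng(spec.seed)
    base = self_avoiding_walk(spec.m, rng)
    mode = _motion_directions(spec.m, rng, k=1, base=base.reshape(-1))[0]
    amplitudes = np.linspace(-spec.amplitude, spec.amplitude, spec.n)
    coords = (base.reshape(-1)[None, :]
              + amplitudes[:, None] * mode[None, :] * np.sqrt(spec.m))
    coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
    sequence = random_sequence(spec.m, rng)
    ens = _ensemble_from_coords(coords.reshape(spec.n, spec.m, 3), sequence,
                                rng, spec.missing_fraction)
    truth = {"mode": mode, "amplitudes": amplitudes,
             "base": base.reshape(-1), "sequence": sequence}
    return ens, truth


def make_arc_ensemble(spec: SyntheticSpec) -> tuple[ConformationalEnsemble, dict]:
    """Ensemble on a curved one-parameter manifold spanning two directions.

    Displacements follow amplitude * (sin(t) u1 + (1 - cos(t)) u2) for t
    on [-pi/2, pi/2]: locally one-dimensional but curved, so a linear
    model extrapolates poorly beyond the sampled range.
    """
    if spec.motion != "arc":
        raise ValueError("spec.motion must be 'arc'")
    rng = np.random.default_rng(spec.seed)
    base = self_avoiding_walk(spec.m, rng)
    u1, u2 = _motion_directions(spec.m, rng, k=2, base=base.reshape(-1))
    t = np.linspace(-np.pi / 2, np.pi / 2, spec.n)
    disp = (np.sin(t)[:, None] * u1[None, :]
            + (1 - np.cos(t))[:, None] * u2[None, :])
    coords = base.reshape(-1)[None, :] + spec.amplitude * np.sqrt(spec.m) * disp
    coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
    sequence = random_sequence(spec.m, rng)
    ens = _ensemble_from_coords(coords.reshape(spec.n, spec.m, 3), sequence,
                                rng, spec.missing_fraction)
    return ens, {"u1": u1, "u2": u2, "t": t, "base": base.reshape(-1),
                 "sequence": sequence}


def make_hinge_ensemble(spec: SyntheticSpec, angle_range: float = 1.0
                        ) -> tuple[ConformationalEnsemble, dict]:
    """Two rigid pseudo-domains rotating about a pivot.

    Conformations sample hinge angles evenly on [0, angle_range] (rad),
    rotating the second domain about an axis through the pivot chosen so
    the inter-domain centroid distance grows monotonically with angle.
    """
    if spec.motion != "hinge":
        raise ValueError("spec.motion must be 'hinge'")
    rng = np.random.default_rng(spec.seed)
    base = self_avoiding_walk(spec.m, rng)
    split = spec.m // 2
    pivot = base[split]
    cen_a = base[:split].mean(axis=0) - pivot
    cen_b = base[split:].mean(axis=0) - pivot
    axis = np.cross(cen_a, cen_b)
    axis /= np.linalg.norm(axis)
    phi0 = np.arccos(np.clip(cen_a @ cen_b
                             / (np.linalg.norm(cen_a) * np.linalg.norm(cen_b)),
                             -1, 1))
    max_open = max(0.0, np.pi - phi0 - 0.05)
    angles = np.linspace(0.0, min(angle_range, max_open), spec.n)

    from scipy.spatial.transform import Rotation

    coords = np.empty((spec.n, spec.m, 3))
    distances = np.empty(spec.n)
    for i, theta in enumerate(angles):
        rot = Rotation.from_rotvec(axis * theta).as_matrix()
        conf = base.copy()
        conf[split:] = (base[split:] - pivot) @ rot.T + pivot
        conf += rng.normal(0.0, spec.noise_sd, size=conf.shape)
        coords[i] = conf
        distances[i] = np.linalg.norm(conf[:split].mean(axis=0)
                                      - conf[split:].mean(axis=0))
    sequence = random_sequence(spec.m, rng)
    ens = _ensemble_from_coords(coords, sequence, rng, spec.missing_fraction)
    return ens, {"angles": angles, "interdomain_distance": distances,
                 "pivot": pivot, "split": split, "sequence": sequence}


# ---------------------------------------------------------------------------
# toy structure files
# ---------------------------------------------------------------------------

def make_gapped_cif_fixture(spec: SyntheticSpec, out_dir: str | Path,
                            include_duplicate: bool = False,
                            prefix: str = "s"
                            ) -> tuple[list[Path], dict]:
    """Write per-conformation mmCIF files with declared-but-missing residues.

    A random ``missing_fraction`` of residues per file are declared in the
    polymer sequence but carry no atoms (every position stays resolved in
    at least one file). The first file carries a second, rotated decoy
    model (only model 1 should be read) and a second 4-residue decoy
    chain (filtered by the >= 5 resolved residues rule). Optionally an
    exact duplicate of conformation 0 is written under a new code to
    exercise redundancy removal. Returns the file paths and the ground
    truth (coordinates, sequence, per-file missing masks, member ids).
    """
    rng = np.random.default_rng(spec.seed)
    lin_spec = dataclasses.replace(spec, motion="linear", missing_fraction=0.0)
    ens, truth = make_linear_motion_ensemble(lin_spec)
    n, m = spec.n, spec.m
    coords = ens.R.reshape(n, m, 3)
    sequence = truth["sequence"]

    mask = np.ones((n, m), dtype=bool)
    if spec.missing_fraction > 0:
        for i in range(n):
            for j in rng.permutation(m)[: int(round(spec.missing_fraction * m))]:
                if mask[:, j].sum() > 1 and mask[i].sum() > 5:
                    mask[i, j] = False

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n):
        sid = f"{prefix}{i:03d}"
        path = out_dir / f"{sid}.cif"
        _write_cif(path, sid, sequence, coords[i], mask[i],
                   decoy_model=(i == 0), decoy_chain=(i == 0), rng=rng)
        paths.append(path)
    member_ids = [f"{prefix.upper()}{i:03d}_A" for i in range(n)]
    if include_duplicate:
        sid = f"{prefix}{n:03d}"
        path = out_dir / f"{sid}.cif"
        _write_cif(path, sid, sequence, coords[0], mask[0],
                   decoy_model=False, decoy_chain=False, rng=rng)
        paths.append(path)
    truth = {"coords": coords, "sequence": sequence, "mask": mask,
             "member_ids": member_ids, "mode": truth["mode"],
             "amplitudes": truth["amplitudes"]}
    return paths, truth


def _write_cif(path: Path, sid: str, sequence: str, ca: np.ndarray,
               mask: np.ndarray, decoy_model: bool, decoy_chain: bool,
               rng: np.random.Generator) -> None:
    structure = gemmi.Structure()
    structure.name = sid.upper()

    def build_model(name: str, coords: np.ndarray) -> gemmi.Model:
        model = gemmi.Model(name)
        chain = gemmi.Chain("A")
        residues = expand_backbone(coords)
        for j, br in enumerate(residues):
            if not mask[j]:
                continue
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE[sequence[j]]
            res.seqid = gemmi.SeqId(j + 1, " ")
            res.label_seq = j + 1
            for atom_name, element, pos in (("N", "N", br.n), ("CA", "C", br.ca),
                                            ("C", "C", br.c), ("O", "O", br.o)):
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*map(float, pos))
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        return model

    structure.add_model(build_model("1", ca))
    if decoy_model:
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.0, 0.0, 1.3]).as_matrix()
        structure.add_model(build_model("2", ca @ rot.T + 25.0))
    if decoy_chain:
        chain = gemmi.Chain("B")
        stub = expand_backbone(ca[:4] + np.array([40.0, 0.0, 0.0]))
        for j, br in enumerate(stub):
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE[sequence[j]]
            res.seqid = gemmi.SeqId(j + 1, " ")
            for atom_name, element, pos in (("N", "N", br.n), ("CA", "C", br.ca),
                                            ("C", "C", br.c), ("O", "O", br.o)):
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*map(float, pos))
                res.add_atom(atom)
            chain.add_residue(res)
        structure[0].add_chain(chain)

    structure.setup_entities()
    # declare the full polymer sequence so unresolved residues are recoverable
    for entity in structure.entities:
        if entity.entity_type != gemmi.EntityType.Polymer:
            continue
        span_len = 0
        for sub in entity.subchains:
            span = structure[0].get_subchain(sub)
            if len(span):
                span_len = max(span_len,
                               max((r.label_seq or 0) for r in span), len(span))
        if span_len > 4:
            entity.full_sequence = [_ONE_TO_THREE[c] for c in sequence]
    structure.make_mmcif_document().write_file(str(path))
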