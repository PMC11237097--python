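"""End-to-end orchestration: structures in, conformational collections out.

The default entry point (:func:`run_full`) runs sequence extraction,
clustering, per-cluster alignment, ensemble construction, superposition,
redundancy reduction, file output and PCA for every cluster. The
alternative entry point (:func:`run_from_alignment`) bypasses clustering
and alignment, consuming a pre-computed MSA plus coordinate files — the
route used for superfamilies grouped by structural rather than sequence
similarity — and supports reference centering and uncertainty weighting.

Stage failures isolate the affected cluster; the run report lists
per-stage counts and failures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import ensemble as ens_mod
from . import motions as motions_mod
from .grouping import Msa, align_cluster, cluster_sequences, msa_identity_coverage, \
    postprocess_msa, sum_of_pairs_score
from .structure_io import ChainRecord, extract_chain_records, read_fasta_rows, \
    read_multimodel_ca, write_ensemble_files

logger = logging.getLogger("conformotion")


@dataclass
class RunConfig:
    inputs: list[Path] = field(default_factory=list)
    out_dir: Path = Path("conformotion_out")
    identity: float = 0.8
    coverage: float = 0.8
    rms_cut: float = 0.1
    atoms: str = "ca"                  # ca | backbone
    centering: str = "mean"            # mean | reference
    weighting: bool = False
    monomer_only: bool = False
    min_aligned: int = 5
    cluster_backend: str = "builtin"
    align_backend: str = "auto"
    fmt: str = "cif"
    reference_id: Optional[str] = None
    invert_consensus_priority: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.identity <= 1 or not 0 < self.coverage <= 1:
            raise ValueError("identity/coverage thresholds must be in (0, 1]")
        if self.rms_cut < 0:
            raise ValueError("rms_cut must be non-negative")
        self.inputs = [Path(p) for p in self.inputs]
        self.out_dir = Path(self.out_dir)


def _collection_stats(collection: ens_mod.ConformationalEnsemble,
                      decomp: Optional[motions_mod.MotionDecomposition]) -> dict:
    rmsd = ens_mod.rmsd_matrix(collection)
    identity, coverage = msa_identity_coverage(collection.msa)
    stats = {
        "n_conformations": collection.n,
        "n_positions": collection.m,
        "reference_id": collection.member_ids[collection.reference_index],
        "max_rmsd": float(np.nanmax(rmsd.values)) if collection.n > 1 else 0.0,
        "msa_identity_pct": identity,
        "msa_coverage_pct": coverage,
        "msa_score_rel": (sum_of_pairs_score(collection.msa)
                          if collection.n >= 2 else 1.0),
        "removed_redundant": collection.meta.get("removed_redundant", []),
        "dropped_min_aligned": collection.meta.get("dropped_min_aligned", []),
        "excluded_from_statistics": collection.n < 3,  # singleton or pair
    }
    if decomp is not None:
        stats.update(motions_mod.motion_summary(decomp))
    return stats


def build_collection(records: dict[str, ChainRecord], msa: Msa,
                     config: RunConfig, name: str,
                     write: bool = True
                     ) -> tuple[ens_mod.ConformationalEnsemble,
                                Optional[motions_mod.MotionDecomposition], dict]:
    """Steps shared by both entry points, from an aligned cluster onward."""
    collection = ens_mod.build_ensemble(records, msa)
    if config.reference_id and config.reference_id in collection.member_ids:
        collection.reference_index = collection.member_ids.index(config.reference_id)
    else:
        collection.reference_index = ens_mod.select_reference(
            collection.msa, config.invert_consensus_priority)
    collection.centering = config.centering
    if config.weighting:
        collection.weights = ens_mod.position_weights(collection.msa)
    collection = ens_mod.superimpose_ensemble(collection, config.atoms,
                                              config.min_aligned)
    collection = ens_mod.reduce_redundancy(collection, config.rms_cut)
    collection.meta.update({"identity": config.identity,
                            "coverage": config.coverage,
                            "rms_cut": config.rms_cut,
                            "atoms": config.atoms,
                            "centering": config.centering,
                            "weighting": config.weighting,
                            "monomer_only": config.monomer_only})

    decomp = None
    if collection.n >= 2:
        dense, _ = ens_mod.fill_gaps(collection)
        decomp = motions_mod.decompose(
            dense, weights=collection.weights,
            centering=collection.centering,
            reference_row=collection.reference_index)
    if write:
        paths = write_ensemble_files(collection, config.out_dir, config.fmt, name)
        if decomp is not None:
            motions_mod.save_decomposition(decomp,
                                           config.out_dir / f"{name}_modes.npz")
        logger.info("collection %s: wrote %s", name, paths["structure"])
    stats = _collection_stats(collection, decomp)
    stats["name"] = name
    return collection, decomp, stats


def run_full(config: RunConfig) -> dict:
    """Run the whole pipeline; returns (and writes) the run report."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    records: dict[str, ChainRecord] = {}
    n_files = 0
    for path in config.inputs:
        n_files += 1
        for record in extract_chain_records(path, config.monomer_only):
            records[record.record_id] = record
    logger.info("parsed %d chains from %d files", len(records), n_files)

    clusters = cluster_sequences(records.values(), config.identity,
                                 config.coverage, config.cluster_backend)
    report = {"config": {k: str(v) if isinstance(v, (Path, list)) else v
                         for k, v in dataclasses.asdict(config).items()},
              "n_input_files": n_files, "n_chains": len(records),
              "n_clusters": len(clusters), "collections": [], "failures": []}
    for idx, cluster in enumerate(clusters):
        name = f"cluster_{idx:03d}"
        try:
            seqs = [(mid, records[mid].sequence) for mid in cluster.member_ids]
            msa = align_cluster(seqs, config.align_backend)
            _, _, stats = build_collection(records, msa, config, name)
            stats["representative_id"] = cluster.representative_id
            report["collections"].append(stats)
        except Exception as exc:  # isolate the cluster, keep going
            logger.exception("collection %s failed", name)
            report["failures"].append({"name": name, "error": str(exc)})
    with open(config.out_dir / "report.json", "w") as handle:
        json.dump(report, handle, indent=1)
    return report


def run_from_alignment(msa_path: str | Path, coord_paths: Sequence[str | Path],
                       config: RunConfig) -> dict:
    """Alternative entry: pre-computed MSA + coordinate files.

    MSA rows must map one-to-one onto chain records extracted from the
    coordinate files (row id = ``<structure>_<chain>``), with unresolved
    residues lowercase as in pipeline-produced alignments. Supports
    reference centering and uncertainty weighting via the config.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    records: dict[str, ChainRecord] = {}
    for path in coord_paths:
        for record in extract_chain_records(path, config.monomer_only):
            records[record.record_id] = record
    rows = read_fasta_rows(msa_path)
    missing = [rid for rid, _ in rows if rid not in records]
    if missing:
        raise ValueError("MSA rows without a matching coordinate file: "
                         + ", ".join(missing))
    msa = postprocess_msa(rows)
    _, _, stats = build_collection(records, msa, config, "collection")
    report = {"n_chains": len(records), "collections": [stats], "failures": []}
    with open(config.out_dir / "report.json", "w") as handle:
        json.dump(report, handle, indent=1)
    return report


def ensemble_from_files(structure_path: str | Path, msa_path: str | Path
                        ) -> ens_mod.ConformationalEnsemble:
    """Rebuild an ensemble from its written multi-model file + FASTA MSA.

    Coordinates come from the structure models (one per MSA row, same
    order); the resolved mask comes from the MSA case/gap encoding. The
    backbone store holds whatever atoms the file provides.
    """
    rows = read_fasta_rows(msa_path)
    models = read_multimodel_ca(structure_path)
    if len(models) != len(rows):
        raise ValueError(f"{len(models)} models but {len(rows)} MSA rows")
    msa = Msa(rows)
    n, m = len(rows), msa.n_cols
    R = np.full((n, 3 * m), np.nan)
    mask = np.zeros((n, m), dtype=bool)
    for i, (_, coords) in enumerate(models):
        for col, ca in coords.items():
            if 0 <= col < m:
                R[i, 3 * col:3 * col + 3] = ca
                mask[i, col] = True
    return ens_mod.ConformationalEnsemble(
        msa=msa, member_ids=msa.ids, R=R, resolved_mask=mask,
        backbone_store=[{} for _ in range(n)], superimposed=True)
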