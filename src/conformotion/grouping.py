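"""Sequence clustering and per-cluster multiple sequence alignments.

Chains are grouped at configurable identity/coverage thresholds (80%/80%
by default, bidirectional coverage). Each cluster is aligned — with MAFFT
when available, otherwise with a built-in center-star progressive aligner
intended for test-scale inputs — and the alignment is post-processed:
columns containing only 'X'/gaps are removed and rows are reordered by
structure code. Three quality scores describe an MSA: column-wise pair
identity, coverage (fraction of columns with <20% gaps), and a normalized
sum-of-pairs score.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

from ._substitution import is_gap_like, substitution_matrix

#: affine gap penalties of the built-in aligner (BLOSUM62 convention)
GAP_OPEN, GAP_EXTEND = -11, -1

DEFAULT_IDENTITY = 0.8
DEFAULT_COVERAGE = 0.8


class ClusteringBackendError(RuntimeError):
    pass


class AlignmentBackendError(RuntimeError):
    pass


@dataclass
class SequenceCluster:
    member_ids: list[str]
    representative_id: str


@dataclass
class Msa:
    """Aligned sequences of one cluster; columns define ensemble positions."""

    rows: list[tuple[str, str]]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    def column(self, j: int) -> list[str]:
        return [aligned[j] for _, aligned in self.rows]


def postprocess_msa(rows: Sequence[tuple[str, str]]) -> Msa:
    """Drop all-'X'/gap columns and sort rows by identifier."""
    rows = sorted(rows, key=lambda r: r[0])
    if not rows:
        return Msa([])
    keep = [j for j in range(len(rows[0][1]))
            if any(not is_gap_like(aligned[j]) for _, aligned in rows)]
    return Msa([(rid, "".join(aligned[j] for j in keep)) for rid, aligned in rows])


# ---------------------------------------------------------------------------
# pairwise comparison (built-in clustering backend)
# ---------------------------------------------------------------------------

def _to_biotite(seq: str) -> bseq.ProteinSequence:
    return bseq.ProteinSequence(seq.upper().replace("-", ""))


def _pairwise_alignment(a: str, b: str) -> balign.Alignment:
    ali = balign.align_optimal(_to_biotite(a), _to_biotite(b),
                               substitution_matrix(),
                               gap_penalty=(GAP_OPEN, GAP_EXTEND),
                               terminal_penalty=False)
    return ali[0]


def pairwise_identity_coverage(a: str, b: str) -> tuple[float, float, float]:
    """(identity, coverage_a, coverage_b) from a semi-global alignment.

    Identity is the fraction of aligned residue pairs with equal amino
    acids ('X' never matches); each coverage is the number of aligned
    pairs over that sequence's length.
    """
    ali = _pairwise_alignment(a, b)
    ua, ub = a.upper(), b.upper()
    trace = ali.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    n_pairs = int(both.sum())
    if n_pairs == 0:
        return 0.0, 0.0, 0.0
    ia, ib = trace[both, 0], trace[both, 1]
    matches = sum(1 for x, y in zip(ia, ib)
                  if ua[x] == ub[y] and ua[x] != "X")
    return matches / n_pairs, n_pairs / len(a), n_pairs / len(b)


def cluster_sequences(records, identity_threshold: float = DEFAULT_IDENTITY,
                      coverage_threshold: float = DEFAULT_COVERAGE,
                      backend: str = "builtin") -> list[SequenceCluster]:
    """Partition sequences into clusters at the given thresholds.

    ``records`` holds ChainRecord-like objects (``record_id``/``sequence``)
    or plain ``(id, sequence)`` pairs. The builtin backend is a greedy
    incremental clusterer over descending sequence length: a sequence joins
    the first cluster whose representative it matches at pairwise identity
    >= ``identity_threshold`` with bidirectional coverage >=
    ``coverage_threshold``. The external backend shells out to MMseqs2 and
    raises :class:`ClusteringBackendError` if the executable is absent.
    """
    if not 0 < identity_threshold <= 1 or not 0 < coverage_threshold <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    pairs = [(r.record_id, r.sequence) if hasattr(r, "record_id") else tuple(r)
             for r in records]
    if backend == "mmseqs2":
        return _cluster_mmseqs2(pairs, identity_threshold, coverage_threshold)
    if backend != "builtin":
        raise ValueError(f"unknown clustering backend: {backend!r}")

    order = sorted(pairs, key=lambda p: (-len(p[1]), p[0]))
    clusters: list[SequenceCluster] = []
    reps: list[str] = []
    for rid, seq in order:
        placed = False
        for cluster, rep_seq in zip(clusters, reps):
            ident, cov_rep, cov_new = pairwise_identity_coverage(rep_seq, seq)
            if (ident >= identity_threshold and cov_rep >= coverage_threshold
                    and cov_new >= coverage_threshold):
                cluster.member_ids.append(rid)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster([rid], rid))
            reps.append(seq)
    for cluster in clusters:
        cluster.member_ids.sort()
    clusters.sort(key=lambda c: c.representative_id)
    return clusters


def _cluster_mmseqs2(pairs, identity, coverage) -> list[SequenceCluster]:
    exe = shutil.which("mmseqs")
    if exe is None:
        raise ClusteringBackendError(
            "MMseqs2 executable not found on PATH; rerun with backend='builtin'")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        fasta = tmp / "in.fasta"
        fasta.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in pairs))
        db, cdb, tsv = tmp / "DB", tmp / "clusterDB", tmp / "clusters.tsv"
        for cmd in ([exe, "createdb", str(fasta), str(db)],
                    [exe, "cluster", str(db), str(cdb), str(tmp / "tmp"),
                     "--cov-mode", "0", "-c", str(coverage),
                     "--min-seq-id", str(identity)],
                    [exe, "createtsv", str(db), str(db), str(cdb), str(tsv)]):
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise ClusteringBackendError(proc.stderr)
        members: dict[str, list[str]] = {}
        for line in tsv.read_text().splitlines():
            rep, member = line.split("\t")[:2]
            members.setdefault(rep, []).append(member)
    return sorted((SequenceCluster(sorted(v), k) for k, v in members.items()),
                  key=lambda c: c.representative_id)


# ---------------------------------------------------------------------------
# multiple alignment
# ---------------------------------------------------------------------------

def align_cluster(sequences: Sequence[tuple[str, str]],
                  backend: str = "auto") -> Msa:
    """Align the (id, sequence) pairs of one cluster and post-process.

    ``backend``: "mafft" (external, options auto/amino/preservecase),
    "builtin" (center-star progressive alignment, BLOSUM62, affine gaps),
    or "auto" (MAFFT when on PATH, builtin otherwise).
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("empty cluster")
    if len(sequences) == 1:
        return postprocess_msa(sequences)
    if backend == "auto":
        backend = "mafft" if shutil.which("mafft") else "builtin"
    if backend == "mafft":
        rows = _align_mafft(sequences)
    elif backend == "builtin":
        rows = _align_center_star(sequences)
    else:
        raise ValueError(f"unknown alignment backend: {backend!r}")
    return postprocess_msa(rows)


def _align_mafft(sequences) -> list[tuple[str, str]]:
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        # keys guard against MAFFT id mangling
        fasta.write_text("".join(f">s{i}\n{seq}\n"
                                 for i, (_, seq) in enumerate(sequences)))
        proc = subprocess.run(
            ["mafft", "--auto", "--amino", "--preservecase", str(fasta)],
            capture_output=True, text=True)
    if proc.returncode != 0:
        raise AlignmentBackendError(f"mafft failed: {proc.stderr.strip()}")
    aligned: dict[str, str] = {}
    key = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            key = line[1:].split()[0]
            aligned[key] = ""
        elif key is not None:
            aligned[key] += line.strip()
    return [(rid, aligned[f"s{i}"]) for i, (rid, _) in enumerate(sequences)]


def _align_center_star(sequences) -> list[tuple[str, str]]:
    """Center-star progressive alignment (test-scale fallback).

    The center is the sequence with the highest total pairwise alignment
    score; every other sequence is aligned to it and the pairwise
    alignments are merged with the once-a-gap-always-a-gap rule.
    """
    n = len(sequences)
    seqs = [s for _, s in sequences]
    totals = np.zeros(n)
    cache = {}
    for i, j in combinations(range(n), 2):
        ali = _pairwise_alignment(seqs[i], seqs[j])
        cache[(i, j)] = ali
        totals[i] += ali.score
        totals[j] += ali.score
    center = int(np.argmax(totals))
    lc = len(seqs[center])

    # per sequence: insertions before each center position + match mapping
    inserts, matches = {}, {}
    for other in range(n):
        if other == center:
            continue
        key = (center, other) if (center, other) in cache else (other, center)
        ali = cache[key]
        trace = ali.trace if key == (center, other) else ali.trace[:, ::-1]
        ins = [[] for _ in range(lc + 1)]
        match = [-1] * lc
        cursor = 0
        for c_idx, o_idx in trace:
            if c_idx < 0:
                ins[cursor].append(int(o_idx))
            else:
                if o_idx >= 0:
                    match[c_idx] = int(o_idx)
                cursor = int(c_idx) + 1
        inserts[other], matches[other] = ins, match
    master = [max((len(inserts[o][k]) for o in inserts), default=0)
              for k in range(lc + 1)]

    out = []
    for idx, (rid, seq) in enumerate(sequences):
        chunks = []
        for k in range(lc + 1):
            if idx == center:
                chunk = "-" * master[k]
            else:
                ins = "".join(seq[i] for i in inserts[idx][k])
                chunk = ins + "-" * (master[k] - len(ins))
            chunks.append(chunk)
            if k < lc:
                if idx == center:
                    chunks.append(seq[k])
                else:
                    m = matches[idx][k]
                    chunks.append(seq[m] if m >= 0 else "-")
        out.append((rid, "".join(chunks)))
    return out


# ---------------------------------------------------------------------------
# MSA quality
# ---------------------------------------------------------------------------

def msa_identity_coverage(msa: Msa) -> tuple[float, float]:
    """(identity %, coverage %) of an alignment.

    Identity: average over columns of the fraction of row pairs sharing
    the same amino acid, among pairs where both rows have a residue ('X'
    counts as gap). Coverage: percentage of columns with a gap proportion
    below 20%.
    """
    n, p = msa.n_rows, msa.n_cols
    if p == 0:
        return 100.0, 100.0
    if n == 1:
        return 100.0, 100.0
    col_identities = []
    covered = 0
    for j in range(p):
        column = msa.column(j)
        residues = [c.upper() for c in column if not is_gap_like(c)]
        n_gaps = n - len(residues)
        if n_gaps / n < 0.2:
            covered += 1
        n_pairs = len(residues) * (len(residues) - 1) // 2
        if n_pairs == 0:
            continue
        same = sum(1 for a, b in combinations(residues, 2) if a == b)
        col_identities.append(same / n_pairs)
    identity = 100.0 * float(np.mean(col_identities)) if col_identities else 0.0
    return identity, 100.0 * covered / p


def sum_of_pairs_score(msa: Msa) -> float:
    """Normalized sum-of-pairs score of an alignment (<= 1).

    Column pairs score +1 for a match, -0.5 for a mismatch, -0.5 for a
    residue against a gap; gap-gap pairs (with 'X' counted as gap) score
    0. The raw score is divided by C(n,2) * L_eff, where L_eff is the
    largest per-row count of amino-acid characters.
    """
    n, p = msa.n_rows, msa.n_cols
    if n < 2:
        raise ValueError("sum-of-pairs score requires at least 2 rows")
    raw = 0.0
    for j in range(p):
        column = [c.upper() if not is_gap_like(c) else "-" for c in msa.column(j)]
        for a, b in combinations(column, 2):
            if a == "-" and b == "-":
                continue
            if a == "-" or b == "-":
                raw -= 0.5
            elif a == b:
                raw += 1.0
            else:
                raw -= 0.5
    l_eff = max(sum(1 for c in aligned if not is_gap_like(c))
                for _, aligned in msa.rows)
    if l_eff == 0:
        return 0.0
    return raw / (n * (n - 1) / 2 * l_eff)
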