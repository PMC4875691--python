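"""Per-cluster multiple alignment, supermatrix concatenation, gap stripping.

The built-in aligner is deterministic progressive alignment: a guide tree is
built from pairwise k-mer distances (UPGMA, ties broken by input order) and
profiles are merged along it with affine-gap global dynamic programming over
profile column frequencies.  An ``external_aligner`` escape hatch accepts
any FASTA-in/FASTA-out command for users who prefer a consistency-based
tool.  Downstream, per-gene alignments sharing one taxon set are
concatenated into a partitioned supermatrix, and columns containing at
least one gap can be stripped with the partition table remapped onto the
surviving columns.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._errors import ArgumentError, DataError
from .search import ScoringScheme

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap

GAP = "-"
_NUC_LETTERS = "ACGT"
_PROT_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "Alignment", "Supermatrix",
    "progressive_align", "concatenate_supermatrix", "strip_gap_columns",
    "write_alignment_fasta", "read_alignment_fasta",
    "write_partitions", "write_phylip",
]


@dataclass
class Alignment:
    """An aligned set of sequences with equal-length gapped rows."""

    ids: list[str]
    rows: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise DataError("ids and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise DataError("rows differ in length")

    @property
    def columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def row_for(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


@dataclass
class Supermatrix:
    """Concatenated alignment with a partition table.

    ``partitions`` holds (source id, start, end) in 0-based half-open
    column coordinates; partitions tile [0, columns) without overlap.
    """

    ids: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def as_alignment(self) -> Alignment:
        return Alignment(ids=list(self.ids), rows=list(self.rows), source="supermatrix")


# ---------------------------------------------------------------------------
# profile-profile affine-gap global DP


@_njit(cache=False)
def _nw_affine_ops(S, gap_open, gap_extend):  # pragma: no cover - jitted
    na, nb = S.shape
    NEG = -1e30
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)  # gap in B (consume A)
    Y = np.full((na + 1, nb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, nb + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + S[i - 1, j - 1]
            xo = M[i - 1, j] - gap_open - gap_extend
            xe = X[i - 1, j] - gap_extend
            X[i, j] = xo if xo >= xe else xe
            yo = M[i, j - 1] - gap_open - gap_extend
            ye = Y[i, j - 1] - gap_extend
            Y[i, j] = yo if yo >= ye else ye
    # traceback; prefer diagonal, then consuming A, then consuming B
    ops = np.empty(na + nb, dtype=np.int8)
    k = 0
    i, j = na, nb
    state = 0
    if X[i, j] > M[i, j] and X[i, j] >= Y[i, j]:
        state = 1
    elif Y[i, j] > M[i, j]:
        state = 2
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops[k] = 0
            k += 1
            prev = M[i - 1, j - 1]
            ns = 0
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                ns = 1
            if Y[i - 1, j - 1] > prev:
                ns = 2
            i -= 1
            j -= 1
            state = ns
        elif state == 1 or j == 0:
            ops[k] = 1
            k += 1
            if M[i - 1, j] - gap_open - gap_extend >= X[i - 1, j] - gap_extend:
                state = 0
            else:
                state = 1
            i -= 1
            if i == 0 and j > 0 and state == 0:
                state = 2
        else:
            ops[k] = 2
            k += 1
            if M[i, j - 1] - gap_open - gap_extend >= Y[i, j - 1] - gap_extend:
                state = 0
            else:
                state = 2
            j -= 1
            if j == 0 and i > 0 and state == 0:
                state = 1
    return ops[:k][::-1]


def _letters(scheme: ScoringScheme) -> str:
    return _NUC_LETTERS if scheme.mode == "nucleotide" else _PROT_LETTERS


def _score_matrix(scheme: ScoringScheme) -> np.ndarray:
    letters = _letters(scheme)
    n = len(letters)
    M = np.empty((n, n))
    if scheme.mode == "nucleotide":
        M.fill(scheme.mismatch)
        np.fill_diagonal(M, scheme.match)
    else:
        tbl = scheme.substitution_table
        for i, a in enumerate(letters):
            for j, b in enumerate(letters):
                M[i, j] = tbl[a, b]
    return M


def _profile_freqs(rows: Sequence[str], letters: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate(letters)}
    n = len(letters)
    cols = len(rows[0])
    F = np.zeros((cols, n))
    for row in rows:
        for j, c in enumerate(row):
            i = lut.get(c)
            if i is not None:
                F[j, i] += 1.0
    return F / len(rows)


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme, M: np.ndarray
) -> tuple[list[str], list[str]]:
    letters = _letters(scheme)
    FA = _profile_freqs(rows_a, letters)
    FB = _profile_freqs(rows_b, letters)
    S = FA @ M @ FB.T
    ops = _nw_affine_ops(
        np.ascontiguousarray(S, dtype=np.float64),
        float(scheme.gap_open), float(scheme.gap_extend),
    )
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == 0:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ia += 1
            ib += 1
        elif op == 1:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r in out_b:
                r.append(GAP)
            ia += 1
        else:
            for r in out_a:
                r.append(GAP)
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _kmer_distance_matrix(seqs: Sequence[str], k: int) -> np.ndarray:
    sets = [{s[i:i + k] for i in range(max(len(s) - k + 1, 1))} for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j]))
            D[i, j] = D[j, i] = 1.0 - shared / denom if denom else 1.0
    return D


def _upgma_merge_order(D: np.ndarray) -> list[tuple[int, int]]:
    """Greedy average-linkage merge order; ties broken by input order.

    Returns merges as (i, j) over cluster slots; the merged cluster keeps
    slot i (the lower index), so the order is reproducible for a fixed
    input ordering.
    """
    n = D.shape[0]
    D = D.astype(float).copy()
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int]] = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = D[i, j]
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        _, i, j = best
        merges.append((i, j))
        for m in active:
            if m in (i, j):
                continue
            D[i, m] = D[m, i] = (
                sizes[i] * D[i, m] + sizes[j] * D[j, m]
            ) / (sizes[i] + sizes[j])
        sizes[i] += sizes[j]
        active.remove(j)
    return merges


def progressive_align(
    sequences: Sequence[tuple[str, str]] | Mapping[str, str],
    scheme: ScoringScheme | None = None,
    guide_k: int = 6,
    source: str = "",
    external_aligner: str | None = None,
) -> Alignment:
    """Align two or more co-oriented sequences progressively.

    Deterministic for a fixed input order.  With ``external_aligner`` the
    sequences are instead piped through the given FASTA-in/FASTA-out
    command (e.g. ``"mafft --auto -"``) and the result is read back.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if len(items) < 2:
        raise ArgumentError("need at least two sequences to align")
    ids = [i for i, _ in items]
    seqs = [s.upper() for _, s in items]
    if external_aligner:
        return _run_external(ids, seqs, external_aligner, source)
    scheme = scheme or ScoringScheme.nucleotide()
    M = _score_matrix(scheme)
    D = _kmer_distance_matrix(seqs, guide_k)
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(seqs))
    }
    for i, j in _upgma_merge_order(D):
        idx_a, rows_a = profiles.pop(i)
        idx_b, rows_b = profiles.pop(j)
        new_a, new_b = _merge_profiles(rows_a, rows_b, scheme, M)
        profiles[i] = (idx_a + idx_b, new_a + new_b)
    (_, (order, rows)), = profiles.items()
    by_input = dict(zip(order, rows))
    aln = Alignment(
        ids=ids, rows=[by_input[i] for i in range(len(seqs))], source=source
    )
    for i, s in enumerate(seqs):  # invariant: ungapping reproduces inputs
        assert aln.ungapped(i) == s
    return aln


def _run_external(ids, seqs, command: str, source: str) -> Alignment:
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        with open(fin, "w") as fh:
            for i, s in zip(ids, seqs):
                fh.write(f">{i}\n{s}\n")
        out = subprocess.run(
            command.split() + [str(fin)], capture_output=True, text=True, check=True
        ).stdout
    got: dict[str, list[str]] = {}
    current = None
    for line in out.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            got[current] = []
        elif current is not None:
            got[current].append(line.strip())
    return Alignment(
        ids=list(ids), rows=["".join(got[i]).upper() for i in ids], source=source
    )


def concatenate_supermatrix(
    alignments: Sequence[Alignment], taxon_order: Sequence[str] | None = None
) -> Supermatrix:
    """Row-wise concatenation of alignments sharing one taxon set."""
    if not alignments:
        raise ArgumentError("no alignments to concatenate")
    taxa = set(alignments[0].ids)
    for aln in alignments:
        if set(aln.ids) != taxa:
            raise DataError(
                f"alignment {aln.source!r} has taxon set {sorted(aln.ids)}, "
                f"expected {sorted(taxa)}"
            )
    order = list(taxon_order) if taxon_order else sorted(taxa)
    if set(order) != taxa:
        raise DataError("taxon_order does not match the alignments' taxon set")
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in order}
    pos = 0
    for aln in alignments:
        for t in order:
            chunks[t].append(aln.row_for(t))
        parts.append((aln.source or f"part{len(parts)}", pos, pos + aln.columns))
        pos += aln.columns
    return Supermatrix(
        ids=order, rows=["".join(chunks[t]) for t in order], partitions=parts
    )


def strip_gap_columns(matrix: Supermatrix) -> Supermatrix:
    """Drop every column in which any row has a gap; remap partitions.

    Idempotent; surviving columns keep their relative order.
    """
    if not matrix.rows:
        return Supermatrix(ids=list(matrix.ids), rows=[], partitions=[])
    arr = np.array([list(r) for r in matrix.rows])
    keep = ~(arr == GAP).any(axis=0)
    kept_before = np.concatenate([[0], np.cumsum(keep)])
    rows = ["".join(r) for r in arr[:, keep]]
    parts = [
        (name, int(kept_before[s]), int(kept_before[e]))
        for name, s, e in matrix.partitions
    ]
    return Supermatrix(ids=list(matrix.ids), rows=rows, partitions=parts)


# ---------------------------------------------------------------------------
# I/O


def write_alignment_fasta(path, aln: Alignment | Supermatrix) -> None:
    with open(path, "w") as fh:
        for i, row in zip(aln.ids, aln.rows):
            fh.write(f">{i}\n{row}\n")


def read_alignment_fasta(path, source: str = "") -> Alignment:
    from .search import read_fasta

    recs = read_fasta(path)
    return Alignment(ids=[i for i, _ in recs], rows=[s for _, s in recs], source=source)


def write_partitions(path, matrix: Supermatrix) -> None:
    with open(path, "w") as fh:
        fh.write("source\tstart\tend\n")
        for name, s, e in matrix.partitions:
            fh.write(f"{name}\t{s}\t{e}\n")


def write_phylip(path, matrix: Supermatrix | Alignment) -> None:
    """Relaxed PHYLIP export."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.ids)} {matrix.columns}\n")
        for i, row in zip(matrix.ids, matrix.rows):
            fh.write(f"{i}  {row}\n")
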