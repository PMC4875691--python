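"""Local-alignment homology search with BLAST-style statistics and filters.

The searches in this pipeline mirror the classic tabular workflow: pairwise
local alignment (Smith-Waterman with affine gaps), bit scores and E-values
from Karlin-Altschul theory, and a three-way filter on E-value, alignment
length and percent identity.  The alignment engine is Biopython's
:class:`Bio.Align.PairwiseAligner`; this module owns the scoring conventions,
the seeded candidate discovery, the statistics and the filtering contract.

Sign/gap conventions
--------------------
``mismatch`` is stored as a negative score.  ``gap_open`` and ``gap_extend``
are stored as positive penalties; a gap of length ``L`` costs
``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._errors import ArgumentError, DataError

NUC_ALPHABET = frozenset("ACGTN")
PROT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

__all__ = [
    "ScoringScheme",
    "LocalHit",
    "FilterPolicy",
    "score_local_alignment",
    "seeded_search",
    "bit_score_evalue",
    "percent_identity",
    "filter_hits",
    "read_fasta",
    "write_fasta",
    "write_hit_table",
    "read_hit_table",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters for one search mode plus Karlin-Altschul constants.

    ``lam`` and ``K`` are supplied as constants of the scheme (they are not
    estimated from the data); the pipeline's decisions depend only on
    threshold crossings, so standard published values are adequate.
    """

    mode: str  # "nucleotide" | "protein"
    match: int = 1
    mismatch: int = -2
    substitution_table: object | None = None  # Bio.Align substitution matrix
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 1.33
    K: float = 0.621
    word_size: int = 11

    def __post_init__(self) -> None:
        if self.mode not in ("nucleotide", "protein"):
            raise ArgumentError(f"unknown mode {self.mode!r}")
        if self.mode == "nucleotide" and self.match <= 0:
            raise ArgumentError("match reward must be positive")
        if self.mode == "nucleotide" and self.mismatch >= 0:
            raise ArgumentError("mismatch score must be negative")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ArgumentError("gap penalties are stored positive")
        if self.lam <= 0 or self.K <= 0:
            raise ArgumentError("Karlin-Altschul lambda and K must be > 0")

    @classmethod
    def nucleotide(cls, **kw) -> "ScoringScheme":
        """Default nucleotide scheme: +1/-2, gaps 5/2, k=11."""
        return cls(mode="nucleotide", **kw)

    @classmethod
    def protein(cls, **kw) -> "ScoringScheme":
        """Default protein scheme: BLOSUM62, gaps 11/1, k=3."""
        kw.setdefault("substitution_table", substitution_matrices.load("BLOSUM62"))
        kw.setdefault("gap_open", 11)
        kw.setdefault("gap_extend", 1)
        kw.setdefault("lam", 0.267)
        kw.setdefault("K", 0.041)
        kw.setdefault("word_size", 3)
        return cls(mode="protein", **kw)

    @property
    def alphabet(self) -> frozenset:
        return NUC_ALPHABET if self.mode == "nucleotide" else PROT_ALPHABET


@dataclass
class LocalHit:
    """One best-scoring local alignment between a query and a subject.

    Coordinates are 0-based half-open on the forward strand of both
    sequences; ``subject_strand`` is "-" when the alignment pairs the query
    with the reverse complement of the subject.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    subject_strand: str = "+"
    query_row: str = field(default="", repr=False)
    subject_row: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise DataError("identity outside [0, 1]")
        if self.evalue < 0:
            raise DataError("negative E-value")
        if self.q_end - self.q_start > self.aln_length or self.s_end - self.s_start > self.aln_length:
            raise DataError("span exceeds alignment length")


@dataclass(frozen=True)
class FilterPolicy:
    """The study's hit filters: E <= 1e-5, length >= 100, identity >= 70 %.

    ``min_aln_length`` is in bp for nucleotide searches; for protein
    searches supply a value in residues.
    """

    max_evalue: float = 1e-5
    min_aln_length: int = 100
    min_identity: float = 0.70

    def __post_init__(self) -> None:
        if not (math.isfinite(self.max_evalue) and self.max_evalue > 0):
            raise ArgumentError("max_evalue must be finite and positive")
        if self.min_aln_length <= 0 or self.min_identity <= 0:
            raise ArgumentError("thresholds must be positive")

    def keeps(self, hit: LocalHit) -> bool:
        # Inclusive comparisons at the stated values ("maximum"/"minimum").
        return (
            hit.evalue <= self.max_evalue
            and hit.aln_length >= self.min_aln_length
            and hit.identity >= self.min_identity
        )


def _make_aligner(scheme: ScoringScheme, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if scheme.mode == "nucleotide":
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    else:
        aligner.substitution_matrix = scheme.substitution_table
    # Biopython charges open_gap_score on the first gap position; our
    # convention charges open + extend there.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _check_sequence(seq: str, scheme: ScoringScheme, what: str) -> str:
    if not seq:
        raise ArgumentError(f"empty {what} sequence")
    seq = seq.upper()
    bad = set(seq) - scheme.alphabet
    if bad:
        raise DataError(f"{what} contains symbols {sorted(bad)} outside the {scheme.mode} alphabet")
    return seq


def _rows_from_alignment(aln) -> tuple[str, str]:
    """Rebuild gapped query/subject rows from a Bio.Align.Alignment."""
    q, s = aln.sequences
    cq, cs = aln.coordinates
    rq, rs = [], []
    for i in range(1, len(cq)):
        dq, ds = cq[i] - cq[i - 1], cs[i] - cs[i - 1]
        if dq and ds:  # aligned block
            rq.append(str(q[cq[i - 1]:cq[i]]))
            rs.append(str(s[cs[i - 1]:cs[i]]))
        elif dq:
            rq.append(str(q[cq[i - 1]:cq[i]]))
            rs.append("-" * dq)
        else:
            rq.append("-" * ds)
            rs.append(str(s[cs[i - 1]:cs[i]]))
    return "".join(rq), "".join(rs)


def _count_gap_opens(row: str) -> int:
    opens = 0
    in_gap = False
    for c in row:
        if c == "-":
            if not in_gap:
                opens += 1
            in_gap = True
        else:
            in_gap = False
    return opens


def _align_one_strand(query: str, subject: str, scheme: ScoringScheme):
    aligner = _make_aligner(scheme)
    score = aligner.score(query, subject)
    if score <= 0:  # no positive-scoring local alignment exists
        return score, None
    return score, aligner.align(query, subject)[0]


def score_local_alignment(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    both_strands: bool = False,
) -> LocalHit | None:
    """Optimal affine-gap local alignment of two sequences.

    Returns the maximal-scoring local alignment as a :class:`LocalHit`
    (E-value computed with the pair's own ``m*n`` search space), or ``None``
    when no pair of residues scores positively.  With ``both_strands`` the
    reverse complement of the subject is also tried (nucleotide mode only)
    and the better strand wins; coordinates are always reported on the
    forward strand.
    """
    scheme = scheme or ScoringScheme.nucleotide()
    query = _check_sequence(query, scheme, "query")
    subject = _check_sequence(subject, scheme, "subject")

    score_f, aln_f = _align_one_strand(query, subject, scheme)
    strand, score, aln, subj_used = "+", score_f, aln_f, subject
    if both_strands and scheme.mode == "nucleotide":
        rc = str(Seq(subject).reverse_complement())
        score_r, aln_r = _align_one_strand(query, rc, scheme)
        if score_r > score_f:
            strand, score, aln, subj_used = "-", score_r, aln_r, rc
    if score <= 0 or aln is None:
        return None

    qrow, srow = _rows_from_alignment(aln)
    q_start, q_end = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    s_start, s_end = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
    if strand == "-":  # map back onto the forward strand
        n = len(subject)
        s_start, s_end = n - s_end, n - s_start
    cols = len(qrow)
    ident_cols = sum(a == b and a != "-" for a, b in zip(qrow, srow))
    mism = sum(a != b and a != "-" and b != "-" for a, b in zip(qrow, srow))
    gap_opens = _count_gap_opens(qrow) + _count_gap_opens(srow)
    bits, evalue = bit_score_evalue(score, scheme, len(query), len(subject))
    return LocalHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=int(round(score)),
        bit_score=bits,
        evalue=evalue,
        identity=ident_cols / cols,
        aln_length=cols,
        mismatches=mism,
        gap_opens=gap_opens,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        subject_strand=strand,
        query_row=qrow,
        subject_row=srow,
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def seeded_search(
    queries: Sequence[tuple[str, str]] | Mapping[str, str],
    subjects: Sequence[tuple[str, str]] | Mapping[str, str],
    scheme: ScoringScheme | None = None,
    word_size: int | None = None,
    score_cutoff: int = 0,
) -> list[LocalHit]:
    """Word-seeded all-vs-all local alignment search.

    Every query/subject pair sharing at least one exact ``word_size``-mer
    (on either strand in nucleotide mode) is extended to its optimal local
    alignment; the best hit per ``(query, subject)`` pair with raw score
    above ``score_cutoff`` is reported.  E-values use the database-wide
    search space ``m * n_total`` where ``n_total`` is the summed subject
    length.
    """
    scheme = scheme or ScoringScheme.nucleotide()
    k = word_size or scheme.word_size
    if scheme.mode == "nucleotide" and k < 4:
        raise ArgumentError("word size must be >= 4 in nucleotide mode")
    if scheme.mode == "protein" and k < 2:
        raise ArgumentError("word size must be >= 2 in protein mode")

    qitems = list(queries.items()) if isinstance(queries, Mapping) else list(queries)
    sitems = list(subjects.items()) if isinstance(subjects, Mapping) else list(subjects)
    qitems = [(i, _check_sequence(s, scheme, "query")) for i, s in qitems]
    sitems = [(i, _check_sequence(s, scheme, "subject")) for i, s in sitems]
    n_total = sum(len(s) for _, s in sitems)
    if n_total == 0 or not qitems:
        return []

    index: dict[str, set[int]] = {}
    for j, (_, sseq) in enumerate(sitems):
        for w in _kmer_set(sseq, k):
            index.setdefault(w, set()).add(j)

    hits: list[LocalHit] = []
    for qid, qseq in qitems:
        fwd_words = _kmer_set(qseq, k)
        cand_f: set[int] = set()
        for w in fwd_words:
            cand_f |= index.get(w, set())
        cand_r: set[int] = set()
        if scheme.mode == "nucleotide":
            rc_words = _kmer_set(str(Seq(qseq).reverse_complement()), k)
            for w in rc_words:
                cand_r |= index.get(w, set())
        per_query: list[LocalHit] = []
        for j in sorted(cand_f | cand_r):
            sid, sseq = sitems[j]
            best = score_local_alignment(
                qseq, sseq, scheme, qid, sid, both_strands=(j in cand_r)
            )
            if best is None or best.raw_score < score_cutoff or best.raw_score <= 0:
                continue
            _, best.evalue = bit_score_evalue(best.raw_score, scheme, len(qseq), n_total)
            per_query.append(best)
        per_query.sort(key=lambda h: (-h.raw_score, h.subject_id))
        hits.extend(per_query)
    return hits


def bit_score_evalue(
    raw_score: float, scheme: ScoringScheme, m: int, n: int
) -> tuple[float, float]:
    """Karlin-Altschul normalized score and expectation.

    S' = (lambda*S - ln K) / ln 2 ;  E = m * n * 2**(-S').
    """
    if m < 1 or n < 1:
        raise ArgumentError("search-space lengths must be >= 1")
    bits = (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)
    evalue = m * n * math.pow(2.0, -bits)
    return bits, evalue


def percent_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical columns over all alignment columns.

    Gapped columns count in the denominator, never the numerator; the
    statistic is symmetric in its arguments.
    """
    if len(row_a) != len(row_b):
        raise DataError("aligned rows differ in length")
    if not row_a:
        raise ArgumentError("empty alignment")
    same = sum(a == b and a != "-" for a, b in zip(row_a, row_b))
    return same / len(row_a)


def filter_hits(hits: Iterable[LocalHit], policy: FilterPolicy | None = None) -> list[LocalHit]:
    """Apply the E-value / length / identity filters, preserving order."""
    policy = policy or FilterPolicy()
    return [h for h in hits if policy.keeps(h)]


# ---------------------------------------------------------------------------
# FASTA and tabular I/O


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


_TABLE_COLS = (
    "query subject pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def write_hit_table(path, hits: Iterable[LocalHit]) -> None:
    """12-column tab-separated hit table, 1-based inclusive coordinates.

    On the minus strand the subject coordinates are swapped (start > end),
    the usual tabular signal for a reverse-strand hit.
    """
    with open(path, "w") as fh:
        for h in hits:
            if h.subject_strand == "+":
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.identity * 100:.2f}",
                        h.aln_length, h.mismatches, h.gap_opens,
                        h.q_start + 1, h.q_end, ss, se,
                        f"{h.evalue:.3g}", f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


def read_hit_table(path) -> list[LocalHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            strand = "+" if ss <= se else "-"
            if strand == "-":
                ss, se = se, ss
            hits.append(
                LocalHit(
                    query_id=f[0], subject_id=f[1],
                    raw_score=0,
                    bit_score=float(f[11]), evalue=float(f[10]),
                    identity=float(f[2]) / 100.0, aln_length=int(f[3]),
                    mismatches=int(f[4]), gap_opens=int(f[5]),
                    q_start=qs - 1, q_end=qe, s_start=ss - 1, s_end=se,
                    subject_strand=strand,
                )
            )
    return hits
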