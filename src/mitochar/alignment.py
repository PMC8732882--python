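"""Global pairwise and progressive multiple alignment with affine gaps.

Mitogenome-scale comparisons involve closely related sequences (often >90%
identity), so a straightforward Needleman-Wunsch/Gotoh aligner with a
k-mer guide tree and profile merging is adequate; no iterative refinement
is attempted.  Gap columns use '-'; N is an ambiguous base.

A gap of length k costs ``gap_open + k * gap_extend`` (both negative).
Traceback ties are broken deterministically: substitution first, then a
gap in the first profile, then a gap in the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

ALIGN_ALPHABET = frozenset("ACGTN-")


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring parameters (penalties are negative)."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class Alignment:
    """Equal-length aligned rows over {A,C,G,T,-,N} with unique taxon names."""

    names: list[str]
    rows: list[str]
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        for name, row in zip(self.names, self.rows):
            bad = set(row.upper()) - ALIGN_ALPHABET
            if bad:
                raise ValueError(f"{name}: illegal characters {sorted(bad)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def to_fasta(self, path) -> None:
        from .genome_io import write_fasta
        write_fasta(zip(self.names, self.rows), path)

    def columns(self) -> np.ndarray:
        """(n_sites, n_taxa) array of single characters."""
        mat = np.frombuffer("".join(self.rows).encode(), dtype="S1")
        return mat.reshape(self.n_taxa, self.n_sites).T


_COL_ORDER = "ACGTN-"
_COL_INDEX = {c: i for i, c in enumerate(_COL_ORDER)}


def _profile_counts(rows: list[str]) -> np.ndarray:
    """(n_columns, 6) counts of A,C,G,T,N,- per column."""
    n = len(rows[0])
    counts = np.zeros((n, 6))
    for r in rows:
        codes = np.frombuffer(r.encode(), dtype=np.uint8)
        for c, k in _COL_INDEX.items():
            counts[codes == ord(c), k] += 1
    return counts


def _substitution_matrix(rows_a: list[str], rows_b: list[str],
                         p: AlignParams) -> np.ndarray:
    """Column-pair scores: mean pair score over non-gap residue pairs
    (N pairs score 0; columns with no residue pairs score 0)."""
    S = np.zeros((6, 6))
    for i in range(4):
        for j in range(4):
            S[i, j] = p.match if i == j else p.mismatch
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    num = ca @ S @ cb.T
    den = np.outer(ca[:, :5].sum(axis=1), cb[:, :5].sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        sub = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return sub


def align_profiles(rows_a: list[str], rows_b: list[str],
                   params: AlignParams = AlignParams()) -> tuple[list[str], list[str], float]:
    """Gotoh global alignment of two profiles (each a list of aligned rows).

    Returns the gapped versions of both row sets and the alignment score.
    States: M (substitution column), X (gap in profile B: consumes A),
    Y (gap in profile A: consumes B).  Tie order M > Y > X makes the result
    deterministic and, for single sequences, prefers a gap in the first
    sequence over the second.  The recurrences are row-vectorized (the
    in-row Y dependence reduces to a running maximum), so kb-scale profiles
    align in seconds; quadratic memory still limits inputs to a few kb.
    """
    n, m = len(rows_a[0]), len(rows_b[0])
    p = params
    if (n + 1) * (m + 1) > 60_000_000:
        raise MemoryError(
            f"alignment DP of {n} x {m} exceeds the supported size; align "
            f"per-gene rather than whole genomes")
    sub = _substitution_matrix(rows_a, rows_b, p)

    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)   # gap in B (A advances)
    Y = np.full((n + 1, m + 1), NEG)   # gap in A (B advances)
    M[0, 0] = 0.0
    go_ge = p.gap_open + p.gap_extend
    X[1:, 0] = p.gap_open + np.arange(1, n + 1) * p.gap_extend
    Y[0, 1:] = p.gap_open + np.arange(1, m + 1) * p.gap_extend

    jj = np.arange(1, m + 1)
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        M[i, 1:] = np.maximum(np.maximum(Mi1[:-1], Xi1[:-1]), Yi1[:-1]) + sub[i - 1]
        X[i, 1:] = np.maximum(np.maximum(Mi1[1:], Yi1[1:]) + go_ge,
                              Xi1[1:] + p.gap_extend)
        # Y[i, j] = max_k<=j (max(M[i,k-1], X[i,k-1]) + go + (j-k+1)*ge)
        u = np.maximum(M[i, :-1], X[i, :-1])
        t = u + p.gap_open - (jj - 1) * p.gap_extend
        Y[i, 1:] = np.maximum.accumulate(t) + jj * p.gap_extend

    # traceback, tie order M > Y > X
    i, j = n, m
    state = max((("M", M[i, j]), ("Y", Y[i, j]), ("X", X[i, j])),
                key=lambda kv: kv[1])[0]
    score = max(M[n, m], X[n, m], Y[n, m])
    ops: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand in ("M", "Y", "X"):
                if abs({"M": M, "X": X, "Y": Y}[cand][i, j] - target) < tol:
                    state = cand
                    break
        elif state == "X":
            ops.append("X")
            if abs(X[i, j] - (M[i - 1, j] + p.gap_open + p.gap_extend)) < tol:
                state = "M"
            elif abs(X[i, j] - (Y[i - 1, j] + p.gap_open + p.gap_extend)) < tol:
                state = "Y"
            else:
                state = "X"
            i -= 1
        else:
            ops.append("Y")
            if abs(Y[i, j] - (M[i, j - 1] + p.gap_open + p.gap_extend)) < tol:
                state = "M"
            elif abs(Y[i, j] - (X[i, j - 1] + p.gap_open + p.gap_extend)) < tol:
                state = "X"
            else:
                state = "Y"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    ops.reverse()

    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "M":
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ia += 1
            ib += 1
        elif op == "X":
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ib += 1
    return (["".join(r) for r in out_a], ["".join(r) for r in out_b],
            float(score))


def pairwise_align(a: str, b: str,
                   params: AlignParams = AlignParams(),
                   names: tuple[str, str] = ("seq1", "seq2")) -> Alignment:
    """Global affine-gap alignment of two sequences.

    The returned alignment carries the optimal score in ``.score``.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    rows_a, rows_b, score = align_profiles([a.upper()], [b.upper()], params)
    return Alignment(names=list(names), rows=[rows_a[0], rows_b[0]],
                     score=score)


def pairwise_identity(a: str, b: str, exclude_gaps: bool = True) -> float:
    """Percent identity between two aligned rows.

    With ``exclude_gaps`` (default) columns containing a gap or an N in
    either row are excluded from the denominator; otherwise all columns
    count and gap/N columns count as mismatches.
    """
    if len(a) != len(b):
        raise ValueError("aligned rows differ in length")
    matches = denom = 0
    for x, y in zip(a.upper(), b.upper()):
        ambiguous = x in "-N" or y in "-N"
        if ambiguous and exclude_gaps:
            continue
        denom += 1
        if x == y and not ambiguous:
            matches += 1
    if denom == 0:
        raise ZeroDivisionError("no comparable columns")
    return 100.0 * matches / denom


def _kmer_profile(seq: str, k: int = 6) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        prof[kmer] = prof.get(kmer, 0) + 1
    return prof


def kmer_distance(a: str, b: str, k: int = 6) -> float:
    """1 - fraction of shared k-mers (of the smaller sequence's k-mer count)."""
    pa, pb = _kmer_profile(a, k), _kmer_profile(b, k)
    shared = sum(min(pa[m], pb[m]) for m in pa.keys() & pb.keys())
    denom = min(sum(pa.values()), sum(pb.values()))
    return 1.0 - shared / denom if denom else 1.0


def progressive_align(seqs: Sequence[tuple[str, str]] | Mapping[str, str],
                      params: AlignParams = AlignParams(),
                      k: int = 6) -> Alignment:
    """Progressive multiple alignment guided by k-mer distances.

    A UPGMA guide tree is built on pairwise k-mer distances and profiles
    are merged in guide-tree order by profile-profile Gotoh alignment.
    """
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    names = [n for n, _ in items]
    plain = [s.upper().replace("-", "") for _, s in items]
    if len(items) == 2:
        ra, rb, score = align_profiles([plain[0]], [plain[1]], params)
        return Alignment(names=names, rows=[ra[0], rb[0]], score=score)

    n = len(items)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = kmer_distance(plain[i], plain[j], k)
    order = linkage(squareform(dm, checks=False), method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([names[i]], [plain[i]]) for i in range(n)
    }
    total_score = 0.0
    for step, (ia, ib, _dist, _cnt) in enumerate(order):
        na, ra = clusters.pop(int(ia))
        nb, rb = clusters.pop(int(ib))
        ga, gb, score = align_profiles(ra, rb, params)
        total_score += score
        clusters[n + step] = (na + nb, ga + gb)
    (merged_names, merged_rows), = clusters.values()
    # restore input order
    perm = [merged_names.index(nm) for nm in names]
    return Alignment(names=names, rows=[merged_rows[i] for i in perm],
                     score=total_score)


def concatenate_genes(blocks: Sequence[tuple[str, Alignment]]
                      ) -> tuple[Alignment, list[tuple[str, int, int]]]:
    """Column-wise concatenation of per-gene alignments sharing one taxon set.

    Returns the supermatrix and a partition map of 1-based inclusive column
    ranges per gene.  A taxon missing from any block is an error naming the
    taxon and gene.
    """
    if not blocks:
        raise ValueError("no alignment blocks given")
    taxa = list(blocks[0][1].names)
    taxon_set = set(taxa)
    parts: list[tuple[str, int, int]] = []
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    col = 0
    for gene, aln in blocks:
        missing = taxon_set - set(aln.names)
        extra = set(aln.names) - taxon_set
        if missing or extra:
            problem = sorted(missing or extra)
            raise ValueError(f"gene {gene}: taxon set mismatch ({problem})")
        for t in taxa:
            pieces[t].append(aln.row(t))
        parts.append((gene, col + 1, col + aln.n_sites))
        col += aln.n_sites
    rows = ["".join(pieces[t]) for t in taxa]
    return Alignment(names=taxa, rows=rows), parts
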