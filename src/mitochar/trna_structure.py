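"""tRNA cloverleaf secondary-structure prediction by constrained stem search.

A mitochondrial tRNA (55-95 nt) is modelled as the canonical cloverleaf:
acceptor stem, DHU arm, anticodon arm, variable region and T-psi-C arm, in
5'->3' order with the acceptor stem's 3' half closing the molecule.  The
fold is found by exhaustive enumeration of all arm placements within
canonical geometry bounds, scoring each placement by the number of paired
bases (Watson-Crick A·U/G·C plus G·U wobble; T is treated as U).  No
thermodynamic energies are used: the criterion is combinatorial, which
keeps an independent brute-force oracle exact.

Mitochondrial tRNA-Ser(GCU) typically lacks the DHU arm; a fold where no
DHU placement achieves the minimum number of stem pairs is returned as a
degenerate cloverleaf with ``dhu_arm = None``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genetic_code import GeneticCode, VERTEBRATE_MITO
from .genome_io import reverse_complement

# valid base pairs on the DNA alphabet (T == U): WC and G.U wobble
_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


class FoldError(ValueError):
    """No cloverleaf placement satisfies the constraints."""


@dataclass(frozen=True)
class GeometryBounds:
    """Canonical cloverleaf arm-geometry bounds (inclusive ranges, nt/bp).

    Defaults follow canonical tRNA architecture; widen them for unusual
    structures.  ``min_dhu_pairs`` is the threshold below which the DHU arm
    is reported absent.
    """

    acceptor_stem: tuple[int, int] = (6, 7)
    spacer1: tuple[int, int] = (1, 3)        # acceptor 5' -> DHU stem
    dhu_stem: tuple[int, int] = (3, 4)
    dhu_loop: tuple[int, int] = (4, 11)
    spacer2: tuple[int, int] = (0, 2)        # DHU -> anticodon stem
    dhu_absent_region: tuple[int, int] = (4, 19)  # unpaired stretch when no DHU arm
    anticodon_stem: tuple[int, int] = (4, 5)
    anticodon_loop: int = 7                  # fixed; anticodon at loop 3-5
    variable_region: tuple[int, int] = (3, 23)
    tpsic_stem: tuple[int, int] = (4, 5)
    tpsic_loop: tuple[int, int] = (4, 9)
    tail: tuple[int, int] = (0, 4)           # discriminator / NCCA remnant
    min_dhu_pairs: int = 3
    min_len: int = 50
    max_len: int = 100


@dataclass(frozen=True)
class Stem:
    """One stem: aligned 5' and 3' halves with their valid paired positions.

    ``pairs`` is the longest contiguous run of valid pairs within the
    aligned halves (mismatched alignments contribute no pairs; bulges are
    not modelled).  Positions are 1-based within the tRNA.
    """

    five_prime_start: int
    five_prime_end: int
    three_prime_start: int
    three_prime_end: int
    pairs: tuple[tuple[int, int], ...]
    n_wc: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def nominal_length(self) -> int:
        return self.five_prime_end - self.five_prime_start + 1


@dataclass(frozen=True)
class Arm:
    """A stem plus its closing loop interval."""

    stem: Stem
    loop_start: int
    loop_end: int


@dataclass(frozen=True)
class Cloverleaf:
    """A folded tRNA: four arms (DHU optional) plus unpaired regions."""

    sequence: str
    acceptor_stem: Stem
    dhu_arm: Arm | None
    anticodon_arm: Arm
    anticodon: str  # loop positions 3-5, RNA alphabet
    tpsic_arm: Arm
    variable_region: tuple[int, int] | None
    score: int      # total paired bases (2 x number of pairs)
    n_wc_pairs: int

    @property
    def dhu_present(self) -> bool:
        return self.dhu_arm is not None

    def all_pairs(self) -> list[tuple[int, int]]:
        pairs = list(self.acceptor_stem.pairs)
        if self.dhu_arm is not None:
            pairs += list(self.dhu_arm.stem.pairs)
        pairs += list(self.anticodon_arm.stem.pairs)
        pairs += list(self.tpsic_arm.stem.pairs)
        return pairs

    def dot_bracket(self) -> str:
        s = ["."] * len(self.sequence)
        for i, j in self.all_pairs():
            s[i - 1], s[j - 1] = "(", ")"
        return "".join(s)


def _pair_kind(a: str, b: str) -> int:
    """2 for Watson-Crick, 1 for G.U wobble, 0 for no pair."""
    if (a, b) in _WC_PAIRS:
        return 2
    if (a, b) in _WOBBLE_PAIRS:
        return 1
    return 0


def _score_stem(seq: str, p5: int, p3: int, k: int) -> tuple[int, int, tuple[tuple[int, int], ...]]:
    """Longest contiguous valid-pair run of a k-bp stem placement.

    The 5' half starts at ``p5`` and the 3' half at ``p3`` (both 1-based);
    aligned pair i is (p5 + i, p3 + k - 1 - i).  Returns (run length,
    WC pairs in the run, run pairs).
    """
    best_len = best_wc = 0
    best_run: tuple[tuple[int, int], ...] = ()
    run: list[tuple[int, int]] = []
    run_wc = 0
    for i in range(k):
        a, b = p5 + i, p3 + k - 1 - i
        kind = _pair_kind(seq[a - 1], seq[b - 1])
        if kind:
            run.append((a, b))
            run_wc += 1 if kind == 2 else 0
            if len(run) > best_len or (len(run) == best_len and run_wc > best_wc):
                best_len, best_wc, best_run = len(run), run_wc, tuple(run)
        else:
            run, run_wc = [], 0
    return best_len, best_wc, best_run


def _iter_range(lo_hi: tuple[int, int]):
    return range(lo_hi[0], lo_hi[1] + 1)


def _placements(s: str, bounds: GeometryBounds, L: int, ac_dna: str | None):
    """Yield (key, cloverleaf) for every valid placement.

    key = (score, n_wc, -unpaired, -dhu_start) so that max(key) implements
    the documented tie-breaking.
    """
    loop7 = bounds.anticodon_loop
    for a in _iter_range(bounds.acceptor_stem):
        for t in _iter_range(bounds.tail):
            acc3 = L - t - a + 1
            tpsic_end_limit = acc3 - 1  # T-psi-C arm must end before acceptor 3'
            if acc3 - 1 <= a:
                continue
            _, acc_wc, acc_pairs = _score_stem(s, 1, acc3, a)
            acceptor = Stem(1, a, acc3, L - t, acc_pairs, acc_wc)

            for st in _iter_range(bounds.tpsic_stem):
                for lt in _iter_range(bounds.tpsic_loop):
                    # T-psi-C arm spans 2*st + lt and ends at tpsic_end_limit
                    tp_len = 2 * st + lt
                    tp_start = tpsic_end_limit - tp_len + 1
                    if tp_start <= a:
                        continue
                    _, tp_wc, tp_pairs = _score_stem(
                        s, tp_start, tp_start + st + lt, st)
                    tpsic = Arm(
                        Stem(tp_start, tp_start + st - 1,
                             tp_start + st + lt, tpsic_end_limit,
                             tp_pairs, tp_wc),
                        tp_start + st, tp_start + st + lt - 1)

                    for c in _iter_range(bounds.anticodon_stem):
                        ac_arm_len = 2 * c + loop7
                        # variable region sits between anticodon arm and T-psi-C arm
                        for v in _iter_range(bounds.variable_region):
                            ac_start = tp_start - v - ac_arm_len
                            if ac_start <= a + 1:
                                continue
                            loop_start = ac_start + c
                            anticodon_seq = s[loop_start + 1 : loop_start + 4]
                            if ac_dna is not None and anticodon_seq != ac_dna:
                                continue
                            _, ac_wc, ac_pairs = _score_stem(
                                s, ac_start, loop_start + loop7, c)
                            ac_arm = Arm(
                                Stem(ac_start, ac_start + c - 1,
                                     loop_start + loop7,
                                     ac_start + ac_arm_len - 1,
                                     ac_pairs, ac_wc),
                                loop_start, loop_start + loop7 - 1)
                            var = ((tp_start - v, tp_start - 1) if v > 0 else None)
                            anticodon_rna = anticodon_seq.replace("T", "U")

                            # --- DHU-present placements ---
                            for g1 in _iter_range(bounds.spacer1):
                                for d in _iter_range(bounds.dhu_stem):
                                    for g2 in _iter_range(bounds.spacer2):
                                        ld = ac_start - g2 - (a + g1) - 2 * d - 1
                                        if not (bounds.dhu_loop[0] <= ld
                                                <= bounds.dhu_loop[1]):
                                            continue
                                        d_start = a + g1 + 1
                                        run, d_wc, d_pairs = _score_stem(
                                            s, d_start, d_start + d + ld, d)
                                        if run < bounds.min_dhu_pairs:
                                            continue
                                        dhu = Arm(
                                            Stem(d_start, d_start + d - 1,
                                                 d_start + d + ld,
                                                 d_start + 2 * d + ld - 1,
                                                 d_pairs, d_wc),
                                            d_start + d, d_start + d + ld - 1)
                                        n_pairs = (len(acc_pairs) + run
                                                   + len(ac_pairs) + len(tp_pairs))
                                        n_wc = acc_wc + d_wc + ac_wc + tp_wc
                                        score = 2 * n_pairs
                                        unpaired = L - score
                                        cl = Cloverleaf(
                                            sequence=s, acceptor_stem=acceptor,
                                            dhu_arm=dhu, anticodon_arm=ac_arm,
                                            anticodon=anticodon_rna,
                                            tpsic_arm=tpsic,
                                            variable_region=var,
                                            score=score, n_wc_pairs=n_wc)
                                        yield ((score, n_wc, -unpaired,
                                                -d_start), cl)

                            # --- degenerate (DHU absent) placement ---
                            u = ac_start - a - 1
                            if (bounds.dhu_absent_region[0] <= u
                                    <= bounds.dhu_absent_region[1]):
                                n_pairs = (len(acc_pairs) + len(ac_pairs)
                                           + len(tp_pairs))
                                n_wc = acc_wc + ac_wc + tp_wc
                                score = 2 * n_pairs
                                cl = Cloverleaf(
                                    sequence=s, acceptor_stem=acceptor,
                                    dhu_arm=None, anticodon_arm=ac_arm,
                                    anticodon=anticodon_rna, tpsic_arm=tpsic,
                                    variable_region=var,
                                    score=score, n_wc_pairs=n_wc)
                                yield ((score, n_wc, -(L - score),
                                        -(L + 1)), cl)


def fold_cloverleaf(seq: str, anticodon: str | None = None,
                    bounds: GeometryBounds = GeometryBounds()) -> Cloverleaf:
    """Best-scoring cloverleaf fold of a tRNA sequence.

    Enumerates every arm placement within ``bounds`` and scores it by total
    paired bases (WC or G·U).  Among placements whose DHU stem achieves at
    least ``bounds.min_dhu_pairs`` pairs the best is returned; if none
    exists the best degenerate placement (``dhu_arm = None``) is returned —
    the typical state of mitochondrial tRNA-Ser(GCU).  Ties are broken by
    more WC pairs, then fewer unpaired nucleotides, then leftmost DHU arm.

    If ``anticodon`` is given (RNA alphabet), only placements whose
    anticodon-loop positions 3-5 spell it are considered; absence of any
    such placement raises :class:`FoldError`.
    """
    s = seq.upper().replace("U", "T")
    L = len(s)
    if not (bounds.min_len <= L <= bounds.max_len):
        raise FoldError(f"sequence length {L} outside bounds "
                        f"[{bounds.min_len}, {bounds.max_len}]")
    ac_dna = anticodon.upper().replace("U", "T") if anticodon else None
    if ac_dna is not None and ac_dna not in s:
        raise FoldError(
            f"anticodon {anticodon} does not occur in the sequence; no "
            f"anticodon-loop placement is possible")

    best_present = best_degenerate = None
    for key, cl in _placements(s, bounds, L, ac_dna):
        if cl.dhu_present:
            if best_present is None or key > best_present[0]:
                best_present = (key, cl)
        else:
            if best_degenerate is None or key > best_degenerate[0]:
                best_degenerate = (key, cl)
    if best_present is not None:
        return best_present[1]
    if best_degenerate is not None:
        return best_degenerate[1]
    raise FoldError(
        "no arm placement satisfies the geometry bounds"
        + (f" with anticodon {anticodon} centred in the anticodon loop"
           if ac_dna else ""))


def anticodon_to_amino_acid(anticodon: str,
                            code: GeneticCode = VERTEBRATE_MITO) -> str:
    """Three-letter amino acid decoded by an anticodon (5'->3', RNA).

    The anticodon is reverse-complemented to the codon it reads and decoded
    with the supplied genetic code; decoding to a stop raises ValueError.
    """
    ac = anticodon.upper().replace("U", "T")
    if len(ac) != 3 or any(b not in "ACGT" for b in ac):
        raise ValueError(f"bad anticodon {anticodon!r}")
    codon = reverse_complement(ac)
    if code.is_stop(codon):
        raise ValueError(f"anticodon {anticodon} decodes to stop codon {codon}")
    return code.amino_acid_3letter(codon)


def structure_report(cloverleaves: list[tuple[str, Cloverleaf]]):
    """Tabular summary of folded tRNAs.

    One row per tRNA: arm coordinates, pair counts, DHU-absence flag and
    dot-bracket string; total paired bases in column ``pairs``.
    """
    import pandas as pd

    recs = []
    for name, cl in cloverleaves:
        def _fmt(stem: Stem) -> str:
            return (f"{stem.five_prime_start}-{stem.five_prime_end}/"
                    f"{stem.three_prime_start}-{stem.three_prime_end}")
        recs.append({
            "name": name,
            "length": len(cl.sequence),
            "anticodon": cl.anticodon,
            "acceptor": _fmt(cl.acceptor_stem),
            "dhu": _fmt(cl.dhu_arm.stem) if cl.dhu_arm else "absent",
            "anticodon_arm": _fmt(cl.anticodon_arm.stem),
            "tpsic": _fmt(cl.tpsic_arm.stem),
            "pairs": cl.score,
            "wc_pairs": cl.n_wc_pairs,
            "dhu_present": cl.dhu_present,
            "dot_bracket": cl.dot_bracket(),
        })
    df = pd.DataFrame(recs, columns=[
        "name", "length", "anticodon", "acceptor", "dhu", "anticodon_arm",
        "tpsic", "pairs", "wc_pairs", "dhu_present", "dot_bracket"])
    df.attrs["n_degenerate"] = int((~df["dhu_present"]).sum()) if len(df) else 0
    return df
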