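"""Base composition, AT/GC skew and codon-usage statistics.

Skews quantify strand asymmetry of the mitochondrial duplex:

    AT skew = (A - T) / (A + T)
    GC skew = (G - C) / (G + C)

Both are scale-invariant (counts or percentages give the same value) and
flip sign under reverse complementation, so genes encoded on the light
strand show inverted skews when composed on their coding strand.

Provenance matters for reproduction of printed tables: skews computed from
raw counts generally differ in the fourth decimal from skews recomputed
from percentages that were first rounded to one or two decimals.  The
functions here accept either; callers choose the provenance explicitly.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .genetic_code import GeneticCode, VERTEBRATE_MITO
from .genome_io import Mitogenome, extract_feature


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding as used in printed tables (2.5 -> 3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionRow:
    """Composition of one region: percentages, skews and raw counts."""

    label: str
    pct_A: float
    pct_C: float
    pct_G: float
    pct_T: float
    pct_AT: float
    at_skew: float
    gc_skew: float
    length_bp: int
    counts: tuple[int, int, int, int]  # raw A, C, G, T counts (N excluded)


def at_skew(freq_A: float, freq_T: float) -> float:
    """(A - T) / (A + T); accepts counts or percentages (scale-invariant)."""
    denom = freq_A + freq_T
    if denom <= 0:
        raise ZeroDivisionError("AT skew undefined: A + T == 0")
    return (freq_A - freq_T) / denom


def gc_skew(freq_G: float, freq_C: float) -> float:
    """(G - C) / (G + C); accepts counts or percentages (scale-invariant)."""
    denom = freq_G + freq_C
    if denom <= 0:
        raise ZeroDivisionError("GC skew undefined: G + C == 0")
    return (freq_G - freq_C) / denom


def base_composition(seq: str, label: str = "", pct_decimals: int = 2,
                     skew_decimals: int = 4) -> CompositionRow:
    """Base percentages, A+T content and skews of a sequence.

    N bases are excluded from both numerator and denominator; percentages
    are rounded half-up to ``pct_decimals`` and skews to ``skew_decimals``
    for display, while ``counts`` retains the raw tallies.
    """
    if not seq:
        raise ValueError(f"{label or '<sequence>'}: empty sequence")
    tally = Counter(seq.upper())
    a, c, g, t = tally["A"], tally["C"], tally["G"], tally["T"]
    n_valid = a + c + g + t
    if n_valid == 0:
        raise ValueError(f"{label or '<sequence>'}: no unambiguous bases")
    pct = {b: 100.0 * tally[b] / n_valid for b in "ACGT"}
    at = at_skew(a, t) if a + t > 0 else float("nan")
    gc = gc_skew(g, c) if g + c > 0 else float("nan")
    return CompositionRow(
        label=label,
        pct_A=round_half_up(pct["A"], pct_decimals),
        pct_C=round_half_up(pct["C"], pct_decimals),
        pct_G=round_half_up(pct["G"], pct_decimals),
        pct_T=round_half_up(pct["T"], pct_decimals),
        pct_AT=round_half_up(pct["A"] + pct["T"], pct_decimals),
        at_skew=round_half_up(at, skew_decimals) if at == at else at,
        gc_skew=round_half_up(gc, skew_decimals) if gc == gc else gc,
        length_bp=len(seq),
        counts=(a, c, g, t),
    )


def skews_from_percentages(pct_A: float, pct_C: float, pct_G: float,
                           pct_T: float, decimals: int = 4) -> tuple[float, float]:
    """Recompute (AT skew, GC skew) from already-rounded printed percentages.

    This is the entry point for verifying printed tables: it deliberately
    uses the rounded percentages as given, so its output matches a table
    whose skews were derived from those displayed values.
    """
    return (round_half_up(at_skew(pct_A, pct_T), decimals),
            round_half_up(gc_skew(pct_G, pct_C), decimals))


def composition_report(genome: Mitogenome, pct_decimals: int = 2,
                       skew_decimals: int = 4) -> list[CompositionRow]:
    """Per-region composition rows for a characterized genome.

    Row order: whole genome; pooled rRNA; each rRNA; pooled PCGs; each PCG;
    pooled tRNA.  Pooled rows concatenate the coding-strand sequences of
    their genes (overlapping genome positions counted once per gene), so a
    light-strand gene such as ND6 contributes — and individually shows —
    skews of inverted sign relative to heavy-strand genes.
    """
    kw = dict(pct_decimals=pct_decimals, skew_decimals=skew_decimals)
    by_cat: dict[str, list[tuple[str, str]]] = {"rRNA": [], "PCG": [], "tRNA": []}
    for f in genome.features:
        if f.category in by_cat:
            by_cat[f.category].append((f.name, extract_feature(genome, f)))

    rows = [base_composition(genome.sequence, label="whole genome", **kw)]
    for cat, pooled_label in (("rRNA", "ribosomal RNA"),
                              ("PCG", "protein-coding genes")):
        seqs = by_cat[cat]
        if seqs:
            rows.append(base_composition("".join(s for _, s in seqs),
                                         label=pooled_label, **kw))
            rows.extend(base_composition(s, label=name, **kw) for name, s in seqs)
    if by_cat["tRNA"]:
        rows.append(base_composition("".join(s for _, s in by_cat["tRNA"]),
                                     label="transfer RNA", **kw))
    return rows


def composition_frame(rows: Sequence[CompositionRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "Region": [r.label for r in rows],
        "Adenine(%)": [r.pct_A for r in rows],
        "Cytosine(%)": [r.pct_C for r in rows],
        "Guanine(%)": [r.pct_G for r in rows],
        "Thymine(%)": [r.pct_T for r in rows],
        "A+T(%)": [r.pct_AT for r in rows],
        "AT skew": [r.at_skew for r in rows],
        "GC skew": [r.gc_skew for r in rows],
        "Length (bp)": [r.length_bp for r in rows],
    })


class InternalStopWarning(UserWarning):
    """An in-frame stop codon occurs before the end of a CDS."""


@dataclass
class CodonUsageTable:
    """Per-codon counts and relative synonymous codon usage (RSCU).

    RSCU of a codon is its observed count divided by the mean count over
    its synonymous family; within a used family RSCU values average to 1.
    Stop codons are tallied separately and excluded from RSCU.
    """

    counts: dict[str, int]
    rscu: dict[str, float]
    stop_counts: dict[str, int]
    n_codons: int


def codon_usage(cds_list: Sequence[str] | Sequence[tuple[str, str]],
                code: GeneticCode = VERTEBRATE_MITO) -> CodonUsageTable:
    """Codon counts and RSCU over a set of strand-oriented CDS sequences.

    Incomplete trailing codons (from T--/TA- stops) are excluded.  A final
    complete stop codon is tallied under ``stop_counts``; an internal stop
    raises :class:`InternalStopWarning` naming the gene and codon position.
    """
    counts: Counter[str] = Counter()
    stop_counts: Counter[str] = Counter()
    for entry in cds_list:
        name, cds = entry if isinstance(entry, tuple) else ("<cds>", entry)
        cds = cds.upper().replace("U", "T")
        n_full = len(cds) // 3
        for k in range(n_full):
            codon = cds[3 * k : 3 * k + 3]
            if code.is_stop(codon):
                if k == n_full - 1:
                    stop_counts[codon] += 1
                else:
                    warnings.warn(
                        f"{name}: internal stop codon {codon} at codon "
                        f"position {k + 1}", InternalStopWarning, stacklevel=2,
                    )
                    counts[codon] += 1
            else:
                counts[codon] += 1

    rscu: dict[str, float] = {}
    for _aa, family in code.synonymous_families().items():
        total = sum(counts[c] for c in family)
        if total == 0:
            continue
        mean = total / len(family)
        for c in family:
            rscu[c] = counts[c] / mean
    return CodonUsageTable(counts=dict(counts), rscu=rscu,
                           stop_counts=dict(stop_counts),
                           n_codons=sum(counts.values()) + sum(stop_counts.values()))


def codon_usage_frame(table: CodonUsageTable,
                      code: GeneticCode = VERTEBRATE_MITO) -> pd.DataFrame:
    """Codon usage as a DataFrame sorted by amino acid then codon."""
    recs = []
    for aa, family in sorted(code.synonymous_families().items()):
        for codon in family:
            recs.append({
                "AminoAcid": aa, "Codon": codon,
                "Count": table.counts.get(codon, 0),
                "RSCU": round_half_up(table.rscu.get(codon, 0.0), 4)
                        if codon in table.rscu else float("nan"),
            })
    for codon in sorted(code.stop_codons):
        recs.append({"AminoAcid": "*", "Codon": codon,
                     "Count": table.stop_counts.get(codon, 0),
                     "RSCU": float("nan")})
    return pd.DataFrame(recs)
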