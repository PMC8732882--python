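"""Annotation-table metrics for a characterized mitogenome.

Given a genome and its ordered feature list, this module computes the
columns of a standard mitogenome characterization table: gene lengths,
intergenic nucleotides (negative values denote overlaps), start codons and
complete/incomplete stop codons under the vertebrate mitochondrial code.

Conventions
-----------
* Gene length is ``to - from + 1`` (1-based closed intervals).
* Intergenic nucleotides of row *i* (in table order) are
  ``from(i) - to(i-1) - 1`` computed on H-strand coordinates regardless of
  strand; the first row is 0 by convention.  The circular gap from the last
  feature back to the first is reported separately.
* A PCG whose length is divisible by 3 must end on a complete stop codon;
  length mod 3 == 1 requires a trailing T ("T--"), mod 3 == 2 a trailing
  TA ("TA-") — the incomplete stops completed by polyadenylation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genetic_code import GeneticCode, VERTEBRATE_MITO
from .genome_io import GeneFeature, Mitogenome, extract_feature

INCOMPLETE_STOP_T = "T--"
INCOMPLETE_STOP_TA = "TA-"


class AnnotationInconsistency(ValueError):
    """Trailing bases of a PCG are not a valid (incomplete) stop codon."""


class NonCanonicalStartWarning(UserWarning):
    """A PCG does not start with an ATN codon."""


@dataclass(frozen=True)
class CharacterizationRow:
    """One line of the characterization table."""

    name: str
    start: int
    end: int
    length_bp: int
    anticodon: str | None
    start_codon: str | None
    stop_codon: str | None
    intergenic: int
    strand: str


def gene_length(feature: GeneFeature) -> int:
    """Length in bp of a 1-based closed interval."""
    return feature.end - feature.start + 1


def intergenic_nucleotides(features: Sequence[GeneFeature]) -> list[int]:
    """Spacer lengths between consecutive features in table order.

    Negative values are overlaps. The first feature gets 0 by convention.
    """
    values: list[int] = []
    for i, f in enumerate(features):
        if i == 0:
            values.append(0)
        else:
            values.append(f.start - features[i - 1].end - 1)
    return values


def circular_gap(features: Sequence[GeneFeature], genome_length: int) -> int:
    """Unannotated nucleotides between the last feature's end and the first
    feature's start going around the circle."""
    if not features:
        return genome_length
    return (genome_length - features[-1].end) + (features[0].start - 1)


def detect_start_codon(cds: str, code: GeneticCode = VERTEBRATE_MITO) -> tuple[str, bool]:
    """First codon of a strand-oriented CDS and whether it is an ATN start."""
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon: {cds!r}")
    first = cds[:3].upper()
    return first, first in code.start_codons


def classify_stop_codon(cds: str, code: GeneticCode = VERTEBRATE_MITO,
                        gene: str = "<gene>") -> str:
    """Stop label of a strand-oriented CDS.

    Complete stops are returned as the triplet (TAA/TAG/AGA/AGG); a CDS of
    length mod 3 == 1 must end in T ("T--"), mod 3 == 2 in TA ("TA-").
    """
    if len(cds) < 3:
        raise ValueError(f"{gene}: CDS shorter than one codon")
    rem = len(cds) % 3
    if rem == 0:
        last = cds[-3:]
        if not code.is_stop(last):
            raise AnnotationInconsistency(
                f"{gene}: length divisible by 3 but final codon {last} is not "
                f"a stop in the {code.id} code"
            )
        return last
    if rem == 1:
        if cds[-1] != "T":
            raise AnnotationInconsistency(
                f"{gene}: expected trailing T (incomplete stop), found {cds[-1]!r}"
            )
        return INCOMPLETE_STOP_T
    if cds[-2:] != "TA":
        raise AnnotationInconsistency(
            f"{gene}: expected trailing TA (incomplete stop), found {cds[-2:]!r}"
        )
    return INCOMPLETE_STOP_TA


def build_characterization_table(genome: Mitogenome,
                                 code: GeneticCode = VERTEBRATE_MITO,
                                 ) -> list[CharacterizationRow]:
    """One row per feature in table order, with all computed columns.

    Non-ATN start codons raise :class:`NonCanonicalStartWarning` (a warning,
    not an error: other taxa may legitimately use them); inconsistent stop
    annotations raise :class:`AnnotationInconsistency`.
    """
    rows: list[CharacterizationRow] = []
    gaps = intergenic_nucleotides(genome.features)
    for feature, gap in zip(genome.features, gaps):
        start_codon = stop_codon = None
        if feature.category == "PCG":
            cds = extract_feature(genome, feature)
            start_codon, is_atn = detect_start_codon(cds, code)
            if not is_atn:
                warnings.warn(
                    f"{feature.name}: non-ATN start codon {start_codon}",
                    NonCanonicalStartWarning, stacklevel=2,
                )
            stop_codon = classify_stop_codon(cds, code, gene=feature.name)
        rows.append(CharacterizationRow(
            name=feature.name, start=feature.start, end=feature.end,
            length_bp=gene_length(feature), anticodon=feature.anticodon,
            start_codon=start_codon, stop_codon=stop_codon,
            intergenic=gap, strand=feature.strand,
        ))
    return rows


def characterization_frame(rows: Sequence[CharacterizationRow]) -> pd.DataFrame:
    """Characterization rows as a DataFrame with the standard column set."""
    return pd.DataFrame({
        "Gene": [r.name for r in rows],
        "From": [r.start for r in rows],
        "To": [r.end for r in rows],
        "Length": [r.length_bp for r in rows],
        "Anticodon": [r.anticodon or "" for r in rows],
        "Start": [r.start_codon or "" for r in rows],
        "Stop": [r.stop_codon or "" for r in rows],
        "Intergenic": [r.intergenic for r in rows],
        "Strand": [r.strand for r in rows],
    })


def count_by_strand_and_category(features: Sequence[GeneFeature]) -> dict[str, dict[str, int]]:
    """Feature counts per category and strand, e.g. counts['PCG']['H']."""
    counts: dict[str, dict[str, int]] = {
        cat: {"H": 0, "L": 0} for cat in ("PCG", "tRNA", "rRNA", "control")
    }
    for f in features:
        counts[f.category][f.strand] += 1
    return counts


def overlapping_pairs(features: Sequence[GeneFeature]) -> list[tuple[str, str, int]]:
    """Consecutive feature pairs that overlap, with overlap size in bp."""
    out = []
    gaps = intergenic_nucleotides(features)
    for i in range(1, len(features)):
        if gaps[i] < 0:
            out.append((features[i - 1].name, features[i].name, -gaps[i]))
    return out
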