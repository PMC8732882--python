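"""Synthetic annotated mitogenomes and evolved sequence sets.

The generator realizes a :class:`GenomeTemplate` — an ordered gene plan of
lengths, strands, start codons, stop types and intergenic spacing
(negative values are overlaps, as in real mitogenomes where e.g. ATP8 and
ATP6 share 40 bp) — into a concrete genome whose characterization
reproduces the plan exactly.  The default template mirrors the 38-feature
organization of a Chinese-pangolin mitochondrial genome, including its
annotation quirks (a 27-bp gene/tRNA overlap, a 113-nt spacer before the
control region), so downstream code is exercised on realistic oddities.

Overlap handling: protein-coding start/stop positions are written first as
hard constraints (conflicting writes make the template unrealizable);
tRNA cloverleaf sequences and composition-sampled filler follow; finally a
repair pass resamples free positions of any in-frame stop codon until
every PCG frame is stop-free.  tRNA bases inside a PCG overlap may be
adjusted by repair, mildly degrading that tRNA's fold — as in real
genomes, where overlapping tRNAs are completed by mRNA editing.

All sampling flows through one seeded ``numpy`` generator; identical
(template, seed) pairs give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .annotation_metrics import build_characterization_table
from .genetic_code import GeneticCode, VERTEBRATE_MITO
from .genome_io import (GeneFeature, Mitogenome, read_feature_table,
                        reverse_complement)
from .phylogeny import PhyloModel, PhyloTree, _TransitionCache
from .trna_structure import (Arm, Cloverleaf, GeometryBounds, Stem,
                             fold_cloverleaf)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = np.array(list("ACGT"))

#: Default per-category base-composition targets (A, C, G, T fractions) on
#: the coding strand, chosen to match typical pangolin mitogenome values.
DEFAULT_COMPOSITION: dict[str, tuple[float, float, float, float]] = {
    "PCG": (0.3184, 0.2935, 0.1328, 0.2553),
    "rRNA": (0.3792, 0.2154, 0.1774, 0.2280),
    "tRNA": (0.3646, 0.2094, 0.1538, 0.2722),
    "control": (0.345, 0.269, 0.132, 0.254),
    "spacer": (0.345, 0.269, 0.132, 0.254),
}

STOP_TYPES = ("TAA", "TAG", "AGA", "AGG", "T--", "TA-")


class TemplateError(ValueError):
    """The template cannot be realized as a concrete genome."""


@dataclass(frozen=True)
class TemplateFeature:
    """One planned feature: length/strand plus codon plan for PCGs."""

    name: str
    category: str
    length: int
    strand: str = "H"
    intergenic: int = 0          # gap to previous feature; first feature: offset from 1
    anticodon: str | None = None
    start_codon: str | None = None
    stop_type: str | None = None
    dhu_present: bool = True     # tRNA only


@dataclass(frozen=True)
class GenomeTemplate:
    """An ordered gene plan plus per-category composition targets."""

    features: tuple[TemplateFeature, ...]
    composition: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    id: str = "synthetic-mitogenome"
    trailing_bases: int = 0      # unannotated bases after the last feature

    def realized_coordinates(self) -> list[tuple[int, int]]:
        """1-based (start, end) for each feature from lengths + intergenic."""
        coords = []
        prev_end = 0
        for i, f in enumerate(self.features):
            start = (1 + f.intergenic) if i == 0 else prev_end + f.intergenic + 1
            end = start + f.length - 1
            if start < 1:
                raise TemplateError(f"{f.name}: start {start} < 1")
            coords.append((start, end))
            prev_end = end
        return coords

    def genome_length(self) -> int:
        return max(e for _s, e in self.realized_coordinates()) + self.trailing_bases

    def validate(self, code: GeneticCode = VERTEBRATE_MITO) -> None:
        coords = self.realized_coordinates()
        for i, (f, (s, e)) in enumerate(zip(self.features, coords)):
            if f.category == "PCG":
                if f.start_codon is None or f.stop_type is None:
                    raise TemplateError(f"{f.name}: PCG needs start codon and stop type")
                if f.start_codon not in code.start_codons:
                    raise TemplateError(f"{f.name}: start {f.start_codon} is not ATN")
                if f.stop_type not in STOP_TYPES:
                    raise TemplateError(f"{f.name}: unknown stop type {f.stop_type}")
                want = {"T--": 1, "TA-": 2}.get(f.stop_type, 0)
                if f.length % 3 != want:
                    raise TemplateError(
                        f"{f.name}: length {f.length} mod 3 = {f.length % 3} "
                        f"inconsistent with stop type {f.stop_type}")
                if f.length < 6:
                    raise TemplateError(f"{f.name}: PCG too short")
            if f.category == "tRNA" and f.anticodon is None:
                raise TemplateError(f"{f.name}: tRNA needs an anticodon")
            if i > 0 and f.intergenic < 0:
                overlap = -f.intergenic
                if overlap >= f.length or overlap >= self.features[i - 1].length:
                    raise TemplateError(
                        f"{f.name}: overlap {overlap} not shorter than both genes")

    def to_features(self) -> list[GeneFeature]:
        return [GeneFeature(name=f.name, category=f.category, start=s, end=e,
                            anticodon=f.anticodon, strand=f.strand)
                for f, (s, e) in zip(self.features, self.realized_coordinates())]


@dataclass
class SimulationTruth:
    """Everything needed to check and regenerate a synthetic dataset."""

    template: GenomeTemplate
    features: list[GeneFeature]
    seed: int
    trna_arms: dict[str, Cloverleaf] = field(default_factory=dict)

    def to_json(self) -> str:
        def feat_dict(tf: TemplateFeature) -> dict:
            return {k: getattr(tf, k) for k in (
                "name", "category", "length", "strand", "intergenic",
                "anticodon", "start_codon", "stop_type", "dhu_present")}
        return json.dumps({
            "id": self.template.id,
            "seed": self.seed,
            "trailing_bases": self.template.trailing_bases,
            "composition": {k: list(v) for k, v in
                            self.template.composition.items()},
            "plan": [feat_dict(f) for f in self.template.features],
            "coordinates": {f.name: [f.start, f.end] for f in self.features},
        }, indent=1)

    @staticmethod
    def template_from_json(text: str) -> tuple["GenomeTemplate", int]:
        obj = json.loads(text)
        feats = tuple(TemplateFeature(**d) for d in obj["plan"])
        tpl = GenomeTemplate(
            features=feats,
            composition={k: tuple(v) for k, v in obj["composition"].items()},
            id=obj["id"], trailing_bases=obj.get("trailing_bases", 0))
        return tpl, obj["seed"]


# ---------------------------------------------------------------------------
# default template mirroring the reference pangolin annotation
# ---------------------------------------------------------------------------

def reference_features() -> list[GeneFeature]:
    """The packaged 38-feature reference annotation (coordinates included)."""
    ref = resources.files("mitochar.data") / "pangolin_mtdna_features.tsv"
    with resources.as_file(ref) as path:
        return read_feature_table(path)


def default_template() -> GenomeTemplate:
    """Template whose plan reproduces the packaged reference annotation:
    38 features, reference lengths/overlaps, ATN starts, the observed mix
    of complete and incomplete stops, and a DHU-less tRNA-Ser(GCU)."""
    feats = reference_features()
    plan_text = (resources.files("mitochar.data") / "pcg_codon_plan.json").read_text()
    pcg_plan = json.loads(plan_text)["plan"]
    out: list[TemplateFeature] = []
    prev_end = 0
    for i, f in enumerate(feats):
        intergenic = (f.start - 1) if i == 0 else f.start - prev_end - 1
        codons = pcg_plan.get(f.name, {})
        out.append(TemplateFeature(
            name=f.name, category=f.category, length=f.length,
            strand=f.strand, intergenic=intergenic, anticodon=f.anticodon,
            start_codon=codons.get("start"), stop_type=codons.get("stop"),
            dhu_present=(f.name != "tRNA-Ser(GCU)"),
        ))
        prev_end = f.end
    return GenomeTemplate(features=tuple(out), id="synthetic-pangolin-mtDNA")


# ---------------------------------------------------------------------------
# tRNA generation
# ---------------------------------------------------------------------------

def _geometry_combos(length: int, dhu_present: bool,
                     bounds: GeometryBounds) -> list[tuple[int, ...]]:
    """All arm-geometry tuples realizing a given total length."""
    combos = []
    rng_ = lambda pair: range(pair[0], pair[1] + 1)
    for a in rng_(bounds.acceptor_stem):
        for c in rng_(bounds.anticodon_stem):
            for s in rng_(bounds.tpsic_stem):
                for lt in rng_(bounds.tpsic_loop):
                    for t in rng_(bounds.tail):
                        fixed = 2 * a + (2 * c + 7) + (2 * s + lt) + t
                        if dhu_present:
                            for g1 in rng_(bounds.spacer1):
                                for d in rng_(bounds.dhu_stem):
                                    for g2 in rng_(bounds.spacer2):
                                        for ld in rng_(bounds.dhu_loop):
                                            for v in rng_(bounds.variable_region):
                                                if (fixed + g1 + 2 * d + ld
                                                        + g2 + v == length):
                                                    combos.append(
                                                        (a, g1, d, ld, g2, c,
                                                         v, s, lt, t))
                        else:
                            for u in rng_(bounds.dhu_absent_region):
                                for v in rng_(bounds.variable_region):
                                    if fixed + u + v == length:
                                        combos.append((a, u, c, v, s, lt, t))
    return combos


def _sample_bases(rng: np.random.Generator, n: int,
                  freqs: Sequence[float] | None = None) -> str:
    p = None if freqs is None else np.asarray(freqs) / np.sum(freqs)
    return "".join(rng.choice(_BASES, size=n, p=p))


def _complement_stem(seq5: str, rng: np.random.Generator,
                     wobble_fraction: float) -> str:
    """3' stem half pairing with seq5 (antiparallel), with optional G.U."""
    out = []
    for b in seq5:
        c = _COMPLEMENT[b]
        if wobble_fraction > 0 and rng.random() < wobble_fraction:
            if b == "G":
                c = "T"   # G.U wobble
            elif b == "T":
                c = "G"
        out.append(c)
    return "".join(reversed(out))


def generate_trna(anticodon: str, length: int = 69, dhu_present: bool = True,
                  seed: int | np.random.Generator = 0,
                  wobble_fraction: float = 0.0,
                  bounds: GeometryBounds = GeometryBounds(),
                  composition: Sequence[float] | None = None,
                  max_tries: int = 60) -> tuple[str, Cloverleaf]:
    """Sample a tRNA sequence with a known cloverleaf structure.

    Stems are sampled as perfectly complementary halves (optionally with a
    G·U fraction); loops and spacers are sampled from ``composition``; the
    anticodon occupies loop positions 3-5.  With ``dhu_present=False``
    candidates are resampled until the anticodon-constrained
    :func:`fold_cloverleaf` confirms no DHU stem of ``bounds.min_dhu_pairs``
    pairs exists, mirroring the degenerate tRNA-Ser(GCU) of mammalian
    mitogenomes (an unconstrained fold may still relocate the anticodon
    loop and report a DHU arm; the guarantee is for the constrained fold).

    Returns (sequence, construction-truth cloverleaf).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ac_dna = anticodon.upper().replace("U", "T")
    combos = _geometry_combos(length, dhu_present, bounds)
    if not combos:
        raise TemplateError(
            f"no cloverleaf geometry of total length {length} "
            f"(dhu_present={dhu_present}) within bounds")
    comp = composition or DEFAULT_COMPOSITION["tRNA"]

    for _try in range(max_tries):
        geom = combos[int(rng.integers(len(combos)))]
        if dhu_present:
            a, g1, d, ld, g2, c, v, s, lt, t = geom
        else:
            a, u, c, v, s, lt, t = geom

        acc5 = _sample_bases(rng, a, comp)
        loop_ac = (_sample_bases(rng, 2, comp) + ac_dna
                   + _sample_bases(rng, 2, comp))
        stem_ac5 = _sample_bases(rng, c, comp)
        stem_tp5 = _sample_bases(rng, s, comp)
        loop_tp = _sample_bases(rng, lt, comp)
        var = _sample_bases(rng, v, comp)
        tail = _sample_bases(rng, t, comp)

        parts: list[str] = [acc5]
        pos = a
        if dhu_present:
            sp1 = _sample_bases(rng, g1, comp)
            dhu5 = _sample_bases(rng, d, comp)
            dloop = _sample_bases(rng, ld, comp)
            parts += [sp1, dhu5, dloop,
                      _complement_stem(dhu5, rng, wobble_fraction),
                      _sample_bases(rng, g2, comp)]
            dhu_start = a + g1 + 1
            pos = a + g1 + 2 * d + ld + g2
        else:
            parts.append(_sample_bases(rng, u, comp))
            pos = a + u
        ac_start = pos + 1
        parts += [stem_ac5, loop_ac,
                  _complement_stem(stem_ac5, rng, wobble_fraction), var]
        tp_start = ac_start + 2 * c + 7 + v
        parts += [stem_tp5, loop_tp,
                  _complement_stem(stem_tp5, rng, wobble_fraction)]
        acc3_start = tp_start + 2 * s + lt
        parts += [_complement_stem(acc5, rng, wobble_fraction), tail]
        seq = "".join(parts)
        assert len(seq) == length, (len(seq), length, geom)

        def stem(p5: int, p3: int, k: int) -> Stem:
            pairs = tuple((p5 + i, p3 + k - 1 - i) for i in range(k))
            n_wc = sum(1 for i, j in pairs
                       if (seq[i - 1], seq[j - 1]) in
                       {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})
            return Stem(p5, p5 + k - 1, p3, p3 + k - 1, pairs, n_wc)

        dhu_arm = None
        if dhu_present:
            dhu_arm = Arm(stem(dhu_start, dhu_start + d + ld, d),
                          dhu_start + d, dhu_start + d + ld - 1)
        truth = Cloverleaf(
            sequence=seq,
            acceptor_stem=stem(1, acc3_start, a),
            dhu_arm=dhu_arm,
            anticodon_arm=Arm(stem(ac_start, ac_start + c + 7, c),
                              ac_start + c, ac_start + c + 6),
            anticodon=ac_dna.replace("T", "U"),
            tpsic_arm=Arm(stem(tp_start, tp_start + s + lt, s),
                          tp_start + s, tp_start + s + lt - 1),
            variable_region=((tp_start - v, tp_start - 1) if v else None),
            score=2 * (a + (d if dhu_present else 0) + c + s),
            n_wc_pairs=0,
        )
        if not dhu_present:
            folded = fold_cloverleaf(seq, anticodon=anticodon, bounds=bounds)
            if folded.dhu_present:
                continue  # accidental DHU-capable region; resample
        return seq, truth
    raise TemplateError(
        f"could not sample a DHU-less tRNA of length {length} in {max_tries} tries")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

class _GenomeBuilder:
    def __init__(self, length: int):
        self.seq: list[str | None] = [None] * length
        self.locked = np.zeros(length + 1, dtype=bool)  # 1-based

    def coding_pos(self, feat: GeneFeature, k: int) -> int:
        """H-strand position of coding-strand offset k (0-based)."""
        return feat.start + k if feat.strand == "H" else feat.end - k

    def get_coding(self, feat: GeneFeature, k: int) -> str | None:
        h = self.coding_pos(feat, k)
        b = self.seq[h - 1]
        if b is None:
            return None
        return b if feat.strand == "H" else _COMPLEMENT[b]

    def set_coding(self, feat: GeneFeature, k: int, base: str,
                   lock: bool = False) -> None:
        h = self.coding_pos(feat, k)
        hb = base if feat.strand == "H" else _COMPLEMENT[base]
        if self.locked[h] and self.seq[h - 1] != hb:
            raise TemplateError(
                f"{feat.name}: position {h} already locked to "
                f"{self.seq[h - 1]} (wanted {hb}); template unrealizable")
        self.seq[h - 1] = hb
        if lock:
            self.locked[h] = True


def _pcg_codon_ranges(feat: GeneFeature, stop_type: str) -> tuple[int, int]:
    """(first, last) 0-based indices of internal codons (non-start, non-stop)."""
    n_full = feat.length // 3
    last_internal = n_full - 2 if feat.length % 3 == 0 else n_full - 1
    return 1, last_internal


def generate_mitogenome(template: GenomeTemplate, seed: int,
                        code: GeneticCode = VERTEBRATE_MITO,
                        ) -> tuple[Mitogenome, SimulationTruth]:
    """Realize a template into a concrete annotated genome.

    The returned genome characterizes back to the plan exactly: every
    length, intergenic value, start codon and stop label matches the
    template.  Unrealizable templates raise :class:`TemplateError` before
    any sequence is committed.
    """
    template.validate(code)
    rng = np.random.default_rng(seed)
    features = template.to_features()
    L = template.genome_length()
    builder = _GenomeBuilder(L)
    plan = {f.name: tf for f, tf in zip(features, template.features)}

    pcgs = [f for f in features if f.category == "PCG"]

    # 1. hard constraints: PCG start codons and stop bases
    for f in pcgs:
        tf = plan[f.name]
        for k, b in enumerate(tf.start_codon):
            builder.set_coding(f, k, b, lock=True)
        stop = tf.stop_type
        tail = stop.replace("-", "")
        for k, b in enumerate(tail):
            builder.set_coding(f, f.length - len(tail) + k, b, lock=True)

    # 2. tRNA cloverleaf sequences (free positions only)
    trna_truths: dict[str, Cloverleaf] = {}
    for f in features:
        if f.category != "tRNA":
            continue
        tf = plan[f.name]
        seq, truth = generate_trna(tf.anticodon, length=f.length,
                                   dhu_present=tf.dhu_present, seed=rng,
                                   composition=template.composition["tRNA"])
        trna_truths[f.name] = truth
        for k, b in enumerate(seq):
            h = builder.coding_pos(f, k)
            if not builder.locked[h]:
                builder.set_coding(f, k, b)

    # 3. composition-sampled fill: feature bodies then spacers.
    # Composition targets describe the H strand (the strand the replication
    # asymmetry acts on), so light-strand gene bodies are sampled on the H
    # strand: their coding-strand rows then show inverted skews, as real
    # L-strand genes (e.g. ND6) do.
    def _fill_base(f: GeneFeature, k: int, comp) -> None:
        b = _sample_bases(rng, 1, comp)
        builder.set_coding(f, k, b if f.strand == "H" else _COMPLEMENT[b])

    for f in features:
        if f.category == "tRNA":
            continue  # cloverleaf content already written
        comp = template.composition.get(f.category,
                                        template.composition["spacer"])
        for k in range(f.length):
            h = builder.coding_pos(f, k)
            if builder.seq[h - 1] is None:
                _fill_base(f, k, comp)
    spacer_comp = template.composition["spacer"]
    for h in range(1, L + 1):
        if builder.seq[h - 1] is None:
            builder.seq[h - 1] = _sample_bases(rng, 1, spacer_comp)

    # 4. repair: no internal stop codon in any PCG frame
    pcg_comp = template.composition["PCG"]
    for _sweep in range(200):
        dirty = False
        for f in pcgs:
            first, last = _pcg_codon_ranges(f, plan[f.name].stop_type)
            for ci in range(first, last + 1):
                codon = "".join(builder.get_coding(f, 3 * ci + j)
                                for j in range(3))
                if not code.is_stop(codon):
                    continue
                free = [j for j in range(3)
                        if not builder.locked[builder.coding_pos(f, 3 * ci + j)]]
                if not free:
                    raise TemplateError(
                        f"{f.name}: fully locked stop codon {codon} at codon "
                        f"{ci}; template unrealizable")
                dirty = True
                for _try in range(100):
                    for j in free:
                        _fill_base(f, 3 * ci + j, pcg_comp)
                    codon = "".join(builder.get_coding(f, 3 * ci + j)
                                    for j in range(3))
                    if not code.is_stop(codon):
                        break
                else:
                    raise TemplateError(f"{f.name}: cannot clear stop at codon {ci}")
        if not dirty:
            break
    else:
        raise TemplateError("stop-codon repair did not converge")

    genome = Mitogenome(id=template.id, sequence="".join(builder.seq),
                        circular=True, features=features)

    # verify the plan round-trips through characterization
    for row, tf in zip(build_characterization_table(genome, code),
                       template.features):
        if tf.category == "PCG":
            if row.start_codon != tf.start_codon or row.stop_codon != tf.stop_type:
                raise TemplateError(
                    f"{tf.name}: generated codons ({row.start_codon}, "
                    f"{row.stop_codon}) do not match plan "
                    f"({tf.start_codon}, {tf.stop_type})")

    truth = SimulationTruth(template=template, features=features, seed=seed,
                            trna_arms=trna_truths)
    return genome, truth


# ---------------------------------------------------------------------------
# sequence evolution along a tree
# ---------------------------------------------------------------------------

def evolve_sequences(root_seq: str, tree: PhyloTree, model: PhyloModel,
                     seed: int, root: int | None = None) -> dict[str, str]:
    """Simulate site-independent evolution of ``root_seq`` along ``tree``.

    Each site draws a rate from the +I+G mixture (invariant with
    probability ``p_inv``, otherwise a discrete-gamma category rescaled to
    keep the mean rate at 1), then evolves by the model's transition
    probabilities down every branch.  Returns tip-name -> sequence.
    """
    rng = np.random.default_rng(seed)
    s = root_seq.upper().replace("U", "T")
    idx = {b: i for i, b in enumerate("ACGT")}
    try:
        states = np.array([idx[b] for b in s])
    except KeyError as exc:
        raise ValueError(f"root sequence contains non-ACGT base {exc}") from None
    n = len(states)

    mixture = model.mixture()
    weights = np.array([w for w, _ in mixture])
    rates = np.array([r for _, r in mixture])
    site_cat = rng.choice(len(mixture), size=n, p=weights)
    site_rate = rates[site_cat]

    cache = _TransitionCache(model)
    if root is None:
        internals = [u for u in sorted(tree.adj) if len(tree.adj[u]) > 1]
        root = internals[0] if internals else sorted(tree.adj)[0]

    seqs: dict[int, np.ndarray] = {root: states}
    out: dict[str, str] = {}
    if len(tree.adj[root]) == 1 and root in tree.labels:
        out[tree.labels[root]] = s
    order = list(reversed(tree.postorder(root)))  # parents before children
    unique_rates = np.unique(site_rate)
    for node, parent in order:
        if parent is None:
            continue
        t = tree.adj[parent][node]
        parent_states = seqs[parent]
        child = parent_states.copy()
        for r in unique_rates:
            if r == 0 or t == 0:
                continue
            mask = site_rate == r
            P = cache.P(t * r)
            cum = P.cumsum(axis=1)
            u = rng.random(mask.sum())
            ps = parent_states[mask]
            child[mask] = (u[:, None] > cum[ps]).sum(axis=1)
        seqs[node] = child
        if len(tree.adj[node]) == 1:
            out[tree.labels[node]] = "".join("ACGT"[i] for i in child)
    return out
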