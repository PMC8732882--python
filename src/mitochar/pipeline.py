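"""End-to-end workflow functions tying the analysis stages together.

These functions are the programmatic equivalent of a pipeline run:
``run_characterize`` produces the characterization, composition, codon
usage and tRNA-structure tables for one annotated genome;
``run_phylo`` aligns a set of genomes (or takes a prebuilt alignment),
fits a GTR+F+I+G4 ML tree with bootstrap supports, and classifies
user-specified groups; ``run_simulate`` writes a synthetic genome with its
ground truth.  All outputs are plain text (TSV/FASTA/Newick/JSON) and
byte-deterministic given the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from .alignment import Alignment, concatenate_genes, progressive_align
from .annotation_metrics import (build_characterization_table,
                                 characterization_frame, circular_gap,
                                 count_by_strand_and_category)
from .composition import (codon_usage, codon_usage_frame, composition_frame,
                          composition_report)
from .genome_io import (Mitogenome, extract_feature, read_fasta,
                        read_feature_table, write_fasta)
from .phylogeny import (FitResult, SearchSettings, bootstrap_support,
                        classify_group, fit_and_search)
from .synthetic_data import (GenomeTemplate, SimulationTruth,
                             default_template, generate_mitogenome)
from .trna_structure import GeometryBounds, fold_cloverleaf, structure_report


@dataclass
class RunConfig:
    """Settings for a reproducible pipeline run."""

    out_dir: str = "."
    seed: int = 0
    pct_decimals: int = 2
    skew_decimals: int = 4
    bootstrap_replicates: int = 100
    gene_set: str = "full"        # 'full' or 'pcg13'
    groups: dict[str, list[str]] = field(default_factory=dict)
    outgroup: str | list[str] | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _write_log(out: Path, config: RunConfig, messages: Sequence[str]) -> None:
    from . import __version__
    lines = [
        f"mitochar {__version__}",
        f"config hash {config.config_hash()}",
        f"seed {config.seed}",
        *messages,
    ]
    (out / "run.log").write_text("\n".join(lines) + "\n")


def load_genome(fasta_path, features_path, circular: bool = True) -> Mitogenome:
    """Assemble a Mitogenome from a FASTA file and a feature TSV."""
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one record, "
                         f"got {len(records)}")
    name, seq = records[0]
    return Mitogenome(id=name, sequence=seq, circular=circular,
                      features=read_feature_table(features_path))


def run_characterize(genome: Mitogenome, config: RunConfig | None = None
                     ) -> dict[str, Path]:
    """Characterize one genome: annotation metrics, composition, codon
    usage and tRNA secondary structures, written as TSV files."""
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    rows = build_characterization_table(genome)
    table1 = characterization_frame(rows)
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)

    comp = composition_report(genome, pct_decimals=config.pct_decimals,
                              skew_decimals=config.skew_decimals)
    composition_frame(comp).to_csv(out / "table2.tsv", sep="\t", index=False)

    cds = [(f.name, extract_feature(genome, f))
           for f in genome.features if f.category == "PCG"]
    usage = codon_usage(cds)
    codon_usage_frame(usage).to_csv(out / "codon_usage.tsv", sep="\t",
                                    index=False)

    folded = []
    for f in genome.features:
        if f.category == "tRNA":
            try:
                folded.append((f.name, fold_cloverleaf(
                    extract_feature(genome, f), anticodon=f.anticodon)))
            except Exception:
                # overlap-degraded tRNAs may not place the anticodon; fold free
                folded.append((f.name, fold_cloverleaf(
                    extract_feature(genome, f))))
    trna_df = structure_report(folded)
    trna_df.to_csv(out / "trna_structures.tsv", sep="\t", index=False)

    counts = count_by_strand_and_category(genome.features)
    _write_log(out, config, [
        f"genome {genome.id} length {len(genome)}",
        f"features {len(genome.features)}",
        f"strand/category counts {counts}",
        f"circular gap {circular_gap(genome.features, len(genome))}",
        f"degenerate tRNAs {trna_df.attrs.get('n_degenerate', 0)}",
        f"elapsed {time.perf_counter() - t0:.2f}s",
    ])
    return {name: out / f"{name}.tsv" for name in
            ("table1", "table2", "codon_usage", "trna_structures")} | {
            "log": out / "run.log"}


def run_phylo(genomes: Sequence[Mitogenome] | None = None,
              alignment: Alignment | None = None,
              config: RunConfig | None = None,
              settings: SearchSettings | None = None) -> FitResult:
    """Align, fit a GTR+F+I+G4 ML tree, bootstrap, classify groups.

    Either annotated ``genomes`` (aligned per the config's gene set: 'full'
    genomes or the concatenated 13 PCGs) or a prebuilt ``alignment``.
    """
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    messages: list[str] = []

    if alignment is None:
        if genomes is None or len(genomes) < 4:
            raise ValueError("phylogeny needs >= 4 genomes or an alignment")
        if config.gene_set == "pcg13":
            pcg_names = [f.name for f in genomes[0].features
                         if f.category == "PCG"]
            blocks = []
            for gene in pcg_names:
                seqs = []
                for g in genomes:
                    feats = {f.name: f for f in g.features}
                    if gene not in feats:
                        raise ValueError(f"genome {g.id} lacks gene {gene}")
                    seqs.append((g.id, extract_feature(g, feats[gene])))
                blocks.append((gene, progressive_align(seqs)))
            alignment, parts = concatenate_genes(blocks)
            messages.append(f"partitions {parts}")
        else:
            alignment = progressive_align([(g.id, g.sequence) for g in genomes])
    if alignment.n_taxa < 4:
        raise ValueError("phylogeny needs >= 4 taxa")
    alignment.to_fasta(out / "alignment.fasta")

    fit = fit_and_search(alignment, settings)
    if config.bootstrap_replicates > 0:
        fit = bootstrap_support(alignment, settings,
                                config.bootstrap_replicates,
                                seed=config.seed, fit=fit)
    (out / "tree.nwk").write_text(fit.tree.to_newick() + "\n")

    model = fit.model
    model_lines = ["parameter\tvalue"]
    for label, rate in zip(("AC", "AG", "AT", "CG", "CT", "GT"), model.rates):
        model_lines.append(f"rate_{label}\t{rate:.6g}")
    for label, fr in zip("ACGT", model.freqs):
        model_lines.append(f"freq_{label}\t{fr:.6g}")
    model_lines += [f"p_inv\t{model.p_inv:.6g}",
                    f"alpha\t{model.alpha if model.alpha is not None else 'none'}",
                    f"logL\t{fit.log_likelihood:.6f}"]
    (out / "model.tsv").write_text("\n".join(model_lines) + "\n")

    if config.groups:
        if config.outgroup is None:
            raise ValueError("group classification requires an outgroup")
        class_lines = ["group\tclassification"]
        for name, taxa in config.groups.items():
            missing = set(taxa) - set(fit.tree.tip_names)
            if missing:
                raise ValueError(f"group {name}: unknown taxa {sorted(missing)}")
            cls = classify_group(fit.tree, taxa, config.outgroup)
            class_lines.append(f"{name}\t{cls}")
        (out / "groups.tsv").write_text("\n".join(class_lines) + "\n")
        messages.append("groups classified: "
                        + ", ".join(config.groups))

    messages.append(f"logL {fit.log_likelihood:.4f}; converged {fit.converged}")
    _write_log(out, config, messages)
    return fit


def run_simulate(template: GenomeTemplate | None = None,
                 config: RunConfig | None = None
                 ) -> tuple[Mitogenome, SimulationTruth, dict[str, Path]]:
    """Generate a synthetic annotated genome and write genome.fasta,
    features.tsv and truth.json."""
    from .genome_io import write_feature_table

    config = config or RunConfig()
    template = template or default_template()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome, truth = generate_mitogenome(template, seed=config.seed)
    write_fasta([(genome.id, genome.sequence)], out / "genome.fasta")
    write_feature_table(genome.features, out / "features.tsv")
    (out / "truth.json").write_text(truth.to_json())
    _write_log(out, config, [f"generated {genome.id} length {len(genome)}"])
    return genome, truth, {
        "genome": out / "genome.fasta",
        "features": out / "features.tsv",
        "truth": out / "truth.json",
        "log": out / "run.log",
    }
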