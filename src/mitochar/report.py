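"""Report rendering: paper-style tables as TSV (rounded) + JSON (full precision).

Every number in a rendered TSV equals the module-level computation
rounded to the documented precision (percentages 2 dp, skews 4 dp, RSCU
and codon % 2 dp); the JSON twin carries full precision so tests and
downstream code never depend on the rounding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from mitochar import architecture, cloverleaf, codon, composition, model, phylo

log = logging.getLogger("mitochar")


@dataclass
class PipelineConfig:
    genome_genbank: Optional[str] = None
    genome_fasta: Optional[str] = None
    genome_features: Optional[str] = None
    alignments_dir: Optional[str] = None
    outgroup: list[str] = field(default_factory=list)
    out_dir: str = "mitochar_out"
    bootstrap: int = 100
    seed: int = 0
    distance_method: str = "k2p"
    tr_min_period: int = 2
    tr_max_period: int = 50
    tr_min_copies: float = 2.0
    tr_min_identity: float = 0.8
    # rounding conventions (documented, not meant to be tuned)
    pct_decimals: int = 2
    skew_decimals: int = 4
    rscu_decimals: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def load_genome(config: PipelineConfig) -> model.Mitogenome:
    if config.genome_genbank:
        return model.read_genbank(config.genome_genbank)
    if config.genome_fasta and config.genome_features:
        return model.read_feature_table(config.genome_fasta, config.genome_features)
    raise ValueError("config must give genome_genbank or genome_fasta+genome_features")


def run_characterize(config: PipelineConfig, genome: Optional[model.Mitogenome] = None) -> dict:
    """Run the full characterization and write the report bundle.

    Emits a feature ledger (with computed intergenic/overlap columns), a
    per-region composition table, the codon-usage table, the
    architecture report and the tRNA fold report, each as TSV + JSON.
    Returns the bundle as a dict.
    """
    g = genome if genome is not None else load_genome(config)
    model.require_features(g)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spacers, overlaps = architecture.spacers_and_overlaps(g)
    gap_after = {s.upstream: s.length for s in spacers}
    ovl_after = {o.first: o.length for o in overlaps}

    # --- feature ledger (gene map with computed gap/overlap margins) ---
    ledger_rows = []
    for f in g.features:
        start_codon = stop_codon = "-"
        if f.ftype == "PCG":
            call = codon.call_start_stop(model.extract_feature_seq(g, f), f.name)
            start_codon, stop_codon = call.start_codon, call.stop_codon
            if call.warning:
                log.warning("%s: %s", f.name, call.warning)
        ledger_rows.append(
            [
                f.name,
                f.ftype,
                f.strand,
                f.start,
                f.end,
                model.feature_length(f, g.length),
                start_codon,
                stop_codon,
                f.anticodon or "-",
                gap_after.get(f.name, ""),
                ovl_after.get(f.name, ""),
            ]
        )
    _write_tsv(
        out / "features.tsv",
        ["name", "ftype", "strand", "start", "end", "length",
         "start_codon", "stop_codon", "anticodon", "intergenic_after", "overlap_after"],
        ledger_rows,
    )

    # --- composition ---
    profiles = composition.region_profiles(g)
    comp_rows = [list(p.rounded().values()) for p in profiles]
    _write_tsv(
        out / "composition.tsv",
        ["region", "A", "T", "C", "G", "A+T", "G+C", "AT_skew", "GC_skew"],
        comp_rows,
    )
    with open(out / "composition.json", "w") as fh:
        json.dump([asdict(p) for p in profiles], fh, indent=1)

    # --- codon usage ---
    usage = codon.genome_usage_table(g)
    _write_tsv(
        out / "codon_usage.tsv",
        ["codon", "amino_acid", "n", "pct", "RSCU"],
        [
            [r.rna_codon, r.amino_acid, r.n,
             f"{r.pct:.{config.rscu_decimals}f}", f"{r.rscu:.{config.rscu_decimals}f}"]
            for r in usage.rows
        ],
    )
    with open(out / "codon_usage.json", "w") as fh:
        json.dump(
            {"n_total": usage.n_total,
             "rows": [asdict(r) for r in usage.rows],
             "empty_families": usage.empty_families},
            fh, indent=1,
        )
    tally = codon.strand_amino_acid_tally(g)
    anticorr = codon.anticodon_correspondence(usage, g.trnas)

    # --- architecture ---
    conservation = architecture.conservation_check(g)
    try:
        control = architecture.control_region_record(g)
        control_seq = model.extract_feature_seq(
            g, next(f for f in g.features if f.ftype == "control")
        )
        repeats = architecture.find_tandem_repeats(
            control_seq,
            min_period=config.tr_min_period,
            max_period=config.tr_max_period,
            min_copies=config.tr_min_copies,
            min_identity=config.tr_min_identity,
        )
    except LookupError:
        log.warning("no control region annotated; control record omitted")
        control, repeats = None, []
    order = architecture.gene_order(g)
    arch = {
        "n_spacers": len(spacers),
        "spacer_total": sum(s.length for s in spacers),
        "spacers": [asdict(s) for s in spacers],
        "n_overlaps": len(overlaps),
        "overlap_total": sum(o.length for o in overlaps),
        "overlaps": [asdict(o) for o in overlaps],
        "conservation": conservation,
        "control_region": (
            {"length": control[0], "upstream": control[1], "downstream": control[2]}
            if control else None
        ),
        "control_tandem_repeats": [asdict(r) for r in repeats],
        "gene_order": list(order.order),
        "strand_amino_acid_tally": {s: dict(c) for s, c in tally.items()},
        "anticodon_correspondence": [asdict(e) for e in anticorr],
    }
    with open(out / "architecture.json", "w") as fh:
        json.dump(arch, fh, indent=1)
    with open(out / "gene_order.txt", "w") as fh:
        fh.write(" ".join(f"{'-' if s == 'L' else ''}{n}" for n, s in order.order) + "\n")

    # --- tRNA folds ---
    folds, names = [], []
    for f in g.trnas:
        if not f.anticodon:
            log.warning("%s: no anticodon annotated; fold skipped", f.name)
            continue
        try:
            folds.append(cloverleaf.fold_trna(model.extract_feature_seq(g, f), f.anticodon))
            names.append(f.name)
        except ValueError as exc:
            log.warning("%s: %s", f.name, exc)
    fold_rows = []
    for name, fd in zip(names, folds):
        fold_rows.append(
            [name, int(fd.foldable), fd.acceptor_len,
             fd.dhu_arm.stem_len if fd.dhu_arm else 0,
             fd.anticodon_arm.stem_len if fd.anticodon_arm else 0,
             fd.tpsic_arm.stem_len if fd.tpsic_arm else 0,
             fd.wobble_pairs, ";".join(fd.missing_arms) or "-",
             fd.dot_bracket() if fd.foldable else "-"]
        )
    _write_tsv(
        out / "trna_folds.tsv",
        ["name", "foldable", "acceptor_bp", "dhu_bp", "anticodon_bp",
         "tpsic_bp", "wobble_pairs", "missing_arms", "dot_bracket"],
        fold_rows,
    )
    summary = cloverleaf.summarize_folds(folds, names) if folds else None
    with open(out / "trna_summary.json", "w") as fh:
        json.dump(asdict(summary) if summary else None, fh, indent=1)

    return {
        "ledger": ledger_rows,
        "composition": profiles,
        "codon_usage": usage,
        "architecture": arch,
        "trna_folds": dict(zip(names, folds)),
        "trna_summary": summary,
    }


def run_phylo(config: PipelineConfig) -> dict:
    """Concatenate alignments, build the NJ tree with bootstrap support,
    optionally root on the outgroup; writes newick, support table and the
    distance matrix."""
    aln_dir = Path(config.alignments_dir or "")
    files = sorted(aln_dir.glob("*.fa")) + sorted(aln_dir.glob("*.fasta"))
    if not files:
        raise ValueError(f"no alignment FASTA files in {aln_dir}")
    alignments = {f.stem: phylo.read_alignment(f) for f in files}
    m = phylo.concatenate(alignments)
    if len(m.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    dm = phylo.distance_matrix(m, config.distance_method)
    tree = phylo.bootstrap_support(m, B=config.bootstrap, seed=config.seed,
                                   method=config.distance_method)
    if config.outgroup:
        unknown = set(config.outgroup) - set(m.taxa)
        if unknown:
            raise ValueError(f"outgroup taxa not in alignments: {sorted(unknown)}")
        tree = phylo.root_with_outgroup(tree, config.outgroup)
        if tree.outgroup_monophyletic is False:
            log.warning("outgroup is not monophyletic; rooted on smallest containing edge")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "tree.nwk", "w") as fh:
        fh.write(tree.newick() + "\n")
    with open(out / "distances.phy", "w") as fh:
        fh.write(dm.to_phylip())
    with open(out / "partitions.txt", "w") as fh:
        fh.write(m.partition_text() + "\n")
    supports = {
        ",".join(sorted(bp)): None for bp in tree.bipartitions()
    }

    def collect(node):
        for child, _ in node.children:
            if not child.is_leaf and child.support is not None:
                supports[",".join(sorted(child.leaves()))] = child.support
            collect(child)

    collect(tree.root)
    _write_tsv(out / "supports.tsv", ["clade", "support_pct"],
               [[k, v if v is not None else ""] for k, v in sorted(supports.items())])
    return {"tree": tree, "distances": dm, "supermatrix": m}
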