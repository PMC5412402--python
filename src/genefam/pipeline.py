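"""Pipeline driver: configuration and the end-to-end run.

Binds the stages together in the order a gene-family survey runs them:
simulate (or load) inputs -> motif scan -> subfamily classification ->
conservation statistics -> NJ tree with bootstrap -> paralog detection,
Ka/Ks, dating and selection calls -> salt-stress DE calls -> qPCR
relative expression.  Every applied parameter and the seed are recorded in
a machine-readable run log so a rerun with the same config is identical.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import duplication, expression, identify, io, phylo, simulate

_THRESHOLD_DOMAINS = {
    "bootstrap_replicates": (1, 100000),
    "min_bootstrap": (0, 100),
    "min_identity": (0.0, 1.0),
    "min_coverage": (0.0, 1.0),
    "tandem_window": (1, 10**6),
    "fc_threshold": (1.0, float("inf")),
    "fdr_threshold": (0.0, 1.0),
    "pseudocount": (0.0, float("inf")),
    "k_groups": (1, 10**6),
    "scan_quantile": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the survey's defaults."""

    outdir: str = "genefam_out"
    rng_seed: int = 0
    # simulator
    n_background_genes: int = 100
    n_family_genes: int = 40
    motif_length: int = 48
    n_chromosomes: int = 20
    loci_per_chromosome: int = 50
    duplication_events: list = field(
        default_factory=lambda: [[10.0, "tandem", 0.2]] * 10 + [[10.0, "segmental", 0.2]] * 10
    )
    lambda_rate: float = simulate.DEFAULT_LAMBDA
    codon_length: int = 300
    # scan / classify
    scan_quantile: float = 0.99
    # tree
    bootstrap_replicates: int = 1000
    # duplication
    min_bootstrap: float = 90.0
    min_identity: float = 0.70
    min_coverage: float = 0.80
    tandem_window: int = 20
    # expression
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    pseudocount: float = 1.0
    dispersion: float = 0.1
    k_groups: int = 6
    de_control: str = "0h"
    de_treated: list = field(default_factory=lambda: ["1h", "6h", "12h"])
    qpcr_reference: str = "GmREF1"

    def __post_init__(self) -> None:
        for name, (lo, hi) in _THRESHOLD_DOMAINS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a simulated gene family and write all outputs.

    Returns a result bundle (in-memory objects plus output paths); the run
    log with every applied parameter goes to ``<outdir>/run_log.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    stage = "simulate"
    try:
        sim_cfg = simulate.SimConfig(
            n_background_genes=config.n_background_genes,
            n_family_genes=config.n_family_genes,
            motif_length=config.motif_length,
            n_chromosomes=config.n_chromosomes,
            loci_per_chromosome=config.loci_per_chromosome,
            duplication_events=[tuple(e) for e in config.duplication_events],
            lambda_rate=config.lambda_rate,
            codon_length=config.codon_length,
            rng_seed=config.rng_seed,
        )
        sim = simulate.simulate_proteome(sim_cfg)
        io.write_fasta(sim.proteins, out / "proteins.fasta")
        io.write_fasta(sim.cds, out / "cds.fasta")
        io.write_fasta(sim.seed_alignment, out / "seed_alignment.fasta")
        io.write_loci(sim.loci, out / "loci.tsv")
        io.write_domains(sim.domains, out / "domains.tsv")

        stage = "scan"
        profile = identify.build_profile(sim.seed_alignment)
        background = {g: s for g, s in sim.proteins.items() if g.startswith("GmBG")}
        threshold = identify.calibrate_threshold(profile, background, config.scan_quantile)
        hits = identify.scan(sim.proteins, profile, threshold)
        family = sorted(h.gene for h in hits if h.passed)
        hits_df = pd.DataFrame(
            [dict(gene=h.gene, start=h.start, score=h.score, passed=h.passed) for h in hits]
        )
        io.write_table(hits_df, out / "hits.tsv")

        stage = "classify"
        labels = identify.classify_subfamily({g: sim.domains[g] for g in family})
        io.write_table(
            pd.DataFrame(sorted(labels.items()), columns=["gene", "subfamily"]),
            out / "subfamilies.tsv",
        )

        stage = "conservation"
        motif_aln = {
            g: sim.proteins[g][p : p + config.motif_length]
            for g, p in sim.truth.motif_positions.items()
        }
        cons = identify.conservation(motif_aln)
        cons_df = pd.DataFrame(cons.frequencies, columns=list(identify.AMINO_ACIDS))
        cons_df["identity"] = cons.identity
        cons_df["information_bits"] = cons.information
        io.write_table(cons_df, out / "conservation.tsv", index=True)

        stage = "tree"
        tree, _ = phylo.bootstrap(
            motif_aln, n_replicates=config.bootstrap_replicates, rng=rng
        )
        io.atomic_write(out / "tree.nwk", phylo.write_newick(tree) + "\n")

        stage = "duplicates"
        pairs, _rejected = duplication.detect_pairs(
            tree, sim.proteins,
            min_bootstrap=config.min_bootstrap,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
        )
        pairs_df = duplication.analyze_pairs(
            pairs, sim.proteins, sim.cds, sim.loci,
            tandem_window=config.tandem_window,
            lambda_rate=config.lambda_rate,
        )
        io.write_table(pairs_df, out / "paralog_pairs.tsv")

        stage = "expression"
        design = simulate.salt_design()
        de_plan = {g: {"1h": 3.0, "6h": -3.0} for g in family[: max(1, len(family) // 4)]}
        matrix = simulate.simulate_expression(
            sorted(sim.proteins), design, de_plan, dispersion=config.dispersion, rng=rng
        )
        io.write_matrix(matrix, out / "expression.tsv")
        io.write_table(design, out / "expression_metadata.tsv")
        de_tables = {}
        for treated in config.de_treated:
            de = expression.call_de(
                matrix, design, config.de_control, treated,
                fc_threshold=config.fc_threshold,
                fdr_threshold=config.fdr_threshold,
                pseudocount=config.pseudocount,
            )
            de_tables[treated] = de
            io.write_table(de, out / f"de_{treated}.tsv", index=True)
        tissues, truth_groups = simulate.simulate_tissue_archetypes(
            n_genes=min(300, len(sim.proteins)), n_archetypes=config.k_groups, rng=rng
        )
        groups, linkage = expression.cluster_tissues(
            expression.log2_matrix(tissues, config.pseudocount), config.k_groups
        )
        io.write_table(groups.reset_index(), out / "tissue_groups.tsv")
        io.atomic_write(
            out / "tissue_dendrogram.nwk",
            expression.linkage_to_newick(linkage, list(tissues.index)) + "\n",
        )

        stage = "qpcr"
        qpcr_truth = {family[0]: {"1h": 4.0, "6h": 0.5}}
        ct = simulate.simulate_qpcr(
            qpcr_truth, reference_gene=config.qpcr_reference, rng=rng
        )
        io.write_table(ct, out / "ct.tsv")
        rel = expression.delta_delta_ct(ct, config.qpcr_reference, control="0h")
        io.write_table(rel, out / "relative_expression.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log = dict(config=config.to_dict(), applied=dict(scan_threshold=threshold,
               n_family_detected=len(family), n_pairs=len(pairs)))
    io.atomic_write(out / "run_log.json", json.dumps(log, indent=2, default=str))
    digest = hashlib.sha256()
    for p in sorted(out.glob("*")):
        if p.name != "run_log.json":
            digest.update(p.read_bytes())
    return dict(
        outdir=str(out), family=family, labels=labels, pairs=pairs_df,
        de=de_tables, groups=groups, relative_expression=rel,
        scan_threshold=threshold, bundle_sha256=digest.hexdigest(),
    )
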