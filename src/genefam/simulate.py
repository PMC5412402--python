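"""Synthetic gene-family generator with full ground truth.

Emulates the inputs of a genome-wide gene-family survey: a proteome with
motif-bearing family members and motif-free background proteins, CDS
sequences that diverge under a codon-level mutation process with a known
synonymous clock and a known dN/dS ratio (omega), gene loci with planted
tandem (same chromosome, adjacent loci) and segmental (different
chromosomes) duplicate pairs, C-terminal domain annotations covering all
nine subfamilies, multi-tissue expression with planted cluster structure,
salt-treatment time courses with planted fold changes, and qPCR Ct tables
with a stable reference gene.  Every draw goes through a caller-supplied
or config-seeded numpy Generator, so outputs are reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codons import (
    CODON_TO_AA,
    NONSYN_MOVES,
    SENSE_CODONS,
    SYN_MOVES,
    SYN_SITES,
    split_codons,
    translate_codons,
)
from .identify import AMINO_ACIDS, BACKGROUND_FREQS, background_vector

DEFAULT_LAMBDA = 6.1e-9  # synonymous substitutions / synonymous site / year


@dataclass
class SimConfig:
    """Free parameters of the synthetic gene family."""

    n_background_genes: int = 100
    n_family_genes: int = 40
    motif_length: int = 48
    n_chromosomes: int = 20
    loci_per_chromosome: int = 50
    #: each event creates one duplicate pair: (time in Mya, class, omega)
    duplication_events: list[tuple[float, str, float]] = field(default_factory=list)
    lambda_rate: float = DEFAULT_LAMBDA
    codon_length: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background_genes", "n_family_genes", "motif_length",
                     "n_chromosomes", "loci_per_chromosome", "codon_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be positive")
        if self.motif_length > self.codon_length:
            raise ValueError("motif cannot be longer than the protein")
        for t, cls, omega in self.duplication_events:
            if t < 0 or omega < 0:
                raise ValueError("duplication times and omega must be >= 0")
            if cls not in ("tandem", "segmental"):
                raise ValueError(f"unknown duplication class {cls!r}")
        if 2 * len(self.duplication_events) > self.n_family_genes:
            raise ValueError("more duplicate genes than family genes")


@dataclass
class SimTruth:
    """Ground-truth ledger emitted alongside the synthetic data."""

    motif_positions: dict[str, int]
    pair_table: list[tuple[str, str, float, str, float]]
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    reference_gene: str = "GmREF1"


@dataclass
class MotifModel:
    """Position-specific generating frequencies for the family motif."""

    freqs: np.ndarray  # (length, 20)

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.freqs.argmax(axis=1))

    def sample(self, rng: np.random.Generator) -> str:
        cols = [rng.choice(20, p=self.freqs[p]) for p in range(self.length)]
        return "".join(AMINO_ACIDS[i] for i in cols)


def make_motif_model(
    length: int,
    rng: np.random.Generator,
    conservation: tuple[float, float] = (0.55, 0.9),
) -> MotifModel:
    """Random motif model: per position one consensus residue at frequency
    drawn from ``conservation``, the remainder spread as background."""
    bg = background_vector()
    freqs = np.empty((length, 20))
    for p in range(length):
        cons = rng.integers(20)
        c = rng.uniform(*conservation)
        rest = np.delete(bg, cons)
        freqs[p] = np.insert((1 - c) * rest / rest.sum(), cons, c)
    return MotifModel(freqs)


def sample_seed_alignment(
    model: MotifModel, n_sequences: int, rng: np.random.Generator
) -> dict[str, str]:
    """Seed alignment for profile building, drawn from the motif model."""
    return {f"seed{i+1}": model.sample(rng) for i in range(n_sequences)}


def _random_protein(length: int, rng: np.random.Generator) -> str:
    bg = background_vector()
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=bg))


_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _CODONS_BY_AA.setdefault(CODON_TO_AA[_c], []).append(_c)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein, synonymous codons chosen uniformly at random."""
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in protein.upper())


def evolve_codon_pair(
    ancestor_cds: str,
    time_mya: float,
    omega: float,
    lambda_rate: float = DEFAULT_LAMBDA,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, str]:
    """Diverge two lineages from an ancestral CDS for ``time_mya`` each.

    Substitutions arrive as a Poisson process: synonymous changes at rate
    lambda per synonymous site (NG86 site counting) and nonsynonymous
    changes at rate omega * lambda per nonsynonymous site.  A proposed
    change that would create a stop codon is rejected and redrawn.  In the
    small-T regime the expected NG86 pS between the two lineages is
    approximately 2 * lambda * T.
    """
    if time_mya < 0:
        raise ValueError("time_mya must be >= 0")
    if omega < 0 or lambda_rate <= 0:
        raise ValueError("omega must be >= 0 and lambda_rate > 0")
    rng = np.random.default_rng(rng)
    codons = split_codons(ancestor_cds.upper())
    for i, c in enumerate(codons):
        if CODON_TO_AA.get(c, "*") == "*":
            raise ValueError(f"ancestor contains a stop or invalid codon {c} at {i}")
    t_years = time_mya * 1e6

    def _evolve_one() -> str:
        seq = list(codons)
        s_sites = np.array([SYN_SITES[c] for c in seq])
        n_nonsyn = np.array([len(NONSYN_MOVES[c]) for c in seq], dtype=float)
        t = 0.0
        while True:
            total_s = s_sites.sum()
            total_n = 3 * len(seq) - total_s
            rate = lambda_rate * (total_s + omega * total_n)
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t > t_years:
                break
            if rng.random() < lambda_rate * total_s / rate:
                # synonymous event: pick a codon weighted by its syn sites
                i = rng.choice(len(seq), p=s_sites / total_s)
                _, new = SYN_MOVES[seq[i]][rng.integers(len(SYN_MOVES[seq[i]]))]
            else:
                # nonsynonymous event; reject-and-redraw proposals to stops
                while True:
                    i = rng.choice(len(seq), p=n_nonsyn / n_nonsyn.sum())
                    _, new = NONSYN_MOVES[seq[i]][rng.integers(len(NONSYN_MOVES[seq[i]]))]
                    if CODON_TO_AA[new] != "*":
                        break
            seq[i] = new
            s_sites[i] = SYN_SITES[new]
            n_nonsyn[i] = len(NONSYN_MOVES[new])
        return "".join(seq)

    return _evolve_one(), _evolve_one()


@dataclass
class SimOutput:
    """Bundle returned by :func:`simulate_proteome`."""

    proteins: dict[str, str]
    cds: dict[str, str]
    loci: pd.DataFrame
    domains: dict[str, list[str]]
    seed_alignment: dict[str, str]
    truth: SimTruth
    motif_model: MotifModel


#: domain archetypes cycled over family genes; covers all nine subfamilies
DOMAIN_ARCHETYPES = [
    [], ["LRR"], ["Kelch"], ["FBA"], ["FBD"], ["TUB"], ["PP2"], ["WD40"],
    ["Actin"], ["LRR", "Kelch"],
]


def simulate_proteome(config: SimConfig, n_seed_sequences: int = 60) -> SimOutput:
    """Generate the synthetic proteome, CDS set, loci, domains and truth.

    Family genes carry exactly one motif instance sampled from the motif
    model; background genes carry none.  Each duplication event produces a
    pair diverged from a common ancestor for the stated time at the stated
    omega, placed at adjacent loci on one chromosome (tandem) or on two
    different chromosomes (segmental).
    """
    rng = np.random.default_rng(config.rng_seed)
    capacity = config.n_chromosomes * config.loci_per_chromosome
    total = config.n_background_genes + config.n_family_genes
    if capacity < total:
        raise ValueError(
            f"loci capacity {capacity} < total genes {total}; "
            "increase n_chromosomes or loci_per_chromosome"
        )

    model = make_motif_model(config.motif_length, rng)
    seed_aln = sample_seed_alignment(model, n_seed_sequences, rng)

    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    motif_positions: dict[str, int] = {}
    pair_table: list[tuple[str, str, float, str, float]] = []
    domains: dict[str, list[str]] = {}

    def _family_ancestor() -> tuple[str, int]:
        prot = list(_random_protein(config.codon_length, rng))
        pos = int(rng.integers(0, config.codon_length - config.motif_length + 1))
        prot[pos : pos + config.motif_length] = model.sample(rng)
        return "".join(prot), pos

    gene_counter = 0

    def _next_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"GmFBX{gene_counter:03d}"

    unit = 0
    for t_mya, dup_class, omega in config.duplication_events:
        anc_prot, pos = _family_ancestor()
        anc_cds = reverse_translate(anc_prot, rng)
        cds_a, cds_b = evolve_codon_pair(anc_cds, t_mya, omega, config.lambda_rate, rng)
        ga, gb = _next_id(), _next_id()
        for g, c in ((ga, cds_a), (gb, cds_b)):
            proteins[g] = translate_codons(split_codons(c))
            cds[g] = c
            motif_positions[g] = pos
            domains[g] = list(DOMAIN_ARCHETYPES[unit % len(DOMAIN_ARCHETYPES)])
        pair_table.append((ga, gb, t_mya, dup_class, omega))
        unit += 1

    for _ in range(config.n_family_genes - 2 * len(config.duplication_events)):
        prot, pos = _family_ancestor()
        g = _next_id()
        proteins[g] = prot
        cds[g] = reverse_translate(prot, rng)
        motif_positions[g] = pos
        domains[g] = list(DOMAIN_ARCHETYPES[unit % len(DOMAIN_ARCHETYPES)])
        unit += 1

    for i in range(config.n_background_genes):
        g = f"GmBG{i+1:03d}"
        prot = _random_protein(config.codon_length, rng)
        proteins[g] = prot
        cds[g] = reverse_translate(prot, rng)
        domains[g] = []

    loci = _assign_loci(config, pair_table, list(proteins), rng)
    truth = SimTruth(motif_positions=motif_positions, pair_table=pair_table)
    return SimOutput(proteins, cds, loci, domains, seed_aln, truth, model)


def _assign_loci(
    config: SimConfig,
    pair_table: list[tuple[str, str, float, str, float]],
    genes: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    chroms = [f"Chr{i+1:02d}" for i in range(config.n_chromosomes)]
    free: dict[str, list[int]] = {c: list(range(config.loci_per_chromosome)) for c in chroms}
    placed: dict[str, tuple[str, int]] = {}

    def _take(chrom: str, slot: int) -> None:
        free[chrom].remove(slot)

    for ga, gb, _t, dup_class, _w in pair_table:
        if dup_class == "tandem":
            # adjacent free slots on one chromosome
            candidates = [
                (c, s) for c in chroms for s in free[c] if s + 1 in free[c]
            ]
            if not candidates:
                raise ValueError("no adjacent loci left for a tandem pair")
            c, s = candidates[rng.integers(len(candidates))]
            placed[ga], placed[gb] = (c, s), (c, s + 1)
            _take(c, s), _take(c, s + 1)
        else:
            avail = [c for c in chroms if free[c]]
            if len(avail) < 2:
                raise ValueError("no two chromosomes left for a segmental pair")
            ca, cb = rng.choice(avail, size=2, replace=False)
            sa = free[ca][rng.integers(len(free[ca]))]
            sb = free[cb][rng.integers(len(free[cb]))]
            placed[ga], placed[gb] = (ca, sa), (cb, sb)
            _take(ca, sa), _take(cb, sb)

    remaining = [g for g in genes if g not in placed]
    open_slots = [(c, s) for c in chroms for s in free[c]]
    idx = rng.choice(len(open_slots), size=len(remaining), replace=False)
    for g, k in zip(remaining, idx):
        c, s = open_slots[k]
        placed[g] = (c, s)

    gene_len = 3 * config.codon_length
    rows = []
    for g in genes:
        c, s = placed[g]
        start = 1 + s * (gene_len + 5000)
        rows.append(dict(gene=g, chromosome=c, start=start, end=start + gene_len - 1,
                         strand=rng.choice(["+", "-"]), slot=s))
    df = pd.DataFrame(rows)
    df["locus_rank"] = (
        df.groupby("chromosome")["start"].rank(method="first").astype(int)
    )
    df = df.drop(columns="slot").set_index("gene")
    return df


# ---------------------------------------------------------------------------
# expression and qPCR simulation


def tissue_design(n_tissues: int = 14) -> pd.DataFrame:
    """One-sample-per-tissue design mirroring a 14-tissue RPKM atlas."""
    tissues = [f"tissue{i+1:02d}" for i in range(n_tissues)]
    return pd.DataFrame(
        dict(sample=tissues, condition=tissues, time=[""] * n_tissues,
             replicate=[1] * n_tissues)
    )


def salt_design(n_replicates: int = 3,
                timepoints: tuple[str, ...] = ("0h", "1h", "6h", "12h")) -> pd.DataFrame:
    """Salt time-course design: control (0h) plus treated time points."""
    rows = [
        dict(sample=f"{tp}_r{r+1}", condition=tp, time=tp, replicate=r + 1)
        for tp in timepoints
        for r in range(n_replicates)
    ]
    return pd.DataFrame(rows)


def simulate_expression(
    genes: list[str],
    design: pd.DataFrame,
    de_plan: dict[str, dict[str, float]] | None = None,
    dispersion: float = 0.3,
    rng: np.random.Generator | int | None = None,
    baseline_log2_mean: float = 6.0,
    baseline_log2_sd: float = 1.5,
) -> pd.DataFrame:
    """Gene x sample abundance matrix from a negative-binomial model.

    Each gene gets a log-normal baseline mean; a planted gene's mean in a
    condition is shifted by its planted log2 fold change; counts are drawn
    as gamma-Poisson with the given dispersion (var = mu + dispersion*mu^2).
    """
    de_plan = de_plan or {}
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    missing = set(de_plan) - set(genes)
    if missing:
        raise ValueError(f"de_plan genes not in gene list: {sorted(missing)}")
    rng = np.random.default_rng(rng)
    base = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=len(genes))
    conditions = design["condition"].tolist()
    shifts = np.array(
        [[de_plan.get(g, {}).get(c, 0.0) for c in conditions] for g in genes]
    )
    mu = base[:, None] * 2.0 ** shifts
    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    values = rng.poisson(lam).astype(float)
    return pd.DataFrame(values, index=genes, columns=design["sample"].tolist())


def simulate_tissue_archetypes(
    n_genes: int,
    n_archetypes: int,
    n_tissues: int = 14,
    noise_sd: float = 0.3,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Tissue matrix with planted expression-profile clusters.

    Each archetype is a log2 profile over tissues; genes get their
    archetype profile plus Gaussian noise, returned on the linear scale
    with the true group labels.
    """
    if n_archetypes < 1 or n_genes < n_archetypes:
        raise ValueError("need 1 <= n_archetypes <= n_genes")
    rng = np.random.default_rng(rng)
    profiles = rng.normal(6.0, 2.0, size=(n_archetypes, n_tissues))
    labels = np.repeat(np.arange(n_archetypes), int(np.ceil(n_genes / n_archetypes)))[:n_genes]
    log2_vals = profiles[labels] + rng.normal(0.0, noise_sd, size=(n_genes, n_tissues))
    genes = [f"gene{i+1:04d}" for i in range(n_genes)]
    tissues = [f"tissue{i+1:02d}" for i in range(n_tissues)]
    m = pd.DataFrame(2.0 ** log2_vals, index=genes, columns=tissues)
    return m, pd.Series(labels, index=genes, name="group")


def simulate_qpcr(
    expression_ratio: dict[str, dict[str, float]],
    reference_gene: str = "GmREF1",
    control: str = "0h",
    conditions: tuple[str, ...] = ("0h", "1h", "6h", "12h"),
    n_replicates: int = 3,
    base_ct: float = 24.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Ct table for target genes plus a condition-stable reference gene.

    Ct = base_ct - log2(relative abundance) + Gaussian noise; one PCR cycle
    per two-fold abundance change.  The reference gene's abundance is 1 in
    every condition.  ``expression_ratio`` maps gene -> condition -> fold
    change relative to the control (control itself is 1).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not in conditions")
    for g, ratios in expression_ratio.items():
        for cond, fc in ratios.items():
            if fc <= 0:
                raise ValueError(f"fold change must be positive ({g}, {cond})")
    rng = np.random.default_rng(rng)
    rows = []
    genes = list(expression_ratio) + [reference_gene]
    for g in genes:
        for cond in conditions:
            if g == reference_gene or cond == control:
                fc = 1.0
            else:
                fc = expression_ratio[g].get(cond, 1.0)
            for r in range(n_replicates):
                ct = base_ct - math.log2(fc) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                rows.append(dict(gene=g, sample=f"{cond}_r{r+1}", condition=cond,
                                 replicate=r + 1, ct=ct))
    return pd.DataFrame(rows)
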