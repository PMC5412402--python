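"""Paralog-pair detection, duplication classification, Ka/Ks estimation and dating.

Duplicate gene pairs are read off the phylogeny as cherries (two leaves
sharing an internal node) with strong bootstrap support and high pairwise
similarity: aligned region covering > 80% of the longer protein at > 70%
identity.  Pairs on one chromosome within a 20-locus window are tandem
duplicates; pairs on different chromosomes are segmental.  Synonymous (Ks)
and nonsynonymous (Ka) substitution rates come from the Nei-Gojobori (1986)
unweighted-pathway method with Jukes-Cantor correction, the duplication is
dated with the synonymous clock T = Ks / (2 lambda), and the Ka/Ks ratio
calls the selection mode.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._codons import CODON_TO_AA, SYN_SITES, split_codons

logger = logging.getLogger(__name__)

#: synonymous substitutions / synonymous site / year (plant nuclear clock)
DEFAULT_LAMBDA = 6.1e-9

_AMBIGUOUS = set("NRYSWKMBDHV")


@dataclass
class NGResult:
    """Nei-Gojobori estimates for one codon-aligned pair."""

    ka: float
    ks: float
    pn: float
    ps: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    codons_compared: int
    saturated_ka: bool = False
    saturated_ks: bool = False
    stop_pathway_fallback: bool = False


@dataclass
class ParalogPair:
    gene_a: str
    gene_b: str
    bootstrap: float
    identity: float
    coverage: float
    dup_class: str = "unclassified"
    ka: float = math.nan
    ks: float = math.nan
    ka_ks: float = math.nan
    t_mya: float = math.nan
    selection: str = "undetermined"
    flags: list[str] = field(default_factory=list)


def _codon_comparable(a: str, b: str) -> bool:
    if "-" in a or "-" in b:
        return False
    if _AMBIGUOUS & set(a) or _AMBIGUOUS & set(b):
        return False
    return CODON_TO_AA.get(a, "*") != "*" and CODON_TO_AA.get(b, "*") != "*"


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Average (syn, nonsyn) differences over all minimal pathways a -> b.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all are used and the fallback flag is raised.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0, False
    pathways: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            if CODON_TO_AA[nxt] == "*":
                through_stop = True
            cur = nxt
        (blocked if through_stop else pathways).append((sd, nd))
    fallback = not pathways
    use = blocked if fallback else pathways
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd, fallback


def nei_gojobori(cds_a: str, cds_b: str, correction: str = "jc") -> NGResult:
    """Ka/Ks for a codon-aligned CDS pair by the Nei-Gojobori method.

    Parameters
    ----------
    cds_a, cds_b :
        Equal-length nucleotide strings, length a multiple of 3.  Codons
        containing a gap ("-") or an ambiguity code in either sequence are
        skipped pairwise.  Internal stop codons are rejected.
    correction :
        "jc" applies K = -(3/4) ln(1 - (4/3) p) to both rates (undefined at
        p >= 3/4, reported as saturated); "none" returns the raw proportions.

    Symmetric in its arguments: site counts are averaged between the two
    sequences and pathway counting is direction-independent.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must be codon-aligned to equal length")
    if correction not in ("jc", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    codons_a = split_codons(cds_a.upper())
    codons_b = split_codons(cds_b.upper())
    for i, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        for name, c in (("cds_a", ca), ("cds_b", cb)):
            if "-" not in c and not (_AMBIGUOUS & set(c)):
                if CODON_TO_AA.get(c) == "*" and i < len(codons_a) - 1:
                    raise ValueError(f"{name}: internal stop codon {c} at codon {i}")

    s_sites = n_sites = 0.0
    sd = nd = 0.0
    compared = 0
    fallback = False
    for ca, cb in zip(codons_a, codons_b):
        if not _codon_comparable(ca, cb) :
            continue
        compared += 1
        s_sites += (SYN_SITES[ca] + SYN_SITES[cb]) / 2.0
        n_sites += 3.0 - (SYN_SITES[ca] + SYN_SITES[cb]) / 2.0
        d_s, d_n, fb = _pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
        fallback = fallback or fb

    if compared == 0:
        raise ValueError("no comparable codons between the two sequences")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0

    def _correct(p: float) -> tuple[float, bool]:
        if correction == "none":
            return p, False
        if p >= 0.75:
            return math.nan, True
        return -0.75 * math.log1p(-(4.0 / 3.0) * p), False

    ks, sat_s = _correct(ps)
    ka, sat_n = _correct(pn)
    return NGResult(
        ka=ka, ks=ks, pn=pn, ps=ps, n_sites=n_sites, s_sites=s_sites,
        nd=nd, sd=sd, codons_compared=compared,
        saturated_ka=sat_n, saturated_ks=sat_s, stop_pathway_fallback=fallback,
    )


def date_pair(ks: float, lambda_rate: float = DEFAULT_LAMBDA) -> float:
    """Duplication age in Mya from Ks via T = Ks / (2 lambda).

    A saturated (NaN) Ks yields an undetermined (NaN) date.
    """
    if lambda_rate <= 0:
        raise ValueError("lambda_rate must be positive")
    if math.isnan(ks):
        return math.nan
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * lambda_rate) / 1e6


def selection_mode(ka: float, ks: float, neutral_band: float = 0.0) -> str:
    """Call purifying / neutral / positive selection from Ka and Ks.

    Ka/Ks < 1 - band is purifying, > 1 + band positive, inside the band
    neutral.  Ks = 0 with Ka > 0 is positive (infinite ratio); Ka = Ks = 0
    is undetermined, as is any saturated (NaN) input.
    """
    if math.isnan(ka) or math.isnan(ks):
        return "undetermined"
    if ka < 0 or ks < 0:
        raise ValueError("Ka and Ks must be non-negative")
    if ks == 0:
        return "positive" if ka > 0 else "undetermined"
    ratio = ka / ks
    if ratio < 1.0 - neutral_band:
        return "purifying"
    if ratio > 1.0 + neutral_band:
        return "positive"
    return "neutral"


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def _identity_coverage(aln, len_a: int, len_b: int) -> tuple[float, float]:
    a_blocks, b_blocks = aln.aligned
    seq_a, seq_b = aln.sequences
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        aligned_cols += a1 - a0
        matches += sum(1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]) if x == y)
    longer = max(len_a, len_b)
    if aligned_cols == 0:
        return 0.0, 0.0
    return matches / aligned_cols, aligned_cols / longer


def find_cherries(tree) -> list[tuple[str, str, float]]:
    """All (leaf_a, leaf_b, support) cherries of a tree.

    Support is read from the internal node's name (bootstrap percentage set
    by ``phylo.bootstrap``); an unlabeled cherry has support 0.
    """
    cherries = []
    for node in tree.non_tips(include_self=False):
        children = node.children
        if len(children) == 2 and all(c.is_tip() for c in children):
            try:
                support = float(node.name) if node.name is not None else 0.0
            except ValueError:
                support = 0.0
            a, b = sorted(c.name for c in children)
            cherries.append((a, b, support))
    return sorted(cherries)


def detect_pairs(
    tree,
    proteins: dict[str, str],
    min_bootstrap: float = 90.0,
    min_identity: float = 0.70,
    min_coverage: float = 0.80,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[ParalogPair], list[ParalogPair]]:
    """Paralogous pairs from tree cherries passing support/similarity filters.

    Returns ``(pairs, rejected)``: cherries passing bootstrap > min_bootstrap,
    identity > min_identity and coverage > min_coverage, and the candidate
    cherries that failed a filter.  Cherries are disjoint by topology, so each
    gene appears in at most one pair.
    """
    aligner = aligner or _default_aligner()
    pairs: list[ParalogPair] = []
    rejected: list[ParalogPair] = []
    for gene_a, gene_b, support in find_cherries(tree):
        for g in (gene_a, gene_b):
            if g not in proteins:
                raise KeyError(f"no protein sequence for tree leaf {g!r}")
        aln = aligner.align(proteins[gene_a], proteins[gene_b])[0]
        identity, coverage = _identity_coverage(
            aln, len(proteins[gene_a]), len(proteins[gene_b])
        )
        pair = ParalogPair(gene_a, gene_b, support, identity, coverage)
        ok = support > min_bootstrap and identity > min_identity and coverage > min_coverage
        (pairs if ok else rejected).append(pair)
    return pairs, rejected


UNPLACED_PREFIXES = ("scaffold", "unplaced", "contig")


def classify_pair(
    gene_a: str,
    gene_b: str,
    loci: pd.DataFrame,
    tandem_window: int = 20,
) -> str:
    """Tandem / segmental / dispersed call for one gene pair.

    ``loci`` is indexed by gene id with columns ``chromosome`` and
    ``locus_rank``.  Same chromosome within ``tandem_window`` locus ranks is
    tandem; different chromosomes segmental; same chromosome beyond the
    window dispersed.  Genes on scaffolds or unplaced contigs cannot be
    classified and yield "undetermined".
    """
    for g in (gene_a, gene_b):
        if g not in loci.index:
            raise KeyError(f"gene {g!r} absent from loci table")
    chrom_a = str(loci.at[gene_a, "chromosome"])
    chrom_b = str(loci.at[gene_b, "chromosome"])
    if any(c.lower().startswith(UNPLACED_PREFIXES) for c in (chrom_a, chrom_b)):
        logger.warning("pair (%s, %s) on unplaced sequence; class undetermined", gene_a, gene_b)
        return "undetermined"
    if chrom_a != chrom_b:
        return "segmental"
    gap = abs(int(loci.at[gene_a, "locus_rank"]) - int(loci.at[gene_b, "locus_rank"]))
    return "tandem" if gap <= tandem_window else "dispersed"


def codon_align(protein_aln, cds_a: str, cds_b: str) -> tuple[str, str]:
    """Back-translate a pairwise protein alignment into a codon alignment."""
    a_blocks, b_blocks = protein_aln.aligned
    seq_a, seq_b = protein_aln.sequences
    out_a: list[str] = []
    out_b: list[str] = []
    pa = pb = 0
    for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks):
        while pa < a0:
            out_a.append(cds_a[3 * pa : 3 * pa + 3])
            out_b.append("---")
            pa += 1
        while pb < b0:
            out_a.append("---")
            out_b.append(cds_b[3 * pb : 3 * pb + 3])
            pb += 1
        for i in range(a1 - a0):
            out_a.append(cds_a[3 * (a0 + i) : 3 * (a0 + i) + 3])
            out_b.append(cds_b[3 * (b0 + i) : 3 * (b0 + i) + 3])
        pa, pb = a1, b1
    while pa * 3 < len(cds_a):
        out_a.append(cds_a[3 * pa : 3 * pa + 3])
        out_b.append("---")
        pa += 1
    while pb * 3 < len(cds_b):
        out_a.append("---")
        out_b.append(cds_b[3 * pb : 3 * pb + 3])
        pb += 1
    return "".join(out_a), "".join(out_b)


def analyze_pairs(
    pairs: list[ParalogPair],
    proteins: dict[str, str],
    cds: dict[str, str],
    loci: pd.DataFrame,
    tandem_window: int = 20,
    lambda_rate: float = DEFAULT_LAMBDA,
    neutral_band: float = 0.0,
    correction: str = "jc",
    aligner: Align.PairwiseAligner | None = None,
) -> pd.DataFrame:
    """Classify, estimate Ka/Ks, date and call selection for detected pairs."""
    aligner = aligner or _default_aligner()
    rows = []
    for pair in pairs:
        a, b = pair.gene_a, pair.gene_b
        for g in (a, b):
            if g not in cds:
                raise KeyError(f"no CDS for gene {g!r}")
        pair.dup_class = classify_pair(a, b, loci, tandem_window)
        # strip the stop codon if present so NG86 sees sense codons only
        cds_a, cds_b = cds[a], cds[b]
        if CODON_TO_AA.get(cds_a[-3:].upper()) == "*":
            cds_a = cds_a[:-3]
        if CODON_TO_AA.get(cds_b[-3:].upper()) == "*":
            cds_b = cds_b[:-3]
        aln = aligner.align(proteins[a], proteins[b])[0]
        ca, cb = codon_align(aln, cds_a, cds_b)
        ng = nei_gojobori(ca, cb, correction=correction)
        pair.ka, pair.ks = ng.ka, ng.ks
        if ng.saturated_ks:
            pair.flags.append("ks_saturated")
        if ng.saturated_ka:
            pair.flags.append("ka_saturated")
        if ng.stop_pathway_fallback:
            pair.flags.append("stop_pathway_fallback")
        pair.ka_ks = (
            pair.ka / pair.ks
            if pair.ks and not math.isnan(pair.ks) and not math.isnan(pair.ka)
            else math.nan
        )
        pair.t_mya = date_pair(pair.ks, lambda_rate) if not math.isnan(pair.ks) else math.nan
        pair.selection = selection_mode(pair.ka, pair.ks, neutral_band)
        rows.append(
            dict(
                gene_a=a, gene_b=b, bootstrap=pair.bootstrap,
                identity=pair.identity, coverage=pair.coverage,
                dup_class=pair.dup_class, ka=pair.ka, ks=pair.ks,
                ka_ks=pair.ka_ks, t_mya=pair.t_mya, selection=pair.selection,
                flags=";".join(pair.flags),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "bootstrap", "identity", "coverage",
            "dup_class", "ka", "ks", "ka_ks", "t_mya", "selection", "flags",
        ],
    )
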