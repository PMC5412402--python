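"""Family-member identification and characterization.

A position-specific scoring matrix (PSSM) built from a seed alignment of
the family motif is slid along every protein; the best-scoring window per
protein is compared against a bit-score threshold calibrated on background
(non-family) sequences.  Detected members are classified into the nine
C-terminal-domain subfamilies (FBU, FBL, FBK, FBA, FBD, FBT, FBP, FBW,
FBO), the motif alignment is summarized into sequence-logo statistics
(per-column frequencies, identity, information content in bits), and basic
protein physical properties (molecular weight, isoelectric point) are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = set("-.")

#: Average amino-acid composition of a typical proteome (UniProt/Swiss-Prot
#: release statistics, renormalized over the 20 standard residues).
BACKGROUND_FREQS = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0664, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


def background_vector(freqs: dict[str, float] | None = None) -> np.ndarray:
    freqs = freqs or BACKGROUND_FREQS
    vec = np.array([freqs[a] for a in AMINO_ACIDS], dtype=float)
    return vec / vec.sum()


@dataclass
class MotifProfile:
    """Log-odds PSSM over the 20 standard amino acids, scores in bits."""

    log_odds: np.ndarray  # (length, 20)
    background: np.ndarray  # (20,)
    pseudocount: float

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_odds).all():
            raise ValueError("profile scores must be finite")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")


@dataclass
class MotifHit:
    gene: str
    start: int
    score: float
    passed: bool
    extra_starts: list[int] = field(default_factory=list)


def build_profile(
    seed_alignment: dict[str, str],
    pseudocount: float = 1.0,
    background: dict[str, float] | None = None,
) -> MotifProfile:
    """Build a log-odds PSSM from an aligned set of motif sequences.

    score[p][a] = log2( (count[p][a] + pc * bg[a]) / (n[p] + pc) / bg[a] ),
    with gap characters excluded from the counts.  The pseudocount keeps
    empty columns finite (their scores go to 0 as the column approaches the
    background distribution).
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    lengths = {len(s) for s in seed_alignment.values()}
    if len(lengths) > 1:
        raise ValueError("ragged seed alignment: unequal row lengths")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = background_vector(background)
    length = lengths.pop()
    counts = np.zeros((length, 20))
    for seq in seed_alignment.values():
        for p, ch in enumerate(seq.upper()):
            if ch in GAP_CHARS:
                continue
            if ch not in AA_INDEX:
                raise ValueError(f"non-standard residue {ch!r} in seed alignment")
            counts[p, AA_INDEX[ch]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount * bg) / (totals + pseudocount)
    return MotifProfile(np.log2(probs / bg), bg, pseudocount)


def _window_scores(profile: MotifProfile, protein: str) -> np.ndarray:
    """Score of every window of width profile.length along the protein."""
    seq = protein.upper()
    idx = np.array([AA_INDEX.get(ch, -1) for ch in seq])
    if (idx < 0).any():
        bad = seq[int(np.argmax(idx < 0))]
        raise ValueError(f"non-standard residue {bad!r} in protein sequence")
    n_win = len(seq) - profile.length + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, profile.length)
    return profile.log_odds[np.arange(profile.length), windows].sum(axis=1)


def scan(
    proteome: dict[str, str],
    profile: MotifProfile,
    threshold: float,
    report_multiple: bool = True,
) -> list[MotifHit]:
    """Slide the PSSM along every protein and report the best window.

    Every protein at least as long as the profile yields one hit with
    ``passed = score >= threshold``.  Shorter proteins yield no hit.  When
    ``report_multiple`` is set, additional non-overlapping windows that
    also pass the threshold are reported in ``extra_starts`` (greedy by
    descending score), so proteins carrying two motif copies are visible.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    hits = []
    for gene, seq in proteome.items():
        scores = _window_scores(profile, seq)
        if scores.size == 0:
            continue
        best = int(np.argmax(scores))
        hit = MotifHit(gene, best, float(scores[best]), bool(scores[best] >= threshold))
        if report_multiple and hit.passed:
            taken = [(best, best + profile.length)]
            for cand in np.argsort(scores)[::-1]:
                if scores[cand] < threshold:
                    break
                c0, c1 = int(cand), int(cand) + profile.length
                if all(c1 <= s or c0 >= e for s, e in taken):
                    taken.append((c0, c1))
                    hit.extra_starts.append(c0)
        hits.append(hit)
    return hits


def calibrate_threshold(
    profile: MotifProfile,
    background_proteome: dict[str, str],
    quantile: float = 0.99,
) -> float:
    """Bit-score threshold: a quantile of best-window scores on background.

    Mirrors an empirical false-positive calibration: at the default 99th
    percentile roughly 1% of background proteins score above threshold.
    """
    best = []
    for seq in background_proteome.values():
        scores = _window_scores(profile, seq)
        if scores.size:
            best.append(scores.max())
    if not best:
        raise ValueError("no background protein is as long as the profile")
    return float(np.quantile(best, quantile))


@dataclass
class ConservationProfile:
    """Per-column logo statistics of a motif alignment."""

    frequencies: np.ndarray  # (length, 20), rows sum to 1 (or flagged)
    identity: np.ndarray  # max frequency per column
    information: np.ndarray  # bits, log2(20) - entropy
    flagged: np.ndarray  # all-gap columns


def conservation(motif_alignment: dict[str, str]) -> ConservationProfile:
    """Column frequencies, top-residue identity and information content.

    Frequencies are over non-gap residues; information content is
    log2(20) - H(column) in bits with no small-sample correction, matching
    the bit axis of a sequence logo.  All-gap columns are flagged and get
    information 0.
    """
    if not motif_alignment:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in motif_alignment.values()}
    if len(lengths) > 1:
        raise ValueError("ragged alignment: unequal row lengths")
    length = lengths.pop()
    counts = np.zeros((length, 20))
    for seq in motif_alignment.values():
        for p, ch in enumerate(seq.upper()):
            if ch in GAP_CHARS:
                continue
            if ch not in AA_INDEX:
                raise ValueError(f"non-standard residue {ch!r}")
            counts[p, AA_INDEX[ch]] += 1
    totals = counts.sum(axis=1)
    flagged = totals == 0
    freqs = np.zeros_like(counts)
    np.divide(counts, totals[:, None], out=freqs, where=totals[:, None] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = np.where(flagged, 0.0, np.log2(20.0) + plogp.sum(axis=1))
    identity = freqs.max(axis=1)
    return ConservationProfile(freqs, identity, np.clip(info, 0.0, np.log2(20.0)), flagged)


SUBFAMILIES = ("FBU", "FBL", "FBK", "FBA", "FBD", "FBT", "FBP", "FBW", "FBO")

#: C-terminal domain -> dedicated subfamily (everything else known -> FBO)
DEFAULT_DOMAIN_MAP = {
    "LRR": "FBL",
    "Kelch": "FBK",
    "FBA": "FBA",
    "FBD": "FBD",
    "TUB": "FBT",
    "PP2": "FBP",
    "WD40": "FBW",
}


def classify_subfamily(
    domains: dict[str, list[str]],
    known_domain_map: dict[str, str] | None = None,
    unknown_domain: str = "other",
) -> dict[str, str]:
    """Assign each gene one of the nine C-terminal-domain subfamilies.

    No known C-terminal domain -> FBU; exactly one domain with a dedicated
    subfamily -> that subfamily; one other known domain, or more than one
    known domain -> FBO.  Domain names absent from the map are treated as
    "other" known domains by default, or rejected with
    ``unknown_domain="error"``.
    """
    if unknown_domain not in ("other", "error"):
        raise ValueError("unknown_domain must be 'other' or 'error'")
    dmap = known_domain_map or DEFAULT_DOMAIN_MAP
    labels: dict[str, str] = {}
    for gene, doms in domains.items():
        doms = [d for d in doms if d]
        if not doms:
            labels[gene] = "FBU"
            continue
        for d in doms:
            if d not in dmap and unknown_domain == "error":
                raise ValueError(f"unknown domain name {d!r} for gene {gene!r}")
        if len(doms) > 1:
            labels[gene] = "FBO"
        else:
            labels[gene] = dmap.get(doms[0], "FBO")
    return labels


#: EMBOSS pKa values for ionizable groups (iep program defaults).
PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
_POSITIVE = ("Nterm", "H", "K", "R")
_NEGATIVE = ("Cterm", "C", "D", "E", "Y")


def net_charge(protein: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (EMBOSS pKa set)."""
    seq = protein.upper()
    counts = {a: seq.count(a) for a in "CDEHKRY"}
    charge = 0.0
    for group in _POSITIVE:
        n = 1 if group == "Nterm" else counts[group]
        charge += n / (1.0 + 10.0 ** (ph - PKA[group]))
    for group in _NEGATIVE:
        n = 1 if group == "Cterm" else counts[group]
        charge -= n / (1.0 + 10.0 ** (PKA[group] - ph))
    return charge


def protein_properties(protein: str) -> tuple[float, float]:
    """(molecular weight in Da, theoretical pI) of a protein sequence.

    Molecular weight uses average residue masses plus one water; the pI is
    found by bisection of the net-charge curve to |charge| < 1e-4.  Only
    the 20 standard amino acids are accepted.
    """
    seq = protein.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)}")
    mw = ProteinAnalysis(seq).molecular_weight()
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(seq, mid)
        if abs(c) < 1e-4:
            return mw, mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return mw, 0.5 * (lo + hi)


def family_counts(passing_ids: list[str]) -> tuple[int, int]:
    """(transcript count, gene count) for family members.

    Alternative transcripts share a gene name with a dotted isoform
    suffix (e.g. ``GmFBX3.1``, ``GmFBX3.2``); duplicate ids collapse, so
    the counts reflect id-level union of any number of search strategies.
    """
    transcripts = set(passing_ids)
    genes = {t.split(".", 1)[0] for t in transcripts}
    return len(transcripts), len(genes)
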