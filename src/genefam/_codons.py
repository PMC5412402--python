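"""Standard genetic code tables used by the Ka/Ks estimator and the simulator.

Everything here is precomputed once at import: codon -> amino acid, the
Nei-Gojobori fractional synonymous-site count per codon, and the single-
nucleotide mutational neighborhood of every sense codon.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

#: codon -> one-letter amino acid; stop codons map to "*"
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")


def _neighbors(codon: str):
    """All single-nucleotide mutants of a codon as (position, new_codon)."""
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield pos, codon[:pos] + nt + codon[pos + 1 :]


def _syn_site_count(codon: str) -> float:
    # NG86: fraction of the 3 possible changes per position that are
    # synonymous; changes to stop codons count as nonsynonymous.
    aa = CODON_TO_AA[codon]
    syn = sum(1 for _, mut in _neighbors(codon) if CODON_TO_AA[mut] == aa)
    return syn / 3.0


#: codon -> NG86 synonymous sites (0..3); nonsynonymous sites are 3 - S
SYN_SITES: dict[str, float] = {c: _syn_site_count(c) for c in SENSE_CODONS}

#: codon -> list of (position, mutant_codon) whose translation is unchanged
SYN_MOVES: dict[str, list[tuple[int, str]]] = {
    c: [(p, m) for p, m in _neighbors(c) if CODON_TO_AA[m] == CODON_TO_AA[c]]
    for c in SENSE_CODONS
}

#: codon -> nonsynonymous single-nt mutants, stops included (NG86 universe)
NONSYN_MOVES: dict[str, list[tuple[int, str]]] = {
    c: [(p, m) for p, m in _neighbors(c) if CODON_TO_AA[m] != CODON_TO_AA[c]]
    for c in SENSE_CODONS
}


def translate_codons(codons: list[str]) -> str:
    return "".join(CODON_TO_AA[c] for c in codons)


def split_codons(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
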