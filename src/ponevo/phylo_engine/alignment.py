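"""Alignment container for protein and in-frame codon data.

Sequences are held as plain strings; the numeric encoding used by the
likelihood engine (state indices with -1 for gap/ambiguity, treated as
missing data) is derived on demand.  Site-pattern compression is exposed
here so the engine can sum per-pattern log-likelihoods with weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# 61 sense codons of the standard genetic code, in lexicographic (TCAG) order
# as conventionally printed by codon-model software.
_NUC_ORDER = "TCAG"
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(
    a + b + c
    for a in _NUC_ORDER
    for b in _NUC_ORDER
    for c in _NUC_ORDER
    if a + b + c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def translate_codon(codon: str) -> str:
    return standard_dna_table.forward_table[codon]


@dataclass
class Alignment:
    """Equal-length named sequences, protein or in-frame codon flavor."""

    names: list[str]
    rows: list[str]
    flavor: str = "protein"  # or "codon"

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows have unequal lengths")
        self.rows = [r.upper() for r in self.rows]
        if self.flavor == "codon":
            (length,) = lengths
            if length % 3 != 0:
                raise ValueError("codon alignment length not divisible by 3")
            for name, row in zip(self.names, self.rows):
                for j in range(0, length, 3):
                    codon = row[j : j + 3]
                    if codon in STOP_CODONS:
                        raise ValueError(
                            f"internal stop codon {codon} in {name} at nt {j + 1}"
                        )
        elif self.flavor != "protein":
            raise ValueError(f"unknown flavor {self.flavor!r}")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        """Number of columns (codons for codon flavor)."""
        n = len(self.rows[0])
        return n // 3 if self.flavor == "codon" else n

    @property
    def n_states(self) -> int:
        return 61 if self.flavor == "codon" else 20

    def state_matrix(self) -> np.ndarray:
        """(n_seqs, n_sites) int8/int matrix; -1 marks gap/ambiguity."""
        if self.flavor == "protein":
            out = np.full((len(self.rows), self.n_sites), -1, dtype=np.int64)
            for i, row in enumerate(self.rows):
                for j, ch in enumerate(row):
                    out[i, j] = AA_INDEX.get(ch, -1)
            return out
        out = np.full((len(self.rows), self.n_sites), -1, dtype=np.int64)
        for i, row in enumerate(self.rows):
            for j in range(self.n_sites):
                out[i, j] = CODON_INDEX.get(row[3 * j : 3 * j + 3], -1)
        return out

    def patterns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Compressed site patterns.

        Returns ``(pattern_matrix, weights, site_to_pattern)`` where
        ``pattern_matrix`` is (n_seqs, n_patterns), ``weights`` the column
        multiplicities, and ``site_to_pattern`` maps original columns to
        pattern indices, so per-site quantities can be expanded exactly.
        """
        mat = self.state_matrix()
        pats, site_to_pat, counts = np.unique(
            mat.T, axis=0, return_inverse=True, return_counts=True
        )
        return pats.T, counts.astype(float), site_to_pat

    # ------------------------------------------------------------------
    def empirical_codon_frequencies(self, method: str = "F3x4") -> np.ndarray:
        """Codon frequency vector (61,) from the alignment.

        F3x4 multiplies per-position nucleotide frequencies; F1x4 uses a
        single pooled nucleotide distribution; F61 counts codons directly.
        All renormalize after removing stop codons.
        """
        if self.flavor != "codon":
            raise ValueError("codon frequencies require codon flavor")
        if method == "F61":
            counts = np.zeros(61)
            for row in self.rows:
                for j in range(self.n_sites):
                    idx = CODON_INDEX.get(row[3 * j : 3 * j + 3])
                    if idx is not None:
                        counts[idx] += 1
            counts += 0.5  # avoid zero-frequency states
            return counts / counts.sum()
        nuc_idx = {n: i for i, n in enumerate(_NUC_ORDER)}
        pos_counts = np.ones((3, 4))  # +1 pseudocount per nucleotide
        for row in self.rows:
            for j, ch in enumerate(row):
                if ch in nuc_idx:
                    pos_counts[j % 3, nuc_idx[ch]] += 1
        pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
        if method == "F1x4":
            pooled = pos_counts.sum(axis=0)
            pos_freq = np.tile(pooled / pooled.sum(), (3, 1))
        elif method != "F3x4":
            raise ValueError(f"unknown codon frequency method {method!r}")
        freqs = np.array(
            [
                pos_freq[0, nuc_idx[c[0]]]
                * pos_freq[1, nuc_idx[c[1]]]
                * pos_freq[2, nuc_idx[c[2]]]
                for c in SENSE_CODONS
            ]
        )
        return freqs / freqs.sum()

    def translated(self) -> "Alignment":
        """Amino-acid view of a codon alignment (gaps/ambiguity -> '-')."""
        if self.flavor != "codon":
            raise ValueError("can only translate codon alignments")
        rows = []
        for row in self.rows:
            aas = []
            for j in range(self.n_sites):
                codon = row[3 * j : 3 * j + 3]
                aas.append(translate_codon(codon) if codon in CODON_INDEX else "-")
            rows.append("".join(aas))
        return Alignment(list(self.names), rows, flavor="protein")


# ----------------------------------------------------------------------
def read_fasta(path, flavor: str = "protein") -> Alignment:
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq))
    return Alignment(names, rows, flavor=flavor)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")
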