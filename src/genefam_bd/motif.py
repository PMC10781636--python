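"""Upstream-window extraction, IUPAC word scanning and PWM comparison.

Offsets are reported relative to the A of the start codon as negative,
-1-based positions: the base immediately 5' of ATG sits at -1, and a hit's
offset is the position of its 5'-most base on the coding strand.  Scanning
covers both strands by default; a minus-strand hit means the word occurs as
its reverse complement in the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .trees import GeneModel, Tree

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class UpstreamWindow:
    """Coding-strand sequence immediately 5' of a start codon."""

    species: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("window contains non-ACGTN characters")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def offset_of(self, index: int) -> int:
        """Offset from the start codon of the base at string index."""
        return index - self.length


@dataclass(frozen=True)
class MotifHit:
    species: str
    gene: str
    offset: int          # negative, position of the 5'-most matched base
    strand: str          # '+' or '-'
    word: str            # matched window substring (coding strand)


def extract_upstream(genome: Mapping[str, str], model: GeneModel,
                     L: int = 300) -> UpstreamWindow:
    """Window of up to ``L`` bp immediately 5' of the start codon.

    Minus-strand genes are reverse-complemented so the window reads on the
    coding strand.  Truncated at scaffold edges, never padded.
    """
    scaffold = genome[model.scaffold].upper()
    pos = model.start_codon_position
    if not (0 <= pos < len(scaffold)):
        raise ValueError(f"start codon outside scaffold: {pos}")
    if model.strand == "+":
        lo = max(0, pos - L)
        window = scaffold[lo:pos]
    else:
        hi = min(len(scaffold), pos + 1 + L)
        window = reverse_complement(scaffold[pos + 1:hi])
    return UpstreamWindow(species=model.species_id, gene=model.gene_id,
                          sequence=window)


def _matches(word: str, text: str, index: int) -> bool:
    for k, symbol in enumerate(word):
        if text[index + k] not in IUPAC[symbol]:
            return False
    return True


def scan_word(windows: Iterable[UpstreamWindow], word: str = "ATGCAAAT",
              strands: str = "both") -> list[MotifHit]:
    """All IUPAC-compatible occurrences of ``word`` in the windows.

    Deterministic order: (species, gene, offset, strand).  ``strands`` is
    "+", "-", or "both".
    """
    word = word.upper()
    bad = set(word) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC character(s): {sorted(bad)}")
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both': {strands!r}")
    rc = reverse_complement(word)
    hits: list[MotifHit] = []
    for window in windows:
        seq = window.sequence
        w = len(word)
        for i in range(len(seq) - w + 1):
            if strands in ("+", "both") and _matches(word, seq, i):
                hits.append(MotifHit(window.species, window.gene,
                                     window.offset_of(i), "+", seq[i:i + w]))
            if strands in ("-", "both") and _matches(rc, seq, i):
                hits.append(MotifHit(window.species, window.gene,
                                     window.offset_of(i), "-", seq[i:i + w]))
    hits.sort(key=lambda h: (h.species, h.gene, h.offset, h.strand))
    return hits


@dataclass
class ConservationCall:
    conserved: bool
    supporting_species: list[str]
    spanning_node: Optional[str]   # species-tree MRCA of the supporters


def conservation_call(hits: Iterable[MotifHit], species_tree: Tree,
                      min_species: int,
                      band: tuple[int, int] = (-300, -1)) -> ConservationCall:
    """Call the motif conserved if >= ``min_species`` species have a hit
    whose offset falls inside ``band`` (inclusive offset interval)."""
    lo, hi = band
    supporters = sorted({h.species for h in hits if lo <= h.offset <= hi})
    conserved = len(supporters) >= min_species
    spanning = None
    if supporters:
        known = [sp for sp in supporters if sp in species_tree]
        if known:
            spanning = species_tree.mrca(known).id
    return ConservationCall(conserved=conserved, supporting_species=supporters,
                            spanning_node=spanning)


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Per-position base probabilities (rows A, C, G, T)."""

    probabilities: np.ndarray      # shape (4, width)
    pseudocount: float = 0.0
    site_count: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != 4:
            raise ValueError("PWM must be a 4 x width matrix")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if self.pseudocount > 0 and (p <= 0).any():
            raise ValueError("positive pseudocount implies strictly positive entries")
        self.probabilities = p

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    def reverse_complement(self) -> "PWM":
        return PWM(self.probabilities[::-1, ::-1].copy(),
                   pseudocount=self.pseudocount, site_count=self.site_count)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=0))

    def to_jaspar(self, name: str = "motif") -> str:
        lines = [f">{name}"]
        for i, base in enumerate(BASES):
            values = " ".join(f"{v:.6f}" for v in self.probabilities[i])
            lines.append(f"{base} [ {values} ]")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jaspar(cls, text: str) -> "PWM":
        rows = []
        for line in text.strip().splitlines():
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            inner = line.split("[", 1)[1].rsplit("]", 1)[0]
            rows.append([float(v) for v in inner.split()])
        matrix = np.array(rows, dtype=float)
        if matrix.shape[0] != 4:
            raise ValueError("JASPAR text must have 4 base rows")
        colsums = matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            matrix = matrix / colsums   # accept count matrices
        return cls(matrix)


def build_pwm(sites: Sequence[str], pseudocount: float = 0.5) -> PWM:
    """Column-normalised count matrix: p(b, j) = (n_bj + pc) / (N + 4 pc)."""
    if not sites:
        raise ValueError("at least one site is required")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites must share one length")
    counts = np.zeros((4, width))
    index = {b: i for i, b in enumerate(BASES)}
    for site in sites:
        for j, base in enumerate(site.upper()):
            if base not in index:
                raise ValueError(f"non-ACGT base in site: {base!r}")
            counts[index[base], j] += 1
    n = len(sites)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    return PWM(probs, pseudocount=pseudocount, site_count=n)


@dataclass
class PWMComparison:
    score: float
    offset: int
    strand: str


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two probability columns (length-4 vectors)."""
    da, db = a - a.mean(), b - b.mean()
    na, nb = float(np.sqrt((da * da).sum())), float(np.sqrt((db * db).sum()))
    if na == 0.0 and nb == 0.0:
        return 1.0 if np.allclose(a, b) else 0.0
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float((da * db).sum() / (na * nb))


def compare_pwm(pwm_a: PWM, pwm_b: PWM, min_overlap: int = 6) -> PWMComparison:
    """Best mean column-wise Pearson correlation over ungapped offsets.

    Both strands of ``pwm_b`` are searched; ties prefer the '+' strand and
    then the smallest offset.  The score is symmetric in its arguments and
    invariant to reverse-complementing either input.
    """
    if pwm_a.width < min_overlap or pwm_b.width < min_overlap:
        raise ValueError(f"PWMs must each have >= {min_overlap} columns")
    best: Optional[PWMComparison] = None
    for strand, b in (("+", pwm_b), ("-", pwm_b.reverse_complement())):
        wa, wb = pwm_a.width, b.width
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            a_lo, b_lo = max(0, offset), max(0, -offset)
            overlap = min(wa - a_lo, wb - b_lo)
            if overlap < min_overlap:
                continue
            cols = [
                _column_corr(pwm_a.probabilities[:, a_lo + k],
                             b.probabilities[:, b_lo + k])
                for k in range(overlap)
            ]
            score = float(np.mean(cols))
            candidate = PWMComparison(score=score, offset=offset, strand=strand)
            if best is None or score > best.score + 1e-12:
                best = candidate
    assert best is not None
    return best
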