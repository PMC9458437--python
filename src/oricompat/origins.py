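"""Sequence-side calculus for ColE1 RNAI origin libraries.

ColE1-type plasmid copy number is controlled by the antisense RNA RNAI,
a ~108-nt transcript folding into three stem-loops (hairpins III, II and I,
5'->3').  Engineering compatible origins means diversifying the hairpin
loops; this module provides the supporting arithmetic:

* exact sizing of IUPAC-degenerate oligonucleotide libraries,
* dot-bracket parsing and terminal hairpin-loop extraction,
* ordinary least squares of plasmid copy number on summed loop length,
* the NGS variant-counting workflow (quality trim, flank filter,
  dedup/count) used to census a transformed library.

Structures are consumed as dot-bracket strings (ViennaRNA-style output);
no folding is performed here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_DEGENERACY",
    "DEFAULT_FLANK_MOTIFS",
    "FULL_RNAI_TEMPLATE",
    "LOOP_RESTRICTED_TEMPLATES",
    "OriginVariant",
    "LoopFit",
    "degenerate_space_size",
    "parse_dot_bracket",
    "hairpin_loops",
    "loop_length_sum",
    "fit_copy_number_vs_loop",
    "count_variants",
    "top_k_fraction",
    "read_fastq",
    "write_variant_table",
]

#: Number of bases each IUPAC nucleotide code stands for.
IUPAC_DEGENERACY: dict[str, int] = {
    "A": 1, "C": 1, "G": 1, "T": 1, "U": 1,
    "R": 2, "Y": 2, "S": 2, "W": 2, "K": 2, "M": 2,
    "B": 3, "D": 3, "H": 3, "V": 3,
    "N": 4,
}

#: Base sets for IUPAC codes (DNA alphabet; U is canonicalised to T).
IUPAC_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Constant sequences flanking the library diversity in the NGS workflow,
#: in read order.  Reads failing to contain all four, in order, are dropped.
DEFAULT_FLANK_MOTIFS: tuple[str, ...] = (
    "CGTAATCTGCTGCTTGCAAA",
    "GGTTTGTTTGCCGGA",
    "TTTCCGAAGGTAACT",
    "AGCGCAG",
)

#: Unrestricted diversification of the full ~100-nt RNAI: 4^100 sequences.
FULL_RNAI_TEMPLATE: str = "N" * 100

#: Default loop-restricted combined library design.  The deposited design
#: diversifies the three hairpin loops (N codes) and a few immediately
#: adjacent positions (K = G/T two-fold codes); this is a synthetic
#: reconstruction with 13 N and 6 K positions, total degeneracy
#: 4^13 * 2^6 = 4^16 = 4 294 967 296 (~4.3e9).
LOOP_RESTRICTED_TEMPLATES: tuple[str, ...] = (
    "KK" + "N" * 7 + "KK" + "N" * 6 + "KK",
)


# ---------------------------------------------------------------------------
# degenerate library sizing

def _template_size(template: str) -> int:
    size = 1
    for pos, code in enumerate(template.upper()):
        try:
            size *= IUPAC_DEGENERACY[code]
        except KeyError:
            raise ValueError(
                f"invalid IUPAC code {code!r} at position {pos}"
            ) from None
    return size


def degenerate_space_size(templates: str | Iterable[str]) -> int:
    """Exact number of sequences encoded by one or more IUPAC templates.

    A template is a string over the IUPAC nucleotide alphabet; its size is
    the product of per-position degeneracies.  Several templates (a combined
    library design) contribute additively — the result is an upper bound on
    the union, duplicates across templates are not collapsed.  Computed in
    exact integer arithmetic, so 100-N templates (4^100) do not overflow.
    """
    if isinstance(templates, str):
        templates = [templates]
    templates = list(templates)
    if not templates:
        raise ValueError("at least one template is required")
    return sum(_template_size(t) for t in templates)


# ---------------------------------------------------------------------------
# dot-bracket parsing and hairpin loops

def parse_dot_bracket(structure: str) -> list[tuple[int, int]]:
    """Stack-match a dot-bracket string into 0-based (i, j) pairs, i < j.

    Raises ``ValueError`` naming the index of the first unmatched bracket
    or invalid character.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unmatched ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unmatched '(' at position {stack[-1]}")
    pairs.sort()
    return pairs


def hairpin_loops(structure: str) -> list[tuple[tuple[int, int], int]]:
    """Terminal hairpin loops of a dot-bracket structure, 5'->3'.

    A hairpin loop is the run of unpaired positions ``i+1..j-1`` enclosed by
    a pair ``(i, j)`` that encloses no other pair.  Bulges and internal
    loops are deliberately excluded: only terminal loops count.  Returns
    ``[((start, end), length), ...]`` with 0-based half-open spans in
    sequence order.
    """
    pairs = parse_dot_bracket(structure)
    loops: list[tuple[tuple[int, int], int]] = []
    for (i, j) in pairs:
        # innermost pair: nothing between i and j is paired
        if all(not (i < k < j or i < l < j) for (k, l) in pairs if (k, l) != (i, j)):
            loops.append(((i + 1, j), j - i - 1))
    loops.sort(key=lambda item: item[0][0])
    return loops


def loop_length_sum(variant_or_structure: "OriginVariant | str") -> int:
    """Sum of terminal hairpin-loop lengths; 0 if the structure has none."""
    structure = (
        variant_or_structure.structure
        if isinstance(variant_or_structure, OriginVariant)
        else variant_or_structure
    )
    return sum(length for _, length in hairpin_loops(structure))


# ---------------------------------------------------------------------------
# domain types

@dataclass
class OriginVariant:
    """One origin's identity: sequence, structure, loop metrics, copy number.

    ``loop_lengths`` is derived from the structure when not supplied; when
    supplied it is validated against the hairpin-loop rule.
    """

    id: str
    sequence: str
    structure: str
    loop_lengths: list[int] = field(default_factory=list)
    copy_number: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )
        if not set(self.sequence) <= set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise ValueError(f"{self.id}: non-nucleotide characters {bad}")
        derived = [length for _, length in hairpin_loops(self.structure)]
        if self.loop_lengths:
            if list(self.loop_lengths) != derived:
                raise ValueError(
                    f"{self.id}: loop_lengths {self.loop_lengths} inconsistent "
                    f"with structure-derived {derived}"
                )
        else:
            self.loop_lengths = derived
        if self.copy_number is not None and not self.copy_number > 0:
            raise ValueError(f"{self.id}: copy_number must be positive")

    @property
    def loop_sum(self) -> int:
        return sum(self.loop_lengths)


@dataclass(frozen=True)
class LoopFit:
    """OLS of copy number on summed loop length."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def fit_copy_number_vs_loop(variants: Sequence[OriginVariant]) -> LoopFit:
    """Regress plasmid copy number on the summed RNAI loop length.

    Ordinary least squares over all variants carrying a ``copy_number``.
    Requires at least 3 points with non-zero variance in loop sum.
    """
    pts = [(v.loop_sum, v.copy_number) for v in variants if v.copy_number is not None]
    if len(pts) < 3:
        raise ValueError(f"need >=3 variants with copy_number, got {len(pts)}")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in summed loop length")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LoopFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=len(pts),
    )


# ---------------------------------------------------------------------------
# NGS variant counting

def _coerce_read(read) -> tuple[str, list[int]]:
    if isinstance(read, SeqRecord):
        return str(read.seq), list(read.letter_annotations["phred_quality"])
    seq, qual = read[-2], read[-1]  # (id, seq, qual) or (seq, qual)
    return str(seq), list(qual)


def _quality_trim(seq: str, qual: list[int], window: int, min_mean: float) -> str | None:
    """Sliding-window 3' trim; None when the trimmed read is shorter than
    the window (discarded)."""
    while len(seq) >= window and (sum(qual[-window:]) / window) <= min_mean:
        seq = seq[:-1]
        qual = qual[:-1]
    if len(seq) < window:
        return None
    return seq


def extract_variant_region(seq: str, motifs: Sequence[str]) -> str | None:
    """Region between the first and last flank motif, or None if the read
    does not contain every motif in order.  The inner motifs stay inside
    the extracted region (they are constant across variants)."""
    pos = 0
    hits: list[int] = []
    for m in motifs:
        idx = seq.find(m, pos)
        if idx < 0:
            return None
        hits.append(idx)
        pos = idx + len(m)
    return seq[hits[0] + len(motifs[0]): hits[-1]]


def count_variants(
    reads: Iterable,
    flank_motifs: Sequence[str] = DEFAULT_FLANK_MOTIFS,
    quality_window: int = 10,
    min_mean_quality: float = 20.0,
) -> pd.DataFrame:
    """NGS census of a variant library.

    Pipeline, in fixed order: (1) sliding-window quality trim from the 3'
    end (a read is trimmed while the mean Phred score of its last
    ``quality_window`` bases is <= ``min_mean_quality``; reads ending up
    shorter than the window are discarded); (2) discard reads not containing
    all ``flank_motifs`` in order; (3) extract the inter-motif variant
    region; (4) deduplicate and count.

    Returns a VariantTable ``DataFrame`` with columns ``sequence``,
    ``count``, ``frequency``, sorted by descending count (ties broken by
    lexicographic sequence order).  Empty input yields an empty table.
    """
    if not flank_motifs:
        raise ValueError("flank_motifs must not be empty")
    counts: Counter[str] = Counter()
    for read in reads:
        seq, qual = _coerce_read(read)
        trimmed = _quality_trim(seq, qual, quality_window, min_mean_quality)
        if trimmed is None:
            continue
        region = extract_variant_region(trimmed, flank_motifs)
        if region is None:
            continue
        counts[region] += 1
    if not counts:
        return pd.DataFrame(columns=["sequence", "count", "frequency"])
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(rows, columns=["sequence", "count"])
    table["frequency"] = table["count"] / table["count"].sum()
    return table


def top_k_fraction(table: pd.DataFrame, k: int) -> float:
    """Summed frequency of the k most frequent variants.

    Ties are broken by lexicographic sequence order.  ``k`` past the table
    length returns 1.0 (all mass).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if table.empty:
        return 0.0
    ordered = table.sort_values(
        ["count", "sequence"], ascending=[False, True], kind="mergesort"
    )
    return float(ordered["frequency"].head(k).sum())


# ---------------------------------------------------------------------------
# I/O helpers

def read_fastq(path) -> list[SeqRecord]:
    """Read a FASTQ file (Phred+33) into SeqRecords."""
    return list(SeqIO.parse(str(path), "fastq"))


def write_variant_table(table: pd.DataFrame, path) -> None:
    """Write a VariantTable as TSV (sequence, count, frequency)."""
    table.to_csv(path, sep="\t", index=False)
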