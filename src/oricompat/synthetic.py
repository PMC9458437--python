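"""Seeded generators for every input the pipeline consumes.

All wet-lab inputs have a synthetic counterpart here with the statistical
structure the analysis assumes: origin variants on a three-hairpin RNAI
scaffold whose copy number falls linearly with summed loop length (plus
noise), FASTQ-like reads carrying library variants between the constant
flank motifs, Poisson-occupied dPCR chips, and co-transformed starting
populations for the segregation simulator.

Every generator is a pure function of its arguments and a seed.  Each
draws from its own named substream of the master seed, so adding a new
generator (or reordering calls) never perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .origins import DEFAULT_FLANK_MOTIFS, OriginVariant
from .quantify import DPCRChip
from .segregation import Population, initial_population

__all__ = [
    "substream",
    "gen_origin_set",
    "gen_reads",
    "variant_region",
    "gen_dpcr_chip",
    "gen_two_plasmid_population",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream of a master seed (stable across versions)."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# origin variants

def gen_origin_set(
    n_origins: int = 24,
    seed: int = 0,
    loop_length_range: tuple[int, int] = (4, 9),
    stem_length: int = 8,
    intercept: float = 260.0,
    slope: float = -8.0,
    noise_sd: float = 5.0,
) -> list[OriginVariant]:
    """Random origin variants on a fixed three-hairpin RNAI-like scaffold.

    Loop lengths are uniform over ``loop_length_range`` (inclusive); stems
    are random but perfectly paired, so the dot-bracket structure is
    consistent with the sequence.  Copy number follows the inverse law

        K = intercept + slope * (sum of loop lengths) + N(0, noise_sd),

    truncated below at 1 (slope must be <= 0: longer RNAI loops mean more
    effective antisense inhibition, hence fewer plasmids).  Defaults span
    roughly 40-200 copies per genome — a synthetic calibration in the
    qualitative high-copy (pUC-like, Rom/Rop-free) range, not measured
    values.
    """
    if slope > 0:
        raise ValueError("the copy-number law requires slope <= 0")
    lo, hi = loop_length_range
    if not (0 < lo <= hi):
        raise ValueError("invalid loop_length_range")
    rng = substream(seed, "origin_set")
    variants: list[OriginVariant] = []
    for k in range(n_origins):
        loops = rng.integers(lo, hi + 1, size=3)
        seq_parts = ["A"]  # 5' unpaired leader
        struct_parts = ["."]
        for loop_len in loops:
            stem = "".join(rng.choice(_BASES, size=stem_length))
            loop = "".join(rng.choice(_BASES, size=int(loop_len)))
            seq_parts += [stem, loop, _revcomp(stem), "AA"]
            struct_parts += ["(" * stem_length, "." * int(loop_len),
                            ")" * stem_length, ".."]
        loop_sum = int(loops.sum())
        K = intercept + slope * loop_sum
        if noise_sd > 0:
            K += rng.normal(0.0, noise_sd)
        variants.append(OriginVariant(
            id=f"V{k + 1:03d}",
            sequence="".join(seq_parts),
            structure="".join(struct_parts),
            copy_number=max(float(K), 1.0),
        ))
    return variants


# ---------------------------------------------------------------------------
# NGS reads

def variant_region(
    segments: Sequence[str],
    motifs: Sequence[str] = DEFAULT_FLANK_MOTIFS,
) -> str:
    """Assemble the inter-flank variant region from three loop segments:
    seg1 + inner_motif_2 + seg2 + inner_motif_3 + seg3."""
    if len(segments) != 3 or len(motifs) != 4:
        raise ValueError("expected 3 segments and 4 flank motifs")
    return segments[0] + motifs[1] + segments[1] + motifs[2] + segments[2]


def _allocate_counts(weights: np.ndarray, n_reads: int) -> np.ndarray:
    """Largest-remainder allocation: counts proportional to weights, exact
    total, deterministic — so a 60/30/10 mixture is recovered exactly."""
    ideal = weights / weights.sum() * n_reads
    base = np.floor(ideal).astype(int)
    rem = n_reads - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    base[order[:rem]] += 1
    return base


def gen_reads(
    mixture: Sequence[tuple[str, float]],
    n_reads: int = 1000,
    error_rate: float = 0.0,
    seed: int = 0,
    motifs: Sequence[str] = DEFAULT_FLANK_MOTIFS,
    base_quality: int = 38,
    low_quality_tail: int = 0,
    tail_quality: int = 2,
) -> list[SeqRecord]:
    """FASTQ-like reads carrying library variants between the flank motifs.

    ``mixture`` maps variant-region strings (the sequence between the
    outer flanks, inner motifs included — see `variant_region`) to weights.
    Reads are ``motifs[0] + region + motifs[3]``, with per-base substitution
    errors at ``error_rate`` and flat Phred ``base_quality``; an optional
    low-quality 3' tail exercises the quality trimmer.  Read counts per
    variant are allocated deterministically in proportion to the weights;
    read order is shuffled under the seed.
    """
    if not mixture:
        raise ValueError("mixture must not be empty")
    rng = substream(seed, "reads")
    regions = [m[0] for m in mixture]
    weights = np.asarray([m[1] for m in mixture], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    counts = _allocate_counts(weights, n_reads)

    records: list[SeqRecord] = []
    idx = 0
    for region, count in zip(regions, counts):
        seq = motifs[0] + region + motifs[3]
        for _ in range(count):
            bases = np.array(list(seq))
            if error_rate > 0:
                hit = rng.random(bases.size) < error_rate
                if hit.any():
                    subs = rng.choice(_BASES, size=int(hit.sum()))
                    # substitution must change the base
                    same = subs == bases[hit]
                    while same.any():
                        subs[same] = rng.choice(_BASES, size=int(same.sum()))
                        same = subs == bases[hit]
                    bases[hit] = subs
            read_seq = "".join(bases)
            if low_quality_tail > 0:
                read_seq = read_seq + "".join(
                    rng.choice(_BASES, size=low_quality_tail)
                )
            qual = [base_quality] * len(seq) + [tail_quality] * low_quality_tail
            rec = SeqRecord(
                Seq(read_seq), id=f"read{idx:06d}", description=""
            )
            rec.letter_annotations["phred_quality"] = qual
            records.append(rec)
            idx += 1
    perm = rng.permutation(len(records))
    return [records[i] for i in perm]


# ---------------------------------------------------------------------------
# dPCR chips

def gen_dpcr_chip(
    true_ratio: float,
    lambda_genome: float = 0.5,
    n_partitions: int = 20_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> DPCRChip:
    """Synthetic two-channel chip at a known plasmid/genome ratio.

    Each channel's positives are Binomial(n_partitions, 1 - e^-lambda)
    with lambda_plasmid = true_ratio * lambda_genome.
    """
    if rng is None:
        rng = substream(0 if seed is None else seed, "dpcr")
    if true_ratio < 0 or lambda_genome < 0:
        raise ValueError("ratio and lambda must be non-negative")
    lam_p = true_ratio * lambda_genome
    pos_p = int(rng.binomial(n_partitions, 1.0 - np.exp(-lam_p)))
    pos_g = int(rng.binomial(n_partitions, 1.0 - np.exp(-lambda_genome)))
    return DPCRChip(
        n_partitions=n_partitions,
        positives_plasmid=pos_p,
        positives_genome=pos_g,
    )


# ---------------------------------------------------------------------------
# populations

def gen_two_plasmid_population(
    n_cells: int,
    K: Sequence[float],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Population:
    """Co-transformed starting culture: every cell carries every origin at
    Poisson-around-K copies (minimum 1)."""
    if rng is None:
        rng = substream(0 if seed is None else seed, "population")
    return initial_population(n_cells, K, rng)
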