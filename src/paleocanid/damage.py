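"""Authenticity summaries of aligned ancient-DNA read sets.

Ancient DNA is recognised by short fragment lengths and elevated
cytosine-deamination damage at fragment ends, read as C->T substitutions
at the 5' terminus and G->A at the 3' terminus (on double-stranded
libraries), both decaying toward the fragment interior.  This module
computes those summaries -- fragment-length statistics, per-position
terminal misincorporation profiles and reference coverage -- from an
already-aligned read set.  Mapping and consensus calling are out of
scope; substitutions are counted directly against the provided reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadSet:
    """Aligned ancient fragments against a reference sequence.

    ``starts`` are 0-based positions on the reference; ``strands`` holds
    ``'+'`` or ``'-'``; ``seqs`` stores each read as sequenced (i.e.
    reverse-strand reads are the reverse complement of the reference
    segment they cover).  ``min_len`` records the retention filter that
    was applied upstream.
    """

    reference: str
    ids: list[str]
    starts: np.ndarray
    strands: np.ndarray
    seqs: list[str]
    min_len: int = 30

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)
        self.strands = np.asarray(self.strands)
        n = len(self.seqs)
        if not (len(self.ids) == len(self.starts) == len(self.strands) == n):
            raise ValueError("read fields have inconsistent lengths")
        lens = self.lengths
        rl = len(self.reference)
        if n and (self.starts.min() < 0 or (self.starts + lens).max() > rl):
            raise ValueError("reads map outside the reference bounds")
        if n and lens.min() < self.min_len:
            raise ValueError(f"read shorter than the min_len filter ({self.min_len})")

    @property
    def n_reads(self) -> int:
        return len(self.seqs)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.seqs], dtype=int)

    def expected_read(self, i: int) -> str:
        """Reference-derived sequence in read orientation (no damage)."""
        seg = self.reference[self.starts[i] : self.starts[i] + len(self.seqs[i])]
        return revcomp(seg) if self.strands[i] == "-" else seg


@dataclass
class DamageProfile:
    """Terminal misincorporation rates per position from each end."""

    ct5: np.ndarray  # C->T rate at positions 1..K from the 5' end
    ga3: np.ndarray  # G->A rate at positions 1..K from the 3' end
    ct5_denominator: np.ndarray
    ga3_denominator: np.ndarray

    @property
    def k(self) -> int:
        return len(self.ct5)

    def window_means(self, w: int = 5) -> dict:
        """Average terminal rates over the first ``w`` positions."""
        def wmean(rate, denom):
            r, d = rate[:w], denom[:w]
            ok = d > 0
            return float((r[ok] * d[ok]).sum() / d[ok].sum()) if ok.any() else np.nan

        return {
            "ct5_window": wmean(self.ct5, self.ct5_denominator),
            "ga3_window": wmean(self.ga3, self.ga3_denominator),
        }


def fragment_length_stats(reads: ReadSet) -> dict:
    """Count, mean, median and sample SD of read lengths.

    With a single read the SD is reported as NaN (undefined by the n-1
    convention).
    """
    if reads.n_reads == 0:
        raise ValueError("empty read set")
    lens = reads.lengths.astype(float)
    sd = float(np.std(lens, ddof=1)) if len(lens) > 1 else float("nan")
    return {
        "n": int(len(lens)),
        "mean": float(lens.mean()),
        "median": float(np.median(lens)),
        "sd": sd,
    }


def damage_profile(reads: ReadSet, k: int = 25) -> DamageProfile:
    """Strand-aware terminal substitution profile.

    At 5' position i (1-based from the read's 5' end) the C->T rate is the
    number of reads whose reference base (in read orientation) is C and
    whose read base is T, divided by the number of reads with reference C
    at that position; G->A is mirrored from the 3' end.  Positions with no
    opportunities get a NaN rate.
    """
    if reads.n_reads == 0:
        raise ValueError("empty read set")
    ct_num = np.zeros(k, dtype=np.int64)
    ct_den = np.zeros(k, dtype=np.int64)
    ga_num = np.zeros(k, dtype=np.int64)
    ga_den = np.zeros(k, dtype=np.int64)
    for i in range(reads.n_reads):
        obs = reads.seqs[i].upper()
        exp = reads.expected_read(i).upper()
        length = len(obs)
        kk = min(k, length)
        for j in range(kk):
            if exp[j] == "C":
                ct_den[j] += 1
                if obs[j] == "T":
                    ct_num[j] += 1
            e3 = exp[length - 1 - j]
            if e3 == "G":
                ga_den[j] += 1
                if obs[length - 1 - j] == "A":
                    ga_num[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = np.where(ct_den > 0, ct_num / np.maximum(ct_den, 1), np.nan)
        ga = np.where(ga_den > 0, ga_num / np.maximum(ga_den, 1), np.nan)
    return DamageProfile(ct5=ct, ga3=ga, ct5_denominator=ct_den, ga3_denominator=ga_den)


def depth_vector(reads: ReadSet) -> np.ndarray:
    """Per-position read depth over the reference."""
    depth = np.zeros(len(reads.reference), dtype=np.int64)
    lens = reads.lengths
    np.add.at(depth, reads.starts, 1)
    ends = reads.starts + lens
    inside = ends < len(depth)
    np.add.at(depth, ends[inside], -1)
    return np.cumsum(depth)


def coverage_summary(depth: np.ndarray) -> dict:
    """Fraction of reference covered at >= 1x and mean depth.

    The mean is taken over *all* reference positions, including those with
    zero depth.
    """
    d = np.asarray(depth)
    if d.size == 0:
        raise ValueError("empty depth vector")
    return {
        "fraction_covered": float((d >= 1).mean()),
        "mean_depth": float(d.mean()),
    }
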