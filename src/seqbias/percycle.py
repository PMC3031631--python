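"""Per-cycle nucleotide composition of mapped reads.

Sequencing reactions over-sample certain bases at the first read cycles
(strongest at cycle 0).  This module applies the read filters used when
quantifying that bias (unique mapping, no first-cycle mismatch, optional
tag deduplication and mismatch cap) and computes the cycle x base
frequency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import numpy as np

from ._util import BASES, encode
from .core_io import MappedRead


@dataclass
class FilterReport:
    n_input: int = 0
    removed_not_unique: int = 0
    removed_max_mismatches: int = 0
    removed_first_mismatch: int = 0
    removed_duplicate_tag: int = 0
    n_output: int = 0


def filter_reads(
    reads: Iterable[MappedRead],
    require_unique: bool = True,
    drop_first_mismatch: bool = True,
    dedup_tags: bool = False,
    max_mismatches: Optional[int] = None,
) -> Tuple[List[MappedRead], FilterReport]:
    """Apply the standard read filters; returns (kept reads, attrition report).

    ``dedup_tags`` keeps the first read seen per distinct sequence string
    (collapsing PCR-amplified tags).
    """
    report = FilterReport()
    seen: set = set()
    kept: List[MappedRead] = []
    for read in reads:
        report.n_input += 1
        if require_unique and not read.unique:
            report.removed_not_unique += 1
            continue
        if max_mismatches is not None and read.n_mismatches > max_mismatches:
            report.removed_max_mismatches += 1
            continue
        if drop_first_mismatch and 0 in read.mismatch_positions:
            report.removed_first_mismatch += 1
            continue
        if dedup_tags:
            if read.sequence in seen:
                report.removed_duplicate_tag += 1
                continue
            seen.add(read.sequence)
        kept.append(read)
    report.n_output = len(kept)
    return kept, report


@dataclass
class PositionalComposition:
    """Cycle x base frequency matrix over {A,C,G,T}.

    N bases are excluded from both numerator and denominator per cycle, so
    each defined row sums to 1.  ``undefined_cycles`` flags rows where no
    non-N base was observed.
    """

    read_length: int
    freq: np.ndarray  # (read_length, 4)
    counts: np.ndarray  # (read_length, 4) integer counts
    n_reads: int
    n_rejected_short: int = 0
    undefined_cycles: List[int] = field(default_factory=list)

    def base_freq(self, cycle: int, base: str) -> float:
        return float(self.freq[cycle, BASES.index(base)])


def positional_composition(
    reads: Iterable[MappedRead], read_length: int
) -> PositionalComposition:
    """Base frequencies at each sequencing cycle.

    Reads longer than ``read_length`` are truncated; shorter reads are
    rejected (and counted) rather than padded.
    """
    counts = np.zeros((read_length, 5), dtype=np.int64)
    n_reads = 0
    n_short = 0
    for read in reads:
        if read.length < read_length:
            n_short += 1
            continue
        codes = encode(read.sequence[:read_length])
        counts[np.arange(read_length), codes] += 1
        n_reads += 1
    acgt = counts[:, :4]
    denom = acgt.sum(axis=1, keepdims=True)
    undefined = [int(c) for c in np.flatnonzero(denom[:, 0] == 0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, acgt / np.maximum(denom, 1), np.nan)
    return PositionalComposition(
        read_length, freq, acgt.copy(), n_reads, n_short, undefined
    )


def composition_table(comp: PositionalComposition):
    """Composition as a pandas DataFrame (cycle, A, C, G, T)."""
    import pandas as pd

    df = pd.DataFrame(comp.freq, columns=list(BASES))
    df.insert(0, "cycle", np.arange(comp.read_length))
    return df


def plot_composition(comp: PositionalComposition, path: str) -> None:
    """Frequency-scaled positional chart (letter height ~ frequency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    x = np.arange(comp.read_length)
    bottom = np.zeros(comp.read_length)
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    for i, base in enumerate(BASES):
        vals = np.nan_to_num(comp.freq[:, i])
        ax.bar(x, vals, bottom=bottom, label=base, color=colors[base], width=0.9)
        bottom += vals
    ax.set_xlabel("sequencing cycle")
    ax.set_ylabel("base frequency")
    ax.set_ylim(0, 1)
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
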