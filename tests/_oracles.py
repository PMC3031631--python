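"""Independent oracles used by the tests.

These deliberately avoid the implementation's code paths: the mappability
oracle is a literal all-pairs window-vs-window comparison (integer-encoded
for speed but still O(n^2) pairwise), and the pileup oracle is plain
counting.
"""

from collections import Counter

import numpy as np

from seqbias._util import encode, revcomp


def allpairs_mappability(genome, L):
    """All-pairs window comparison over both strands.

    Returns {(contig, strand, anchor): bool}; anchors with no full window
    or with N in the window are absent (hence unmappable).
    """
    wins = []
    anchors = []
    for name, seq in genome.contigs.items():
        n = len(seq)
        for i in range(n - L + 1):
            w = seq[i : i + L]
            if "N" not in w:
                wins.append(w)
                anchors.append((name, "+", i))
        rc = revcomp(seq)
        for i in range(n - L + 1):
            w = rc[i : i + L]
            if "N" not in w:
                wins.append(w)
                anchors.append((name, "-", n - 1 - i))
    if not wins:
        return {}
    arr = np.array([encode(w) for w in wins], dtype=np.uint8)
    codes = np.zeros(len(arr), dtype=np.uint64)
    for j in range(L):
        codes = codes * np.uint64(4) + arr[:, j].astype(np.uint64)
    out = {}
    M = len(codes)
    for lo in range(0, M, 4096):
        eq = (codes[lo : lo + 4096, None] == codes[None, :]).sum(axis=1)
        for k, cnt in enumerate(eq):
            out[anchors[lo + k]] = bool(cnt == 1)  # count includes self
    return out


def pileup_counts(reads):
    """Plain read-start counting: {(contig, strand, pos): n}."""
    c = Counter()
    for r in reads:
        c[(r.contig, r.strand, r.five_prime_pos)] += 1
    return c
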