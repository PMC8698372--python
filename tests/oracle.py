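"""Independent brute-force reference implementation used only by tests.

Everything here is written from first principles with explicit Python
loops — no numpy ranking, no scipy — so it can serve as an oracle for
the vectorised implementation: mid-rank assignment by sorting, the rank
correlation computed term by term, per-pair gap handling and the global
matrix as a per-column summation.
"""

import math

from sdpscan.alignment import GAP
from sdpscan.scales import AMINO_ACIDS, SubstitutionMatrix

#: Same documented rounding contract as the implementation: channel
#: similarities are rounded to 9 decimals before ranking.
DECIMALS = 9


def midranks(values):
    """Ranks 1..n with tied values all given the average of their span."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def rho(x, y):
    """Spearman correlation via explicit mid-ranks and the product-moment
    formula, term by term; None when either rank vector is constant."""
    rx, ry = midranks(x), midranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx)
    dy = sum((b - my) ** 2 for b in ry)
    if dx == 0 or dy == 0:
        return None
    return num / math.sqrt(dx * dy)


def channel_similarity(channel, m, n):
    """Pair similarity of two residues under a channel, from raw values."""
    if isinstance(channel, SubstitutionMatrix):
        return round(channel.value(m, n), DECIMALS)
    maxdiff = max(
        abs(channel.values[a] - channel.values[b])
        for a in AMINO_ACIDS for b in AMINO_ACIDS
    )
    return round(maxdiff - abs(channel.values[n] - channel.values[m]), DECIMALS)


def pairs(n):
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def global_pair_vector(alignment, subst):
    """Mean per-column substitution similarity for every protein pair;
    a column with a gap in either protein contributes 0, denominator is
    the alignment length."""
    vec = []
    for i, j in pairs(alignment.n_sequences):
        total = 0.0
        for a, b in zip(alignment.rows[i], alignment.rows[j]):
            if a != GAP and b != GAP:
                total += subst.value(a, b)
        vec.append(total / alignment.length)
    return vec


def position_pair_vector(alignment, k, channel):
    col = [row[k - 1] for row in alignment.rows]
    vec = []
    for i, j in pairs(len(col)):
        if col[i] == GAP or col[j] == GAP:
            vec.append(0.0)
        else:
            vec.append(channel_similarity(channel, col[i], col[j]))
    return vec


def score_alignment(alignment, channels, subst, gap_threshold=0.10, target=None):
    """All (column, channel-label) scores, or None where undefined.

    Columns with more than ``gap_threshold`` gaps are dropped entirely.
    ``target`` defaults to the brute-force global pair vector.
    """
    if target is None:
        target = global_pair_vector(alignment, subst)
    n = alignment.n_sequences
    out = {}
    for k in range(1, alignment.length + 1):
        col = [row[k - 1] for row in alignment.rows]
        if col.count(GAP) / n > gap_threshold:
            continue
        for channel in channels:
            label = "" if isinstance(channel, SubstitutionMatrix) else channel.name
            out[(k, label)] = rho(position_pair_vector(alignment, k, channel), target)
    return out
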