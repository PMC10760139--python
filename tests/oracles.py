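"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's vectorized code paths: they work
step by step on Python strings, lists and dicts, so that agreement with
the library is a meaningful cross-check.
"""

from __future__ import annotations

from haplosample.kmer_index import canonical_kmer, encode_kmer, minimizer_key

HOM = "homozygous"
HET = "heterozygous"
ABS = "absent"
FRQ = "frequent"


def bruteforce_minimizers(seq: str, k: int, w: int) -> list[tuple[int, str]]:
    """Quadratic sliding-window minimizer scan (same key function)."""
    n = len(seq) - k + 1
    if n <= 0:
        return []
    keyed = []
    for p in range(n):
        can = canonical_kmer(seq[p : p + k])
        key = None if can is None else minimizer_key(encode_kmer(can))
        keyed.append((key, can))
    selected = {}
    ww = min(w, n)
    for start in range(n - ww + 1):
        best_pos = None
        for p in range(start, start + ww):
            if keyed[p][0] is None:
                continue
            if best_pos is None or keyed[p][0] < keyed[best_pos][0]:
                best_pos = p
        if best_pos is not None:
            selected[best_pos] = keyed[best_pos][1]
    return sorted(selected.items())


def substring_occurrences(haystacks: list[str], kmer: str) -> int:
    """Occurrences of a canonical k-mer over sequences, both strands.

    Counts distinct (sequence, offset) placements of the k-mer or its
    reverse complement.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(kmer))
    total = 0
    for seq in haystacks:
        for p in range(len(seq) - len(kmer) + 1):
            window = seq[p : p + len(kmer)]
            if window == kmer or window == rc:
                total += 1
    return total


def count_kmers_naive(reads: list[str], k: int, min_count: int = 2) -> dict[str, int]:
    """Dictionary-of-substrings canonical k-mer counter."""
    counts: dict[str, int] = {}
    for read in reads:
        for p in range(len(read) - k + 1):
            can = canonical_kmer(read[p : p + k])
            if can is not None:
                counts[can] = counts.get(can, 0) + 1
    return {km: c for km, c in counts.items() if c >= min_count}


def greedy_oracle(
    presence: list[list[bool]],
    classes: list[str],
    n: int,
    hom_present: float = 1.0,
    hom_absent: float = -1.0,
    abs_present: float = -0.8,
    abs_absent: float = 0.8,
    hom_discount: float = 0.9,
    het_adjust: float = 0.05,
) -> list[int]:
    """Step-by-step simulator of the greedy scoring/update rules.

    Homozygous k-mers start at (+1, -1) (present, absent), absent-class
    at (-0.8, +0.8), heterozygous at (0, 0); frequent k-mers carry no
    entry.  Each round picks the highest-total row (lowest index on
    ties), multiplies both entries of homozygous k-mers present in the
    pick by 0.9, and moves heterozygous entries 0.05 toward the state
    opposite the pick.  Rows are not reselected; if n exceeds the row
    count the greedy order repeats cyclically.  Totals are compared at
    1e-9 resolution, matching the library's tie policy.
    """
    rows = len(presence)
    cols = [c for c in range(len(classes)) if classes[c] != FRQ]
    score = {}
    for c in cols:
        if classes[c] == HOM:
            score[c] = [hom_present, hom_absent]
        elif classes[c] == ABS:
            score[c] = [abs_present, abs_absent]
        else:
            score[c] = [0.0, 0.0]
    picked: list[int] = []
    available = list(range(rows))
    for _ in range(min(n, rows)):
        best, best_total = None, None
        for r in available:
            total = 0.0
            for c in cols:
                total += score[c][0] if presence[r][c] else score[c][1]
            total = round(total, 9)
            if best is None or total > best_total:
                best, best_total = r, total
        picked.append(best)
        available.remove(best)
        for c in cols:
            if classes[c] == HOM and presence[best][c]:
                score[c][0] *= hom_discount
                score[c][1] *= hom_discount
            elif classes[c] == HET:
                if presence[best][c]:
                    score[c][0] -= het_adjust
                    score[c][1] += het_adjust
                else:
                    score[c][0] += het_adjust
                    score[c][1] -= het_adjust
    base = list(picked)
    while len(picked) < n:
        picked.append(base[len(picked) % rows])
    return picked


def diploid_oracle(
    candidates: list[int], presence: list[list[bool]], classes: list[str]
) -> tuple[tuple[int, int], float]:
    """Exhaustive enumeration of unordered candidate pairs.

    Expected copies x: absent 0, heterozygous 1, homozygous 2; realised
    copies y: pair members containing the k-mer; pair score is
    sum(1 - |x - y|) over non-frequent k-mers.  First maximal pair in
    lexicographic row order wins.
    """
    expected = {ABS: 0, HET: 1, HOM: 2}
    cols = [c for c in range(len(classes)) if classes[c] != FRQ]
    rows = sorted(set(candidates))
    best, best_score = None, None
    for ai, a in enumerate(rows):
        for b in rows[ai:]:
            s = 0.0
            for c in cols:
                y = int(presence[a][c]) + int(presence[b][c])
                s += 1 - abs(expected[classes[c]] - y)
            if best is None or s > best_score:
                best, best_score = (a, b), s
    return best, best_score
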