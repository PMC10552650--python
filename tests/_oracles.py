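"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive pure-Python routines (dynamic-programming edit
distance, exhaustive graph search, O(n*m) interval scans) that share no code
with the package modules they verify.
"""

from __future__ import annotations

import math


def edit_distance(a: str, b: str) -> int:
    """Plain O(len(a)*len(b)) Levenshtein DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def adapter_scan(sequence: str, adapter: str, max_error_rate: float, min_match: int = 3):
    """Exhaustive suffix-anchored scan: fewest edits win, leftmost on ties."""
    n = len(sequence)
    best = None
    for i in range(0, n - min_match + 1):
        m = min(len(adapter), n - i)
        allowed = math.floor(max_error_rate * m)
        d = edit_distance(adapter[:m], sequence[i : i + m])
        if d <= allowed and (best is None or (d, i) < best):
            best = (d, i)
    return None if best is None else best[1]


def directional_dedup(members: dict[str, int]) -> set[str]:
    """Exhaustive directional UMI clustering via repeated transitive closure.

    Edges a->b exist when Hamming(a, b) == 1 and count(a) >= 2*count(b) - 1.
    Repeatedly take the highest-count unclaimed UMI (lexicographic on ties),
    claim everything reachable from it through unclaimed nodes (computed by
    full closure, not incremental search), and keep it as a representative.
    """
    umis = list(members)
    edge = {
        (a, b)
        for a in umis
        for b in umis
        if a != b
        and sum(x != y for x, y in zip(a, b)) == 1
        and members[a] >= 2 * members[b] - 1
    }
    unclaimed = set(umis)
    reps = set()
    while unclaimed:
        root = max(unclaimed, key=lambda u: (members[u], [-ord(c) for c in u]))
        reps.add(root)
        reachable = {root}
        changed = True
        while changed:
            changed = False
            for a, b in edge:
                if a in reachable and b in unclaimed and b not in reachable:
                    reachable.add(b)
                    changed = True
        unclaimed -= reachable
    return reps


def assign_read_naive(chrom, blocks, strand, genes):
    """O(genes) read assignment: (gene_id or None, category).

    Mirrors the assignment contract: same-strand genes preferred, gene with
    the largest exonic overlap wins (span overlap, then smaller id, on
    ties); exonic iff exonic overlap is a strict majority of aligned bases.
    """

    def ov(iv_list):
        t = 0
        for bs, be in blocks:
            for s, e in iv_list:
                t += max(0, min(be, e) - max(bs, s))
        return t

    alen = sum(e - s for s, e in blocks)
    scored = []
    for g in genes.values():
        if g.chrom != chrom:
            continue
        span_ov = ov([g.span])
        if span_ov == 0:
            continue
        scored.append((g.strand == strand, ov(g.exons), span_ov, g))
    if not scored:
        return None, "intergenic"
    same = [s for s in scored if s[0]]
    pool = same if same else scored
    best = sorted(pool, key=lambda s: (-s[1], -s[2], s[3].gene_id))[0]
    category = "exonic" if best[1] * 2 > alen else "intronic"
    return best[3].gene_id, category


def window_bin_naive(alignments, genome_lengths, window_size):
    """Brute-force window binning by leftmost aligned base."""
    counts = {}
    for chrom, L in genome_lengths.items():
        n = (L + window_size - 1) // window_size
        for w in range(n):
            counts[(chrom, w * window_size)] = 0
    for rec in alignments:
        key = (rec.reference, (rec.start // window_size) * window_size)
        if key in counts:
            counts[key] += rec.count
    return counts


def exonic_fraction_naive(molecules, genes) -> float:
    """Ground-truth exonic fraction among gene-overlapping molecules."""
    ex = intr = 0
    for mol in molecules:
        gid, cat = assign_read_naive(mol.chrom, mol.blocks, mol.strand, genes)
        if gid is None:
            continue
        if cat == "exonic":
            ex += 1
        else:
            intr += 1
    return ex / (ex + intr)
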