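"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations


def naive_identity(a: str, b: str) -> float:
    """Reference identity: full DP over (matches, paired columns) tuples.

    Maximises the number of matching columns under global alignment with
    match +1, mismatch 0, gap 0; among alignments with maximal matches the
    one with the most paired columns (fewest gaps) is taken, giving
    identity = matches / (len(a) + len(b) - paired).
    """
    la, lb = len(a), len(b)
    dp = [[(0, 0)] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        ai = a[i - 1]
        row = dp[i]
        prev = dp[i - 1]
        for j in range(1, lb + 1):
            m, p = prev[j - 1]
            best = (m + (ai == b[j - 1]), p + 1)
            if prev[j] > best:
                best = prev[j]
            if row[j - 1] > best:
                best = row[j - 1]
            row[j] = best
    m, p = dp[la][lb]
    return m / (la + lb - p)


def naive_greedy_cluster(uniques, threshold: float):
    """All-pairs greedy centroid clustering, same visit order as the package.

    Returns a list of clusters, each a list of (sequence, counts) members,
    in founding order.
    """
    ordered = sorted(uniques, key=lambda e: (-sum(e[1].values()), e[0]))
    centroids: list[str] = []
    clusters: list[list] = []
    for seq, counts in ordered:
        for ci, cent in enumerate(centroids):
            if naive_identity(seq, cent) >= threshold:
                clusters[ci].append((seq, counts))
                break
        else:
            centroids.append(seq)
            clusters.append([(seq, counts)])
    return clusters
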