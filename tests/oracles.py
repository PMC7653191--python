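"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: per-base scoring by
explicit character loops, window maxima by enumerating every window, the
G4 motif grammar by a recursive left-to-right scanner, and average
precision by walking the sorted confusion counts.
"""

from functools import lru_cache


def brute_base_scores(seq: str) -> list[int]:
    """G4Hunter per-base scores by explicit run scanning."""
    n = len(seq)
    scores = [0] * n
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = j - i
        if seq[i] == "G":
            val = min(run, 4)
        elif seq[i] == "C":
            val = -min(run, 4)
        else:
            val = 0
        for t in range(i, j):
            scores[t] = val
        i = j
    return scores


def brute_g4hunter(seq: str, window: int = 25, threshold: float = 0.0) -> float:
    """Max window mean over every window, enumerated one by one."""
    scores = brute_base_scores(seq)
    w = min(window, len(scores))
    best = None
    for start in range(len(scores) - w + 1):
        mean = sum(scores[start : start + w]) / w
        if best is None or mean > best:
            best = mean
    return best if best is not None and best > threshold else 0.0


def scan_g4_motif(seq: str) -> bool:
    """Left-to-right scanner for (G{3,}[ATGCN]{1,7}){3,}G{3,}.

    Recursive descent over the grammar: from each start, consume a G-run of
    >= 3, then either stop (if four tracts are done) or consume a 1-7 nt
    loop and recurse. Memoized on (position, capped tract count).
    """

    @lru_cache(maxsize=None)
    def from_pos(pos: int, tracts_done: int) -> bool:
        # count Gs available here
        g = 0
        while pos + g < len(seq) and seq[pos + g] == "G":
            g += 1
        if g < 3:
            return False
        for take in range(3, g + 1):
            done = min(tracts_done + 1, 4)
            if done >= 4:
                return True
            after = pos + take
            for loop in range(1, 8):
                nxt = after + loop
                if nxt >= len(seq):
                    break
                if from_pos(nxt, done):
                    return True
        return False

    result = any(from_pos(i, 0) for i in range(len(seq)))
    from_pos.cache_clear()
    return result


def brute_average_precision(scores, labels) -> float:
    """Step-rule AP by accumulating over the sorted confusion counts."""
    pairs = sorted(zip(scores, labels), key=lambda p: -p[0])
    n_pos = sum(labels)
    distinct = sorted({s for s, _ in pairs}, reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for thr in distinct:
        tp = sum(1 for s, y in pairs if s >= thr and y == 1)
        calls = sum(1 for s, _ in pairs if s >= thr)
        precision = tp / calls if calls else 0.0
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap
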