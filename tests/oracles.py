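"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (recursion / enumeration / flood fill) and
shares no code with the implementation it checks.
"""

from functools import lru_cache
from itertools import combinations


def brute_edit_distance(a: str, b: str) -> int:
    """Plain recursive Levenshtein definition (exponential; lengths <= ~8)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1, rec(i - 1, j - 1) + cost)

    return rec(len(a), len(b))


def brute_lcs_length(a: str, b: str) -> int:
    """Enumerate all subsequences of the shorter string, test membership in
    the longer one (lengths <= ~10)."""
    if len(a) > len(b):
        a, b = b, a

    def is_subsequence(s: str, t: str) -> bool:
        it = iter(t)
        return all(ch in it for ch in s)

    for k in range(len(a), 0, -1):
        for combo in combinations(a, k):
            if is_subsequence("".join(combo), b):
                return k
    return 0


def brute_alignment(a: str, b: str, match: int, mismatch: int, gap: int
                    ) -> tuple[int, int]:
    """Exhaustively enumerate all global alignments; returns (best score,
    max matches among best-score alignments). Lengths <= ~6."""

    best: list[tuple[int, int]] = [(-(10 ** 9), 0)]

    def rec(i: int, j: int, score: int, matches: int) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], (score, matches))
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            rec(i + 1, j + 1, score + (match if hit else mismatch), matches + hit)
        if i < len(a):
            rec(i + 1, j, score + gap, matches)
        if j < len(b):
            rec(i, j + 1, score + gap, matches)

    rec(0, 0, 0, 0)
    return best[0]


def flood_fill_components(mask) -> list[tuple[int, int, int, int]]:
    """8-connected components by BFS flood fill; returns sorted (x, y, w, h)
    boxes."""
    h = len(mask)
    w = len(mask[0]) if h else 0
    seen = [[False] * w for _ in range(h)]
    boxes = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy][sx] or seen[sy][sx]:
                continue
            stack = [(sy, sx)]
            seen[sy][sx] = True
            xs, ys = [], []
            while stack:
                y, x = stack.pop()
                xs.append(x)
                ys.append(y)
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny][nx] \
                                and not seen[ny][nx]:
                            seen[ny][nx] = True
                            stack.append((ny, nx))
            boxes.append((min(xs), min(ys), max(xs) - min(xs) + 1,
                          max(ys) - min(ys) + 1))
    return sorted(boxes)
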