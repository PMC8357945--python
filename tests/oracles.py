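"""Independent brute-force reference implementations for metric checks.

Deliberately naive single-pass Python: these re-derive every
architecture statistic straight from its definition, without sharing
any code with the package, so agreement is a meaningful check.
"""

from __future__ import annotations

EPOCH = 8.0
W, N, R = 0, 1, 2


def episodes(states) -> list[tuple[int, int, int]]:
    """(state, start_epoch, n_epochs) by walking the sequence."""
    out = []
    for i, s in enumerate(states):
        if out and out[-1][0] == s:
            st, start, n = out[-1]
            out[-1] = (st, start, n + 1)
        else:
            out.append((int(s), i, 1))
    return out


def totals(states) -> dict[int, float]:
    t = {W: 0.0, N: 0.0, R: 0.0}
    for s in states:
        t[int(s)] += EPOCH
    return t


def transition_counts(states) -> dict[tuple[int, int], int]:
    c = {(a, b): 0 for a in (W, N, R) for b in (W, N, R) if a != b}
    eps = episodes(states)
    for (a, _, _), (b, _, _) in zip(eps[:-1], eps[1:]):
        c[(a, b)] += 1
    return c


def interruptions(states, cap_s: float = 64.0) -> int:
    eps = episodes(states)
    count = 0
    for i in range(1, len(eps) - 1):
        s, _, n = eps[i]
        if (
            s == W
            and n * EPOCH <= cap_s
            and eps[i - 1][0] == N
            and eps[i + 1][0] == N
        ):
            count += 1
    return count


def latency(states, min_bout_s: float = 300.0) -> float | None:
    for s, start, n in episodes(states):
        if s == N and n * EPOCH > min_bout_s:
            return start * EPOCH
    return None


def bout_hist(states, state: int, edges: list[float]) -> list[int]:
    counts = [0] * (len(edges) + 1)
    for s, _, n in episodes(states):
        if s != state:
            continue
        d = n * EPOCH
        for i, e in enumerate(edges):
            if d <= e:
                counts[i] += 1
                break
        else:
            counts[-1] += 1
    return counts
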